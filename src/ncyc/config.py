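"""Run configuration: every tunable constant of the pipeline in one place.

The defaults are the literal parameters of the study the pipeline models:
reads kept when strictly longer than 100 nt; E-value cutoff 1e-6 for both the
nucleotide confirmation search and the translated protein searches; SSU
mapping with mismatch cost 2, insertion/deletion cost 3, length fraction 0.5
and similarity fraction 0.8; MEGAN-style LCA with min score 50, max expected
0.01, top percent 1, max support percent 0.0, min support 1, LCA percent 50
and min complexity 0; bit-score-ratio curation with a default cutoff of 0.8.

``RunConfig`` serializes losslessly to a flat ``key=value`` text file
(dotted keys for nested sections, ``curation.cutoff.<gene>`` for per-gene
cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Any


@dataclass(slots=True)
class ScoringScheme:
    """Protein search scoring: BLOSUM62, affine gaps, Karlin-Altschul stats.

    ``lam`` and ``k`` are the standard gapped BLOSUM62 / (11, 1) parameters;
    a gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(slots=True)
class MappingConfig:
    """SSU read-mapper parameters (CLC-style per-operation costs)."""

    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.5
    similarity_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("mapping costs must be positive")
        for v in (self.length_fraction, self.similarity_fraction):
            if not 0 < v <= 1:
                raise ValueError("fractions must be in (0, 1]")


@dataclass(slots=True)
class LcaConfig:
    """MEGAN-style LCA parameters."""

    min_score: float = 50.0
    max_expected: float = 0.01
    top_percent: float = 1.0
    max_support_percent: float = 0.0
    min_support: int = 1
    lca_percent: float = 50.0
    min_complexity: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        if not 0 < self.lca_percent <= 100:
            raise ValueError("lca_percent must be in (0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(slots=True)
class CurationConfig:
    """Per-gene bit-score-ratio cutoffs; families not listed use the default."""

    cutoffs: dict[str, float] = field(default_factory=dict)
    default_cutoff: float = 0.8

    def __post_init__(self) -> None:
        for fam, v in list(self.cutoffs.items()) + [("default", self.default_cutoff)]:
            if not 0 < v <= 1:
                raise ValueError(f"cutoff for {fam!r} must be in (0, 1]")

    def cutoff_for(self, gene_family: str) -> float:
        return self.cutoffs.get(gene_family, self.default_cutoff)


@dataclass(slots=True)
class ErrorModel:
    """Ion-Torrent-like read noise: substitutions plus homopolymer-biased indels.

    ``indel_rate`` is the per-base probability of an indel event next to a
    non-repeated base; inside a homopolymer run (length >= 2) it is multiplied
    by ``homopolymer_multiplier``, reproducing the platform's dominant error
    mode.
    """

    substitution_rate: float = 0.005
    indel_rate: float = 0.008
    homopolymer_multiplier: float = 3.0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if self.homopolymer_multiplier < 1:
            raise ValueError("homopolymer multiplier must be >= 1")


@dataclass(slots=True)
class RunConfig:
    """Top-level pipeline configuration."""

    min_read_len_exclusive: int = 100
    evalue_cutoff: float = 1e-6
    mapping: MappingConfig = field(default_factory=MappingConfig)
    lca: LcaConfig = field(default_factory=LcaConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_read_len_exclusive < 0:
            raise ValueError("min_read_len_exclusive must be >= 0")
        if not (math.isfinite(self.evalue_cutoff) and self.evalue_cutoff > 0):
            raise ValueError("evalue_cutoff must be finite and positive")

    # -- flat key=value serialization ------------------------------------

    _SECTIONS = {
        "mapping": MappingConfig,
        "lca": LcaConfig,
        "curation": CurationConfig,
        "scoring": ScoringScheme,
    }

    def to_flat(self) -> dict[str, str]:
        """Flatten to string key/value pairs (lossless round trip)."""
        out: dict[str, str] = {
            "min_read_len_exclusive": repr(self.min_read_len_exclusive),
            "evalue_cutoff": repr(self.evalue_cutoff),
            "seed": repr(self.seed),
        }
        for section, cls in self._SECTIONS.items():
            obj = getattr(self, section)
            for f in fields(cls):
                val = getattr(obj, f.name)
                if f.name == "cutoffs":
                    for fam, v in sorted(val.items()):
                        out[f"curation.cutoff.{fam}"] = repr(v)
                elif f.name == "matrix_name":
                    out[f"{section}.{f.name}"] = val
                else:
                    out[f"{section}.{f.name}"] = repr(val)
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "RunConfig":
        """Rebuild a RunConfig from :meth:`to_flat` output."""
        kwargs: dict[str, Any] = {}
        section_kwargs: dict[str, dict[str, Any]] = {s: {} for s in cls._SECTIONS}
        cutoffs: dict[str, float] = {}
        for key, raw in flat.items():
            if key.startswith("curation.cutoff."):
                cutoffs[key.split(".", 2)[2]] = float(raw)
            elif "." in key:
                section, name = key.split(".", 1)
                if section not in section_kwargs:
                    raise ValueError(f"unknown config section {section!r}")
                val: Any = raw if name == "matrix_name" else _parse_scalar(raw)
                section_kwargs[section][name] = val
            else:
                kwargs[key] = _parse_scalar(raw)
        section_kwargs["curation"]["cutoffs"] = cutoffs
        for section, scls in cls._SECTIONS.items():
            kwargs[section] = scls(**section_kwargs[section])
        return cls(**kwargs)


def _parse_scalar(raw: str) -> int | float:
    try:
        return int(raw)
    except ValueError:
        return float(raw)
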