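"""Synthetic sediment metagenomes with known ground truth.

Generates everything the pipeline consumes, without downloads:

* a curated functional-gene protein database (the 13 N-cycle marker
  families), each family with several member proteins carrying realistic
  lineages;
* a background protein database that is a strict superset of the curated
  one, extended with decoy homologs (family proteins mutated to a requested
  divergence and labeled ``background``) and unrelated random proteins —
  the stand-in for nr, making the BSR <= 1 invariant hold by construction;
* an SSU rRNA nucleotide reference spanning three domains with lineages;
* three depth-zone read sets (OAZ / SMTZ / MZ analogues) of
  Ion-Torrent-like reads: mean length 290 nt (sd 60, minimum 30),
  substitution plus homopolymer-biased indel errors, planted fragments of
  marker genes, SSU fragments, decoy fragments and random background reads,
  with a per-read ground-truth table.

Planted abundances are realized by deterministic largest-remainder quotas,
so category counts are exact; ``multinomial=True`` restores independent
sampling. Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ErrorModel
from .io_formats import write_reference_db
from .records import MARKER_FAMILIES, ReferenceRecord, SequenceRead
from .translated_search import reverse_complement, translate_frame

__all__ = [
    "CommunitySpec",
    "ReferenceSets",
    "make_reference_sets",
    "simulate_reads",
    "default_zone_specs",
    "MG_I_LINEAGE",
    "FAMILY_AA_LENGTHS",
]

#: Marine Group I Thaumarchaeota — the dominant aerobic ammonia oxidizers.
MG_I_LINEAGE = ("Archaea", "Thaumarchaeota", "Nitrosopumilales")

#: Protein lengths per marker family (amino acids). Within a factor ~2 of
#: the real genes, scaled where necessary to keep desk-scale searches fast.
FAMILY_AA_LENGTHS = {
    "narG": 420, "napA": 280, "nxrA": 380, "nirK": 180, "nirS": 240,
    "nor": 230, "nod": 240, "nosZ": 320, "nrfA": 250, "hao": 300,
    "hzsA": 350, "amoA": 160, "nifH": 150,
}

# four-rank lineages (domain, phylum, order, genus) echoing the taxa the
# study reports for each marker family
_FAMILY_LINEAGES: dict[str, list[tuple[str, ...]]] = {
    "narG": [
        ("Bacteria", "Proteobacteria", "Rhodocyclales", "Thauera"),
        ("Bacteria", "Proteobacteria", "Methylococcales", "Methylococcus"),
        ("Bacteria", "Omnitrophica", "Omnitrophales", "Omnitrophus"),
        ("Archaea", "Euryarchaeota", "Halobacteriales", "Haloarcula"),
    ],
    "napA": [
        ("Bacteria", "Proteobacteria", "Campylobacterales", "Sulfurimonas"),
        ("Bacteria", "Proteobacteria", "Alteromonadales", "Shewanella"),
        ("Bacteria", "Bacteroidetes", "Flavobacteriales", "Muricauda"),
    ],
    "nxrA": [
        ("Bacteria", "Nitrospirae", "Nitrospirales", "Nitrospira"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Kuenenia"),
        ("Bacteria", "Nitrospinae", "Nitrospinales", "Nitrospina"),
    ],
    "nirK": [
        ("Archaea", "Thaumarchaeota", "Nitrosopumilales", "Nitrosopumilus"),
        ("Bacteria", "Proteobacteria", "Rhizobiales", "Bradyrhizobium"),
        ("Bacteria", "Actinobacteria", "Actinomycetales", "Mycobacterium"),
    ],
    "nirS": [
        ("Bacteria", "Proteobacteria", "Rhodocyclales", "Azoarcus"),
        ("Bacteria", "Proteobacteria", "Pseudomonadales", "Pseudomonas"),
        ("Bacteria", "Proteobacteria", "Burkholderiales", "Ralstonia"),
    ],
    "nor": [
        ("Bacteria", "Proteobacteria", "Myxococcales", "Anaeromyxobacter"),
        ("Bacteria", "Bacteroidetes", "Flavobacteriales", "Flavobacterium"),
        ("Bacteria", "Proteobacteria", "Burkholderiales", "Cupriavidus"),
    ],
    "nod": [
        ("Bacteria", "NC10", "Methylomirabilales", "Methylomirabilis"),
        ("Bacteria", "Proteobacteria", "Oceanospirillales", "HdN1"),
        ("Bacteria", "Bacteroidetes", "Flavobacteriales", "Muricauda"),
    ],
    "nosZ": [
        ("Bacteria", "Bacteroidetes", "Flavobacteriales", "Flavobacterium"),
        ("Bacteria", "Bacteroidetes", "Cytophagales", "Cytophaga"),
        ("Bacteria", "Proteobacteria", "Myxococcales", "Myxococcus"),
    ],
    "nrfA": [
        ("Bacteria", "Proteobacteria", "Campylobacterales", "Sulfurospirillum"),
        ("Bacteria", "Proteobacteria", "Desulfovibrionales", "Desulfovibrio"),
        ("Bacteria", "Bacteroidetes", "Bacteroidales", "Bacteroides"),
    ],
    "hao": [
        ("Bacteria", "Planctomycetes", "Brocadiales", "Kuenenia"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Scalindua"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Brocadia"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Jettenia"),
        ("Bacteria", "Proteobacteria", "Nitrosomonadales", "Nitrosomonas"),
    ],
    "hzsA": [
        ("Bacteria", "Planctomycetes", "Brocadiales", "Kuenenia"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Scalindua"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Brocadia"),
        ("Bacteria", "Planctomycetes", "Brocadiales", "Jettenia"),
    ],
    "amoA": [
        ("Archaea", "Thaumarchaeota", "Nitrosopumilales", "Nitrosopumilus"),
        ("Archaea", "Thaumarchaeota", "Nitrosopumilales", "Nitrosoarchaeum"),
        ("Bacteria", "Proteobacteria", "Nitrosomonadales", "Nitrosomonas"),
    ],
    "nifH": [
        ("Bacteria", "Proteobacteria", "Rhizobiales", "Bradyrhizobium"),
        ("Archaea", "Euryarchaeota", "Methanosarcinales", "Methanosarcina"),
        ("Bacteria", "Firmicutes", "Clostridiales", "Clostridium"),
    ],
}

_DECOY_LINEAGES = [
    ("Bacteria", "Firmicutes", "Bacillales", "Bacillus"),
    ("Bacteria", "Actinobacteria", "Streptomycetales", "Streptomyces"),
    ("Bacteria", "Proteobacteria", "Enterobacterales", "Escherichia"),
    ("Eukaryota", "Ascomycota", "Saccharomycetales", "Saccharomyces"),
]

_SSU_TAXA: list[tuple[str, ...]] = [
    ("Bacteria", "Proteobacteria", "Methylococcales", "Methylococcus"),
    ("Bacteria", "Proteobacteria", "Desulfobacterales", "Desulfosarcina"),
    ("Bacteria", "Proteobacteria", "Campylobacterales", "Sulfurimonas"),
    ("Bacteria", "Planctomycetes", "Brocadiales", "Kuenenia"),
    ("Bacteria", "Planctomycetes", "Brocadiales", "Scalindua"),
    ("Bacteria", "Bacteroidetes", "Flavobacteriales", "Flavobacterium"),
    ("Bacteria", "Chloroflexi", "Anaerolineales", "Anaerolinea"),
    ("Archaea", "Thaumarchaeota", "Nitrosopumilales", "Nitrosopumilus"),
    ("Archaea", "Euryarchaeota", "Thermoplasmatales", "Thermoplasma"),
    ("Archaea", "Euryarchaeota", "Methanosarcinales", "ANME-2"),
    ("Eukaryota", "Bacillariophyta", "Thalassiosirales", "Thalassiosira"),
]

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_NT4 = "ACGT"

# sense codons of the bacterial/archaeal code, grouped by amino acid
_SENSE_CODONS: dict[str, list[str]] = {}
for _c in ("".join(t) for t in __import__("itertools").product(_NT4, repeat=3)):
    _aa = translate_frame(_c, 11)
    if _aa != "*":
        _SENSE_CODONS.setdefault(_aa, []).append(_c)


@dataclass(slots=True)
class CommunitySpec:
    """Composition of one synthetic depth-zone sample.

    Fractions are expected read proportions; with the default quota
    realization the emitted counts are exact. ``ssu_taxon_weights`` keys
    are SSU genus names (or full semicolon-joined lineages) and are
    normalized internally; all category fractions plus the background must
    sum to 1.
    """

    sample_id: str
    n_reads: int
    family_fractions: dict[str, float] = field(default_factory=dict)
    ssu_fraction: float = 0.0
    ssu_taxon_weights: dict[str, float] = field(default_factory=dict)
    decoy_fraction: float = 0.0
    background_fraction: float = 0.0
    read_len_mean: float = 290.0
    read_len_sd: float = 60.0
    read_len_min: int = 30
    error_model: ErrorModel = field(default_factory=ErrorModel)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        fractions = list(self.family_fractions.values()) + [
            self.ssu_fraction, self.decoy_fraction, self.background_fraction]
        for f in fractions:
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1, got {sum(fractions)!r}"
            )
        if self.ssu_fraction > 0 and not self.ssu_taxon_weights:
            raise ValueError("ssu_fraction > 0 requires ssu_taxon_weights")


@dataclass(slots=True)
class ReferenceSets:
    """The three reference databases plus the source nucleotide genes."""

    curated: list[ReferenceRecord]
    background: list[ReferenceRecord]
    ssu: list[ReferenceRecord]
    gene_nt: dict[str, str]           # protein ref_id -> source CDS (nt)
    decoy_ids: list[str]

    def curated_families(self) -> set[str]:
        return {r.gene_family for r in self.curated}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reference_db(self.curated, outdir / "curated.fasta",
                           outdir / "curated_lineages.tsv")
        write_reference_db(self.background, outdir / "background.fasta",
                           outdir / "background_lineages.tsv")
        write_reference_db(self.ssu, outdir / "ssu.fasta",
                           outdir / "ssu_lineages.tsv")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            choices = [c for c in _AA20 if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _SENSE_CODONS[aa][rng.integers(len(_SENSE_CODONS[aa]))]
        for aa in protein
    )


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NT4), size=length))


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for nt in seq:
        if rng.random() < rate:
            choices = [c for c in _NT4 if c != nt]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(nt)
    return "".join(out)


def make_reference_sets(seed: int,
                        n_families: int = 13,
                        n_taxa_per_family: int = 3,
                        divergence: float = 0.7,
                        within_family_divergence: float = 0.2,
                        n_background_extra: int = 10,
                        family_lengths: Mapping[str, int] | None = None,
                        ssu_length: int = 1200) -> ReferenceSets:
    """Generate curated, background and SSU reference sets.

    ``divergence`` is the per-residue substitution probability applied to a
    family protein to produce its decoy homolog (0 = identical decoys,
    making decoy-hit reads reach BSR 1). Families are the marker genes, in
    canonical order. Deterministic given the seed.
    """
    if not 0 <= divergence < 0.9:
        raise ValueError("divergence must lie in [0, 0.9)")
    if not 1 <= n_families <= len(MARKER_FAMILIES):
        raise ValueError(
            f"n_families must be in [1, {len(MARKER_FAMILIES)}]"
        )
    rng = np.random.default_rng(seed)
    families = MARKER_FAMILIES[:n_families]
    lengths = dict(FAMILY_AA_LENGTHS)
    if family_lengths:
        lengths.update(family_lengths)

    curated: list[ReferenceRecord] = []
    background: list[ReferenceRecord] = []
    gene_nt: dict[str, str] = {}
    decoy_ids: list[str] = []

    for fam in families:
        ancestor = _random_protein(rng, lengths[fam])
        pool = _FAMILY_LINEAGES[fam]
        members: list[str] = []
        for t in range(n_taxa_per_family):
            protein = _mutate_protein(rng, ancestor, within_family_divergence)
            lineage = pool[t % len(pool)]
            suffix = "" if t < len(pool) else f"_{t // len(pool) + 1}"
            ref_id = f"{fam}_{lineage[-1]}{suffix}"
            rec = ReferenceRecord(ref_id, protein, fam, lineage,
                                  3 * len(protein))
            curated.append(rec)
            gene_nt[ref_id] = _reverse_translate(rng, protein)
            members.append(protein)
        # decoy homolog: first member mutated to the requested divergence
        decoy = _mutate_protein(rng, members[0], divergence)
        decoy_id = f"decoy_{fam}"
        lineage = _DECOY_LINEAGES[len(decoy_ids) % len(_DECOY_LINEAGES)]
        background.append(ReferenceRecord(decoy_id, decoy, "background",
                                          lineage, 3 * len(decoy)))
        gene_nt[decoy_id] = _reverse_translate(rng, decoy)
        decoy_ids.append(decoy_id)

    background.extend(curated)  # strict superset of the curated database
    for i in range(n_background_extra):
        protein = _random_protein(rng, 250)
        lineage = _DECOY_LINEAGES[i % len(_DECOY_LINEAGES)]
        background.append(ReferenceRecord(f"bg_{i:03d}", protein,
                                          "background", lineage, 750))
    background.sort(key=lambda r: r.ref_id)

    root = _random_nt(rng, ssu_length)
    domain_seq = {
        dom: _mutate_nt(rng, root, 0.25)
        for dom in ("Bacteria", "Archaea", "Eukaryota")
    }
    ssu = []
    for lineage in _SSU_TAXA:
        seq = _mutate_nt(rng, domain_seq[lineage[0]], 0.12)
        ssu.append(ReferenceRecord(f"ssu_{lineage[-1]}", seq, "SSU",
                                   lineage, len(seq)))
    return ReferenceSets(curated, background, ssu, gene_nt, decoy_ids)


def _largest_remainder_counts(weights: Sequence[float], total: int
                              ) -> list[int]:
    """Integer quotas proportional to weights, summing exactly to total."""
    s = sum(weights)
    if s <= 0:
        raise ValueError("weights must have a positive sum")
    exact = [w / s * total for w in weights]
    floors = [math.floor(x) for x in exact]
    remainder = total - sum(floors)
    order = sorted(range(len(exact)),
                   key=lambda i: (-(exact[i] - floors[i]), i))
    out = list(floors)
    for i in order[:remainder]:
        out[i] += 1
    return out


def _resolve_ssu_weights(spec: CommunitySpec, refs: ReferenceSets
                         ) -> list[tuple[ReferenceRecord, float]]:
    resolved: list[tuple[ReferenceRecord, float]] = []
    for key, weight in sorted(spec.ssu_taxon_weights.items()):
        matches = [r for r in refs.ssu
                   if r.lineage[-1] == key or ";".join(r.lineage) == key]
        if not matches:
            raise ValueError(f"SSU taxon {key!r} not present in references")
        for r in matches:
            resolved.append((r, weight / len(matches)))
    return resolved


def _apply_errors(rng: np.random.Generator, seq: str,
                  em: ErrorModel) -> str:
    """Substitutions plus homopolymer-weighted indels."""
    if em.substitution_rate == 0 and em.indel_rate == 0:
        return seq
    out: list[str] = []
    n = len(seq)
    for i, base in enumerate(seq):
        in_run = (i > 0 and seq[i - 1] == base) or \
                 (i + 1 < n and seq[i + 1] == base)
        mult = em.homopolymer_multiplier if in_run else 1.0
        p_indel = min(0.5, em.indel_rate * mult)
        r = rng.random()
        if r < p_indel / 2:
            continue  # deletion
        if rng.random() < em.substitution_rate:
            choices = [c for c in _NT4 if c != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
        if r >= p_indel / 2 and r < p_indel:
            out.append(base)  # insertion extends the (putative) run
    return "".join(out) if out else seq[:1]


def simulate_reads(spec: CommunitySpec, refs: ReferenceSets, seed: int,
                   multinomial: bool = False
                   ) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Emit exactly ``spec.n_reads`` reads plus a ground-truth table.

    Buckets (marker families, SSU taxa, decoys, background) receive
    deterministic largest-remainder quotas of the read total (or a
    multinomial draw with ``multinomial=True``). Fragments are cut
    uniformly from their source sequence on a uniform random strand, with
    truncated-normal lengths and the Ion-Torrent-like error model applied.

    Truth columns: read_id, category (gene_family | SSU | decoy |
    background), source_ref, source_lineage, gene_family, decoy_of.
    """
    rng = np.random.default_rng(seed)
    curated_by_family: dict[str, list[ReferenceRecord]] = {}
    for rec in refs.curated:
        curated_by_family.setdefault(rec.gene_family, []).append(rec)

    buckets: list[tuple[str, ReferenceRecord | None, float]] = []
    for fam in MARKER_FAMILIES:
        frac = spec.family_fractions.get(fam, 0.0)
        if frac > 0:
            if fam not in curated_by_family:
                raise ValueError(
                    f"family {fam!r} requested but absent from references"
                )
            buckets.append(("family:" + fam, None, frac))
    if spec.ssu_fraction > 0:
        resolved = _resolve_ssu_weights(spec, refs)
        wsum = sum(w for _, w in resolved)
        for rec, weight in resolved:
            buckets.append(("ssu", rec, spec.ssu_fraction * weight / wsum))
    if spec.decoy_fraction > 0:
        for decoy_id in refs.decoy_ids:
            bg = next(r for r in refs.background if r.ref_id == decoy_id)
            buckets.append(("decoy", bg,
                            spec.decoy_fraction / len(refs.decoy_ids)))
    buckets.append(("background", None, spec.background_fraction))

    weights = [b[2] for b in buckets]
    if multinomial:
        counts = rng.multinomial(
            spec.n_reads, np.asarray(weights) / sum(weights)).tolist()
    else:
        counts = _largest_remainder_counts(weights, spec.n_reads)

    reads: list[SequenceRead] = []
    truth_rows: list[tuple] = []
    idx = 0
    for (kind, rec, _w), count in zip(buckets, counts):
        for _ in range(count):
            read_id = f"{spec.sample_id}_r{idx:06d}"
            idx += 1
            length = int(round(rng.normal(spec.read_len_mean,
                                          spec.read_len_sd)))
            length = max(spec.read_len_min, length)
            if kind == "background":
                seq = _random_nt(rng, length)
                seq = _apply_errors(rng, seq, spec.error_model)
                reads.append(SequenceRead(read_id, seq))
                truth_rows.append((read_id, "background", "random", "",
                                   "background", ""))
                continue
            if kind.startswith("family:"):
                fam = kind.split(":", 1)[1]
                members = curated_by_family[fam]
                source = members[rng.integers(len(members))]
                template = refs.gene_nt[source.ref_id]
                category = fam
                true_family = fam
                decoy_of = ""
            elif kind == "ssu":
                source = rec
                template = rec.seq
                category = "SSU"
                true_family = "SSU"
                decoy_of = ""
            else:  # decoy
                source = rec
                template = refs.gene_nt[rec.ref_id]
                category = "decoy"
                true_family = "background"
                decoy_of = rec.ref_id.removeprefix("decoy_")
            length = min(length, len(template))
            start = int(rng.integers(0, len(template) - length + 1))
            frag = template[start:start + length]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            frag = _apply_errors(rng, frag, spec.error_model)
            reads.append(SequenceRead(read_id, frag))
            truth_rows.append((read_id, category, source.ref_id,
                               ";".join(source.lineage), true_family,
                               decoy_of))
    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "category", "source_ref", "source_lineage",
        "gene_family", "decoy_of",
    ])
    return reads, truth


# nrc values the study reports per zone (reads normalized to metagenome
# size and gene length); used as relative planting weights so that the
# synthetic zones echo the observed depth trends
_ZONE_NRC = {
    "OAZ":  {"narG": 55, "napA": 30, "nxrA": 39, "nirK": 92, "nirS": 50,
             "nor": 38, "nod": 3, "nosZ": 53, "nrfA": 5, "hao": 5,
             "hzsA": 0.6, "amoA": 23, "nifH": 10},
    "SMTZ": {"narG": 34, "napA": 12, "nxrA": 41, "nirK": 68, "nirS": 35,
             "nor": 29, "nod": 2.2, "nosZ": 40, "nrfA": 8, "hao": 10,
             "hzsA": 2.4, "amoA": 9, "nifH": 8},
    "MZ":   {"narG": 3, "napA": 1, "nxrA": 4, "nirK": 15, "nirS": 5,
             "nor": 5, "nod": 0.5, "nosZ": 8, "nrfA": 1, "hao": 1,
             "hzsA": 0.0, "amoA": 6, "nifH": 2},
}

#: amoA : MG-I 16S nrc ratios observed per zone (~2, ~2, 0.3).
_ZONE_AMOA_MGI_RATIO = {"OAZ": 2.0, "SMTZ": 2.0, "MZ": 0.3}

# SSU composition (genus weights) echoing the 16S profiles per zone;
# the MG-I (Nitrosopumilus) weight is overridden from the amoA ratio
_ZONE_SSU_BASE = {
    "OAZ":  {"Methylococcus": 0.22, "Sulfurimonas": 0.15,
             "Desulfosarcina": 0.08, "Flavobacterium": 0.12,
             "Kuenenia": 0.02, "Scalindua": 0.05, "Anaerolinea": 0.05,
             "Thermoplasma": 0.03, "ANME-2": 0.01, "Thalassiosira": 0.02},
    "SMTZ": {"Methylococcus": 0.05, "Sulfurimonas": 0.05,
             "Desulfosarcina": 0.25, "Flavobacterium": 0.10,
             "Kuenenia": 0.15, "Scalindua": 0.03, "Anaerolinea": 0.08,
             "Thermoplasma": 0.04, "ANME-2": 0.08, "Thalassiosira": 0.01},
    "MZ":   {"Methylococcus": 0.03, "Sulfurimonas": 0.03,
             "Desulfosarcina": 0.08, "Flavobacterium": 0.10,
             "Kuenenia": 0.01, "Scalindua": 0.02, "Anaerolinea": 0.15,
             "Thermoplasma": 0.06, "ANME-2": 0.05, "Thalassiosira": 0.02},
}


def default_zone_specs(n_reads: int,
                       marker_total: float = 0.06,
                       ssu_fraction: float = 0.08,
                       decoy_fraction: float = 0.03,
                       error_model: ErrorModel | None = None,
                       ssu_length: int = 1200
                       ) -> dict[str, CommunitySpec]:
    """Three depth-zone community specs echoing the study's depth trends.

    Marker read fractions are proportional to the per-zone reported nrc
    values times gene length (nrc is per-copy, reads scale with length).
    ``marker_total`` is the marker read fraction of the most gene-rich zone
    (OAZ); the other zones are scaled down by their relative total marker
    load, preserving the observed decline of N-cycle genes with depth. The
    planted MG-I 16S share is derived from the observed amoA : MG-I ratios
    (2, 2, 0.3). Markers are planted far above their abundance in the real
    sediment so that desk-scale samples carry measurable counts.
    """
    em = error_model or ErrorModel()
    zone_weights = {
        zone: {fam: v * 3 * FAMILY_AA_LENGTHS[fam]
               for fam, v in nrc_vals.items() if v > 0}
        for zone, nrc_vals in _ZONE_NRC.items()
    }
    max_load = max(sum(w.values()) for w in zone_weights.values())
    specs = {}
    for zone, weights in zone_weights.items():
        fracs = {fam: marker_total * w / max_load
                 for fam, w in weights.items()}
        # planted amoA:MG-I nrc ratio R  =>  MG-I read fraction
        amo_frac = fracs.get("amoA", 0.0)
        ratio = _ZONE_AMOA_MGI_RATIO[zone]
        mgi_frac = amo_frac * ssu_length / \
            (3 * FAMILY_AA_LENGTHS["amoA"] * ratio)
        if mgi_frac >= ssu_fraction:
            raise ValueError("MG-I share exceeds the SSU fraction")
        base = _ZONE_SSU_BASE[zone]
        rest = ssu_fraction - mgi_frac
        base_total = sum(base.values())
        ssu_weights = {g: rest * w / base_total for g, w in base.items()}
        ssu_weights["Nitrosopumilus"] = mgi_frac
        background = 1.0 - sum(fracs.values()) - ssu_fraction - \
            decoy_fraction
        specs[zone] = CommunitySpec(
            sample_id=zone,
            n_reads=n_reads,
            family_fractions=fracs,
            ssu_fraction=ssu_fraction,
            ssu_taxon_weights=ssu_weights,
            decoy_fraction=decoy_fraction,
            background_fraction=background,
            error_model=em,
        )
    return specs
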