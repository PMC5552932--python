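"""Core domain records shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 13 diagnostic N-cycle marker gene families profiled by the pipeline:
#: dissimilatory nitrate reductases (narG, napA), nitrite:nitrate
#: oxidoreductase (nxrA), NO-forming nitrite reductases (nirK, nirS), nitric
#: oxide reductase (nor) and dismutase (nod), nitrous oxide reductase (nosZ),
#: ammonia-forming nitrite reductase (nrfA), hydroxylamine oxidoreductase
#: (hao), hydrazine synthase (hzsA), ammonia monooxygenase (amoA) and
#: nitrogenase (nifH).
MARKER_FAMILIES = (
    "narG", "napA", "nxrA", "nirK", "nirS", "nor", "nod",
    "nosZ", "nrfA", "hao", "hzsA", "amoA", "nifH",
)

#: All legal gene_family labels on reference records.
GENE_FAMILIES = MARKER_FAMILIES + ("SSU", "background")


@dataclass(slots=True)
class SequenceRead:
    """One metagenomic read: identifier, sequence, optional Phred qualities."""

    read_id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class ReferenceRecord:
    """A reference sequence with gene-family label and taxonomic lineage.

    ``seq`` holds amino acids for protein databases and nucleotides for the
    SSU rRNA database. ``length_nt`` is the nucleotide length of the full
    source gene (3x the protein length for protein records); it feeds the
    average-gene-length term of the nrc normalization.
    """

    ref_id: str
    seq: str
    gene_family: str
    lineage: tuple[str, ...]
    length_nt: int

    def __post_init__(self) -> None:
        if self.gene_family not in GENE_FAMILIES:
            raise ValueError(f"unknown gene family {self.gene_family!r}")
        if not self.lineage:
            raise ValueError(f"reference {self.ref_id!r} has an empty lineage")
        self.lineage = tuple(self.lineage)


@dataclass(slots=True)
class AlignmentHit:
    """One read-vs-reference local alignment.

    ``frame`` is +1..+3 / -1..-3 for translated hits and 0 for nucleotide
    hits. Coordinates are 1-based inclusive; for negative frames
    ``q_start > q_end`` (coordinates on the forward read), matching the
    standard tabular dialect.
    """

    query_id: str
    subject_id: str
    frame: int
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float
    aligned_cols: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


@dataclass(slots=True)
class BsrRecord:
    """Per-read curation record: curated vs background best bit scores.

    ``ratio`` is bit_curated / bit_background; reads without any background
    hit keep ratio 1.0 and are flagged, since absence of a better generalist
    hit is no evidence of a false positive.
    """

    read_id: str
    gene_family: str
    bit_curated: float
    bit_background: float | None
    ratio: float
    no_background_hit: bool = False


@dataclass(slots=True)
class SampleStats:
    """Per-sample read-QC summary."""

    sample_id: str
    n_reads_raw: int
    n_reads_kept: int
    mean_len_kept: float | None

    def __post_init__(self) -> None:
        if self.n_reads_kept > self.n_reads_raw:
            raise ValueError("n_reads_kept cannot exceed n_reads_raw")


@dataclass(slots=True)
class SsuAssignment:
    """A read recruited to the SSU rRNA reference with an assigned lineage."""

    read_id: str
    ref_id: str
    lineage: tuple[str, ...]
    identity_fraction: float
    aligned_read_fraction: float


@dataclass(slots=True)
class GeneProfile:
    """Per-sample, per-gene read count and normalized read count (nrc)."""

    sample_id: str
    gene_family: str
    read_count: int
    avg_gene_length_nt: float
    total_reads: int
    nrc: float
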