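"""Per-gene, per-sample quantification.

The cross-sample abundance unit is the normalized read count:

    nrc = read_count * 1e9 / (total_reads * avg_gene_length_nt)

with ``read_count`` the post-curation read count of the gene family,
``total_reads`` the post-QC metagenome size and ``avg_gene_length_nt`` the
mean nucleotide length of the family's curated references. Dividing by the
gene length corrects for longer genes recruiting more reads at equal copy
number; dividing by the metagenome size makes samples of different depth
comparable.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .records import (AlignmentHit, BsrRecord, GeneProfile, ReferenceRecord,
                      SampleStats)

__all__ = ["nrc", "average_gene_lengths", "profile_table", "marker_ratio",
           "identity_breakdown"]


def nrc(read_count: int, total_reads: int, avg_gene_length_nt: float) -> float:
    """Normalized read count (reads per billion per nt of gene length)."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not avg_gene_length_nt > 0:
        raise ValueError("avg_gene_length_nt must be positive")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count * 1e9 / (total_reads * avg_gene_length_nt)


def average_gene_lengths(curated_db: Sequence[ReferenceRecord]
                         ) -> dict[str, float]:
    """Mean nucleotide gene length per family over the curated references."""
    sums: dict[str, list[float]] = {}
    for rec in curated_db:
        sums.setdefault(rec.gene_family, []).append(rec.length_nt)
    return {fam: sum(v) / len(v) for fam, v in sums.items()}


def profile_table(kept_records: Sequence[BsrRecord],
                  stats: SampleStats,
                  curated_db: Sequence[ReferenceRecord],
                  ssu_read_count: int | None = None,
                  ssu_avg_length_nt: float | None = None) -> pd.DataFrame:
    """Per-gene profile for one sample, with a proportional-distribution column.

    One row per curated gene family (zero counts included), plus a 16S row
    when the SSU read count is supplied. ``proportion`` is each row's nrc
    divided by the summed nrc of all rows (analyzed genes plus 16S), i.e.
    the proportional-distribution panel.
    """
    if not curated_db:
        raise ValueError("profile_table requires curated references")
    lengths = average_gene_lengths(curated_db)
    counts: dict[str, int] = {fam: 0 for fam in lengths}
    for rec in kept_records:
        if rec.gene_family not in counts:
            raise ValueError(
                f"gene family {rec.gene_family!r} has no curated references"
            )
        counts[rec.gene_family] += 1
    total = stats.n_reads_kept
    rows = []
    for fam in sorted(lengths):
        value = nrc(counts[fam], total, lengths[fam]) if total else 0.0
        rows.append((stats.sample_id, fam, counts[fam], lengths[fam],
                     total, value))
    if ssu_read_count is not None:
        if not ssu_avg_length_nt:
            raise ValueError("ssu_avg_length_nt required with ssu_read_count")
        value = nrc(ssu_read_count, total, ssu_avg_length_nt) if total else 0.0
        rows.append((stats.sample_id, "16S", ssu_read_count,
                     ssu_avg_length_nt, total, value))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "gene_family", "read_count", "avg_gene_length_nt",
        "total_reads", "nrc",
    ])
    denom = df["nrc"].sum()
    df["proportion"] = df["nrc"] / denom if denom > 0 else 0.0
    return df


def gene_profiles(df: pd.DataFrame) -> list[GeneProfile]:
    """Materialize :class:`GeneProfile` records from a profile table."""
    return [
        GeneProfile(r.sample_id, r.gene_family, int(r.read_count),
                    float(r.avg_gene_length_nt), int(r.total_reads),
                    float(r.nrc))
        for r in df.itertuples()
    ]


def marker_ratio(gene_nrc: float, taxon_ssu_nrc: float) -> float | None:
    """Ratio of a marker gene's nrc to a taxon-restricted 16S nrc.

    Returns None (a flagged missing value) when the denominator is zero,
    rather than raising: a taxon absent from the SSU profile is an
    observation, not an error.
    """
    if taxon_ssu_nrc == 0:
        return None
    return gene_nrc / taxon_ssu_nrc


def identity_breakdown(top_hits: Mapping[str, AlignmentHit],
                       subject_lineages: Mapping[str, Sequence[str]],
                       gene_families: Mapping[str, str],
                       rank_index: int = 3) -> pd.DataFrame:
    """Per-gene, per-closest-taxon read shares and identity ranges.

    ``top_hits`` maps read_id to its best curated hit. Reads are grouped by
    the top hit's taxon at ``rank_index`` (default genus, the last level of
    the four-rank lineages). Shares are integer percentages (largest
    remainder, summing to 100 within each gene family); identity ranges are
    whole percents.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for read_id, hit in top_hits.items():
        lineage = tuple(subject_lineages[hit.subject_id])
        taxon = lineage[rank_index] if len(lineage) > rank_index \
            else lineage[-1]
        fam = gene_families[hit.subject_id]
        groups.setdefault((fam, taxon), []).append(hit.identity_fraction)
    rows = []
    for fam in sorted({f for f, _ in groups}):
        fam_groups = {t: v for (f, t), v in groups.items() if f == fam}
        n_total = sum(len(v) for v in fam_groups.values())
        shares = _largest_remainder(
            [100.0 * len(fam_groups[t]) / n_total for t in sorted(fam_groups)]
        )
        for taxon, share in zip(sorted(fam_groups), shares):
            idents = fam_groups[taxon]
            rows.append((
                fam, taxon, len(idents), share,
                int(round(100.0 * min(idents))),
                int(round(100.0 * max(idents))),
            ))
    return pd.DataFrame(rows, columns=[
        "gene_family", "taxon", "n_reads", "share_pct",
        "identity_min_pct", "identity_max_pct",
    ])


def _largest_remainder(values: Sequence[float], total: int = 100) -> list[int]:
    """Round percentages to integers that sum exactly to ``total``."""
    floors = [math.floor(v) for v in values]
    remainder = total - sum(floors)
    order = sorted(range(len(values)),
                   key=lambda i: (-(values[i] - floors[i]), i))
    out = list(floors)
    for i in order[:remainder]:
        out[i] += 1
    return out
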