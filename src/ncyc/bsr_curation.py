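"""Bit-score-ratio (BSR) curation of translated-search hits.

A read recruited by the curated functional-gene database may be a false
positive: its true closest relative could be an out-of-family homolog that
merely resembles the target family. The curation step re-searches the
extracted reads against a comprehensive background database (standing in
for NCBI nr) and computes, per read,

    BSR = best curated-DB bit score / best background-DB bit score.

A read whose closest relative really is in the target family scores as well
against the curated set as against the background (BSR near 1); a read
whose closest relative lies outside the family scores markedly better
against the background (BSR well below 1). Reads are kept when
BSR >= cutoff(gene_family); cutoffs are per-family with a default of 0.8,
keeping divergent in-family reads while rejecting out-of-family ones.

When the background database is a superset of the curated database and both
searches use one scoring scheme, BSR <= 1 holds by construction. Reads with
no background hit at all keep ratio 1.0 (flagged): absence of a better
generalist hit is no evidence of a false positive.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .config import CurationConfig
from .records import AlignmentHit, BsrRecord

__all__ = ["compute_bsr", "apply_cutoffs", "export_ratio_plot_data"]

log = logging.getLogger(__name__)


def compute_bsr(curated_hits: Mapping[str, Sequence[AlignmentHit]],
                background_hits: Mapping[str, Sequence[AlignmentHit]],
                gene_families: Mapping[str, str]) -> list[BsrRecord]:
    """One BSR record per read with a curated hit.

    ``gene_families`` maps curated subject ids to their family label; the
    family of the record comes from the top curated hit (ties broken by
    subject id, which is the hit tables' ordering). Reads with a background
    hit but no curated hit are excluded with a logged count.
    """
    orphans = sum(1 for rid in background_hits if rid not in curated_hits)
    if orphans:
        log.info("compute_bsr: %d reads had background hits only "
                 "(excluded)", orphans)
    records: list[BsrRecord] = []
    for read_id in sorted(curated_hits):
        chits = curated_hits[read_id]
        if not chits:
            continue
        top = chits[0]
        bit_curated = max(h.bit_score for h in chits)
        bhits = background_hits.get(read_id, ())
        if bhits:
            bit_background = max(h.bit_score for h in bhits)
            ratio = bit_curated / bit_background
            flag = False
        else:
            bit_background = None
            ratio = 1.0
            flag = True
        records.append(BsrRecord(
            read_id=read_id,
            gene_family=gene_families[top.subject_id],
            bit_curated=bit_curated,
            bit_background=bit_background,
            ratio=ratio,
            no_background_hit=flag,
        ))
    return records


def apply_cutoffs(records: Sequence[BsrRecord],
                  cfg: CurationConfig | None = None
                  ) -> tuple[list[BsrRecord], list[BsrRecord]]:
    """Partition records into (kept, rejected) by per-family ratio cutoffs.

    Families without an explicit cutoff use ``cfg.default_cutoff`` (logged
    once per family).
    """
    cfg = cfg or CurationConfig()
    defaulted: set[str] = set()
    kept: list[BsrRecord] = []
    rejected: list[BsrRecord] = []
    for rec in records:
        if rec.gene_family not in cfg.cutoffs and \
                rec.gene_family not in defaulted:
            defaulted.add(rec.gene_family)
            log.info("apply_cutoffs: no cutoff configured for %s; using "
                     "default %.3g", rec.gene_family, cfg.default_cutoff)
        if rec.ratio >= cfg.cutoff_for(rec.gene_family):
            kept.append(rec)
        else:
            rejected.append(rec)
    return kept, rejected


def export_ratio_plot_data(records: Sequence[BsrRecord],
                           path: str | None = None,
                           cfg: CurationConfig | None = None
                           ) -> pd.DataFrame:
    """Per-read scatter data for the bit-score-ratio plot.

    Columns: read_id, gene_family, bit_background, bit_curated, ratio,
    kept. True positives lie on the diagonal (ratio 1); false positives
    fall below the per-family cutoff line.
    """
    cfg = cfg or CurationConfig()
    rows = [
        (r.read_id, r.gene_family,
         r.bit_background if r.bit_background is not None else float("nan"),
         r.bit_curated, r.ratio,
         r.ratio >= cfg.cutoff_for(r.gene_family))
        for r in records
    ]
    df = pd.DataFrame(rows, columns=[
        "read_id", "gene_family", "bit_background", "bit_curated",
        "ratio", "kept",
    ])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
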