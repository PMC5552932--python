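"""End-to-end orchestration of the marker-gene profiling pipeline.

Stage order for one sample:

1. length QC (keep reads strictly longer than the threshold);
2. SSU recruitment: mapping, nucleotide confirmation, lineage assignment;
3. translated search of all kept reads against the curated protein DB
   (reads with significant hits form the extracted set);
4. translated search of the extracted reads against the background DB;
5. bit-score-ratio curation with per-family cutoffs;
6. LCA taxonomic assignment of curated reads from their background hits;
7. per-gene nrc quantification and the proportional-distribution table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import bsr_curation, lca_classifier, quantify, read_qc, ssu_profiler
from .config import RunConfig
from .records import (AlignmentHit, BsrRecord, ReferenceRecord, SampleStats,
                      SequenceRead, SsuAssignment)
from .ssu_profiler import SsuDatabase, SsuMapping
from .synthetic_community import MG_I_LINEAGE, ReferenceSets
from .translated_search import ProteinDatabase, search_reads

__all__ = ["SampleResult", "run_sample"]


@dataclass
class SampleResult:
    """All per-sample pipeline outputs."""

    sample_id: str
    stats: SampleStats
    reads_kept: list[SequenceRead]
    ssu_mappings: dict[str, SsuMapping]
    ssu_confirmed: dict[str, list[AlignmentHit]]
    ssu_assignments: list[SsuAssignment]
    curated_hits: dict[str, list[AlignmentHit]]
    background_hits: dict[str, list[AlignmentHit]]
    bsr_records: list[BsrRecord]
    kept_records: list[BsrRecord]
    rejected_records: list[BsrRecord]
    lca_assignments: dict[str, tuple[str, ...] | None]
    profile: pd.DataFrame
    ssu_avg_length_nt: float

    def gene_nrc(self, gene_family: str) -> float:
        row = self.profile[self.profile.gene_family == gene_family]
        return float(row.nrc.iloc[0]) if len(row) else 0.0

    def ssu_nrc(self, scope: Sequence[str] | None = None) -> float:
        """nrc of SSU reads, optionally restricted to a lineage prefix."""
        scope_t = tuple(scope) if scope else ()
        count = sum(1 for a in self.ssu_assignments
                    if a.lineage[:len(scope_t)] == scope_t)
        if self.stats.n_reads_kept == 0:
            return 0.0
        return quantify.nrc(count, self.stats.n_reads_kept,
                            self.ssu_avg_length_nt)

    def amoa_mgi_ratio(self) -> float | None:
        """amoA nrc over MG-I Thaumarchaeota 16S nrc (None when MG-I absent)."""
        return quantify.marker_ratio(self.gene_nrc("amoA"),
                                     self.ssu_nrc(MG_I_LINEAGE))


def run_sample(reads_raw: Sequence[SequenceRead],
               refs: ReferenceSets,
               config: RunConfig | None = None,
               sample_id: str = "sample",
               prefilter: bool = False,
               run_ssu: bool = True) -> SampleResult:
    """Run the full pipeline on one sample's raw reads.

    ``prefilter`` enables the exact-k-mer subject prefilter of the
    translated searches (a speed device for large simulations; results on
    planted reads are unchanged because true sources always share k-mers
    with their reads). ``run_ssu=False`` skips stage 2 for runs that only
    need the functional-gene profile.
    """
    config = config or RunConfig()

    kept = read_qc.filter_by_length(reads_raw, config.min_read_len_exclusive)
    stats = read_qc.summarize(kept, sample_id, n_reads_raw=len(reads_raw))

    ssu_mappings: dict[str, SsuMapping] = {}
    ssu_confirmed: dict[str, list[AlignmentHit]] = {}
    ssu_assignments: list[SsuAssignment] = []
    ssu_avg_len = sum(len(r.seq) for r in refs.ssu) / len(refs.ssu)
    if run_ssu:
        ssu_db = SsuDatabase(refs.ssu)
        mappings = ssu_profiler.map_reads(kept, ssu_db, config.mapping)
        ssu_mappings = {m.read_id: m for m in mappings}
        mapped_reads = [r for r in kept if r.read_id in ssu_mappings]
        ssu_confirmed = ssu_profiler.confirm_by_search(
            mapped_reads, ssu_db, config.evalue_cutoff)
        ssu_assignments = ssu_profiler.assign_lineages(
            ssu_confirmed, ssu_db, ssu_mappings)

    curated_db = ProteinDatabase(refs.curated)
    background_db = ProteinDatabase(refs.background)
    curated_hits = search_reads(kept, curated_db, config.scoring,
                                config.evalue_cutoff, prefilter=prefilter)
    extracted = [r for r in kept if r.read_id in curated_hits]
    background_hits = search_reads(extracted, background_db, config.scoring,
                                   config.evalue_cutoff, prefilter=prefilter)

    families = {r.ref_id: r.gene_family for r in refs.curated}
    bsr_records = bsr_curation.compute_bsr(curated_hits, background_hits,
                                           families)
    kept_records, rejected_records = bsr_curation.apply_cutoffs(
        bsr_records, config.curation)

    bg_lineages = {r.ref_id: r.lineage for r in refs.background}
    kept_ids = {rec.read_id for rec in kept_records}
    hits_for_lca = {rid: background_hits[rid]
                    for rid in kept_ids if rid in background_hits}
    lca = lca_classifier.classify_reads(hits_for_lca, bg_lineages, config.lca)
    for rid in kept_ids - set(lca):
        lca[rid] = None

    profile = quantify.profile_table(
        kept_records, stats, refs.curated,
        ssu_read_count=len(ssu_assignments) if run_ssu else None,
        ssu_avg_length_nt=ssu_avg_len if run_ssu else None,
    )
    return SampleResult(
        sample_id=sample_id,
        stats=stats,
        reads_kept=kept,
        ssu_mappings=ssu_mappings,
        ssu_confirmed=ssu_confirmed,
        ssu_assignments=ssu_assignments,
        curated_hits=curated_hits,
        background_hits=background_hits,
        bsr_records=bsr_records,
        kept_records=kept_records,
        rejected_records=rejected_records,
        lca_assignments=lca,
        profile=profile,
        ssu_avg_length_nt=ssu_avg_len,
    )
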