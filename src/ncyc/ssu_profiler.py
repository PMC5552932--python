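"""SSU rRNA fragment recruitment and community composition summaries.

Stage 1 recruits reads to an SSU rRNA reference set with a CLC-style read
mapper: local alignment scored match +1, mismatch -mismatch_cost, gap in the
read -insertion_cost per base, gap in the reference -deletion_cost per base
(linear, per-operation costs). A mapping is accepted when the aligned read
fraction reaches ``length_fraction`` and the identity over aligned columns
reaches ``similarity_fraction``.

Stage 2 confirms mapped reads by a nucleotide similarity search against the
same reference set (match +2, mismatch -3, gap open 5, gap extend 2;
Karlin-Altschul lambda = 0.625, K = 0.41) keeping best hits with
E <= 1e-6. The confirmed best hit wins over the mapping hit, and its
lineage is assigned to the read (optionally an LCA over near-best hits
within 1% of the top bit score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _alignment as _al
from .config import MappingConfig
from .records import AlignmentHit, ReferenceRecord, SequenceRead, SsuAssignment
from .translated_search import reverse_complement

__all__ = [
    "SsuDatabase",
    "SsuMapping",
    "map_read",
    "map_reads",
    "confirm_by_search",
    "assign_lineages",
    "summarize_composition",
    "RANKS",
]

#: Named lineage ranks (index into the root-to-leaf lineage path).
RANKS = {"domain": 0, "phylum": 1, "order": 2, "genus": 3}

#: Nucleotide Karlin-Altschul parameters for the confirmation search.
NT_MATCH, NT_MISMATCH = 2, -3
NT_GAP_OPEN, NT_GAP_EXTEND = 5, 2
NT_LAMBDA, NT_K = 0.625, 0.41


class SsuDatabase:
    """An SSU nucleotide reference set with a k-mer candidate index.

    The exact-k-mer index (default k=12) is a speed device: subjects sharing
    no k-mer with either read strand are skipped. ``exhaustive=True`` on the
    mapping/search calls disables it.
    """

    def __init__(self, records: Sequence[ReferenceRecord], k: int = 12):
        if not records:
            raise ValueError("empty SSU database")
        self.records = sorted(records, key=lambda r: r.ref_id)
        self.by_id = {r.ref_id: r for r in self.records}
        self.encoded = [_al.encode_nucleotide(r.seq) for r in self.records]
        self.total_nt = sum(len(r.seq) for r in self.records)
        self.k = k
        self._kmers = [
            frozenset(r.seq[i:i + k] for i in range(len(r.seq) - k + 1))
            for r in self.records
        ]

    def candidates(self, seq: str) -> list[int]:
        k = self.k
        rc = reverse_complement(seq)
        kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        kmers.update(rc[i:i + k] for i in range(len(rc) - k + 1))
        return [i for i, km in enumerate(self._kmers)
                if not kmers.isdisjoint(km)]


@dataclass(slots=True)
class SsuMapping:
    """An accepted read-to-reference mapping."""

    read_id: str
    ref_id: str
    strand: int  # +1 forward, -1 reverse complement
    score: int
    identity_fraction: float
    aligned_read_fraction: float


def map_read(read: SequenceRead, db: SsuDatabase,
             cfg: MappingConfig | None = None,
             exhaustive: bool = False) -> SsuMapping | None:
    """Map one read; return the best acceptable mapping or None.

    Candidates are ranked by raw score (ties: ref_id lexicographic, forward
    strand first) and the best candidate satisfying both the length and
    similarity fractions is returned.
    """
    cfg = cfg or MappingConfig()
    if not read.seq:
        return None
    idx = range(len(db.records)) if exhaustive else db.candidates(read.seq)
    fwd = _al.encode_nucleotide(read.seq)
    rev = _al.encode_nucleotide(reverse_complement(read.seq))
    scored: list[tuple[int, str, int, int]] = []
    for i in idx:
        for strand, enc in ((1, fwd), (-1, rev)):
            s = int(_al.map_score(enc, db.encoded[i], 1, cfg.mismatch_cost,
                                  cfg.insertion_cost, cfg.deletion_cost))
            if s > 0:
                scored.append((s, db.records[i].ref_id, strand, i))
    scored.sort(key=lambda t: (-t[0], t[1], -t[2]))
    read_len = len(read.seq)
    for s, ref_id, strand, i in scored:
        enc = fwd if strand == 1 else rev
        res = _al.map_traceback(enc, db.encoded[i], 1, cfg.mismatch_cost,
                                cfg.insertion_cost, cfg.deletion_cost)
        score, r1, r2, _s1, _s2, cols, ident, _mism, _gaps = \
            [int(x) for x in res]
        if cols == 0:
            continue
        read_frac = (r2 - r1 + 1) / read_len
        identity = ident / cols
        if read_frac >= cfg.length_fraction and \
                identity >= cfg.similarity_fraction:
            return SsuMapping(read.read_id, ref_id, strand, score,
                              identity, read_frac)
    return None


def map_reads(reads: Sequence[SequenceRead], db: SsuDatabase,
              cfg: MappingConfig | None = None,
              exhaustive: bool = False) -> list[SsuMapping]:
    out = []
    for read in reads:
        m = map_read(read, db, cfg, exhaustive=exhaustive)
        if m is not None:
            out.append(m)
    return out


def _nt_karlin_altschul(raw: int, m: int, n: int) -> tuple[float, float]:
    bit = (NT_LAMBDA * raw - math.log(NT_K)) / math.log(2.0)
    return bit, m * n * 2.0 ** (-bit)


def confirm_by_search(reads: Sequence[SequenceRead], db: SsuDatabase,
                      evalue_cutoff: float = 1e-6,
                      exhaustive: bool = False
                      ) -> dict[str, list[AlignmentHit]]:
    """Nucleotide similarity search of mapped reads against the SSU set.

    Returns per read all hits with E <= cutoff, sorted by descending bit
    score (ties: subject id). Reads failing the cutoff are absent.
    """
    mat = _al.nucleotide_matrix(NT_MATCH, NT_MISMATCH)
    results: dict[str, list[AlignmentHit]] = {}
    for read in reads:
        idx = range(len(db.records)) if exhaustive \
            else db.candidates(read.seq)
        fwd = _al.encode_nucleotide(read.seq)
        rev = _al.encode_nucleotide(reverse_complement(read.seq))
        L = len(read.seq)
        hits: list[AlignmentHit] = []
        for i in idx:
            best = None
            for strand, enc in ((1, fwd), (-1, rev)):
                res = _al.sw_traceback(enc, db.encoded[i], mat,
                                       NT_GAP_OPEN, NT_GAP_EXTEND)
                raw = int(res[0])
                if best is None or raw > best[0]:
                    best = (raw, strand, res)
            raw, strand, res = best
            if raw <= 0:
                continue
            bit, evalue = _nt_karlin_altschul(raw, L, db.total_nt)
            if evalue > evalue_cutoff:
                continue
            _raw, a1, a2, b1, b2, cols, ident, mism, gopen, _gc = \
                [int(x) for x in res]
            if strand == 1:
                q1, q2 = a1, a2
            else:
                q1, q2 = L - a1 + 1, L - a2 + 1
            hits.append(AlignmentHit(
                query_id=read.read_id, subject_id=db.records[i].ref_id,
                frame=0, raw_score=raw, bit_score=bit, evalue=evalue,
                identity_fraction=ident / cols if cols else 0.0,
                aligned_cols=cols, mismatches=mism, gap_opens=gopen,
                q_start=q1, q_end=q2, s_start=b1, s_end=b2,
            ))
        if hits:
            hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
            results[read.read_id] = hits
    return results


def assign_lineages(confirmed: dict[str, list[AlignmentHit]],
                    db: SsuDatabase,
                    mappings: dict[str, SsuMapping] | None = None,
                    near_best_lca: bool = False,
                    near_best_fraction: float = 0.01
                    ) -> list[SsuAssignment]:
    """Assign each confirmed read the lineage of its best hit.

    The confirmed hit takes precedence over the stage-1 mapping hit; the
    mapping (if supplied) only contributes the accepted identity and aligned
    read fraction diagnostics. With ``near_best_lca`` the assignment is the
    strict LCA of the lineages of all hits within ``near_best_fraction`` of
    the top bit score, truncating the path at the deepest rank on which
    those references agree.
    """
    out: list[SsuAssignment] = []
    for read_id in sorted(confirmed):
        hits = confirmed[read_id]
        top = hits[0]
        lineage = db.by_id[top.subject_id].lineage
        if near_best_lca and len(hits) > 1:
            floor = top.bit_score * (1.0 - near_best_fraction)
            paths = [db.by_id[h.subject_id].lineage
                     for h in hits if h.bit_score >= floor]
            lineage = _strict_lca(paths)
        mapping = mappings.get(read_id) if mappings else None
        out.append(SsuAssignment(
            read_id=read_id, ref_id=top.subject_id, lineage=lineage,
            identity_fraction=mapping.identity_fraction if mapping
            else top.identity_fraction,
            aligned_read_fraction=mapping.aligned_read_fraction if mapping
            else 1.0,
        ))
    return out


def _strict_lca(paths: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    common: list[str] = []
    for level in zip(*paths):
        if all(t == level[0] for t in level):
            common.append(level[0])
        else:
            break
    return tuple(common)


def summarize_composition(assignments: Sequence[SsuAssignment],
                          rank: str,
                          reporting_floor: float = 0.0,
                          scope: Sequence[str] | None = None
                          ) -> pd.DataFrame:
    """Per-taxon read proportions at a rank, normalized within a scope.

    ``scope`` is a lineage prefix (e.g. ``("Bacteria", "Proteobacteria")``);
    only reads whose assigned lineage starts with it are counted and
    proportions are normalized within that subset. Groups below
    ``reporting_floor`` are folded into "other"; reads whose lineage is
    shorter than the rank are reported as "unclassified".
    """
    if rank not in RANKS:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {sorted(RANKS)}"
        )
    if not assignments:
        raise ValueError("no assignments to summarize")
    level = RANKS[rank]
    scope_t = tuple(scope) if scope else ()
    counts: dict[str, int] = {}
    total = 0
    for a in assignments:
        if scope_t and a.lineage[:len(scope_t)] != scope_t:
            continue
        taxon = a.lineage[level] if len(a.lineage) > level else "unclassified"
        counts[taxon] = counts.get(taxon, 0) + 1
        total += 1
    if total == 0:
        return pd.DataFrame(columns=["taxon", "n_reads", "proportion"])
    rows = []
    other = 0
    for taxon in sorted(counts):
        prop = counts[taxon] / total
        if prop < reporting_floor and taxon != "unclassified":
            other += counts[taxon]
        else:
            rows.append((taxon, counts[taxon], prop))
    if other:
        rows.append(("other", other, other / total))
    return pd.DataFrame(rows, columns=["taxon", "n_reads", "proportion"])
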