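"""Six-frame translated protein search with Karlin-Altschul statistics.

This is the pipeline's blastx-equivalent: every read is translated in all
six frames (bacterial/archaeal genetic code 11 by default), each frame is
aligned to every database protein by full Smith-Waterman under BLOSUM62 with
affine gaps (open 11, extend 1), and raw scores are converted to bit scores
and E-values with the gapped Karlin-Altschul parameters lambda = 0.267,
K = 0.041:

    S' = (lambda * S - ln K) / ln 2        E = m * n * 2**(-S')

where m is the translated query frame length and n the total residue count
of the searched database.

No seeding heuristic is applied by default; an optional exact-k-mer
prefilter (``prefilter=True``) skips subjects sharing no k-mer with any
reading frame, which is a pure speed device for large simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import _alignment as _al
from .config import ScoringScheme
from .records import AlignmentHit, ReferenceRecord, SequenceRead

__all__ = [
    "six_frame_translate",
    "reverse_complement",
    "smith_waterman",
    "karlin_altschul",
    "search_reads",
    "LocalAlignment",
    "ProteinDatabase",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_map(genetic_code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


_CODON_CACHE: dict[int, dict[str, str]] = {}


def translate_frame(seq: str, genetic_code: int = 11) -> str:
    """Translate one forward frame; codons containing N give X."""
    if genetic_code not in _CODON_CACHE:
        _CODON_CACHE[genetic_code] = _codon_map(genetic_code)
    codons = _CODON_CACHE[genetic_code]
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(codons.get(seq[i:i + 3], "X"))
    return "".join(out)


def six_frame_translate(read: SequenceRead | str,
                        genetic_code: int = 11) -> list[str]:
    """All six reading frames, ordered +1, +2, +3, -1, -2, -3.

    Frames -1..-3 are frames +1..+3 of the reverse complement. Trailing
    partial codons are dropped; stop codons appear as ``*``.
    """
    seq = read.seq if isinstance(read, SequenceRead) else read
    rc = reverse_complement(seq)
    return [translate_frame(seq[f:], genetic_code) for f in range(3)] + \
           [translate_frame(rc[f:], genetic_code) for f in range(3)]


@dataclass(slots=True)
class LocalAlignment:
    """Optimal local alignment summary (1-based inclusive coordinates)."""

    raw_score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_cols: int
    identities: int
    mismatches: int
    gap_opens: int
    gap_cols: int

    @property
    def identity_fraction(self) -> float:
        if self.aligned_cols == 0:
            return 0.0
        return self.identities / self.aligned_cols


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _matrix(name: str) -> np.ndarray:
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = _al.load_protein_matrix(name)
    return _MATRIX_CACHE[name]


def smith_waterman(peptide: str, protein: str,
                   scoring: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal local alignment of two peptides under the scoring scheme.

    Residues outside the matrix alphabet are treated as X; traceback ties
    resolve diagonal > up > left. An all-mismatch pair yields score 0 and an
    empty alignment.
    """
    if not peptide or not protein:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    mat = _matrix(scoring.matrix_name)
    res = _al.sw_traceback(
        _al.encode_protein(peptide), _al.encode_protein(protein),
        mat, scoring.gap_open, scoring.gap_extend,
    )
    return LocalAlignment(*[int(x) for x in res])


def karlin_altschul(raw_score: float, scoring: ScoringScheme,
                    m: int, n: int) -> tuple[float, float]:
    """Bit score and E-value for a raw score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    bit = (scoring.lam * raw_score - math.log(scoring.k)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bit)
    return bit, evalue


class ProteinDatabase:
    """A protein reference set pre-encoded for repeated searching."""

    def __init__(self, records: Sequence[ReferenceRecord],
                 prefilter_k: int = 5):
        if not records:
            raise ValueError("empty protein database")
        self.records = list(records)
        self.by_id: dict[str, ReferenceRecord] = {
            r.ref_id: r for r in self.records
        }
        enc = [_al.encode_protein(r.seq) for r in self.records]
        self.offsets = np.zeros(len(enc) + 1, dtype=np.int64)
        self.offsets[1:] = np.cumsum([e.size for e in enc])
        self.flat = np.concatenate(enc).astype(np.int8) if enc else \
            np.zeros(0, dtype=np.int8)
        self.total_residues = int(self.offsets[-1])
        self.prefilter_k = prefilter_k
        self._kmers = [
            frozenset(
                r.seq[i:i + prefilter_k]
                for i in range(len(r.seq) - prefilter_k + 1)
            )
            for r in self.records
        ]

    def candidate_subjects(self, frames: Sequence[str]) -> list[int]:
        """Indices of subjects sharing at least one exact k-mer with a frame."""
        k = self.prefilter_k
        query_kmers = {
            f[i:i + k]
            for f in frames for i in range(len(f) - k + 1)
        }
        return [
            idx for idx, km in enumerate(self._kmers)
            if not query_kmers.isdisjoint(km)
        ]


def _frame_to_read_coords(frame: int, read_len: int,
                          pep_start: int, pep_end: int) -> tuple[int, int]:
    """Map 1-based peptide coordinates to 1-based nt coordinates on the read."""
    f = abs(frame)
    nt_start = f + 3 * (pep_start - 1)
    nt_end = f + 3 * pep_end - 1
    if frame > 0:
        return nt_start, nt_end
    return read_len - nt_start + 1, read_len - nt_end + 1


def _min_raw_score(scoring: ScoringScheme, m: int, n: int,
                   evalue_cutoff: float) -> int:
    """Smallest integer raw score whose E-value is <= the cutoff."""
    bits_needed = math.log2(m * n / evalue_cutoff)
    s = (bits_needed * math.log(2.0) + math.log(scoring.k)) / scoring.lam
    return max(0, math.ceil(s - 1e-9))


def search_reads(reads: Sequence[SequenceRead],
                 db: ProteinDatabase | Sequence[ReferenceRecord],
                 scoring: ScoringScheme | None = None,
                 evalue_cutoff: float = 1e-6,
                 genetic_code: int = 11,
                 prefilter: bool = False) -> dict[str, list[AlignmentHit]]:
    """Search reads against a protein database in all six frames.

    Returns, per read with at least one significant hit, the hits with
    E <= ``evalue_cutoff`` sorted by descending bit score (ties broken by
    subject id). One hit is reported per (read, subject): the best-scoring
    frame. Reads present in the returned mapping form the "extracted" set.
    """
    if not isinstance(db, ProteinDatabase):
        db = ProteinDatabase(db)
    scoring = scoring or ScoringScheme()
    mat = _matrix(scoring.matrix_name)
    n_total = db.total_residues
    results: dict[str, list[AlignmentHit]] = {}

    for read in reads:
        frames = six_frame_translate(read.seq, genetic_code)
        frame_nums = (1, 2, 3, -1, -2, -3)
        enc_frames = [_al.encode_protein(f) if f else
                      np.zeros(0, dtype=np.int8) for f in frames]
        f_off = np.zeros(7, dtype=np.int64)
        f_off[1:] = np.cumsum([e.size for e in enc_frames])
        flat_frames = np.concatenate(enc_frames) if f_off[-1] else \
            np.zeros(0, dtype=np.int8)

        subject_idx = db.candidate_subjects(frames) if prefilter \
            else range(len(db.records))
        pairs_q = []
        pairs_s = []
        for s in subject_idx:
            for fi in range(6):
                if enc_frames[fi].size:
                    pairs_q.append(fi)
                    pairs_s.append(s)
        if not pairs_q:
            continue
        pq = np.asarray(pairs_q, dtype=np.int64)
        ps = np.asarray(pairs_s, dtype=np.int64)
        scores = np.zeros(pq.size, dtype=np.int32)
        _al.sw_score_batch(flat_frames, f_off, db.flat, db.offsets,
                           mat, scoring.gap_open, scoring.gap_extend,
                           pq, ps, scores)

        # best frame per subject (first-listed frame wins ties)
        best: dict[int, tuple[int, int]] = {}
        for p in range(pq.size):
            s = int(ps[p])
            sc = int(scores[p])
            if s not in best or sc > best[s][0]:
                best[s] = (sc, int(pq[p]))

        hits: list[AlignmentHit] = []
        for s, (sc, fi) in best.items():
            m = len(frames[fi])
            if sc < _min_raw_score(scoring, m, n_total, evalue_cutoff):
                continue
            bit, evalue = karlin_altschul(sc, scoring, m, n_total)
            if evalue > evalue_cutoff:
                continue
            aln = _al.sw_traceback(enc_frames[fi], db.flat[
                db.offsets[s]:db.offsets[s + 1]],
                mat, scoring.gap_open, scoring.gap_extend)
            (raw, a1, a2, b1, b2, cols, ident, mism, gopen, _gc) = \
                [int(x) for x in aln]
            frame = frame_nums[fi]
            q1, q2 = _frame_to_read_coords(frame, len(read.seq), a1, a2)
            hits.append(AlignmentHit(
                query_id=read.read_id,
                subject_id=db.records[s].ref_id,
                frame=frame,
                raw_score=raw,
                bit_score=bit,
                evalue=evalue,
                identity_fraction=ident / cols if cols else 0.0,
                aligned_cols=cols,
                mismatches=mism,
                gap_opens=gopen,
                q_start=q1,
                q_end=q2,
                s_start=b1,
                s_end=b2,
            ))
        if hits:
            hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
            results[read.read_id] = hits
    return results
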