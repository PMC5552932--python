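"""Low-level local-alignment kernels.

Numba-compiled Smith–Waterman implementations used by the translated protein
search (affine gaps, BLOSUM-style matrix) and the SSU read mapper (linear,
per-operation gap costs). Sequences are int8-encoded; scoring matrices are
dense int32 arrays. Gap cost conventions:

* affine: a gap of length L costs ``gap_open + gap_extend * L`` (BLAST
  convention, so (11, 1) charges 12 for a single-residue gap);
* linear: each inserted read base costs ``insertion_cost`` and each deleted
  reference base costs ``deletion_cost``.

Stop codons are handled upstream by assigning them a large negative score so
that optimal local alignments can never cross them.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_X = AA_ALPHABET.index("X")
STOP_SCORE = -10_000

NT_ALPHABET = "ACGTN"
NT_N = NT_ALPHABET.index("N")

_AA_ENCODE = np.full(256, AA_X, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_ENCODE[ord(_c)] = _i
    _AA_ENCODE[ord(_c.lower())] = _i

_NT_ENCODE = np.full(256, NT_N, dtype=np.int8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_ENCODE[ord(_c)] = _i
    _NT_ENCODE[ord(_c.lower())] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string; residues outside the alphabet become X."""
    return _AA_ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_nucleotide(seq: str) -> np.ndarray:
    """Encode a nucleotide string over {A,C,G,T,N}; others become N."""
    return _NT_ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def load_protein_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Dense int32 substitution matrix over AA_ALPHABET.

    Pairs involving the stop symbol score ``STOP_SCORE`` so local alignments
    never include a stop codon.
    """
    sm = substitution_matrices.load(name)
    mat = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a == "*" or b == "*":
                mat[i, j] = STOP_SCORE
            else:
                mat[i, j] = int(sm[a][b])
    return mat


def nucleotide_matrix(match: int, mismatch: int) -> np.ndarray:
    """Match/mismatch matrix over {A,C,G,T,N}; N never matches anything."""
    n = len(NT_ALPHABET)
    mat = np.full((n, n), mismatch, dtype=np.int32)
    for i in range(4):
        mat[i, i] = match
    mat[NT_N, :] = mismatch
    mat[:, NT_N] = mismatch
    return mat


@njit(cache=True)
def sw_score(a, b, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local alignment score of a vs b under affine gaps."""
    m = a.shape[0]
    n = b.shape[0]
    neg = -1_000_000
    h_prev = np.zeros(n + 1, dtype=np.int32)
    f_col = np.full(n + 1, neg, dtype=np.int32)
    best = 0
    go = gap_open + gap_extend
    for i in range(1, m + 1):
        h_diag = 0
        h_left = 0
        e = neg
        ai = a[i - 1]
        for j in range(1, n + 1):
            # E: gap in a (horizontal), F: gap in b (vertical)
            e -= gap_extend
            t = h_left - go
            if t > e:
                e = t
            f = f_col[j] - gap_extend
            t = h_prev[j] - go
            if t > f:
                f = t
            f_col[j] = f
            h = h_diag + mat[ai, b[j - 1]]
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0:
                h = 0
            h_diag = h_prev[j]
            h_prev[j] = h
            h_left = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_batch(frames, frame_off, db, db_off, mat, gap_open, gap_extend,
                   pairs_q, pairs_s, out):  # pragma: no cover - numba
    """Score selected (frame, subject) pairs; write best scores into out."""
    for p in range(pairs_q.shape[0]):
        q0 = frame_off[pairs_q[p]]
        q1 = frame_off[pairs_q[p] + 1]
        s0 = db_off[pairs_s[p]]
        s1 = db_off[pairs_s[p] + 1]
        out[p] = sw_score(frames[q0:q1], db[s0:s1], mat, gap_open, gap_extend)


@njit(cache=True)
def sw_traceback(a, b, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Full DP with traceback.

    Returns (score, a_start, a_end, b_start, b_end, aligned_cols, identities,
    mismatches, gap_opens, gap_cols); coordinates are 1-based inclusive.
    Traceback ties resolve diagonal > up (gap in b) > left (gap in a).
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)
    F = np.full((m + 1, n + 1), -1_000_000, dtype=np.int32)
    go = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            t = H[i, j - 1] - go
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            t = H[i - 1, j] - go
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj) in state H until score 0
    i = bi
    j = bj
    aligned = 0
    ident = 0
    mism = 0
    gap_opens = 0
    gap_cols = 0
    state = 0  # 0=H, 1=E (gap in a / left), 2=F (gap in b / up)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if h == diag:
                aligned += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:
            # gap in a: consume b[j-1]
            aligned += 1
            gap_cols += 1
            e = E[i, j]
            if e == H[i, j - 1] - go:
                gap_opens += 1
                state = 0
            j -= 1
        else:
            aligned += 1
            gap_cols += 1
            f = F[i, j]
            if f == H[i - 1, j] - go:
                gap_opens += 1
                state = 0
            i -= 1
    return best, i + 1, bi, j + 1, bj, aligned, ident, mism, gap_opens, gap_cols


@njit(cache=True)
def map_score(read, ref, match, mismatch_cost, insertion_cost,
              deletion_cost):  # pragma: no cover - numba
    """Local alignment score with linear per-operation gap costs.

    Match scores ``match``; a mismatch costs ``mismatch_cost``; a base present
    in the read but not the reference (insertion) costs ``insertion_cost``;
    a reference base absent from the read (deletion) costs ``deletion_cost``.
    """
    m = read.shape[0]
    n = ref.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        h_diag = 0
        h_left_cur = 0  # H[i, j-1]
        ri = read[i - 1]
        for j in range(1, n + 1):
            if ri == ref[j - 1] and ri != 4:
                h = h_diag + match
            else:
                h = h_diag - mismatch_cost
            t = h_prev[j] - insertion_cost
            if t > h:
                h = t
            t = h_left_cur - deletion_cost
            if t > h:
                h = t
            if h < 0:
                h = 0
            h_diag = h_prev[j]
            h_prev[j] = h
            h_left_cur = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def map_traceback(read, ref, match, mismatch_cost, insertion_cost,
                  deletion_cost):  # pragma: no cover - numba
    """Linear-gap local alignment with traceback.

    Returns (score, r_start, r_end, s_start, s_end, aligned_cols, identities,
    mismatches, gap_cols); 1-based inclusive coordinates on read and ref.
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            if ri == ref[j - 1] and ri != 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] - mismatch_cost
            t = H[i - 1, j] - insertion_cost
            if t > h:
                h = t
            t = H[i, j - 1] - deletion_cost
            if t > h:
                h = t
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    i = bi
    j = bj
    aligned = 0
    ident = 0
    mism = 0
    gap_cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        ri = read[i - 1]
        if ri == ref[j - 1] and ri != 4:
            diag = H[i - 1, j - 1] + match
        else:
            diag = H[i - 1, j - 1] - mismatch_cost
        if H[i, j] == diag:
            aligned += 1
            if ri == ref[j - 1] and ri != 4:
                ident += 1
            else:
                mism += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - insertion_cost:
            aligned += 1
            gap_cols += 1
            i -= 1
        else:
            aligned += 1
            gap_cols += 1
            j -= 1
    return best, i + 1, bi, j + 1, bj, aligned, ident, mism, gap_cols
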