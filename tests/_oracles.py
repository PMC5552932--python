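"""Independent oracles used by the test suite.

These deliberately use different formulations from the package code:
top-down memoized recursion and explicit path enumeration for local
alignment, and direct path intersection for the LCA.
"""

from __future__ import annotations

from functools import lru_cache


def recursive_local_score(a: str, b: str, score, gap_open: int,
                          gap_extend: int) -> int:
    """Optimal local alignment score by top-down memoized recursion.

    States: best score of an alignment ending at (i, j) with the last
    column being a substitution (M), a gap in ``a`` (GA, consuming b[j]) or
    a gap in ``b`` (GB, consuming a[i]). A gap of length L costs
    gap_open + L * gap_extend.
    """
    go = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def m(i: int, j: int) -> int:
        prev = 0
        if i > 0 and j > 0:
            prev = max(0, m(i - 1, j - 1), ga(i - 1, j - 1), gb(i - 1, j - 1))
        return score(a[i], b[j]) + prev

    @lru_cache(maxsize=None)
    def ga(i: int, j: int) -> int:
        best = -10**9
        if j > 0:
            best = max(m(i, j - 1) - go, ga(i, j - 1) - gap_extend,
                       gb(i, j - 1) - go)
        return best

    @lru_cache(maxsize=None)
    def gb(i: int, j: int) -> int:
        best = -10**9
        if i > 0:
            best = max(m(i - 1, j) - go, gb(i - 1, j) - gap_extend,
                       ga(i - 1, j) - go)
        return best

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, m(i, j))
    return best


def enumerate_local_score(a: str, b: str, score, gap_open: int,
                          gap_extend: int) -> int:
    """Truly exhaustive enumeration of all local alignments (tiny inputs).

    Walks every monotone path through the alignment grid from every start
    cell, charging affine gap costs, and keeps the best running score over
    all alignment prefixes.
    """
    go = gap_open + gap_extend
    best = 0

    def walk(i: int, j: int, running: int, last: str) -> None:
        nonlocal best
        if running > best and last == "M":
            best = running
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, running + score(a[i], b[j]), "M")
        if j < len(b):
            cost = gap_extend if last == "GA" else go
            walk(i, j + 1, running - cost, "GA")
        if i < len(a):
            cost = gap_extend if last == "GB" else go
            walk(i + 1, j, running - cost, "GB")

    for i in range(len(a)):
        for j in range(len(b)):
            walk(i, j, 0, "start")
    return best


def path_intersection_lca(paths) -> tuple[str, ...]:
    """Strict LCA: the longest common prefix of the lineage paths."""
    common: list[str] = []
    for level in zip(*[tuple(p) for p in paths]):
        if all(t == level[0] for t in level):
            common.append(level[0])
        else:
            break
    return tuple(common)


def coverage_lca_bruteforce(paths, lca_percent: float) -> tuple[str, ...]:
    """Deepest node covering >= lca_percent % of paths, over ALL nodes.

    Ties at the maximal depth resolve to the common ancestor of the
    qualifying nodes (the shallower node wins).
    """
    paths = [tuple(p) for p in paths]
    n = len(paths)
    need = lca_percent / 100.0 * n - 1e-9
    nodes = {()}
    for p in paths:
        for d in range(1, len(p) + 1):
            nodes.add(p[:d])
    qualifying = [
        node for node in nodes
        if sum(1 for p in paths if p[:len(node)] == node) >= need
    ]
    max_depth = max(len(node) for node in qualifying)
    deepest = [node for node in qualifying if len(node) == max_depth]
    if len(deepest) == 1:
        return deepest[0]
    return path_intersection_lca(deepest)
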