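"""MEGAN-style LCA taxonomic assignment of curated reads.

Hits are first filtered per read (min bit score, max E-value, then a
top-percent window below the best hit); the read is then assigned to the
deepest taxonomy node whose subtree covers at least ``lca_percent`` percent
of the retained hits (weighted LCA; with lca_percent = 100 this is the
strict path-intersection LCA). A final support pass moves reads on taxa
with fewer than ``min_support`` assigned reads up to the parent.

Defaults reproduce a MEGAN run with min score 50, max expected 0.01, top
percent 1, max support percent 0.0, min support 1, LCA percent 50 and min
complexity 0; min complexity 0 and max support percent 0.0 disable those
filters (a non-zero min_complexity is accepted but warned about and
ignored).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .config import LcaConfig
from .records import AlignmentHit

__all__ = ["TaxonomyTree", "filter_hits", "assign_lca", "apply_support",
           "classify_reads"]

log = logging.getLogger(__name__)

#: Node key: the lineage path from the root, as a tuple. The root is ().
Path = tuple[str, ...]


class TaxonomyTree:
    """A rooted taxonomy built from the union of lineage paths.

    Nodes are keyed by their full path from the root so that identically
    named taxa under different parents stay distinct.
    """

    def __init__(self, lineages: Sequence[Sequence[str]]):
        self.nodes: set[Path] = {()}
        self.children: dict[Path, set[Path]] = {(): set()}
        for lineage in lineages:
            self.add_lineage(lineage)

    def add_lineage(self, lineage: Sequence[str]) -> None:
        path: Path = ()
        for name in lineage:
            child = path + (name,)
            if child not in self.nodes:
                self.nodes.add(child)
                self.children.setdefault(path, set()).add(child)
                self.children.setdefault(child, set())
            path = child

    def parent(self, path: Path) -> Path | None:
        return path[:-1] if path else None

    def __contains__(self, path: Sequence[str]) -> bool:
        return tuple(path) in self.nodes


def filter_hits(hits: Sequence[AlignmentHit],
                cfg: LcaConfig | None = None) -> list[AlignmentHit]:
    """Per-read hit filtering: min score, max expected, top-percent window.

    Hits below ``min_score`` bits or above ``max_expected`` E-value are
    dropped; of the rest, only hits with bit score >=
    (1 - top_percent/100) * best are retained. ``min_complexity`` 0
    disables the complexity filter.
    """
    cfg = cfg or LcaConfig()
    if cfg.min_complexity != 0:
        log.warning("min_complexity=%s is not implemented and is ignored",
                    cfg.min_complexity)
    passing = [h for h in hits
               if h.bit_score >= cfg.min_score and h.evalue <= cfg.max_expected]
    if not passing:
        return []
    best = max(h.bit_score for h in passing)
    floor = best * (1.0 - cfg.top_percent / 100.0)
    return [h for h in passing if h.bit_score >= floor]


def assign_lca(lineages: Sequence[Sequence[str]],
               tree: TaxonomyTree,
               lca_percent: float = 50.0) -> Path:
    """Deepest node covering >= lca_percent % of the hit lineages.

    ``lineages`` carries one entry per retained hit (so multiplicity
    weights the vote). Starting from the root (which always covers 100%),
    the walk descends while exactly one child reaches the coverage
    threshold; if two children qualify simultaneously (possible only at
    lca_percent <= 50) the shallower node — their parent — wins. With
    lca_percent = 100 this is the strict path-intersection LCA.
    """
    if not lineages:
        raise ValueError("assign_lca requires at least one lineage")
    paths = []
    for lineage in lineages:
        p = tuple(lineage)
        if p not in tree:
            raise KeyError(f"lineage {';'.join(lineage)!r} not in taxonomy")
        paths.append(p)
    n = len(paths)
    need = lca_percent / 100.0 * n
    node: Path = ()
    while True:
        depth = len(node)
        counts: dict[Path, int] = {}
        for p in paths:
            if len(p) > depth and p[:depth] == node:
                child = p[:depth + 1]
                counts[child] = counts.get(child, 0) + 1
        qualifying = [c for c in sorted(counts)
                      if counts[c] >= need - 1e-9]
        if len(qualifying) != 1:
            return node
        node = qualifying[0]


def apply_support(assignments: Mapping[str, Path],
                  tree: TaxonomyTree,
                  cfg: LcaConfig | None = None) -> dict[str, Path | None]:
    """Move reads on weakly supported taxa up to the parent.

    Taxa with fewer than ``min_support`` assigned reads have their reads
    promoted to the parent node, iterating until stable; reads promoted
    past the root become unassigned (None). ``min_support`` 1 and
    ``max_support_percent`` 0.0 (the defaults) make this a no-op.
    """
    cfg = cfg or LcaConfig()
    result: dict[str, Path | None] = dict(assignments)
    if cfg.min_support <= 1:
        return result
    while True:
        counts: dict[Path, int] = {}
        for path in result.values():
            if path is not None:
                counts[path] = counts.get(path, 0) + 1
        # support of a taxon counts its whole subtree, so reads promoted
        # into a well-populated branch stay there
        def subtree(node: Path) -> int:
            return sum(c for p, c in counts.items()
                       if p[:len(node)] == node)
        weak = {p for p in counts if subtree(p) < cfg.min_support}
        if not weak:
            return result
        # promote the deepest weak taxon first; root-level reads unassign
        target = max(weak, key=len)
        parent = target[:-1] if target else None
        for read_id, path in result.items():
            if path == target:
                result[read_id] = parent


def classify_reads(hits_by_read: Mapping[str, Sequence[AlignmentHit]],
                   subject_lineages: Mapping[str, Sequence[str]],
                   cfg: LcaConfig | None = None,
                   tree: TaxonomyTree | None = None
                   ) -> dict[str, Path | None]:
    """Filter, LCA-assign and support-filter a batch of reads.

    Returns read_id -> assigned taxonomy path (None = unassigned). The tree
    defaults to the union of the subject lineages.
    """
    cfg = cfg or LcaConfig()
    if tree is None:
        tree = TaxonomyTree(list(subject_lineages.values()))
    assigned: dict[str, Path] = {}
    unassigned: list[str] = []
    for read_id in sorted(hits_by_read):
        retained = filter_hits(hits_by_read[read_id], cfg)
        if not retained:
            unassigned.append(read_id)
            continue
        lineages = []
        for h in retained:
            if h.subject_id not in subject_lineages:
                raise KeyError(
                    f"subject {h.subject_id!r} has no lineage entry"
                )
            lineages.append(tuple(subject_lineages[h.subject_id]))
        assigned[read_id] = assign_lca(lineages, tree, cfg.lca_percent)
    result = apply_support(assigned, tree, cfg)
    for read_id in unassigned:
        result[read_id] = None
    return result
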