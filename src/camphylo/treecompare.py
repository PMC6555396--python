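"""Unrooted, polytomy-tolerant tree comparison by shared bipartitions.

Removing an internal edge of an unrooted tree splits the leaf set in two — a
*bipartition*.  Two trees agree on an edge when they induce the same
bipartition.  The edge-similarity score of a recovered tree against a
reference is the percentage of the recovered tree's non-trivial bipartitions
that also occur in the reference, after both trees are pruned to their shared
leaf set.  The score depends only on topology: branch lengths, rootings and
child orderings are irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

from .errors import InsufficientOverlapError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bipartition:
    """An unordered split of the leaf set induced by one internal edge.

    ``side_a`` is canonically the side containing the lexicographically
    smallest leaf label, so equal splits compare equal regardless of which
    side was enumerated first.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @classmethod
    def of(cls, one_side: frozenset[str], leaf_set: frozenset[str]) -> "Bipartition":
        other = leaf_set - one_side
        if not one_side or not other:
            raise ValueError("bipartition sides must be non-empty")
        if min(one_side) < min(other):
            return cls(one_side, other)
        return cls(other, one_side)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) < 2 or len(self.side_b) < 2


def leaf_labels(t: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())


def bipartitions(t: dendropy.Tree) -> frozenset[Bipartition]:
    """All non-trivial bipartitions of an unrooted tree.

    One bipartition per internal edge; polytomies simply contribute fewer of
    them (a star tree yields none).  A bifurcating anchor node would expose
    the same split through two edges; duplicates collapse in the returned set.
    """
    leaves = leaf_labels(t)
    if len(leaves) < 4:
        raise ValueError(f"need >= 4 leaves, got {len(leaves)}")
    splits: set[Bipartition] = set()
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node is t.seed_node:
            continue
        side = below[node]
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(Bipartition.of(side, leaves))
    return frozenset(splits)


def prune_to_shared(
    source: dendropy.Tree, ref: dendropy.Tree
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Restrict both trees to the intersection of their leaf sets.

    Degree-2 nodes created by pruning are contracted with branch lengths
    merged additively.  The inputs are not modified.  Raises when fewer than
    four leaves are shared.
    """
    shared = leaf_labels(source) & leaf_labels(ref)
    if len(shared) < 4:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared leaves; need >= 4"
        )
    out = []
    for tree in (source, ref):
        pruned = tree.clone(depth=1)
        pruned.retain_taxa_with_labels(sorted(shared))
        pruned.is_rooted = False
        out.append(pruned)
    return out[0], out[1]


def edge_similarity(
    source: dendropy.Tree,
    ref: dendropy.Tree,
    denominator: str = "source",
) -> float:
    """Percentage of one tree's non-trivial splits present in the other.

    After pruning to the shared leaf set, returns
    ``100 * |B(source) ∩ B(ref)| / |B(denom)|`` where the denominator tree is
    the source by default (how much of the recovered tree the reference
    supports); ``denominator="ref"`` flips the orientation.  A fully
    unresolved denominator tree has no splits to contradict and scores 100
    with a logged warning.
    """
    if denominator not in ("source", "ref"):
        raise ValueError(f"denominator must be 'source' or 'ref', got {denominator!r}")
    src_p, ref_p = prune_to_shared(source, ref)
    b_src = bipartitions(src_p)
    b_ref = bipartitions(ref_p)
    denom = b_src if denominator == "source" else b_ref
    if not denom:
        logger.warning("denominator tree has no non-trivial splits; similarity = 100")
        return 100.0
    return 100.0 * len(b_src & b_ref) / len(denom)


def compare_report(source: dendropy.Tree, ref: dendropy.Tree) -> str:
    """One-line human-readable comparison summary used by the CLI."""
    src_p, ref_p = prune_to_shared(source, ref)
    b_src = bipartitions(src_p)
    b_ref = bipartitions(ref_p)
    pct = 100.0 if not b_src else 100.0 * len(b_src & b_ref) / len(b_src)
    return (
        f"shared_leaves={len(leaf_labels(src_p))}\t"
        f"source_splits={len(b_src)}\tref_splits={len(b_ref)}\t"
        f"shared_splits={len(b_src & b_ref)}\tsimilarity={pct:.2f}"
    )
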