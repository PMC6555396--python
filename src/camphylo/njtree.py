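"""Neighbor joining and Newick serialization.

Canonical Saitou–Nei neighbor joining with the Studier–Keppler O(n³) update:
at each step join the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - Σ_k d(i, k) - Σ_k d(j, k)

with limb lengths from the standard formulas.  Ties in Q break toward the
lexicographically smallest label pair (each cluster represented by its
smallest leaf label), so the output Newick bytes are deterministic for a
given matrix.  The result is an unrooted tree serialized with a trifurcating
anchor node; negative limb lengths are clamped to zero at serialization only,
so internally the tree reproduces an additive input matrix exactly.

Trees are :class:`dendropy.Tree` objects throughout.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .errors import NewickParseError

logger = logging.getLogger(__name__)


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Requires ≥ 3 taxa and finite entries.  Leaf labels equal the matrix
    labels; the seed node is the final trifurcation.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("distance matrix contains non-finite entries")

    tns = dendropy.TaxonNamespace(m.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in m.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    reps = list(m.labels)  # cluster representative = smallest member label
    D = m.values.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best_q is None or q < best_q or (q == best_q and key < best[0]):
                    best_q = q
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # Studier–Keppler reduction
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        newD = np.zeros((k - 1, k - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        reps = [reps[x] for x in keep] + [min(reps[i], reps[j])]
        D = newD

    # final three-point join
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    for node, limb in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        center.add_child(node)
        node.edge.length = limb
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def write_newick(t: dendropy.Tree, path=None) -> str:
    """Serialize with 6-decimal branch lengths; negatives clamped to zero.

    Labels containing Newick metacharacters or spaces are quoted.  The clamp
    happens on a clone, so the in-memory tree keeps raw limb lengths.
    """
    out = t.clone(depth=1)
    n_clamped = 0
    for edge in out.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative branch lengths to 0 at output", n_clamped)
    text = out.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        preserve_spaces=True,
    )
    if not text.endswith("\n"):
        text += "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text; polytomies allowed, branch lengths optional.

    Missing lengths stay ``None`` (absent, not zero).  Malformed input or
    duplicate leaf labels raise :class:`~camphylo.errors.NewickParseError`
    carrying dendropy's position message.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickParseError(str(exc)) from exc
    tree.is_rooted = False
    return tree


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def path_length_matrix(t: dendropy.Tree, labels: list[str] | None = None) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances as a DistanceMatrix.

    Edges without a length count as zero.  Label order defaults to sorted.
    """
    pdm = t.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.taxon_namespace if tx.label is not None}
    if labels is None:
        labels = sorted(taxa)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
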