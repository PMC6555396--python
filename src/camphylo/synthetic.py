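"""Synthetic CDS data with controlled codon-aversion structure.

The generator makes the one assumption the whole method rests on — codon
aversion is phylogenetically conserved in orthologs — explicit and tunable:
an ancestral genome of genes, each with a random aversion set, is copied down
a known tree, and on every branch each gene's aversion set may gain or lose
one codon with probability proportional to branch length.  Leaves are then
*realized* as CDS FASTA in which every non-averted codon appears at least
once, so the motif extracted from an emitted gene equals the intended
aversion set exactly and simulator tests are decoupled from sampling noise.

This is a test harness, not a model of molecular evolution: no substitution
model, no indels, no GC bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import ConfigurationError
from .motifs import CODONS, AversionMotif
from .njtree import write_newick

_START = "ATG"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``flip_rate`` is the per-unit-branch-length probability that a gene's
    aversion set gains or loses one codon on a branch (capped at 1 per
    branch); ``aversion_rate`` is the expected fraction of the non-start
    codon table excluded per ancestral gene.
    """

    tree: dendropy.Tree
    seed: int
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (80, 300)
    aversion_rate: float = 0.2
    flip_rate: float = 1.0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed is mandatory and must be an integer")
        if not 0.0 <= self.aversion_rate <= 1.0:
            raise ConfigurationError("aversion_rate must be in [0, 1]")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ConfigurationError("flip_rate must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo < 10 or hi < lo:
            raise ConfigurationError(
                "gene_length_range must satisfy 10 <= min <= max (codons)"
            )


@dataclass
class SimulationResult:
    """Leaf FASTA texts plus the ground truth they were generated from."""

    config: SimulationConfig
    fastas: dict[str, str]                       # leaf label -> FASTA text
    leaf_sets: dict[str, list[frozenset[str]]]   # leaf label -> per-gene aversion sets
    true_tree_newick: str

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write one FASTA per leaf, the true tree, and true motifs as TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for label in sorted(self.fastas):
            p = out_dir / f"{label}.fasta"
            p.write_text(self.fastas[label])
            written.append(p)
        tree_path = out_dir / "true_tree.nwk"
        tree_path.write_text(self.true_tree_newick)
        written.append(tree_path)
        tsv = ["species\tgene\tmotif"]
        for label in sorted(self.leaf_sets):
            for i, s in enumerate(self.leaf_sets[label]):
                tsv.append(f"{label}\tg{i:05d}\t{','.join(sorted(s))}")
        motifs_path = out_dir / "true_motifs.tsv"
        motifs_path.write_text("\n".join(tsv) + "\n")
        written.append(motifs_path)
        return written


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    branch_length_range: tuple[float, float] = (0.05, 0.2),
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Random unrooted binary tree with positive branch lengths.

    Topology by random agglomeration; every edge length drawn uniformly from
    ``branch_length_range``.  The returned tree is anchored at a trifurcation
    like an NJ result.
    """
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves")
    if labels is None:
        labels = [f"sp{i:02d}" for i in range(n_leaves)]
    lo, hi = branch_length_range
    if lo <= 0:
        raise ValueError("branch lengths must be positive")
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for child in nodes:
        center.add_child(child)
        child.edge.length = float(rng.uniform(lo, hi))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _sample_aversion_set(rng: np.random.Generator, rate: float) -> frozenset[str]:
    """Each non-start codon excluded independently; >= 1 stop codon retained."""
    averted = {c for c in CODONS if c != _START and rng.random() < rate}
    if all(s in averted for s in _STOPS):
        averted.discard(_STOPS[rng.integers(len(_STOPS))])
    return frozenset(averted)


def _realize_cds(
    aversion: frozenset[str], length: int, rng: np.random.Generator
) -> str:
    """A CDS of ``length`` codons whose observed codon set is exactly the
    complement of ``aversion`` (coverage guarantee)."""
    complement = sorted(set(CODONS) - aversion)
    k = len(complement)
    if length < k:
        raise ConfigurationError(
            f"gene length {length} codons cannot cover the {k}-codon complement; "
            f"raise gene_length_range above {k}"
        )
    codons = list(complement)
    codons += [complement[i] for i in rng.integers(k, size=length - k)]
    rng.shuffle(codons)
    # cosmetic CDS shape: start codon first, one stop codon last
    codons.insert(0, codons.pop(codons.index(_START)))
    stop_idx = max(i for i, c in enumerate(codons) if c in _STOPS and i > 0)
    codons.append(codons.pop(stop_idx))
    return "".join(codons)


def sequence_for_motif(motif, mode: str = "codon") -> str:
    """Deterministic CDS whose codon aversion motif is exactly ``motif``.

    Every codon outside the motif appears exactly once (start codon first, a
    stop codon last when available).  Useful for building exact fixtures.
    """
    elements = set(motif.elements if isinstance(motif, AversionMotif) else motif)
    complement = sorted(set(CODONS) - elements)
    if not complement:
        raise ValueError("motif excludes every codon; no sequence exists")
    if _START in complement:
        complement.insert(0, complement.pop(complement.index(_START)))
    stops = [i for i, c in enumerate(complement) if c in _STOPS and i > 0]
    if stops:
        complement.append(complement.pop(stops[-1]))
    return "".join(complement)


def simulate_ancestor(
    config: SimulationConfig,
) -> tuple[list[frozenset[str]], list[str]]:
    """Ancestral genome: per-gene aversion sets and realized CDS strings."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    sets, seqs = [], []
    for _ in range(config.n_genes):
        s = _sample_aversion_set(rng, config.aversion_rate)
        length = int(rng.integers(lo, hi + 1))
        sets.append(s)
        seqs.append(_realize_cds(s, length, rng))
    return sets, seqs


def _perturb(
    sets: list[frozenset[str]],
    p: float,
    rng: np.random.Generator,
) -> list[frozenset[str]]:
    out = []
    for s in sets:
        if rng.random() >= p:
            out.append(s)
            continue
        s = set(s)
        removable = sorted(s)
        free_stops = [x for x in _STOPS if x not in s]
        addable = sorted(
            c for c in CODONS
            if c not in s and c != _START
            and not (c in _STOPS and len(free_stops) == 1 and free_stops[0] == c)
        )
        add = rng.random() < 0.5
        if add and not addable:
            add = False
        if not add and not removable:
            add = True
        if add and addable:
            s.add(addable[rng.integers(len(addable))])
        elif removable:
            s.discard(removable[rng.integers(len(removable))])
        out.append(frozenset(s))
    return out


def _fasta_text(label: str, seqs: list[str]) -> str:
    lines = []
    for i, seq in enumerate(seqs):
        lines.append(f">g{i:05d} [gene=g{i:05d}] [species={label}]")
        for start in range(0, len(seq), 60):
            lines.append(seq[start : start + 60])
    return "\n".join(lines) + "\n"


def evolve_along_tree(config: SimulationConfig) -> SimulationResult:
    """Copy the ancestral genome down the tree, perturbing per branch.

    On each branch every gene's aversion set is hit with probability
    ``min(1, flip_rate * branch_length)``; a hit adds or removes one
    uniformly chosen eligible codon (the start codon is never averted, one
    stop codon always remains available).  Leaves are realized as FASTA with
    the coverage guarantee.  Output is byte-identical for a fixed config.
    """
    leaves = [l.taxon.label for l in config.tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise ConfigurationError("tree must have >= 4 leaves")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range

    ancestor = [
        _sample_aversion_set(rng, config.aversion_rate)
        for _ in range(config.n_genes)
    ]
    node_sets: dict[dendropy.Node, list[frozenset[str]]] = {}
    leaf_sets: dict[str, list[frozenset[str]]] = {}
    fastas: dict[str, str] = {}
    for node in config.tree.preorder_node_iter():
        if node.parent_node is None:
            node_sets[node] = ancestor
        else:
            length = node.edge.length or 0.0
            p = min(1.0, config.flip_rate * length)
            node_sets[node] = _perturb(node_sets[node.parent_node], p, rng)
        if node.is_leaf():
            label = node.taxon.label
            sets = node_sets[node]
            seqs = [
                _realize_cds(s, int(rng.integers(lo, hi + 1)), rng) for s in sets
            ]
            leaf_sets[label] = sets
            fastas[label] = _fasta_text(label, seqs)

    return SimulationResult(
        config=config,
        fastas=fastas,
        leaf_sets=leaf_sets,
        true_tree_newick=write_newick(config.tree),
    )
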