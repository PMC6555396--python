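# Methods

## Motif construction

A codon aversion motif is the complement, within the full 64-codon table, of
the set of codons observed among the in-frame, non-overlapping codons of one
CDS. Design choices that the definition leaves open:

- **Stop codons count.** The codon universe is all 64 codons, so unused stop
  codons contribute to aversion like any other codon. A gene normally uses
  one of the three stops, which is why the effective motif space has
  64 − 1 start − 2 unused stops = 61 degrees of freedom (2^61 motifs); the
  amino-acid space has 20 (2^20).
- **Trailing incomplete codons** (length not divisible by 3, common in
  partial annotations) are dropped with a logged warning rather than treated
  as errors, so partial genes can participate.
- **Ambiguity codes.** A codon containing any character outside {A,C,G,T}
  (N, R, Y, …) marks no table entry as used: there is no evidence for any
  specific codon. The character itself passes through normalization
  (uppercasing, U→T, whitespace stripping) untouched.
- **The empty motif** (a gene using all 64 codons) is a valid motif and
  enters the species set like any other; the distance formula handles it
  through ordinary set semantics.
- **Amino-acid mode** translates first (NCBI table, default 1, selectable
  per run but not per species), emitting `*` for stops and `X` for ambiguous
  codons; both symbols are ignored when forming the 20-letter motif.

Preprocessing of RefSeq-style CDS FASTA: gene identifiers are parsed from
`[gene=...]` header attributes (configurable regex); per gene only the
longest isoform is kept, ties resolved by file order, and records without a
gene tag are always retained. Records whose headers contain `exception` or
`transl_except` are dropped by default; records containing `partial` are
kept by default (both switchable). Genes that are unusable after
normalization (empty, shorter than one codon) are skipped with a warning; a
species with zero usable genes is an error.

## Distance

`Dist(A,B) = 1 − |a∩b| / min(|a|,|b|)` over the species' unique-motif sets,
computed in exact rational arithmetic and emitted as 6-decimal text so
matrix bytes are identical across platforms. The minimum-overlap rule is
interpreted as a threshold on the shared fraction `s = |a∩b| / min(|a|,|b|)`:
when `s < min_overlap` (default 0.05) the distance is exactly 1.0.
Consequently no emitted value lies strictly inside `(1 − min_overlap, 1)`;
setting `--min-overlap 0` disables the rule for sensitivity checks. The
denominator of the rule is the same `min(|a|,|b|)` as the distance itself —
the natural reading, kept configurable since other denominators are
conceivable.

Two matrix dialects are supported: a self-describing tab-separated layout
(header of labels, then label + distances per row) and square PHYLIP (count
line, 10-character names). Lower-triangle PHYLIP variants are rejected with
an explicit message. On reading, asymmetry up to 1e-6 (rounding) is averaged
away; more is a parse error.

## Neighbor joining

Canonical Saitou–Nei NJ with the Studier–Keppler O(n³) update: join the pair
minimizing `Q(i,j) = (n−2) d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, standard limb
lengths, final three clusters joined at a trifurcation. Implemented directly
rather than delegated so the behavior is the textbook one: ties in Q break
toward the lexicographically smallest pair of cluster representatives (each
cluster represented by its smallest leaf label), making the output Newick
byte-deterministic. Negative limb lengths — possible on non-additive input —
are kept internally (so additive matrices round-trip exactly, the testable
consistency property) and clamped to zero only at serialization, with a log
note. Trees are dendropy objects; Newick output uses 6-decimal lengths and
quotes labels containing metacharacters or spaces.

## Tree comparison

Both trees are first pruned to their shared leaf set (references rarely
cover exactly the same species); degree-2 nodes created by pruning are
contracted with branch lengths merged additively. Similarity is
`100 × |B(source) ∩ B(ref)| / |B(source)|` over non-trivial bipartitions.
Choices made here:

- The denominator is the source (recovered) tree's split count — "how much
  of the recovered tree does the reference support" — switchable to the
  reference via a flag, since both orientations are in common use.
- Multifurcating splits are matched by exact set identity only; no partial
  credit for compatibility. A fully unresolved source tree has nothing to
  contradict and scores 100 with a logged warning.
- The score uses topology only; branch lengths and rootings never enter
  (tested by invariance under re-anchoring).

Fewer than four shared leaves is an error: no non-trivial split exists.

## Synthetic data generator

The generator makes the method's one biological premise — codon aversion is
conserved along the tree — explicit and tunable, so every pipeline stage is
testable without downloads. An ancestral genome of `n_genes` genes is
created; each gene's aversion set excludes every non-start codon
independently with probability `aversion_rate` (at least one stop codon is
always left available, and ATG is never averted). Sets are copied down a
given tree; on each branch each gene is hit with probability
`min(1, flip_rate × branch length)`, and a hit adds or removes one uniformly
chosen eligible codon. Leaves are *realized* as CDS in which every
non-averted codon appears at least once (start codon first, a stop last),
so the motif extracted from an emitted gene equals the intended set exactly
— the coverage guarantee that decouples simulator tests from sampling noise.
Output (FASTA per leaf, true tree, true motif TSV) is byte-identical for a
fixed seed.

Defaults: 200 genes, gene length 80–300 codons, `aversion_rate` 0.2,
`flip_rate` 1.0 per unit branch length, random test trees with branch
lengths U(0.05, 0.2). With these values a leaf-to-leaf path of ~10 edges
leaves a gene's motif unchanged with probability ≈ Π(1 − ℓ_e) ≳ 0.2, so even
the most distant pair retains an informative shared fraction above the 5%
clamp. The mean motif size under `aversion_rate` 0.2 (~13 codons) is in the
realistic range for real coding sequences.

What the generator does **not** emulate: codon substitution processes (no
GY94-style model), indels, GC-biased gene conversion, gene gain/loss,
isoforms, annotation noise, or correlated aversion between genes. Passing
recovery tests therefore shows the pipeline is correct and that conserved
aversion suffices for topology recovery under the stated perturbation model
— not that real genomes satisfy that model.

## Problem sizes and numerical choices

The test and acceptance batteries use sizes chosen to exercise the
asymptotics while keeping a desk-scale run: exhaustive distance pairs over a
4-codon universe plus 10,000 random motif-set pairs; 500 random additive
matrices on 4–16 leaves (recovery demanded exact, path lengths within 1e-9);
200 random quartets against a brute-force Q oracle; and 20 seeded
16-species, 200-gene simulations for end-to-end split recovery (≥ 90% of
true splits expected in ≥ 18 of 20 seeds). Matrix symmetry tolerance on
parse is 1e-6 (6-decimal serialization); internal symmetry is exact.

## Known limitations

- The distance is not additive, so NJ on CAM distances is a heuristic (as
  for most real distance measures); consistency is only guaranteed for
  additive input.
- Species with very small genomes interact with the clamp rule: everything
  sufficiently unrelated collapses to distance 1, which carries no ranking
  information.
- Edge similarity here follows the conventions documented above; it is not
  claimed to be bit-identical to any particular external comparison tool's
  normalization of polytomies.
- Full RefSeq-scale statistics (tens of millions of unique motifs) are out
  of desk-scale scope; the summaries module computes the statistics, but no
  corpus-scale values are asserted anywhere.
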