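from collections import Counter

import pytest

from camphylo import AversionMotif, GeneRecord, SpeciesProfile, sequence_for_motif

# the four-gene example species: motifs per gene, two genes sharing one motif
EXAMPLE_GENE_MOTIFS = [
    ("AAA", "ATA"),
    ("AAA", "ACG", "CTC"),
    ("AAA", "ATA"),
    ("CGC",),
]
EXAMPLE_UNIQUE_MOTIFS = {
    ("AAA", "ATA"),
    ("AAA", "ACG", "CTC"),
    ("CGC",),
}


def make_profile(label, motif_tuples, mode="codon"):
    """Profile from an iterable of element tuples (repeats = gene counts)."""
    counts = Counter(AversionMotif(tuple(sorted(t)), mode) for t in motif_tuples)
    return SpeciesProfile(species=label, motif_counts=dict(counts), mode=mode)


def fasta_for_motifs(gene_motifs, species="species"):
    """FASTA text whose genes realize exactly the given codon motifs."""
    lines = []
    for i, motif in enumerate(gene_motifs):
        lines.append(f">g{i:03d} [gene=g{i:03d}] [species={species}]")
        lines.append(sequence_for_motif(motif))
    return "\n".join(lines) + "\n"


@pytest.fixture
def example_records():
    return [
        GeneRecord(gene_id=f"g{i}", species="example",
                   sequence=sequence_for_motif(m), record_id=f"g{i}")
        for i, m in enumerate(EXAMPLE_GENE_MOTIFS)
    ]


@pytest.fixture
def example_fasta(tmp_path):
    path = tmp_path / "example.fasta"
    path.write_text(fasta_for_motifs(EXAMPLE_GENE_MOTIFS, "example"))
    return path
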