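"""Descriptive statistics over motif profiles.

Covers the standard reporting around aversion motifs: how many codons a gene
typically avoids (motif-size distribution), how often each codon is averted,
how often the same motif recurs in multiple genes or species, and how the
unique-motif pool splits into singletons versus shared motifs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .motifs import AMINO_ACIDS, CODONS, AversionMotif, SpeciesProfile


@dataclass
class MotifStats:
    """Aggregate motif statistics over one or more species profiles."""

    size_histogram: dict[int, int]       # motif length -> number of genes
    per_codon_freq: dict[str, float]     # alphabet element -> fraction of genes averting it
    repetition_spectrum: dict[int, int]  # total occurrence count -> number of motifs
    n_unique_motifs: int
    n_genes: int
    mean_size: float
    sd_size: float


def _check_modes(profiles: Sequence[SpeciesProfile]) -> str:
    if not profiles:
        raise ValueError("need at least one profile")
    modes = {p.mode for p in profiles}
    if len(modes) != 1:
        raise ConfigurationError(f"mixed profile modes: {sorted(modes)}")
    return modes.pop()


def _total_counts(profiles: Sequence[SpeciesProfile]) -> Counter[AversionMotif]:
    """Occurrence count per motif summed over genes of all species."""
    totals: Counter[AversionMotif] = Counter()
    for p in profiles:
        totals.update(p.motif_counts)
    return totals


def motif_stats(profiles: Sequence[SpeciesProfile]) -> MotifStats:
    """Compute the full statistics bundle.

    Genes are weighted equally across species.  The unique-motif count is
    over the union across species; the repetition spectrum counts total
    occurrences including repeats within one species.  ``sd_size`` is the
    population standard deviation (a single gene has sd 0).
    """
    mode = _check_modes(profiles)
    alphabet = CODONS if mode == "codon" else AMINO_ACIDS

    size_hist: Counter[int] = Counter()
    avert_genes: Counter[str] = Counter()
    n_genes = 0
    for p in profiles:
        for motif, count in p.motif_counts.items():
            size_hist[len(motif)] += count
            n_genes += count
            for element in motif:
                avert_genes[element] += count

    totals = _total_counts(profiles)
    spectrum = Counter(totals.values())

    sizes = np.repeat(
        list(size_hist.keys()), list(size_hist.values())
    ).astype(float)
    return MotifStats(
        size_histogram=dict(sorted(size_hist.items())),
        per_codon_freq={e: avert_genes[e] / n_genes for e in alphabet},
        repetition_spectrum=dict(sorted(spectrum.items())),
        n_unique_motifs=len(totals),
        n_genes=n_genes,
        mean_size=float(sizes.mean()),
        sd_size=float(sizes.std(ddof=0)),
    )


def per_species_codon_freq(profiles: Sequence[SpeciesProfile]) -> pd.DataFrame:
    """Per-species aversion fraction for every alphabet element.

    Rows are species, columns alphabet elements; a cell holds the fraction of
    that species' genes whose motif contains the element (a species averting
    a codon in half its genes gets 0.50).  This is the per-species view used
    for cross-species boxplots; aggregation across species is left to the
    caller.
    """
    mode = _check_modes(profiles)
    alphabet = CODONS if mode == "codon" else AMINO_ACIDS
    rows = {}
    for p in profiles:
        counts = Counter()
        for motif, count in p.motif_counts.items():
            for element in motif:
                counts[element] += count
        rows[p.species] = [counts[e] / p.n_genes for e in alphabet]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(alphabet))


def shared_vs_unique(profiles: Sequence[SpeciesProfile]) -> tuple[int, int]:
    """Partition the unique-motif pool into shared and singleton motifs.

    A motif is a singleton when its total occurrence count across all genes
    and species is exactly 1, shared otherwise.  Returns
    ``(n_shared, n_singleton)``; the two always sum to the unique-motif count.
    """
    _check_modes(profiles)
    totals = _total_counts(profiles)
    n_singleton = sum(1 for c in totals.values() if c == 1)
    return len(totals) - n_singleton, n_singleton


def stats_tables(stats: MotifStats) -> dict[str, pd.DataFrame]:
    """Tabular (TSV-ready) views of a :class:`MotifStats` bundle."""
    return {
        "size_histogram": pd.DataFrame(
            {"motif_size": list(stats.size_histogram),
             "n_genes": list(stats.size_histogram.values())}
        ),
        "per_codon_freq": pd.DataFrame(
            {"element": list(stats.per_codon_freq),
             "aversion_fraction": list(stats.per_codon_freq.values())}
        ),
        "repetition_spectrum": pd.DataFrame(
            {"occurrences": list(stats.repetition_spectrum),
             "n_motifs": list(stats.repetition_spectrum.values())}
        ),
        "summary": pd.DataFrame(
            {"statistic": ["n_unique_motifs", "n_genes", "mean_size", "sd_size"],
             "value": [stats.n_unique_motifs, stats.n_genes,
                       stats.mean_size, stats.sd_size]}
        ),
    }
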