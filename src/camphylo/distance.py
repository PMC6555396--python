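"""Pairwise species distances from motif-set overlap.

The distance between species A and B with motif sets *a* and *b* is

    Dist(A, B) = 1 - |a ∩ b| / min(|a|, |b|)

i.e. one minus the overlap coefficient of the two sets.  When the shared
fraction falls below a minimum-overlap threshold (default 5%), the overlap is
deemed uninformative — a small genome can share a few motifs with anything by
chance — and the distance is clamped to exactly 1.0.  Consequently no emitted
value ever lies strictly between ``1 - min_overlap`` and 1.

Distances are computed in exact rational arithmetic and serialized as
6-decimal text, so matrix bytes are reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, MatrixParseError, ProfileError
from .motifs import SpeciesProfile

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 0.05
Dialect = Literal["native", "phylip"]

_PHYLIP_NAME_WIDTH = 10


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise distances in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({n}, {n}) for {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("matrix not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def pairwise_distance(
    a: SpeciesProfile,
    b: SpeciesProfile,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> float:
    """CAM distance between two species profiles.

    Returns ``1 - s`` with ``s = |a∩b| / min(|a|,|b|)``, or exactly 1.0 when
    ``s < min_overlap``.  Symmetric by construction; 0 for identical sets.
    """
    if a.mode != b.mode:
        raise ConfigurationError(
            f"mode mismatch: {a.species}={a.mode!r} vs {b.species}={b.mode!r}"
        )
    na, nb = len(a.motifs), len(b.motifs)
    if na == 0 or nb == 0:
        raise ProfileError("empty motif set")
    shared = Fraction(len(a.motifs & b.motifs), min(na, nb))
    if shared < Fraction(min_overlap):
        return 1.0
    return float(1 - shared)


def distance_matrix(
    profiles: Sequence[SpeciesProfile],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs CAM distances; label order follows input order."""
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 profiles, got {len(profiles)}")
    labels = [p.species for p in profiles]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate species labels: {dupes}")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(profiles[i], profiles[j], min_overlap)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def write_matrix(m: DistanceMatrix, dialect: Dialect = "native") -> str:
    """Serialize a matrix as tab-separated native text or square PHYLIP."""
    if dialect == "native":
        lines = ["\t".join(m.labels)]
        for label, row in zip(m.labels, m.values):
            lines.append(label + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"
    if dialect == "phylip":
        short = [label[:_PHYLIP_NAME_WIDTH] for label in m.labels]
        if len(set(short)) != len(short):
            dupes = sorted({s for s in short if short.count(s) > 1})
            raise ValueError(
                f"PHYLIP name collision after 10-character truncation: {dupes}"
            )
        lines = [str(len(m.labels))]
        for name, row in zip(short, m.values):
            lines.append(
                f"{name:<{_PHYLIP_NAME_WIDTH}}" + " ".join(f"{v:.6f}" for v in row)
            )
        return "\n".join(lines) + "\n"
    raise ConfigurationError(f"unknown matrix dialect {dialect!r}")


def _symmetrize(values: np.ndarray, labels: list[str]) -> DistanceMatrix:
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > 1e-6:
        raise MatrixParseError(f"matrix asymmetric beyond tolerance ({asym:.2e} > 1e-6)")
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(labels, sym)


def _parse_native(lines: list[str]) -> DistanceMatrix:
    labels = lines[0].rstrip("\n").split("\t")
    n = len(labels)
    if len(lines) - 1 != n:
        raise MatrixParseError(f"expected {n} rows after header, got {len(lines) - 1}")
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n + 1:
            raise MatrixParseError(
                f"expected label + {n} values, got {len(fields)} fields", line=i
            )
        if fields[0] != labels[i - 2]:
            raise MatrixParseError(
                f"row label {fields[0]!r} != header label {labels[i - 2]!r}", line=i
            )
        try:
            values[i - 2] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise MatrixParseError(f"non-numeric field: {exc}", line=i) from None
    return _symmetrize(values, labels)


def _parse_phylip(lines: list[str]) -> DistanceMatrix:
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise MatrixParseError("first PHYLIP line must be the taxon count", line=1) from None
    rows = [l for l in lines[1:] if l.strip()]
    if len(rows) != n:
        raise MatrixParseError(f"count line says {n} taxa but found {len(rows)} rows")
    labels: list[str] = []
    values = np.zeros((n, n))
    for i, line in enumerate(rows, start=2):
        head = line[:_PHYLIP_NAME_WIDTH]
        rest = line[_PHYLIP_NAME_WIDTH:].split()
        if len(rest) != n:
            # fall back to whitespace-delimited names
            tokens = line.split()
            head, rest = tokens[0], tokens[1:]
        label = head.strip()
        if not label:
            raise MatrixParseError("empty taxon name", line=i)
        if len(rest) != n:
            k = i - 2  # 0-based row index: lower-triangle rows carry k or k+1 fields
            if len(rest) in (k, k + 1):
                raise MatrixParseError(
                    "lower-triangle PHYLIP matrices are not supported; "
                    "provide a full square matrix", line=i,
                )
            raise MatrixParseError(
                f"expected {n} distances, got {len(rest)}", line=i
            )
        try:
            values[i - 2] = [float(x) for x in rest]
        except ValueError as exc:
            raise MatrixParseError(f"non-numeric field: {exc}", line=i) from None
        labels.append(label)
    if len(set(labels)) != n:
        raise MatrixParseError("duplicate taxon names in PHYLIP matrix")
    return _symmetrize(values, labels)


def read_matrix(text: str, dialect: Dialect = "native") -> DistanceMatrix:
    """Parse a distance matrix written by :func:`write_matrix`.

    Mild asymmetry (≤ 1e-6, e.g. from 6-decimal rounding) is averaged away;
    anything larger is a parse error.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise MatrixParseError("empty matrix text")
    if dialect == "native":
        return _parse_native(lines)
    if dialect == "phylip":
        return _parse_phylip(lines)
    raise ConfigurationError(f"unknown matrix dialect {dialect!r}")
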