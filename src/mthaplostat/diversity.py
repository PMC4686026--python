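"""Molecular diversity indices and pairwise-distance summaries.

Gene diversity (h) is the probability that two individuals sampled without
replacement carry different haplotypes, estimated without bias as

    h = n (1 - sum_h p_h^2) / (n - 1)

with sampling variance

    V(h) = 2 / (n (n-1)) * { 2 (n-2) [ sum p^3 - (sum p^2)^2 ]
                             + sum p^2 - (sum p^2)^2 }.

Per-haplotype frequency standard deviations use the binomial form with an
n-1 denominator, sqrt(p (1-p) / (n-1)).

Distances between haplotypes come in two modes: ``identity`` (0 if same
haplotype, 1 otherwise) and ``pairwise_differences`` (number of alignment
columns at which the two profiles differ; a gap versus a base counts one
difference per column, gap versus gap counts none).  The mean pairwise
difference within a population under identity distances coincides exactly
with gene diversity h — a useful internal consistency check.

Nei's distance d between populations X and Y is the corrected average
pairwise difference, d = pi_XY - (pi_X + pi_Y) / 2.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeCatalog

MODES = ("identity", "pairwise_differences")


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyTable:
    """Per-haplotype counts, relative frequencies and sampling s.d."""

    names: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise DiversityError("negative haplotype counts")
        if self.n < 1:
            raise DiversityError("empty sample")

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.counts)

    @property
    def sd(self) -> tuple[float, ...]:
        """Binomial sampling s.d. of each frequency, denominator n-1."""
        n = self.n
        if n == 1:
            return tuple(0.0 for _ in self.counts)
        return tuple(
            math.sqrt(p * (1.0 - p) / (n - 1)) for p in self.frequencies
        )

    @property
    def n_haplotypes(self) -> int:
        """A: number of haplotypes actually observed (count > 0)."""
        return sum(1 for c in self.counts if c > 0)

    def to_frame(self, decimals: int = 4) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": self.names,
                "n": self.counts,
                "f": [round(p, decimals) for p in self.frequencies],
                "sd": [round(s, decimals) for s in self.sd],
            }
        )


@dataclass(frozen=True)
class DiversityResult:
    h: float
    sd: float
    n: int
    sum_p2: float
    sum_p3: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal haplotype distance matrix."""

    names: tuple[str, ...]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DiversityError(f"unknown distance mode {self.mode!r}")
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise DiversityError("matrix shape inconsistent with names")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise DiversityError("distance matrix must be symmetric with zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.names.index(pair[0])
        j = self.names.index(pair[1])
        return float(self.values[i, j])


def haplotype_frequencies(counts: Mapping[str, int]) -> FrequencyTable:
    """Tabulate counts into frequencies with sampling standard deviations."""
    names = tuple(counts)
    return FrequencyTable(names=names, counts=tuple(int(counts[n]) for n in names))


def gene_diversity(counts: Mapping[str, int] | Sequence[int]) -> DiversityResult:
    """Unbiased gene diversity and its sampling standard deviation."""
    values = (
        [int(v) for v in counts.values()]
        if isinstance(counts, Mapping)
        else [int(v) for v in counts]
    )
    if any(v < 0 for v in values):
        raise DiversityError("negative haplotype counts")
    n = sum(values)
    if n < 2:
        raise DiversityError("gene diversity requires n >= 2")
    p = [v / n for v in values]
    s2 = sum(x * x for x in p)
    s3 = sum(x ** 3 for x in p)
    h = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2 * s2) + s2 - s2 * s2
    )
    return DiversityResult(h=h, sd=math.sqrt(max(var, 0.0)), n=n, sum_p2=s2, sum_p3=s3)


def pairwise_difference_matrix(
    catalog: HaplotypeCatalog, mode: str = "pairwise_differences"
) -> DistanceMatrix:
    """Distance matrix over catalog haplotypes in the requested mode."""
    if mode not in MODES:
        raise DiversityError(f"unknown distance mode {mode!r}")
    if len(catalog) == 0:
        raise DiversityError("empty catalog")
    names = catalog.names
    k = len(names)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if mode == "identity":
                d = 1.0
            else:
                a, b = catalog.states[names[i]], catalog.states[names[j]]
                d = float(sum(x != y for x, y in zip(a, b)))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names=names, values=values, mode=mode)


def _counts_of(members: Iterable[str]) -> Counter:
    return Counter(members)


def mean_pairwise_within(members: Iterable[str], matrix: DistanceMatrix) -> float:
    """Mean distance over all unordered pairs of samples in one population."""
    counts = _counts_of(members)
    n = sum(counts.values())
    if n < 2:
        raise DiversityError("within-population mean requires n >= 2")
    idx = {name: i for i, name in enumerate(matrix.names)}
    total = 0.0
    haps = list(counts)
    for a_i, ha in enumerate(haps):
        for hb in haps[a_i + 1:]:
            total += counts[ha] * counts[hb] * matrix.values[idx[ha], idx[hb]]
    return total / (n * (n - 1) / 2)


def mean_pairwise_between(
    pop_x: Iterable[str], pop_y: Iterable[str], matrix: DistanceMatrix
) -> float:
    """Mean distance over all cross-population sample pairs (pi_XY)."""
    cx, cy = _counts_of(pop_x), _counts_of(pop_y)
    nx, ny = sum(cx.values()), sum(cy.values())
    if nx == 0 or ny == 0:
        raise DiversityError("both populations must be non-empty")
    idx = {name: i for i, name in enumerate(matrix.names)}
    total = sum(
        cx[ha] * cy[hb] * matrix.values[idx[ha], idx[hb]]
        for ha in cx for hb in cy
    )
    return total / (nx * ny)


def neis_distance(
    pop_x: Sequence[str], pop_y: Sequence[str], matrix: DistanceMatrix
) -> float:
    """Corrected average pairwise difference between two populations.

    A population compared with itself is at distance 0 (the diagonal
    convention of within/between distance tables).
    """
    if _counts_of(pop_x) == _counts_of(pop_y):
        return 0.0
    pi_xy = mean_pairwise_between(pop_x, pop_y, matrix)
    pi_x = mean_pairwise_within(pop_x, matrix)
    pi_y = mean_pairwise_within(pop_y, matrix)
    return pi_xy - (pi_x + pi_y) / 2.0


def nucleotide_diversity(
    members: Iterable[str], matrix: DistanceMatrix, n_columns: int
) -> float:
    """Per-site mean pairwise difference within a population."""
    if n_columns < 1:
        raise DiversityError("n_columns must be >= 1")
    if matrix.mode != "pairwise_differences":
        raise DiversityError("nucleotide diversity needs pairwise_differences mode")
    return mean_pairwise_within(members, matrix) / n_columns
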