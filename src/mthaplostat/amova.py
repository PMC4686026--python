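"""One-level analysis of molecular variance (AMOVA) with a permutation test.

Total molecular variance is partitioned into an among-population component
(Va) and a within-population component (Vb) from pairwise distances between
individuals.  Distance-matrix entries are used directly as squared distances
(the convention of the classic molecular-data implementations), so with
identity distances the decomposition reduces to haplotype-frequency
variance and Fst coincides with the conventional fixation index.

With N samples in P populations of sizes N_p:

    SSD_total  = (1 / 2N)   * sum over all ordered sample pairs of delta
    SSD_within = sum_p (1 / 2N_p) * sum over ordered pairs within p of delta
    SSD_among  = SSD_total - SSD_within
    Vb  = SSD_within / (N - P)
    n'  = (N - sum_p N_p^2 / N) / (P - 1)
    Va  = (SSD_among / (P - 1) - Vb) / n'
    Fst = Va / (Va + Vb)

Significance is assessed by permuting individuals among populations
(sizes held fixed) and counting permuted Fst values at least as large as
the observed one: p = (1 + #{Fst* >= Fst_obs}) / (R + 1).

A negative Va (possible when populations are effectively undifferentiated)
is reported as computed, with a warning, so the sum-of-squares identities
remain exact.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import DistanceMatrix


class AmovaError(ValueError):
    pass


@dataclass(frozen=True)
class AmovaResult:
    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    va: float
    vb: float
    n_prime: float
    fst: float
    percent_among: float
    percent_within: float
    mode: str
    p_value: float | None = None

    def __post_init__(self) -> None:
        if abs(self.ssd_among + self.ssd_within - self.ssd_total) > 1e-9:
            raise AmovaError("sums of squares do not add up")


def _pair_sums(
    members: Sequence[str],
    populations: Sequence[str],
    matrix: DistanceMatrix,
) -> tuple[float, float, dict[str, int]]:
    """Ordered-pair distance sums: total, per-population-within, pop sizes.

    Works from haplotype counts per population rather than an N x N loop.
    """
    idx = {name: i for i, name in enumerate(matrix.names)}
    by_pop: dict[str, Counter] = defaultdict(Counter)
    for hap, pop in zip(members, populations):
        if hap not in idx:
            raise AmovaError(f"haplotype {hap!r} missing from distance matrix")
        by_pop[pop][hap] += 1

    def ordered_sum(counter: Counter) -> float:
        haps = list(counter)
        total = 0.0
        for ha in haps:
            for hb in haps:
                total += counter[ha] * counter[hb] * matrix.values[idx[ha], idx[hb]]
        return total

    pooled = Counter()
    for c in by_pop.values():
        pooled.update(c)
    sizes = {p: sum(c.values()) for p, c in by_pop.items()}
    total_pairs = ordered_sum(pooled)
    within = {p: ordered_sum(c) for p, c in by_pop.items()}
    n = sum(sizes.values())
    ssd_total = total_pairs / (2 * n)
    ssd_within = sum(within[p] / (2 * sizes[p]) for p in sizes)
    return ssd_total, ssd_within, sizes


def amova_one_level(
    members: Sequence[str],
    populations: Sequence[str],
    matrix: DistanceMatrix,
) -> AmovaResult:
    """Partition molecular variance among and within populations.

    ``members`` gives each sample's haplotype, ``populations`` its population
    label, in the same order.
    """
    if len(members) != len(populations):
        raise AmovaError("members and populations must have equal length")
    n = len(members)
    if n < 3:
        raise AmovaError("AMOVA requires at least 3 samples")
    pops = sorted(set(populations))
    if len(pops) < 2:
        raise AmovaError("AMOVA requires at least 2 populations")

    ssd_total, ssd_within, sizes = _pair_sums(members, populations, matrix)
    ssd_among = ssd_total - ssd_within
    p = len(pops)
    df_among, df_within = p - 1, n - p
    vb = ssd_within / df_within
    n_prime = (n - sum(s * s for s in sizes.values()) / n) / (p - 1)
    va = (ssd_among / df_among - vb) / n_prime
    if va < 0:
        warnings.warn(
            "negative among-population variance component (Va); reported as "
            "computed, Fst may be negative",
            stacklevel=2,
        )
    if va + vb == 0:
        raise AmovaError("Fst undefined: total variance is zero")
    fst = va / (va + vb)
    return AmovaResult(
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        ssd_total=ssd_total,
        df_among=df_among,
        df_within=df_within,
        va=va,
        vb=vb,
        n_prime=n_prime,
        fst=fst,
        percent_among=100.0 * va / (va + vb),
        percent_within=100.0 * vb / (va + vb),
        mode=matrix.mode,
    )


def permutation_test(
    observed: AmovaResult,
    members: Sequence[str],
    populations: Sequence[str],
    matrix: DistanceMatrix,
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the observed Fst.

    Population labels are reassigned to individuals uniformly at random
    (population sizes fixed) ``permutations`` times;
    p = (1 + #{Fst* >= Fst_observed}) / (permutations + 1).
    """
    if permutations < 1:
        raise AmovaError("at least one permutation is required")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    members = list(members)
    labels = np.asarray(populations)
    exceed = 0
    for _ in range(permutations):
        permuted = labels[rng.permutation(len(labels))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # negative Va is routine here
                fst_star = amova_one_level(members, list(permuted), matrix).fst
        except AmovaError:
            continue  # degenerate permutation: no variance; cannot exceed
        if fst_star >= observed.fst:
            exceed += 1
    return (1 + exceed) / (permutations + 1)
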