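"""Exact small-sample rank statistics and descriptive summaries.

Figure-legend comparisons in this kind of study run on tiny groups
(n of 4-6 animals or electrodes), where the asymptotic normal
approximation to the Mann-Whitney U distribution is unreliable and the
printed p-values are exact-enumeration floors.  The test here enumerates
all group assignments whenever that is feasible and falls back to a
seeded Monte-Carlo permutation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import InputError

# Enumerating C(n1+n2, n1) assignments is exact but exponential; above
# this count the permutation path is used instead.
MAX_ENUMERATION = 200_000
DEFAULT_MC_DRAWS = 100_000


@dataclass(frozen=True)
class MWResult:
    """Outcome of a two-tailed Mann-Whitney rank-sum test.

    ``u_statistic`` is the U of the first sample (number of pairs (a, b)
    with a > b, counting ties as 1/2).  ``p_two_sided`` doubles the
    smaller exact tail probability and caps at 1, the convention that
    yields 2/C(n1+n2, n1) for tie-free complete separation.
    """

    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact_enumeration" | "permutation_mc"
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError("p outside (0, 1]")


@dataclass(frozen=True)
class SummaryStats:
    """Five-number summary plus mean, sample s.d. and s.e.m.

    For n = 1 the dispersion fields are NaN (undefined), never zero.
    Quantiles use linear interpolation between order statistics.
    """

    n: int
    min: float
    q25: float
    median: float
    q75: float
    max: float
    mean: float
    sd: float = field(default=math.nan)
    sem: float = field(default=math.nan)


def _u_statistic(pooled_ranks: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> float:
    r1 = float(pooled_ranks[idx_a].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_exact(
    a,
    b,
    *,
    method: str = "auto",
    n_permutations: int = DEFAULT_MC_DRAWS,
    seed: int | None = None,
    two_sided_rule: str = "double_tail",
) -> MWResult:
    """Two-tailed Mann-Whitney rank-sum test with exact enumeration.

    The U statistic always uses midranks.  With ``method="auto"``
    (default): when the pooled sample is tie-free and
    C(n1+n2, n1) <= ``MAX_ENUMERATION``, the null
    distribution of U is obtained by full enumeration of group
    assignments; otherwise a seeded Monte-Carlo permutation with
    ``n_permutations`` draws (including the observed assignment, so
    p >= 1/(n_permutations+1)) is used.

    ``two_sided_rule`` is ``"double_tail"`` (2 x min tail, capped at 1;
    default) or ``"u_distance"`` (probability of |U - n1*n2/2| at least
    as extreme as observed).

    Parameters
    ----------
    a, b : array-like
        The two samples; each must be non-empty.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise InputError("both groups must be non-empty")
    if two_sided_rule not in ("double_tail", "u_distance"):
        raise InputError(f"unknown two_sided_rule: {two_sided_rule!r}")
    if method not in ("auto", "exact", "mc"):
        raise InputError(f"unknown method: {method!r}")

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    idx_a = np.arange(n1)
    u_obs = _u_statistic(ranks, idx_a, n1, n2)

    has_ties = np.unique(pooled).size < pooled.size
    n_comb = math.comb(n1 + n2, n1)

    use_exact = not has_ties and n_comb <= MAX_ENUMERATION
    if method == "exact" and not use_exact:
        raise InputError("exact enumeration unavailable: ties present or "
                         "too many assignments")
    if method == "mc":
        use_exact = False
    if use_exact:
        u_null = np.empty(n_comb)
        for k, comb in enumerate(itertools.combinations(range(n1 + n2), n1)):
            u_null[k] = _u_statistic(ranks, np.asarray(comb), n1, n2)
        p = _two_sided_p(u_null, u_obs, n1 * n2, two_sided_rule)
        return MWResult(u_obs, n1, n2, p, "exact_enumeration")

    rng = np.random.default_rng(seed)
    u_null = np.empty(n_permutations + 1)
    u_null[0] = u_obs  # include the observed assignment
    perm = np.arange(n1 + n2)
    for k in range(1, n_permutations + 1):
        rng.shuffle(perm)
        u_null[k] = _u_statistic(ranks, perm[:n1], n1, n2)
    p = _two_sided_p(u_null, u_obs, n1 * n2, two_sided_rule)
    return MWResult(u_obs, n1, n2, p, "permutation_mc",
                    n_permutations=n_permutations, seed=seed)


def _two_sided_p(u_null: np.ndarray, u_obs: float, u_max: float, rule: str) -> float:
    eps = 1e-9
    n = u_null.size
    if rule == "double_tail":
        lo = np.count_nonzero(u_null <= u_obs + eps) / n
        hi = np.count_nonzero(u_null >= u_obs - eps) / n
        return min(1.0, 2.0 * min(lo, hi))
    d_obs = abs(u_obs - u_max / 2.0)
    return np.count_nonzero(np.abs(u_null - u_max / 2.0) >= d_obs - eps) / n


def summary_stats(values) -> SummaryStats:
    """Descriptive summary: five-number summary, mean, sd (n-1), sem."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise InputError("summary_stats requires at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    if x.size >= 2:
        sd = float(np.std(x, ddof=1))
        sem = sd / math.sqrt(x.size)
    else:
        sd = sem = math.nan
    return SummaryStats(
        n=int(x.size), min=float(x.min()), q25=float(q25), median=float(med),
        q75=float(q75), max=float(x.max()), mean=float(x.mean()), sd=sd, sem=sem,
    )
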