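"""Frequentist spatial pattern tests: Moran's I, Oden's population-adjusted
I_pop, and the Pearson correlation used for between-period comparisons.

Weights are the binary adjacency matrix throughout (a row-standardised
option exists for Moran's I).  Inference is by randomisation: value
permutation for Moran's I, and conditional multinomial redistribution of
cases proportional to population for I_pop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .geography import Adjacency

__all__ = [
    "SpatialTestResult",
    "morans_i",
    "oden_ipop",
    "oden_ipop_bruteforce",
    "pearson_r",
]


@dataclass
class SpatialTestResult:
    statistic: float
    expectation: float
    p_value: float
    method: str                      # "permutation" | "normal-approx"
    n_permutations: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("statistic", "expectation", "p_value", "method",
                 "n_permutations", "seed")}


def _weights(values, adjacency: Adjacency, row_standardize: bool):
    w = adjacency.to_sparse().toarray().astype(float)
    if row_standardize:
        rs = w.sum(axis=1)
        rs[rs == 0] = 1.0
        w = w / rs[:, None]
    return w


def morans_i(values, adjacency: Adjacency, inference: str = "permutation",
             n_permutations: int = 9999, seed: int | None = None,
             row_standardize: bool = False) -> SpatialTestResult:
    """Global Moran's I with binary (optionally row-standardised) weights.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z`` the
    centred values.  The permutation p-value is the upper tail of the
    randomisation distribution (evidence of *positive* autocorrelation);
    the normal approximation uses the first two moments of I under
    randomisation and is one-sided to match.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least three units")
    if np.ptp(x) == 0:
        raise ValueError("values are constant; Moran's I undefined")
    w = _weights(values, adjacency, row_standardize)
    s0 = w.sum()
    z = x - x.mean()
    denom = float(z @ z)
    i_obs = n / s0 * float(z @ w @ z) / denom
    e_i = -1.0 / (n - 1)
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            i_p = n / s0 * float(zp @ w @ zp) / denom
            count += i_p >= i_obs
        p = (1.0 + count) / (n_permutations + 1.0)
        return SpatialTestResult(i_obs, e_i, p, "permutation",
                                 n_permutations, seed)
    elif inference == "normal":
        # moments of I under randomisation
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
        b2 = n * (z ** 4).sum() / denom ** 2
        var = ((n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
                - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
               / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2)) - e_i ** 2
        zscore = (i_obs - e_i) / np.sqrt(var)
        p = float(stats.norm.sf(zscore))
        return SpatialTestResult(i_obs, e_i, p, "normal-approx")
    raise ValueError("inference must be 'permutation' or 'normal'")


# ---------------------------------------------------------------------------
# Oden's I_pop
# ---------------------------------------------------------------------------

def _ipop_from_aggregates(cases, pops, w) -> float:
    """Closed-form I_pop: Moran's I of individual case indicators where two
    distinct individuals have weight w_ij of their regions, and individuals
    within the same region have weight 1."""
    x = np.asarray(cases, float)
    m = np.asarray(pops, float)
    bigx, bign = x.sum(), m.sum()
    b = bigx / bign
    z_sum = x - b * m                              # sum of z over region i
    z_sq = x * (1 - b) ** 2 + (m - x) * b ** 2     # sum of z^2 over region i
    w = np.asarray(w, float)
    cross = float(z_sum @ w @ z_sum)               # i != j regional pairs
    within = float((z_sum ** 2 - z_sq).sum())      # same region, k != l
    s0 = float(m @ w @ m) + float((m * (m - 1)).sum())
    denom = float(z_sq.sum())
    return bign / s0 * (cross + within) / denom


def oden_ipop(cases, populations, adjacency: Adjacency,
              n_permutations: int = 999,
              seed: int | None = None) -> SpatialTestResult:
    """Oden's population-adjusted spatial association statistic.

    Equivalent to computing plain Moran's I on the individual level, where
    every person carries a 0/1 case indicator, persons in neighbouring
    regions have weight 1 (the binary adjacency), and persons within the
    same region have weight 1; the aggregate closed form avoids the
    expansion.  Inference redistributes the observed case total across
    regions multinomially, proportional to population (conditional
    randomisation); the p-value is the upper tail.
    """
    x = np.asarray(cases, float)
    m = np.asarray(populations, float)
    if (m <= 0).any():
        raise ValueError("populations must be positive")
    if x.sum() < 1:
        raise ValueError("need at least one case")
    if ((x < 0) | (x > m)).any():
        raise ValueError("cases must lie in [0, population]")
    w = adjacency.to_sparse().toarray().astype(float)
    i_obs = _ipop_from_aggregates(x, m, w)
    rng = np.random.default_rng(seed)
    total = int(x.sum())
    probs = m / m.sum()
    count = 0
    for _ in range(n_permutations):
        xp = rng.multinomial(total, probs)
        # multinomial can exceed a region's population for tiny pops; clip
        xp = np.minimum(xp, m).astype(float)
        count += _ipop_from_aggregates(xp, m, w) >= i_obs
    p = (1.0 + count) / (n_permutations + 1.0)
    return SpatialTestResult(i_obs, 0.0, p, "permutation", n_permutations, seed)


def oden_ipop_bruteforce(cases, populations, adjacency: Adjacency) -> float:
    """Literal individual-level evaluation of I_pop, used as the oracle for
    the closed aggregate form: expand every region into its individuals and
    compute Moran's I over the expanded weight matrix."""
    x = np.asarray(cases, int)
    m = np.asarray(populations, int)
    w = adjacency.to_sparse().toarray().astype(float)
    region = np.repeat(np.arange(len(m)), m)
    y = np.concatenate([np.r_[np.ones(xi), np.zeros(mi - xi)]
                        for xi, mi in zip(x, m)])
    big_n = len(y)
    z = y - y.mean()
    a = w[np.ix_(region, region)]
    same = region[:, None] == region[None, :]
    a[same] = 1.0
    np.fill_diagonal(a, 0.0)
    s0 = a.sum()
    return float(big_n / s0 * (z @ a @ z) / (z @ z))


def pearson_r(x, y) -> float:
    """Product-moment correlation of two aligned per-unit vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
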