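"""Sample coverage and rarefaction/extrapolation of species richness.

Inventory completeness is judged from the pooled abundance vector of a
species group. Sample coverage — the estimated fraction of total community
abundance belonging to species already detected — is the Chao–Jost
abundance-based estimator driven by singletons (f1) and doubletons (f2)::

    C_hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]

Coverage above 0.90 is conventionally read as an adequate inventory.
Richness is interpolated by classical hypergeometric rarefaction and
extrapolated beyond the sample with the Chao1-style estimate of the number
of undetected species (f0_hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ADEQUATE_COVERAGE = 0.90


@dataclass(frozen=True)
class CoverageResult:
    group: str
    n: int
    s_obs: int
    f1: int
    f2: int
    coverage: float
    adequate: bool
    curve: pd.DataFrame  # columns: m, richness, method


def _clean(x) -> np.ndarray:
    x = np.asarray(pd.Series(x).to_numpy(), dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty abundance vector")
    return np.round(x).astype(np.int64)


def sample_coverage(x) -> float:
    """Estimated sample coverage of a pooled abundance vector."""
    x = _clean(x)
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:  # n == 1: a single singleton, nothing is covered
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)


def _rarefy(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """E[S(m)] = sum_i 1 - P(species i absent from a subsample of size m)."""
    n = int(x.sum())
    # absence probability = hypergeom pmf of drawing 0 of the x_i individuals
    absent = stats.hypergeom.pmf(0, n, x[:, None], m[None, :])
    return (1.0 - absent).sum(axis=0)


def _f0_hat(n: int, f1: int, f2: int) -> float:
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def richness_curve(x, m_max: int | None = None, n_knots: int = 40) -> pd.DataFrame:
    """Rarefaction (m <= n) and extrapolation (m > n) of expected richness.

    ``m_max`` defaults to 2n. Returns a DataFrame of (m, richness, method)
    with the reference point m = n always included, where the curve equals
    the observed richness exactly.
    """
    x = _clean(x)
    n = int(x.sum())
    s_obs = len(x)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if m_max is None:
        m_max = 2 * n
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    grid = np.unique(np.clip(np.round(np.linspace(1, m_max, n_knots)), 1, m_max)).astype(int)
    if n <= m_max:
        grid = np.unique(np.concatenate([grid, [n]]))

    m_in = grid[grid <= n]
    m_out = grid[grid > n]
    rar = _rarefy(x, m_in)
    f0 = _f0_hat(n, f1, f2)
    if f0 > 0:
        mstar = (m_out - n).astype(float)
        ext = s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar)
    else:
        ext = np.full(m_out.shape, float(s_obs))
    return pd.DataFrame(
        {
            "m": np.concatenate([m_in, m_out]),
            "richness": np.concatenate([rar, ext]),
            "method": ["rarefaction" if m < n else "observed" for m in m_in]
            + ["extrapolation"] * len(m_out),
        }
    )


def coverage_result(x, group: str = "all", m_max: int | None = None) -> CoverageResult:
    """Bundle coverage, counts and the richness curve for one species group."""
    xc = _clean(x)
    n = int(xc.sum())
    cov = sample_coverage(xc)
    return CoverageResult(
        group=group,
        n=n,
        s_obs=len(xc),
        f1=int((xc == 1).sum()),
        f2=int((xc == 2).sum()),
        coverage=cov,
        adequate=cov > ADEQUATE_COVERAGE,
        curve=richness_curve(xc, m_max=m_max),
    )
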