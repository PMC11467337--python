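"""Nonparametric group comparison of morphometric parameters.

Each cell (HT image) is one observation; the two genotype groups are compared
per parameter with the Mann-Whitney U test, and significance is reported in
the three-tier star convention used throughout this analysis:

    *    P < 0.01
    **   P < 0.001
    ***  P < 0.0001

P-values are two-sided.  For small samples (n1 + n2 <= 20) the exact
permutation distribution of U is enumerated (midranks make this correct under
ties); larger samples use the normal approximation with tie and continuity
corrections.  No multiple-testing correction is applied, and observations are
pooled across patients without a clustering adjustment, mirroring the
original per-cell analysis; both caveats are deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["MannWhitneyResult", "GroupComparison", "mann_whitney_u",
           "significance_tier", "compare_groups", "EXACT_LIMIT"]

#: Largest pooled sample size for which the exact permutation null is used.
EXACT_LIMIT = 20


@dataclass
class MannWhitneyResult:
    u: float                 # U statistic of the first sample
    p_value: float           # two-sided
    method: str              # "exact" or "normal"
    degenerate: bool = False  # all pooled values identical


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact P over all C(n, n1) group assignments.

    Works on midranks, so tied pooled values are handled exactly.  Midranks
    are doubled to integers and the permutation distribution of the rank sum
    is counted by dynamic programming over (items taken, rank sum) -- the
    exact multiset-subset count, equivalent to full enumeration.  The
    two-sided P doubles the smaller tail (capped at 1), matching the usual
    convention for the exact test.
    """
    n = len(ranks)
    r2 = np.rint(2.0 * np.asarray(ranks)).astype(np.int64)  # doubled midranks
    total = int(r2.sum())
    # dp[k, s] = number of n1-free subsets of size k with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        kmax = n1
        dp[1:kmax + 1, r:] += dp[0:kmax, : total + 1 - r]
    counts = dp[n1]  # distribution of doubled rank sums over C(n, n1) subsets
    m = counts.sum()
    u2 = 2.0 * (u_obs + n1 * (n1 + 1) / 2.0)  # doubled rank sum of the sample
    sums = np.arange(total + 1)
    lo = counts[sums <= u2 + 1e-9].sum() / m
    hi = counts[sums >= u2 - 1e-9].sum() / m
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns the U statistic of ``x`` (in [0, n1*n2]) and a two-sided P.
    A degenerate comparison (every pooled value identical) returns P = 1 with
    the ``degenerate`` flag set rather than dividing by a zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)

    if n1 + n2 <= EXACT_LIMIT:
        p = _exact_p(rankdata(pooled), n1, u)
        return MannWhitneyResult(u=u, p_value=p, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return MannWhitneyResult(u=u, p_value=p, method="normal")


def significance_tier(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    parameter: str
    n_wt: int
    n_mut: int
    mean_wt: float
    sd_wt: float
    mean_mut: float
    sd_mut: float
    u: float
    p_value: float
    tier: str
    method: str


def compare_groups(morpho, genotypes, parameters=None) -> "object":
    """Per-parameter WT-vs-MUT comparison table.

    Parameters
    ----------
    morpho
        DataFrame of per-cell morphometric parameters (rows align with
        ``genotypes``).
    genotypes
        Sequence of "WT"/"MUT" labels, one per row of ``morpho``.
    parameters
        Column subset to compare; defaults to all numeric columns.

    Returns a DataFrame with one row per parameter (means +- SD per group,
    U, two-sided P, significance tier).
    """
    import pandas as pd

    genotypes = np.asarray(genotypes)
    if len(genotypes) != len(morpho):
        raise ValueError("genotype labels must align with the morphometry table")
    if parameters is None:
        parameters = [c for c in morpho.columns if np.issubdtype(morpho[c].dtype, np.number)]
    rows = []
    for param in parameters:
        vals = morpho[param].to_numpy(dtype=np.float64)
        keep = np.isfinite(vals)
        wt = vals[keep & (genotypes == "WT")]
        mut = vals[keep & (genotypes == "MUT")]
        if len(wt) == 0 or len(mut) == 0:
            raise ValueError(f"parameter {param!r}: one of the groups is empty")
        res = mann_whitney_u(wt, mut)
        rows.append(GroupComparison(
            parameter=param, n_wt=len(wt), n_mut=len(mut),
            mean_wt=float(wt.mean()), sd_wt=float(wt.std(ddof=1)) if len(wt) > 1 else 0.0,
            mean_mut=float(mut.mean()), sd_mut=float(mut.std(ddof=1)) if len(mut) > 1 else 0.0,
            u=res.u, p_value=res.p_value, tier=significance_tier(res.p_value),
            method=res.method,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def swarm_plot(morpho, genotypes, parameter, ax=None):
    """Per-cell swarm/strip chart of one parameter by genotype (convenience)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    import pandas as pd

    df = pd.DataFrame({"value": morpho[parameter], "genotype": list(genotypes)})
    for i, g in enumerate(("WT", "MUT")):
        v = df.loc[df.genotype == g, "value"].dropna()
        jitter = (np.random.default_rng(0).random(len(v)) - 0.5) * 0.6
        ax.plot(i + jitter, v, ".", ms=2, alpha=0.5)
        ax.errorbar([i + 0.4], [v.mean()], yerr=[v.std()], fmt="o", color="k", ms=4)
    ax.set_xticks([0, 1], ["WT", "MUT"])
    ax.set_ylabel(parameter)
    return ax
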