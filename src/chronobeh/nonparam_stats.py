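"""Rank-based statistics: Kruskal-Wallis, Scheirer-Ray-Hare, Conover-style
LSD post hoc, Mann-Whitney, and a Kolmogorov-Smirnov normality check.

All tests use mid-ranks for ties.  Tie correction enters the Kruskal-Wallis
and Scheirer-Ray-Hare statistics through the total mean square computed
from the actual mid-ranks (exact under ties) rather than the no-tie
closed form N(N+1)/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st


@dataclass
class RankTestResult:
    """One test result: statistic, degrees of freedom, p value."""

    test: str
    effect: str
    statistic: float
    df: int
    p: float
    n: tuple = ()
    tie_correction: float = 1.0

    def __post_init__(self):
        if self.statistic < -1e-12:
            raise ValueError("statistic must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "effect": self.effect,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "n": ",".join(str(k) for k in self.n),
        }


def midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    return _st.rankdata(np.asarray(x, float), method="average")


def _tie_factor(ranks: np.ndarray) -> float:
    """Classical tie correction 1 - sum(t^3 - t)/(N^3 - N)."""
    n = ranks.size
    if n < 2:
        return 1.0
    _, counts = np.unique(ranks, return_counts=True)
    denom = n**3 - n
    return 1.0 - float(((counts**3 - counts).sum()) / denom) if denom else 1.0


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H test over k independent groups.

    H = (12 / (N(N+1))) * sum n_i (Rbar_i - Rbar)^2, divided by the tie
    correction factor; p from chi-square with k-1 df.  All-identical data
    give H = 0, p = 1.
    """
    groups = [np.asarray(list(g), float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [g.size for g in groups]
    if min(sizes) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = midranks(pooled)
    rbar = (n + 1) / 2.0
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + g.size]
        h += g.size * (r.mean() - rbar) ** 2
        i += g.size
    h *= 12.0 / (n * (n + 1))
    tie = _tie_factor(ranks)
    if tie <= 0:  # every observation identical
        return RankTestResult("kruskal_wallis", "group", 0.0, len(groups) - 1, 1.0, tuple(sizes), 0.0)
    h /= tie
    df = len(groups) - 1
    p = float(_st.chi2.sf(h, df))
    return RankTestResult("kruskal_wallis", "group", float(h), df, p, tuple(sizes), tie)


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare two-way rank test
# ---------------------------------------------------------------------------

def _type2_ss(ranks, a_codes, b_codes):
    """Type-II sums of squares of a two-way layout computed on ranks via
    nested least-squares model comparisons (reduces to the classical
    balanced decomposition when cells are balanced)."""

    def design(cols):
        return np.column_stack(cols) if cols else np.ones((ranks.size, 1))

    def dummies(codes):
        levels = np.unique(codes)
        return [np.asarray(codes == l, float) for l in levels[1:]]

    def rss(X):
        beta, res, rank, _ = np.linalg.lstsq(X, ranks, rcond=None)
        fitted = X @ beta
        return float(((ranks - fitted) ** 2).sum())

    one = [np.ones(ranks.size)]
    da, db = dummies(a_codes), dummies(b_codes)
    dab = [xa * xb for xa in da for xb in db]
    rss_ab = rss(design(one + da + db))
    rss_a = rss(design(one + da))
    rss_b = rss(design(one + db))
    rss_full = rss(design(one + da + db + dab))
    ss_a = rss_b - rss_ab  # A adjusted for B
    ss_b = rss_a - rss_ab  # B adjusted for A
    ss_ab = rss_ab - rss_full
    return ss_a, ss_b, ss_ab


def scheirer_ray_hare(values, factor_a, factor_b) -> dict:
    """Scheirer-Ray-Hare rank test for a two-factor crossed design.

    All N observations are mid-ranked jointly; two-way ANOVA sums of
    squares are computed on the ranks; each effect's statistic is
    H = SS_effect / MS_total with MS_total = SS_total/(N-1) (the variance
    of the ranks, which embodies the tie correction), referred to
    chi-square with the effect's ANOVA degrees of freedom.  Unbalanced
    designs use Type-II sums of squares on the ranks.

    Returns ``{"factor_a": RankTestResult, "factor_b": ..., "interaction": ...}``.
    """
    values = np.asarray(list(values), float)
    a = np.asarray(list(factor_a))
    b = np.asarray(list(factor_b))
    if not (values.size == a.size == b.size):
        raise ValueError("values and factors must have equal length")
    la, lb = np.unique(a), np.unique(b)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    for ai in la:
        for bi in lb:
            if not np.any((a == ai) & (b == bi)):
                raise ValueError(f"empty cell ({ai!r}, {bi!r})")
    n = values.size
    ranks = midranks(values)
    ms_total = float(np.var(ranks, ddof=1))
    names = ("factor_a", "factor_b", "interaction")
    dfs = (la.size - 1, lb.size - 1, (la.size - 1) * (lb.size - 1))
    if ms_total == 0.0:  # constant data
        return {
            nm: RankTestResult("scheirer_ray_hare", nm, 0.0, d, 1.0, (n,), 0.0)
            for nm, d in zip(names, dfs)
        }
    ss = _type2_ss(ranks, a, b)
    out = {}
    tie = _tie_factor(ranks)
    for nm, s, d in zip(names, ss, dfs):
        h = max(s, 0.0) / ms_total
        out[nm] = RankTestResult(
            "scheirer_ray_hare", nm, float(h), d, float(_st.chi2.sf(h, d)), (n,), tie
        )
    return out


# ---------------------------------------------------------------------------
# post hoc comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    group_i: object
    group_j: object
    statistic: float
    df: int
    p: float
    significant: bool
    marker: str = ""


def lsd_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence] = None,
    alpha: float = 0.05,
    omnibus: Optional[RankTestResult] = None,
    control_label=None,
    high_label=None,
) -> list:
    """Fisher-LSD-style pairwise comparisons on ranks (Conover-Iman).

    t statistics are built from rank means with a pooled rank variance
    adjusted for the omnibus H; p values are unadjusted, and all pairs are
    declared non-significant when the omnibus test is itself
    non-significant (omnibus gating).  ``marker`` carries the reporting
    convention: ``*`` vs the control group, ``#`` vs the highest-dose
    group.
    """
    groups = [np.asarray(list(g), float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = list(range(k))
    if omnibus is None:
        omnibus = kruskal_wallis(groups)
    gate_open = omnibus.p < alpha
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = midranks(pooled)
    rank_groups = []
    i = 0
    for g in groups:
        rank_groups.append(ranks[i : i + g.size])
        i += g.size
    h = omnibus.statistic
    df = n - k
    # Conover-Iman pooled variance of ranks given the omnibus statistic
    s2 = float(np.var(ranks, ddof=1))
    factor = s2 * (n - 1 - h) / df if df > 0 else np.nan
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            ri, rj = rank_groups[i], rank_groups[j]
            se = np.sqrt(factor * (1.0 / ri.size + 1.0 / rj.size))
            t = (ri.mean() - rj.mean()) / se if se > 0 else 0.0
            p = float(2 * _st.t.sf(abs(t), df)) if df > 0 else 1.0
            sig = bool(gate_open and p < alpha)
            marker = ""
            if sig and control_label is not None and control_label in (labels[i], labels[j]):
                marker += "*"
            if sig and high_label is not None and high_label in (labels[i], labels[j]):
                marker += "#"
            out.append(
                PairwiseComparison(labels[i], labels[j], float(t), df, p, sig, marker)
            )
    return out


# ---------------------------------------------------------------------------
# two-sample and normality tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> RankTestResult:
    """Mann-Whitney U with mid-rank ties and the tie-corrected normal
    approximation.  The reported statistic is U for the first sample."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    ranks = midranks(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        p = 1.0
    else:
        z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(var)  # continuity corrected
        p = float(2 * _st.norm.sf(abs(z)))
    return RankTestResult("mann_whitney", "group", float(u1), 1, min(p, 1.0), (n1, n2))


def ks_normality(x) -> RankTestResult:
    """Kolmogorov-Smirnov test against a normal with moments estimated
    from the sample.

    Caveat: estimating the moments from the same sample makes the classical
    KS p value conservative (the Lilliefors situation); the p value is
    reported as the classical KS tail all the same, mirroring common
    statistical-package behaviour.
    """
    x = np.asarray(list(x), float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test is degenerate")
    d, p = _st.kstest(x, "norm", args=(x.mean(), sd))
    return RankTestResult("ks_normality", "sample", float(d), 1, float(p), (x.size,))


def results_to_frame(results) -> pd.DataFrame:
    """Flatten RankTestResults (or dicts of them) into a tidy table."""
    rows = []
    for r in results:
        if isinstance(r, dict):
            rows.extend(v.to_row() for v in r.values())
        else:
            rows.append(r.to_row())
    return pd.DataFrame(rows)
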