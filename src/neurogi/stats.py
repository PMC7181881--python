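"""Shared statistical routines.

Group comparisons in the downstream pipelines all funnel through here:
two-sided t-tests (from raw samples or from published mean/SEM/n summaries),
Fisher's exact test for 2x2 prevalence tables, Benjamini-Hochberg style FDR
adjustment, fold-change arithmetic, Kaplan-Meier / log-rank survival
comparison, and one-way ANOVA with Dunnett-type many-to-one comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "SurvivalRecord",
    "TestResult",
    "ttest_from_summary",
    "ttest_raw",
    "fisher_exact",
    "bh_adjust",
    "fold_change",
    "km_logrank",
    "anova_dunnett",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: mean, standard error of the mean, group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be a positive integer")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject in a survival experiment."""

    subject: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, ...] | None
    p: float
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Two-sided two-sample t-test from mean/SEM/n summaries.

    ``variant='pooled'`` is the classic Student test (equal variances,
    df = n_a + n_b - 2); ``'welch'`` uses Satterthwaite degrees of freedom.
    SDs are recovered from the SEMs as SEM * sqrt(n).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both groups")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue), f"t-{variant}")


def ttest_raw(x, y, variant: str = "pooled") -> TestResult:
    """Two-sided t-test on raw samples; mirrors :func:`ttest_from_summary`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in both groups")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
    return TestResult(float(res.statistic), df, float(res.pvalue), f"t-{variant}")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Two-sidedness by summing the probabilities of all tables (with the same
    margins) no more likely than the observed one.  A table with an all-zero
    margin has p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return TestResult(np.nan, None, 1.0, "fisher-exact")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), None, float(p), "fisher-exact")


def bh_adjust(pvalues, method: str = "bh"):
    """FDR step-up adjustment of a vector of p-values.

    ``method='bh'`` is classic Benjamini-Hochberg; ``'two-stage'`` is the
    Benjamini-Krieger-Yekutieli two-stage step-up (estimates the number of
    true nulls, then rescales).  Adjusted values are monotone and clipped
    at 1; output order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "two-stage": "fdr_tsbky"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=sm_method)[1]


def fold_change(a: GroupSummary | float, b: GroupSummary | float):
    """Ratio a/b and the corresponding percent change, 100*(ratio - 1)."""
    ma = a.mean if isinstance(a, GroupSummary) else float(a)
    mb = b.mean if isinstance(b, GroupSummary) else float(b)
    if mb == 0:
        raise ValueError("reference mean is zero; fold change undefined")
    ratio = ma / mb
    return ratio, 100.0 * (ratio - 1.0)


def km_logrank(records: list[SurvivalRecord]):
    """Kaplan-Meier curves, per-group median survival, and the Mantel-Cox test.

    Median survival follows the standard convention: the smallest observed
    time at which the product-limit estimate drops to <= 0.5 (inf if the
    curve never reaches 0.5).  Returns ``(curves, medians, TestResult)``
    where curves maps group -> DataFrame(time, survival).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if not records:
        raise ValueError("no survival records")
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [bool(r.event) for r in records],
            "group": [r.group for r in records],
        }
    )
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
        )
        medians[g] = float(kmf.median_survival_time_)
    a, b = groups
    da, db = df[df["group"] == a], df[df["group"] == b]
    lr = logrank_test(da["time"], db["time"], da["event"], db["event"])
    res = TestResult(float(lr.test_statistic), 1, float(lr.p_value), "logrank")
    return curves, medians, res


def anova_dunnett(
    groups,
    control: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> list[TestResult]:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control.

    Adjusted two-sided p-values come from a seeded Monte-Carlo sample of the
    joint null distribution of the correlated treatment-vs-control t
    statistics: p_adj_i = P(max_j |T_j| >= |t_i|) under H0.  The first
    returned entry is the ANOVA F test; the rest are the Dunnett comparisons
    in group order (control omitted), each carrying its unadjusted t-test p
    in ``extra['p_unadjusted']``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if not (0 <= control < len(arrs)):
        raise ValueError("control group index out of range")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")

    f_res = sps.f_oneway(*arrs)
    k = len(arrs)
    n_tot = sum(a.size for a in arrs)
    df_err = n_tot - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_err

    ctrl = arrs[control]
    others = [(i, a) for i, a in enumerate(arrs) if i != control]
    t_obs = np.array(
        [
            (a.mean() - ctrl.mean()) / np.sqrt(mse * (1 / a.size + 1 / ctrl.size))
            for _, a in others
        ]
    )

    # Null: T_j = Z_j / sqrt(W), Z ~ MVN(0, R) with the Dunnett correlation
    # structure, W ~ chi2(df_err)/df_err shared across comparisons.
    ns = np.array([a.size for _, a in others], dtype=float)
    n0 = float(ctrl.size)
    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_mc, len(others))) @ chol.T
    w = rng.chisquare(df_err, size=n_mc) / df_err
    max_abs_t = np.abs(z / np.sqrt(w)[:, None]).max(axis=1)

    out = [TestResult(float(f_res.statistic), (k - 1, df_err), float(f_res.pvalue), "anova-F")]
    for (i, a), t in zip(others, t_obs):
        p_adj = float((max_abs_t >= abs(t)).mean())
        p_raw = float(2 * sps.t.sf(abs(t), df_err))
        out.append(
            TestResult(
                float(t),
                df_err,
                min(1.0, p_adj),
                "dunnett-mc",
                extra={"group": i, "p_unadjusted": p_raw, "n_mc": n_mc, "seed": seed},
            )
        )
    return out
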