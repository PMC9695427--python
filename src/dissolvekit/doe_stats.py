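"""Statistics for the dissolution/discoloration experiments.

Group summaries, one-way ANOVA with Tukey HSD post hoc comparisons,
fixed-effects factorial screening with chosen two-way interactions, the
pooled two-sample t-test, cell-mean response matrices, and the impeller
Reynolds-number scale-up rule for rotor speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "AnovaTukeyResult",
    "TTestResult",
    "group_summary",
    "anova_tukey",
    "factorial_effects",
    "ttest_two_sample",
    "cell_mean_matrix",
    "reynolds_speed_factor",
    "DEFAULT_INTERACTIONS",
]

logger = logging.getLogger(__name__)

#: two-way interactions screened by default in the factorial model
DEFAULT_INTERACTIONS = (("particle_class", "viscosity_mPas"),
                        ("rpm", "viscosity_mPas"))


@dataclass
class GroupData:
    """Replicate measurements for one labelled group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a nonempty 1-D array")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    df_between: int
    df_within: int
    alpha: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, p_adj, significant

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class TTestResult:
    t: float
    dof: int
    p: float


def group_summary(groups: list[GroupData]) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per group; SD is missing
    (NaN) for single-replicate groups."""
    rows = []
    for g in groups:
        rows.append({
            "group": g.label,
            "n": g.n,
            "mean": float(g.values.mean()),
            "sd": float(g.values.std(ddof=1)) if g.n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def anova_tukey(groups: list[GroupData], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA followed by Tukey HSD pairwise tests.

    Equal within-group variance is assumed (not tested). Family-wise
    error across all pairs is controlled at ``alpha`` by the studentized
    range distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has n < 2")
    samples = [g.values for g in groups]
    f, p = stats.f_oneway(*samples)
    k = len(groups)
    n_total = sum(g.n for g in groups)
    # identical groups -> 0/0; define F = 0, p = 1 (no evidence of effect)
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            p_adj = float(hsd.pvalue[i, j])
            if not np.isfinite(p_adj):
                p_adj = 1.0
            rows.append({
                "group_a": groups[i].label,
                "group_b": groups[j].label,
                "diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            })
    return AnovaTukeyResult(f=float(f), p=float(p), df_between=k - 1,
                            df_within=n_total - k, alpha=alpha,
                            pairwise=pd.DataFrame(rows))


def _check_cells(design: pd.DataFrame, pairs) -> None:
    missing = []
    for a, b in pairs:
        la, lb = design[a].unique(), design[b].unique()
        counts = design.groupby([a, b]).size()
        for va in la:
            for vb in lb:
                if (va, vb) not in counts.index:
                    missing.append(f"{a}={va!r} x {b}={vb!r}")
    if missing:
        raise ValueError("empty design cells for requested interaction terms: "
                         + "; ".join(missing))


def factorial_effects(design: pd.DataFrame,
                      response: str = "response_s",
                      factors: list[str] | None = None,
                      interactions=DEFAULT_INTERACTIONS,
                      alpha: float = 0.05) -> pd.DataFrame:
    """F-tests for factor main effects and chosen two-way interactions.

    Fits a fixed-effects linear model with every factor treated as
    categorical, then performs type-II ANOVA per term. Rows flagged
    ``censored`` are excluded (with a logged count). Returns a table
    with columns term, F, df1, df2, p, significant.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = design.copy()
    if "censored" in df.columns:
        n_censored = int(df["censored"].astype(bool).sum())
        if n_censored:
            logger.info("excluding %d censored runs from factorial analysis", n_censored)
        df = df[~df["censored"].astype(bool)]
    if factors is None:
        factors = [c for c in df.columns if c not in (response, "censored")]
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"unknown factor {f!r}")
    if response not in df.columns:
        raise ValueError(f"unknown response column {response!r}")

    interactions = [tuple(p) for p in interactions
                    if p[0] in factors and p[1] in factors]
    _check_cells(df, interactions)

    # statsmodels formulas dislike arbitrary column names only mildly;
    # use Q() quoting to be safe.
    def q(name: str) -> str:
        return f'C(Q("{name}"))'

    terms = [q(f) for f in factors] + [f"{q(a)}:{q(b)}" for a, b in interactions]
    formula = f'Q("{response}") ~ ' + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()

    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom: add replicates "
                         "or drop terms")

    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(model, typ=2)

    label_map = {q(f): f for f in factors}
    label_map.update({f"{q(a)}:{q(b)}": f"{a}:{b}" for a, b in interactions})
    rows = []
    resid_ss = float(table.loc["Residual", "sum_sq"])
    df2 = int(table.loc["Residual", "df"])
    for term_label, term_name in label_map.items():
        ss = float(table.loc[term_label, "sum_sq"])
        df1 = int(table.loc[term_label, "df"])
        F = float(table.loc[term_label, "F"])
        p = float(table.loc[term_label, "PR(>F)"])
        if not np.isfinite(F):
            # zero residual variance: an exactly-zero effect SS is no
            # evidence; a positive one is exact determination
            if ss <= 1e-12:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
        rows.append({"term": term_name, "F": F, "df1": df1, "df2": df2,
                     "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def ttest_two_sample(a: GroupData, b: GroupData,
                     two_sided: bool = True) -> TTestResult:
    """Classical pooled-variance (equal-variance) Student's t-test.

    With zero pooled variance: equal means give p = 1; unequal means are
    declared significant by convention (t = +/-inf, p = 0).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    dof = a.n + b.n - 2
    pooled = ((a.n - 1) * a.values.var(ddof=1)
              + (b.n - 1) * b.values.var(ddof=1)) / dof
    dmean = a.values.mean() - b.values.mean()
    if pooled == 0:
        if dmean == 0:
            return TTestResult(t=0.0, dof=dof, p=1.0)
        return TTestResult(t=float(np.sign(dmean) * np.inf), dof=dof, p=0.0)
    se = np.sqrt(pooled * (1 / a.n + 1 / b.n))
    t = dmean / se
    p = 2 * stats.t.sf(abs(t), dof) if two_sided else stats.t.sf(t, dof)
    return TTestResult(t=float(t), dof=dof, p=float(p))


def cell_mean_matrix(design: pd.DataFrame, factor_a: str, factor_b: str,
                     response: str = "response_s") -> pd.DataFrame:
    """Mean response per (factor_a level, factor_b level) cell,
    marginalized over all other factors. Empty cells are NaN."""
    for f in (factor_a, factor_b, response):
        if f not in design.columns:
            raise ValueError(f"unknown column {f!r}")
    df = design
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    return df.pivot_table(index=factor_a, columns=factor_b, values=response,
                          aggfunc="mean", dropna=False)


def reynolds_speed_factor(diameter_ratio: float) -> float:
    """Rotor-speed multiplier keeping the impeller Reynolds number
    constant under a vessel-diameter change.

    Re is proportional to N * D^2 at fixed fluid properties, so an
    inner-diameter ratio r requires an r**2-fold speed change (a
    four-fold diameter increase needs 16x the rotor speed).
    """
    if not diameter_ratio > 0:
        raise ValueError("diameter ratio must be positive")
    return float(diameter_ratio) ** 2
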