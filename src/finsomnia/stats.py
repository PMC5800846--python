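"""Group statistics: two-group tests, factorial ANOVA, Holm-Sidak, regression.

The analysis layer of the study design: per-fish metrics are compared between
two populations (surface vs cave morph) crossed with a treatment factor.
The factorial model is a two-way ANOVA of ``response ~ population * treatment``;
with unbalanced cells, partial (Type-III-style) sums of squares under
sum-to-zero contrasts are used, reducing to the textbook balanced
decomposition when cell sizes are equal.  Families of post-hoc comparisons
are corrected with the Holm-Sidak step-down procedure.  Two-sided tests
throughout, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class StatResult:
    effect: str
    statistic: float
    df: tuple  # (df1,) for t; (df1, df2) for F
    p_raw: float
    p_adjusted: float | None = None
    estimate: float | None = None
    ci: tuple | None = None
    n: int | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    stderr: float | None = None


def two_group_test(a, b, method: str = "t_unpaired") -> StatResult:
    """Two-sided two-group test.

    ``t_unpaired`` is the classical pooled-variance t test;
    ``rank_nonparametric`` is the two-sample rank-sum test with normal
    approximation and tie correction (the statistic reported is the
    standardized rank sum z, so swapping the groups negates it).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite responses")
    n = a.size + b.size

    if method == "t_unpaired":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return StatResult("t_unpaired", 0.0, (n - 2,), 1.0,
                                  estimate=0.0, n=n)
            sign = 1.0 if a.mean() > b.mean() else -1.0
            return StatResult("t_unpaired", sign * np.inf, (n - 2,), 0.0,
                              estimate=float(a.mean() - b.mean()), n=n)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        diff = float(a.mean() - b.mean())
        se = diff / t if t != 0 else np.nan
        tcrit = sps.t.ppf(0.975, n - 2)
        ci = (diff - tcrit * se, diff + tcrit * se) if np.isfinite(se) else None
        return StatResult("t_unpaired", float(t), (n - 2,), float(p),
                          estimate=diff, ci=ci, n=n)

    if method == "rank_nonparametric":
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            return StatResult("rank_nonparametric", 0.0, (n,), 1.0, n=n)
        n1, n2 = a.size, b.size
        ranks = sps.rankdata(pooled)
        r1 = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        # tie-corrected variance of the rank sum
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / ((n1 + n2) * (n1 + n2 - 1))
        var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
        z = (r1 - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        return StatResult("rank_nonparametric", float(z), (n,), min(p, 1.0), n=n)

    raise ValidationError(f"unknown method {method!r}")


def _validate_design(df, response, factor_a, factor_b):
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ValidationError(f"design missing column {col!r}")
    if not np.all(np.isfinite(df[response].to_numpy(dtype=float))):
        raise ValidationError("non-finite responses in design")
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValidationError("each factor needs >= 2 levels")
    expected = df[factor_a].nunique() * df[factor_b].nunique()
    if len(cells) < expected:
        raise ValidationError("every factor-level cell must be non-empty")
    if cells.min() < 2:
        raise ValidationError(
            "a cell with n=1 leaves no within-cell error for the interaction"
        )


def two_way_anova(
    design: pd.DataFrame,
    response: str = "response",
    factor_a: str = "population",
    factor_b: str = "treatment",
) -> list[StatResult]:
    """Two-way factorial ANOVA; returns [factor_a, factor_b, interaction].

    Partial (each-effect-adjusted-for-all-others) sums of squares under
    sum-to-zero contrasts, equal to the classical balanced decomposition
    when cells are equal-sized.
    """
    df = design.copy()
    _validate_design(df, response, factor_a, factor_b)
    df = df.rename(columns={response: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa, Sum) * C(_fb, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    mapping = {
        "C(_fa, Sum)": factor_a,
        "C(_fb, Sum)": factor_b,
        "C(_fa, Sum):C(_fb, Sum)": f"{factor_a}:{factor_b}",
    }
    df_resid = float(table.loc["Residual", "df"])
    out = []
    for key, name in mapping.items():
        row = table.loc[key]
        out.append(
            StatResult(
                effect=name,
                statistic=float(row["F"]),
                df=(int(row["df"]), int(df_resid)),
                p_raw=float(row["PR(>F)"]),
                n=len(df),
            )
        )
    return out


def holm_sidak(p_raw) -> np.ndarray:
    """Holm-Sidak step-down adjusted p values, returned in input order.

    Sort ascending, ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)``, enforce
    monotone non-decreasing, cap at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def regress_sleep_on_cells(cells, sleep) -> RegressionResult:
    """OLS of a sleep metric on the number of (silenced) cells per fish."""
    x = np.asarray(cells, dtype=float)
    y = np.asarray(sleep, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("regression needs n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor: cell counts all equal")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=int(x.size),
        stderr=float(res.stderr),
    )


def pairwise_contrasts(
    df: pd.DataFrame,
    metric: str,
    contrasts: list,
    method: str = "t_unpaired",
    group_cols: tuple = ("population", "treatment"),
) -> pd.DataFrame:
    """Run an explicit family of two-group contrasts with Holm-Sidak correction.

    ``contrasts`` is a list of ``(selector_a, selector_b)`` where each
    selector is a dict of column -> value (e.g. ``{"population": "cavefish",
    "treatment": "control"}``).  The comparison family is exactly the list
    given; no contrasts are inferred.
    """

    def select(sel):
        mask = np.ones(len(df), dtype=bool)
        for col, val in sel.items():
            mask &= df[col].to_numpy() == val
        return df.loc[mask, metric].to_numpy(dtype=float)

    rows = []
    for sel_a, sel_b in contrasts:
        res = two_group_test(select(sel_a), select(sel_b), method=method)
        rows.append(
            {
                "metric": metric,
                "group_a": "/".join(str(sel_a[c]) for c in sel_a),
                "group_b": "/".join(str(sel_b[c]) for c in sel_b),
                "statistic": res.statistic,
                "df": res.df[0],
                "p_raw": res.p_raw,
                "n": res.n,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = holm_sidak(out["p_raw"].to_numpy())
    return out


def anova_table(results: list[StatResult]) -> pd.DataFrame:
    """Tidy effects table (effect, F, df1, df2, p_raw, p_adj)."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "df1": r.df[0],
                "df2": r.df[1] if len(r.df) > 1 else np.nan,
                "p_raw": r.p_raw,
                "p_adj": r.p_adjusted if r.p_adjusted is not None else np.nan,
            }
            for r in results
        ]
    )
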