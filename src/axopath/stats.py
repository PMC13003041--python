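"""Statistical procedures applied to the pipeline's outputs.

Covers the rank-based sex comparison (Mann-Whitney U with midranks, tie
correction and continuity correction), the Shapiro-Wilk normality check,
two-way factorial ANOVA with Type II sums of squares, ANCOVA with a single
covariate, and the two-sample power/sample-size approximation used at the
design stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class TestResult:
    """One statistical test outcome with its reporting metadata."""

    method: str
    statistic_name: str
    statistic: float
    p_value: float | None = None
    df: tuple[float, ...] | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class AnovaSpec:
    """Two-way factorial model specification."""

    response: str
    factor_a: str = "group"
    factor_b: str = "sex"
    interaction: bool = True
    transform: str = "none"  # or "log"

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log"):
            raise ValueError("transform must be 'none' or 'log'")


# ---------------------------------------------------------------------------
# Mann-Whitney


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Exact two-sided p by enumeration of group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    ranks = sps.rankdata(pooled)
    count = 0
    total = 0
    u_obs_dev = abs(u - n_x * len(y) / 2)
    for idx in itertools.combinations(range(len(pooled)), n_x):
        r = ranks[list(idx)].sum()
        u_perm = r - n_x * (n_x + 1) / 2
        total += 1
        if abs(u_perm - n_x * len(y) / 2) >= u_obs_dev - 1e-12:
            count += 1
    return count / total


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Mann-Whitney U test with midranks for ties.

    U is computed for the first sample: U = R_x - n_x(n_x+1)/2, where R_x
    is the sum of midranks of x in the pooled sample.  The two-sided
    p-value uses the normal approximation with tie-corrected variance

        var(U) = n_x n_y [(N + 1) - sum(t^3 - t) / (N (N - 1))] / 12

    and a 0.5 continuity correction.  With ``method='exact'`` (or 'auto'
    on small untied samples, N <= 12) the p-value is computed by exhaustive
    enumeration instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    big_n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n_x].sum()
    u = r_x - n_x * (n_x + 1) / 2

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    notes: dict = {"ties": bool(has_ties)}
    if method == "exact" or (method == "auto" and not has_ties and big_n <= 12):
        p = _exact_mw_p(x, y, u)
        notes["p_method"] = "exact enumeration"
    else:
        mu = n_x * n_y / 2
        var = n_x * n_y / 12 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = 2 * sps.norm.sf(z)
        notes["p_method"] = "normal approximation, tie-corrected, continuity-corrected"
    return TestResult(
        method="Mann-Whitney U",
        statistic_name="U",
        statistic=float(u),
        p_value=float(min(p, 1.0)),
        df=None,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Shapiro-Wilk


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston's algorithm, 3 <= n <= 50)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError("shapiro_wilk requires 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    w, p = sps.shapiro(x)
    return TestResult(
        method="Shapiro-Wilk",
        statistic_name="W",
        statistic=float(w),
        p_value=float(p),
        notes={"n": int(x.size)},
    )


# ---------------------------------------------------------------------------
# factorial models


def two_way_anova(table: pd.DataFrame, spec: AnovaSpec) -> list[TestResult]:
    """Two-way factorial ANOVA with Type II sums of squares.

    Fits ``response ~ A * B`` (or ``A + B``) by least squares and reports
    F and p for each main effect and, when requested, the interaction.
    An optional log transform of the response is applied first and
    recorded in the result notes.
    """
    df = table.copy()
    resp = spec.response
    for fac in (spec.factor_a, spec.factor_b):
        levels = df[fac].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    counts = df.groupby([spec.factor_a, spec.factor_b]).size()
    full = pd.MultiIndex.from_product(
        [df[spec.factor_a].unique(), df[spec.factor_b].unique()]
    )
    missing = [c for c in full if c not in counts.index or counts[c] == 0]
    if missing:
        raise ValueError(f"empty design cell(s): {missing}")

    if spec.transform == "log":
        if (df[resp] <= 0).any():
            raise ValueError("log transform requires strictly positive response")
        df = df.assign(**{resp: np.log(df[resp])})

    op = "*" if spec.interaction else "+"
    formula = f"{resp} ~ C({spec.factor_a}) {op} C({spec.factor_b})"
    model = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)

    name_map = {
        f"C({spec.factor_a})": spec.factor_a,
        f"C({spec.factor_b})": spec.factor_b,
        f"C({spec.factor_a}):C({spec.factor_b})": f"{spec.factor_a}:{spec.factor_b}",
    }
    df_resid = float(aov.loc["Residual", "df"])
    results = []
    for row_name, effect in name_map.items():
        if row_name not in aov.index:
            continue
        f_val = float(aov.loc[row_name, "F"])
        p_val = float(aov.loc[row_name, "PR(>F)"])
        results.append(
            TestResult(
                method="two-way ANOVA (Type II SS)",
                statistic_name="F",
                statistic=f_val,
                p_value=p_val,
                df=(float(aov.loc[row_name, "df"]), df_resid),
                notes={"effect": effect, "transform": spec.transform},
            )
        )
    return results


def ancova(
    table: pd.DataFrame, response: str, group: str, covariate: str
) -> TestResult:
    """One-way ANCOVA: group effect adjusted for a numeric covariate.

    Fits ``response ~ group + covariate`` and reports the Type II F test
    of the group factor.
    """
    df = table.copy()
    cov = df[covariate].astype(float)
    if cov.nunique() <= 1:
        raise ValueError(f"covariate {covariate!r} is constant")
    if df.groupby(group)[covariate].nunique().le(1).all():
        raise ValueError(
            f"covariate {covariate!r} is constant within every level of {group!r}"
        )
    model = smf.ols(f"{response} ~ C({group}) + {covariate}", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    row = f"C({group})"
    return TestResult(
        method="ANCOVA",
        statistic_name="F",
        statistic=float(aov.loc[row, "F"]),
        p_value=float(aov.loc[row, "PR(>F)"]),
        df=(float(aov.loc[row, "df"]), float(aov.loc["Residual", "df"])),
        notes={"covariate": covariate},
    )


# ---------------------------------------------------------------------------
# power


def power_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.80
) -> dict:
    """Per-group n for a two-sample, two-sided comparison at effect size d.

    Normal approximation with a small-sample correction,

        n = 2 (z_{1-a/2} + z_{power})^2 / d^2 + z_{1-a/2}^2 / 4,

    rounded to the nearest integer; an exact solution based on the
    noncentral-t power of the two-sample t-test is reported alongside.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    n_approx = 2 * (z_a + z_b) ** 2 / d**2 + z_a**2 / 4

    def achieved_power(n: float) -> float:
        nu = 2 * (n - 1)
        if nu <= 0:
            return 0.0
        nc = d * np.sqrt(n / 2)
        t_crit = sps.t.ppf(1 - alpha / 2, nu)
        return float(sps.nct.sf(t_crit, nu, nc) + sps.nct.cdf(-t_crit, nu, nc))

    n_exact = 2.0
    while achieved_power(n_exact) < power and n_exact < 1e6:
        n_exact += 1
    return {
        "n_per_group": int(round(n_approx)),
        "n_approx": float(n_approx),
        "n_exact": int(n_exact),
        "achieved_power_exact": achieved_power(n_exact),
    }
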