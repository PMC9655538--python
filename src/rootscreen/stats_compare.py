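"""Treatment-comparison statistics: per-timepoint two-sample t-tests,
two-way (microbe × temperature) ANOVA, trendline fits and mean ± SE curves.

The per-day comparison is the classical equal-variance two-tailed Student
t-test (Welch available via a flag); the factorial analysis is a
fixed-effects two-way ANOVA with interaction, either per imaging day or
over the whole period with DAI as an additive fixed block.  No
multiple-testing correction is applied by default (only raw p < 0.05 is
interpreted); Benjamini–Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .plate_core import TreatmentLabel

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "TrendFit",
    "ttest_groups",
    "ttest_per_timepoint",
    "two_way_anova",
    "fit_trend",
    "summarize_treatment_curves",
    "adjust_bh",
    "add_factor_columns",
]


@dataclass(frozen=True)
class ComparisonResult:
    trait: str
    dai: int | None
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    scope: str  # "dai=<d>" or "whole_period"
    effects: dict  # name -> {"F": float, "df": (num, den), "p": float}

    def p(self, name: str) -> float:
        return self.effects[name]["p"]


@dataclass(frozen=True)
class TrendFit:
    x_trait: str
    y_trait: str
    group: str | None
    model: str  # "exponential" or "polynomial"
    coefficients: tuple
    r_squared: float
    r_squared_scale: str  # "log" for exponential, "original" for polynomial


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def ttest_groups(
    a: np.ndarray,
    b: np.ndarray,
    trait: str = "",
    dai: int | None = None,
    group_a: str = "a",
    group_b: str = "b",
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample two-tailed t-test; equal-variance (Student) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 observations per group (got {len(a)}, {len(b)})")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return ComparisonResult(
        trait=trait, dai=dai, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        se_a=_se(a), se_b=_se(b),
        t_statistic=float(t), p_value=float(p), alpha=alpha,
    )


def add_factor_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Derive ``temperature`` and ``inoculation`` factor columns from the
    ``treatment`` name column (Amb-Ctl, Amb-PsJN, HT-Ctl, HT-PsJN)."""
    out = table.copy()
    labels = {n: TreatmentLabel.from_name(n) for n in out["treatment"].unique()}
    out["temperature"] = out["treatment"].map(
        lambda n: labels[n].temperature.value)
    out["inoculation"] = out["treatment"].map(
        lambda n: labels[n].inoculation.value)
    return out


def ttest_per_timepoint(
    table: pd.DataFrame,
    trait: str,
    dai: int,
    temperature: str = "ambient",
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult | None:
    """Inoculated-vs-control comparison of one trait at one imaging day
    within one temperature regime (the comparison the asterisks in the
    trait-curve figures encode).

    Returns None (with a diagnostic warning) when a group has fewer than
    two observations.
    """
    t = table if "inoculation" in table.columns else add_factor_columns(table)
    sub = t[(t["dai"] == dai) & (t["temperature"] == temperature)]
    ctl = sub.loc[sub["inoculation"] == "control", trait].to_numpy()
    ino = sub.loc[sub["inoculation"] == "psjn", trait].to_numpy()
    try:
        return ttest_groups(
            ino, ctl, trait=trait, dai=dai,
            group_a=f"{temperature}:psjn", group_b=f"{temperature}:control",
            alpha=alpha, welch=welch)
    except ValueError as err:
        import warnings

        warnings.warn(f"t-test skipped for {trait} at DAI {dai}: {err}",
                      stacklevel=2)
        return None


def two_way_anova(
    table: pd.DataFrame,
    trait: str,
    scope: str = "per_day",
    dai: int | None = None,
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction: microbe × temperature.

    ``scope="per_day"`` (requires ``dai``) analyses a single imaging day;
    ``scope="whole_period"`` pools all days with DAI as an additive fixed
    block.  All four treatment cells must be present.
    """
    t = table if "inoculation" in table.columns else add_factor_columns(table)
    if scope == "per_day":
        if dai is None:
            raise ValueError("per_day scope requires dai")
        t = t[t["dai"] == dai]
        scope_name = f"dai={dai}"
        formula = f"{trait} ~ C(inoculation) * C(temperature)"
    elif scope == "whole_period":
        scope_name = "whole_period"
        formula = f"{trait} ~ C(inoculation) * C(temperature) + C(dai)"
    else:
        raise ValueError("scope must be 'per_day' or 'whole_period'")

    cells = t.groupby(["inoculation", "temperature"], observed=True)[trait] \
        .apply(lambda s: s.notna().sum())
    for ino in ("control", "psjn"):
        for temp in ("ambient", "high"):
            if (ino, temp) not in cells.index or cells[(ino, temp)] == 0:
                raise ValueError(
                    f"empty treatment cell: inoculation={ino}, "
                    f"temperature={temp} ({scope_name})")

    model = smf.ols(formula, data=t.dropna(subset=[trait])).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    resid_df = float(aov.loc["Residual", "df"])
    key = {
        "microbe": "C(inoculation)",
        "temperature": "C(temperature)",
        "interaction": "C(inoculation):C(temperature)",
    }
    effects = {}
    for name, row in key.items():
        effects[name] = {
            "F": float(aov.loc[row, "F"]),
            "df": (float(aov.loc[row, "df"]), resid_df),
            "p": float(aov.loc[row, "PR(>F)"]),
        }
    return AnovaResult(trait=trait, scope=scope_name, effects=effects)


def fit_trend(
    x: np.ndarray,
    y: np.ndarray,
    model: str,
    x_trait: str = "x",
    y_trait: str = "y",
    group: str | None = None,
) -> TrendFit:
    """Fit a trendline between two traits.

    ``model="exponential"`` fits y = a·exp(b·x) by least squares on log y
    (R² reported on the log scale); ``model="polynomial"`` fits a quadratic
    by OLS (R² on the original scale).  Needs at least three points; the
    exponential model requires strictly positive y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points")

    def r2(obs, fit):
        # centred data with no spread explain nothing: R^2 = 0 by convention
        ss_res = float(np.sum((obs - fit) ** 2))
        ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
        if ss_tot == 0:
            return 0.0
        return max(0.0, 1.0 - ss_res / ss_tot)

    if model == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential model requires y > 0")
        ly = np.log(y)
        b, loga = np.polyfit(x, ly, 1)
        a = float(np.exp(loga))
        return TrendFit(x_trait, y_trait, group, "exponential",
                        (a, float(b)), r2(ly, loga + b * x), "log")
    if model == "polynomial":
        coeffs = np.polyfit(x, y, 2)
        fit = np.polyval(coeffs, x)
        return TrendFit(x_trait, y_trait, group, "polynomial",
                        tuple(float(c) for c in coeffs), r2(y, fit), "original")
    raise ValueError("model must be 'exponential' or 'polynomial'")


def summarize_treatment_curves(
    table: pd.DataFrame,
    trait_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ± standard error (sd/√n) per treatment per DAI per trait.

    SE is missing for single observations; ``n`` is reported alongside.
    """
    if trait_cols is None:
        skip = {"plant_id", "treatment", "dai", "temperature", "inoculation"}
        trait_cols = [c for c in table.columns
                      if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for (tr, dai), sub in table.groupby(["treatment", "dai"], sort=True):
        for col in trait_cols:
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append({
                "treatment": tr, "dai": dai, "trait": col,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "se": _se(vals),
            })
    return pd.DataFrame(rows)


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default in
    every pipeline entry point)."""
    return multipletests(np.asarray(p_values), method="fdr_bh")[1]
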