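"""Allometric scaling statistics: outlier screening, AICc-ranked ANCOVA
model search with Type III tests, reduced-major-axis (RMA) and OLS scaling
with isometry verdicts, auxiliary group comparisons, and the handedness
summary.

Scaling analyses operate on log10-transformed traits against log10 SVL
(snout-vent length).  Under geometric similarity the expected log-log slope
is 1 for linear measurements and 3 for mass; a trait is scored allometric
when that expectation falls outside the 95% CI of its RMA slope.

Type III sums of squares are contrast-dependent; all factor terms use
sum-to-zero coding, so main effects are evaluated at the (unweighted)
average of the factor levels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "OutlierReport",
    "AncovaResult",
    "RMAResult",
    "ScalingFit",
    "detect_outliers",
    "ancova_search",
    "rma_fit",
    "ols_fit",
    "isometry_test",
    "scaling_fits",
    "aux_tests",
    "welch_t",
    "handedness_summary",
    "isometry_expectation",
]

#: expected log-log scaling exponents under geometric similarity
ISOMETRY_MASS = 3.0
ISOMETRY_LINEAR = 1.0


def isometry_expectation(trait: str) -> float:
    """3 for mass, 1 for linear measurements."""
    return ISOMETRY_MASS if "mass" in trait else ISOMETRY_LINEAR


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    trait: str
    flagged_ids: list[str]
    rule: str
    residuals: pd.DataFrame  # id, age_class, std_resid


def detect_outliers(df: pd.DataFrame, trait: str, rule: str = "and",
                    svl: str = "svl_cm") -> OutlierReport:
    """Screen a trait for outliers on standardized log-log residuals.

    Within each age class, log10(trait) is regressed on log10(SVL) + sex and
    the residuals standardized.  A point is flagged when its |standardized
    residual| exceeds 3 and (``rule="and"``, the default) / or
    (``rule="or"``) it sits more than 1 s.d. from the next most extreme
    residual.  Flagged individuals are meant to be excluded from all later
    analyses of this trait.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    rows = []
    for age, sub in df.groupby("age_class"):
        if len(sub) < 4:
            raise ValueError(
                f"age group {age!r} has {len(sub)} individuals; need >= 4")
        work = pd.DataFrame({
            "y": np.log10(sub[trait].to_numpy(float)),
            "log_svl": np.log10(sub[svl].to_numpy(float)),
            "sex": sub["sex"].to_numpy(),
        })
        res = smf.ols("y ~ log_svl + C(sex, Sum)", data=work).fit()
        if res.df_resid <= 0 or not np.isfinite(res.params).all():
            raise ValueError(f"singular design for trait {trait!r} in {age}")
        resid = res.resid.to_numpy()
        sd = resid.std(ddof=1)
        # an essentially perfect fit has no outliers; do not standardize
        # floating-point noise
        scale = max(1.0, np.abs(work["y"]).max())
        z = resid / sd if sd > 1e-10 * scale else np.zeros_like(resid)
        for i, zi in zip(sub["id"], z):
            rows.append({"id": i, "age_class": age, "std_resid": zi})
    table = pd.DataFrame(rows)
    flagged = []
    for _, sub in table.groupby("age_class"):
        order = sub.reindex(sub["std_resid"].abs()
                            .sort_values(ascending=False).index)
        absz = order["std_resid"].abs().to_numpy()
        for j in range(len(order)):
            gap = absz[j] - (absz[j + 1] if j + 1 < len(order) else 0.0)
            big = absz[j] > 3.0
            separated = gap > 1.0
            hit = (big and separated) if rule == "and" else (big or separated)
            # under the OR rule, separation alone only marks points that are
            # at least as extreme as an already-flagged one
            if rule == "or" and not big and j > 0:
                hit = False
            if hit:
                flagged.append(order["id"].iloc[j])
    return OutlierReport(trait=trait, flagged_ids=flagged, rule=rule,
                         residuals=table)


# ---------------------------------------------------------------------------
# ANCOVA search
# ---------------------------------------------------------------------------

_TERMS = {
    "svl": "log_svl",
    "sex": "C(sex, Sum)",
    "age": "C(age_class, Sum)",
    "svl:sex": "log_svl:C(sex, Sum)",
    "svl:age": "log_svl:C(age_class, Sum)",
    "sex:age": "C(sex, Sum):C(age_class, Sum)",
    "svl:sex:age": "log_svl:C(sex, Sum):C(age_class, Sum)",
    "temperature": "temperature_C",
}

_MARGINS = {
    "svl": set(), "sex": set(), "age": set(), "temperature": set(),
    "svl:sex": {"svl", "sex"},
    "svl:age": {"svl", "age"},
    "sex:age": {"sex", "age"},
    "svl:sex:age": {"svl", "sex", "age", "svl:sex", "svl:age", "sex:age"},
}


def _marginal_subsets(include_temperature: bool):
    base = ["svl", "sex", "age", "svl:sex", "svl:age", "sex:age",
            "svl:sex:age"]
    out = []
    for r in range(len(base) + 1):
        for combo in itertools.combinations(base, r):
            s = set(combo)
            if all(_MARGINS[t] <= s for t in s):
                out.append(list(combo))
    if include_temperature:
        # temperature enters additively only; no interactions with it
        out = out + [terms + ["temperature"] for terms in out]
    return out


def _aicc_from_fit(res) -> float:
    n = res.nobs
    k = len(res.params) + 1          # coefficients + residual variance
    aic = -2.0 * res.llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class AncovaResult:
    response: str
    table: pd.DataFrame               # terms, k, aicc, delta, rank
    selected_terms: list[str]
    best_by_aicc_terms: list[str]
    anova_type3: pd.DataFrame | None  # F and p for the selected model
    model: object                     # fitted statsmodels results

    @property
    def grouping(self) -> list[str]:
        """Factors the selected model says should split the scaling sample."""
        g = []
        if any("sex" in t for t in self.selected_terms):
            g.append("sex")
        if any("age" in t for t in self.selected_terms):
            g.append("age_class")
        return g


def ancova_search(df: pd.DataFrame, response: str,
                  include_temperature: bool = False,
                  tie_window: float = 2.0) -> AncovaResult:
    """AICc model search over the marginality-respecting ANCOVA lattice.

    Fits the full model SVL+sex+age with all interactions (optionally plus
    additive body temperature) and every hierarchical submodel, ranks by
    AICc, and selects the lowest-AICc model -- except that when other models
    fall within ``tie_window`` AICc units of the best, the one with the most
    predictors among them is selected (favouring the more granular view of
    group-specific scaling).  Type III F and p values are reported for each
    term of the selected model under sum-to-zero factor coding.

    ``df`` needs columns ``log_svl``, ``sex``, ``age_class``, the response,
    and ``temperature_C`` when temperature is considered.
    """
    need = ["log_svl", "sex", "age_class", response]
    if include_temperature:
        need.append("temperature_C")
    data = df.dropna(subset=[c for c in need if c in df.columns])
    rows = []
    fits = {}
    for terms in _marginal_subsets(include_temperature):
        rhs = " + ".join(_TERMS[t] for t in terms) if terms else "1"
        formula = f"{response} ~ {rhs}"
        try:
            res = smf.ols(formula, data=data).fit()
        except Exception as exc:   # singular designs etc.
            warnings.warn(f"model {terms} failed to fit: {exc}")
            continue
        if res.nobs - len(res.params) - 2 <= 0:
            warnings.warn(f"model {terms} skipped: too few observations")
            continue
        key = tuple(terms)
        fits[key] = res
        rows.append({"terms": key, "n_terms": len(terms),
                     "k": len(res.params) + 1, "aicc": _aicc_from_fit(res)})
    if not rows:
        raise ValueError("no ANCOVA model could be fitted")
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)

    best_key = table["terms"].iloc[0]
    window = table[table["delta"] < tie_window]
    sel = window.sort_values(["n_terms", "aicc"],
                             ascending=[False, True]).iloc[0]
    selected_key = sel["terms"]

    model = fits[selected_key]
    anova = None
    if selected_key:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                anova = sm.stats.anova_lm(model, typ=3)
            except Exception:
                anova = None
    return AncovaResult(
        response=response, table=table,
        selected_terms=list(selected_key),
        best_by_aicc_terms=list(best_key),
        anova_type3=anova, model=model,
    )


# ---------------------------------------------------------------------------
# RMA / OLS scaling
# ---------------------------------------------------------------------------

@dataclass
class RMAResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r: float
    n: int


def rma_fit(x: np.ndarray, y: np.ndarray) -> RMAResult:
    """Reduced-major-axis line with the standard 95% CI.

    slope = sign(r) * sd(y)/sd(x); the line passes through the means.  The
    CI uses B = t^2 (1 - r^2)/(n - 2):  CI = slope * (sqrt(B+1) +/- sqrt(B)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: RMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = (np.sign(r) if r != 0 else 1.0) * sy / sx
    t = stats.t.ppf(0.975, n - 2)
    B = t * t * (1.0 - r * r) / (n - 2)
    lo = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    if slope < 0:
        lo, hi = hi, lo
    return RMAResult(slope=float(slope),
                     intercept=float(y.mean() - slope * x.mean()),
                     ci_low=float(lo), ci_high=float(hi), r=r, n=n)


def ols_fit(x: np.ndarray, y: np.ndarray) -> RMAResult:
    """OLS slope with 95% CI, in the same container for symmetry."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    lo, hi = res.conf_int()[1]
    r = float(np.corrcoef(x, y)[0, 1])
    return RMAResult(slope=float(res.params[1]),
                     intercept=float(res.params[0]),
                     ci_low=float(lo), ci_high=float(hi), r=r, n=x.size)


def isometry_test(fit: RMAResult, expected: float) -> str:
    """'isometric' iff the expectation lies inside the CI, else the side."""
    if fit.ci_low <= expected <= fit.ci_high:
        return "isometric"
    return ("positive allometry" if fit.slope > expected
            else "negative allometry")


@dataclass
class ScalingFit:
    """RMA/OLS scaling of one trait within one subgroup."""

    trait: str
    group: str
    rma: RMAResult
    ols: RMAResult
    isometry_expected: float
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = isometry_test(self.rma, self.isometry_expected)


def scaling_fits(df: pd.DataFrame, trait: str,
                 grouping: list[str] | None = None,
                 expected: float | None = None,
                 svl: str = "svl_cm") -> list[ScalingFit]:
    """RMA and OLS log-log scaling of a trait, split into subgroups.

    ``grouping`` is typically ``AncovaResult.grouping`` (sex and/or age when
    the selected ANCOVA model retains them); an empty list fits the pooled
    sample.
    """
    if expected is None:
        expected = isometry_expectation(trait)
    if not grouping:
        groups = [("all", df)]
    else:
        groups = [(" / ".join(map(str, k if isinstance(k, tuple) else (k,))),
                   sub) for k, sub in df.groupby(grouping)]
    out = []
    for label, sub in groups:
        x = np.log10(sub[svl].to_numpy(float))
        y = np.log10(sub[trait].to_numpy(float))
        out.append(ScalingFit(trait=trait, group=label,
                              rma=rma_fit(x, y), ols=ols_fit(x, y),
                              isometry_expected=expected))
    return out


# ---------------------------------------------------------------------------
# auxiliary tests and handedness
# ---------------------------------------------------------------------------

def welch_t(a: np.ndarray, b: np.ndarray):
    """Welch's t with Satterthwaite df, computed explicitly."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def aux_tests(groups: list[np.ndarray]) -> dict:
    """One-way ANOVA, Levene's test (center=mean) and, for two groups,
    Welch's t-test."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    F, p = stats.f_oneway(*groups)
    lF, lp = stats.levene(*groups, center="mean")
    out = {"anova_F": float(F), "anova_p": float(p),
           "levene_F": float(lF), "levene_p": float(lp)}
    if len(groups) == 2:
        t, df, tp = welch_t(groups[0], groups[1])
        out.update({"welch_t": t, "welch_df": df, "welch_p": tp})
    return out


def handedness_summary(trials: pd.DataFrame, k_trials: int = 3) -> dict:
    """Counts of left/right/switched trials and the all-same-handedness rate.

    Among individuals with exactly ``k_trials`` scored (non-switching)
    trials, reports the proportion showing the same handedness in all of
    them, alongside the analytic expectation under i.i.d. fair-coin
    handedness, 2 * (1/2)^k (25% for three trials).
    """
    counts = trials["handedness"].value_counts().to_dict()
    pure = trials[trials["handedness"].isin(["left", "right"])]
    per_ind = pure.groupby("individual_id")["handedness"]
    n_k = 0
    n_same = 0
    for _, hands in per_ind:
        if len(hands) == k_trials:
            n_k += 1
            if hands.nunique() == 1:
                n_same += 1
    expectation = 2.0 * 0.5 ** k_trials * 100.0
    return {
        "counts": {kk: int(v) for kk, v in counts.items()},
        "n_individuals_with_k_trials": n_k,
        "n_all_same": n_same,
        "proportion_all_same_percent":
            100.0 * n_same / n_k if n_k else float("nan"),
        "random_expectation_percent": expectation,
    }
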