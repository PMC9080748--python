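"""Observed-variable path analysis by maximum likelihood on a covariance
(or correlation) matrix.

A path model over p observed variables is an acyclic set of directed paths
(matrix B) plus free variances and selected covariances among the error
terms (matrix Psi); the model-implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T.

Fitting minimises the Wishart ML discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p,

with chi^2 = (n - 1) F at the optimum, df = p(p+1)/2 - n_free, standard
errors from the inverse expected (Fisher) information, RMSEA as lack of fit per
degree of freedom, per-path likelihood-ratio tests, and a model-menu
comparison (reject on chi^2 lack of fit, rank survivors by RMSEA then
AICc).

By default models are fitted to the correlation matrix of residuals (the
standardized solution), so a squared path coefficient reads directly as the
fraction of variance explained.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "PathModelSpec",
    "parse_model_spec",
    "PathFitResult",
    "residualize",
    "pearson_matrix",
    "fit_path_model",
    "rmsea",
    "lrt_path",
    "model_menu_search",
    "simulate_from_model",
    "default_speed_path_model",
    "build_model_menu",
    "variance_explained_percent",
    "MenuReport",
]

MAX_VARIABLES = 7


def variance_explained_percent(coef: float) -> float:
    """Squared standardized path coefficient as a percentage."""
    return 100.0 * coef * coef


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModelSpec:
    """Directed paths plus free (error) covariances over <= 7 variables."""

    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]          # (source, target)
    covariances: tuple[tuple[str, str], ...]    # unordered pairs

    def __init__(self, variables, paths=(), covariances=()):
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(self, "paths",
                           tuple((str(a), str(b)) for a, b in paths))
        object.__setattr__(self, "covariances",
                           tuple((str(a), str(b)) for a, b in covariances))
        self._validate()

    def _validate(self) -> None:
        vs = self.variables
        if len(set(vs)) != len(vs):
            raise ValueError("duplicate variable names")
        if len(vs) > MAX_VARIABLES:
            raise ValueError(
                f"path models are limited to {MAX_VARIABLES} variables")
        for a, b in self.paths + self.covariances:
            if a not in vs or b not in vs:
                raise ValueError(f"unknown variable in ({a}, {b})")
        for a, b in self.covariances:
            if a == b:
                raise ValueError("a covariance pair needs two variables")
        seen = {frozenset(p) for p in self.covariances}
        if len(seen) != len(self.covariances):
            raise ValueError("duplicate covariance pair")
        # acyclicity by Kahn's algorithm
        children: dict[str, set[str]] = {v: set() for v in vs}
        indeg = {v: 0 for v in vs}
        for a, b in self.paths:
            if b not in children[a]:
                children[a].add(b)
                indeg[b] += 1
        queue = [v for v in vs if indeg[v] == 0]
        visited = 0
        while queue:
            v = queue.pop()
            visited += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if visited != len(vs):
            raise ValueError("directed paths must form an acyclic graph")

    @property
    def n_free(self) -> int:
        return len(self.paths) + len(self.variables) + len(self.covariances)

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.paths}
        return tuple(v for v in self.variables if v not in targets)

    def without_path(self, path: tuple[str, str]) -> "PathModelSpec":
        if tuple(path) not in self.paths:
            raise ValueError(f"path {path} not in model")
        return PathModelSpec(
            self.variables,
            tuple(p for p in self.paths if p != tuple(path)),
            self.covariances,
        )


def parse_model_spec(text: str) -> PathModelSpec:
    """Parse a plain-text model description.

    Three sections: ``variables:`` (whitespace/comma separated names, may
    continue on the same line), then any number of ``a -> b`` directed
    paths and ``a ~~ b`` free covariances, one per line.  ``#`` starts a
    comment.
    """
    variables: list[str] = []
    paths: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("variables:"):
            variables += line.split(":", 1)[1].replace(",", " ").split()
        elif low in ("paths:", "covariances:"):
            continue
        elif "->" in line:
            a, b = (s.strip() for s in line.split("->", 1))
            paths.append((a, b))
        elif "~~" in line:
            a, b = (s.strip() for s in line.split("~~", 1))
            covs.append((a, b))
        else:
            raise ValueError(f"unparseable model line: {raw!r}")
    if not variables:
        raise ValueError("model spec declares no variables")
    return PathModelSpec(variables, paths, covs)


@dataclass
class PathFitResult:
    spec: PathModelSpec
    estimates: dict            # ('path'|'var'|'cov', a, b) -> value
    se: dict
    chi_square: float
    df: int
    p_lack_of_fit: float
    rmsea: float
    aicc: float
    n: int
    converged: bool
    discrepancy: float
    sigma_hat: np.ndarray
    path_lrt: dict = field(default_factory=dict)  # (a,b) -> (chi2, p)

    def path(self, a: str, b: str) -> float:
        return self.estimates[("path", a, b)]

    def path_se(self, a: str, b: str) -> float:
        return self.se[("path", a, b)]


# ---------------------------------------------------------------------------
# core fitting
# ---------------------------------------------------------------------------

def _param_keys(spec: PathModelSpec):
    keys = [("path", a, b) for a, b in spec.paths]
    keys += [("var", v, v) for v in spec.variables]
    keys += [("cov", a, b) for a, b in spec.covariances]
    return keys


def _unpack(spec: PathModelSpec, theta: np.ndarray):
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    k = 0
    for a, b in spec.paths:
        B[idx[b], idx[a]] = theta[k]
        k += 1
    for v in spec.variables:
        Psi[idx[v], idx[v]] = theta[k]
        k += 1
    for a, b in spec.covariances:
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = theta[k]
        k += 1
    return B, Psi, idx


def _discrepancy_and_grad(spec: PathModelSpec, theta: np.ndarray,
                          S: np.ndarray, logdet_S: float):
    p = len(spec.variables)
    B, Psi, idx = _unpack(spec, theta)
    I = np.eye(p)
    try:
        A = np.linalg.inv(I - B)
    except np.linalg.LinAlgError:
        return np.inf, None
    Sigma = A @ Psi @ A.T
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, None
    Sigma_inv = np.linalg.inv(Sigma)
    F = logdet + float(np.trace(S @ Sigma_inv)) - logdet_S - p

    C = Sigma_inv - Sigma_inv @ S @ Sigma_inv   # dF = tr(C dSigma)
    M = A.T @ C @ A
    SCA = Sigma @ C @ A
    grad = np.empty(theta.size)
    k = 0
    for a, b in spec.paths:
        grad[k] = 2.0 * SCA[idx[a], idx[b]]
        k += 1
    for v in spec.variables:
        grad[k] = M[idx[v], idx[v]]
        k += 1
    for a, b in spec.covariances:
        grad[k] = 2.0 * M[idx[a], idx[b]]
        k += 1
    return F, grad


def _sigma_derivatives(spec: PathModelSpec, theta: np.ndarray):
    """dSigma/dtheta_k for every free parameter."""
    p = len(spec.variables)
    B, Psi, idx = _unpack(spec, theta)
    A = np.linalg.inv(np.eye(p) - B)
    Sigma = A @ Psi @ A.T
    derivs = []
    for a, b in spec.paths:
        E = np.zeros((p, p))
        E[idx[b], idx[a]] = 1.0
        D = A @ E @ Sigma
        derivs.append(D + D.T)
    for v in spec.variables:
        E = np.zeros((p, p))
        E[idx[v], idx[v]] = 1.0
        derivs.append(A @ E @ A.T)
    for a, b in spec.covariances:
        E = np.zeros((p, p))
        E[idx[a], idx[b]] = E[idx[b], idx[a]] = 1.0
        derivs.append(A @ E @ A.T)
    return Sigma, derivs


def _expected_information(spec: PathModelSpec, theta: np.ndarray,
                          n: int) -> np.ndarray:
    """Fisher information of the Wishart likelihood at theta.

    I_jk = (n-1)/2 * tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k).
    """
    Sigma, derivs = _sigma_derivatives(spec, theta)
    Sinv = np.linalg.inv(Sigma)
    W = [Sinv @ D for D in derivs]
    k = len(derivs)
    I = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            I[i, j] = I[j, i] = np.trace(W[i] @ W[j])
    return 0.5 * (n - 1) * I


def fit_path_model(spec: PathModelSpec, S: np.ndarray, n: int,
                   restarts: int = 10, seed: int = 0,
                   compute_se: bool = True) -> PathFitResult:
    """Fit a path model to a sample covariance/correlation matrix.

    ``S`` must be positive definite and ordered like ``spec.variables``;
    ``n`` is the number of (complete-case) individuals behind ``S``.  The
    optimizer is quasi-Newton with an analytic gradient from a sample-moment
    start, with ``restarts`` jittered restarts guarding against local
    minima.  Non-convergence is flagged, never silently reported.
    """
    S = np.asarray(S, float)
    p = len(spec.variables)
    if S.shape != (p, p):
        raise ValueError("S shape does not match the model's variables")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("S must be positive definite")
    if spec.df < 0:
        raise ValueError(
            f"negative degrees of freedom ({spec.df}): model over-parameterized")

    idx = {v: i for i, v in enumerate(spec.variables)}
    theta0 = np.empty(spec.n_free)
    k = 0
    for a, b in spec.paths:
        theta0[k] = 0.0
        k += 1
    for v in spec.variables:
        theta0[k] = S[idx[v], idx[v]]
        k += 1
    for a, b in spec.covariances:
        theta0[k] = 0.5 * S[idx[a], idx[b]]
        k += 1

    fun = lambda th: _discrepancy_and_grad(spec, th, S, logdet_S)

    def safe(th):
        F, g = fun(th)
        if g is None:
            return 1e10, np.zeros_like(th)
        return F, g

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, restarts)):
        start = theta0 if trial == 0 else theta0 + rng.normal(
            0.0, 0.1 * (1.0 + np.abs(theta0)))
        res = minimize(safe, start, jac=True, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = best.x
    F, grad = fun(theta)
    converged = bool(np.isfinite(F) and grad is not None
                     and np.linalg.norm(grad, np.inf) < 1e-5)
    if not converged:
        warnings.warn("path model fit did not converge; result flagged")

    chi2 = max((n - 1) * F, 0.0)
    df = spec.df
    p_fit = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    k_free = spec.n_free
    aicc = chi2 + 2.0 * k_free
    if n - k_free - 1 > 0:
        aicc += 2.0 * k_free * (k_free + 1) / (n - k_free - 1)

    keys = _param_keys(spec)
    estimates = {key: float(v) for key, v in zip(keys, theta)}
    se = {key: np.nan for key in keys}
    if compute_se and converged:
        try:
            info = _expected_information(spec, theta, n)
            cov = np.linalg.pinv(info)
            d = np.diag(cov)
            se = {key: float(np.sqrt(v)) if v > 0 else np.nan
                  for key, v in zip(keys, d)}
        except np.linalg.LinAlgError:
            pass

    B, Psi, _ = _unpack(spec, theta)
    A = np.linalg.inv(np.eye(p) - B)
    return PathFitResult(
        spec=spec, estimates=estimates, se=se,
        chi_square=float(chi2), df=df, p_lack_of_fit=p_fit,
        rmsea=rmsea(chi2, df, n) if df > 0 else np.nan,
        aicc=float(aicc), n=n, converged=converged,
        discrepancy=float(F), sigma_hat=A @ Psi @ A.T,
    )


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root mean square error of approximation.

    sqrt(max(chi^2 - df, 0) / (df * (n - 1))); zero means the model fits as
    well as (or better than) expected by chance.
    """
    if df < 1:
        raise ValueError("RMSEA undefined for df < 1")
    if n < 2:
        raise ValueError("RMSEA needs n >= 2")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))


def lrt_path(spec: PathModelSpec, path: tuple[str, str], S: np.ndarray,
             n: int, full: PathFitResult | None = None,
             restarts: int = 10, seed: int = 0):
    """Likelihood-ratio test of one directed path (fixed to zero).

    Returns (chi2_diff, p) with p from chi^2(1); never negative because the
    models are nested.
    """
    if full is None:
        full = fit_path_model(spec, S, n, restarts=restarts, seed=seed,
                              compute_se=False)
    restricted = fit_path_model(spec.without_path(path), S, n,
                                restarts=restarts, seed=seed,
                                compute_se=False)
    if not restricted.converged:
        warnings.warn(f"restricted fit for path {path} did not converge")
    diff = max(restricted.chi_square - full.chi_square, 0.0)
    return float(diff), float(stats.chi2.sf(diff, 1))


# ---------------------------------------------------------------------------
# residualization and correlations
# ---------------------------------------------------------------------------

def residualize(df: pd.DataFrame, svl: str = "svl_cm",
                config: dict | None = None) -> pd.DataFrame:
    """Residuals of each variable from its log-log regression on SVL.

    ``config`` maps column name -> {"log": bool, "covariates": [...]}; the
    covariates ("sex", "age_class") reflect each variable's best ANCOVA
    model.  Signed variables (skew angle) are not log-transformed.  Returns
    residuals aligned on the input index; rows with missing values for a
    variable are NaN there (complete-case handling is per model downstream).
    """
    config = config or {}
    out = {}
    log_svl = np.log10(df[svl].to_numpy(float))
    for col, opts in config.items():
        use_log = opts.get("log", True)
        covs = list(opts.get("covariates", []))
        y = df[col].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(log_svl)
        if ok.sum() < 3:
            raise ValueError(f"variable {col!r} has no complete cases")
        yy = np.log10(y[ok]) if use_log else y[ok]
        if np.ptp(yy) == 0:
            raise ValueError(f"variable {col!r} is constant")
        X = [np.ones(ok.sum()), log_svl[ok]]
        for cv in covs:
            codes, _ = pd.factorize(df.loc[ok, cv])
            X.append(codes.astype(float))
        X = np.column_stack(X)
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = np.full(len(df), np.nan)
        resid[ok] = yy - X @ beta
        out[col] = resid
    return pd.DataFrame(out, index=df.index)


def pearson_matrix(df: pd.DataFrame):
    """Pairwise-complete Pearson correlations with two-sided p-values."""
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols,
                     columns=cols)
    for a, b in itertools.combinations(cols, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        if sub[a].std() == 0 or sub[b].std() == 0:
            warnings.warn(f"zero variance in pair ({a}, {b}); r undefined")
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        rr, pp = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    return r, p


# ---------------------------------------------------------------------------
# default model and menu
# ---------------------------------------------------------------------------

def _fig_covariances(variables, paths):
    """All exogenous pairs, plus the wavelength (and, if endogenous,
    frequency) residual with each exogenous non-parent."""
    targets = {b for _, b in paths}
    exog = [v for v in variables if v not in targets]
    covs = list(itertools.combinations(exog, 2))
    for endo in ("wavelength", "frequency"):
        if endo in targets:
            parents = {a for a, b in paths if b == endo}
            covs += [(endo, v) for v in exog if v not in parents]
    return covs


def default_speed_path_model() -> PathModelSpec:
    """The preferred seven-variable model of sidewinding speed.

    Frequency, wavelength, amplitude and skew angle carry hypothesized
    causal paths into mean centroid speed; mid-body width drives wavelength
    (stouter snakes form looser curves); height lifted participates through
    covariances only.  Counting moments minus free parameters gives df = 2.
    """
    variables = ("frequency", "wavelength", "amplitude", "skew", "height",
                 "width50", "speed")
    paths = (
        ("frequency", "speed"),
        ("wavelength", "speed"),
        ("amplitude", "speed"),
        ("skew", "speed"),
        ("width50", "wavelength"),
    )
    return PathModelSpec(variables, paths, _fig_covariances(variables, paths))


def build_model_menu() -> list[PathModelSpec]:
    """The 16 candidate seven-variable models.

    Every model contains speed, frequency, wavelength and amplitude with
    causal paths from the latter three into speed; the remaining three
    slots take every 3-subset of {skew, height, tail, ventral, mass,
    width50} except those holding both stoutness measures (mass and
    width50), which are redundant -- 16 models in all.  Skew adds a path to
    speed; each stoutness/vertebral variable adds a path to wavelength;
    tail length adds a path to frequency; height enters via covariances
    only.
    """
    base = ["frequency", "wavelength", "amplitude", "speed"]
    extras = ["skew", "height", "tail", "ventral", "mass", "width50"]
    menu = []
    for combo in itertools.combinations(extras, 3):
        if "mass" in combo and "width50" in combo:
            continue
        variables = base + list(combo)
        paths = [("frequency", "speed"), ("wavelength", "speed"),
                 ("amplitude", "speed")]
        if "skew" in combo:
            paths.append(("skew", "speed"))
        for stout in ("mass", "width50", "ventral"):
            if stout in combo:
                paths.append((stout, "wavelength"))
        if "tail" in combo:
            paths.append(("tail", "frequency"))
        menu.append(PathModelSpec(variables, paths,
                                  _fig_covariances(variables, paths)))
    assert len(menu) == 16
    return menu


@dataclass
class MenuReport:
    table: pd.DataFrame
    selected: int | None        # index into the menu, None if all rejected
    fits: list[PathFitResult]


def model_menu_search(menu: list[PathModelSpec], data: pd.DataFrame,
                      alpha: float = 0.05, use_correlation: bool = True,
                      restarts: int = 10, seed: int = 0) -> MenuReport:
    """Fit a menu of path models and pick the best-supported one.

    Each model is fitted to the (complete-case) correlation matrix of its
    own variable subset of ``data``; models with significant chi^2 lack of
    fit (p < alpha) are rejected; survivors are ranked by RMSEA ascending
    with AICc breaking ties.
    """
    rows = []
    fits = []
    for i, spec in enumerate(menu):
        sub = data[list(spec.variables)].dropna()
        n = len(sub)
        S = (np.corrcoef(sub.to_numpy(), rowvar=False) if use_correlation
             else np.cov(sub.to_numpy(), rowvar=False))
        fit = fit_path_model(spec, S, n, restarts=restarts, seed=seed,
                             compute_se=False)
        fits.append(fit)
        rejected = (fit.df > 0 and np.isfinite(fit.p_lack_of_fit)
                    and fit.p_lack_of_fit < alpha) or not fit.converged
        rows.append({
            "model": i, "variables": ",".join(spec.variables),
            "n": n, "chi_square": fit.chi_square, "df": fit.df,
            "p_lack_of_fit": fit.p_lack_of_fit,
            "rmsea": fit.rmsea if fit.df > 0 else 0.0,
            "aicc": fit.aicc, "converged": fit.converged,
            "rejected": rejected,
        })
    table = pd.DataFrame(rows)
    surv = table[~table["rejected"]]
    selected = None
    if len(surv):
        surv = surv.sort_values(["rmsea", "aicc"])
        selected = int(surv["model"].iloc[0])
    return MenuReport(table=table, selected=selected, fits=fits)


# ---------------------------------------------------------------------------
# simulation (ground truth for recovery tests)
# ---------------------------------------------------------------------------

def simulate_from_model(spec: PathModelSpec, params: dict, n: int,
                        seed: int = 0) -> pd.DataFrame:
    """Draw n multivariate-normal observations from a path model.

    ``params`` maps the same keys as ``PathFitResult.estimates``; the error
    vector e ~ N(0, Psi) and x = (I - B)^-1 e.
    """
    p = len(spec.variables)
    theta = np.array([params[k] for k in _param_keys(spec)])
    B, Psi, _ = _unpack(spec, theta)
    vals = np.linalg.eigvalsh(Psi)
    if vals.min() <= 0:
        raise ValueError("Psi implied by params is not positive definite")
    rng = np.random.default_rng(seed)
    e = rng.multivariate_normal(np.zeros(p), Psi, size=n,
                                method="cholesky")
    A = np.linalg.inv(np.eye(p) - B)
    x = e @ A.T
    return pd.DataFrame(x, columns=list(spec.variables))
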