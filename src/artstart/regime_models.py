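"""Penalized-spline additive models for the g-formula's Step-1 fits.

For every fit time t in {1, 3, ..., 36} months four models are fitted on the
children still at risk at t:

* three Gaussian additive models for the time-dependent confounders
  (sqrt CD4 count, CD4%, WAZ) at t, and
* one logistic additive model for death in the interval ending at t,

all on the covariate recipe: disease-progression history (CD4, CD4%, WAZ at
t-1, CD4 on the sqrt scale), baseline characteristics (CD4, CD4%, WAZ, HAZ),
demographics (age, sex, region) and ART at t-1.  Continuous covariates enter
through cubic P-splines (B-spline basis, difference penalty) with smoothing
chosen by generalized cross-validation, GCV = n*RSS/(n-edf)^2 (deviance
analogue for the logistic model).  When a time point is too sparse (too few
rows or deaths) the fit falls back to a single pooled model across time with
a smooth time effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .grid import FIT_TIMES, grid_times

__all__ = [
    "SmoothTerm",
    "PSplineBasis",
    "pspline_design",
    "AdditiveSpec",
    "FittedAdditiveModel",
    "fit_additive",
    "gcv_select",
    "ModelRecipe",
    "ModelSet",
    "make_fit_frame",
    "fit_confounder_model",
    "fit_death_model",
    "fit_model_set",
]

LOG_LAM_RANGE = (-4.0, 8.0)
_GOLD = (math.sqrt(5) - 1) / 2


class DegenerateBasisError(ValueError):
    """The covariate has too few distinct values to support a spline basis."""


class FittingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# P-spline basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothTerm:
    covariate: str
    n_basis: int = 8
    degree: int = 3
    penalty_order: int = 2
    lam: float | None = None  # None -> chosen by GCV
    by: str | None = None     # varying-coefficient interaction column (0/1)

    def __post_init__(self) -> None:
        if self.n_basis <= self.penalty_order:
            raise ValueError("basis count must exceed the penalty order")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")


class PSplineBasis:
    """Centred B-spline basis with a difference penalty, fitted to an x range.

    Equally spaced knots over the observed range; the basis is constrained
    to sum to zero over the fitting data (so smooths are identifiable next
    to an intercept) by projecting onto the null space of the column-sum
    constraint.  Evaluation outside the fitted range extrapolates linearly
    from the boundary.
    """

    def __init__(self, x: np.ndarray, term: SmoothTerm):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if np.unique(x).size < 2:
            raise DegenerateBasisError(f"covariate {term.covariate!r} is constant")
        self.term = term
        self.xmin, self.xmax = float(x.min()), float(x.max())
        k, deg = term.n_basis, term.degree
        # uniform knots extended past the range (Eilers-Marx): equally spaced
        # Greville points make the difference-penalty null space exactly the
        # polynomials of degree < penalty order
        h = (self.xmax - self.xmin) / (k - deg)
        self.knots = self.xmin + h * (np.arange(k + deg + 1) - deg)
        raw = self._raw(x)
        c = raw.sum(axis=0)
        c = c / np.linalg.norm(c)
        # orthonormal null-space basis of the constraint c' beta = 0
        q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, : k - 1]]))
        self.z = q[:, 1:k]
        d = np.diff(np.eye(k), n=term.penalty_order, axis=0)
        self.penalty = self.z.T @ (d.T @ d) @ self.z
        self._spl = BSpline(self.knots, np.eye(k), deg, extrapolate=True)
        self._dspl = self._spl.derivative()

    @property
    def n_cols(self) -> int:
        return self.z.shape[1]

    def _raw(self, x: np.ndarray) -> np.ndarray:
        # callers clip to [xmin, xmax]; extrapolate=True only relaxes the
        # exact-boundary bounds check
        return BSpline.design_matrix(x, self.knots, self.term.degree,
                                     extrapolate=True).toarray()

    def design(self, x) -> np.ndarray:
        """Basis values at x, linearly extrapolated beyond the fitted range."""
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.xmin, self.xmax)
        b = self._raw(xc)
        below, above = x < self.xmin, x > self.xmax
        if below.any():
            b[below] += np.outer(x[below] - self.xmin, self._dspl(self.xmin))
        if above.any():
            b[above] += np.outer(x[above] - self.xmax, self._dspl(self.xmax))
        return b @ self.z


def pspline_design(x, term: SmoothTerm):
    """Constrained B-spline design and scaled difference penalty for x.

    Returns ``(design, penalty)`` with ``penalty = lam * Z'D'D Z`` (lam = 1
    when the term leaves it unspecified).  Raises
    :class:`DegenerateBasisError` for a constant covariate.
    """
    basis = PSplineBasis(np.asarray(x, dtype=float), term)
    lam = 1.0 if term.lam is None else term.lam
    return basis.design(x), lam * basis.penalty


# ---------------------------------------------------------------------------
# additive model specification and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdditiveSpec:
    linear: tuple[str, ...] = ()
    smooth: tuple[SmoothTerm, ...] = ()
    family: str = "gaussian"  # "gaussian" | "binomial"

    def with_interaction(self, term: SmoothTerm, by: str) -> "AdditiveSpec":
        return replace(self, smooth=self.smooth + (replace(term, by=by),))


class _Design:
    """Assembled design: intercept | linear columns | smooth blocks."""

    def __init__(self, df: pd.DataFrame, spec: AdditiveSpec):
        self.spec = spec
        self.linear = list(spec.linear)
        self.bases: list[PSplineBasis | None] = []
        self.demoted: list[str] = []
        kept: list[SmoothTerm] = []
        for term in spec.smooth:
            try:
                basis = PSplineBasis(df[term.covariate].to_numpy(), term)
            except DegenerateBasisError:
                warnings.warn(f"smooth term {term.covariate!r} demoted to linear (constant)")
                self.demoted.append(term.covariate)
                if term.covariate not in self.linear:
                    self.linear.append(term.covariate)
                continue
            kept.append(term)
            self.bases.append(basis)
        self.smooth = kept
        self.slices: list[slice] = []
        p = 1 + len(self.linear)
        for basis in self.bases:
            self.slices.append(slice(p, p + basis.n_cols))
            p += basis.n_cols
        self.p = p

    def build(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        x = np.empty((n, self.p))
        x[:, 0] = 1.0
        for j, c in enumerate(self.linear, start=1):
            x[:, j] = df[c].to_numpy(dtype=float)
        for term, basis, sl in zip(self.smooth, self.bases, self.slices):
            block = basis.design(df[term.covariate].to_numpy())
            if term.by is not None:
                block = block * df[term.by].to_numpy(dtype=float)[:, None]
            x[:, sl] = block
        return x

    def penalty(self, lams: np.ndarray) -> np.ndarray:
        p = np.zeros((self.p, self.p))
        for lam, basis, sl in zip(lams, self.bases, self.slices):
            p[sl, sl] += lam * basis.penalty
        return p


@dataclass
class FittedAdditiveModel:
    """A fitted (penalized) additive model with everything needed to predict."""

    design: _Design
    coef: np.ndarray
    family: str
    lams: np.ndarray
    gcv: float
    edf: float
    sigma: float | None  # residual SD (gaussian only)
    n_obs: int
    target: str = ""
    t: float | None = None
    pooled: bool = False
    coef_cov: np.ndarray | None = None  # sandwich covariance of coef

    def linear_coef(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) of an unpenalized linear term."""
        idx = 1 + self.design.linear.index(name)
        se = float(np.sqrt(self.coef_cov[idx, idx])) if self.coef_cov is not None else np.nan
        return float(self.coef[idx]), se

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.design.build(df) @ self.coef

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(df)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return eta


def _gauss_eval(xtx, xty, yty, n, design, lams, ridge):
    a = xtx + design.penalty(lams) + ridge * np.eye(design.p)
    try:
        beta = np.linalg.solve(a, xty)
        edf = float(np.trace(np.linalg.solve(a, xtx)))
    except np.linalg.LinAlgError:
        return None, np.inf, np.nan, np.nan
    rss = float(yty - 2 * beta @ xty + beta @ xtx @ beta)
    rss = max(rss, 0.0)
    denom = max(n - edf, 1e-8)
    gcv = n * rss / denom ** 2
    return beta, gcv, edf, rss


def _coordinate_search(eval_at, n_terms, passes=2):
    """Coordinate-wise golden-section on log10(lambda) per smooth term."""
    lams = np.ones(n_terms)
    if n_terms == 0:
        return lams, eval_at(lams)
    best = eval_at(lams)
    for _ in range(passes):
        for j in range(n_terms):
            lo, hi = LOG_LAM_RANGE

            def f(loglam):
                trial = lams.copy()
                trial[j] = 10.0 ** loglam
                return eval_at(trial)

            x1 = hi - _GOLD * (hi - lo)
            x2 = lo + _GOLD * (hi - lo)
            f1, f2 = f(x1), f(x2)
            while hi - lo > 0.35:
                if f1 <= f2:
                    hi, x2, f2 = x2, x1, f1
                    x1 = hi - _GOLD * (hi - lo)
                    f1 = f(x1)
                else:
                    lo, x1, f1 = x1, x2, f2
                    x2 = lo + _GOLD * (hi - lo)
                    f2 = f(x2)
            cand = x1 if f1 <= f2 else x2
            val = min(f1, f2)
            if val < best:
                best = val
                lams[j] = 10.0 ** cand
    return lams, best


def _irls(x, y, design, lams, ridge, beta0=None, max_iter=50, tol=1e-8):
    n = len(y)
    pen = design.penalty(lams) + ridge * np.eye(design.p)
    beta = np.zeros(design.p) if beta0 is None else beta0.copy()
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = x * w[:, None]
        a = x.T @ xw + pen
        try:
            beta = np.linalg.solve(a, xw.T @ z)
        except np.linalg.LinAlgError:
            # complete separation or collinearity: penalized refit
            warnings.warn("singular IRLS system; adding ridge")
            a += 1e-4 * np.trace(a) / design.p * np.eye(design.p)
            beta = np.linalg.solve(a, xw.T @ z)
        if np.abs(beta).max() > 30.0:
            # quasi-separation: the penalty null space lets coefficients run
            # away; refit with an explicit ridge on the whole vector
            warnings.warn("quasi-separated logistic fit; adding ridge")
            pen = pen + 1e-2 * np.eye(design.p)
            beta = np.zeros(design.p)
            dev_old = np.inf
            continue
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = -2.0 * float(np.sum(y * np.log(np.clip(mu, 1e-12, None))
                                  + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    w = np.clip(mu * (1 - mu), 1e-10, None)
    xw = x * w[:, None]
    xtwx = x.T @ xw
    a = xtwx + pen
    edf = float(np.trace(np.linalg.solve(a, xtwx)))
    return beta, dev, edf, w, eta + (y - mu) / w


def fit_additive(df: pd.DataFrame, y: np.ndarray, spec: AdditiveSpec,
                 search: bool = True, ridge: float = 1e-8,
                 xtx_cache: dict | None = None) -> FittedAdditiveModel:
    """Fit a penalized additive model, choosing lambdas by GCV.

    Gaussian responses profile the smoothing parameters on the precomputed
    normal equations.  Binomial responses use performance iteration: a pilot
    IRLS fit at unit lambdas freezes the working weights, the lambdas are
    profiled on the weighted least-squares criterion, and IRLS is re-run at
    the selection.  ``xtx_cache`` lets several targets sharing one design
    matrix (the per-time confounder models) reuse X and X'X.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = _Design(df, spec)
    if n <= design.p // 4:
        raise FittingError(f"{n} rows is too few for {design.p} coefficients")
    fixed = [t.lam for t in design.smooth]
    if xtx_cache is not None and "x" in xtx_cache:
        x, xtx = xtx_cache["x"], xtx_cache["xtx"]
    else:
        x = design.build(df)
        xtx = x.T @ x
        if xtx_cache is not None:
            xtx_cache.update(x=x, xtx=xtx)

    if spec.family == "gaussian":
        xty = x.T @ y
        yty = float(y @ y)

        def eval_at(lams):
            full = _merge_lams(fixed, lams)
            return _gauss_eval(xtx, xty, yty, n, design, full, ridge)[1]

        free = sum(1 for f in fixed if f is None)
        if search and free:
            lams_free, _ = _coordinate_search(eval_at, free)
        else:
            lams_free = np.ones(free)
        lams = _merge_lams(fixed, lams_free)
        beta, gcv, edf, rss = _gauss_eval(xtx, xty, yty, n, design, lams, ridge)
        if beta is None:
            raise FittingError("normal equations are singular")
        sigma = math.sqrt(max(rss, 0.0) / max(n - edf, 1.0))
        a_inv = np.linalg.inv(xtx + design.penalty(lams) + ridge * np.eye(design.p))
        cov = sigma ** 2 * a_inv @ xtx @ a_inv
        return FittedAdditiveModel(design, beta, "gaussian", lams, gcv, edf, sigma, n,
                                   coef_cov=cov)

    if spec.family != "binomial":
        raise ValueError(f"unknown family {spec.family!r}")
    if y.min() == y.max():
        raise FittingError("binomial response is constant")

    pilot = _merge_lams(fixed, np.ones(sum(1 for f in fixed if f is None)))
    beta, dev, edf, w, z = _irls(x, y, design, pilot, ridge)
    free = sum(1 for f in fixed if f is None)
    if search and free:
        xw = x * w[:, None]
        xtwx = x.T @ xw
        xtwz = xw.T @ z
        ztwz = float((w * z) @ z)

        def eval_at(lams):
            full = _merge_lams(fixed, lams)
            return _gauss_eval(xtwx, xtwz, ztwz, n, design, full, ridge)[1]

        lams_free, _ = _coordinate_search(eval_at, free, passes=1)
        lams = _merge_lams(fixed, lams_free)
        beta, dev, edf, w, z = _irls(x, y, design, lams, ridge, beta0=beta)
    else:
        lams = pilot
    gcv = n * dev / max(n - edf, 1e-8) ** 2
    xtwx = (x * w[:, None]).T @ x
    a_inv = np.linalg.inv(xtwx + design.penalty(lams) + ridge * np.eye(design.p))
    cov = a_inv @ xtwx @ a_inv
    return FittedAdditiveModel(design, beta, "binomial", lams, gcv, edf, None, n,
                               coef_cov=cov)


def _merge_lams(fixed, free_values):
    out, i = [], 0
    free_values = np.atleast_1d(free_values)
    for f in fixed:
        if f is None:
            out.append(float(free_values[i]))
            i += 1
        else:
            out.append(float(f))
    return np.asarray(out)


def gcv_select(candidates, df: pd.DataFrame, y, family: str = "gaussian",
               margin: float = 0.005):
    """Fit each candidate AdditiveSpec and return the GCV minimiser.

    A later candidate displaces the incumbent only when it lowers the GCV
    score by at least the relative ``margin`` (default 0.5%): GCV alone,
    like AIC, admits spurious terms a sizeable fraction of the time, and the
    parsimony margin is far below the improvement a real effect produces.
    Deterministic: ties keep the earliest candidate.  Candidates that fail
    to fit are skipped; if none fit a FittingError is raised.
    """
    best = None
    best_gcv = np.inf
    for spec in candidates:
        try:
            fit = fit_additive(df, y, replace(spec, family=family))
        except (FittingError, DegenerateBasisError):
            continue
        if fit.gcv < best_gcv * (1 - margin):
            best, best_gcv = fit, fit.gcv
    if best is None:
        raise FittingError("no candidate model could be fitted")
    return best


# ---------------------------------------------------------------------------
# the per-time model set
# ---------------------------------------------------------------------------

TARGETS = ("sqrt_cd4", "cd4pct", "waz")


@dataclass(frozen=True)
class ModelRecipe:
    """Covariate recipe shared by the confounder and death models.

    History at t-1 (sqrt CD4, CD4%, WAZ, on the lag), baseline clinical
    values, demographics and ART at t-1.  Continuous covariates are smooth;
    sex, region and ART enter linearly.  At t=1 the lagged values *are* the
    baseline values, so the duplicated baseline terms are dropped there.
    """

    smooth_history: tuple[str, ...] = ("sqrt_cd4_lag", "cd4pct_lag", "waz_lag")
    smooth_baseline: tuple[str, ...] = ("sqrt_cd4_0", "cd4pct_0", "waz_0", "haz_0", "age")
    n_basis: int = 8
    degree: int = 3
    penalty_order: int = 2
    min_rows: int = 25
    min_deaths: int = 25
    explore_interactions: bool = False

    def _smooths(self, names) -> tuple[SmoothTerm, ...]:
        return tuple(SmoothTerm(c, self.n_basis, self.degree, self.penalty_order)
                     for c in names)

    def spec(self, linear_extra: tuple[str, ...], t: float | None,
             region_cols: tuple[str, ...], pooled: bool = False) -> AdditiveSpec:
        smooth_names = list(self.smooth_history)
        dup = {"sqrt_cd4_0", "cd4pct_0", "waz_0"}
        for c in self.smooth_baseline:
            if t == FIT_TIMES[0] and c in dup and not pooled:
                continue
            smooth_names.append(c)
        if pooled:
            smooth_names.append("t")
        linear = ("male",) + region_cols + ("art_lag",) + linear_extra
        return AdditiveSpec(linear=linear, smooth=self._smooths(smooth_names))


@dataclass
class ModelSet:
    """Fitted models for every fit time: three confounder models + death."""

    models: dict[float, dict[str, FittedAdditiveModel]]
    recipe: ModelRecipe
    region_cols: tuple[str, ...]
    horizon: float

    def model(self, t: float, target: str) -> FittedAdditiveModel:
        return self.models[float(t)][target]

    @property
    def complete(self) -> bool:
        need = set(TARGETS) | {"death"}
        return all(need <= set(v.keys()) for v in self.models.values()) and \
            set(self.models) == {float(t) for t in grid_times(self.horizon)[1:]}

    def summary(self) -> dict:
        """JSON-serialisable per-time fit report (sigma, GCV, edf, terms)."""
        out: dict = {}
        for t, entry in sorted(self.models.items()):
            out[f"t{t:g}"] = {
                target: {
                    "pooled": m.pooled,
                    "n_obs": m.n_obs,
                    "edf": round(m.edf, 2),
                    "gcv": m.gcv,
                    "sigma": m.sigma,
                    "n_coef": len(m.coef),
                    "lambda": [float(l) for l in m.lams],
                } for target, m in entry.items()}
        return out


def make_fit_frame(panel) -> pd.DataFrame:
    """Stacked per-time regression frame with lagged history and baselines.

    One row per (child, t > 0) still in follow-up at t, with the target
    values at t, history at the previous grid time, baseline covariates and
    the death indicator for the interval ending at t.
    """
    d = panel.data.sort_values(["child", "t"], kind="stable").reset_index(drop=True)
    d["sqrt_cd4"] = np.sqrt(d["cd4"])
    g = d.groupby("child")
    out = d[["child", "t", "death", "censor"]].copy()
    out["sqrt_cd4"] = d["sqrt_cd4"]
    out["cd4pct"] = d["cd4pct"]
    out["waz"] = d["waz"]
    for c in ("sqrt_cd4", "cd4pct", "waz"):
        out[f"{c}_lag"] = g[c].shift(1)
    out["art_lag"] = g["art"].shift(1)
    out = out[out["t"] > 0]

    base = panel.baseline.copy()
    base["sqrt_cd4_0"] = np.sqrt(base["cd4_0"])
    base["male"] = (base["sex"] == "male").astype(float)
    region_cols = tuple(f"region_{r}" for r in sorted(base["region"].unique())[1:])
    for rc in region_cols:
        base[rc] = (base["region"] == rc.removeprefix("region_")).astype(float)
    keep = ["child", "age", "male", "sqrt_cd4_0", "cd4pct_0", "waz_0", "haz_0"] + list(region_cols)
    out = out.merge(base[keep].rename(columns={"cd4pct_0": "cd4pct_0", "waz_0": "waz_0"}),
                    on="child", how="left")
    out.attrs["region_cols"] = region_cols
    return out


def fit_confounder_model(frame_t: pd.DataFrame, target: str, recipe: ModelRecipe,
                         t: float, region_cols: tuple[str, ...],
                         xtx_cache: dict | None = None,
                         pooled: bool = False) -> FittedAdditiveModel:
    """Gaussian additive fit for one confounder at one time point.

    Rows must be survivors of the interval ending at t with complete
    covariates; CD4 is handled on the sqrt scale on both sides.
    """
    spec = recipe.spec((), t, region_cols, pooled=pooled)
    y = frame_t[target].to_numpy(dtype=float)
    fit = fit_additive(frame_t, y, spec, xtx_cache=xtx_cache)
    fit.target, fit.t, fit.pooled = target, t, pooled
    return fit


def fit_death_model(frame_t: pd.DataFrame, recipe: ModelRecipe, t: float,
                    region_cols: tuple[str, ...],
                    xtx_cache: dict | None = None,
                    pooled: bool = False) -> FittedAdditiveModel:
    """Logistic additive fit for death in the interval ending at t."""
    spec = replace(recipe.spec((), t, region_cols, pooled=pooled), family="binomial")
    y = frame_t["death"].to_numpy(dtype=float)
    fit = fit_additive(frame_t, y, spec, xtx_cache=xtx_cache)
    fit.target, fit.t, fit.pooled = "death", t, pooled
    return fit


_COVARIATE_COLS = ("sqrt_cd4_lag", "cd4pct_lag", "waz_lag", "art_lag",
                   "sqrt_cd4_0", "cd4pct_0", "waz_0", "haz_0", "age", "male")


def fit_model_set(panel, recipe: ModelRecipe | None = None) -> ModelSet:
    """Fit the full per-time model set, with pooled fallback where sparse.

    The three confounder targets at a time point share one design matrix and
    its cross-products.  A time point falls back to the pooled-across-time
    model (with a smooth time effect) when it has fewer than ``min_rows``
    usable rows, or fewer than ``min_deaths`` deaths for the death model.
    """
    recipe = recipe or ModelRecipe()
    frame = make_fit_frame(panel)
    region_cols = frame.attrs["region_cols"]
    frame = frame[frame["censor"] == 0]
    needed = list(_COVARIATE_COLS) + list(region_cols)
    usable = frame.dropna(subset=needed)

    times = [float(t) for t in grid_times(panel.horizon)[1:]]
    pooled_cache: dict[str, FittedAdditiveModel] = {}

    def pooled_model(kind: str) -> FittedAdditiveModel:
        if kind not in pooled_cache:
            surv = usable[usable["death"] == 0].dropna(subset=list(TARGETS))
            if kind == "death":
                pooled_cache[kind] = fit_death_model(usable, recipe, np.nan,
                                                     region_cols, pooled=True)
            else:
                pooled_cache[kind] = fit_confounder_model(surv, kind, recipe, np.nan,
                                                          region_cols, pooled=True)
        return pooled_cache[kind]

    models: dict[float, dict[str, FittedAdditiveModel]] = {}
    for t in times:
        ft = usable[usable["t"] == t]
        surv = ft[ft["death"] == 0].dropna(subset=list(TARGETS))
        entry: dict[str, FittedAdditiveModel] = {}
        cache: dict = {}
        for target in TARGETS:
            if len(surv) < recipe.min_rows:
                entry[target] = pooled_model(target)
                continue
            try:
                entry[target] = fit_confounder_model(surv, target, recipe, t,
                                                     region_cols, xtx_cache=cache)
            except (FittingError, DegenerateBasisError):
                entry[target] = pooled_model(target)
        n_deaths = int(ft["death"].sum())
        if len(ft) < recipe.min_rows or n_deaths < recipe.min_deaths:
            entry["death"] = pooled_model("death")
        else:
            try:
                entry["death"] = fit_death_model(ft, recipe, t, region_cols)
            except FittingError:
                entry["death"] = pooled_model("death")
        models[t] = entry
    return ModelSet(models, recipe, region_cols, panel.horizon)
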