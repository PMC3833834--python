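"""Longitudinal multiple imputation in the EM-bootstrap style.

Remaining missing baseline and follow-up values (after the 9-month LOCF
window) are imputed under a joint multivariate-normal model: for each of m
replicates, a child-level bootstrap resample is drawn, the normal parameters
are estimated by expectation maximisation, and the *original* data's missing
cells are filled with draws from the estimated conditional distribution
given each row's observed cells.  CD4 counts are modelled on the square-root
scale and back-transformed with truncation at zero; CD4% is clamped to
[0, 100].  Rubin's rules combine estimates across the m completed datasets.

The default matrix layout is child-level wide (one row per child,
time-indexed columns), which encodes the longitudinal structure directly:
each column's neighbours in time are its lags and leads.  A long layout
(one row per child-time with explicit lag/lead columns and polynomial time
trends) is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .grid import grid_times
from .cohort_prep import IntervalPanel, CONFOUNDERS

__all__ = [
    "ImputationSpec",
    "ImputedSet",
    "build_imputation_matrix",
    "em_mvnorm",
    "em_bootstrap_impute",
    "impute_panel",
    "overimpute",
    "rubin_combine",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputationSpec:
    m: int = 10
    ridge: float = 1e-4          # scaled by trace(cov)/p each M-step
    max_em_iter: int = 1500
    tol: float = 1e-4            # relative parameter change
    time_trend: int = 2          # polynomial degree (long layout)
    layout: str = "wide"         # "wide" | "long"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ImputedSet:
    """m completed panels plus per-replicate EM diagnostics."""

    panels: list[IntervalPanel]
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.panels)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_imputation_matrix(panel: IntervalPanel, spec: ImputationSpec | None = None):
    """Encode the panel as a numeric matrix for the normal imputation model.

    Returns ``(df, colmap)`` where ``colmap`` inverts matrix cells back to
    panel/baseline cells.  The model includes all baseline and follow-up
    variables, mortality, follow-up time, the carried-forward indicator and
    region (as indicator contrasts).  Cells structurally absent (after the
    death or censoring row) are masked and never imputed.

    Wide layout: one row per child, columns ``sqrt_cd4_t{t}`` etc. per grid
    time.  Long layout: one row per child-time with lag-1/lead-1 columns for
    CD4, CD4% and WAZ and polynomial time trends.
    """
    spec = spec or ImputationSpec()
    base = panel.baseline.set_index("child")
    d = panel.data

    demo = pd.DataFrame(index=base.index)
    demo["age"] = base["age"]
    demo["male"] = (base["sex"] == "male").astype(float)
    for r in sorted(base["region"].unique())[1:]:
        demo[f"region_{r}"] = (base["region"] == r).astype(float)
    demo["haz_0"] = base["haz_0"]

    died = d.groupby("child")["death"].max()
    fup = d.groupby("child")["t"].max()
    carried_cols = [f"carried_{c}" for c in CONFOUNDERS]
    carried_frac = d[carried_cols].any(axis=1).groupby(d["child"]).mean()
    demo["died"] = died.reindex(demo.index).fillna(0)
    demo["followup_months"] = fup.reindex(demo.index)
    demo["carried_frac"] = carried_frac.reindex(demo.index).fillna(0)

    if spec.layout == "wide":
        times = grid_times(panel.horizon)
        wide = d.pivot(index="child", columns="t", values=list(CONFOUNDERS))
        # structural mask: rows after death/censor simply do not exist in the
        # panel -> their cells are absent from `wide` and must not be imputed
        exists = d.assign(one=1.0).pivot(index="child", columns="t", values="one")
        blocks, colmap = [demo], {}
        for c in CONFOUNDERS:
            for t in times:
                name = f"{'sqrt_cd4' if c == 'cd4' else c}_t{t:g}"
                if c in wide.columns.get_level_values(0) and t in wide[c].columns:
                    v = wide[(c, t)].reindex(demo.index)
                else:
                    v = pd.Series(np.nan, index=demo.index)
                if c == "cd4":
                    v = np.sqrt(v)
                structural = exists.reindex(demo.index).get(t)
                structural = (structural.isna() if structural is not None
                              else pd.Series(True, index=demo.index))
                blocks.append(v.rename(name).to_frame())
                colmap[name] = {"var": c, "t": t, "sqrt": c == "cd4",
                                "structural_missing": structural}
        df = pd.concat(blocks, axis=1)
    elif spec.layout == "long":
        df = d.set_index(["child", "t"])[list(CONFOUNDERS)].copy()
        df["sqrt_cd4"] = np.sqrt(df.pop("cd4"))
        g = df.groupby(level="child")
        for c in ("sqrt_cd4", "cd4pct", "waz"):
            df[f"{c}_lag1"] = g[c].shift(1)
            df[f"{c}_lead1"] = g[c].shift(-1)
        df["carried"] = d.set_index(["child", "t"])[carried_cols].any(axis=1).astype(float)
        tvals = df.index.get_level_values("t").to_numpy(dtype=float)
        for p in range(1, spec.time_trend + 1):
            df[f"t_pow{p}"] = tvals ** p
        df = df.join(demo, on="child")
        colmap = {c: {"var": c} for c in ("sqrt_cd4", "cd4pct", "waz")}
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")

    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing columns {all_missing}")
        df = df.drop(columns=all_missing)
        for c in all_missing:
            colmap.pop(c, None)
    return df, colmap


# ---------------------------------------------------------------------------
# EM for the multivariate normal with missing data
# ---------------------------------------------------------------------------

def _pattern_groups(mask: np.ndarray):
    """Group row indices by missingness pattern (True = missing)."""
    order = np.lexsort(mask.T[::-1])
    sm = mask[order]
    change = np.any(sm[1:] != sm[:-1], axis=1)
    starts = np.concatenate([[0], np.nonzero(change)[0] + 1, [len(order)]])
    for a, b in zip(starts[:-1], starts[1:]):
        yield sm[a], order[a:b]


def _loglik(x: np.ndarray, mask: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    ll = 0.0
    for pat, rows in _pattern_groups(mask):
        o = ~pat
        if not o.any():
            continue
        xo = x[np.ix_(rows, np.nonzero(o)[0])] - mu[o]
        so = sigma[np.ix_(o, o)]
        chol = np.linalg.cholesky(so)
        zz = solve_triangular(chol, xo.T, lower=True)
        ll += (-0.5 * (zz ** 2).sum()
               - len(rows) * (np.log(np.diag(chol)).sum() + 0.5 * o.sum() * np.log(2 * np.pi)))
    return float(ll)


def em_mvnorm(x: np.ndarray, max_iter: int = 500, tol: float = 1e-4,
              ridge: float = 1e-4, track_loglik: bool = False):
    """EM estimate of (mu, Sigma) under MAR missingness.

    ``ridge`` is scaled by trace(Sigma)/p and added to the diagonal each
    M-step to stabilise near-singular covariances.  Returns a dict with
    mu, sigma, n_iter, converged, and (optionally) the loglik trace.
    """
    x = np.asarray(x, dtype=float)
    mask = np.isnan(x)
    n, p = x.shape
    col_obs = ~mask
    if (col_obs.sum(axis=0) < 2).any():
        raise ValueError("every modelled column needs >= 2 observed rows")

    mu = np.nanmean(x, axis=0)
    xf = np.where(mask, mu, x)
    sigma = np.cov(xf, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    # ridge pinned to the initial scale so the EM fixed point is stationary
    ridge_term = (ridge * np.trace(sigma) / p) * np.eye(p)

    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pat, rows in _pattern_groups(mask):
            o, m = np.nonzero(~pat)[0], np.nonzero(pat)[0]
            xr = x[rows]
            if m.size == 0:
                sum_x += xr.sum(axis=0)
                sum_xx += xr.T @ xr
                continue
            if o.size == 0:
                cond_mean = np.tile(mu[m], (len(rows), 1))
                cond_cov = sigma[np.ix_(m, m)]
            else:
                soo = sigma[np.ix_(o, o)]
                som = sigma[np.ix_(o, m)]
                try:
                    w = np.linalg.solve(soo, som)
                except np.linalg.LinAlgError:
                    raise ConvergenceError("singular covariance despite ridge") from None
                cond_mean = mu[m] + (xr[:, o] - mu[o]) @ w
                cond_cov = sigma[np.ix_(m, m)] - som.T @ w
            filled = xr.copy()
            filled[:, m] = cond_mean
            sum_x += filled.sum(axis=0)
            cross = filled.T @ filled
            cross[np.ix_(m, m)] += len(rows) * cond_cov
            sum_xx += cross
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new) + ridge_term

        denom = max(np.abs(mu).max(), np.abs(sigma).max(), 1e-12)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()) / denom
        mu, sigma = mu_new, sigma_new
        if track_loglik:
            lls.append(_loglik(x, mask, mu, sigma))
        if delta < tol:
            converged = True
            break
    return {"mu": mu, "sigma": sigma, "n_iter": it, "converged": converged,
            "loglik_trace": lls}


def _conditional_draws(x: np.ndarray, mask: np.ndarray, mu: np.ndarray,
                       sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw missing cells from N(mu, Sigma) conditional on observed cells."""
    out = x.copy()
    for pat, rows in _pattern_groups(mask):
        o, m = np.nonzero(~pat)[0], np.nonzero(pat)[0]
        if m.size == 0:
            continue
        if o.size == 0:
            cond_mean = np.tile(mu[m], (len(rows), 1))
            cond_cov = sigma[np.ix_(m, m)]
        else:
            soo = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            w = np.linalg.solve(soo, som)
            cond_mean = mu[m] + (x[np.ix_(rows, o)] - mu[o]) @ w
            cond_cov = sigma[np.ix_(m, m)] - som.T @ w
        cond_cov = (cond_cov + cond_cov.T) / 2
        evals, evecs = np.linalg.eigh(cond_cov)
        root = evecs * np.sqrt(np.clip(evals, 0, None))
        draws = cond_mean + rng.standard_normal((len(rows), m.size)) @ root.T
        out[np.ix_(rows, m)] = draws
    return out


def em_bootstrap_impute(matrix: pd.DataFrame, spec: ImputationSpec, seed: int):
    """m completed copies of ``matrix`` via the EM-bootstrap algorithm.

    Each replicate estimates the normal parameters on a row-level (child-
    level, since rows are children in the wide layout) bootstrap resample
    and imputes the original data's missing cells by conditional draws.
    Fully observed input short-circuits to m identical copies.
    """
    x = matrix.to_numpy(dtype=float)
    mask = np.isnan(x)
    if not mask.any():
        return [matrix.copy() for _ in range(spec.m)], [
            {"n_iter": 0, "converged": True} for _ in range(spec.m)]

    n = x.shape[0]
    completed, diags = [], []
    root = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    for j, ss in enumerate(root.spawn(spec.m)):
        rng = np.random.Generator(np.random.PCG64(ss))
        fit = None
        for attempt in range(3):
            idx = rng.integers(0, n, size=n)
            xb = x[idx]
            # a resample may lose (nearly) all observations of a column, or
            # land on a slowly-converging configuration; redraw in either case
            if (~np.isnan(xb)).sum(axis=0).min() < 2:
                continue
            fit = em_mvnorm(xb, max_iter=spec.max_em_iter, tol=spec.tol,
                            ridge=spec.ridge)
            if fit["converged"]:
                break
        if fit is None or not fit["converged"]:
            raise ConvergenceError(f"EM did not converge in replicate {j}")
        filled = _conditional_draws(x, mask, fit["mu"], fit["sigma"], rng)
        completed.append(pd.DataFrame(filled, index=matrix.index, columns=matrix.columns))
        diags.append({"n_iter": fit["n_iter"], "converged": True})
    return completed, diags


# ---------------------------------------------------------------------------
# panel-level orchestration
# ---------------------------------------------------------------------------

def impute_panel(panel: IntervalPanel, spec: ImputationSpec | None = None,
                 seed: int = 0) -> ImputedSet:
    """Multiply-impute a LOCF'd panel (wide layout) into m completed panels.

    Observed cells (including LOCF fills) are never altered; only cells
    still missing after the 9-month window - and the missing baseline
    clinical values - are filled.  Imputed CD4 is squared back from the
    sqrt scale with truncation at 0; CD4% is clamped to [0, 100].
    """
    spec = spec or ImputationSpec()
    matrix, colmap = build_imputation_matrix(panel, spec)
    completed, diags = em_bootstrap_impute(matrix, spec, seed)

    panels = []
    base_cols = {"cd4": "cd4_0", "cd4pct": "cd4pct_0", "waz": "waz_0"}
    for comp in completed:
        newp = panel.copy()
        d = newp.data.set_index(["child", "t"])
        nb = newp.baseline.set_index("child")
        if "haz_0" in nb.columns and "haz_0" in comp.columns:
            miss = nb["haz_0"].isna()
            nb.loc[miss, "haz_0"] = comp["haz_0"].reindex(nb.index)[miss]
        for name, info in colmap.items():
            if "t" not in info:
                continue
            var, t = info["var"], info["t"]
            vals = comp[name].reindex(d.index.get_level_values("child").unique())
            if info.get("sqrt"):
                vals = np.clip(vals, 0.0, None) ** 2
            if var == "cd4pct":
                vals = np.clip(vals, 0.0, 100.0)
            structural = info["structural_missing"]
            fillable = ~structural.reindex(vals.index).fillna(True)
            key = pd.MultiIndex.from_product([vals.index[fillable], [t]])
            key = key.intersection(d.index)
            still_missing = d.loc[key, var].isna()
            tgt = key[still_missing.to_numpy()]
            d.loc[tgt, var] = vals.loc[tgt.get_level_values(0)].to_numpy()
            if t == 0.0:
                bmiss = nb[base_cols[var]].isna()
                nb.loc[bmiss, base_cols[var]] = vals.reindex(nb.index)[bmiss]
        newp.data = d.reset_index()
        newp.baseline = nb.reset_index()
        panels.append(newp)
    return ImputedSet(panels, diags)


def overimpute(matrix: pd.DataFrame, spec: ImputationSpec, seed: int,
               frac: float = 0.05) -> dict:
    """Overimputation diagnostic: hide a fraction of observed cells, impute
    them, and report the RMSE against the hidden truth per column (plus the
    observed-column SD for scale).  Large ratios flag a poorly fitting
    imputation model."""
    rng = np.random.default_rng(seed)
    x = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    hide = obs & (rng.random(x.shape) < frac)
    masked = x.copy()
    masked[hide] = np.nan
    completed, _ = em_bootstrap_impute(
        pd.DataFrame(masked, index=matrix.index, columns=matrix.columns), spec, seed)
    stacked = np.mean([c.to_numpy(dtype=float) for c in completed], axis=0)
    out = {}
    for j, col in enumerate(matrix.columns):
        sel = hide[:, j]
        if sel.sum() < 3:
            continue
        rmse = float(np.sqrt(np.mean((stacked[sel, j] - x[sel, j]) ** 2)))
        out[col] = {"rmse": rmse, "n_hidden": int(sel.sum()),
                    "observed_sd": float(np.nanstd(x[:, j]))}
    return out


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_combine(point_estimates, within_variances):
    """Pool estimates across imputations by Rubin's rules.

    Returns ``(pooled, total_variance, between, within)`` with
    ``total = within_mean + (1 + 1/m) * between``; m = 1 degenerates to the
    single estimate with zero between-variance.
    """
    est = np.asarray(point_estimates, dtype=float)
    wv = np.asarray(within_variances, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    if est.shape != wv.shape:
        raise ValueError("estimates and variances must have equal length")
    m = est.shape[0]
    pooled = est.mean(axis=0)
    within = wv.mean(axis=0)
    between = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(pooled)
    total = within + (1.0 + 1.0 / m) * between
    return pooled, total, between, within
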