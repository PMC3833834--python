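"""Pre-ART time-to-threshold analyses and the naive confounded comparison.

Children presenting above both CD4 thresholds are followed until their CD4
count or CD4% first drops below the threshold pair.  The crossing
probability is estimated two ways: (A) one minus the Kaplan-Meier survival
function, censoring ART initiation, death and LTFU; and (B) an
Aalen-Johansen cumulative incidence of crossing treated against those
competing events, divided by one minus the probability that a competing
event occurred first, with child-level bootstrap confidence intervals.

``naive_art_association`` fits the deliberately confounded comparison: a
pooled discrete-time logistic hazard model of death on time-varying ART
status adjusted only for baseline severity and demographics - the analysis
whose upward bias motivates the g-formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from .cohort_prep import IntervalPanel
from .grid import grid_times

__all__ = [
    "SurvivalCurve",
    "km_threshold_crossing",
    "cif_threshold_crossing",
    "naive_art_association",
]


@dataclass
class SurvivalCurve:
    """A cumulative-probability curve with 95% bounds and the risk set."""

    times: np.ndarray
    estimate: np.ndarray   # cumulative probability, nondecreasing
    lower: np.ndarray
    upper: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.estimate[idx]) if idx >= 0 else 0.0


def _threshold_events(panel: IntervalPanel, cd4_threshold: float, pct_threshold: float):
    """Per-child first crossing / competing-event / censoring times.

    Eligibility: starting at or above BOTH thresholds at t=0.  Event =
    first grid time with an observed value below either threshold, using
    only pre-ART follow-up.  Competing events: ART initiation, death, LTFU.
    Administrative end of follow-up (the child's last panel row) censors.
    """
    base = panel.baseline
    eligible = base[(base["cd4_0"] >= cd4_threshold) & (base["cd4pct_0"] >= pct_threshold)]
    if eligible.empty:
        raise ValueError("no children start above both thresholds")
    d = panel.data[panel.data["child"].isin(eligible["child"])]
    d = d.sort_values(["child", "t"], kind="stable")

    below = (d["cd4"] < cd4_threshold) | (d["cd4pct"] < pct_threshold)
    compete = (d["art"] == 1) | (d["death"] == 1) | (d["censor"] == 1)

    rows = []
    for child, g in d.groupby("child", sort=False):
        cross_t = g.loc[below.loc[g.index], "t"].min()
        comp_t = g.loc[compete.loc[g.index], "t"].min()
        end_t = g["t"].max()
        cands = [(cross_t, 1), (comp_t, 2), (end_t, 0)]
        cands = [(t, e) for t, e in cands if np.isfinite(t)]
        t_ev, ev = min(cands, key=lambda p: (p[0], p[1] == 0))
        rows.append((child, t_ev, ev))
    return pd.DataFrame(rows, columns=["child", "time", "event"])


def km_threshold_crossing(panel: IntervalPanel, cd4_threshold: float,
                          pct_threshold: float) -> SurvivalCurve:
    """1 - Kaplan-Meier probability of staying above the threshold pair.

    ART initiation, death and LTFU censor; Greenwood-type 95% intervals.
    """
    ev = _threshold_events(panel, cd4_threshold, pct_threshold)
    kmf = KaplanMeierFitter()
    kmf.fit(ev["time"], event_observed=(ev["event"] == 1))
    tl = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    lower = 1.0 - ci.iloc[:, 1].to_numpy()
    upper = 1.0 - ci.iloc[:, 0].to_numpy()
    at_risk = np.array([(ev["time"] >= t).sum() for t in tl])
    return SurvivalCurve(tl, 1.0 - surv, lower, upper, at_risk)


def cif_threshold_crossing(panel: IntervalPanel, cd4_threshold: float,
                           pct_threshold: float, n_boot: int = 200,
                           seed: int = 0) -> SurvivalCurve:
    """Competing-risks crossing probability with bootstrap intervals.

    Estimate(t) = AJ cumulative incidence of crossing / (1 - AJ cumulative
    incidence of any competing event), capped at 1; times where the
    denominator vanishes are returned as NaN.  95% bounds are child-level
    bootstrap percentiles over ``n_boot`` resamples.
    """
    ev = _threshold_events(panel, cd4_threshold, pct_threshold)
    times = grid_times(panel.horizon)

    def estimate(frame: pd.DataFrame) -> np.ndarray:
        return _cif_ratio(frame, times)

    est = estimate(ev)
    rng = np.random.default_rng(seed)
    if n_boot > 0:
        draws = np.empty((n_boot, len(times)))
        for b in range(n_boot):
            idx = rng.integers(0, len(ev), size=len(ev))
            draws[b] = estimate(ev.iloc[idx].reset_index(drop=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lower = np.nanpercentile(draws, 2.5, axis=0)
            upper = np.nanpercentile(draws, 97.5, axis=0)
    else:
        lower = np.full_like(est, np.nan)
        upper = np.full_like(est, np.nan)
    at_risk = np.array([(ev["time"] >= t).sum() for t in times])
    return SurvivalCurve(times, est, lower, upper, at_risk)


def _aj_cif(frame: pd.DataFrame, event_of_interest: int, times: np.ndarray) -> np.ndarray:
    if not (frame["event"] == event_of_interest).any():
        return np.zeros(len(times))
    ajf = AalenJohansenFitter(calculate_variance=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ajf.fit(frame["time"], frame["event"], event_of_interest=event_of_interest)
    cif = ajf.cumulative_density_
    tl = cif.index.to_numpy(dtype=float)
    vals = cif.iloc[:, 0].to_numpy()
    idx = np.searchsorted(tl, times, side="right") - 1
    return np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)


def _cif_ratio(frame: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    num = _aj_cif(frame, 1, times)
    comp = _aj_cif(frame, 2, times)
    denom = 1.0 - comp
    out = np.full(len(times), np.nan)
    ok = denom > 1e-12
    out[ok] = np.minimum(num[ok] / denom[ok], 1.0)
    if (~ok).any():
        warnings.warn("competing-event probability reached 1; estimate undefined "
                      "from that time onward")
    return out


def naive_art_association(panel: IntervalPanel):
    """Hazard ratio for death on time-varying ART, baseline adjustment only.

    Pooled discrete-time logistic model of Y_t on the ART indicator at the
    start of the interval, baseline CD4 (sqrt scale), CD4%, WAZ, HAZ, age,
    sex, region, and a cubic B-spline time effect.  Returns
    ``(hazard_ratio, (lower, upper))`` from the Wald interval of the
    exponentiated ART coefficient.  This estimator ignores time-dependent
    confounding by design.
    """
    from .regime_models import make_fit_frame

    frame = make_fit_frame(panel)
    frame = frame[frame["censor"] == 0]
    region_cols = list(frame.attrs.get("region_cols", ()))
    covs = ["art_lag", "sqrt_cd4_0", "cd4pct_0", "waz_0", "haz_0",
            "age", "male"] + region_cols
    frame = frame.dropna(subset=covs + ["death"])
    if frame["death"].sum() == 0:
        raise ValueError("no deaths: hazard ratio is not estimable")

    t = frame["t"].to_numpy(dtype=float)
    knots = np.percentile(t, [25, 50, 75])
    tb = _natural_time_basis(t, knots)
    x = np.column_stack([frame[c].to_numpy(dtype=float) for c in covs] + [tb])
    x = sm.add_constant(x, prepend=True)
    fit = sm.GLM(frame["death"].to_numpy(), x, family=sm.families.Binomial()).fit()
    coef = fit.params[1]          # art_lag
    se = fit.bse[1]
    hr = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)))
    return hr, ci


def _natural_time_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Small unpenalized truncated-power basis for a smooth time trend."""
    cols = [t, t ** 2 / 36.0]
    for k in np.unique(knots):
        cols.append(np.clip(t - k, 0, None) ** 2 / 36.0)
    return np.column_stack(cols)
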