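"""From raw visit tables to the analysis-ready discrete-time panel.

The panel holds, per child and nominal time t in {0, 1, 3, ..., 36} months:
the time-dependent confounders L_t = (CD4, CD4%, WAZ) with carried-forward
flags, the on-ART indicator A_t (1 from the first grid time >= ART start,
intention-to-treat), the death indicator Y_t for the interval ending at t,
and the censoring indicator C_t.  Y and C are absorbing: the terminal row is
kept, nothing follows it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VISIT_GRID, HORIZON, window_bounds, grid_times, next_grid_time
from .synthetic_cohort import RawCohort

__all__ = [
    "IntervalPanel",
    "filter_eligible",
    "discretise",
    "apply_locf",
    "flag_ltfu",
]

CONFOUNDERS = ("cd4", "cd4pct", "waz")

#: maximum age gap (months) over which a last observation may be carried
LOCF_MAX_GAP = 9.0
#: months without facility contact before database closure that define LTFU
LTFU_GAP = 9.0


@dataclass
class IntervalPanel:
    """Tidy discrete-time panel plus the child-level baseline table.

    ``data`` columns: child, t, cd4, cd4pct, waz, carried_cd4, carried_cd4pct,
    carried_waz, art, death, censor, censor_reason.
    ``baseline`` columns: child, age, sex, region, cd4_0, cd4pct_0, waz_0, haz_0.
    """

    data: pd.DataFrame
    baseline: pd.DataFrame
    events: pd.DataFrame | None = None
    horizon: float = HORIZON

    def copy(self) -> "IntervalPanel":
        return IntervalPanel(self.data.copy(), self.baseline.copy(),
                             None if self.events is None else self.events.copy(),
                             self.horizon)

    def validate(self) -> None:
        d = self.data
        if not set(d["t"].unique()) <= set(VISIT_GRID):
            raise ValueError("panel times off the visit grid")
        g = d.sort_values(["child", "t"]).groupby("child")
        if (g["art"].diff().dropna() < 0).any():
            raise ValueError("A_t must be nondecreasing within child")
        for col in ("death", "censor"):
            # absorbing: at most one 1 per child and nothing after it
            after = g[col].cumsum().groupby(d["child"]).shift(1).fillna(0)
            if (after > 0).any():
                raise ValueError(f"rows exist after the first {col}=1")
        for c in CONFOUNDERS:
            both = d[f"carried_{c}"] & d[c].isna()
            if both.any():
                raise ValueError("carried flag set on a missing cell")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def filter_eligible(raw: RawCohort) -> tuple[RawCohort, dict[str, int]]:
    """Apply the cohort's entry criteria; returns (filtered cohort, exclusion log).

    Children must be 24-60 months old at enrolment, ART-naive at entry
    (no ART start strictly before the first visit), and have at least one
    follow-up visit after the enrolment visit.
    """
    base = raw.baseline
    ev = raw.events.set_index("child")
    age_months = base["age"].to_numpy() * 12.0
    ok_age = (age_months >= 24.0) & (age_months <= 60.0)

    art = ev["art_start"].reindex(base["child"]).to_numpy()
    naive = ~(np.nan_to_num(art, nan=np.inf) < 0.0)

    n_visits = raw.visits[raw.visits["t"] > 0].groupby("child").size()
    has_fup = base["child"].map(n_visits).fillna(0).to_numpy() >= 1

    log = {
        "age_ineligible": int((~ok_age).sum()),
        "not_art_naive": int((ok_age & ~naive).sum()),
        "no_followup": int((ok_age & naive & ~has_fup).sum()),
    }
    keep = base.loc[ok_age & naive & has_fup, "child"]
    log["included"] = int(keep.size)

    out = RawCohort(
        baseline=raw.baseline[raw.baseline["child"].isin(keep)].reset_index(drop=True),
        visits=raw.visits[raw.visits["child"].isin(keep)].reset_index(drop=True),
        events=raw.events[raw.events["child"].isin(keep)].reset_index(drop=True),
        truth=None if raw.truth is None else
        raw.truth[raw.truth["child"].isin(keep)].reset_index(drop=True),
    )
    return out, log


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def _assign_windows(visits: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Map each observation to its nominal grid time, keeping the winner per window.

    Within a window the observation minimising |observed - nominal| wins;
    on a tie the earlier observation wins.
    """
    bounds = window_bounds(horizon)
    t_obs = visits["t"].to_numpy(dtype=float)
    nominal = np.full(t_obs.shape, np.nan)
    for t_nom, (lo, hi) in bounds.items():
        if t_nom == 0.0:
            sel = t_obs == 0.0
        else:
            sel = (t_obs > lo) & (t_obs <= hi)
        nominal[sel] = t_nom
    beyond = t_obs > max(b[1] for b in bounds.values())
    if beyond.any():
        warnings.warn(f"{int(beyond.sum())} visit(s) beyond the horizon ignored")
    v = visits.assign(nominal=nominal).dropna(subset=["nominal"])
    v = v.assign(dist=(v["t"] - v["nominal"]).abs())
    v = v.sort_values(["child", "nominal", "dist", "t"], kind="stable")
    return v.groupby(["child", "nominal"], as_index=False).first()


def discretise(raw: RawCohort, horizon: float = HORIZON) -> IntervalPanel:
    """Build the discrete-time panel from an eligible raw cohort.

    Rows run from t=0 until the death row (Y=1 at the first grid time >=
    the death month), or the horizon.  Censoring is applied separately by
    :func:`flag_ltfu`.
    """
    times = grid_times(horizon)
    picked = _assign_windows(raw.visits, horizon)
    children = raw.baseline["child"].to_numpy()
    ev = raw.events.set_index("child").reindex(children)
    death = ev["death_month"].to_numpy(dtype=float)
    art = ev["art_start"].to_numpy(dtype=float)

    # grid time of the death row (first grid time >= death month), NaN otherwise
    y_idx = np.searchsorted(times, np.nan_to_num(death, nan=np.inf))
    has_death = np.isfinite(death) & (y_idx < len(times))
    y_t = np.where(has_death, times[np.minimum(y_idx, len(times) - 1)], np.inf)

    # cross product child x grid, truncated after the death row
    n, k = len(children), len(times)
    data = pd.DataFrame({
        "child": np.repeat(children, k),
        "t": np.tile(times, n),
    })
    end_t = np.repeat(y_t, k)
    data = data[data["t"].to_numpy() <= end_t].reset_index(drop=True)

    wide = picked.pivot(index="child", columns="nominal", values=list(CONFOUNDERS))
    key = pd.MultiIndex.from_arrays([data["child"], data["t"]])
    for c in CONFOUNDERS:
        if c in wide.columns.get_level_values(0):
            stacked = wide[c].stack()
            data[c] = stacked.reindex(key).to_numpy()
        else:
            data[c] = np.nan
        data[f"carried_{c}"] = False

    child_pos = pd.Series(np.arange(n), index=children)
    pos = child_pos[data["child"]].to_numpy()
    data["art"] = (np.isfinite(art[pos]) & (data["t"].to_numpy() >= art[pos])).astype(int)
    data["death"] = (has_death[pos] & (data["t"].to_numpy() == y_t[pos])).astype(int)
    # the visit at the death time does not happen
    dead_rows = data["death"] == 1
    for c in CONFOUNDERS:
        data.loc[dead_rows, c] = np.nan
    data["censor"] = 0
    data["censor_reason"] = ""
    base = raw.baseline.copy()
    panel = IntervalPanel(data, base, events=raw.events.copy(), horizon=horizon)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# last observation carried forward
# ---------------------------------------------------------------------------

def apply_locf(panel: IntervalPanel, max_gap: float = LOCF_MAX_GAP) -> IntervalPanel:
    """Forward-fill missing confounders within ``max_gap`` months (default 9).

    Filling is forward-only (no backward carry into t=0) and the carried
    flag is set exactly on the filled cells; cells whose most recent
    observation is further back than the gap stay missing for the
    imputation stage.
    """
    out = panel.copy()
    d = out.data.sort_values(["child", "t"], kind="stable")
    for c in CONFOUNDERS:
        obs_t = d["t"].where(d[c].notna())
        last_t = obs_t.groupby(d["child"]).ffill()
        last_v = d[c].groupby(d["child"]).ffill()
        fill = d[c].isna() & last_v.notna() & ((d["t"] - last_t) <= max_gap)
        d.loc[fill, c] = last_v[fill]
        d.loc[fill, f"carried_{c}"] = True
    out.data = d
    out.validate()
    return out


# ---------------------------------------------------------------------------
# loss to follow-up
# ---------------------------------------------------------------------------

def flag_ltfu(panel: IntervalPanel, closure: float) -> IntervalPanel:
    """Censor children lost to follow-up or administratively at closure.

    A child not recorded dead whose last facility contact precedes database
    closure by more than 9 months is LTFU: C=1 at the first grid time after
    the last contact, no rows beyond.  Other survivors are in care through
    closure: when closure precedes the horizon they are administratively
    censored at the first grid time past closure, otherwise they keep their
    full row set (their horizon row is genuinely observed follow-up).
    """
    if panel.events is None:
        raise ValueError("panel carries no event table")
    ev = panel.events.set_index("child")
    if (ev["last_contact"] > closure + 1e-9).any():
        raise ValueError("closure precedes a recorded contact")
    out = panel.copy()
    d = out.data
    times = grid_times(panel.horizon)

    dead = np.isfinite(ev["death_month"].to_numpy(dtype=float))
    lc = ev["last_contact"].to_numpy(dtype=float)
    is_ltfu = (closure - lc) > LTFU_GAP
    # LTFU: first grid time strictly after the last contact; administrative:
    # first grid time strictly after closure (only binding below the horizon)
    cut = np.where(is_ltfu, lc, closure)
    cidx = np.searchsorted(times, cut, side="right")
    cens_t = np.where(cidx < len(times), times[np.minimum(cidx, len(times) - 1)], np.inf)
    apply = ~dead & np.isfinite(cens_t)

    cens_map = pd.Series(np.where(apply, cens_t, np.inf), index=ev.index)
    reason_map = pd.Series(np.where(is_ltfu, "ltfu", "admin"), index=ev.index)
    ct = cens_map.reindex(d["child"]).to_numpy()
    keep = d["t"].to_numpy() <= ct
    at = d["t"].to_numpy() == ct
    d.loc[at, "censor"] = 1
    d.loc[at, "censor_reason"] = reason_map.reindex(d.loc[at, "child"]).to_numpy()
    out.data = d[keep].reset_index(drop=True)
    out.validate()
    return out
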