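"""Forward Monte-Carlo g-computation under dynamic ART-initiation regimes.

Given the per-time fitted models, each child's observed baseline state is
carried forward in simulated time: at every grid time the regime sets the
treatment decision from the *simulated* CD4/CD4% at the previous time
(absorbing), the three confounders are drawn from the normal predictive
distributions of their additive models, and death is drawn from the
logistic model; a dead child has no further follow-up and no censoring
exists in the simulated world.  Cumulative mortality per regime is the
fraction of children dead by each grid time.  Percentile bootstrap
confidence intervals resample children (whole trajectories), refit the
models and rerun the simulation; estimates are combined across multiply
imputed datasets by Rubin's-rules point pooling with intervals from the
pooled B x m bootstrap draws.  Regimes are compared on common random
numbers: the same simulation stream is reused for every regime within a
(imputation, bootstrap) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import grid_times
from .regimes import (Regime, MortalityCurve, regime_decision,
                      classify_initiation_band, standard_regimes)
from .regime_models import ModelSet, ModelRecipe, fit_model_set, TARGETS, FittingError
from .cohort_prep import IntervalPanel

__all__ = [
    "Regime",
    "MortalityCurve",
    "GcompResult",
    "SimulatedPanel",
    "regime_decision",
    "classify_initiation_band",
    "standard_regimes",
    "simulate_forward",
    "estimate_mortality",
    "run_gcomputation",
]


class ContractError(RuntimeError):
    """A precondition of the engine (complete models, complete baselines) failed."""


@dataclass
class SimulatedPanel:
    """Counterfactual trajectories for one regime (array layout).

    ``states[i, k]`` is child i's (sqrt CD4, CD4%, WAZ) at grid index k;
    ``death_idx[i]`` is the grid index of death (-1 = survived to horizon).
    """

    times: np.ndarray
    states: np.ndarray     # (n, K+1, 3)
    on_art: np.ndarray     # (n, K+1) int
    death_idx: np.ndarray  # (n,)
    label: str = ""

    @property
    def n_children(self) -> int:
        return self.states.shape[0]


def _baseline_sim_frame(baseline: pd.DataFrame, region_cols) -> pd.DataFrame:
    b = baseline.copy()
    need = ["cd4_0", "cd4pct_0", "waz_0", "haz_0", "age"]
    if b[need].isna().any().any():
        raise ContractError("baseline rows must be complete (run imputation first)")
    b["sqrt_cd4_0"] = np.sqrt(b["cd4_0"])
    b["male"] = (b["sex"] == "male").astype(float)
    for rc in region_cols:
        b[rc] = (b["region"] == rc.removeprefix("region_")).astype(float)
    return b


def simulate_forward(baseline: pd.DataFrame, models: ModelSet, regime: Regime,
                     seed, k_rep: int = 1) -> SimulatedPanel:
    """Simulate every child forward under one regime.

    ``baseline`` needs child, age, sex, region and complete cd4_0, cd4pct_0,
    waz_0, haz_0.  ``seed`` may be an int or a numpy SeedSequence (the
    engine passes one stream per (imputation, bootstrap) cell so regimes
    share random numbers).  ``k_rep`` replicates each child k times to
    shrink simulation Monte-Carlo noise.
    """
    if not models.complete:
        raise ContractError("ModelSet does not cover the full grid")
    times = grid_times(models.horizon)
    n_steps = len(times) - 1

    b = _baseline_sim_frame(baseline, models.region_cols)
    if k_rep > 1:
        b = pd.concat([b] * k_rep, ignore_index=True)
    n = len(b)
    if n == 0:
        raise ValueError("empty baseline table")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    eps = rng.standard_normal((n, n_steps, 3))
    u_death = rng.random((n, n_steps))

    states = np.empty((n, n_steps + 1, 3))
    states[:, 0, 0] = np.sqrt(b["cd4_0"].to_numpy(dtype=float))
    states[:, 0, 1] = b["cd4pct_0"].to_numpy(dtype=float)
    states[:, 0, 2] = b["waz_0"].to_numpy(dtype=float)

    static = b[["sqrt_cd4_0", "cd4pct_0", "waz_0", "haz_0", "age", "male"]
               + list(models.region_cols)].reset_index(drop=True)

    on_art = np.empty((n, n_steps + 1), dtype=int)
    on_art[:, 0] = regime_decision(regime, states[:, 0, 0] ** 2, states[:, 0, 1],
                                   np.zeros(n, dtype=int))
    death_idx = np.full(n, -1)
    alive = np.ones(n, dtype=bool)

    for k in range(1, n_steps + 1):
        t = float(times[k])
        frame = static.copy()
        frame["sqrt_cd4_lag"] = states[:, k - 1, 0]
        frame["cd4pct_lag"] = states[:, k - 1, 1]
        frame["waz_lag"] = states[:, k - 1, 2]
        frame["art_lag"] = on_art[:, k - 1].astype(float)
        frame["t"] = t  # consumed only by pooled-fallback models

        for j, target in enumerate(TARGETS):
            m = models.model(t, target)
            draw = m.predict(frame) + m.sigma * eps[:, k - 1, j]
            states[:, k, j] = draw
        states[:, k, 0] = np.clip(states[:, k, 0], 0.0, None)
        states[:, k, 1] = np.clip(states[:, k, 1], 0.0, 100.0)

        p_die = models.model(t, "death").predict(frame)
        dies = alive & (u_death[:, k - 1] < p_die)
        death_idx[dies] = k
        alive &= ~dies

        dec = regime_decision(regime, states[:, k, 0] ** 2, states[:, k, 1], on_art[:, k - 1])
        on_art[:, k] = np.asarray(dec)

    return SimulatedPanel(times, states, on_art, death_idx, label=regime.label)


def estimate_mortality(sim: SimulatedPanel) -> MortalityCurve:
    """Cumulative mortality = (number dead by t) / (number of children)."""
    if sim.n_children == 0:
        raise ValueError("empty simulated panel")
    k = np.arange(len(sim.times))
    dead = sim.death_idx[:, None]
    cum = ((dead >= 0) & (dead <= k[None, :])).mean(axis=0)
    return MortalityCurve(sim.times, cum, label=sim.label)


# ---------------------------------------------------------------------------
# bootstrap + multiple-imputation orchestration
# ---------------------------------------------------------------------------

@dataclass
class GcompResult:
    """Counterfactual mortality per regime with percentile bootstrap bounds."""

    point: dict[str, MortalityCurve]
    lower: dict[str, MortalityCurve]
    upper: dict[str, MortalityCurve]
    n_boot: int
    m: int
    seed: int
    boot_draws: dict[str, np.ndarray] = field(default_factory=dict)  # (B*m, K+1)

    def table(self, months=(12.0, 24.0, 36.0)) -> pd.DataFrame:
        """Table of estimates (and bounds, if bootstrapped) at selected months."""
        rows = []
        for label, curve in self.point.items():
            for t in months:
                row = {"regime": label, "months": t, "estimate": curve.at(t)}
                if self.n_boot:
                    row["lower"] = self.lower[label].at(t)
                    row["upper"] = self.upper[label].at(t)
                rows.append(row)
        return pd.DataFrame(rows)


def _resample_children(panel: IntervalPanel, rng: np.random.Generator) -> IntervalPanel:
    """Child-level bootstrap: sampled children keep their whole trajectories."""
    ids = panel.baseline["child"].to_numpy()
    pick = rng.integers(0, len(ids), size=len(ids))
    sampled = ids[pick]
    new_ids = np.arange(len(sampled))

    base = panel.baseline.set_index("child").loc[sampled].reset_index()
    base["child"] = new_ids
    counts = panel.data.groupby("child").size()
    d = panel.data.set_index("child")
    frames = d.loc[sampled].reset_index()
    reps = counts.loc[sampled].to_numpy()
    frames["child"] = np.repeat(new_ids, reps)
    return IntervalPanel(frames.reset_index(drop=True), base, events=None,
                         horizon=panel.horizon)


def run_gcomputation(panels, regimes=None, B: int = 200, seed: int = 0,
                     recipe: ModelRecipe | None = None, k_rep: int = 1,
                     max_retries: int = 5) -> GcompResult:
    """Steps 2-6 of the g-formula: simulate, estimate, bootstrap, pool.

    ``panels`` is an ImputedSet or a list of IntervalPanels (one per
    imputation).  ``B = 0`` skips the bootstrap and returns point curves
    only.  Deterministic given (panels, B, seed).
    """
    panel_list = list(getattr(panels, "panels", panels))
    if not panel_list:
        raise ValueError("no panels supplied")
    if B < 0:
        raise ValueError("B must be >= 0")
    regimes = list(regimes) if regimes is not None else standard_regimes()
    recipe = recipe or ModelRecipe()
    m = len(panel_list)
    root = np.random.SeedSequence(seed)

    point_curves: dict[str, list[np.ndarray]] = {r.label: [] for r in regimes}
    boot_curves: dict[str, list[np.ndarray]] = {r.label: [] for r in regimes}
    times = None

    # simulation and resampling streams are shared across imputations (and
    # across regimes): identical inputs give identical estimates, and regimes
    # are compared on common random numbers
    for im, panel in enumerate(panel_list):
        fit = fit_model_set(panel, recipe)
        sim_ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
        for r in regimes:
            sim = simulate_forward(panel.baseline, fit, r,
                                   seed=_respawn(sim_ss), k_rep=k_rep)
            curve = estimate_mortality(sim)
            times = curve.times
            point_curves[r.label].append(curve.cumulative)

        for b in range(1, B + 1):
            for attempt in range(max_retries + 1):
                boot_ss = np.random.SeedSequence(entropy=seed,
                                                 spawn_key=(1, b, attempt))
                rng = np.random.Generator(np.random.PCG64(boot_ss))
                bpanel = _resample_children(panel, rng)
                try:
                    bfit = fit_model_set(bpanel, recipe)
                    sim_ss_b = np.random.SeedSequence(entropy=seed,
                                                      spawn_key=(1, b, attempt, 1))
                    for r in regimes:
                        sim = simulate_forward(bpanel.baseline, bfit, r,
                                               seed=_respawn(sim_ss_b), k_rep=k_rep)
                        boot_curves[r.label].append(estimate_mortality(sim).cumulative)
                    break
                except FittingError:
                    if attempt == max_retries:
                        raise FittingError(
                            f"bootstrap replicate {b} failed {max_retries} retries")

    point, lower, upper, draws = {}, {}, {}, {}
    for r in regimes:
        stack = np.vstack(point_curves[r.label])
        point[r.label] = MortalityCurve(times, stack.mean(axis=0), label=r.label)
        if B:
            bd = np.vstack(boot_curves[r.label])
            draws[r.label] = bd
            lo = np.percentile(bd, 2.5, axis=0)
            hi = np.percentile(bd, 97.5, axis=0)
            lower[r.label] = MortalityCurve(times, np.minimum(lo, point[r.label].cumulative),
                                            label=r.label)
            upper[r.label] = MortalityCurve(times, np.maximum(hi, point[r.label].cumulative),
                                            label=r.label)
    return GcompResult(point, lower, upper, n_boot=B, m=m, seed=seed, boot_draws=draws)


def _respawn(ss: np.random.SeedSequence) -> np.random.SeedSequence:
    """A fresh copy of a seed sequence so every regime sees identical draws."""
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key)
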