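"""Synthetic longitudinal cohorts of ART-naive children aged 2-5 years.

The generator draws from an explicit structural causal model (SCM) with the
statistical structure the downstream analysis assumes:

* baseline covariates (age, sex, region, CD4 count, CD4%, WAZ, HAZ) with
  marginals calibrated to the source cohort's published medians/quartiles,
  coupled through a Gaussian copula;
* first-order autoregressive evolution of (sqrt CD4, CD4%, WAZ) with
  independent Gaussian residuals (CD4% clamped to [0, 100], sqrt CD4
  truncated at 0);
* confounding by indication: a logistic treatment-assignment model in which
  sicker children (lower CD4 / CD4% / WAZ) are more likely to start ART;
  treatment is absorbing;
* a per-interval logistic death model in which ART acts multiplicatively on
  the death odds (``art_effect``; 1.0 = null);
* observation-level noise applied *after* outcomes are generated: visit-time
  jitter, missing-at-random recording gaps, and loss to follow-up - so the
  counterfactual ground truth is untouched by observation parameters.

``true_regime_mortality`` computes exact counterfactual cumulative mortality
for any regime by brute-force Monte Carlo on the same SCM, giving the oracle
against which the g-computation pipeline is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .grid import VISIT_GRID, HORIZON, grid_times
from .regimes import Regime, MortalityCurve, regime_decision

__all__ = [
    "SimParams",
    "RawCohort",
    "TransitionCoefs",
    "StateLogit",
    "BaselineDists",
    "generate_cohort",
    "true_regime_mortality",
]


class ParameterError(ValueError):
    """A SimParams field is non-finite or out of its domain."""


class GridError(ValueError):
    """The horizon is not a member of the visit grid."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionCoefs:
    """AR(1) transition for one confounder: x_t = rho*x_{t-1} + intercept + art*A_{t-1} + N(0, sigma)."""

    rho: float
    intercept: float
    art: float
    sigma: float


@dataclass(frozen=True)
class StateLogit:
    """Logistic model on the current state: logit p = intercept + b.(sqrt_cd4, cd4pct, waz)."""

    intercept: float
    sqrt_cd4: float
    cd4pct: float
    waz: float

    def logit(self, sqrt_cd4, cd4pct, waz):
        return (self.intercept
                + self.sqrt_cd4 * sqrt_cd4
                + self.cd4pct * cd4pct
                + self.waz * waz)


@dataclass(frozen=True)
class BaselineDists:
    """Marginal targets for the baseline draws.

    sqrt CD4 is normal, CD4% lognormal, WAZ/HAZ normal, age uniform on the
    eligible range; location/scale values are solved from the published
    medians and quartiles (median 592 cells/mm3 with quartiles 356-895;
    CD4% 16 [10.3; 23]; WAZ -1.4 [-2.3; -0.5]; HAZ -2.6 [-3.5; -1.6]).
    """

    age_range: tuple[float, float] = (2.0, 5.0)  # years
    male_prop: float = 0.512
    region_probs: tuple[float, ...] = (0.73, 0.12, 0.10, 0.05)
    sqrt_cd4_mean: float = 24.33
    sqrt_cd4_sd: float = 8.19
    log_cd4pct_mean: float = math.log(16.0)
    log_cd4pct_sd: float = 0.595
    waz_mean: float = -1.4
    waz_sd: float = 1.33
    haz_mean: float = -2.6
    haz_sd: float = 1.41
    # Gaussian-copula correlations between (sqrt CD4, CD4%, WAZ, HAZ) latents
    corr_cd4_pct: float = 0.55
    corr_cd4_waz: float = 0.25
    corr_waz_haz: float = 0.50


REGIONS = ("south_africa_urban", "south_africa_rural", "malawi", "zimbabwe")


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of the synthetic-cohort SCM.

    ``art_effect`` is the multiplicative effect of being on ART on the
    per-interval death *odds* (1.0 = null, values < 1 protective).  The
    transition ``art`` coefficients default to zero so that by default
    treatment acts on mortality directly; parameter-recovery tests switch
    them on explicitly.
    """

    n_children: int = 2934
    baseline_dists: BaselineDists = field(default_factory=BaselineDists)
    cd4_trans: TransitionCoefs = TransitionCoefs(rho=0.72, intercept=5.6, art=0.0, sigma=3.4)
    pct_trans: TransitionCoefs = TransitionCoefs(rho=0.72, intercept=3.36, art=0.0, sigma=2.5)
    waz_trans: TransitionCoefs = TransitionCoefs(rho=0.72, intercept=-0.518, art=0.0, sigma=0.60)
    assignment_coefs: StateLogit = StateLogit(intercept=4.4, sqrt_cd4=-0.30, cd4pct=-0.10, waz=-0.80)
    death_coefs: StateLogit = StateLogit(intercept=-4.9, sqrt_cd4=-0.15, cd4pct=-0.04, waz=-1.15)
    art_effect: float = 0.4
    missing_rate: float = 0.15
    ltfu_hazard: float = 0.02
    visit_jitter: float = 1.0  # months; the t=1 visit uses at most +-0.4
    horizon_months: float = HORIZON
    seed: int = 0

    def validate(self) -> None:
        flat = []
        for obj in (self.baseline_dists, self.cd4_trans, self.pct_trans, self.waz_trans,
                    self.assignment_coefs, self.death_coefs):
            for v in asdict(obj).values():
                if isinstance(v, (tuple, list)):
                    flat.extend(v)
                else:
                    flat.append(v)
        flat += [self.art_effect, self.missing_rate, self.ltfu_hazard,
                 self.visit_jitter, self.horizon_months]
        if not all(np.isfinite(flat)):
            raise ParameterError("SimParams contains non-finite values")
        if self.n_children < 0:
            raise ParameterError("n_children must be >= 0")
        for p in (self.missing_rate, self.ltfu_hazard):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.art_effect <= 0:
            raise ParameterError("art_effect must be a positive odds multiplier")
        if float(self.horizon_months) not in VISIT_GRID:
            raise GridError(f"horizon {self.horizon_months} is not on the visit grid")

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["baseline_dists"] = BaselineDists(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["baseline_dists"].items()})
        for key in ("cd4_trans", "pct_trans", "waz_trans"):
            raw[key] = TransitionCoefs(**raw[key])
        for key in ("assignment_coefs", "death_coefs"):
            raw[key] = StateLogit(**raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# raw cohort container
# ---------------------------------------------------------------------------

@dataclass
class RawCohort:
    """The three observed tables plus (optionally) the generator's truth panel.

    baseline: child, age, sex, region, cd4_0, cd4pct_0, waz_0, haz_0
    visits:   child, t (months since first visit), cd4, cd4pct, waz
    events:   child, art_start, death_month, last_contact
    truth:    child, t, cd4, cd4pct, waz, art, death - untouched by
              missingness/LTFU; None unless requested from the generator.
    """

    baseline: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        if (self.visits["t"] < 0).any():
            raise ValueError("visit times must be >= 0")
        ev = self.events.set_index("child")
        last_visit = self.visits.groupby("child")["t"].max()
        dead = ev["death_month"].dropna()
        common = dead.index.intersection(last_visit.index)
        if (dead.loc[common] < last_visit.loc[common] - 1e-9).any():
            raise ValueError("death month precedes a recorded visit")
        if self.events["child"].duplicated().any():
            raise ValueError("more than one event row (hence ART start) per child")

    def to_csv(self, directory) -> None:
        """Write baseline/visits/events as CSVs (missing cells as empty strings)."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(d / "baseline.csv", index=False)
        self.visits.to_csv(d / "visits.csv", index=False)
        self.events.to_csv(d / "events.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "RawCohort":
        import pathlib

        d = pathlib.Path(directory)
        return cls(
            baseline=pd.read_csv(d / "baseline.csv"),
            visits=pd.read_csv(d / "visits.csv"),
            events=pd.read_csv(d / "events.csv"),
        )


# ---------------------------------------------------------------------------
# shared SCM pieces (used by both the generator and the oracle)
# ---------------------------------------------------------------------------

def _baseline_latent_corr(bd: BaselineDists) -> np.ndarray:
    r = np.eye(4)
    r[0, 1] = r[1, 0] = bd.corr_cd4_pct
    r[0, 2] = r[2, 0] = bd.corr_cd4_waz
    r[1, 2] = r[2, 1] = bd.corr_cd4_waz
    r[2, 3] = r[3, 2] = bd.corr_waz_haz
    return r


def _baseline_from_latents(z: np.ndarray, u_cat: np.ndarray, bd: BaselineDists) -> pd.DataFrame:
    """Map standard-normal latents + categorical uniforms to baseline covariates."""
    n = z.shape[0]
    chol = np.linalg.cholesky(_baseline_latent_corr(bd))
    zc = z @ chol.T
    sqrt_cd4 = np.clip(bd.sqrt_cd4_mean + bd.sqrt_cd4_sd * zc[:, 0], 0.0, None)
    cd4pct = np.clip(np.exp(bd.log_cd4pct_mean + bd.log_cd4pct_sd * zc[:, 1]), 0.0, 60.0)
    waz = bd.waz_mean + bd.waz_sd * zc[:, 2]
    haz = bd.haz_mean + bd.haz_sd * zc[:, 3]
    lo, hi = bd.age_range
    age = lo + (hi - lo) * u_cat[:, 0]
    sex = np.where(u_cat[:, 1] < bd.male_prop, "male", "female")
    edges = np.cumsum(bd.region_probs)
    region = np.asarray(REGIONS)[np.searchsorted(edges, u_cat[:, 2], side="right").clip(0, 3)]
    return pd.DataFrame({
        "age": age, "sex": sex, "region": region,
        "sqrt_cd4_0": sqrt_cd4, "cd4pct_0": cd4pct, "waz_0": waz, "haz_0": haz,
    })


def _step_state(state: np.ndarray, a_prev: np.ndarray, eps: np.ndarray, p: SimParams) -> np.ndarray:
    """One AR(1) transition of the (sqrt CD4, CD4%, WAZ) state; vectorised."""
    out = np.empty_like(state)
    for j, tc in enumerate((p.cd4_trans, p.pct_trans, p.waz_trans)):
        out[:, j] = tc.rho * state[:, j] + tc.intercept + tc.art * a_prev + tc.sigma * eps[:, j]
    out[:, 0] = np.clip(out[:, 0], 0.0, None)      # sqrt CD4 >= 0
    out[:, 1] = np.clip(out[:, 1], 0.0, 100.0)     # CD4% in [0, 100]
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _death_prob(state: np.ndarray, a_prev: np.ndarray, p: SimParams) -> np.ndarray:
    lg = p.death_coefs.logit(state[:, 0], state[:, 1], state[:, 2])
    return _sigmoid(lg + math.log(p.art_effect) * a_prev)


def _assign_prob(state: np.ndarray, p: SimParams) -> np.ndarray:
    return _sigmoid(p.assignment_coefs.logit(state[:, 0], state[:, 1], state[:, 2]))


# ---------------------------------------------------------------------------
# observational generator
# ---------------------------------------------------------------------------

def _child_noise(params: SimParams, n: int, n_steps: int):
    """Per-child noise blocks from hierarchical child-level streams.

    Each child's stream derives from (master seed, child index) so that the
    child's full trajectory is bit-reproducible under cohort subsetting.
    The draw layout is fixed (independent of outcomes), which keeps the
    ground truth invariant to missingness/LTFU parameters.
    """
    shapes = {
        "base_z": (n, 4), "u_cat": (n, 3),
        "eps": (n, n_steps, 3),
        "u_assign": (n, n_steps + 1),
        "u_death": (n, n_steps),
        "u_ltfu": (n, n_steps),
        "jit": (n, n_steps + 1),
        "u_miss": (n, n_steps + 1, 3),
        "u_bmiss": (n, 4),
    }
    blocks = {k: np.empty(s) for k, s in shapes.items()}
    for i in range(n):
        g = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))))
        blocks["base_z"][i] = g.standard_normal(4)
        blocks["u_cat"][i] = g.random(3)
        blocks["eps"][i] = g.standard_normal((n_steps, 3))
        blocks["u_assign"][i] = g.random(n_steps + 1)
        blocks["u_death"][i] = g.random(n_steps)
        blocks["u_ltfu"][i] = g.random(n_steps)
        blocks["jit"][i] = g.random(n_steps + 1)
        blocks["u_miss"][i] = g.random((n_steps + 1, 3))
        blocks["u_bmiss"][i] = g.random(4)
    return blocks


def _empty_cohort() -> RawCohort:
    baseline = pd.DataFrame(columns=["child", "age", "sex", "region",
                                     "cd4_0", "cd4pct_0", "waz_0", "haz_0"])
    visits = pd.DataFrame(columns=["child", "t", "cd4", "cd4pct", "waz"])
    events = pd.DataFrame(columns=["child", "art_start", "death_month", "last_contact"])
    truth = pd.DataFrame(columns=["child", "t", "cd4", "cd4pct", "waz", "art", "death"])
    return RawCohort(baseline, visits, events, truth)


def generate_cohort(params: SimParams, return_truth: bool = False) -> RawCohort:
    """Draw one observed cohort from the SCM.

    Trajectory order per child: observe state at each grid time; decide ART
    start at the visit (confounded by the current state); die during the
    following interval with probability from the death model evaluated at
    the interval-start state and treatment.  Missingness, visit jitter and
    LTFU are applied afterwards as pure observation noise.
    """
    params.validate()
    n = params.n_children
    times = grid_times(params.horizon_months)
    n_steps = len(times) - 1
    if n == 0:
        return _empty_cohort()

    nz = _child_noise(params, n, n_steps)
    base = _baseline_from_latents(nz["base_z"], nz["u_cat"], params.baseline_dists)

    # --- forward dynamics (truth) ---
    states = np.empty((n, n_steps + 1, 3))
    states[:, 0, 0] = base["sqrt_cd4_0"].to_numpy()
    states[:, 0, 1] = base["cd4pct_0"].to_numpy()
    states[:, 0, 2] = base["waz_0"].to_numpy()

    on_art = np.zeros(n, dtype=bool)
    art_idx = np.full(n, -1)                      # grid index of ART start
    death_idx = np.full(n, -1)                    # grid index of death row
    alive = np.ones(n, dtype=bool)

    start0 = ~on_art & (nz["u_assign"][:, 0] < _assign_prob(states[:, 0], params))
    on_art |= start0
    art_idx[start0] = 0

    for k in range(1, n_steps + 1):
        a_prev = on_art.copy()
        p_die = _death_prob(states[:, k - 1], a_prev.astype(float), params)
        dies = alive & (nz["u_death"][:, k - 1] < p_die)
        death_idx[dies] = k
        alive &= ~dies
        states[:, k] = _step_state(states[:, k - 1], a_prev.astype(float), nz["eps"][:, k - 1], params)
        starts = alive & ~on_art & (nz["u_assign"][:, k] < _assign_prob(states[:, k], params))
        on_art |= starts
        art_idx[starts] = k

    # --- observation process ---
    # dropout: first interval k (1..n_steps) with u < hazard; visits strictly
    # before that interval's end are attended
    drop = np.where(nz["u_ltfu"] < params.ltfu_hazard, 1, 0)
    drop_idx = np.where(drop.any(axis=1), drop.argmax(axis=1) + 1, n_steps + 1)

    jitter_amp = np.minimum(params.visit_jitter, np.where(times == 1.0, 0.4, 1.0))
    jitter_amp[0] = 0.0
    obs_times = times[None, :] + (2.0 * nz["jit"] - 1.0) * jitter_amp[None, :]

    child_ids = np.arange(n)
    vis_rows, truth_rows = [], []
    art_start = np.full(n, np.nan)
    death_month = np.full(n, np.nan)
    last_contact = np.zeros(n)

    death_time = np.where(death_idx > 0,
                          (times[np.maximum(death_idx - 1, 0)] + times[np.clip(death_idx, 0, n_steps)]) / 2.0,
                          np.nan)

    cd4_raw = states[:, :, 0] ** 2
    for k, t in enumerate(times):
        attended = (death_idx == -1) | (death_idx > k)
        attended &= drop_idx > k
        miss = nz["u_miss"][:, k, :] < params.missing_rate
        row = pd.DataFrame({
            "child": child_ids[attended],
            "t": obs_times[attended, k],
            "cd4": np.where(miss[attended, 0], np.nan, cd4_raw[attended, k]),
            "cd4pct": np.where(miss[attended, 1], np.nan, states[attended, k, 1]),
            "waz": np.where(miss[attended, 2], np.nan, states[attended, k, 2]),
        })
        vis_rows.append(row)
        last_contact[attended] = obs_times[attended, k]

    # ART start is observed only if it happened at an attended visit; death is
    # ascertained only if the child had not already dropped out of care.
    art_observed = (art_idx >= 0) & (art_idx < drop_idx)
    art_start[art_observed] = times[art_idx[art_observed]]
    death_observed = (death_idx > 0) & (death_idx <= drop_idx)
    death_month[death_observed] = death_time[death_observed]

    if return_truth:
        for k, t in enumerate(times):
            in_panel = (death_idx == -1) | (death_idx >= k)
            is_death_row = death_idx == k
            truth_rows.append(pd.DataFrame({
                "child": child_ids[in_panel],
                "t": t,
                "cd4": np.where(is_death_row[in_panel], np.nan, cd4_raw[in_panel, k]),
                "cd4pct": np.where(is_death_row[in_panel], np.nan, states[in_panel, k, 1]),
                "waz": np.where(is_death_row[in_panel], np.nan, states[in_panel, k, 2]),
                "art": ((art_idx[in_panel] >= 0) & (art_idx[in_panel] <= k)
                        & ~is_death_row[in_panel] |
                        ((art_idx[in_panel] >= 0) & (art_idx[in_panel] < k)
                         & is_death_row[in_panel])).astype(int),
                "death": is_death_row[in_panel].astype(int),
            }))

    baseline = base.copy()
    baseline.insert(0, "child", child_ids)
    bmiss = nz["u_bmiss"] < params.missing_rate
    baseline["cd4_0"] = np.where(bmiss[:, 0], np.nan, cd4_raw[:, 0])
    baseline["cd4pct_0"] = np.where(bmiss[:, 1], np.nan, baseline["cd4pct_0"])
    baseline["waz_0"] = np.where(bmiss[:, 2], np.nan, baseline["waz_0"])
    baseline["haz_0"] = np.where(bmiss[:, 3], np.nan, baseline["haz_0"])
    baseline = baseline[["child", "age", "sex", "region", "cd4_0", "cd4pct_0", "waz_0", "haz_0"]]

    visits = pd.concat(vis_rows, ignore_index=True).sort_values(["child", "t"], kind="stable")
    # keep the visit tables consistent with the baseline mask at t=0
    at0 = np.isclose(visits["t"], 0.0)
    v0 = visits.loc[at0].set_index("child")
    for col, bcol in (("cd4", "cd4_0"), ("cd4pct", "cd4pct_0"), ("waz", "waz_0")):
        visits.loc[at0, col] = baseline.set_index("child").loc[v0.index, bcol].to_numpy()

    events = pd.DataFrame({
        "child": child_ids,
        "art_start": art_start,
        "death_month": death_month,
        "last_contact": last_contact,
    })

    truth = None
    if return_truth:
        truth = (pd.concat(truth_rows, ignore_index=True)
                 .sort_values(["child", "t"], kind="stable").reset_index(drop=True))
    cohort = RawCohort(baseline.reset_index(drop=True),
                       visits.reset_index(drop=True), events, truth)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# brute-force counterfactual oracle
# ---------------------------------------------------------------------------

def true_regime_mortality(params: SimParams, regime: Regime, n_mc: int) -> MortalityCurve:
    """Exact Monte-Carlo counterfactual cumulative mortality under a regime.

    Treatment is forced by the regime at every decision point (no assignment
    model); missingness and LTFU do not exist in the counterfactual world.
    All regimes share one random stream (common random numbers), so under a
    null ``art_effect`` with zero transition ART effects the curves agree
    exactly.
    """
    params.validate()
    if not isinstance(regime, Regime):
        raise ValueError("unknown regime")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    times = grid_times(params.horizon_months)
    n_steps = len(times) - 1

    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(999_983,))))
    z = rng.standard_normal((n_mc, 4))
    u_cat = rng.random((n_mc, 3))
    eps = rng.standard_normal((n_mc, n_steps, 3))
    u_death = rng.random((n_mc, n_steps))

    base = _baseline_from_latents(z, u_cat, params.baseline_dists)
    state = np.column_stack([base["sqrt_cd4_0"], base["cd4pct_0"], base["waz_0"]])

    on_art = np.asarray(regime_decision(regime, state[:, 0] ** 2, state[:, 1],
                                        np.zeros(n_mc, dtype=int)), dtype=bool)
    alive = np.ones(n_mc, dtype=bool)
    cum = np.zeros(n_steps + 1)
    for k in range(1, n_steps + 1):
        a_prev = on_art.astype(float)
        p_die = _death_prob(state, a_prev, params)
        dies = alive & (u_death[:, k - 1] < p_die)
        alive &= ~dies
        cum[k] = 1.0 - alive.mean()
        state = _step_state(state, a_prev, eps[:, k - 1], params)
        dec = regime_decision(regime, state[:, 0] ** 2, state[:, 1], on_art.astype(int))
        on_art = np.asarray(dec, dtype=bool)
    return MortalityCurve(times, cum, label=regime.label)
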