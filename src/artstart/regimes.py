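"""Dynamic ART-initiation regimes.

A regime maps the child's current (simulated) immunological state to an
absorbing treat/defer decision: once ART is started it is never stopped
(intention-to-treat encoding).  The regimes compared in the analysis are

* ``immediate``  - start ART at the first visit irrespective of CD4 criteria;
* ``threshold``  - defer until CD4 count falls below ``cd4_threshold``
  cells/mm3 *or* CD4% falls below ``pct_threshold`` percent (a disjunction,
  with strict inequalities);
* ``never``      - never start ART.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regime",
    "MortalityCurve",
    "regime_decision",
    "classify_initiation_band",
    "standard_regimes",
]


@dataclass(frozen=True)
class Regime:
    kind: str  # "immediate" | "threshold" | "never"
    cd4_threshold: float | None = None  # cells/mm3
    pct_threshold: float | None = None  # percent
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("immediate", "threshold", "never"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "threshold":
            if not (self.cd4_threshold and self.cd4_threshold > 0):
                raise ValueError("threshold regime needs a positive cd4_threshold")
            if not (self.pct_threshold and self.pct_threshold > 0):
                raise ValueError("threshold regime needs a positive pct_threshold")
        if not self.label:
            object.__setattr__(self, "label", _default_label(self))


def _default_label(r: Regime) -> str:
    if r.kind == "immediate":
        return "immediate"
    if r.kind == "never":
        return "never"
    return f"<{r.cd4_threshold:g} cells/mm3 or <{r.pct_threshold:g}%"


def standard_regimes() -> list[Regime]:
    """The five initiation strategies of the main analysis."""
    return [
        Regime("immediate"),
        Regime("threshold", 750.0, 25.0),
        Regime("threshold", 500.0, 20.0),
        Regime("threshold", 250.0, 15.0),
        Regime("never"),
    ]


def regime_decision(regime: Regime, cd4, cd4pct, on_art):
    """Treat/defer decision given the current state; vectorised.

    Parameters are the current CD4 count (cells/mm3), CD4%, and the current
    on-ART indicator.  Returns an int array (or scalar) of 0/1 decisions.
    The decision is absorbing: ``on_art == 1`` always yields 1.
    """
    cd4 = np.asarray(cd4, dtype=float)
    cd4pct = np.asarray(cd4pct, dtype=float)
    on_art = np.asarray(on_art)
    if regime.kind == "immediate":
        out = np.ones(np.broadcast(cd4, cd4pct, on_art).shape, dtype=int)
    elif regime.kind == "never":
        # "never" overrides even a (contractually impossible) prior start
        out = np.zeros(np.broadcast(cd4, cd4pct, on_art).shape, dtype=int)
    else:
        if np.any(~np.isfinite(cd4)) or np.any(~np.isfinite(cd4pct)):
            raise ValueError("threshold regime decision requires complete state")
        below = (cd4 < regime.cd4_threshold) | (cd4pct < regime.pct_threshold)
        out = (below | (on_art.astype(bool))).astype(int)
    if out.shape == ():
        return int(out)
    return out


#: Initiation bands of the descriptive table, checked in order.
_BANDS: tuple[tuple[float, float, str], ...] = (
    (250.0, 15.0, "<250 cells/mm3 or <15%"),
    (500.0, 20.0, "<500 cells/mm3 or <20%"),
    (750.0, 25.0, "<750 cells/mm3 or <25%"),
)


def classify_initiation_band(cd4_at_start: float | None, pct_at_start: float | None) -> str:
    """Mutually exclusive CD4/CD4% band at ART initiation.

    The first matching band in the order <250 or <15%, <500 or <20%,
    <750 or <25% wins; children above both 750 and 25% form the residual
    band.  A child with both values unrecorded is "Unknown"; a single
    recorded value is classified on that value alone.
    """
    cd4_missing = cd4_at_start is None or (isinstance(cd4_at_start, float) and np.isnan(cd4_at_start))
    pct_missing = pct_at_start is None or (isinstance(pct_at_start, float) and np.isnan(pct_at_start))
    if cd4_missing and pct_missing:
        return "Unknown"
    for cd4_thr, pct_thr, label in _BANDS:
        below_cd4 = (not cd4_missing) and cd4_at_start < cd4_thr
        below_pct = (not pct_missing) and pct_at_start < pct_thr
        if below_cd4 or below_pct:
            return label
    return ">750 cells/mm3 and >25%"


@dataclass
class MortalityCurve:
    """Cumulative mortality on the visit grid for one regime."""

    times: np.ndarray  # months, on the grid
    cumulative: np.ndarray  # in [0, 1], nondecreasing
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.times.shape != self.cumulative.shape:
            raise ValueError("times and cumulative must have equal length")
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative mortality must be nondecreasing")
        if np.any((self.cumulative < -1e-12) | (self.cumulative > 1 + 1e-12)):
            raise ValueError("cumulative mortality must lie in [0, 1]")

    def at(self, t: float) -> float:
        """Cumulative mortality at grid time t."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not on curve grid")
        return float(self.cumulative[idx[0]])
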