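"""The discrete visit grid shared by every stage of the pipeline.

Follow-up is evaluated 1 month after the first clinic visit and then in
3-month intervals starting 3 months after the first visit, up to 36 months:
t = 0, 1, 3, 6, 9, ..., 36.  Every module (generator, discretisation, model
fitting, forward simulation) works on this grid.
"""

from __future__ import annotations

import numpy as np

#: Nominal follow-up times in months since the first clinic visit.
VISIT_GRID: tuple[float, ...] = (0.0, 1.0) + tuple(float(t) for t in range(3, 37, 3))

#: Times at which transition / death models are fitted (every grid time > 0).
FIT_TIMES: tuple[float, ...] = VISIT_GRID[1:]

#: Default administrative horizon in months.
HORIZON: float = 36.0


def grid_index(t: float) -> int:
    """Position of a nominal time on the grid (raises if not a grid time)."""
    try:
        return VISIT_GRID.index(float(t))
    except ValueError:
        raise ValueError(f"{t} is not on the visit grid {VISIT_GRID}") from None


def window_bounds(horizon: float = HORIZON) -> dict[float, tuple[float, float]]:
    """Half-open windows ``(lo, hi]`` mapping observation times to grid times.

    Boundaries sit at the midpoints of adjacent nominal times so that
    "closest to the middle of the interval" coincides with closest to the
    nominal time.  t=0's window is degenerate (exactly {0}); the last
    window extends 1.5 months past the horizon.
    """
    times = [t for t in VISIT_GRID if t <= horizon]
    out: dict[float, tuple[float, float]] = {0.0: (0.0, 0.0)}
    for i, t in enumerate(times[1:], start=1):
        lo = (times[i - 1] + t) / 2.0
        hi = (t + times[i + 1]) / 2.0 if i + 1 < len(times) else t + 1.5
        out[t] = (lo, hi)
    return out


def next_grid_time(x: float, horizon: float = HORIZON) -> float | None:
    """First grid time >= x, or None if x is past the horizon."""
    for t in VISIT_GRID:
        if t > horizon:
            break
        if t >= x:
            return t
    return None


def grid_times(horizon: float = HORIZON) -> np.ndarray:
    return np.asarray([t for t in VISIT_GRID if t <= horizon], dtype=float)
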