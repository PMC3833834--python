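"""Shared fixtures: tiny hand-built cohorts and panels."""

import numpy as np
import pandas as pd
import pytest

from artstart import IntervalPanel, RawCohort
from artstart.grid import grid_times


def make_raw(children):
    """Build a RawCohort from a list of per-child dicts.

    Each dict: id, age (years), visits=[(t, cd4, cd4pct, waz), ...],
    optional art_start, death_month, last_contact, cd4_0/cd4pct_0/waz_0/haz_0.
    """
    base_rows, visit_rows, event_rows = [], [], []
    for ch in children:
        visits = ch.get("visits", [])
        first = visits[0] if visits else (0.0, np.nan, np.nan, np.nan)
        base_rows.append({
            "child": ch["id"], "age": ch.get("age", 3.0),
            "sex": ch.get("sex", "female"), "region": ch.get("region", "south_africa_urban"),
            "cd4_0": ch.get("cd4_0", first[1]), "cd4pct_0": ch.get("cd4pct_0", first[2]),
            "waz_0": ch.get("waz_0", first[3]), "haz_0": ch.get("haz_0", -2.0),
        })
        for (t, cd4, pct, waz) in visits:
            visit_rows.append({"child": ch["id"], "t": t, "cd4": cd4,
                               "cd4pct": pct, "waz": waz})
        last = max((v[0] for v in visits), default=0.0)
        event_rows.append({
            "child": ch["id"],
            "art_start": ch.get("art_start", np.nan),
            "death_month": ch.get("death_month", np.nan),
            "last_contact": ch.get("last_contact", last),
        })
    return RawCohort(pd.DataFrame(base_rows), pd.DataFrame(visit_rows),
                     pd.DataFrame(event_rows))


def make_panel(children, horizon=36.0):
    """Build an IntervalPanel directly from per-child row dicts.

    Each child dict: id, rows=[(t, cd4, cd4pct, waz, art, death, censor)...],
    optional baseline overrides.
    """
    data_rows, base_rows = [], []
    for ch in children:
        base_rows.append({
            "child": ch["id"], "age": ch.get("age", 3.0),
            "sex": ch.get("sex", "female"), "region": ch.get("region", "south_africa_urban"),
            "cd4_0": ch.get("cd4_0", ch["rows"][0][1]),
            "cd4pct_0": ch.get("cd4pct_0", ch["rows"][0][2]),
            "waz_0": ch.get("waz_0", ch["rows"][0][3]),
            "haz_0": ch.get("haz_0", -2.0),
        })
        for row in ch["rows"]:
            t, cd4, pct, waz = row[:4]
            art = row[4] if len(row) > 4 else 0
            death = row[5] if len(row) > 5 else 0
            censor = row[6] if len(row) > 6 else 0
            data_rows.append({"child": ch["id"], "t": t, "cd4": cd4, "cd4pct": pct,
                              "waz": waz, "carried_cd4": False, "carried_cd4pct": False,
                              "carried_waz": False, "art": art, "death": death,
                              "censor": censor, "censor_reason": ""})
    return IntervalPanel(pd.DataFrame(data_rows), pd.DataFrame(base_rows),
                         events=None, horizon=horizon)


@pytest.fixture
def grid():
    return grid_times()
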