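"""Eligibility filter, interval discretisation, LOCF and LTFU censoring.

Reads results/raw_cohort/, writes the analysis panel and the exclusion log.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from artstart import RawCohort, filter_eligible, discretise, apply_locf, flag_ltfu

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
CLOSURE = 37.5


def main() -> None:
    raw = RawCohort.from_csv(OUT / "raw_cohort")
    eligible, log = filter_eligible(raw)
    panel = flag_ltfu(apply_locf(discretise(eligible)), closure=CLOSURE)

    panel.to_csv(OUT / "panel.csv")
    panel.baseline.to_csv(OUT / "panel_baseline.csv", index=False)
    (OUT / "exclusion_log.json").write_text(json.dumps(log, indent=2))

    d = panel.data
    print(f"Exclusions: {log}")
    print(f"Panel: {d.child.nunique()} children, {len(d)} child-time rows, "
          f"{int(d.death.sum())} deaths, "
          f"{int((d.censor_reason == 'ltfu').sum())} LTFU censorings.")
    carried = d[["carried_cd4", "carried_cd4pct", "carried_waz"]].any(axis=1).mean()
    missing = d[["cd4", "cd4pct", "waz"]].isna().any(axis=1).mean()
    print(f"{carried:.1%} of rows carry forward a value; "
          f"{missing:.1%} still have a missing confounder for imputation.")


if __name__ == "__main__":
    main()
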