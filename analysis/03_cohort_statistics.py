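#!/usr/bin/env python
"""Cohort statistics on the classified synthetic cohort: group contrasts of
EF/EDV/infarct size at both timepoints, the day-3 MVO vs infarct-uptake
regression (independent by construction), the pooled month-1 uptake vs
contractility regression, and qPCR fold changes vs healthy control tissue.

Reads results/cohort/; writes results/stats/.
"""

from pathlib import Path

import pandas as pd

from fdgmismatch.io import read_segment_profiles
from fdgmismatch.polarmap import LAD_TERRITORY
from fdgmismatch.stats import (
    delta_delta_ct,
    group_compare,
    mismatch_association_suite,
    report_to_frame,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    animals = pd.read_csv(BASE / "cohort" / "animals.csv").merge(
        pd.read_csv(BASE / "cohort" / "groups.csv")[["animal_id", "group"]],
        on="animal_id",
    )
    profiles = read_segment_profiles(BASE / "cohort" / "segments.csv")
    out = BASE / "stats"
    out.mkdir(parents=True, exist_ok=True)

    report = mismatch_association_suite(animals, profiles, LAD_TERRITORY)
    frame = report_to_frame(report)
    frame.to_csv(out / "association_report.csv", index=False)

    ef = report["group_compare"]["ef_day3"]
    print("day-3 EF: Mismatch %.1f +/- %.1f vs Match %.1f +/- %.1f (p=%.2g)" % (
        *ef.effect["Mismatch"], *ef.effect["Match"], ef.p_value))
    fit = report["regressions"]["uptake_vs_contractility_month1"]
    print("month-1 uptake~contractility: slope %.3f, r %.3f, p %.2g" % (
        fit["slope"], fit["r"], fit["p"]))
    mvo = report["regressions"]["mvo_vs_uptake_day3"]
    print("day-3 MVO~territory uptake: r %.3f, p %.2g (independent config)" % (
        mvo["r"], mvo["p"]))

    # circulating IL-6 at day 3 between groups
    biomarkers = pd.read_csv(BASE / "cohort" / "biomarkers.csv").merge(
        animals[["animal_id", "group"]], on="animal_id"
    )
    day3 = biomarkers[biomarkers.timepoint == "day3"]
    il6 = group_compare(day3["il6"].to_numpy(), day3["group"].to_numpy())
    print("day-3 IL-6: Mismatch %.0f vs Match %.0f pg/mL (p=%.3g)" % (
        il6.effect["Mismatch"][0], il6.effect["Match"][0], il6.p_value))

    ct = pd.read_csv(BASE / "cohort" / "qpcr_ct.csv")
    folds = pd.concat(
        [delta_delta_ct(ct, target=t) for t in ("CD45", "CD68", "TNFa")],
        ignore_index=True,
    ).drop(columns=["reference_genes"])
    folds.to_csv(out / "qpcr_folds.csv", index=False)
    cd68 = folds[folds.gene == "CD68"].groupby(["group", "region"]).fold.mean()
    print("CD68 mean fold vs control:\n" + cd68.to_string())


if __name__ == "__main__":
    main()
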