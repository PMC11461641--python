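"""Cohort group statistics and qPCR fold-change computation.

Group contrasts use classical one-way ANOVA with Bonferroni-adjusted
pairwise post-hoc t-tests; associations between continuous parameters use
ordinary least squares.  Relative qPCR quantification follows the ddCt
scheme: fold = 2^-(dCt_sample - mean dCt_calibrator), with dCt the target
Ct minus the arithmetic mean of the two reference-gene Cts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import InsufficientDataError, ValidationError
from .polarmap import SegmentProfile, Territory, territory_summary

ALPHA = 0.05  # two-sided significance threshold used throughout


@dataclass
class StatResult:
    """Outcome of a group comparison."""

    statistic: float
    p_value: float
    df: tuple[float, float]
    effect: dict[str, tuple[float, float]]  # group -> (mean, sd)
    method: str
    pairwise: pd.DataFrame | None = None  # post-hoc table with adjusted_p


@dataclass(frozen=True)
class FoldChange:
    gene: str
    sample: str
    region: str
    fold: float
    reference_genes: tuple[str, ...]


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Family-wise correction: multiply by the family size, cap at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p) if m is None else int(m)
    return np.minimum(p * m, 1.0)


def group_compare(values: Sequence[float], groups: Sequence[str]) -> StatResult:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise t-tests.

    The Bonferroni family is one outcome x all group pairs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValidationError("values and groups must align")
    names = list(dict.fromkeys(labels.tolist()))
    if len(names) < 2:
        raise InsufficientDataError("group_compare needs at least 2 groups")
    arrays = {g: values[labels == g] for g in names}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 observations")

    k = len(names)
    n = values.size
    if np.ptp(values) == 0:  # all observations identical: no variance anywhere
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = st.f_oneway(*arrays.values())
        f_stat, p = float(f_stat), float(p)

    pairs = list(combinations(names, 2))
    raw = []
    for g1, g2 in pairs:
        if np.ptp(np.concatenate([arrays[g1], arrays[g2]])) == 0:
            raw.append((0.0, 1.0))
        else:
            t, pv = st.ttest_ind(arrays[g1], arrays[g2], equal_var=True)
            raw.append((float(t), float(pv)))
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "t": [t for t, _ in raw],
            "p": [pv for _, pv in raw],
            "adjusted_p": bonferroni([pv for _, pv in raw], m=len(pairs)),
        }
    )
    effect = {g: (float(arr.mean()), float(arr.std(ddof=1))) for g, arr in arrays.items()}
    return StatResult(
        statistic=f_stat,
        p_value=p,
        df=(float(k - 1), float(n - k)),
        effect=effect,
        method="one-way ANOVA + Bonferroni post hoc",
        pairwise=pairwise,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Ordinary least squares of y on x with Pearson r and a t-test p-value
    on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    if x.size < 3:
        raise InsufficientDataError("linear_fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y.mean()), "r": 0.0, "p": 1.0,
                "n": int(x.size)}
    res = st.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue), "n": int(x.size)}


def delta_delta_ct(
    ct: pd.DataFrame,
    target: str,
    refs: Sequence[str] = ("HPRT", "ACTB"),
    calibrator: str = "Control",
    group_col: str = "group",
) -> pd.DataFrame:
    """Relative expression of ``target`` per sample by the ddCt method.

    Parameters
    ----------
    ct
        Long table with columns ``animal_id``, ``region``, ``gene``, ``ct``
        and a group column.  One sample = one (animal_id, region) pair.
    target
        Target gene symbol.
    refs
        Reference genes; their Cts are combined by arithmetic mean.
    calibrator
        Group whose mean dCt defines fold = 1.

    Returns
    -------
    DataFrame with one row per sample: ``animal_id``, ``region``, ``group``,
    ``delta_ct``, ``fold``.
    """
    required = {"animal_id", "region", "gene", "ct", group_col}
    missing = required - set(ct.columns)
    if missing:
        raise ValidationError(f"ct table missing columns: {sorted(missing)}")
    wide = ct.pivot_table(
        index=["animal_id", "region", group_col], columns="gene", values="ct"
    )
    for gene in (target, *refs):
        if gene not in wide.columns:
            raise ValidationError(f"gene {gene!r} absent from Ct table")
        bad = wide.index[wide[gene].isna()].tolist()
        if bad:
            raise ValidationError(f"missing Ct for gene {gene!r} in samples {bad}")
    dct = wide[target] - wide[list(refs)].mean(axis=1)
    cal = dct[dct.index.get_level_values(group_col) == calibrator]
    if cal.empty:
        raise ValidationError(f"no samples in calibrator group {calibrator!r}")
    ddct = dct - cal.mean()
    dct.name = "delta_ct"
    out = dct.reset_index()
    out["fold"] = np.power(2.0, -ddct.to_numpy())
    out["gene"] = target
    out["reference_genes"] = [tuple(refs)] * len(out)
    return out


def mismatch_association_suite(
    animals: pd.DataFrame,
    profiles: Sequence[SegmentProfile],
    territory: Territory,
    group_col: str = "group",
) -> dict:
    """The cohort-level association report.

    Runs group comparisons of EF/EDV/infarct size per timepoint, the
    day-3 MVO vs infarct-territory-uptake regression, and the pooled
    month-1 segmental uptake vs contractility regression.
    """
    if group_col not in animals.columns:
        raise ValidationError(f"animals table needs a {group_col!r} column")
    report: dict = {"group_compare": {}, "regressions": {}}
    groups = animals[group_col].to_numpy()
    for outcome in ("ef_day3", "ef_month1", "edv_day3", "edv_month1",
                    "infarct_day3", "infarct_month1"):
        if outcome in animals.columns:
            report["group_compare"][outcome] = group_compare(
                animals[outcome].to_numpy(), groups
            )

    by_tp: dict[str, dict[str, SegmentProfile]] = {"day3": {}, "month1": {}}
    for p in profiles:
        by_tp[p.timepoint][p.animal_id] = p

    day3 = [by_tp["day3"][a] for a in animals["animal_id"] if a in by_tp["day3"]]
    if len(day3) >= 3:
        mvo = [p.mvo_extent for p in day3]
        terr_up = [territory_summary(p, territory)["mean_uptake"] for p in day3]
        report["regressions"]["mvo_vs_uptake_day3"] = linear_fit(mvo, terr_up)

    month1 = list(by_tp["month1"].values())
    if month1:
        up = np.concatenate([p.uptake_norm for p in month1])
        co = np.concatenate([p.contractility for p in month1])
        report["regressions"]["uptake_vs_contractility_month1"] = linear_fit(up, co)
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a suite report into one delimited-friendly table."""
    rows = []
    for outcome, res in report.get("group_compare", {}).items():
        row = {"analysis": outcome, "kind": "anova", "statistic": res.statistic,
               "p": res.p_value}
        for g, (m, s) in res.effect.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = s
        if res.pairwise is not None and len(res.pairwise):
            row["adjusted_p_min"] = float(res.pairwise["adjusted_p"].min())
        rows.append(row)
    for name, fit in report.get("regressions", {}).items():
        rows.append({"analysis": name, "kind": "regression", "statistic": fit["slope"],
                     "p": fit["p"], "r": fit["r"], "intercept": fit["intercept"]})
    return pd.DataFrame(rows)
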