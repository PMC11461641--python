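"""Metabolism-contractility mismatch classification.

A segment is *mismatched* when infarct transmurality and normalized FDG
uptake are simultaneously high (both >= 75% by default): metabolically
active tracer signal sitting on top of transmurally scarred, poorly
contracting tissue.  An animal belongs to the Mismatch group when at least
3 of its 17 segments are mismatched on the day-3 scan; otherwise it is a
Match animal (uptake defect co-located with the scar, the expected
viability pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .polarmap import N_SEGMENTS, SegmentProfile

logger = logging.getLogger(__name__)

GROUP_MATCH = "Match"
GROUP_MISMATCH = "Mismatch"


@dataclass(frozen=True)
class MismatchThresholds:
    """Classification thresholds; defaults are the study's operating point."""

    transmurality_min: float = 75.0
    uptake_min: float = 75.0
    min_segments: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.transmurality_min <= 100:
            raise ValidationError("transmurality_min must be in [0, 100]")
        if not 0 <= self.uptake_min <= 100:
            raise ValidationError("uptake_min must be in [0, 100]")
        if not 1 <= int(self.min_segments) <= N_SEGMENTS:
            raise ValidationError(f"min_segments must be in [1, {N_SEGMENTS}]")


DEFAULT_THRESHOLDS = MismatchThresholds()


@dataclass(frozen=True)
class MismatchResult:
    """Per-animal classification outcome."""

    animal_id: str
    segment_mask: np.ndarray
    n_mismatched: int
    group: str

    def __post_init__(self) -> None:
        if int(self.segment_mask.sum()) != self.n_mismatched:
            raise ValidationError("n_mismatched inconsistent with segment_mask")


def classify_segment(
    transmurality: float | np.ndarray,
    uptake_norm: float | np.ndarray,
    th: MismatchThresholds = DEFAULT_THRESHOLDS,
) -> bool | np.ndarray:
    """True iff both transmurality and uptake reach their thresholds (inclusive).

    Accepts scalars or arrays (elementwise).
    """
    t = np.asarray(transmurality, dtype=float)
    u = np.asarray(uptake_norm, dtype=float)
    if np.any(t < 0) or np.any(t > 100) or np.any(u < 0) or np.any(u > 100):
        raise ValidationError("transmurality and uptake_norm must be in [0, 100]")
    out = (t >= th.transmurality_min) & (u >= th.uptake_min)
    return bool(out) if out.ndim == 0 else out


def classify_animal(
    profile: SegmentProfile, th: MismatchThresholds = DEFAULT_THRESHOLDS
) -> MismatchResult:
    """Apply the segment rule to all 17 segments and assign the group label."""
    mask = classify_segment(profile.transmurality, profile.uptake_norm, th)
    n = int(mask.sum())
    group = GROUP_MISMATCH if n >= th.min_segments else GROUP_MATCH
    return MismatchResult(profile.animal_id, mask, n, group)


def cohort_assign(
    profiles: list[SegmentProfile], th: MismatchThresholds = DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every animal from its day-3 profile.

    Animals represented only by non-day-3 profiles are excluded with a
    logged warning rather than imputed.

    Returns
    -------
    assignments
        DataFrame with columns ``animal_id``, ``n_mismatched``, ``group``.
    prevalence
        Dict with keys ``n_total``, ``n_mismatch``, ``percent`` (unrounded)
        and ``percent_rounded`` (nearest integer).
    """
    day3 = [p for p in profiles if p.timepoint == "day3"]
    ids = [p.animal_id for p in day3]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate day-3 profiles for animals: {dupes}")
    skipped = {p.animal_id for p in profiles} - set(ids)
    for animal in sorted(skipped):
        logger.warning("animal %s has no day-3 profile; excluded from assignment", animal)
    if not day3:
        raise ValidationError("no day-3 profiles to classify")

    results = [classify_animal(p, th) for p in day3]
    assignments = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in results],
            "n_mismatched": [r.n_mismatched for r in results],
            "group": [r.group for r in results],
        }
    )
    n_total = len(results)
    n_mis = int((assignments["group"] == GROUP_MISMATCH).sum())
    percent = 100.0 * n_mis / n_total
    prevalence = {
        "n_total": n_total,
        "n_mismatch": n_mis,
        "percent": percent,
        "percent_rounded": int(round(percent)),
    }
    return assignments, prevalence
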