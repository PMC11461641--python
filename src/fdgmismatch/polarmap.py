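"""AHA 17-segment polar-map data model.

The left ventricle is divided into 6 basal, 6 mid-cavity and 4 apical
segments plus the apex (American Heart Association standard).  A
:class:`SegmentProfile` bundles, for one animal at one imaging timepoint,
the per-segment late-gadolinium-enhancement transmurality (percent of wall
thickness), the FDG tracer uptake (raw and normalized to the hottest
segment), the segmental contractility (percent systolic wall thickening)
and the global extent of microvascular obstruction.

All percentages live on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

N_SEGMENTS = 17

#: ring membership per the AHA convention: 1-6 basal, 7-12 mid, 13-16 apical, 17 apex
SEGMENT_RINGS: dict[int, str] = {
    **{i: "basal" for i in range(1, 7)},
    **{i: "mid" for i in range(7, 13)},
    **{i: "apical" for i in range(13, 17)},
    17: "apex",
}

SEGMENT_NAMES: dict[int, str] = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}

TIMEPOINTS = ("day3", "month1")

#: Quantities that can be laid out on a polar map.
POLAR_QUANTITIES = ("transmurality", "uptake_norm", "contractility")

#: Lowest representable wall thickening; dyskinetic segments may be negative.
CONTRACTILITY_FLOOR = -50.0


@dataclass(frozen=True)
class Territory:
    """Named subset of the 17 AHA segments (e.g. a coronary supply territory)."""

    name: str
    segment_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.segment_ids)
        if not ids:
            raise ValidationError(f"territory {self.name!r} has no segments")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"territory {self.name!r} has duplicate segment ids")
        if any(i < 1 or i > N_SEGMENTS for i in ids):
            raise ValidationError(
                f"territory {self.name!r} has segment ids outside 1..{N_SEGMENTS}"
            )
        object.__setattr__(self, "segment_ids", ids)

    def indices(self) -> np.ndarray:
        """Zero-based indices into a 17-vector."""
        return np.asarray(self.segment_ids, dtype=int) - 1


#: Mid-LAD occlusion territory: mid anterior, mid antero-/inferoseptal,
#: apical anterior and apical septal segments.
LAD_TERRITORY = Territory("LAD infarct", (7, 8, 9, 13, 14))


def _as17(x: Iterable[float], what: str) -> np.ndarray:
    arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if arr.shape != (N_SEGMENTS,):
        raise ValidationError(f"{what} must be a {N_SEGMENTS}-vector, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite values")
    return arr


def normalize_uptake(uptake_raw: Iterable[float], animal_id: str | None = None) -> np.ndarray:
    """Normalize raw tracer uptake to percent of the hottest segment.

    ``out_i = 100 * raw_i / max(raw)``, so the maximum of the output is
    exactly 100 and segment order is preserved.

    Raises
    ------
    DegenerateInputError
        If every raw value is zero (no reference segment exists).
    """
    raw = _as17(uptake_raw, "uptake_raw")
    if np.any(raw < 0):
        raise ValidationError("uptake_raw must be nonnegative")
    peak = raw.max()
    if peak <= 0:
        who = f" (animal {animal_id})" if animal_id is not None else ""
        raise DegenerateInputError(f"all-zero uptake vector{who}: no hottest segment")
    # mathematically <= 100; guard the float rounding at the peak
    return np.minimum(100.0 * raw / peak, 100.0)


@dataclass
class SegmentProfile:
    """One animal x timepoint bundle of 17-segment quantities plus MVO.

    ``uptake_norm`` may be omitted, in which case it is derived from
    ``uptake_raw`` via :func:`normalize_uptake`.
    """

    animal_id: str
    timepoint: str
    transmurality: np.ndarray
    uptake_raw: np.ndarray
    contractility: np.ndarray
    mvo_extent: float
    uptake_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        self.transmurality = _as17(self.transmurality, "transmurality")
        if self.transmurality.min() < 0 or self.transmurality.max() > 100:
            raise ValidationError(
                f"transmurality outside [0, 100] for animal {self.animal_id}"
            )
        self.uptake_raw = _as17(self.uptake_raw, "uptake_raw")
        if np.any(self.uptake_raw < 0):
            raise ValidationError(f"uptake_raw negative for animal {self.animal_id}")
        if self.uptake_norm is None:
            self.uptake_norm = normalize_uptake(self.uptake_raw, self.animal_id)
        else:
            self.uptake_norm = _as17(self.uptake_norm, "uptake_norm")
            if self.uptake_norm.min() < 0 or self.uptake_norm.max() > 100 + 1e-9:
                raise ValidationError(
                    f"uptake_norm outside [0, 100] for animal {self.animal_id}"
                )
            if self.uptake_raw.max() > 0 and not np.isclose(
                self.uptake_norm.max(), 100.0, atol=1e-6
            ):
                raise ValidationError(
                    f"uptake_norm of animal {self.animal_id} does not peak at 100"
                )
        self.contractility = _as17(self.contractility, "contractility")
        if self.contractility.min() < CONTRACTILITY_FLOOR - 1e-9:
            raise ValidationError(
                f"contractility below floor {CONTRACTILITY_FLOOR} for {self.animal_id}"
            )
        self.mvo_extent = float(self.mvo_extent)
        if not 0 <= self.mvo_extent <= 100:
            raise ValidationError(f"mvo_extent outside [0, 100] for {self.animal_id}")

    def quantity(self, name: str) -> np.ndarray:
        if name not in POLAR_QUANTITIES:
            raise ValidationError(
                f"unknown quantity {name!r}; choose from {POLAR_QUANTITIES}"
            )
        return getattr(self, name)


def territory_summary(profile: SegmentProfile, territory: Territory) -> dict[str, float]:
    """Unweighted arithmetic means of uptake/transmurality/contractility over a territory."""
    idx = territory.indices()
    return {
        "mean_uptake": float(profile.uptake_norm[idx].mean()),
        "mean_transmurality": float(profile.transmurality[idx].mean()),
        "mean_contractility": float(profile.contractility[idx].mean()),
    }


def polar_table(profile: SegmentProfile, quantity: str) -> pd.DataFrame:
    """Tabular polar map: one row per segment with ring and sector label."""
    values = profile.quantity(quantity)
    return pd.DataFrame(
        {
            "segment_id": np.arange(1, N_SEGMENTS + 1),
            "ring": [SEGMENT_RINGS[i] for i in range(1, N_SEGMENTS + 1)],
            "sector_label": [SEGMENT_NAMES[i] for i in range(1, N_SEGMENTS + 1)],
            "value": values,
        }
    )


def vector_from_polar_table(table: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`polar_table`: reassemble the 17-vector ordered by segment id."""
    if len(table) != N_SEGMENTS:
        raise ValidationError(f"polar table must have {N_SEGMENTS} rows")
    ordered = table.sort_values("segment_id")
    ids = ordered["segment_id"].to_numpy()
    if not np.array_equal(ids, np.arange(1, N_SEGMENTS + 1)):
        raise ValidationError("polar table segment ids must be exactly 1..17")
    return ordered["value"].to_numpy(dtype=float)


def plot_polar_map(profile: SegmentProfile, quantity: str, ax=None, cmap: str = "viridis",
                   vmin: float = 0.0, vmax: float = 100.0):
    """Render a bull's-eye polar map. The tabular form is the testable artifact;
    this rendering is a convenience for visual inspection."""
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    values = profile.quantity(quantity)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
    # (segment ids, inner radius, outer radius, sectors); apex is a full disc
    rings = [(range(1, 7), 0.75, 1.0, 6), (range(7, 13), 0.5, 0.75, 6),
             (range(13, 17), 0.25, 0.5, 4), ([17], 0.0, 0.25, 1)]
    for seg_ids, r0, r1, nsec in rings:
        width = 2 * np.pi / nsec
        for k, seg in enumerate(seg_ids):
            theta0 = np.pi / 2 + k * width  # anterior at the top, counterclockwise
            ax.bar(theta0 + width / 2, r1 - r0, width=width, bottom=r0,
                   color=mapper.to_rgba(values[seg - 1]), edgecolor="white")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{profile.animal_id} {profile.timepoint}: {quantity}")
    return ax
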