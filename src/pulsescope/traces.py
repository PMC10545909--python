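"""Per-ROI fluorescence time series and empty-ROI background correction.

Each region of interest (a chloroplast, a cell, a tissue patch, or an empty
background region) is reduced to its "mean gray value" per time point on the
z-summed series.  The signal in an empty ROI tracks everything that is not
chlorophyll fluorescence of the object — detector offset plus the stray
contribution of the external actinic light — so subtracting a paired
background trace removes both.  Negative corrected values are retained, not
clamped: clamping would bias quenching ratios computed downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .protocol_io import ProjectedSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Roi",
    "FluorescenceTrace",
    "mean_gray",
    "subtract_background",
    "rois_from_labels",
    "traces_to_frame",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass
class Roi:
    """A pixel set on the projected frame, with a role.

    ``mask`` is a full-frame boolean array.  ``role`` is ``"object"`` for a
    measured structure or ``"background"`` for an empty reference region;
    background ROIs cannot have a parent.
    """

    label: str
    mask: np.ndarray
    role: str = "object"
    parent: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be a 2D boolean image")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has an empty mask")
        if self.role not in ("object", "background"):
            raise ValueError(f"unknown ROI role {self.role!r}")
        if self.role == "background" and self.parent is not None:
            raise ValueError("background ROIs cannot have a parent")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FluorescenceTrace:
    """Mean gray value of one ROI over time (arbitrary units)."""

    roi_label: str
    values: np.ndarray
    timestamps: np.ndarray
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps must have equal length")
        if not self.background_corrected and np.any(self.values < 0):
            raise ValueError("uncorrected mean gray values cannot be negative")

    def scaled(self, k: float) -> "FluorescenceTrace":
        return replace(self, values=self.values * k)


def mean_gray(series: ProjectedSeries, roi: Roi) -> FluorescenceTrace:
    """Mean gray value of *roi* at every time point of *series*."""
    if roi.mask.shape != series.frame_shape:
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} does not match frame "
            f"shape {series.frame_shape}"
        )
    values = series.data[:, roi.mask].mean(axis=1)
    return FluorescenceTrace(
        roi_label=roi.label,
        values=values,
        timestamps=np.asarray(series.timestamps, float),
        background_corrected=False,
    )


def subtract_background(
    object_trace: FluorescenceTrace, background_trace: FluorescenceTrace
) -> FluorescenceTrace:
    """Subtract a paired empty-ROI trace, time point by time point."""
    if len(object_trace.timestamps) != len(background_trace.timestamps) or not np.array_equal(
        object_trace.timestamps, background_trace.timestamps
    ):
        raise ValueError("object and background traces have mismatched timestamps")
    corrected = object_trace.values - background_trace.values
    if np.any(corrected < 0):
        logger.warning(
            "ROI %s: %d corrected values are negative (background exceeded signal)",
            object_trace.roi_label,
            int((corrected < 0).sum()),
        )
    return FluorescenceTrace(
        roi_label=object_trace.roi_label,
        values=corrected,
        timestamps=object_trace.timestamps.copy(),
        background_corrected=True,
    )


# ---------------------------------------------------------------------------
# ROI and trace I/O
# ---------------------------------------------------------------------------


def rois_from_labels(
    label_image: np.ndarray | str | Path,
    roles: Mapping[str, str] | str | Path | None = None,
    parents: Mapping[str, str] | None = None,
) -> list[Roi]:
    """Build ROIs from an integer label image plus a {label: role} map.

    Labels absent from *roles* default to ``"object"``.  Label 0 is
    background pixels belonging to no ROI (not a background ROI).
    """
    if isinstance(label_image, (str, Path)):
        label_image = tifffile.imread(str(label_image))
    label_image = np.asarray(label_image)
    if isinstance(roles, (str, Path)):
        roles = json.loads(Path(roles).read_text())
    roles = dict(roles or {})
    parents = dict(parents or {})
    rois = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        name = str(int(lab))
        rois.append(
            Roi(
                label=name,
                mask=label_image == lab,
                role=roles.get(name, "object"),
                parent=parents.get(name),
            )
        )
    return rois


def traces_to_frame(
    raw: Sequence[FluorescenceTrace],
    background: Mapping[str, FluorescenceTrace] | FluorescenceTrace | None = None,
) -> pd.DataFrame:
    """Long-format table of raw / background / corrected values.

    *background* may be a single trace shared by all objects or a mapping
    from object ROI label to its paired background trace.
    """
    rows = []
    for tr in raw:
        if background is None:
            bg = None
        elif isinstance(background, FluorescenceTrace):
            bg = background
        else:
            bg = background.get(tr.roi_label)
        corrected = subtract_background(tr, bg) if bg is not None else None
        for i, t in enumerate(tr.timestamps):
            rows.append(
                {
                    "roi_label": tr.roi_label,
                    "timestamp_s": float(t),
                    "raw": float(tr.values[i]),
                    "background": float(bg.values[i]) if bg is not None else np.nan,
                    "corrected": float(corrected.values[i])
                    if corrected is not None
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_traces_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> dict[str, FluorescenceTrace]:
    """Read corrected traces back as {roi_label: FluorescenceTrace}."""
    df = pd.read_csv(path)
    out: dict[str, FluorescenceTrace] = {}
    for label, grp in df.groupby("roi_label", sort=False):
        grp = grp.sort_values("timestamp_s")
        corrected = grp["corrected"].to_numpy()
        use_corrected = not np.all(np.isnan(corrected))
        out[str(label)] = FluorescenceTrace(
            roi_label=str(label),
            values=corrected if use_corrected else grp["raw"].to_numpy(),
            timestamps=grp["timestamp_s"].to_numpy(),
            background_corrected=use_corrected,
        )
    return out
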