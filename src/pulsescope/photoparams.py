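"""Photosynthetic parameters from protocol-annotated fluorescence traces.

Definitions used throughout (saturation-pulse nomenclature):

* ``Y = (Fm − F′)/Fm`` — maximum PSII photochemical capacity.  F′ is the
  mean dark-adapted fluorescence under the (non-saturating) measuring laser
  alone; Fm is the maximum reached during a saturating pulse.
* ``NPQ(t) = (Fm − Fm′(t))/Fm′(t)`` — non-photochemical quenching.  When the
  measuring laser itself is saturating, every frame directly reads Fm (dark)
  or Fm′ (light), so Fm is the mean over the dark-reference block and Fm′(t)
  is each later frame's corrected value.
* ``ΦPSII = (Fm′ − Fs)/Fm′`` — effective PSII quantum yield in the light,
  from steady-state fluorescence Fs under a sub-saturating laser and Fm′
  during a concurrent saturating pulse.

Undefined values (non-positive denominators, too few points for a slope)
propagate as NaN — never as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol_io import Phase, ProtocolTimeline
from .traces import FluorescenceTrace

logger = logging.getLogger(__name__)

__all__ = [
    "YieldResult",
    "NPQResult",
    "KineticFeatures",
    "compute_Y",
    "compute_npq_series",
    "compute_phi_psii",
    "extract_features",
    "FEATURE_COLUMNS",
]

#: Canonical order of the six per-cell kinetic features.
FEATURE_COLUMNS = ["NPQav", "NPQmax", "Decay", "Induction", "Fmax", "AreaFrac"]

#: Transition-window length for induction/decay slopes, seconds (inclusive).
SLOPE_WINDOW_S = 120.0


@dataclass(frozen=True)
class YieldResult:
    """Maximum PSII capacity from a pulsed acquisition."""

    F_prime: float  # mean pre-pulse fluorescence, a.u.
    Fm: float  # maximum during the saturating pulse, a.u.
    Y: float  # (Fm − F′)/Fm, dimensionless


@dataclass
class NPQResult:
    """Per-frame NPQ from a saturating-measuring-laser acquisition.

    ``npq`` is aligned with the timeline's frames; dark-reference frames and
    undefined frames hold NaN.
    """

    Fm_dark: float
    npq: np.ndarray
    timestamps: np.ndarray


@dataclass
class KineticFeatures:
    """Six-variable kinetic phenotype of a single cell.

    NPQav / NPQmax summarise NPQ during the actinic block; Induction and
    Decay are least-squares NPQ slopes (min⁻¹) over the first 2 min after
    the dark→light and light→dark transitions; Fmax is the dark-adapted mean
    gray value (Fm); AreaFrac is the percent of the cell area occupied by
    plastids.  Undefined entries are NaN.
    """

    npq_av: float = math.nan
    npq_max: float = math.nan
    decay: float = math.nan
    induction: float = math.nan
    fmax: float = math.nan
    area_frac: float = math.nan

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "NPQav": self.npq_av,
                "NPQmax": self.npq_max,
                "Decay": self.decay,
                "Induction": self.induction,
                "Fmax": self.fmax,
                "AreaFrac": self.area_frac,
            }
        )


def compute_Y(
    trace: FluorescenceTrace, pulse_frames: Sequence[int] | np.ndarray
) -> YieldResult:
    """Maximum PSII capacity Y = (Fm − F′)/Fm.

    F′ is the mean over frames preceding the first pulse frame; Fm the
    maximum over the pulse frames.
    """
    pulse_frames = np.asarray(pulse_frames, dtype=int)
    if pulse_frames.size == 0:
        raise ValueError("compute_Y requires at least one pulse frame")
    if pulse_frames.min() < 0 or pulse_frames.max() >= len(trace.values):
        raise ValueError("pulse frame index out of range")
    first_pulse = int(pulse_frames.min())
    if first_pulse == 0:
        raise ValueError("compute_Y requires at least one pre-pulse frame")
    f_prime = float(np.mean(trace.values[:first_pulse]))
    fm = float(np.max(trace.values[pulse_frames]))
    if fm <= 0:
        raise ValueError("Fm ≤ 0: yield undefined (all-zero or negative trace)")
    y = (fm - f_prime) / fm
    if fm < f_prime:
        logger.warning(
            "Fm < F′ (Y = %.3f < 0): measuring light may itself be saturating", y
        )
    return YieldResult(F_prime=f_prime, Fm=fm, Y=y)


def compute_npq_series(
    trace: FluorescenceTrace, timeline: ProtocolTimeline
) -> NPQResult:
    """Per-frame NPQ(t) = (Fm − F(t))/F(t) relative to the dark-block mean.

    Requires a saturating measuring laser, so that each frame's corrected
    value reads Fm (dark block) or Fm′ (later frames) directly.  Frames with
    F(t) ≤ 0 are marked NaN, not dropped.
    """
    if len(trace.values) != timeline.n_frames:
        raise ValueError("trace length does not match timeline frame count")
    dark_idx = timeline.indices(Phase.DARK)
    fm_dark = float(np.mean(trace.values[dark_idx]))
    if fm_dark <= 0:
        raise ValueError("dark-reference mean Fm ≤ 0: NPQ undefined")
    npq = np.full(timeline.n_frames, np.nan)
    after_dark = np.arange(timeline.n_frames) > dark_idx.max()
    f = trace.values
    valid = after_dark & (f > 0)
    npq[valid] = (fm_dark - f[valid]) / f[valid]
    n_undef = int((after_dark & ~valid).sum())
    if n_undef:
        logger.warning(
            "ROI %s: NPQ undefined at %d frame(s) with F(t) ≤ 0",
            trace.roi_label,
            n_undef,
        )
    return NPQResult(Fm_dark=fm_dark, npq=npq, timestamps=timeline.timestamps)


def compute_phi_psii(Fs: float, Fm_pulse: float) -> float:
    """Effective PSII quantum yield ΦPSII = (Fm′ − Fs)/Fm′."""
    if Fm_pulse <= 0:
        raise ValueError("Fm′ must be positive")
    phi = (Fm_pulse - Fs) / Fm_pulse
    if Fs > Fm_pulse:
        logger.warning("Fs > Fm′: ΦPSII = %.3f is negative", phi)
    return phi


def _window_slope_per_min(
    t_s: np.ndarray, values: np.ndarray, t0_s: float
) -> float:
    """OLS slope (min⁻¹) of values vs time over t − t0 ≤ 120 s, inclusive."""
    in_window = (t_s - t0_s) <= SLOPE_WINDOW_S + 1e-9
    keep = in_window & ~np.isnan(values)
    if keep.sum() < 2:
        return math.nan
    slope = np.polyfit(t_s[keep] / 60.0, values[keep], 1)[0]
    return float(slope)


def extract_features(
    npq_result: NPQResult,
    timeline: ProtocolTimeline,
    area_frac: float = math.nan,
) -> KineticFeatures:
    """Derive the six-variable kinetic phenotype from an NPQ series.

    NPQav/NPQmax are computed over the actinic frames; Induction is the
    least-squares slope of NPQ against time over actinic frames within 2 min
    of light-on (window boundary inclusive), Decay likewise over relaxation
    frames within 2 min of light-off.  Fmax is the dark-adapted Fm.
    """
    npq = np.asarray(npq_result.npq, dtype=float)
    t = timeline.timestamps
    feats = KineticFeatures(fmax=npq_result.Fm_dark, area_frac=area_frac)

    light_idx = timeline.indices(Phase.ACTINIC)
    if light_idx.size:
        light_npq = npq[light_idx]
        if np.any(~np.isnan(light_npq)):
            feats.npq_av = float(np.nanmean(light_npq))
            feats.npq_max = float(np.nanmax(light_npq))
        feats.induction = _window_slope_per_min(
            t[light_idx], light_npq, timeline.light_on_time()
        )
    relax_idx = timeline.indices(Phase.RELAXATION)
    if relax_idx.size:
        feats.decay = _window_slope_per_min(
            t[relax_idx], npq[relax_idx], timeline.light_off_time()
        )
    return feats
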