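"""Saturation-pulse light protocols and confocal stack I/O.

A pulse-amplitude-modulated (PAM) style acquisition alternates three light
regimes: a dark-adapted reference block, a continuous actinic block that
drives photosynthesis, and a dark relaxation block.  Saturating pulses (or a
saturating measuring laser) close all PSII reaction centres so the recorded
fluorescence reaches its maximum (Fm in the dark, Fm' in the light).  This
module models that protocol frame-by-frame (:class:`ProtocolTimeline`),
reads/writes 4D ``(t, z, y, x)`` intensity stacks, and performs the
intensity-preserving z "sum projection" that collapses each time point to a
2D image without losing any counts.

Conventions
-----------
* Axis order is ``(t, z, y, x)``, 0-based, pixel centres on integer
  coordinates, physical sizes in micrometres.
* Sum projection accumulates integer inputs in ``int64`` so that the total
  intensity of every time point is conserved exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "ProtocolError",
    "ProtocolFrame",
    "PulseSpec",
    "ProtocolTimeline",
    "AcquisitionStack",
    "ProjectedSeries",
    "build_timeline",
    "read_stack",
    "write_stack",
    "sum_project",
]


class Phase(str, Enum):
    """Light regime of a single acquisition frame."""

    DARK = "dark_reference"
    ACTINIC = "actinic"
    RELAXATION = "relaxation"


#: Phases must appear in this block order within a timeline.
PHASE_ORDER: tuple[Phase, ...] = (Phase.DARK, Phase.ACTINIC, Phase.RELAXATION)


class ProtocolError(ValueError):
    """A light protocol violates its structural invariants."""


@dataclass(frozen=True)
class ProtocolFrame:
    """One acquisition: its time, light phase and pulse flag."""

    timestamp: float  # seconds from the start of the experiment
    phase: Phase
    pulse: bool = False


@dataclass(frozen=True)
class PulseSpec:
    """Saturating-pulse settings: intensity (μmol photons m⁻² s⁻¹),
    duration (s) and the frame indices acquired during a pulse."""

    intensity: float = 2000.0
    duration: float = 1.1
    frames: tuple[int, ...] = ()


@dataclass
class ProtocolTimeline:
    """Frame-by-frame annotation of a saturation-pulse acquisition.

    Invariants (checked on construction): timestamps strictly increasing, at
    least one dark-reference frame, phases in dark → actinic → relaxation
    block order, and a positive pulse duration whenever a pulse flag is set.
    """

    frames: tuple[ProtocolFrame, ...]
    actinic_intensity: float = 0.0  # μmol photons m⁻² s⁻¹
    pulse_intensity: float = 0.0
    pulse_duration: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.frames = tuple(self.frames)
        if not any(f.phase is Phase.DARK for f in self.frames):
            raise ProtocolError(
                "protocol has no dark_reference frame: no Fm reference possible"
            )
        ts = self.timestamps
        if np.any(np.diff(ts) <= 0):
            raise ProtocolError("timestamps must be strictly increasing")
        order = [PHASE_ORDER.index(f.phase) for f in self.frames]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ProtocolError(
                "phases must appear in dark_reference, actinic, relaxation order"
            )
        if any(f.pulse for f in self.frames) and self.pulse_duration <= 0:
            raise ProtocolError("pulse_duration must be > 0 when pulses are set")

    # -- views -------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def indices(self, phase: Phase) -> np.ndarray:
        """Frame indices belonging to *phase*."""
        return np.array(
            [i for i, f in enumerate(self.frames) if f.phase is phase], dtype=int
        )

    @property
    def pulse_indices(self) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.frames) if f.pulse], dtype=int)

    def light_on_time(self) -> float:
        """Timestamp of the first actinic frame (dark → light transition)."""
        idx = self.indices(Phase.ACTINIC)
        if idx.size == 0:
            raise ProtocolError("timeline has no actinic frames")
        return self.frames[int(idx[0])].timestamp

    def light_off_time(self) -> float:
        """Timestamp of the first relaxation frame (light → dark transition)."""
        idx = self.indices(Phase.RELAXATION)
        if idx.size == 0:
            raise ProtocolError("timeline has no relaxation frames")
        return self.frames[int(idx[0])].timestamp

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "actinic_intensity": self.actinic_intensity,
            "pulse_intensity": self.pulse_intensity,
            "pulse_duration": self.pulse_duration,
            "frames": [
                {"timestamp": f.timestamp, "phase": f.phase.value, "pulse": f.pulse}
                for f in self.frames
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolTimeline":
        frames = tuple(
            ProtocolFrame(float(f["timestamp"]), Phase(f["phase"]), bool(f.get("pulse", False)))
            for f in d["frames"]
        )
        return cls(
            frames=frames,
            actinic_intensity=float(d.get("actinic_intensity", 0.0)),
            pulse_intensity=float(d.get("pulse_intensity", 0.0)),
            pulse_duration=float(d.get("pulse_duration", 0.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolTimeline":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_timeline(
    n_dark: int,
    n_light: int,
    n_relax: int,
    interval: float,
    actinic_intensity: float = 0.0,
    pulse: PulseSpec | None = None,
) -> ProtocolTimeline:
    """Build a uniformly spaced dark/actinic/relaxation protocol.

    Parameters
    ----------
    n_dark, n_light, n_relax
        Number of frames in each block; ``n_dark`` must be ≥ 1 (the dark
        block is the Fm reference).
    interval
        Spacing between consecutive acquisitions, seconds.
    actinic_intensity
        Continuous actinic light during the light block, μmol photons m⁻² s⁻¹.
    pulse
        Optional saturating-pulse spec; its ``frames`` lists the indices
        acquired concurrently with a pulse.
    """
    if n_dark < 1:
        raise ProtocolError("need at least one dark_reference frame")
    if min(n_light, n_relax) < 0:
        raise ProtocolError("frame counts must be non-negative")
    if interval <= 0:
        raise ProtocolError("interval must be > 0")
    pulse_frames = set(pulse.frames) if pulse is not None else set()
    phases = (
        [Phase.DARK] * n_dark + [Phase.ACTINIC] * n_light + [Phase.RELAXATION] * n_relax
    )
    bad = [i for i in pulse_frames if not 0 <= i < len(phases)]
    if bad:
        raise ProtocolError(f"pulse frame indices out of range: {bad}")
    frames = tuple(
        ProtocolFrame(timestamp=i * interval, phase=ph, pulse=i in pulse_frames)
        for i, ph in enumerate(phases)
    )
    return ProtocolTimeline(
        frames=frames,
        actinic_intensity=actinic_intensity,
        pulse_intensity=pulse.intensity if pulse else 0.0,
        pulse_duration=pulse.duration if pulse else 0.0,
    )


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionStack:
    """Raw 4D confocal acquisition, axes ``(t, z, y, x)``.

    ``voxel_size`` is the in-plane pixel pitch ``(dy, dx)`` and ``z_step``
    the slice spacing, both in μm.  ``timestamps`` gives the acquisition
    time of each t index, in seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float] = (1.0, 1.0)  # (dy, dx) μm
    z_step: float = 1.0  # μm
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack must be 4D (t, z, y, x); got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError("stack pixel data must be numeric")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.voxel_size[0] <= 0 or self.voxel_size[1] <= 0 or self.z_step <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0], dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != self.data.shape[0]:
            raise ValueError("len(timestamps) must equal the t extent")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical voxel volume dz·dy·dx in μm³."""
        return self.z_step * self.voxel_size[0] * self.voxel_size[1]


@dataclass
class ProjectedSeries:
    """z-summed 2D time series, axes ``(t, y, x)``; total intensity per
    time point equals that of the source stack exactly for integer input."""

    data: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("projected series must be 3D (t, y, x)")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0], dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != self.data.shape[0]:
            raise ValueError("len(timestamps) must equal the t extent")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.data, metadata={"axes": "TYX"})


def sum_project(stack: AcquisitionStack) -> ProjectedSeries:
    """Collapse z by per-pixel summation ("sum slices").

    Integer input is accumulated in ``int64`` so no counts are lost to
    overflow; float input is accumulated in ``float64``.
    """
    if np.issubdtype(stack.data.dtype, np.integer):
        projected = stack.data.astype(np.int64, copy=False).sum(axis=1)
    else:
        projected = stack.data.astype(np.float64, copy=False).sum(axis=1)
    return ProjectedSeries(
        data=projected,
        pixel_size=stack.voxel_size,
        timestamps=stack.timestamps.copy(),
    )


# ---------------------------------------------------------------------------
# TIFF reading / writing
# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: AcquisitionStack) -> None:
    """Write a 4D stack as OME-TIFF with axes TZYX and physical metadata."""
    dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.data,
        ome=True,
        metadata={
            "axes": "TZYX",
            # fixed UUID keeps identically-parameterised writes bit-identical
            "UUID": "urn:uuid:00000000-0000-4000-8000-000000000000",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
        },
    )


def _load_sidecar(sidecar: str | Path | Mapping | None) -> dict:
    if sidecar is None:
        return {}
    if isinstance(sidecar, Mapping):
        return dict(sidecar)
    text = Path(sidecar).read_text()
    if str(sidecar).endswith((".yml", ".yaml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def read_stack(
    path: str | Path,
    sidecar: str | Path | Mapping | None = None,
) -> AcquisitionStack:
    """Read a TIFF / OME-TIFF stack and normalise axes to ``(t, z, y, x)``.

    Metadata resolution: values declared in the *sidecar* config (keys
    ``axes``, ``voxel_size_um`` = [dy, dx], ``z_step_um``, ``timestamps_s``
    or ``interval_s``) take precedence over file tags; a conflict is logged
    as a warning and the sidecar wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = _load_sidecar(sidecar)

    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes  # e.g. 'TZYX', 'ZYX', 'YX', 'QYX'

    axes = cfg.get("axes")
    if axes is not None:
        axes = str(axes).upper()
        if len(axes) != data.ndim:
            raise ValueError(
                f"sidecar axes {axes!r} do not match array dimensionality {data.ndim}"
            )
        if file_axes and set(file_axes) == set(axes) and file_axes != axes:
            logger.warning(
                "axis order mismatch: file says %r, sidecar says %r; sidecar wins",
                file_axes,
                axes,
            )
    else:
        axes = file_axes.upper()

    # Map unknown/sample axes to best-effort names, then normalise to TZYX.
    axes = axes.replace("S", "T").replace("Q", "T").replace("I", "T")
    if not set(axes) <= {"T", "Z", "Y", "X"}:
        raise ValueError(
            f"ambiguous axis order {axes!r}; declare 'axes' in a sidecar config"
        )
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"cannot locate image plane axes in {axes!r}")
    for missing in "TZ":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "TZYX"]
    data = np.transpose(data, order)

    voxel_size = tuple(cfg.get("voxel_size_um", (1.0, 1.0)))
    z_step = float(cfg.get("z_step_um", 1.0))

    timestamps = cfg.get("timestamps_s")
    if timestamps is None and "interval_s" in cfg:
        timestamps = np.arange(data.shape[0], dtype=float) * float(cfg["interval_s"])
    return AcquisitionStack(
        data=data,
        voxel_size=(float(voxel_size[0]), float(voxel_size[1])),
        z_step=z_step,
        timestamps=None if timestamps is None else np.asarray(timestamps, float),
    )
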