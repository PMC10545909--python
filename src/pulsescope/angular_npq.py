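"""Angular NPQ scanning of single cells whose plastids cannot be separated.

Densely packed plastids (e.g. in small symbiotic microalgae) cannot be
segmented individually from confocal slices.  The alternative: approximate
the cell section with its equivalent-area circle, scan fluorescence along
radii at regular angular steps (bilinearly interpolated), and compute the
NPQ quotient per angle from a dark-adapted image (Fm) and a light-exposed
image (Fm′):  NPQ(θ) = (Fm(θ) − Fm′(θ)) / Fm′(θ).  Scanning several z
sections of the same cell and aggregating per angle gives a dispersion
estimate.

Angle convention: 0° along +x (image columns), increasing counter-clockwise
with the y axis pointing up in display coordinates; a radius at angle θ runs
from the centre to centre + r·(cos θ, sin θ) in (x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CellDisk",
    "AngularNPQProfile",
    "fit_disk",
    "radial_profile",
    "angular_npq",
    "aggregate_sections",
    "profile_to_frame",
]


@dataclass(frozen=True)
class CellDisk:
    """Equivalent-area circular approximation of a cell section."""

    center: tuple[float, float]  # (y, x) pixels
    radius: float  # pixels
    z_index: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")


@dataclass
class AngularNPQProfile:
    """Per-angle Fm, Fm′ and NPQ around a cell disk."""

    angle_step: float  # degrees
    angles: np.ndarray  # 0, step, …, 360 − step
    fm: np.ndarray
    fm_prime: np.ndarray
    npq: np.ndarray
    sections_used: int = 1
    npq_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = int(round(360.0 / self.angle_step))
        if n * self.angle_step != 360.0:
            raise ValueError("angle_step must divide 360")
        for arr in (self.angles, self.fm, self.fm_prime, self.npq):
            if len(arr) != n:
                raise ValueError("profile arrays must have 360/angle_step entries")


def fit_disk(section_mask: np.ndarray, z_index: int | None = None) -> CellDisk:
    """Fit the equivalent-area circle: centroid centre, radius √(area/π)."""
    mask = np.asarray(section_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("section mask must be 2D")
    area = mask.sum()
    if area == 0:
        raise ValueError("empty section mask")
    ys, xs = np.nonzero(mask)
    return CellDisk(
        center=(float(ys.mean()), float(xs.mean())),
        radius=float(math.sqrt(area / math.pi)),
        z_index=z_index,
    )


def radial_profile(
    image: np.ndarray,
    disk: CellDisk,
    angle_deg: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Bilinear samples from the disk centre to its rim along one radius.

    ``n_samples`` points are evenly spaced on [0, r]; the default is
    ``ceil(r) + 1`` (about one sample per pixel).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if n_samples is None:
        n_samples = int(math.ceil(disk.radius)) + 1
    if n_samples < 2:
        raise ValueError("need at least 2 samples along the radius")
    theta = math.radians(angle_deg)
    r = np.linspace(0.0, disk.radius, n_samples)
    cy, cx = disk.center
    ys = cy + r * math.sin(theta)
    xs = cx + r * math.cos(theta)
    if (
        ys.min() < 0
        or xs.min() < 0
        or ys.max() > image.shape[0] - 1
        or xs.max() > image.shape[1] - 1
    ):
        raise ValueError("radial samples fall outside the image frame")
    return ndimage.map_coordinates(image, np.vstack([ys, xs]), order=1, mode="nearest")


_REDUCTIONS = {"mean": np.mean, "sum": np.sum, "median": np.median}


def angular_npq(
    dark_image: np.ndarray,
    light_image: np.ndarray,
    disk: CellDisk,
    angle_step: float = 5.0,
    n_samples: int | None = None,
    reduction: str = "mean",
) -> AngularNPQProfile:
    """Per-angle NPQ from a dark-adapted and a light-exposed slice.

    Per angle, Fm is the along-radius reduction (default mean) of the dark
    image and Fm′ of the light image; NPQ = (Fm − Fm′)/Fm′.  Angles where
    Fm′ ≤ 0 are marked NaN.  A 5° step yields 72 angles.
    """
    dark_image = np.asarray(dark_image, dtype=float)
    light_image = np.asarray(light_image, dtype=float)
    if dark_image.shape != light_image.shape:
        raise ValueError("dark and light images must share geometry")
    if reduction not in _REDUCTIONS:
        raise ValueError(f"unknown reduction {reduction!r}")
    reduce = _REDUCTIONS[reduction]
    n_angles = int(round(360.0 / angle_step))
    if n_angles * angle_step != 360.0:
        raise ValueError("angle_step must divide 360")
    angles = np.arange(n_angles) * angle_step
    fm = np.empty(n_angles)
    fm_prime = np.empty(n_angles)
    for i, ang in enumerate(angles):
        fm[i] = reduce(radial_profile(dark_image, disk, ang, n_samples))
        fm_prime[i] = reduce(radial_profile(light_image, disk, ang, n_samples))
    npq = np.full(n_angles, np.nan)
    ok = fm_prime > 0
    npq[ok] = (fm[ok] - fm_prime[ok]) / fm_prime[ok]
    return AngularNPQProfile(
        angle_step=float(angle_step),
        angles=angles.astype(float),
        fm=fm,
        fm_prime=fm_prime,
        npq=npq,
        sections_used=1,
    )


def aggregate_sections(
    profiles: Sequence[AngularNPQProfile],
) -> AngularNPQProfile:
    """Per-angle mean and sample SD of NPQ across z sections of one cell.

    With fewer than two profiles the mean passes through and the dispersion
    is undefined (None).
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.angle_step != ref.angle_step or not np.array_equal(p.angles, ref.angles):
            raise ValueError("profiles have mismatched angle grids")
    fm = np.mean([p.fm for p in profiles], axis=0)
    fm_prime = np.mean([p.fm_prime for p in profiles], axis=0)
    npq_stack = np.vstack([p.npq for p in profiles])
    npq_mean = np.nanmean(npq_stack, axis=0)
    npq_sd = np.nanstd(npq_stack, axis=0, ddof=1) if len(profiles) >= 2 else None
    return AngularNPQProfile(
        angle_step=ref.angle_step,
        angles=ref.angles.copy(),
        fm=fm,
        fm_prime=fm_prime,
        npq=npq_mean,
        sections_used=len(profiles),
        npq_sd=npq_sd,
    )


def profile_to_frame(profile: AngularNPQProfile) -> pd.DataFrame:
    """Tabulate a profile as (angle_deg, Fm, Fm_prime, NPQ, sd)."""
    return pd.DataFrame(
        {
            "angle_deg": profile.angles,
            "Fm": profile.fm,
            "Fm_prime": profile.fm_prime,
            "NPQ": profile.npq,
            "sd": profile.npq_sd if profile.npq_sd is not None else np.nan,
        }
    )


def radar_plot(profile: AngularNPQProfile, path) -> None:
    """Polar (radar) plot of NPQ versus angle, saved to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.deg2rad(np.append(profile.angles, 360.0))
    npq = np.append(profile.npq, profile.npq[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(theta, npq, "s-", color="black", mfc="white")
    if profile.npq_sd is not None:
        sd = np.append(profile.npq_sd, profile.npq_sd[0])
        ax.fill_between(theta, npq - sd, npq + sd, alpha=0.3, color="gray")
    ax.set_title("NPQ vs angle")
    fig.savefig(path, dpi=150)
    plt.close(fig)
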