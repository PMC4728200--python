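"""Line-probe tension measurement on the actin image.

Once the model is calibrated, tension does not have to be read off the
node network: the cross-linear relation converts an image line profile
directly into force.  A probe is a straight segment drawn across a stress
fiber; its length is the fiber width and the mean normalized gray value
along it the fiber's effective actin density.  The tension transiting the
fiber is then ``T_SF = T_cl_max * c_mean * width``.

Probes deliberately operate on the full 256-level normalized image rather
than the 10-label quantization of the model: the image has the greater
spatial definition and finer tones of gray.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_io import ChannelImage

MIN_PROBE_WIDTH = 0.6  # um; below the model definition, tension is underestimated


class UnderResolutionWarning(UserWarning):
    """Probe narrower than the model definition (~0.6 um)."""


@dataclasses.dataclass(frozen=True)
class LineProbe:
    """A measured probe: endpoints, sampled profile and resulting tension."""

    p0: tuple[float, float]  # um
    p1: tuple[float, float]  # um
    samples: np.ndarray  # gray values along the segment
    c_mean: float  # mean gray value across the fiber
    width: float  # um, segment length = fiber width
    tension: float  # nN


def sample_profile(
    image: ChannelImage,
    p0: Sequence[float],
    p1: Sequence[float],
    spacing: float | None = None,
) -> np.ndarray:
    """Bilinearly interpolated gray values at uniform arc-length samples.

    Both endpoints are included.  ``spacing`` defaults to half the pixel
    pitch (sub-pixel sampling keeps the measurement rotation invariant).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("zero-length probe segment")
    pitch = image.pixel_pitch
    if spacing is None:
        spacing = pitch / 2.0
    if spacing > pitch / 2.0 + 1e-12:
        raise ValueError("sampling spacing must not exceed half the pixel pitch")
    h, w = image.intensities.shape
    for p in (p0, p1):
        if not (0.0 <= p[0] <= w * pitch and 0.0 <= p[1] <= h * pitch):
            raise ValueError(f"probe endpoint {tuple(p)} um lies outside the image")
    n = max(2, int(math.ceil(length / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    cols = pts[:, 0] / pitch - 0.5
    rows = pts[:, 1] / pitch - 0.5
    return ndi.map_coordinates(image.intensities, [rows, cols], order=1, mode="nearest")


def _line_average(profile: np.ndarray) -> float:
    """Mean gray value along the segment: trapezoidal average of the
    uniformly spaced samples (an unbiased line integral, unlike the plain
    sample mean which overweights the two endpoints)."""
    if profile.size == 1:
        return float(profile[0])
    return float(np.trapezoid(profile) / (profile.size - 1))


def probe_tension(profile: np.ndarray, width: float, T_cl_max: float) -> float:
    """Tension across a fiber: ``T = T_cl_max * mean(profile) * width`` (nN).

    Warns for widths below 0.6 um, where diffraction and the model
    resolution make the estimate unreliable.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty probe profile")
    if width < 0:
        raise ValueError("width must be non-negative")
    if width < MIN_PROBE_WIDTH:
        warnings.warn(
            f"probe width {width:.2f} um is below the recommended {MIN_PROBE_WIDTH} um",
            UnderResolutionWarning,
            stacklevel=2,
        )
    return float(T_cl_max * _line_average(profile) * width)


def measure_probe(
    image: ChannelImage,
    p0: Sequence[float],
    p1: Sequence[float],
    T_cl_max: float,
    spacing: float | None = None,
) -> LineProbe:
    """Sample a segment and convert it into a tension measurement."""
    profile = sample_profile(image, p0, p1, spacing)
    width = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    tension = probe_tension(profile, width, T_cl_max)
    return LineProbe(
        p0=(float(p0[0]), float(p0[1])),
        p1=(float(p1[0]), float(p1[1])),
        samples=profile,
        c_mean=_line_average(profile),
        width=width,
        tension=tension,
    )


def equivalent_young_modulus(tension: float, diameter: float, strain: float) -> float:
    """Equivalent Young's modulus of a fiber, in kPa, assuming a circular section.

    ``E = T / (pi (d/2)^2 eps)``; with tension in nN and diameter in um the
    quotient nN/um^2 equals kPa exactly.
    """
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    if not strain > 0:
        raise ValueError("strain must be positive")
    return tension / (math.pi * (diameter / 2.0) ** 2 * strain)


def tonus(
    image: ChannelImage,
    p0: Sequence[float],
    p1: Sequence[float],
    T_cl_max: float,
    F_measured: float,
    spacing: float | None = None,
) -> tuple[float, float]:
    """Whole-cell tonus: tension across a cell-spanning segment and its ratio.

    Returns the tension (nN) and its percentage of the measured FA force
    sum (0 when no FA force is available).
    """
    probe = measure_probe(image, p0, p1, T_cl_max, spacing)
    ratio = 100.0 * probe.tension / F_measured if F_measured > 0 else 0.0
    return probe.tension, ratio


def read_probes(path: str | Path, pixel_pitch: float | None = None) -> list[tuple]:
    """Probe definitions from CSV with columns x0,y0,x1,y1 and optional units.

    Coordinates are micrometres unless a ``units`` column says ``px``, in
    which case ``pixel_pitch`` converts pixel indices to physical positions.
    """
    df = pd.read_csv(path)
    probes = []
    for _, row in df.iterrows():
        p0 = (float(row["x0"]), float(row["y0"]))
        p1 = (float(row["x1"]), float(row["y1"]))
        if "units" in df.columns and str(row["units"]).lower() == "px":
            if pixel_pitch is None:
                raise ValueError("pixel probes require a pixel_pitch")
            p0 = ((p0[0] + 0.5) * pixel_pitch, (p0[1] + 0.5) * pixel_pitch)
            p1 = ((p1[0] + 0.5) * pixel_pitch, (p1[1] + 0.5) * pixel_pitch)
        probes.append((p0, p1))
    return probes


def write_probe_results(probes: Sequence[LineProbe], path: str | Path) -> None:
    pd.DataFrame(
        {
            "x0_um": [p.p0[0] for p in probes],
            "y0_um": [p.p0[1] for p in probes],
            "x1_um": [p.p1[0] for p in probes],
            "y1_um": [p.p1[1] for p in probes],
            "width_um": [p.width for p in probes],
            "c_mean": [p.c_mean for p in probes],
            "tension_nN": [p.tension for p in probes],
        }
    ).to_csv(path, index=False)


def plot_probes(image: ChannelImage, probes: Sequence[LineProbe], path: str | Path) -> None:
    """Overlay of probe segments on the actin image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = image.intensities.shape
    pitch = image.pixel_pitch
    fig, ax = plt.subplots(figsize=(6, 6 * h / max(w, 1)))
    ax.imshow(image.intensities, cmap="gray", extent=(0, w * pitch, h * pitch, 0))
    for p in probes:
        ax.plot([p.p0[0], p.p1[0]], [p.p0[1], p.p1[1]], "-", color="magenta", linewidth=1.2)
        mid = ((p.p0[0] + p.p1[0]) / 2, (p.p0[1] + p.p1[1]) / 2)
        ax.annotate(f"{p.tension:.1f} nN", mid, color="yellow", fontsize=6)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
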