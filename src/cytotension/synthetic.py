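"""Synthetic fluorescence triplets with known geometry and ground truth.

Every pipeline stage is testable without a microscope: the generator draws
stress fibers as bright line segments with a Gaussian cross-profile
(FWHM = nominal width, emulating diffraction-limited imaging), an optional
circumferential actin belt, a uniform dendritic background inside the cell
body, vinculin disks of requested areas at fiber termini and a filled
nucleus ellipse.  Overlapping fibers are max-composited (gray values never
exceed 1 without renormalizing).

Noise is applied inside the cell body only, emulating staining
heterogeneity; outside-cell pixels stay exactly zero so the ``c > 0``
footprint rule stays well-posed.  Gaussian fields are truncated below
0.005 for the same reason (finite support).

The ground-truth tables carry, per fiber, a clean probe station (a
cross-segment placed where no other structure contaminates the profile)
and the analytic mean gray value across it; and per focal adhesion the
discretized mask area with its 5.5 nN/um^2 force.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf
from skimage.measure import label as _cc_label, regionprops
from skimage.morphology import convex_hull_image

from .adhesions import FORCE_COEFFICIENT
from .image_io import CellImageSet, ChannelImage, cell_footprint, normalize_actin

FIELD_FLOOR = 0.005  # Gaussian fields below this are zeroed (finite support)
FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.355: FWHM / sigma


@dataclasses.dataclass(frozen=True)
class Fiber:
    """A straight stress fiber: endpoints (um), nominal width (FWHM, um), peak gray."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float
    peak: float
    probe_t: float = 0.5  # clean measurement station along the fiber, in [0, 1]

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("fiber width must be positive")
        if not 0 < self.peak <= 1:
            raise ValueError("fiber peak must lie in ]0, 1]")


@dataclasses.dataclass(frozen=True)
class Belt:
    """Circumferential actin belt: a ring with Gaussian radial profile."""

    center: tuple[float, float]
    radius: float
    width: float
    intensity: float


@dataclasses.dataclass(frozen=True)
class NucleusSpec:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # um


@dataclasses.dataclass(frozen=True)
class AdhesionSite:
    center: tuple[float, float]
    area: float  # um^2

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("FA area must be positive")


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cell."""

    shape: tuple[int, int]  # (height, width) pixels
    pixel_pitch: float = 0.29  # um
    fibers: tuple[Fiber, ...] = ()
    belt: Belt | None = None
    nucleus: NucleusSpec | None = None
    fa_sites: tuple[AdhesionSite, ...] = ()
    background_intensity: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_intensity < 1:
            raise ValueError("background_intensity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    fibers: pd.DataFrame
    adhesions: pd.DataFrame


def _grids(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.shape
    p = spec.pixel_pitch
    Y, X = np.meshgrid((np.arange(h) + 0.5) * p, (np.arange(w) + 0.5) * p, indexing="ij")
    return X, Y


def _segment_distance(X: np.ndarray, Y: np.ndarray, p0, p1) -> np.ndarray:
    x0, y0 = p0
    vx, vy = p1[0] - x0, p1[1] - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return np.hypot(X - x0, Y - y0)
    t = np.clip(((X - x0) * vx + (Y - y0) * vy) / L2, 0.0, 1.0)
    return np.hypot(X - (x0 + t * vx), Y - (y0 + t * vy))


def _truncate(field: np.ndarray) -> np.ndarray:
    field[field < FIELD_FLOOR] = 0.0
    return field


def gaussian_cross_mean(peak: float, width: float) -> float:
    """Analytic mean of a Gaussian fiber profile over a probe of length = width.

    With sigma = width / 2.355 the mean of ``peak exp(-x^2 / 2 sigma^2)``
    over ``[-width/2, width/2]`` has the closed form
    ``peak * (sigma sqrt(2 pi) / width) * erf(width / (2 sqrt(2) sigma))``.
    """
    sigma = width / FWHM_SIGMA
    return float(peak * sigma * math.sqrt(2.0 * math.pi) / width * erf(width / (2.0 * math.sqrt(2.0) * sigma)))


def render(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Raw channel arrays plus exact masks for one synthetic cell."""
    X, Y = _grids(spec)
    h, w = spec.shape

    fiber_fields = []
    for f in spec.fibers:
        sigma = f.width / FWHM_SIGMA
        d = _segment_distance(X, Y, f.p0, f.p1)
        fiber_fields.append(_truncate(f.peak * np.exp(-(d**2) / (2.0 * sigma**2))))

    belt_field = np.zeros((h, w))
    if spec.belt is not None:
        sigma = spec.belt.width / FWHM_SIGMA
        r = np.hypot(X - spec.belt.center[0], Y - spec.belt.center[1])
        belt_field = _truncate(spec.belt.intensity * np.exp(-((r - spec.belt.radius) ** 2) / (2.0 * sigma**2)))

    nucleus_mask = np.zeros((h, w), dtype=bool)
    if spec.nucleus is not None:
        ax, ay = spec.nucleus.semi_axes
        nucleus_mask = ((X - spec.nucleus.center[0]) / ax) ** 2 + ((Y - spec.nucleus.center[1]) / ay) ** 2 <= 1.0

    vinculin_mask = np.zeros((h, w), dtype=bool)
    for site in spec.fa_sites:
        r = math.sqrt(site.area / math.pi)
        vinculin_mask |= np.hypot(X - site.center[0], Y - site.center[1]) <= r
    n_components = int(_cc_label(vinculin_mask, connectivity=2).max())
    if spec.fa_sites and n_components < len(spec.fa_sites):
        warnings.warn(
            f"{len(spec.fa_sites)} FA disks merged into {n_components} components; "
            "ground-truth areas recomputed from the merged mask",
            stacklevel=2,
        )

    support = nucleus_mask | vinculin_mask | (belt_field > 0)
    for field in fiber_fields:
        support |= field > 0
    body = convex_hull_image(support) if support.any() else support

    actin = np.full((h, w), spec.background_intensity)
    for field in fiber_fields:
        np.maximum(actin, field, out=actin)
    np.maximum(actin, belt_field, out=actin)
    actin[~body] = 0.0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        actin[body] += rng.normal(0.0, spec.noise_sd, int(body.sum()))
    np.clip(actin, 0.0, 1.0, out=actin)

    vinculin = vinculin_mask.astype(float) * 0.9
    nucleus = nucleus_mask.astype(float) * 0.8
    return {
        "actin": actin,
        "vinculin": vinculin,
        "nucleus": nucleus,
        "vinculin_mask": vinculin_mask,
        "nucleus_mask": nucleus_mask,
        "body_mask": body,
    }


def _fiber_truth(spec: SyntheticSpec, norm_factor: float) -> pd.DataFrame:
    rows = []
    for k, f in enumerate(spec.fibers):
        ux, uy = f.p1[0] - f.p0[0], f.p1[1] - f.p0[1]
        length = math.hypot(ux, uy)
        ux, uy = ux / length, uy / length
        nx, ny = -uy, ux  # unit normal
        sx = f.p0[0] + f.probe_t * length * ux
        sy = f.p0[1] + f.probe_t * length * uy
        half = f.width / 2.0
        c_mean = gaussian_cross_mean(f.peak, f.width) / norm_factor
        rows.append(
            {
                "fiber_id": k,
                "x0_um": f.p0[0],
                "y0_um": f.p0[1],
                "x1_um": f.p1[0],
                "y1_um": f.p1[1],
                "width_um": f.width,
                "peak": f.peak,
                "c_cross_mean": c_mean,
                "probe_x0_um": sx - half * nx,
                "probe_y0_um": sy - half * ny,
                "probe_x1_um": sx + half * nx,
                "probe_y1_um": sy + half * ny,
                "tension_per_unit_tclmax_um": c_mean * f.width,
            }
        )
    return pd.DataFrame(rows)


def _adhesion_truth(vinculin_mask: np.ndarray, pixel_pitch: float) -> pd.DataFrame:
    labels = _cc_label(vinculin_mask, connectivity=2)
    rows = []
    for prop in regionprops(labels):
        area = float(prop.area) * pixel_pitch**2
        row, col = prop.centroid
        rows.append(
            {
                "component_id": int(prop.label),
                "x_um": (col + 0.5) * pixel_pitch,
                "y_um": (row + 0.5) * pixel_pitch,
                "area_um2": area,
                "force_nN": FORCE_COEFFICIENT * area,
            }
        )
    return pd.DataFrame(rows)


def generate(spec: SyntheticSpec) -> tuple[CellImageSet, GroundTruth]:
    """Render a spec into a ready-to-use channel set plus its ground truth.

    The actin channel is normalized exactly as real input would be; the
    ground-truth mean gray values are divided by the same normalization
    factor so they match what a probe measures on the returned images.
    """
    arrays = render(spec)
    raw = ChannelImage(arrays["actin"], spec.pixel_pitch)
    norm_factor = float(arrays["actin"].max())
    norm = normalize_actin(raw)
    cell_mask = cell_footprint(norm) | arrays["nucleus_mask"] | arrays["vinculin_mask"]
    images = CellImageSet(
        actin=norm,
        vinculin_mask=arrays["vinculin_mask"],
        nucleus_mask=arrays["nucleus_mask"],
        cell_mask=cell_mask,
        pixel_pitch=spec.pixel_pitch,
    )
    truth = GroundTruth(
        fibers=_fiber_truth(spec, norm_factor),
        adhesions=_adhesion_truth(arrays["vinculin_mask"], spec.pixel_pitch),
    )
    return images, truth


def reference_cell() -> SyntheticSpec:
    """The standard synthetic cell: 62 x 35 um at 0.29 um/px, ~35 000 cell pixels.

    Five straight fibers (widths 0.85-1.75 um), a circumferential belt, an
    elliptical 12 x 8 um nucleus and eight vinculin disks of 1-3 um^2 with
    every fiber ending inside a disk.  Probe stations sit at fiber
    parameter t where no other structure crosses the profile.
    """
    return SyntheticSpec(
        shape=(121, 214),  # 35.1 x 62.1 um
        pixel_pitch=0.29,
        fibers=(
            Fiber((6.0, 8.0), (56.0, 8.0), width=1.75, peak=1.0, probe_t=0.2),
            Fiber((6.0, 27.0), (56.0, 27.0), width=1.58, peak=0.9, probe_t=0.2),
            Fiber((6.0, 8.0), (56.0, 27.0), width=1.2, peak=0.8, probe_t=0.2),
            Fiber((6.0, 27.0), (56.0, 8.0), width=1.0, peak=0.7, probe_t=0.2),
            Fiber((31.0, 4.0), (31.0, 31.0), width=0.85, peak=0.6, probe_t=(11.0 - 4.0) / 27.0),
        ),
        belt=Belt(center=(31.0, 17.5), radius=14.0, width=1.0, intensity=0.85),
        nucleus=NucleusSpec(center=(31.0, 17.5), semi_axes=(6.0, 4.0)),
        fa_sites=(
            AdhesionSite((6.0, 8.0), 2.5),
            AdhesionSite((56.0, 8.0), 2.2),
            AdhesionSite((6.0, 27.0), 2.0),
            AdhesionSite((56.0, 27.0), 1.8),
            AdhesionSite((31.0, 4.0), 1.5),
            AdhesionSite((31.0, 31.0), 1.4),
            AdhesionSite((18.0, 5.0), 1.1),
            AdhesionSite((44.0, 30.0), 1.2),
        ),
        background_intensity=0.15,
        noise_sd=0.01,
        seed=7,
    )


def mini_cell() -> SyntheticSpec:
    """A small two-fiber cell for fast end-to-end runs and resolution studies."""
    return SyntheticSpec(
        shape=(56, 84),  # 16.2 x 24.4 um
        pixel_pitch=0.29,
        fibers=(
            Fiber((3.0, 5.0), (21.0, 5.0), width=1.2, peak=1.0, probe_t=0.35),
            Fiber((3.0, 11.0), (21.0, 11.0), width=0.9, peak=0.75, probe_t=0.35),
        ),
        nucleus=NucleusSpec(center=(12.0, 8.0), semi_axes=(3.0, 2.0)),
        fa_sites=(
            AdhesionSite((3.0, 5.0), 1.5),
            AdhesionSite((21.0, 5.0), 1.5),
            AdhesionSite((3.0, 11.0), 1.5),
            AdhesionSite((21.0, 11.0), 1.5),
        ),
        background_intensity=0.12,
        noise_sd=0.0,
        seed=3,
    )


def spacing_study_cell() -> SyntheticSpec:
    """A cell for node-spacing (resolution) studies.

    Every structure is resolved even at the coarsest spacing the study
    doubles to (d0 = 1.16 um): fibers 2.0-2.5 um wide and four large
    6 um^2 adhesion disks.  Under-resolved structures would confound the
    scaling of anchor forces with discretization artefacts.
    """
    return SyntheticSpec(
        shape=(62, 104),  # 18 x 30.2 um
        pixel_pitch=0.29,
        fibers=(
            Fiber((4.5, 6.0), (25.5, 6.0), width=2.5, peak=1.0, probe_t=0.35),
            Fiber((4.5, 12.0), (25.5, 12.0), width=2.0, peak=0.8, probe_t=0.35),
        ),
        fa_sites=(
            AdhesionSite((4.5, 6.0), 6.0),
            AdhesionSite((25.5, 6.0), 6.0),
            AdhesionSite((4.5, 12.0), 6.0),
            AdhesionSite((25.5, 12.0), 6.0),
        ),
        background_intensity=0.1,
        noise_sd=0.0,
    )


def emit(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the three TIFF channels, the ground-truth CSVs and the spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = render(spec)
    paths = {}
    for name in ("actin", "vinculin", "nucleus"):
        path = outdir / f"{name}.tif"
        tifffile.imwrite(str(path), np.round(arrays[name] * 65535.0).astype(np.uint16))
        paths[name] = path
    _, truth = generate(spec)
    paths["fibers"] = outdir / "ground_truth_fibers.csv"
    truth.fibers.to_csv(paths["fibers"], index=False)
    paths["adhesions"] = outdir / "ground_truth_adhesions.csv"
    truth.adhesions.to_csv(paths["adhesions"], index=False)
    paths["spec"] = outdir / "spec.json"
    spec.to_json(paths["spec"])
    return paths
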