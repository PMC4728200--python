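"""Focal-adhesion detection and traction-force estimation from the vinculin mask.

Focal-adhesion (FA) area correlates linearly with the traction force the
cell transmits through it: force = 5.5 nN/um^2 * area, valid for FAs of at
least 1 um^2.  Sub-micrometre adhesions (0.5-1 um^2) carry forces that do
not scale with area; optionally each is assigned a flat force (15 nN by
default) to explore that scenario.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label, regionprops

FORCE_COEFFICIENT = 5.5  # nN per um^2 of vinculin-covered area
MIN_AREA = 1.0  # um^2, below which area-force linearity does not hold
SUBMICRON_FORCE = 15.0  # nN, flat per-FA force for the 0.5-1 um^2 class
SUBMICRON_RANGE = (0.5, 1.0)  # um^2


@dataclasses.dataclass(frozen=True)
class AdhesionConfig:
    """Parameters of FA detection and force conversion."""

    force_coefficient: float = FORCE_COEFFICIENT
    min_area: float = MIN_AREA
    connectivity: int = 8
    submicron_force: float = SUBMICRON_FORCE
    include_submicron: bool = False

    def __post_init__(self) -> None:
        if not self.force_coefficient > 0:
            raise ValueError("force_coefficient must be positive")
        if not self.min_area > 0:
            raise ValueError("min_area must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass(frozen=True)
class FocalAdhesion:
    """One connected vinculin component with its area and estimated force."""

    id: int
    pixel_count: int
    area: float  # um^2
    centroid: tuple[float, float]  # (x, y) um
    force: float = 0.0  # nN


def detect_adhesions(
    mask: np.ndarray, pixel_pitch: float, config: AdhesionConfig | None = None
) -> list[FocalAdhesion]:
    """Identify focal adhesions as connected components of the vinculin mask.

    Returns one :class:`FocalAdhesion` per component, sorted by descending
    area, with areas in um^2 and centroids in physical coordinates.  No
    area filter is applied here.  An empty mask yields an empty list.
    """
    config = config or AdhesionConfig()
    mask = np.asarray(mask, dtype=bool)
    if not pixel_pitch > 0:
        raise ValueError("pixel_pitch must be positive")
    labels = _cc_label(mask, connectivity=1 if config.connectivity == 4 else 2)
    fas = []
    for prop in regionprops(labels):
        row, col = prop.centroid
        fas.append(
            FocalAdhesion(
                id=int(prop.label),
                pixel_count=int(prop.area),
                area=float(prop.area) * pixel_pitch**2,
                centroid=((col + 0.5) * pixel_pitch, (row + 0.5) * pixel_pitch),
            )
        )
    return sorted(fas, key=lambda fa: fa.area, reverse=True)


def filter_by_area(fas: Sequence[FocalAdhesion], min_area: float = MIN_AREA) -> list[FocalAdhesion]:
    """Retain FAs with area >= ``min_area`` (boundary inclusive); order preserved."""
    return [fa for fa in fas if fa.area >= min_area]


def estimate_forces(
    fas: Sequence[FocalAdhesion], config: AdhesionConfig | None = None
) -> tuple[list[FocalAdhesion], float]:
    """Convert FA areas into traction-force magnitudes and sum them.

    Each FA of area >= ``min_area`` is assigned ``force_coefficient * area``
    nN.  When ``include_submicron`` is set, every FA in the 0.5-1 um^2 class
    additionally receives the flat ``submicron_force``.  Returns the FAs with
    forces filled in and ``F_measured``, the sum of all force magnitudes.
    """
    config = config or AdhesionConfig()
    lo, hi = SUBMICRON_RANGE
    out = []
    for fa in fas:
        if fa.area >= config.min_area:
            force = config.force_coefficient * fa.area
        elif config.include_submicron and lo <= fa.area < hi:
            force = config.submicron_force
        else:
            force = 0.0
        out.append(dataclasses.replace(fa, force=force))
    return out, float(sum(fa.force for fa in out))


def adhesion_table(fas: Sequence[FocalAdhesion]) -> pd.DataFrame:
    """FA table with one row per adhesion (areas in um^2, forces in nN)."""
    return pd.DataFrame(
        {
            "id": [fa.id for fa in fas],
            "pixel_count": [fa.pixel_count for fa in fas],
            "area_um2": [fa.area for fa in fas],
            "centroid_x_um": [fa.centroid[0] for fa in fas],
            "centroid_y_um": [fa.centroid[1] for fa in fas],
            "force_nN": [fa.force for fa in fas],
        }
    )


def write_adhesion_table(fas: Sequence[FocalAdhesion], path: str | Path) -> None:
    adhesion_table(fas).to_csv(path, index=False)


def plot_adhesions(mask: np.ndarray, fas: Sequence[FocalAdhesion], pixel_pitch: float, path: str | Path) -> None:
    """Overlay of retained FAs (centroid markers sized by area) on the vinculin mask."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = mask.shape
    fig, ax = plt.subplots(figsize=(6, 6 * h / max(w, 1)))
    ax.imshow(mask, cmap="gray", extent=(0, w * pixel_pitch, h * pixel_pitch, 0))
    for fa in fas:
        ax.plot(*fa.centroid, "r+", markersize=6)
        ax.annotate(f"{fa.area:.1f}", fa.centroid, color="orange", fontsize=6)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
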