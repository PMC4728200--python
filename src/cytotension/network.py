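"""Conversion of image pixels into the labelled mechanical node network.

Every 2x2 block of pixels becomes at most one node (keeping the node count
below 10 000 for a typical ~35 000-pixel cell): vinculin blocks become
immobilized anchor nodes, nucleus blocks become nucleus nodes, and actin
blocks become actin nodes labelled l1..l10 by their mean normalized gray
value (bins ``]0.1(i-1); 0.1 i]``).  Neighbouring nodes closer than
``g_v = 1.1 d0`` are linked by pre-strained tensile interactions acting as
virtual rubber bands; on the square node grid this selects exactly the
4-neighbourhood (diagonal spacing 1.414 d0 > g_v).

Interaction stiffness encodes local actin density: ``K_i = a * 0.1 * i``
for a same-label actin pair, the weakest label wins for mixed actin pairs,
nucleus-nucleus interactions are 10x stiffer than the strongest actin one,
and actin-vinculin / actin-nucleus pairs use the actin partner's label.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .image_io import CellImageSet

D0_DEFAULT = 0.58  # um, node spacing after 2x2 binning of 0.29 um pixels
EPSILON0 = 0.2  # pre-strain of every tensile interaction (myosin contraction)
GV_FACTOR = 1.1  # creation threshold g_v = 1.1 g0
NODE_MASS = 0.8  # pg, water-equivalent mass of the contactor envelope
NODE_CAP = 10_000
CONTACTOR_RADIUS_FACTOR = 0.4  # contactor radius = 0.4 d0 (< d0/2)
NUCLEUS_STIFFNESS_FACTOR = 10.0  # nucleus K = 10x the strongest actin K


@dataclasses.dataclass(frozen=True)
class Node:
    """One mechanical node: a 2x2 pixel block of the cell image."""

    id: int
    kind: str  # "actin" | "nucleus" | "vinculin"
    label: int | None  # l1..l10, actin nodes only
    x: float  # um
    y: float  # um
    mass: float = NODE_MASS  # pg
    fixed: bool = False
    contactor_radius: float = CONTACTOR_RADIUS_FACTOR * D0_DEFAULT  # um

    def __post_init__(self) -> None:
        if self.kind not in ("actin", "nucleus", "vinculin"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "actin" and self.label is None:
            raise ValueError("actin nodes must carry a label")
        if self.kind == "vinculin" and not self.fixed:
            raise ValueError("vinculin nodes must be fixed (substrate anchors)")
        if not self.mass > 0:
            raise ValueError("mass must be positive")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclasses.dataclass(frozen=True)
class TensileInteraction:
    """A pre-strained rubber-band interaction between two nodes.

    The traction magnitude is ``K ((g - g0)/g0 + eps0)`` while taut and 0
    once the band slackens (``g <= (1 - eps0) g0``).
    """

    node_a: int
    node_b: int
    g0: float  # um, rest gap at build time
    K: float  # nN per unit strain
    epsilon0: float = EPSILON0
    gv: float = dataclasses.field(default=0.0)

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("self-interaction is not allowed")
        if not self.g0 > 0:
            raise ValueError("g0 must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if not 0 < self.epsilon0 < 1:
            raise ValueError("epsilon0 must lie in (0, 1)")
        gv = self.gv if self.gv > 0 else GV_FACTOR * self.g0
        if not self.g0 < gv < 2 * self.g0:
            raise ValueError("gv must satisfy g0 < gv < 2 g0")
        object.__setattr__(self, "gv", gv)


@dataclasses.dataclass
class CellModel:
    """The full node-and-interaction model of one cell."""

    nodes: list[Node]
    interactions: list[TensileInteraction]
    d0: float = D0_DEFAULT  # um
    a: float | None = None  # nN, actin-density-to-stiffness coefficient
    F_measured: float | None = None  # nN, experimental FA force sum

    def __post_init__(self) -> None:
        if len(self.nodes) > NODE_CAP:
            raise ValueError(f"node count {len(self.nodes)} exceeds the cap of {NODE_CAP}")
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        seen = set()
        for it in self.interactions:
            if it.node_a not in ids or it.node_b not in ids:
                raise ValueError(f"interaction ({it.node_a}, {it.node_b}) references unknown nodes")
            key = (min(it.node_a, it.node_b), max(it.node_a, it.node_b))
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "d0": self.d0,
            "a": self.a,
            "F_measured": self.F_measured,
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "label": n.label,
                    "x_um": n.x,
                    "y_um": n.y,
                    "mass_pg": n.mass,
                    "fixed": n.fixed,
                    "contactor_radius_um": n.contactor_radius,
                }
                for n in self.nodes
            ],
            "interactions": [
                {"a": it.node_a, "b": it.node_b, "g0": it.g0, "K": it.K, "eps0": it.epsilon0, "gv": it.gv}
                for it in self.interactions
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CellModel":
        payload = json.loads(Path(path).read_text())
        nodes = [
            Node(
                id=d["id"],
                kind=d["kind"],
                label=d["label"],
                x=d["x_um"],
                y=d["y_um"],
                mass=d["mass_pg"],
                fixed=d["fixed"],
                contactor_radius=d["contactor_radius_um"],
            )
            for d in payload["nodes"]
        ]
        interactions = [
            TensileInteraction(
                node_a=d["a"], node_b=d["b"], g0=d["g0"], K=d["K"], epsilon0=d["eps0"], gv=d["gv"]
            )
            for d in payload["interactions"]
        ]
        return cls(nodes, interactions, d0=payload["d0"], a=payload["a"], F_measured=payload["F_measured"])


def label_of(c: float) -> int | None:
    """Label index i in 1..10 with ``c`` in the right-closed bin ``]0.1(i-1); 0.1 i]``.

    ``c = 0`` (no actin) yields ``None``; values outside ``[0, 1]`` are errors.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"gray value {c} outside [0, 1]")
    if c == 0.0:
        return None
    return min(10, max(1, int(math.ceil(c * 10.0 - 1e-12))))


def pixels_to_nodes(
    images: CellImageSet,
    block_size: int = 2,
    mass: float = NODE_MASS,
    contactor_radius: float | None = None,
) -> list[Node]:
    """Partition the image into ``block_size``-square pixel blocks and emit nodes.

    Within a block the kind priority is vinculin > nucleus > actin: anchors
    are the boundary condition of the model and must never be demoted.  An
    actin node is created when the mean normalized gray value of the block
    (restricted to the cell mask) is positive, and is labelled from that
    mean.  Node positions sit at block centres; spacing is
    ``block_size * pixel_pitch``.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    pitch = images.pixel_pitch
    d_node = block_size * pitch
    radius = contactor_radius if contactor_radius is not None else CONTACTOR_RADIUS_FACTOR * d_node
    if not radius < d_node / 2:
        raise ValueError("contactor_radius must be smaller than half the node spacing")

    c = images.actin.intensities * images.cell_mask
    h, w = c.shape
    hb, wb = h // block_size, w // block_size
    if hb == 0 or wb == 0:
        raise ValueError("image smaller than one block")
    crop = (slice(0, hb * block_size), slice(0, wb * block_size))

    def blocks(arr: np.ndarray) -> np.ndarray:
        return arr[crop].reshape(hb, block_size, wb, block_size)

    vin_any = blocks(images.vinculin_mask).any(axis=(1, 3))
    nuc_any = blocks(images.nucleus_mask).any(axis=(1, 3))
    c_mean = blocks(c).mean(axis=(1, 3))

    actin_here = ~vin_any & ~nuc_any & (c_mean > 0)
    n_nodes = int(vin_any.sum() + nuc_any.sum() + actin_here.sum())
    if n_nodes == 0:
        raise ValueError("empty footprint: no blocks produced a node")
    if n_nodes > NODE_CAP:
        raise ValueError(
            f"node count {n_nodes} exceeds the cap of {NODE_CAP}; use a coarser binning (larger block_size)"
        )

    nodes: list[Node] = []
    nid = 0
    for bi in range(hb):
        y = (bi * block_size + block_size / 2.0) * pitch
        for bj in range(wb):
            x = (bj * block_size + block_size / 2.0) * pitch
            if vin_any[bi, bj]:
                kind, lab, fixed = "vinculin", None, True
            elif nuc_any[bi, bj]:
                kind, lab, fixed = "nucleus", None, False
            elif actin_here[bi, bj]:
                kind, lab, fixed = "actin", label_of(float(min(c_mean[bi, bj], 1.0))), False
            else:
                continue
            nodes.append(
                Node(id=nid, kind=kind, label=lab, x=x, y=y, mass=mass, fixed=fixed, contactor_radius=radius)
            )
            nid += 1
    return nodes


def stiffness_for(node_a: Node, node_b: Node, a: float) -> float:
    """Stiffness of the interaction between two nodes for coefficient ``a`` (nN).

    Same-label actin pair: ``a * 0.1 * i``.  Mixed actin labels: the weakest
    label rule, ``a * 0.1 * min(i, j)``.  Nucleus pairs: 10x the strongest
    actin interaction, ``10 a``.  A pair mixing actin with nucleus or
    vinculin uses the actin node's label (the only labelled side); a
    nucleus-vinculin pair uses the nucleus stiffness.
    """
    if not a > 0:
        raise ValueError("coefficient a must be positive")
    kinds = {node_a.kind, node_b.kind}
    if kinds == {"vinculin"}:
        raise ValueError("vinculin-vinculin interactions are not created")
    if kinds == {"nucleus"} or kinds == {"nucleus", "vinculin"}:
        return NUCLEUS_STIFFNESS_FACTOR * a
    labels = [n.label for n in (node_a, node_b) if n.kind == "actin"]
    if any(lab is None for lab in labels):
        raise ValueError("unlabeled actin node")
    return a * 0.1 * min(labels)


def build_interactions(
    nodes: Sequence[Node],
    a: float,
    d0: float = D0_DEFAULT,
    gv_factor: float = GV_FACTOR,
    epsilon0: float = EPSILON0,
) -> list[TensileInteraction]:
    """Create one tensile interaction per node pair closer than ``g_v = gv_factor * d0``.

    Vinculin-vinculin pairs are skipped (both anchors are immobile).  Each
    interaction stores its actual build-time separation as ``g0``.
    """
    if a is None or not a > 0:
        raise ValueError("coefficient a must be set and positive before building interactions")
    pos = np.array([[n.x, n.y] for n in nodes])
    if len(pos) < 2:
        return []
    gv = gv_factor * d0
    pairs = cKDTree(pos).query_pairs(r=gv * (1 + 1e-9), output_type="ndarray")
    interactions: list[TensileInteraction] = []
    for i, j in pairs:
        na, nb = nodes[int(i)], nodes[int(j)]
        if na.kind == "vinculin" and nb.kind == "vinculin":
            continue
        g0 = float(np.hypot(na.x - nb.x, na.y - nb.y))
        if g0 == 0.0:
            raise ValueError(f"coincident nodes {na.id} and {nb.id}")
        interactions.append(
            TensileInteraction(
                node_a=na.id,
                node_b=nb.id,
                g0=g0,
                K=stiffness_for(na, nb, a),
                epsilon0=epsilon0,
                gv=gv_factor * g0,
            )
        )
    return interactions


def build_model(
    images: CellImageSet,
    a: float,
    block_size: int = 2,
    gv_factor: float = GV_FACTOR,
    epsilon0: float = EPSILON0,
    mass: float = NODE_MASS,
    contactor_radius: float | None = None,
    F_measured: float | None = None,
) -> CellModel:
    """Build the full cell model from a channel set at coefficient ``a``."""
    nodes = pixels_to_nodes(images, block_size=block_size, mass=mass, contactor_radius=contactor_radius)
    d0 = block_size * images.pixel_pitch
    interactions = build_interactions(nodes, a, d0=d0, gv_factor=gv_factor, epsilon0=epsilon0)
    return CellModel(nodes, interactions, d0=d0, a=a, F_measured=F_measured)
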