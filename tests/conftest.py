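"""Shared fixtures: synthetic cells, calibration sweeps and an independent
energy-minimization oracle for small interaction systems."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from cytotension import adhesions as adh
from cytotension import build_model, calibration as cal, mechanics as mech
from cytotension import synthetic as syn

ASTAR = 4.4  # nN, ground-truth coefficient used for recovery/ordering studies


@pytest.fixture(scope="session")
def ref_cell():
    """Reference synthetic cell: (images, ground truth)."""
    return syn.generate(syn.reference_cell())


@pytest.fixture(scope="session")
def ref_cell_noiseless():
    import dataclasses

    spec = dataclasses.replace(syn.reference_cell(), noise_sd=0.0)
    return syn.generate(spec)


@pytest.fixture(scope="session")
def ref_builder(ref_cell):
    images, _ = ref_cell

    def builder(a: float):
        return build_model(images, a)

    return builder


@pytest.fixture(scope="session")
def ref_F_measured(ref_cell):
    """Experimentally-style FA force sum of the reference cell (area >= 1 um^2)."""
    images, _ = ref_cell
    fas = adh.detect_adhesions(images.vinculin_mask, images.pixel_pitch)
    _, F = adh.estimate_forces(fas)
    return F


@pytest.fixture(scope="session")
def sweep_mt_plus(ref_builder):
    curve = cal.sweep(ref_builder, cal.DEFAULT_SWEEP, mech.SolverConfig(contact_enabled=True))
    cal.fit_linear(curve)
    return curve


@pytest.fixture(scope="session")
def sweep_mt_minus(ref_builder):
    curve = cal.sweep(ref_builder, cal.DEFAULT_SWEEP, mech.SolverConfig(contact_enabled=False))
    cal.fit_linear(curve)
    return curve


@pytest.fixture(scope="session")
def state_astar_mt_plus(ref_builder):
    return mech.relax(ref_builder(ASTAR), mech.SolverConfig(contact_enabled=True))


@pytest.fixture(scope="session")
def state_astar_mt_minus(ref_builder):
    return mech.relax(ref_builder(ASTAR), mech.SolverConfig(contact_enabled=False))


def energy_minimum_positions(model, config: mech.SolverConfig) -> np.ndarray:
    """Independent oracle: equilibrium positions of a small model by direct
    minimization of the network's potential energy.

    Tensile interaction energy: 0.5 K/g0 * max(0, g - (1-eps0) g0)^2, whose
    gradient magnitude is the rubber-band force law.  Contact energy (when
    enabled): 0.5 * penalty * min(0, gap)^2 over all node pairs.
    """
    nodes = model.nodes
    index = {n.id: k for k, n in enumerate(nodes)}
    pos0 = np.array([[n.x, n.y] for n in nodes], dtype=float)
    fixed = np.array([n.fixed for n in nodes])
    free = np.flatnonzero(~fixed)
    radius = np.array([n.contactor_radius for n in nodes])
    if config.contact_penalty is not None:
        penalty = config.contact_penalty
    else:
        penalty = mech.PENALTY_FACTOR * (model.a or 1.0) / model.d0

    ia = np.array([index[it.node_a] for it in model.interactions], dtype=int)
    ib = np.array([index[it.node_b] for it in model.interactions], dtype=int)
    K = np.array([it.K for it in model.interactions])
    g0 = np.array([it.g0 for it in model.interactions])
    eps0 = np.array([it.epsilon0 for it in model.interactions])
    pairs = np.array([(i, j) for i in range(len(nodes)) for j in range(i + 1, len(nodes))], dtype=int)

    def energy(x: np.ndarray) -> float:
        pos = pos0.copy()
        pos[free] = x.reshape(-1, 2)
        d = pos[ib] - pos[ia]
        g = np.hypot(d[:, 0], d[:, 1])
        stretch = np.maximum(0.0, g - (1.0 - eps0) * g0)
        e = float(np.sum(0.5 * K / g0 * stretch**2))
        if config.contact_enabled and len(pairs):
            dc = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            gap = np.hypot(dc[:, 0], dc[:, 1]) - (radius[pairs[:, 0]] + radius[pairs[:, 1]])
            e += float(np.sum(0.5 * penalty * np.minimum(0.0, gap) ** 2))
        return e

    res = minimize(energy, pos0[free].ravel(), method="BFGS", options={"gtol": 1e-14, "maxiter": 10000})
    out = pos0.copy()
    out[free] = res.x.reshape(-1, 2)
    return out
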