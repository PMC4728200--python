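"""Relaxation of the pre-stressed interaction network to mechanical equilibrium.

Units are pg / um / us throughout, which makes force come out in nN exactly
(1 pg um / us^2 = 1 nN).

The network is integrated with a damped semi-implicit Euler scheme: per
step, forces are accumulated on every free node, velocities are updated and
scaled by a retention factor, positions follow.  Vinculin anchors never
move.  Optional sphere-sphere compression contacts (the microtubule
stand-in, scenario MT+) are a linear penalty regularization of the rigid
frictionless law ``g >= 0, R_N >= 0, g R_N = 0``; the penalty is chosen so
penetration at equilibrium stays below 1% of the node spacing.

The target is the static equilibrium, not the transient: the solver is
strongly overdamped and runs a fixed number of steps, reporting the final
force residual rather than enforcing convergence.  No randomness anywhere:
runs are bit-reproducible for identical inputs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .network import CellModel

DEFAULT_DT = 0.025  # us
DEFAULT_STEPS = 12_000  # dt * steps = 300 us, the standard relaxation horizon
DEFAULT_DAMPING = 0.5  # per-step velocity retention (strongly overdamped)
PENALTY_FACTOR = 100.0  # contact penalty = 100 a / d0 (nN/um)
PENETRATION_LIMIT = 0.01  # max tolerated penetration, as a fraction of d0


class SolverDivergence(RuntimeError):
    """Raised when the free run length grows for many consecutive steps."""


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the relaxation.

    ``contact_enabled`` switches between the MT+ (True) and MT- (False)
    scenarios.  ``contact_penalty`` defaults to ``100 a / d0`` when unset.
    ``enforce_gv`` re-applies the creation threshold during motion (off by
    default: interactions persist under stretch, g_v acts at build time
    only).
    """

    dt: float = DEFAULT_DT  # us
    steps: int = DEFAULT_STEPS
    damping: float = DEFAULT_DAMPING
    contact_enabled: bool = True
    contact_penalty: float | None = None  # nN/um
    equilibrium_tol: float = 0.01  # nN, max residual force on free nodes
    enforce_gv: bool = False
    contact_refresh: int = 100  # steps between contact candidate rebuilds
    contact_skin: float = 0.3  # um, cushion added to the contact search radius
    divergence_window: int = 50

    def __post_init__(self) -> None:
        if not self.dt > 0 or self.steps < 1:
            raise ValueError("dt must be positive and steps >= 1")
        if not 0.0 <= self.damping < 1.0:
            raise ValueError("damping must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class ContactPair:
    """One engaged sphere-sphere contact: surface gap g and normal reaction RN."""

    node_a: int
    node_b: int
    gap: float  # um (negative = penetration of the penalty law)
    normal_force: float  # nN, >= 0


@dataclasses.dataclass
class ModelState:
    """Solver state: positions, velocities, forces and diagnostics."""

    positions: np.ndarray  # (N, 2) um
    velocities: np.ndarray  # (N, 2) um/us
    tensions: np.ndarray  # (E,) nN, per interaction
    contacts: list[ContactPair]
    fa_reactions: dict[int, np.ndarray]  # node id -> net force vector (nN)
    free_run_length: np.ndarray  # um per step
    step: int
    residual: float  # nN, max net force on free nodes
    converged: bool
    max_penetration: float  # um
    complementarity_residual: float  # nN um, max |min(g,0)| * RN


class _System:
    """Vectorized arrays compiled from a CellModel (internal)."""

    def __init__(self, model: CellModel, config: SolverConfig):
        nodes = model.nodes
        self.node_ids = np.array([n.id for n in nodes])
        index = {n.id: k for k, n in enumerate(nodes)}
        self.pos = np.array([[n.x, n.y] for n in nodes], dtype=float)
        self.mass = np.array([n.mass for n in nodes], dtype=float)
        self.fixed = np.array([n.fixed for n in nodes], dtype=bool)
        self.vinculin = np.array([n.kind == "vinculin" for n in nodes], dtype=bool)
        self.radius = np.array([n.contactor_radius for n in nodes], dtype=float)
        self.n = len(nodes)

        self.ia = np.array([index[it.node_a] for it in model.interactions], dtype=np.intp)
        self.ib = np.array([index[it.node_b] for it in model.interactions], dtype=np.intp)
        self.K = np.array([it.K for it in model.interactions], dtype=float)
        self.g0 = np.array([it.g0 for it in model.interactions], dtype=float)
        self.eps0 = np.array([it.epsilon0 for it in model.interactions], dtype=float)
        self.gv = np.array([it.gv for it in model.interactions], dtype=float)

        if config.contact_penalty is not None:
            self.penalty = float(config.contact_penalty)
        else:
            scale = model.a if model.a is not None else (self.K.max() if len(self.K) else 1.0)
            self.penalty = PENALTY_FACTOR * float(scale) / model.d0
        self.config = config
        self.ca = np.empty(0, dtype=np.intp)
        self.cb = np.empty(0, dtype=np.intp)

    def refresh_contacts(self) -> None:
        if self.n < 2:
            return
        r = 2.0 * self.radius.max() + self.config.contact_skin
        pairs = cKDTree(self.pos).query_pairs(r=r, output_type="ndarray")
        if len(pairs):
            both_fixed = self.fixed[pairs[:, 0]] & self.fixed[pairs[:, 1]]
            pairs = pairs[~both_fixed]
        self.ca = pairs[:, 0].astype(np.intp) if len(pairs) else np.empty(0, dtype=np.intp)
        self.cb = pairs[:, 1].astype(np.intp) if len(pairs) else np.empty(0, dtype=np.intp)

    def forces(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Net force per node, tensile-only force, tensions and contact arrays."""
        F = np.zeros_like(self.pos)
        d = self.pos[self.ib] - self.pos[self.ia]
        g = np.hypot(d[:, 0], d[:, 1])
        if len(g) and g.min() <= 0:
            bad = int(self.node_ids[self.ia[int(g.argmin())]])
            raise SolverDivergence(f"coincident interacting nodes (node id {bad})")
        T = tensile_force_array(g, self.K, self.g0, self.eps0)
        if self.config.enforce_gv and len(T):
            T = np.where(g >= self.gv, 0.0, T)
        if len(T):
            u = d / g[:, None]
            fx = T * u[:, 0]
            fy = T * u[:, 1]
            F[:, 0] += np.bincount(self.ia, weights=fx, minlength=self.n)
            F[:, 0] -= np.bincount(self.ib, weights=fx, minlength=self.n)
            F[:, 1] += np.bincount(self.ia, weights=fy, minlength=self.n)
            F[:, 1] -= np.bincount(self.ib, weights=fy, minlength=self.n)
        F_tensile = F.copy()

        gap = np.empty(0)
        RN = np.empty(0)
        if self.config.contact_enabled and len(self.ca):
            dc = self.pos[self.cb] - self.pos[self.ca]
            dist = np.hypot(dc[:, 0], dc[:, 1])
            if dist.min() <= 0:
                bad = int(self.node_ids[self.ca[int(dist.argmin())]])
                raise SolverDivergence(f"coincident contactor centres (node id {bad})")
            gap = dist - (self.radius[self.ca] + self.radius[self.cb])
            RN = self.penalty * np.maximum(0.0, -gap)
            uc = dc / dist[:, None]
            fx = -RN * uc[:, 0]
            fy = -RN * uc[:, 1]
            F[:, 0] += np.bincount(self.ca, weights=fx, minlength=self.n)
            F[:, 0] -= np.bincount(self.cb, weights=fx, minlength=self.n)
            F[:, 1] += np.bincount(self.ca, weights=fy, minlength=self.n)
            F[:, 1] -= np.bincount(self.cb, weights=fy, minlength=self.n)

        if not np.isfinite(F).all():
            bad = int(self.node_ids[int(np.argwhere(~np.isfinite(F))[0][0])])
            raise SolverDivergence(f"non-finite force on node id {bad}")
        return F, F_tensile, T, gap, RN


def tensile_force(g: float, interaction) -> float:
    """Magnitude of the attractive rubber-band force at gap ``g`` (nN).

    Zero in the slack regime ``g <= (1 - eps0) g0``; otherwise
    ``K ((g - g0)/g0 + eps0)``.  The creation threshold g_v is not
    re-applied here (build-time only).
    """
    if g < 0:
        raise ValueError("gap must be non-negative")
    if interaction.g0 <= 0:
        raise ValueError("g0 must be positive")
    stretch = g - (1.0 - interaction.epsilon0) * interaction.g0
    return float(interaction.K * stretch / interaction.g0) if stretch > 0 else 0.0


def tensile_force_array(g: np.ndarray, K: np.ndarray, g0: np.ndarray, eps0: np.ndarray) -> np.ndarray:
    stretch = g - (1.0 - eps0) * g0
    return np.where(stretch > 0, K * stretch / g0, 0.0)


def contact_force(
    center_distance: float, radii: tuple[float, float], penalty: float, enabled: bool = True
) -> float:
    """Normal reaction of the penalty-regularized frictionless contact (nN).

    Surface gap ``g = distance - (r_a + r_b)``; separation gives RN = 0,
    overlap gives ``RN = penalty * (-g)``.  Disabled entirely in the MT-
    scenario (``enabled=False``).
    """
    if not enabled:
        return 0.0
    ra, rb = radii
    if not (ra > 0 and rb > 0):
        raise ValueError("radii must be positive")
    if center_distance == 0:
        raise ValueError("coincident contactor centres")
    gap = center_distance - (ra + rb)
    return float(penalty * -gap) if gap < 0 else 0.0


def _export_state(sys_: _System, vel: np.ndarray, frl: list[float], nstep: int) -> ModelState:
    F, F_tensile, T, gap, RN = sys_.forces()
    free = ~sys_.fixed
    residual = float(np.hypot(F[free, 0], F[free, 1]).max()) if free.any() else 0.0
    contacts = []
    max_pen = 0.0
    comp_res = 0.0
    if len(gap):
        engaged = RN > 0
        max_pen = float(np.maximum(0.0, -gap).max())
        if engaged.any():
            comp_res = float((np.abs(np.minimum(gap, 0.0)) * RN).max())
        for k in np.flatnonzero(engaged):
            contacts.append(
                ContactPair(
                    node_a=int(sys_.node_ids[sys_.ca[k]]),
                    node_b=int(sys_.node_ids[sys_.cb[k]]),
                    gap=float(gap[k]),
                    normal_force=float(RN[k]),
                )
            )
    # FA reactions are the net *tensile* interaction force on each anchor:
    # the pulling force the contractile network transmits to the substrate.
    fa_reactions = {
        int(sys_.node_ids[k]): F_tensile[k].copy() for k in np.flatnonzero(sys_.fixed & sys_.vinculin)
    }
    return ModelState(
        positions=sys_.pos.copy(),
        velocities=vel.copy(),
        tensions=T.copy(),
        contacts=contacts,
        fa_reactions=fa_reactions,
        free_run_length=np.asarray(frl),
        step=nstep,
        residual=residual,
        converged=residual <= sys_.config.equilibrium_tol,
        max_penetration=max_pen,
        complementarity_residual=comp_res,
    )


def _run(sys_: _System, vel: np.ndarray, frl: list[float], start: int, nsteps: int) -> ModelState:
    cfg = sys_.config
    free = ~sys_.fixed
    n_free = int(free.sum())
    grow = 0
    prev_frl = np.inf
    for s in range(start, start + nsteps):
        if cfg.contact_enabled and (s % cfg.contact_refresh == 0):
            sys_.refresh_contacts()
        F, _, _, _, _ = sys_.forces()
        vel = cfg.damping * (vel + (F / sys_.mass[:, None]) * cfg.dt)
        vel[sys_.fixed] = 0.0
        dx = vel * cfg.dt
        sys_.pos += dx
        step_frl = float(np.hypot(dx[free, 0], dx[free, 1]).mean()) if n_free else 0.0
        frl.append(step_frl)
        if s > 20:
            grow = grow + 1 if step_frl > prev_frl else 0
            if grow >= cfg.divergence_window:
                raise SolverDivergence(
                    f"free run length grew for {grow} consecutive steps "
                    f"(step {s}, free run length {step_frl:.3g} um)"
                )
        prev_frl = step_frl
    return _export_state(sys_, vel, frl, start + nsteps)


def step(model: CellModel, state: ModelState, config: SolverConfig | None = None) -> ModelState:
    """Advance the state by a single solver step (convenience for small systems)."""
    config = config or SolverConfig()
    sys_ = _System(model, config)
    sys_.pos = state.positions.copy()
    if config.contact_enabled:
        sys_.refresh_contacts()
    return _run(sys_, state.velocities.copy(), list(state.free_run_length), state.step, 1)


def initial_state(model: CellModel, config: SolverConfig | None = None) -> ModelState:
    """The build-time state: nodes at rest at their image positions."""
    config = config or SolverConfig()
    sys_ = _System(model, config)
    if config.contact_enabled:
        sys_.refresh_contacts()
    return _export_state(sys_, np.zeros_like(sys_.pos), [], 0)


def relax(model: CellModel, config: SolverConfig | None = None) -> ModelState:
    """Run the configured number of steps from rest and return the final state.

    Convergence is reported (``residual``, ``converged``) but not enforced.
    A warning suggests raising the contact penalty if penetration exceeds
    1% of the node spacing.
    """
    config = config or SolverConfig()
    sys_ = _System(model, config)
    state = _run(sys_, np.zeros_like(sys_.pos), [], 0, config.steps)
    if state.max_penetration > PENETRATION_LIMIT * model.d0:
        warnings.warn(
            f"contact penetration {state.max_penetration:.3g} um exceeds "
            f"{PENETRATION_LIMIT:.0%} of d0={model.d0} um; consider a higher contact penalty",
            stacklevel=2,
        )
    return state


def sum_fa_forces(state: ModelState) -> float:
    """Sum over fixed vinculin nodes of the magnitude of their net reaction (nN)."""
    if not state.fa_reactions:
        return 0.0
    return float(sum(np.hypot(f[0], f[1]) for f in state.fa_reactions.values()))


@dataclasses.dataclass(frozen=True)
class ForceSummary:
    """Aggregate tension/compression bookkeeping of one relaxed state."""

    tension_sum: float  # nN
    compression_sum: float  # nN
    ratio: float  # compression over tension
    mean_tension: float  # nN, over active tensile interactions
    mean_compression: float  # nN, over engaged contacts
    n_tensile_active: int
    n_contacts: int


def tension_compression_summary(state: ModelState) -> ForceSummary:
    active = state.tensions[state.tensions > 0]
    t_sum = float(active.sum())
    rn = np.array([c.normal_force for c in state.contacts])
    c_sum = float(rn.sum()) if len(rn) else 0.0
    return ForceSummary(
        tension_sum=t_sum,
        compression_sum=c_sum,
        ratio=c_sum / t_sum if t_sum > 0 else 0.0,
        mean_tension=float(active.mean()) if len(active) else 0.0,
        mean_compression=float(rn.mean()) if len(rn) else 0.0,
        n_tensile_active=int(len(active)),
        n_contacts=int(len(rn)),
    )


def state_tables(model: CellModel, state: ModelState):
    """Node and interaction snapshots as DataFrames (for CSV export)."""
    import pandas as pd

    nodes = pd.DataFrame(
        {
            "id": [n.id for n in model.nodes],
            "kind": [n.kind for n in model.nodes],
            "x_um": state.positions[:, 0],
            "y_um": state.positions[:, 1],
            "fixed": [n.fixed for n in model.nodes],
        }
    )
    inter = pd.DataFrame(
        {
            "node_a": [it.node_a for it in model.interactions],
            "node_b": [it.node_b for it in model.interactions],
            "K_nN": [it.K for it in model.interactions],
            "tension_nN": state.tensions,
        }
    )
    contacts = pd.DataFrame(
        {
            "node_a": [c.node_a for c in state.contacts],
            "node_b": [c.node_b for c in state.contacts],
            "gap_um": [c.gap for c in state.contacts],
            "RN_nN": [c.normal_force for c in state.contacts],
        }
    )
    return nodes, inter, contacts
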