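"""Inverse-mechanics calibration of the actin-density-to-stiffness coefficient.

The pre-strained network pulls on its vinculin anchors; the harder the
interactions (larger coefficient ``a``), the larger the summed anchor
force.  A parametric sweep over ``a`` produces an almost linear relation
``F = alpha * a - beta`` which is fitted by ordinary least squares and
inverted at the experimentally estimated FA force sum to solve for ``a``.
With ``a`` set, tension summaries follow: the mean inter-tension, its
resolution-independent cross-linear form ``T / d0``, and the per-label
stiffness/cross-linear-tension table.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mechanics import ModelState, SolverConfig, SolverDivergence, relax, sum_fa_forces
from .network import CellModel

DEFAULT_SWEEP = (1.0, 4.0, 8.0, 15.0)  # nN, spans the standard 1-15 range


class CalibrationError(RuntimeError):
    pass


@dataclasses.dataclass
class CalibrationCurve:
    """Sweep samples (a, sum of FA forces) and the fitted line F = alpha a - beta."""

    a_values: np.ndarray  # nN
    fa_sums: np.ndarray  # nN
    alpha: float | None = None  # nN per unit a
    beta: float | None = None  # nN, stored with the conventional positive sign
    r2: float | None = None
    a_solved: float | None = None  # nN

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.fa_sums = np.asarray(self.fa_sums, dtype=float)
        if self.a_values.shape != self.fa_sums.shape or len(self.a_values) < 2:
            raise ValueError("need at least 2 matching (a, fa_sum) samples")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a_values": self.a_values.tolist(),
                    "fa_sums": self.fa_sums.tolist(),
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "r2": self.r2,
                    "a_solved": self.a_solved,
                }
            )
        )


def sweep(
    model_builder: Callable[[float], CellModel],
    a_values: Sequence[float] = DEFAULT_SWEEP,
    config: SolverConfig | None = None,
) -> CalibrationCurve:
    """Rebuild and relax the model at each ``a`` and record the FA force sums."""
    if len(a_values) < 2:
        raise ValueError("a sweep needs at least 2 points")
    sums = []
    for a in a_values:
        try:
            state = relax(model_builder(float(a)), config)
        except SolverDivergence as exc:
            raise CalibrationError(f"relaxation diverged at a = {a}: {exc}") from exc
        sums.append(sum_fa_forces(state))
    return CalibrationCurve(np.asarray(a_values, dtype=float), np.asarray(sums))


def fit_linear(curve: CalibrationCurve) -> tuple[float, float, float]:
    """OLS fit of fa_sum on a; returns (alpha, beta, r2) and stores them on the curve.

    ``beta`` follows the convention ``F = alpha * a - beta`` (the positive
    constant).  Warns when the fit quality drops below R^2 = 0.9.
    """
    if np.ptp(curve.a_values) == 0:
        raise CalibrationError("zero variance in the swept a values")
    res = stats.linregress(curve.a_values, curve.fa_sums)
    alpha = float(res.slope)
    beta = float(-res.intercept)
    r2 = float(res.rvalue**2)
    if np.ptp(curve.fa_sums) == 0:
        r2 = 0.0
    if r2 < 0.9:
        warnings.warn(f"calibration fit R^2 = {r2:.3f} < 0.9", stacklevel=2)
    curve.alpha, curve.beta, curve.r2 = alpha, beta, r2
    return alpha, beta, r2


def solve_a(curve: CalibrationCurve, F_measured: float) -> float:
    """Invert the fitted line at the measured FA force sum: a = (F + beta) / alpha.

    Warns when the solution falls outside the swept range (extrapolation).
    """
    if curve.alpha is None:
        fit_linear(curve)
    if curve.alpha is None or curve.alpha <= 0:
        raise CalibrationError("non-positive calibration slope: model is not contractile in a")
    a = (F_measured + curve.beta) / curve.alpha
    lo, hi = curve.a_values.min(), curve.a_values.max()
    if not lo <= a <= hi:
        warnings.warn(f"a_solved = {a:.3g} lies outside the swept range [{lo}, {hi}]", stacklevel=2)
    curve.a_solved = float(a)
    return curve.a_solved


def cross_linear_tension(tension: float, d0: float) -> float:
    """Tension per unit transverse length (nN/um): the resolution-independent density."""
    if not d0 > 0:
        raise ValueError("d0 must be positive")
    return tension / d0


@dataclasses.dataclass
class TensionSummary:
    """Tension quantities of one calibrated, relaxed model.

    ``T_cl_max = a * eps0 / d0`` is the cross-linear tension at maximal
    actin density (gray value 1), the single factor converting image gray
    profiles into tensions.  ``rigidity_cl_max = a / d0`` is the
    cross-linear rigidity of the strongest label, also reported because it
    differs from ``T_cl_max`` only by the pre-strain factor.
    """

    T_mean: float  # nN, mean tension over active interactions
    T_mean_cl: float  # nN/um
    T_cl_max: float  # nN/um
    rigidity_cl_max: float  # nN/um per unit strain
    per_label: pd.DataFrame
    d0: float
    a: float
    epsilon0: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "T_mean_nN": self.T_mean,
                    "T_mean_cl_nN_per_um": self.T_mean_cl,
                    "T_cl_max_nN_per_um": self.T_cl_max,
                    "rigidity_cl_max_nN_per_um": self.rigidity_cl_max,
                    "d0_um": self.d0,
                    "a_nN": self.a,
                    "epsilon0": self.epsilon0,
                    "per_label": self.per_label.to_dict(orient="records"),
                }
            )
        )


def per_label_table(a: float, epsilon0: float, d0: float) -> pd.DataFrame:
    """Per-label stiffness and cross-linear tension ranges.

    ``K_i = a * 0.1 * i``; the cross-linear tension of label i spans
    ``a c eps0 / d0`` for c over the bin ``]0.1(i-1); 0.1 i]``.
    """
    i = np.arange(1, 11)
    return pd.DataFrame(
        {
            "label": i,
            "c_max": 0.1 * i,
            "K_nN": a * 0.1 * i,
            "T_cl_min_nN_per_um": a * 0.1 * (i - 1) * epsilon0 / d0,
            "T_cl_max_nN_per_um": a * 0.1 * i * epsilon0 / d0,
        }
    )


def summarize(state: ModelState, model: CellModel) -> TensionSummary:
    """Tension summary of a relaxed state at the solved coefficient.

    ``T_mean`` averages over taut interactions only (slack members carry no
    force and are excluded).
    """
    if model.a is None:
        raise CalibrationError("model.a is unset: calibrate before summarizing")
    active = state.tensions[state.tensions > 0]
    if len(active) == 0:
        raise CalibrationError("no active tensile interactions")
    eps0 = model.interactions[0].epsilon0 if model.interactions else 0.2
    t_mean = float(active.mean())
    return TensionSummary(
        T_mean=t_mean,
        T_mean_cl=cross_linear_tension(t_mean, model.d0),
        T_cl_max=model.a * eps0 / model.d0,
        rigidity_cl_max=model.a / model.d0,
        per_label=per_label_table(model.a, eps0, model.d0),
        d0=model.d0,
        a=model.a,
        epsilon0=eps0,
    )
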