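"""Inverse recovery of regional stiffness parameters from FRF magnitudes.

Given measured (noisy) response-magnitude data at one or more DOFs, selected
spring constants are estimated by bounded nonlinear least squares:

    minimize  sum_cells (|X_model(k)| - |X_measured|)^2
              + w * sum_params (k - k_init)^2        (optional Tikhonov)

over the free stiffness parameters, with mass and damping fixed at their
baseline values.  Optimization starts from the healthy reference values and
is constrained to a physically plausible box around the baseline
([0.5x, 2.0x] by default).  The trust-region reflective algorithm of
``scipy.optimize.least_squares`` performs the minimization; its accepted
steps decrease the objective monotonically.

By default only the chest-wall (DOF 0) magnitude enters the objective,
emulating a purely external measurement; any DOF subset can be observed.
Residuals are taken on raw magnitude; a log-magnitude mode is available for
data with heavy dynamic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .frf import ExcitationSpec, FrequencyGrid, solve_frf
from .model import ThoraxModel

__all__ = ["FitSpec", "FitResult", "GridAlignmentError", "objective", "fit_stiffness"]


class GridAlignmentError(ValueError):
    """Measured data shape does not match the model grid / observed DOFs."""


@dataclass(frozen=True)
class FitSpec:
    """Configuration of the stiffness-estimation problem.

    Parameters
    ----------
    free_parameters : tuple of str
        Spring names to estimate; default the two chest–lung couplings of
        the right lung.
    bounds_factor : (float, float)
        Box constraints as multiples of the baseline (healthy reference)
        values in the model handed to :func:`fit_stiffness`.
    observed_dofs : tuple of int
        DOFs whose magnitudes enter the objective (default chest wall only).
    regularization_weight : float
        Tikhonov weight w; 0 disables the penalty.
    residual_scale : str
        ``"linear"`` (default) or ``"log"`` residuals.
    n_starts : int
        Number of optimizer starts.  The first start is always the healthy
        reference (or ``initial_values``); additional starts are spread
        deterministically over the bounds box.  Chest-wall-only magnitude
        objectives are multimodal when the true stiffness lies far from the
        reference, so a handful of extra starts makes recovery global.
    """

    free_parameters: tuple[str, ...] = ("k01", "k02")
    bounds_factor: tuple[float, float] = (0.5, 2.0)
    initial_values: tuple[float, ...] | None = None
    observed_dofs: tuple[int, ...] = (0,)
    max_iterations: int = 500
    tolerance: float = 1e-10
    step_tolerance: float = 1e-8
    regularization_weight: float = 0.0
    residual_scale: str = "linear"
    n_starts: int = 5

    def __post_init__(self) -> None:
        if len(self.free_parameters) == 0:
            raise ValueError("at least one free parameter is required")
        lo, hi = self.bounds_factor
        if not (0 < lo < 1 <= hi):
            raise ValueError("bounds_factor must satisfy 0 < low < 1 <= high")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if self.residual_scale not in ("linear", "log"):
            raise ValueError("residual_scale must be 'linear' or 'log'")
        if len(self.observed_dofs) == 0:
            raise ValueError("at least one observed DOF is required")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def resolve_initial(self, model: ThoraxModel) -> np.ndarray:
        """Initial values: explicit if given, else the model's (healthy) values."""
        if self.initial_values is not None:
            init = np.asarray(self.initial_values, dtype=float)
            if init.shape != (len(self.free_parameters),):
                raise ValueError("initial_values must match free_parameters")
            return init
        return np.array(
            [model.spring(p).stiffness for p in self.free_parameters]
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a stiffness fit."""

    estimates: dict[str, float]
    objective: float
    initial_objective: float
    converged: bool
    n_iterations: int
    residuals: np.ndarray
    message: str = ""
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "objective": self.objective,
            "initial_objective": self.initial_objective,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "message": self.message,
            "warnings": list(self.warnings),
        }


def _model_with(values: np.ndarray, model: ThoraxModel, params) -> ThoraxModel:
    out = model
    for p, v in zip(params, values):
        out = out.with_spring(p, float(v))
    return out


def _data_residuals(
    values: np.ndarray,
    measured: np.ndarray,
    model: ThoraxModel,
    spec: FitSpec,
    grid: FrequencyGrid,
    excitation: ExcitationSpec,
) -> np.ndarray:
    pred = solve_frf(
        _model_with(values, model, spec.free_parameters), grid, excitation
    ).magnitude[list(spec.observed_dofs)]
    if spec.residual_scale == "log":
        return (np.log(pred) - np.log(measured)).ravel()
    return (pred - measured).ravel()


def _check_measured(measured, spec: FitSpec, grid: FrequencyGrid) -> np.ndarray:
    measured = np.asarray(measured, dtype=float)
    expected = (len(spec.observed_dofs), len(grid))
    if measured.ndim == 1 and len(spec.observed_dofs) == 1:
        measured = measured[None, :]
    if measured.shape != expected:
        raise GridAlignmentError(
            f"measured magnitudes have shape {measured.shape}; expected "
            f"{expected} for observed DOFs {spec.observed_dofs} on this grid"
        )
    if measured.size < len(spec.free_parameters):
        raise ValueError("fewer observed cells than free parameters")
    return measured


def objective(
    candidate_values,
    measured_magnitudes,
    model: ThoraxModel,
    spec: FitSpec,
    grid: FrequencyGrid,
    excitation: ExcitationSpec = ExcitationSpec(),
) -> float:
    """Sum of squared magnitude residuals, plus the optional Tikhonov term.

    The Tikhonov penalty is ``w * sum((theta - theta_init)^2)`` with
    ``theta_init`` the fit's initial (healthy reference) values.
    """
    values = np.asarray(candidate_values, dtype=float)
    measured = _check_measured(measured_magnitudes, spec, grid)
    res = _data_residuals(values, measured, model, spec, grid, excitation)
    total = float(res @ res)
    if spec.regularization_weight > 0:
        dev = values - spec.resolve_initial(model)
        total += spec.regularization_weight * float(dev @ dev)
    return total


def fit_stiffness(
    measured_magnitudes,
    model: ThoraxModel,
    spec: FitSpec,
    grid: FrequencyGrid,
    excitation: ExcitationSpec = ExcitationSpec(),
) -> FitResult:
    """Estimate the free stiffness parameters by bounded least squares.

    Starts from ``spec.initial_values`` (defaulting to the healthy values in
    ``model``) within ``bounds_factor`` times those values.  A parameter
    whose sensitivity is numerically zero over the observed cells is
    reported in ``FitResult.warnings`` (it cannot be identified from the
    chosen observations).

    Returns the best iterate even when the iteration cap is reached; the
    ``converged`` flag distinguishes the two outcomes.
    """
    measured = _check_measured(measured_magnitudes, spec, grid)
    init = spec.resolve_initial(model)
    baseline = np.array([model.spring(p).stiffness for p in spec.free_parameters])
    lo = spec.bounds_factor[0] * baseline
    hi = spec.bounds_factor[1] * baseline
    if np.any(init < lo) or np.any(init > hi):
        raise ValueError("initial values fall outside the bounds box")

    sqrt_w = np.sqrt(spec.regularization_weight)

    def residual_vector(values: np.ndarray) -> np.ndarray:
        res = _data_residuals(values, measured, model, spec, grid, excitation)
        if sqrt_w > 0:
            res = np.concatenate([res, sqrt_w * (values - init)])
        return res

    fit_warnings: list[str] = []
    # flag parameters with no leverage on the observed cells
    for j, p in enumerate(spec.free_parameters):
        step = np.zeros_like(init)
        step[j] = 1e-6 * max(abs(init[j]), 1.0)
        d = _data_residuals(init + step, measured, model, spec, grid, excitation)
        b = _data_residuals(init, measured, model, spec, grid, excitation)
        if np.max(np.abs(d - b)) == 0.0:
            msg = (
                f"parameter {p!r} has zero sensitivity over the observed "
                "cells and cannot be identified"
            )
            fit_warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    r0 = residual_vector(init)
    initial_objective = float(r0 @ r0)

    best = None
    total_nfev = 0
    for start in _start_points(init, lo, hi, spec.n_starts):
        sol = least_squares(
            residual_vector,
            start,
            bounds=(lo, hi),
            method="trf",
            ftol=spec.tolerance,
            xtol=spec.step_tolerance,
            gtol=1e-12,
            max_nfev=spec.max_iterations * (len(init) + 1),
        )
        total_nfev += int(sol.nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    final = float(2 * best.cost)  # least_squares cost = 0.5 * sum(res^2)
    converged = bool(best.success) and best.status != 0
    x = best.x
    if final > initial_objective:
        # minimizer contract: never return an iterate worse than the start
        x, final = init, initial_objective

    return FitResult(
        estimates={p: float(v) for p, v in zip(spec.free_parameters, x)},
        objective=final,
        initial_objective=initial_objective,
        converged=converged,
        n_iterations=total_nfev,
        residuals=best.fun,
        message=str(best.message),
        warnings=tuple(fit_warnings),
    )


def _start_points(
    init: np.ndarray, lo: np.ndarray, hi: np.ndarray, n_starts: int
) -> list[np.ndarray]:
    """Healthy init plus deterministic starts spread over the bounds box.

    Extra starts are the box corners pulled 20 % toward the centre (all
    2^p of them for p <= 3 parameters), then low-discrepancy interior
    points if still more are requested.
    """
    starts = [init]
    if n_starts == 1:
        return starts
    p = len(init)
    candidates: list[np.ndarray] = []
    if p <= 3:
        from itertools import product

        for corner in product((0.2, 0.8), repeat=p):
            candidates.append(lo + np.array(corner) * (hi - lo))
    if len(candidates) < n_starts - 1:
        from scipy.stats import qmc

        sampler = qmc.Sobol(d=p, scramble=False)
        extra = sampler.random(n_starts)  # deterministic sequence
        for u in extra:
            candidates.append(lo + (0.1 + 0.8 * u) * (hi - lo))
    starts.extend(candidates[: n_starts - 1])
    return starts
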