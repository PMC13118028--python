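"""Local identifiability of stiffness parameters from FRF magnitudes.

Whether two regional stiffness parameters can be estimated jointly from
externally measured responses is a question of local structural
identifiability.  It is answered here in two steps:

1. **Relative sensitivities.**  For each spring parameter k_j, each output
   DOF i and each grid frequency f, the dimensionless log-log sensitivity

       s_ij(f) = d ln|X_i(f)| / d ln k_j

   measures the percent change in response amplitude per percent change in
   stiffness.  It is computed by a forward finite difference with a 1 %
   multiplicative step by default, and is invariant to the excitation
   amplitude (an overall scale cancels in the log difference).

2. **Fisher information.**  Sensitivities across all outputs and
   frequencies are stacked into a Jacobian J (rows = (DOF, frequency)
   cells, columns = parameters).  The Fisher-information matrix F = JᵀJ is
   symmetric positive semidefinite; strictly positive eigenvalues mean the
   parameters are locally identifiable, the condition number
   κ(F) = λmax/λmin measures how well-posed joint estimation is, and the
   normalized inner products of Jacobian columns give the correlation
   between sensitivity directions.

An ``absolute`` sensitivity mode (d|X_i|/dk_j, unnormalized) is available
for studying how the eigenvalue scale depends on normalization; the
relative mode is the default and the one whose conditioning is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frf import ExcitationSpec, FrequencyGrid, solve_frf
from .model import ThoraxModel

__all__ = [
    "SensitivityRecord",
    "FisherSummary",
    "UndefinedSensitivityError",
    "relative_sensitivity",
    "sensitivity_table",
    "fisher_information",
]


class UndefinedSensitivityError(ArithmeticError):
    """Sensitivity undefined because a baseline magnitude is zero."""


@dataclass(frozen=True)
class SensitivityRecord:
    """Log-log sensitivity of one DOF's magnitude to one spring, over a grid.

    ``values`` has shape (n_frequencies,); one record per (parameter, DOF).
    """

    parameter: str
    dof: int
    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.frequencies.shape:
            raise ValueError("values must align with frequencies")
        if not np.all(np.isfinite(self.values)):
            raise UndefinedSensitivityError(
                f"non-finite sensitivity for {self.parameter} at DOF {self.dof}"
            )


@dataclass(frozen=True)
class FisherSummary:
    """Stacked Jacobian, Fisher matrix and its spectral diagnostics.

    ``condition_number`` is ``inf`` when the smallest eigenvalue is
    (numerically) zero, i.e. the parameter set is not locally identifiable.
    ``correlation`` holds the normalized inner product of each Jacobian
    column pair, keyed by parameter-name tuples.
    """

    parameters: tuple[str, ...]
    jacobian: np.ndarray
    fim: np.ndarray
    eigenvalues: np.ndarray
    condition_number: float
    correlation: dict[tuple[str, str], float]

    @property
    def identifiable(self) -> bool:
        """True when every eigenvalue is strictly positive (full-rank Jacobian)."""
        return bool(self.eigenvalues[-1] > 0)


def relative_sensitivity(
    model: ThoraxModel,
    parameter: str,
    grid: FrequencyGrid,
    step_fraction: float = 0.01,
    excitation: ExcitationSpec = ExcitationSpec(),
    scheme: str = "forward",
    mode: str = "relative",
) -> list[SensitivityRecord]:
    """Finite-difference sensitivity of all DOF magnitudes to one spring.

    Parameters
    ----------
    parameter : str
        Spring name (``k01``, ``k02``, ...).
    step_fraction : float
        Multiplicative perturbation step delta; the default 0.01 perturbs
        the stiffness by 1 %.
    scheme : str
        ``"forward"`` (default): [ln|X|(k(1+d)) - ln|X|(k)] / ln(1+d);
        ``"central"``: [ln|X|(k(1+d)) - ln|X|(k(1-d))] / [ln(1+d)-ln(1-d)].
    mode : str
        ``"relative"`` (log-log, default) or ``"absolute"`` (d|X|/dk).

    Returns
    -------
    list of SensitivityRecord, one per DOF.
    """
    if step_fraction <= 0:
        raise ValueError("step_fraction must be > 0")
    if scheme not in ("forward", "central"):
        raise ValueError("scheme must be 'forward' or 'central'")
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    k0 = model.spring(parameter).stiffness
    if k0 <= 0:
        raise ValueError(f"cannot perturb zero-stiffness spring {parameter!r}")

    base = solve_frf(model, grid, excitation).magnitude
    if np.any(base <= 0):
        raise UndefinedSensitivityError(
            "baseline magnitude is zero at some (DOF, frequency) cell"
        )
    up = solve_frf(
        model.with_spring(parameter, k0 * (1 + step_fraction)), grid, excitation
    ).magnitude
    if scheme == "forward":
        lo, dlnk = base, np.log1p(step_fraction)
        dk = k0 * step_fraction
    else:
        lo = solve_frf(
            model.with_spring(parameter, k0 * (1 - step_fraction)), grid, excitation
        ).magnitude
        dlnk = np.log1p(step_fraction) - np.log1p(-step_fraction)
        dk = 2 * k0 * step_fraction
    if mode == "relative":
        values = (np.log(up) - np.log(lo)) / dlnk
    else:
        values = (up - lo) / dk

    return [
        SensitivityRecord(
            parameter=parameter,
            dof=i,
            frequencies=grid.frequencies,
            values=values[i],
        )
        for i in range(model.n_dof)
    ]


def sensitivity_table(
    records: list[SensitivityRecord], dof_labels=None
) -> pd.DataFrame:
    """Long-format table: parameter, dof_label, frequency_hz, value."""
    rows = []
    for rec in records:
        label = dof_labels[rec.dof] if dof_labels else f"dof{rec.dof}"
        rows.append(
            pd.DataFrame(
                {
                    "parameter": rec.parameter,
                    "dof_label": label,
                    "frequency_hz": rec.frequencies,
                    "value": rec.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fisher_information(
    record_sets: dict[str, list[SensitivityRecord]]
) -> FisherSummary:
    """Fisher-information summary from per-parameter sensitivity records.

    Each parameter's records are stacked frequency-major within DOF, DOFs
    in index order, into one Jacobian column; cells must match across
    parameters.  F = JᵀJ; eigenvalues are returned in descending order.

    Raises
    ------
    ValueError
        If the parameters were evaluated on mismatched (DOF, frequency)
        cells, or fewer than two parameters are supplied.
    """
    params = tuple(record_sets)
    if len(params) < 2:
        raise ValueError("need sensitivities for at least two parameters")

    columns = []
    ref_cells = None
    for p in params:
        recs = sorted(record_sets[p], key=lambda r: r.dof)
        cells = tuple((r.dof, len(r.frequencies)) for r in recs)
        freqs = np.concatenate([r.frequencies for r in recs])
        if ref_cells is None:
            ref_cells, ref_freqs = cells, freqs
        elif cells != ref_cells or not np.array_equal(freqs, ref_freqs):
            raise ValueError(
                f"parameter {p!r} evaluated on different (DOF, frequency) "
                "cells than the first parameter"
            )
        columns.append(np.concatenate([r.values for r in recs]))

    jac = np.column_stack(columns)
    fim = jac.T @ jac
    eigvals = np.linalg.eigvalsh(fim)[::-1]
    lam_min = eigvals[-1]
    # numerically-zero smallest eigenvalue => non-identifiable, kappa = inf
    tol = max(jac.shape[0], jac.shape[1]) * np.finfo(float).eps * max(eigvals[0], 1.0)
    condition = float("inf") if lam_min <= tol else float(eigvals[0] / lam_min)

    norms = np.linalg.norm(jac, axis=0)
    correlation = {}
    for a in range(len(params)):
        for b in range(a + 1, len(params)):
            denom = norms[a] * norms[b]
            correlation[(params[a], params[b])] = (
                float(jac[:, a] @ jac[:, b] / denom) if denom > 0 else float("nan")
            )

    return FisherSummary(
        parameters=params,
        jacobian=jac,
        fim=fim,
        eigenvalues=np.maximum(eigvals, 0.0),
        condition_number=condition,
        correlation=correlation,
    )
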