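"""Steady-state frequency response of the lung–thorax model.

The model obeys the linear second-order equations of motion

    M x''(t) + C x'(t) + K x(t) = f(t),

with harmonic forcing f(t) = F0 e^{jωt} e_d applied at a single driven DOF
(the chest wall by default).  Seeking a steady-state response
x(t) = X(ω) e^{jωt} reduces the problem to the complex linear system

    (-ω² M + j ω C + K) X(ω) = F,

solved directly at each grid frequency.  The matrix (-ω²M + jωC + K) is the
dynamic stiffness matrix; its inverse is the full frequency response
function (FRF) matrix H(ω), symmetric at every ω because M, C and K are.

A brute-force time-domain integrator of the same equations is provided as an
independent verification oracle: it integrates the real ODE with cosine
forcing from rest until transients decay and reports last-cycle amplitudes,
which must agree with the frequency-domain magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ThoraxModel, assemble_matrices

__all__ = [
    "FrequencyGrid",
    "ExcitationSpec",
    "FRFResult",
    "TimeDomainTrace",
    "SingularFrequencyError",
    "OracleConvergenceError",
    "default_grid",
    "solve_frf",
    "transfer_functions",
    "time_domain_oracle",
]


class SingularFrequencyError(ArithmeticError):
    """Dynamic stiffness matrix singular at a grid frequency (exact undamped resonance)."""


class OracleConvergenceError(RuntimeError):
    """Time-domain transients did not decay within the requested number of cycles."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive excitation frequencies (Hz)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def angular(self) -> np.ndarray:
        """Angular frequencies ω = 2πf (rad/s)."""
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)


def default_grid(
    f_min: float = 5.0, f_max: float = 150.0, n_points: int = 300
) -> FrequencyGrid:
    """Linear grid of 300 points over 5–150 Hz (inclusive) by default."""
    return FrequencyGrid(np.linspace(f_min, f_max, n_points))


@dataclass(frozen=True)
class ExcitationSpec:
    """Harmonic point force: amplitude F0 applied at ``driven_dof``."""

    amplitude: float = 1.0
    driven_dof: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("excitation amplitude must be > 0")
        if self.driven_dof < 0:
            raise ValueError("driven_dof must be a valid DOF index")


@dataclass(frozen=True)
class FRFResult:
    """Complex steady-state responses X_i(ω) on a frequency grid.

    ``response`` has shape (n_dof, n_frequencies).  ``magnitude`` and
    ``phase`` are the modulus and argument of ``response``; noise injection
    replaces ``magnitude`` only, so the two can legitimately diverge after
    corruption.
    """

    grid: FrequencyGrid
    response: np.ndarray
    excitation: ExcitationSpec
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        resp = np.asarray(self.response)
        if resp.ndim != 2 or resp.shape[1] != len(self.grid):
            raise ValueError(
                "response must be (n_dof, n_frequencies) aligned with the grid"
            )
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", np.abs(resp))
        else:
            mag = np.asarray(self.magnitude, dtype=float)
            if mag.shape != resp.shape:
                raise ValueError("magnitude shape must match response shape")

    @property
    def phase(self) -> np.ndarray:
        """Phase in radians, in (−π, π]."""
        return np.angle(self.response)

    @property
    def n_dof(self) -> int:
        return self.response.shape[0]

    def with_magnitude(self, magnitude: np.ndarray) -> "FRFResult":
        return FRFResult(
            grid=self.grid,
            response=self.response,
            excitation=self.excitation,
            magnitude=magnitude,
        )

    def to_frame(self, dof_labels=None) -> pd.DataFrame:
        """Long-format table: frequency_hz, dof_label, magnitude, phase_rad, real, imag."""
        n_dof, n_f = self.response.shape
        if dof_labels is None:
            dof_labels = [f"dof{i}" for i in range(n_dof)]
        rows = []
        for i in range(n_dof):
            rows.append(
                pd.DataFrame(
                    {
                        "frequency_hz": self.grid.frequencies,
                        "dof_label": dof_labels[i],
                        "magnitude": self.magnitude[i],
                        "phase_rad": self.phase[i],
                        "real": self.response[i].real,
                        "imag": self.response[i].imag,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class TimeDomainTrace:
    """Sampled displacement trajectories x_i(t) from the time-domain oracle."""

    times: np.ndarray
    displacements: np.ndarray  # (n_dof, n_times)

    def __post_init__(self) -> None:
        if self.displacements.shape[1] != self.times.shape[0]:
            raise ValueError("displacements must align with times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# Frequency-domain solve
# ---------------------------------------------------------------------------

def solve_frf(
    model: ThoraxModel,
    grid: FrequencyGrid,
    excitation: ExcitationSpec = ExcitationSpec(),
) -> FRFResult:
    """Solve (-ω²M + jωC + K) X = F at every grid frequency.

    The force vector is zero except for ``excitation.amplitude`` at the
    driven DOF.  Direct dense solves are used (the system is tiny).

    Raises
    ------
    SingularFrequencyError
        If the dynamic stiffness matrix is singular at some frequency
        (an exactly-hit undamped resonance).
    """
    M, C, K = assemble_matrices(model)
    n = model.n_dof
    if not (0 <= excitation.driven_dof < n):
        raise ValueError(f"driven_dof {excitation.driven_dof} out of range")
    force = np.zeros(n, dtype=complex)
    force[excitation.driven_dof] = excitation.amplitude

    omega = grid.angular[:, None, None]
    dyn = -(omega**2) * M + 1j * omega * C + K  # (n_f, n, n)
    rhs = np.broadcast_to(force[:, None], (len(grid), n, 1))
    try:
        x = np.linalg.solve(dyn, rhs)[..., 0]
    except np.linalg.LinAlgError:
        x = None
    if x is None or not np.all(np.isfinite(x)):
        # locate the offending frequency for the error message
        for idx in range(len(grid)):
            try:
                xi = np.linalg.solve(dyn[idx], force)
            except np.linalg.LinAlgError:
                xi = np.full(n, np.nan)
            if not np.all(np.isfinite(xi)):
                raise SingularFrequencyError(
                    "dynamic stiffness singular at "
                    f"{grid.frequencies[idx]:.6g} Hz"
                )
        raise SingularFrequencyError("singular dynamic stiffness on the grid")
    return FRFResult(grid=grid, response=x.T, excitation=excitation)


def transfer_functions(result: FRFResult) -> np.ndarray:
    """Per-DOF transfer functions H_i(ω) = X_i(ω) / F0.

    By linearity H is invariant under rescaling of the excitation amplitude.
    """
    return result.response / result.excitation.amplitude


# ---------------------------------------------------------------------------
# Time-domain oracle
# ---------------------------------------------------------------------------

def time_domain_oracle(
    model: ThoraxModel,
    frequency: float,
    excitation: ExcitationSpec = ExcitationSpec(),
    n_cycles: int | None = None,
    samples_per_cycle: int = 64,
    decay_tol: float = 2e-3,
    return_trace: bool = False,
):
    """Steady-state amplitude per DOF by brute-force ODE integration.

    Integrates M x'' + C x' + K x = F0 cos(ωt) e_d from rest over
    ``n_cycles`` forcing cycles and reports the amplitude (half
    peak-to-peak) of each DOF over the final cycle.  Requires damping so
    that the homogeneous transient decays.

    If ``n_cycles`` is None it is chosen from the slowest modal decay rate
    (largest real part of the first-order state-matrix eigenvalues) so that
    the free transient is attenuated below 1e-5 before the measured cycle.

    Raises
    ------
    OracleConvergenceError
        If the last two cycles' amplitudes differ by more than ``decay_tol``
        relatively (transient not yet decayed).
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    M, C, K = assemble_matrices(model)
    if not np.any(np.diag(C) > 0):
        raise ValueError("time-domain oracle requires at least one damper > 0")
    n = model.n_dof
    Minv = np.linalg.inv(M)
    force = np.zeros(n)
    force[excitation.driven_dof] = excitation.amplitude
    omega = 2.0 * np.pi * frequency

    if n_cycles is None:
        state = np.block(
            [[np.zeros((n, n)), np.eye(n)], [-Minv @ K, -Minv @ C]]
        )
        slowest = -np.max(np.linalg.eigvals(state).real)
        if slowest <= 0:
            raise OracleConvergenceError(
                "undamped/unstable mode: transient will not decay"
            )
        t_decay = np.log(1e5) / slowest
        n_cycles = max(10, int(np.ceil(t_decay * frequency)) + 2)

    def rhs(t, y):
        x, v = y[:n], y[n:]
        a = Minv @ (force * np.cos(omega * t) - C @ v - K @ x)
        return np.concatenate([v, a])

    period = 1.0 / frequency
    t_end = n_cycles * period
    # sample the last two cycles densely for amplitude extraction
    t_eval = np.linspace(
        t_end - 2 * period, t_end, 2 * samples_per_cycle + 1
    )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.zeros(2 * n),
        t_eval=t_eval,
        method="RK45",
        rtol=1e-9,
        atol=1e-12,
        max_step=period / 20,
    )
    if not sol.success:
        raise OracleConvergenceError(f"ODE integration failed: {sol.message}")
    disp = sol.y[:n]
    half = samples_per_cycle
    prev = 0.5 * (disp[:, : half + 1].max(axis=1) - disp[:, : half + 1].min(axis=1))
    last = 0.5 * (disp[:, half:].max(axis=1) - disp[:, half:].min(axis=1))
    scale = np.maximum(np.abs(last), np.finfo(float).tiny)
    if np.any(np.abs(last - prev) / scale > decay_tol):
        raise OracleConvergenceError(
            "transient not decayed: last two cycle amplitudes differ by "
            f"{np.max(np.abs(last - prev) / scale):.3g} (tol {decay_tol:g}); "
            "increase n_cycles"
        )
    if return_trace:
        return last, TimeDomainTrace(times=sol.t, displacements=disp)
    return last
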