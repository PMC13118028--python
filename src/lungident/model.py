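"""Lumped-parameter mechanical model of the lung–thorax system.

The system is represented by four lumped compartments, each a single
translational degree of freedom (DOF):

========  =============================================
index     compartment
========  =============================================
0         chest wall (sternum, ribs, superficial tissue)
1         right upper lung region
2         right lower lung region
3         left lung
========  =============================================

Compartments are coupled by linear springs and dampers; the chest wall is
additionally tethered to ground (spine/body support).  The model yields the
diagonal mass matrix M, and symmetric stiffness and damping matrices K and C
assembled by the standard finite-element-style rule: a spring ``k`` between
DOFs ``i`` and ``j`` contributes ``+k`` to ``K[i,i]`` and ``K[j,j]`` and
``-k`` to the off-diagonal pair; a ground spring contributes to the diagonal
only.  The damping matrix mirrors the spring topology.

Pathologies are modelled as multiplicative perturbations of stiffness
(fibrosis: stiffer, emphysema: softer) and — for focal lesions only — mass.

All mechanical quantities are in arbitrary consistent units; the only
dimensional axis in the package is excitation frequency (Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GROUND",
    "CompartmentSet",
    "SpringSpec",
    "DamperSpec",
    "ThoraxModel",
    "PathologySpec",
    "InvalidModelError",
    "TopologyError",
    "InvalidPerturbationError",
    "assemble_matrices",
    "apply_pathology",
    "wavelength_check",
    "default_model",
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_PATHOLOGIES",
]

#: Sentinel endpoint meaning "attached to ground" (rigid external support).
GROUND = -1

DEFAULT_COMPARTMENTS = (
    "chest_wall",
    "right_upper_lung",
    "right_lower_lung",
    "left_lung",
)


class InvalidModelError(ValueError):
    """Raised when model parameters violate physical validity (e.g. mass <= 0)."""


class TopologyError(ValueError):
    """Raised when an element references a DOF that does not exist."""


class InvalidPerturbationError(ValueError):
    """Raised when a pathology perturbation factor is non-positive."""


@dataclass(frozen=True)
class CompartmentSet:
    """Ordered compartment labels; list position is the DOF index.

    DOF 0 is always the excitation/measurement interface (chest wall).
    """

    labels: tuple[str, ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise InvalidModelError("at least one compartment is required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidModelError("compartment labels must be unique")

    @property
    def n_dof(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class SpringSpec:
    """Linear spring between two DOFs, or between one DOF and ground.

    Parameters
    ----------
    endpoint_a : int
        DOF index of the first attachment point.
    endpoint_b : int
        DOF index of the second attachment point, or :data:`GROUND`.
    stiffness : float
        Spring constant, >= 0 (arbitrary units).
    """

    endpoint_a: int
    endpoint_b: int
    stiffness: float

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise InvalidModelError(f"stiffness must be >= 0, got {self.stiffness}")
        if self.endpoint_a == self.endpoint_b:
            raise TopologyError("spring endpoints must differ")

    @property
    def name(self) -> str:
        """Canonical identifier, e.g. ``k01`` or ``k0g`` for a ground spring."""
        if self.endpoint_b == GROUND:
            return f"k{self.endpoint_a}g"
        i, j = sorted((self.endpoint_a, self.endpoint_b))
        return f"k{i}{j}"


@dataclass(frozen=True)
class DamperSpec:
    """Linear viscous damper; topology mirrors the spring set."""

    endpoint_a: int
    endpoint_b: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise InvalidModelError(
                f"damper coefficient must be >= 0, got {self.coefficient}"
            )
        if self.endpoint_a == self.endpoint_b:
            raise TopologyError("damper endpoints must differ")

    @property
    def name(self) -> str:
        if self.endpoint_b == GROUND:
            return f"c{self.endpoint_a}g"
        i, j = sorted((self.endpoint_a, self.endpoint_b))
        return f"c{i}{j}"


@dataclass(frozen=True)
class ThoraxModel:
    """Complete lumped lung–thorax model: masses plus spring/damper topology."""

    compartments: CompartmentSet
    masses: tuple[float, ...]
    springs: tuple[SpringSpec, ...]
    dampers: tuple[DamperSpec, ...]

    def __post_init__(self) -> None:
        n = self.compartments.n_dof
        if len(self.masses) != n:
            raise InvalidModelError(
                f"expected {n} masses, got {len(self.masses)}"
            )
        if any(m <= 0 for m in self.masses):
            raise InvalidModelError("all masses must be > 0")
        seen_pairs: set[tuple[int, int]] = set()
        for elem in (*self.springs, *self.dampers):
            for ep in (elem.endpoint_a, elem.endpoint_b):
                if ep != GROUND and not (0 <= ep < n):
                    raise TopologyError(f"element references unknown DOF {ep}")
        for s in self.springs:
            pair = tuple(sorted((s.endpoint_a, s.endpoint_b)))
            if pair in seen_pairs:
                raise TopologyError(f"duplicate spring for pair {pair}")
            seen_pairs.add(pair)

    @property
    def n_dof(self) -> int:
        return self.compartments.n_dof

    def spring(self, name: str) -> SpringSpec:
        """Look up a spring by canonical name (``k01``, ``k0g``, ...)."""
        for s in self.springs:
            if s.name == name:
                return s
        raise KeyError(f"no spring named {name!r}")

    def spring_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.springs)

    def with_spring(self, name: str, stiffness: float) -> "ThoraxModel":
        """Return a copy with one spring's stiffness replaced."""
        if not any(s.name == name for s in self.springs):
            raise KeyError(f"no spring named {name!r}")
        springs = tuple(
            replace(s, stiffness=stiffness) if s.name == name else s
            for s in self.springs
        )
        return replace(self, springs=springs)


def _assemble(n: int, elements, value_attr: str) -> np.ndarray:
    mat = np.zeros((n, n))
    for elem in elements:
        v = getattr(elem, value_attr)
        a, b = elem.endpoint_a, elem.endpoint_b
        if b == GROUND:
            mat[a, a] += v
        elif a == GROUND:
            mat[b, b] += v
        else:
            mat[a, a] += v
            mat[b, b] += v
            mat[a, b] -= v
            mat[b, a] -= v
    return mat


def assemble_matrices(
    model: ThoraxModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the (M, C, K) system matrices of a model.

    M is diagonal with the compartment masses.  K and C are assembled from
    the spring and damper lists by symmetric two-node superposition; ground
    elements contribute only to the diagonal entry of their attached DOF.

    Returns
    -------
    (M, C, K) : tuple of (n, n) ndarrays
    """
    n = model.n_dof
    mass_matrix = np.diag(np.asarray(model.masses, dtype=float))
    damping_matrix = _assemble(n, model.dampers, "coefficient")
    stiffness_matrix = _assemble(n, model.springs, "stiffness")
    return mass_matrix, damping_matrix, stiffness_matrix


# ---------------------------------------------------------------------------
# Pathology perturbations
# ---------------------------------------------------------------------------

PATHOLOGY_CONDITIONS = ("healthy", "fibrosis_RU", "fibrosis_RL", "emphysema", "focal")


@dataclass(frozen=True)
class PathologySpec:
    """Multiplicative perturbation of the healthy baseline.

    ``stiffness_factors`` maps spring names to factors (> 1 for fibrosis,
    < 1 for emphysema).  ``mass_factors`` maps DOF indices to factors and is
    only meaningful for focal lesions; damping is never altered.
    """

    condition: str
    stiffness_factors: Mapping[str, float] = field(default_factory=dict)
    mass_factors: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in PATHOLOGY_CONDITIONS:
            raise InvalidPerturbationError(
                f"unknown condition {self.condition!r}; "
                f"expected one of {PATHOLOGY_CONDITIONS}"
            )
        for factors in (self.stiffness_factors, self.mass_factors):
            for key, f in factors.items():
                if f <= 0:
                    raise InvalidPerturbationError(
                        f"perturbation factor for {key!r} must be > 0, got {f}"
                    )


def default_pathologies(
    fibrosis_factor: float = 1.5, emphysema_factor: float = 0.7
) -> dict[str, PathologySpec]:
    """Class-conditional perturbations used throughout the package.

    Right-upper fibrosis stiffens the chest/right-upper coupling k01;
    right-lower fibrosis stiffens k02.  Emphysema softens both chest–lung
    couplings of the right lung.
    """
    return {
        "healthy": PathologySpec("healthy"),
        "fibrosis_RU": PathologySpec(
            "fibrosis_RU", stiffness_factors={"k01": fibrosis_factor}
        ),
        "fibrosis_RL": PathologySpec(
            "fibrosis_RL", stiffness_factors={"k02": fibrosis_factor}
        ),
        "emphysema": PathologySpec(
            "emphysema",
            stiffness_factors={"k01": emphysema_factor, "k02": emphysema_factor},
        ),
    }


DEFAULT_PATHOLOGIES = default_pathologies()


def apply_pathology(model: ThoraxModel, spec: PathologySpec) -> ThoraxModel:
    """Return a new model with pathology factors applied multiplicatively.

    Stiffness factors multiply the named springs; mass factors (focal
    lesions) multiply the masses of the named DOFs.  Dampers and all other
    parameters are untouched.
    """
    names = set(model.spring_names())
    for name in spec.stiffness_factors:
        if name not in names:
            raise TopologyError(f"pathology references unknown spring {name!r}")
    for dof in spec.mass_factors:
        if not (0 <= dof < model.n_dof):
            raise TopologyError(f"pathology references unknown DOF {dof}")

    springs = tuple(
        replace(s, stiffness=s.stiffness * spec.stiffness_factors.get(s.name, 1.0))
        for s in model.springs
    )
    masses = tuple(
        m * spec.mass_factors.get(i, 1.0) for i, m in enumerate(model.masses)
    )
    return replace(model, springs=springs, masses=masses)


# ---------------------------------------------------------------------------
# Lumped-parameter validity
# ---------------------------------------------------------------------------

def wavelength_check(wave_speed: float, frequency: float) -> float:
    """Wavelength (m) of a wave at ``wave_speed`` (m/s) and ``frequency`` (Hz).

    The lumped-parameter idealization holds when the shortest wavelength in
    the excitation band is comparable to or exceeds the compartment size.
    With effective longitudinal wave speeds in aerated lung tissue of roughly
    20–50 m/s, excitation up to 150 Hz gives wavelengths of 0.13–0.33 m —
    on the order of whole-lung dimensions, so collective viscoelastic motion
    dominates over propagating waves.
    """
    if wave_speed <= 0 or frequency <= 0:
        raise ValueError("wave_speed and frequency must both be > 0")
    return wave_speed / frequency


# ---------------------------------------------------------------------------
# Default (healthy baseline) configuration
# ---------------------------------------------------------------------------

#: Baseline spring constants (arbitrary units).  k01 and k02 — the two
#: chest–lung couplings targeted by inverse fitting — are 240 and 154; the
#: remaining values are package defaults.  They are chosen so that (a) the
#: lung/chest resonances (~31, 37, 50 Hz) fall inside the 5–150 Hz
#: excitation band, (b) the rigid-body mode of the thorax on its elastic
#: support sits below the band (~3 Hz), and (c) inter-lung coupling is weak
#: relative to the chest–lung couplings.  (b) and (c) give each lung
#: region's response a clean low-frequency dependence on its own chest
#: coupling: over 5–25 Hz the right-upper response is dominated by k01 and
#: the right-lower response by k02.
DEFAULT_STIFFNESS: dict[str, float] = {
    "k01": 240.0,
    "k02": 154.0,
    "k03": 180.0,
    "k12": 10.0,
    "k13": 8.0,
    "k23": 12.0,
    "k0g": 12.0,
}

#: Baseline masses (arbitrary units): chest wall, RU, RL, left lung.
DEFAULT_MASSES: tuple[float, ...] = (0.02, 0.003, 0.004, 0.006)

#: Stiffness-proportional tissue damping: c_ij = DAMPING_BETA * k_ij
#: (seconds).  Gives visibly underdamped resonances across the band.
DAMPING_BETA: float = 2.0e-4

#: Damping coefficient of the chest-wall/ground support damper.  Support
#: losses (body tissue, posture) are physically distinct from parenchymal
#: viscosity and much larger relative to the weak support spring; this
#: value puts the sub-band support mode near 30 % of critical damping.
DEFAULT_SUPPORT_DAMPING: float = 0.35

_SPRING_ENDPOINTS: dict[str, tuple[int, int]] = {
    "k01": (0, 1),
    "k02": (0, 2),
    "k03": (0, 3),
    "k12": (1, 2),
    "k13": (1, 3),
    "k23": (2, 3),
    "k0g": (0, GROUND),
}


def default_model(
    stiffness: Mapping[str, float] | None = None,
    masses: Sequence[float] | None = None,
    damping_beta: float = DAMPING_BETA,
    support_damping: float = DEFAULT_SUPPORT_DAMPING,
) -> ThoraxModel:
    """Construct the healthy baseline 4-DOF model.

    Parameters
    ----------
    stiffness : mapping, optional
        Overrides for individual spring constants (keys as in
        :data:`DEFAULT_STIFFNESS`).
    masses : sequence of 4 floats, optional
        Compartment masses; defaults to :data:`DEFAULT_MASSES`.
    damping_beta : float
        Stiffness-proportionality constant for the tissue dampers (s).
    support_damping : float
        Coefficient of the chest-wall/ground support damper.
    """
    kvals = dict(DEFAULT_STIFFNESS)
    if stiffness:
        unknown = set(stiffness) - set(kvals)
        if unknown:
            raise TopologyError(f"unknown spring names: {sorted(unknown)}")
        kvals.update(stiffness)
    mvals = tuple(masses) if masses is not None else DEFAULT_MASSES

    springs = tuple(
        SpringSpec(a, b, kvals[name]) for name, (a, b) in _SPRING_ENDPOINTS.items()
    )
    dampers = tuple(
        DamperSpec(
            a,
            b,
            support_damping if b == GROUND else damping_beta * kvals[name],
        )
        for name, (a, b) in _SPRING_ENDPOINTS.items()
    )
    return ThoraxModel(
        compartments=CompartmentSet(),
        masses=mvals,
        springs=springs,
        dampers=dampers,
    )
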