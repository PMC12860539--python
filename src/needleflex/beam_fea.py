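"""Planar Euler-Bernoulli beam finite elements on discrete spring supports.

The needle is modelled as a slender tube bending in a single plane. Each node
carries two degrees of freedom: transverse deflection ``w`` (mm) and rotation
``theta = dw/dx`` (rad). Tissue reaction enters as linear springs attached to
individual nodes; each spring carries a rest deflection ``z0`` (the deflection
at which its force vanishes) so that tissue-channel history can be preserved
as the needle advances.

Units are mm / N / MPa (N/mm^2) throughout, so spring stiffnesses are N/mm
and moments are N*mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeedleSpec",
    "Spring",
    "BeamSystem",
    "element_stiffness",
    "assemble_beam_stiffness",
    "assemble_and_solve",
    "SingularSystemError",
]


class SingularSystemError(RuntimeError):
    """Raised when the constrained beam system has a free mechanism."""


@dataclass(frozen=True)
class NeedleSpec:
    """Geometry and material constants of the biopsy needle.

    Defaults describe an 18-gauge nitinol needle: 140 mm long, 1.27 mm outer
    and 0.838 mm inner diameter, 35 000 MPa elastic modulus, 30-degree bevel,
    discretised into 47 beam elements (48 nodes).
    """

    length: float = 140.0  # mm
    outer_diameter: float = 1.27  # mm
    inner_diameter: float = 0.838  # mm
    elastic_modulus: float = 35_000.0  # MPa
    bevel_angle: float = 30.0  # degrees, stored as printed; radians at use
    n_elements: int = 47

    def __post_init__(self) -> None:
        if self.length <= 0 or self.n_elements < 1:
            raise ValueError("needle length and element count must be positive")
        if not 0.0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 <= inner_diameter < outer_diameter")
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0.0 < self.bevel_angle < 180.0:
            raise ValueError("bevel angle must lie in (0, 180) degrees")

    @property
    def n_nodes(self) -> int:
        return self.n_elements + 1

    @property
    def element_length(self) -> float:
        """Length of one beam element in mm."""
        return self.length / self.n_elements

    @property
    def second_moment(self) -> float:
        """Second moment of area I of the tube cross-section, mm^4."""
        return math.pi * (self.outer_diameter**4 - self.inner_diameter**4) / 64.0

    @property
    def node_positions(self) -> np.ndarray:
        """Axial node positions in mm, base at 0, tip at ``length``."""
        return np.linspace(0.0, self.length, self.n_nodes)


@dataclass
class Spring:
    """Linear tissue spring on one node's w-DOF.

    The spring force on the needle is ``k * (z0 - w)``: zero when the node
    sits at the rest deflection ``z0``, restoring otherwise.
    """

    node_index: int
    stiffness: float  # N/mm
    rest_deflection: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise ValueError("spring stiffness must be non-negative")
        if self.node_index < 0:
            raise ValueError("spring node index must be non-negative")


def element_stiffness(elastic_modulus: float, second_moment: float, element_length: float) -> np.ndarray:
    """4x4 Hermite bending stiffness for DOFs (w_i, theta_i, w_j, theta_j).

    Parameters are E (MPa), I (mm^4) and the element length L (mm); the
    returned matrix maps (mm, rad) displacements to (N, N*mm) loads.
    """
    if elastic_modulus <= 0 or second_moment <= 0 or element_length <= 0:
        raise ValueError("E, I and element length must all be positive")
    L = element_length
    c = elastic_modulus * second_moment / L**3
    return c * np.array(
        [
            [12.0, 6.0 * L, -12.0, 6.0 * L],
            [6.0 * L, 4.0 * L**2, -6.0 * L, 2.0 * L**2],
            [-12.0, -6.0 * L, 12.0, -6.0 * L],
            [6.0 * L, 2.0 * L**2, -6.0 * L, 4.0 * L**2],
        ]
    )


def assemble_beam_stiffness(needle: NeedleSpec) -> np.ndarray:
    """Global 2n x 2n bending stiffness of the unconstrained needle."""
    n_dof = 2 * needle.n_nodes
    K = np.zeros((n_dof, n_dof))
    ke = element_stiffness(needle.elastic_modulus, needle.second_moment, needle.element_length)
    for e in range(needle.n_elements):
        dofs = np.array([2 * e, 2 * e + 1, 2 * e + 2, 2 * e + 3])
        K[np.ix_(dofs, dofs)] += ke
    return K


@dataclass
class BeamSystem:
    """Assembled beam + springs + constraints, ready for a static solve.

    ``loads`` holds external nodal forces (N) at w-DOFs and moments (N*mm) at
    theta-DOFs, indexed like the global DOF vector (2*node for w,
    2*node + 1 for theta). Constrained DOFs are prescribed to zero.
    """

    needle: NeedleSpec
    springs: list[Spring] = field(default_factory=list)
    constrained_dofs: frozenset[int] = frozenset()
    loads: np.ndarray | None = None
    # cached unconstrained beam stiffness, shared across repeated solves
    _beam_K: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_dof = 2 * self.needle.n_nodes
        if self.loads is None:
            self.loads = np.zeros(n_dof)
        self.loads = np.asarray(self.loads, dtype=float)
        if self.loads.shape != (n_dof,):
            raise ValueError(f"load vector must have shape ({n_dof},)")
        bad = [d for d in self.constrained_dofs if not 0 <= d < n_dof]
        if bad:
            raise ValueError(f"constrained DOFs out of range: {bad}")
        for s in self.springs:
            if s.node_index >= self.needle.n_nodes:
                raise ValueError("spring node index beyond needle nodes")

    def beam_stiffness(self) -> np.ndarray:
        if self._beam_K is None:
            self._beam_K = assemble_beam_stiffness(self.needle)
        return self._beam_K

    def total_stiffness(self) -> np.ndarray:
        """Beam stiffness plus spring stiffness on the w-diagonal."""
        K = self.beam_stiffness().copy()
        for s in self.springs:
            K[2 * s.node_index, 2 * s.node_index] += s.stiffness
        return K

    def total_load(self) -> np.ndarray:
        """External loads plus spring preload terms k*z0."""
        F = self.loads.copy()
        for s in self.springs:
            F[2 * s.node_index] += s.stiffness * s.rest_deflection
        return F


def assemble_and_solve(system: BeamSystem) -> np.ndarray:
    """Static solve of (K_beam + K_spring) u = F_ext + F_preload.

    Returns the full DOF vector of length ``2 * n_nodes`` with constrained
    DOFs exactly zero. Raises :class:`SingularSystemError` when the
    constraints and springs leave a rigid-body mechanism.
    """
    n_dof = 2 * system.needle.n_nodes
    K = system.total_stiffness()
    F = system.total_load()
    free = np.ones(n_dof, dtype=bool)
    free[list(system.constrained_dofs)] = False

    u = np.zeros(n_dof)
    if not free.any():
        return u

    # structural mechanism check: transverse supports come from constrained
    # w-DOFs and springs with positive stiffness; fewer than two distinct
    # support locations (with the base rotation free) leaves a rigid-body
    # translation and/or rotation of the needle
    support_nodes = {d // 2 for d in system.constrained_dofs if d % 2 == 0}
    support_nodes |= {s.node_index for s in system.springs if s.stiffness > 0}
    theta_constrained = any(d % 2 == 1 for d in system.constrained_dofs)
    if len(support_nodes) == 0 or (len(support_nodes) == 1 and not theta_constrained):
        raise SingularSystemError(
            "beam system is singular: the constraints and springs leave an "
            "unconstrained rigid-body mechanism (free translation/rotation "
            f"with only {len(support_nodes)} transverse support node(s))"
        )
    K_ff = K[np.ix_(free, free)]
    try:
        u_f = np.linalg.solve(K_ff, F[free])
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            "beam system is singular: the constraints and springs leave an "
            "unconstrained rigid-body mechanism (translation/rotation of the "
            "free segment)"
        ) from exc
    if not np.all(np.isfinite(u_f)):
        raise SingularSystemError(
            "beam solve produced non-finite values; system is numerically "
            "singular (free rigid-body mechanism)"
        )
    u[free] = u_f
    return u


def reaction_forces(system: BeamSystem, solution: np.ndarray) -> np.ndarray:
    """Constraint reactions: K u - F at every DOF (nonzero only where held)."""
    K = system.total_stiffness()
    F = system.total_load()
    return K @ solution - F
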