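"""Quasi-static bevel-tip needle insertion through layered elastic tissue.

The needle advances 1 mm per step. At each step the tissue just traversed is
attached to the shaft as a preloaded linear spring, the bevel-tip cutting
force is recomputed from the local tissue modulus and applied at the tip, and
the needle shape is solved with the planar beam model. After every element
length of advance the spring registry is shifted one node toward the base so
the tissue channel stays fixed in space while the needle moves through it;
the shift preserves each spring's instantaneous force via its rest
deflection.

The portion of the needle still proximal to the tissue surface is held in the
template grid: its deflection is pinned to exactly zero, with rotation fixed
at the base node only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beam_fea import BeamSystem, NeedleSpec, Spring, assemble_and_solve

__all__ = [
    "TissueProfile",
    "InsertionState",
    "Trajectory",
    "cutting_force",
    "deflecting_force",
    "guided_region_constraints",
    "simulate_insertion",
    "MAX_DEPTH",
]

MAX_DEPTH = 125  # mm; tissue properties are defined per mm over depths 1..125

#: Tributary tissue depth converted into each spring, mm. One spring is added
#: per millimetre of advance, so k [N/mm] = C [MPa] * SPRING_TRIBUTARY_MM.
SPRING_TRIBUTARY_MM = 1.0


@dataclass(frozen=True)
class TissueProfile:
    """Per-millimetre tissue elastic modulus, MPa.

    ``modulus_per_mm[i]`` governs the depth interval ``(i, i+1]`` mm, i.e. the
    modulus felt by the tip at integer depth ``d`` is ``modulus_per_mm[d-1]``.
    """

    modulus_per_mm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.modulus_per_mm, dtype=float)
        if arr.shape != (MAX_DEPTH,):
            raise ValueError(f"tissue profile must have exactly {MAX_DEPTH} values")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("tissue moduli must be finite and non-negative")
        object.__setattr__(self, "modulus_per_mm", arr)

    def modulus_at_depth(self, depth: int) -> float:
        """Modulus (MPa) governing integer depth ``depth`` in 1..125."""
        if not 1 <= depth <= MAX_DEPTH:
            raise ValueError(f"depth must be in [1, {MAX_DEPTH}], got {depth}")
        return float(self.modulus_per_mm[depth - 1])


@dataclass(frozen=True)
class InsertionState:
    """Converged needle state at one integer insertion depth."""

    depth: int  # mm
    deflection: np.ndarray  # w per node, mm (length n_nodes)
    slope: np.ndarray  # theta per node, rad (length n_nodes)
    springs: tuple[Spring, ...]
    tip_slope: float  # rad
    tip_force_angle: float  # beta = alpha + tip_slope, rad
    cutting_force: float  # F_c, N
    deflecting_force: float  # F_c,z, N


@dataclass(frozen=True)
class Trajectory:
    """Sequence of insertion states at depths 1..target_depth."""

    needle: NeedleSpec
    tissue: TissueProfile
    states: tuple[InsertionState, ...]

    def __post_init__(self) -> None:
        depths = [s.depth for s in self.states]
        if depths != list(range(1, len(depths) + 1)):
            raise ValueError("trajectory states must cover depths 1..D in order")

    @property
    def target_depth(self) -> int:
        return len(self.states)

    def state_at(self, depth: int) -> InsertionState:
        if not 1 <= depth <= len(self.states):
            raise ValueError(f"no state at depth {depth}")
        return self.states[depth - 1]

    def deflection_matrix(self) -> np.ndarray:
        """(target_depth, n_nodes) array of nodal deflections in mm."""
        return np.stack([s.deflection for s in self.states])


def cutting_force(tip_modulus: float, diameter: float, bevel_angle_deg: float) -> float:
    """Bevel-tip cutting force F_c = C_tip * d^2 / (4 tan(alpha/2)), N.

    ``tip_modulus`` is the tissue elastic modulus at the tip (MPa),
    ``diameter`` the needle outer diameter (mm), ``bevel_angle_deg`` the bevel
    angle alpha in degrees. The model treats the bevel as a wedge compressing
    the tissue ahead of it, so the force is linear in the local modulus.
    """
    if tip_modulus < 0:
        raise ValueError("tissue modulus must be non-negative")
    if diameter <= 0:
        raise ValueError("needle diameter must be positive")
    if not 0.0 < bevel_angle_deg < 180.0:
        raise ValueError("bevel angle must lie in (0, 180) degrees")
    alpha = math.radians(bevel_angle_deg)
    return tip_modulus * diameter**2 / (4.0 * math.tan(alpha / 2.0))


def deflecting_force(f_cut: float, bevel_angle_deg: float, tip_slope: float) -> float:
    """Transverse component F_c,z = F_c * cos(alpha + theta_tip), N.

    ``bevel_angle_deg`` is converted to radians before being summed with the
    tip slope ``tip_slope`` (rad); beta = alpha + theta_tip is the angle
    between the cutting force and the deflection direction.
    """
    if f_cut < 0:
        raise ValueError("cutting force must be non-negative")
    beta = math.radians(bevel_angle_deg) + tip_slope
    return f_cut * math.cos(beta)


def guided_region_constraints(depth: int, needle: NeedleSpec) -> frozenset[int]:
    """Constrained global DOFs for the out-of-tissue (template-guided) region.

    Every node within ``needle.length - depth`` mm of the base is pinned in w;
    rotation is fixed at the base node only. At depth 0 the whole needle is
    outside the tissue and every node is pinned.
    """
    if not 0 <= depth <= MAX_DEPTH:
        raise ValueError(f"depth must be in [0, {MAX_DEPTH}], got {depth}")
    guided_length = needle.length - depth
    positions = needle.node_positions
    constrained = {2 * i for i in range(needle.n_nodes) if positions[i] <= guided_length + 1e-12}
    constrained.add(1)  # base rotation
    return frozenset(constrained)


def _shift_springs(springs: list[Spring], deflection: np.ndarray) -> list[Spring]:
    """Move each spring one node toward the base, preserving its force.

    A spring with force k*(z0 - w_old) re-attached at the proximal node with
    current deflection w_new keeps the same force when
    z0' = w_new + (z0 - w_old).
    """
    moved = []
    for s in springs:
        new_node = s.node_index - 1
        if new_node < 0:
            raise RuntimeError("spring shifted past the needle base")
        z0_new = deflection[new_node] + (s.rest_deflection - deflection[s.node_index])
        moved.append(Spring(new_node, s.stiffness, z0_new))
    return moved


def simulate_insertion(
    needle: NeedleSpec,
    tissue: TissueProfile,
    target_depth: int,
    *,
    bevel_direction: int = 1,
    tip_slope_fixed_point: bool = False,
    fixed_point_tol: float = 1e-8,
    fixed_point_max_iter: int = 50,
) -> Trajectory:
    """Simulate a 1-mm-stepped insertion to ``target_depth`` (mm).

    Per step at depth n: (1) a spring of stiffness C(n) * 1 mm is attached at
    the node immediately proximal to the tip, preloaded to that node's current
    deflection; (2) the cutting force is computed from the tip modulus and its
    transverse component from the previous step's tip slope; (3) the beam
    system is solved with the tip load, all springs, and the guided-region
    constraints; (4) after each accumulated element length of advance the
    springs are shifted one node toward the base, preserving their forces.

    ``bevel_direction`` (+1/-1) selects which side of the needle the bevel
    faces, i.e. the sign of the applied tip load. With
    ``tip_slope_fixed_point`` the tip slope entering the force is iterated to
    self-consistency instead of lagging one step.
    """
    if not isinstance(target_depth, (int, np.integer)):
        raise ValueError("target depth must be an integer number of mm")
    if not 1 <= target_depth <= MAX_DEPTH:
        raise ValueError(f"target depth must be in [1, {MAX_DEPTH}], got {target_depth}")
    if bevel_direction not in (-1, 1):
        raise ValueError("bevel_direction must be +1 or -1")

    n_nodes = needle.n_nodes
    tip_node = n_nodes - 1
    spring_node = tip_node - 1  # first node strictly proximal to the tip
    system = BeamSystem(needle)  # reused so the beam stiffness is cached

    springs: list[Spring] = []
    deflection = np.zeros(n_nodes)
    tip_slope = 0.0
    advance_since_shift = 0.0
    states: list[InsertionState] = []

    for depth in range(1, int(target_depth) + 1):
        modulus = tissue.modulus_at_depth(depth)
        springs.append(
            Spring(spring_node, modulus * SPRING_TRIBUTARY_MM, float(deflection[spring_node]))
        )

        f_cut = cutting_force(modulus, needle.outer_diameter, needle.bevel_angle)
        constraints = guided_region_constraints(depth, needle)

        def _solve(theta_tip: float) -> tuple[np.ndarray, float]:
            # tip slope measured in the bevel frame, so a flipped bevel is
            # the exact mirror problem
            f_cz = deflecting_force(f_cut, needle.bevel_angle, bevel_direction * theta_tip)
            loads = np.zeros(2 * n_nodes)
            loads[2 * tip_node] = bevel_direction * f_cz
            system.springs = springs
            system.constrained_dofs = constraints
            system.loads = loads
            try:
                u = assemble_and_solve(system)
            except Exception as exc:
                raise RuntimeError(f"solve failed at insertion step {depth} mm") from exc
            return u, f_cz

        u, f_cz = _solve(tip_slope)
        if tip_slope_fixed_point:
            for _ in range(fixed_point_max_iter):
                theta_new = u[2 * tip_node + 1]
                if abs(theta_new - tip_slope) < fixed_point_tol:
                    break
                tip_slope = theta_new
                u, f_cz = _solve(tip_slope)

        deflection = u[0::2].copy()
        slope = u[1::2].copy()
        tip_slope = float(slope[tip_node])

        state = InsertionState(
            depth=depth,
            deflection=deflection,
            slope=slope,
            springs=tuple(replace(s) for s in springs),
            tip_slope=tip_slope,
            tip_force_angle=math.radians(needle.bevel_angle) + tip_slope,
            cutting_force=f_cut,
            deflecting_force=f_cz,
        )
        states.append(state)

        advance_since_shift += 1.0
        if advance_since_shift >= needle.element_length:
            advance_since_shift -= needle.element_length
            springs = _shift_springs(springs, deflection)

    return Trajectory(needle=needle, tissue=tissue, states=tuple(states))
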