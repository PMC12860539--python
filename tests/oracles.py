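"""Independent brute-force references used to cross-check the package.

Everything here is deliberately written on a different path from the
implementation under test: the element stiffness comes from numerical
quadrature of Hermite shape-function curvatures (not the closed-form
matrix), constraints are enforced with Lagrange multipliers (not row
reduction), and the insertion ledger is a plain step-by-step transcription
of the algorithm with its own spring bookkeeping.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.integrate import quad


def hermite_element_stiffness(E: float, I: float, L: float) -> np.ndarray:
    """Element stiffness by quadrature: k_ij = EI * integral N_i'' N_j'' dx.

    Hermite cubic shape functions on [0, L] for DOFs (w_i, theta_i, w_j,
    theta_j), differentiated twice as polynomials and integrated with
    adaptive quadrature.
    """
    # shape functions as polynomial coefficient arrays (ascending powers)
    shapes = [
        [1.0, 0.0, -3.0 / L**2, 2.0 / L**3],
        [0.0, 1.0, -2.0 / L, 1.0 / L**2],
        [0.0, 0.0, 3.0 / L**2, -2.0 / L**3],
        [0.0, 0.0, -1.0 / L, 1.0 / L**2],
    ]
    curvatures = [P.polyder(np.array(c), 2) for c in shapes]
    k = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            integrand = lambda x: P.polyval(x, curvatures[i]) * P.polyval(x, curvatures[j])
            k[i, j] = E * I * quad(integrand, 0.0, L)[0]
    return k


def assemble_global(n_elements: int, E: float, I: float, L_total: float) -> np.ndarray:
    Le = L_total / n_elements
    ke = hermite_element_stiffness(E, I, Le)
    n_dof = 2 * (n_elements + 1)
    K = np.zeros((n_dof, n_dof))
    for e in range(n_elements):
        idx = [2 * e, 2 * e + 1, 2 * e + 2, 2 * e + 3]
        for a in range(4):
            for b in range(4):
                K[idx[a], idx[b]] += ke[a, b]
    return K


def lagrange_solve(
    K: np.ndarray,
    F: np.ndarray,
    constrained: list[int],
    springs: list[dict] | None = None,
) -> np.ndarray:
    """Constrained static solve via a KKT (Lagrange multiplier) system.

    ``springs`` entries are dicts with keys node, k, z0; each contributes k
    on the w-diagonal and k*z0 to the load.
    """
    K = K.copy()
    F = F.copy()
    for s in springs or []:
        dof = 2 * s["node"]
        K[dof, dof] += s["k"]
        F[dof] += s["k"] * s["z0"]
    n = K.shape[0]
    m = len(constrained)
    C = np.zeros((m, n))
    for row, dof in enumerate(sorted(constrained)):
        C[row, dof] = 1.0
    A = np.block([[K, C.T], [C, np.zeros((m, m))]])
    rhs = np.concatenate([F, np.zeros(m)])
    sol = np.linalg.solve(A, rhs)
    return sol[:n]


def step_ledger_insertion(
    tissue_moduli: np.ndarray,
    target_depth: int,
    *,
    length: float = 140.0,
    n_elements: int = 47,
    E: float = 35_000.0,
    outer_d: float = 1.27,
    inner_d: float = 0.838,
    bevel_deg: float = 30.0,
    bevel_direction: int = 1,
) -> np.ndarray:
    """Deflection history (target_depth, n_nodes) from a plain step ledger."""
    I = math.pi * (outer_d**4 - inner_d**4) / 64.0
    n_nodes = n_elements + 1
    Le = length / n_elements
    K_beam = assemble_global(n_elements, E, I, length)
    positions = [i * Le for i in range(n_nodes)]

    ledger: list[dict] = []
    w = np.zeros(n_nodes)
    theta_tip = 0.0
    advance = 0.0
    history = np.zeros((target_depth, n_nodes))

    for depth in range(1, target_depth + 1):
        C_here = float(tissue_moduli[depth - 1])
        ledger.append({"node": n_nodes - 2, "k": C_here * 1.0, "z0": float(w[n_nodes - 2])})

        fc = C_here * outer_d**2 / (4.0 * math.tan(math.radians(bevel_deg) / 2.0))
        fcz = fc * math.cos(math.radians(bevel_deg) + theta_tip)

        constrained = [2 * i for i in range(n_nodes) if positions[i] <= (length - depth) + 1e-12]
        constrained.append(1)
        F = np.zeros(2 * n_nodes)
        F[2 * (n_nodes - 1)] = bevel_direction * fcz

        u = lagrange_solve(K_beam, F, constrained, ledger)
        w = u[0::2].copy()
        theta_tip = float(u[2 * (n_nodes - 1) + 1])
        history[depth - 1] = w

        advance += 1.0
        if advance >= Le:
            advance -= Le
            ledger = [
                {"node": s["node"] - 1, "k": s["k"], "z0": float(w[s["node"] - 1] + s["z0"] - w[s["node"]])}
                for s in ledger
            ]
    return history
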