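"""Stability classification of steady states and trajectory integration.

The full Jacobian of a mass-action system with conservation laws always
carries s - rho structurally zero eigenvalues: each conservation vector
w satisfies w^T J = 0 because w . (N v) vanishes identically.  Those
zeros say nothing about stability within the compatibility class the
dynamics actually lives in, so classification uses the Jacobian
restricted to the stoichiometric subspace T: with B an orthonormal
basis of T (rank-revealing orthogonalization of the reaction vectors),
the reduced spectrum is eig(B^T J B), rho eigenvalues, and

    stable    all reduced eigenvalues have real part < 0
    unstable  at least one real part > 0
    marginal  some real part within tolerance of 0 (never silently
              resolved either way)

The choice of B cannot matter: any two orthonormal bases of T are
related by an orthogonal transform, a similarity of B^T J B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .conservation import ConservationAnalysis, analyze_network
from .kinetics import MassActionSystem
from .steady_state import SteadyStatePoint

__all__ = [
    "StabilityReport",
    "classify_jacobian",
    "classify_steady_state",
    "subspace_basis",
    "simulate_trajectory",
    "ZERO_EIG_REL_TOL",
]

#: |Re(lambda)| below this fraction of the spectral radius counts as zero
ZERO_EIG_REL_TOL = 1e-8


@dataclass
class StabilityReport:
    point: SteadyStatePoint
    eigenvalues: list[complex]  # full s x s Jacobian spectrum
    reduced_eigenvalues: list[complex]  # restricted to the stoichiometric subspace
    label: str  # "stable" | "unstable" | "marginal"

    @property
    def n_zero(self) -> int:
        """Near-zero eigenvalues of the full Jacobian (conservation-induced)."""
        scale = max(1e-300, max(abs(e) for e in self.eigenvalues))
        return sum(1 for e in self.eigenvalues if abs(e) <= ZERO_EIG_REL_TOL * scale)


def subspace_basis(analysis: ConservationAnalysis) -> np.ndarray:
    """Orthonormal s x rho basis of the stoichiometric subspace T.

    Rank-revealing: SVD of the reaction-vector matrix, keeping the
    first rho left singular vectors (rho from the exact rank).
    """
    N = np.array(analysis.network.stoichiometric_matrix(), dtype=float)
    U, _, _ = np.linalg.svd(N, full_matrices=False)
    return U[:, : analysis.rank]


def _numeric_jacobian(system: MassActionSystem) -> callable:
    J = system.jacobian()
    fn = sp.lambdify(system.x, J.tolist(), "numpy")
    return lambda x: np.asarray(fn(*x), dtype=float)


def classify_jacobian(
    J: np.ndarray, B: np.ndarray, zero_tol_rel: float = ZERO_EIG_REL_TOL
) -> tuple[np.ndarray, np.ndarray, str]:
    """(full spectrum, T-restricted spectrum, label) for one Jacobian."""
    eig_full = np.linalg.eigvals(J)
    eig_red = np.linalg.eigvals(B.T @ J @ B)
    radius = max(1e-300, float(np.max(np.abs(eig_full))) if eig_full.size else 0.0)
    tol = zero_tol_rel * radius
    re = eig_red.real
    if np.any(re > tol):
        label = "unstable"
    elif np.all(re < -tol):
        label = "stable"
    else:
        label = "marginal"
    return eig_full, eig_red, label


def classify_steady_state(
    system: MassActionSystem,
    point: SteadyStatePoint,
    analysis: ConservationAnalysis | None = None,
    zero_tol_rel: float = ZERO_EIG_REL_TOL,
) -> StabilityReport:
    """Eigenvalue classification of one steady state (see module docstring)."""
    if analysis is None:
        analysis = analyze_network(system.network)
    J = _numeric_jacobian(system)(np.asarray(point.concentrations, dtype=float))
    B = subspace_basis(analysis)
    eig_full, eig_red, label = classify_jacobian(J, B, zero_tol_rel)
    return StabilityReport(
        point=point,
        eigenvalues=[complex(e) for e in eig_full],
        reduced_eigenvalues=[complex(e) for e in eig_red],
        label=label,
    )


def simulate_trajectory(
    system: MassActionSystem,
    x0,
    t_end: float,
    n_points: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate dx/dt = N v(k, x) from x0 with a stiff-capable solver.

    Returns ``(t, y)`` with ``y`` of shape (n_points, s).  Mass-action
    networks are routinely stiff (binding vs turnover time scales), so
    LSODA with the analytic Jacobian is used.  Conservation drift
    |w.x(t) - w.x0| stays at integration tolerance; tests assert it.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    rhs_fn = sp.lambdify(system.x, system.rhs, "numpy")
    jac_fn = _numeric_jacobian(system)
    sol = solve_ivp(
        lambda t, y: np.asarray(rhs_fn(*y), dtype=float),
        (0.0, float(t_end)),
        x0,
        method="LSODA",
        jac=lambda t, y: jac_fn(y),
        t_eval=np.linspace(0.0, float(t_end), n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y.T
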