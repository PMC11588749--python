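"""Crank-Nicolson half-step assembly and the Hines tree-tridiagonal solver.

A branched neuron discretizes to a sparse symmetric system that is
tridiagonal except for extra entries at branch points.  With compartments
numbered so that every parent precedes its children, the matrix is stored as
three vectors -- main diagonal D, off-diagonal U (U[i] couples node i to its
parent) and right-hand side B -- plus the parent-index vector p, and solved
exactly by one backward elimination (descending node order) and one forward
substitution.

The assembled system is the area-scaled, positive-definite form of the
half-step cable equation: multiplying each per-area row by the compartment's
lateral membrane area makes the axial couplings symmetric
(pi * a_iface^2 / (Ra * dx), in uS) so the two-vector storage applies, and
flipping the overall sign gives positive pivots.  Row scaling and negation
leave the solution unchanged; correctness is pinned to the dense oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import CompartmentGrid

__all__ = [
    "AxialCoefficients",
    "HinesSystem",
    "SingularSystemError",
    "precompute_axial",
    "assemble_system",
    "hines_solve",
    "dense_matrix",
    "dense_oracle",
    "advance_full_step",
]

_PIVOT_TOL = 1e-300

try:  # sequential sweeps are the only loops worth compiling
    from numba import njit as _njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


class SingularSystemError(ArithmeticError):
    """Zero pivot during Hines elimination (unreachable for dt > 0)."""


@dataclass
class AxialCoefficients:
    """Symmetric axial coupling conductance to the parent node, in uS.

    ``g_parent[i]`` is pi * a_iface^2 / (Ra_eff * dx_eff) for the boundary
    between node i and parent(i); zero at roots (sealed end: no axial current
    beyond terminal compartments).
    """

    g_parent: np.ndarray

    def __len__(self) -> int:
        return len(self.g_parent)


def precompute_axial(grid: CompartmentGrid) -> AxialCoefficients:
    """Axial coupling conductances for a grid, computed once.

    Within a section the boundary radius is the interface radius a_{i-1/2}
    and dx is uniform; across a junction the series sum of the two half
    compartments is used, R = Ra_i*dx_i/2 / (pi a^2) + Ra_p*dx_p/2 / (pi a^2),
    which reduces to pi a^2/(Ra dx) on a uniform grid and keeps reciprocity.
    """
    n = grid.n_nodes
    g = np.zeros(n)
    cm_per_um = 1e-4  # um -> cm
    for i in range(n):
        j = grid.parent[i]
        if j < 0:
            continue
        a_cm = grid.iface_radius[i] * cm_per_um
        area_x = np.pi * a_cm * a_cm  # cross-section, cm^2
        r_series = (
            grid.ra[i] * grid.dx[i] * cm_per_um / 2.0
            + grid.ra[j] * grid.dx[j] * cm_per_um / 2.0
        ) / area_x  # Ohm
        g[i] = 1e6 / r_series  # S -> uS
    return AxialCoefficients(g_parent=g)


@dataclass
class HinesSystem:
    """One neuron's (or forest's) half-step linear system.

    Convention: the full matrix A has A[i,i] = D[i] and
    A[i,p[i]] = A[p[i],i] = U[i]; ``hines_solve`` consumes D and B in place
    and leaves the half-step voltages in B.
    """

    p: np.ndarray
    D: np.ndarray
    U: np.ndarray
    B: np.ndarray

    @property
    def n(self) -> int:
        return len(self.D)


def assemble_system(
    grid: CompartmentGrid,
    axial: AxialCoefficients,
    g_tot: np.ndarray,
    gE_sum: np.ndarray,
    V_n: np.ndarray,
    I_inj: np.ndarray,
    dt: float,
    cap_nF: np.ndarray | None = None,
    parent: np.ndarray | None = None,
) -> HinesSystem:
    """Assemble the area-scaled half-step system for one time step.

    D[i] = sum of incident axial couplings + 2*c_i/dt + g_tot[i]   [uS]
    U[i] = -coupling(i, parent(i))                                  [uS]
    B[i] = (2*c_i/dt) * V_n[i] + gE_sum[i] + I_inj[i]               [nA]

    with c_i the compartment capacitance in nF.  ``g_tot``/``gE_sum`` are the
    per-node membrane (plus synaptic) conductance sums in uS and uS*mV = nA;
    ``I_inj`` is in nA and already lands on the right node (the point
    injection of the per-area formulation divides by 2*pi*a*dx, which the
    area scaling undoes).  Negative dt assembles the time-reversed half-step
    used by reversibility checks; dt must be nonzero.
    """
    if dt == 0 or not np.isfinite(dt):
        raise ValueError("dt must be nonzero and finite")
    p = grid.parent if parent is None else parent
    n = len(p)
    for name, arr in (("g_tot", g_tot), ("gE_sum", gE_sum), ("V_n", V_n), ("I_inj", I_inj)):
        if len(arr) != n:
            raise ValueError(f"{name} has length {len(arr)}, expected {n}")
    c = grid.cap_nF if cap_nF is None else cap_nF
    gax = axial.g_parent
    dtype = np.result_type(V_n, g_tot)
    two_c_dt = (2.0 / dt) * np.asarray(c, dtype=dtype)

    couple_sum = gax.astype(dtype, copy=True)
    np.add.at(couple_sum, p[p >= 0], gax[p >= 0])
    D = couple_sum + two_c_dt + np.asarray(g_tot, dtype=dtype)
    U = -gax.astype(dtype)
    B = two_c_dt * np.asarray(V_n, dtype=dtype) + np.asarray(gE_sum, dtype=dtype) \
        + np.asarray(I_inj, dtype=dtype)
    return HinesSystem(p=np.asarray(p, dtype=np.int64), D=D, U=U, B=B)


@_njit(cache=True)
def _sweeps(p, D, U, B):  # pragma: no cover - exercised via hines_solve
    n = D.shape[0]
    for i in range(n - 1, 0, -1):
        if p[i] < 0:
            continue
        if abs(D[i]) < _PIVOT_TOL:
            return i
        f = U[i] / D[i]
        D[p[i]] -= f * U[i]
        B[p[i]] -= f * B[i]
    for i in range(n):
        if p[i] >= 0:
            continue
        if abs(D[i]) < _PIVOT_TOL:
            return i
        B[i] = B[i] / D[i]
    for i in range(1, n):
        if p[i] >= 0:
            if abs(D[i]) < _PIVOT_TOL:
                return i
            B[i] = (B[i] - U[i] * B[p[i]]) / D[i]
    return -1


def _sweeps_py(p, D, U, B):
    n = D.shape[0]
    for i in range(n - 1, 0, -1):
        if p[i] < 0:
            continue
        if abs(D[i]) < _PIVOT_TOL:
            return i
        f = U[i] / D[i]
        D[p[i]] -= f * U[i]
        B[p[i]] -= f * B[i]
    for i in range(n):
        if p[i] < 0:
            if abs(D[i]) < _PIVOT_TOL:
                return i
            B[i] = B[i] / D[i]
        else:
            if abs(D[i]) < _PIVOT_TOL:
                return i
            B[i] = (B[i] - U[i] * B[p[i]]) / D[i]
    return -1


def hines_solve(system: HinesSystem, use_numba: bool = True) -> np.ndarray:
    """Solve the Hines system in place; returns (and leaves in B) the voltages.

    Backward elimination runs from the last node down to 1 (valid for any
    Hines ordering, branched or not, and for forests with several roots);
    forward substitution runs in ascending order from each root.
    """
    D, U, B = system.D, system.U, system.B
    p = system.p
    if use_numba and HAVE_NUMBA and D.dtype in (np.float32, np.float64):
        bad = _sweeps(p, D, U, B)
    else:
        bad = _sweeps_py(p, D, U, B)
    if bad >= 0:
        raise SingularSystemError(f"zero pivot at node {bad}")
    return B


def dense_matrix(system: HinesSystem) -> np.ndarray:
    """Scatter p/D/U into the full symmetric matrix (for tests and inspection)."""
    n = system.n
    A = np.zeros((n, n), dtype=np.result_type(system.D, np.float64))
    A[np.arange(n), np.arange(n)] = system.D
    for i in range(n):
        j = system.p[i]
        if j >= 0:
            A[i, j] = system.U[i]
            A[j, i] = system.U[i]
    return A


def dense_oracle(system: HinesSystem) -> np.ndarray:
    """Independent dense-factorization solve of the same system (test oracle)."""
    import scipy.linalg

    return scipy.linalg.solve(dense_matrix(system), np.asarray(system.B, dtype=float))


def advance_full_step(V_half: np.ndarray, V_n: np.ndarray) -> np.ndarray:
    """Crank-Nicolson extrapolation V_{n+1} = 2*V^{n+1/2} - V_n."""
    if len(V_half) != len(V_n):
        raise ValueError("V_half and V_n must have equal length")
    return 2.0 * V_half - V_n
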