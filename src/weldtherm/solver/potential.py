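"""Quasi-static electric potential on the weld grid, and Joule heating.

Solves the discrete conservation law ``div(sigma grad V) = 0`` over the
conducting cells with Dirichlet values on the electrodes: the upper electrode
is the excitation source (``V = v_applied``), the lower electrode the ground
(``V = 0``). Faces towards void/air carry zero normal current.

The linear system (SPD) is solved with conjugate gradients preconditioned by
a cached sparse LU factorisation; on the first solve the preconditioner is
exact, so the result is direct-solver accurate, and later solves with a
slowly drifting sigma field converge in a handful of iterations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Region, WeldGeometry
from ._fv import face_pairs, pair_halfweights, face_conductance

__all__ = ["SolverError", "PotentialSolver", "solve_potential", "joule_power"]


class SolverError(RuntimeError):
    """Linear solver failed to converge."""


class _FrozenLU:
    """Direct solves via a cached LU, kept fresh by iterative refinement.

    The LU of a recent system matrix is reused while the matrix drifts
    slowly (sigma(T) changes a little per step); each solve runs iterative
    refinement ``x += LU^-1 (b - A x)`` until the true residual meets rtol.
    When refinement gets slow the factorisation is refreshed at the current
    matrix, restoring direct-solver accuracy.
    """

    def __init__(self, rtol: float = 1e-10, refresh_iters: int = 6, max_iters: int = 60):
        self.rtol = rtol
        self.refresh_iters = refresh_iters
        self.max_iters = max_iters
        self._lu = None

    def _refine(self, A, b, x, bnorm: float):
        for it in range(self.max_iters):
            r = b - A @ x
            if np.linalg.norm(r) <= self.rtol * bnorm:
                return x, it
            x = x + self._lu.solve(r)
        return x, self.max_iters

    def solve(self, A: sp.csr_matrix, b: np.ndarray, x0=None) -> np.ndarray:
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            return np.zeros_like(b)
        if self._lu is None:
            self._lu = spla.splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        x = x0 if x0 is not None else self._lu.solve(b)
        x, iters = self._refine(A, b, x, bnorm)
        if iters >= self.refresh_iters:
            # matrix drifted too far from the factorised one: refactor
            self._lu = spla.splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
            x = self._lu.solve(b)
            x, iters = self._refine(A, b, x, bnorm)
            if iters >= self.max_iters:
                res = float(np.linalg.norm(b - A @ x)) / bnorm
                raise SolverError(
                    f"linear solve failed to reach rtol={self.rtol:g} "
                    f"(relative residual {res:g})"
                )
        return x


# backwards-compatible alias used by older call sites
_PrecondCG = _FrozenLU


class PotentialSolver:
    """Reusable potential solver bound to one geometry.

    Precomputes the face topology once; each :meth:`solve` call assembles only
    the conductance values for the current sigma field.
    """

    def __init__(self, geom: WeldGeometry, rtol: float = 1e-10):
        self.geom = geom
        self.rtol = rtol
        labels = geom.labels.ravel()
        active = labels != Region.VOID
        unknown = labels == Region.TISSUE
        self.unknown_flat = np.flatnonzero(unknown)
        self.n_unknown = self.unknown_flat.size
        num = -np.ones(labels.size, dtype=np.int64)
        num[self.unknown_flat] = np.arange(self.n_unknown)

        a_all, b_all, wa_all, wb_all = [], [], [], []
        for axis, (a, b) in enumerate(face_pairs(active.reshape(geom.shape))):
            a_all.append(a)
            b_all.append(b)
            wa, wb = pair_halfweights(geom, a, b, axis)
            wa_all.append(np.broadcast_to(wa, a.shape))
            wb_all.append(np.broadcast_to(wb, a.shape))
        self.fa = np.concatenate(a_all)
        self.fb = np.concatenate(b_all)
        self.fwa = np.concatenate(wa_all)
        self.fwb = np.concatenate(wb_all)

        ua, ub = num[self.fa], num[self.fb]
        self.ua, self.ub = ua, ub
        is_src_a = labels[self.fa] == Region.UPPER_ELECTRODE
        is_src_b = labels[self.fb] == Region.UPPER_ELECTRODE
        # Dirichlet boundary value per face endpoint, as a multiple of v_applied
        self.dval_a = np.where(is_src_a, 1.0, 0.0)
        self.dval_b = np.where(is_src_b, 1.0, 0.0)
        self.m_uu = (ua >= 0) & (ub >= 0)
        self.m_ud = (ua >= 0) & (ub < 0)
        self.m_du = (ua < 0) & (ub >= 0)
        self.src_face = is_src_a | is_src_b
        # precomputed assembly structure (values change, indices do not)
        n = self.n_unknown
        self._sel_a = np.flatnonzero(ua >= 0)
        self._sel_b = np.flatnonzero(ub >= 0)
        self._sel_ud = np.flatnonzero(self.m_ud)
        self._sel_du = np.flatnonzero(self.m_du)
        self._sel_uu = np.flatnonzero(self.m_uu)
        self._rows = np.concatenate([np.arange(n), ua[self._sel_uu], ub[self._sel_uu]])
        self._cols = np.concatenate([np.arange(n), ub[self._sel_uu], ua[self._sel_uu]])
        self._cg = _FrozenLU(rtol=rtol)
        self._last_x: np.ndarray | None = None

    # -- assembly ---------------------------------------------------------
    def _conductances(self, sigma_flat: np.ndarray) -> np.ndarray:
        return face_conductance(
            self.fwa, self.fwb, sigma_flat[self.fa], sigma_flat[self.fb]
        )

    def solve(self, sigma_cell: np.ndarray, v_applied: float) -> np.ndarray:
        """Potential field (V) on the full grid for the given sigma field.

        ``sigma_cell`` is a full-grid array (S/m); values on void cells are
        ignored. Returns a full-grid array with the Dirichlet values imposed
        exactly on the electrodes and 0 on void cells.
        """
        labels = self.geom.labels.ravel()
        V = np.zeros(labels.size)
        V[labels == Region.UPPER_ELECTRODE] = v_applied
        if v_applied == 0.0 or self.n_unknown == 0:
            return V.reshape(self.geom.shape)
        sigma_flat = np.asarray(sigma_cell, dtype=float).ravel()
        if np.any(sigma_flat[labels != Region.VOID] <= 0):
            raise SolverError("sigma must be > 0 on all conducting cells")
        G = self._conductances(sigma_flat)

        n = self.n_unknown
        diag = np.bincount(self.ua[self._sel_a], weights=G[self._sel_a], minlength=n)
        diag += np.bincount(self.ub[self._sel_b], weights=G[self._sel_b], minlength=n)
        rhs = np.bincount(
            self.ua[self._sel_ud],
            weights=(G * self.dval_b)[self._sel_ud] * v_applied,
            minlength=n,
        )
        rhs += np.bincount(
            self.ub[self._sel_du],
            weights=(G * self.dval_a)[self._sel_du] * v_applied,
            minlength=n,
        )
        g_uu = G[self._sel_uu]
        data = np.concatenate([diag, -g_uu, -g_uu])
        A = sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsr()

        x0 = self._last_x if self._last_x is not None and self._last_x.size == n else None
        x = self._cg.solve(A, rhs, x0=x0)
        self._last_x = x
        V[self.unknown_flat] = x
        return V.reshape(self.geom.shape)

    # -- derived quantities ----------------------------------------------
    def joule_power(self, V: np.ndarray, sigma_cell: np.ndarray) -> np.ndarray:
        """Volumetric Joule power density q_g (W/m^3) per cell, >= 0.

        Per-face dissipation ``G * dV^2`` is attributed to the two adjacent
        cells in proportion to their resistive share, so the grid total equals
        ``v_applied * I`` identically and the uniform-field case reduces to
        ``sigma * |grad V|^2`` per cell.
        """
        sigma_flat = np.asarray(sigma_cell, dtype=float).ravel()
        v_flat = np.asarray(V, dtype=float).ravel()
        G = self._conductances(sigma_flat)
        dv = v_flat[self.fa] - v_flat[self.fb]
        p_face = G * dv * dv
        # split per-face dissipation by resistive share of each half-cell
        r_a = self.fwa / sigma_flat[self.fa]
        r_b = self.fwb / sigma_flat[self.fb]
        share_a = r_a / (r_a + r_b)
        power = np.zeros(v_flat.size)
        np.add.at(power, self.fa, p_face * share_a)
        np.add.at(power, self.fb, p_face * (1.0 - share_a))
        return (power / self.geom.volume_flat()).reshape(self.geom.shape)

    def boundary_current(self, V: np.ndarray, sigma_cell: np.ndarray) -> float:
        """Total current (A) flowing out of the source electrode."""
        sigma_flat = np.asarray(sigma_cell, dtype=float).ravel()
        v_flat = np.asarray(V, dtype=float).ravel()
        G = self._conductances(sigma_flat)
        labels = self.geom.labels.ravel()
        a_src = labels[self.fa] == Region.UPPER_ELECTRODE
        b_src = labels[self.fb] == Region.UPPER_ELECTRODE
        m = a_src ^ b_src
        sign = np.where(a_src[m], 1.0, -1.0)
        dv = v_flat[self.fa[m]] - v_flat[self.fb[m]]
        return float(np.sum(sign * G[m] * dv))


def solve_potential(
    geom: WeldGeometry, sigma_cell: np.ndarray, v_applied: float, rtol: float = 1e-10
) -> np.ndarray:
    """One-shot potential solve (see :class:`PotentialSolver.solve`)."""
    return PotentialSolver(geom, rtol=rtol).solve(sigma_cell, v_applied)


def joule_power(geom: WeldGeometry, V: np.ndarray, sigma_cell: np.ndarray) -> np.ndarray:
    """One-shot Joule power density field (see :class:`PotentialSolver.joule_power`)."""
    return PotentialSolver(geom).joule_power(V, sigma_cell)
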