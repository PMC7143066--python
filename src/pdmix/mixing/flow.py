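"""Steady incompressible flow in the channel footprint.

Finite-volume discretization on a MAC staggered grid (u on vertical faces,
v on horizontal faces, p at cell centres).  The momentum balance is solved
as creeping (Stokes) flow by default — the device operates at Re ~ 10-20 —
with an optional Picard-linearized first-order-upwind convection term.  The
coupled saddle-point system is solved with a direct sparse factorization, so
discrete mass conservation holds to machine precision.

Boundary conditions: prescribed velocity on the inlet plane (two equal-width
arms, speeds from the arm flow rates over the arm cross-section), no-slip on
walls and obstacles, zero-gradient velocity with a fixed pressure datum on
the outlet plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import spsolve

from ..design import split_flows
from .geometry import ChannelGeometry, Grid

__all__ = ["FlowField", "NonConvergenceError", "inlet_speeds", "solve_flow"]

ML_H_TO_M3_S = 1e-6 / 3600.0

# face states
_UNKNOWN, _VALUE, _MIRROR_NEG, _MIRROR_POS = 0, 1, 2, 3


class NonConvergenceError(RuntimeError):
    """Picard iteration failed to reach the requested tolerance."""

    def __init__(self, msg: str, residuals: list[float]):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class FlowField:
    """Steady velocity/pressure solution on a :class:`Grid`.

    ``u`` has shape (nx+1, ny) (x-faces), ``v`` (nx, ny+1) (y-faces), ``p``
    (nx, ny) with NaN in solid cells.  Flow rates are per metre of depth
    times the physical depth, i.e. true volumetric rates.
    """

    grid: Grid
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    tfr_ml_h: float
    frr: float
    q_in: float
    q_out: float
    meta: dict = field(default_factory=dict)

    @property
    def mass_imbalance(self) -> float:
        """|inflow - outflow| / inflow."""
        return abs(self.q_in - self.q_out) / abs(self.q_in)

    def face_fluxes(self) -> tuple[np.ndarray, np.ndarray]:
        """Volumetric fluxes per unit depth through x- and y-faces."""
        return self.u * self.grid.h, self.v * self.grid.h


def inlet_speeds(tfr_ml_h: float, frr: float,
                 geom: ChannelGeometry) -> tuple[float, float]:
    """(organic, aqueous) inlet arm speeds in m/s.

    Each arm occupies half the channel width at the merge; the organic
    stream (ethanol + lipids) enters the bottom arm.
    """
    flows = split_flows(tfr_ml_h, frr)
    arm_area = (geom.width_um * 1e-6 / 2.0) * (geom.depth_um * 1e-6)
    u_org = flows.q_os * ML_H_TO_M3_S / arm_area
    u_aq = flows.q_as * ML_H_TO_M3_S / arm_area
    return u_org, u_aq


def _inlet_profile(grid: Grid, tfr_ml_h: float, frr: float) -> np.ndarray:
    u_org, u_aq = inlet_speeds(tfr_ml_h, frr, grid.geom)
    prof = np.empty(grid.ny)
    half = grid.ny // 2
    prof[:half] = u_org   # bottom arm: organic
    prof[half:] = u_aq    # top arm: aqueous
    return prof


def _face_states(grid: Grid, u_in: np.ndarray):
    """Classify every u- and v-face and number the unknowns.

    Returns (u_state, u_idx, u_val, v_state, v_idx, v_val, p_idx, n_unknowns).
    States: unknown / prescribed value / mirror across a wall.
    """
    nx, ny = grid.nx, grid.ny
    fluid = grid.fluid

    u_state = np.full((nx + 1, ny), _VALUE, dtype=np.int8)
    u_val = np.zeros((nx + 1, ny))
    u_state[1:nx] = np.where(fluid[:-1] & fluid[1:], _UNKNOWN, _VALUE)
    u_state[0] = _VALUE
    u_val[0] = np.where(fluid[0], u_in, 0.0)
    u_state[nx] = np.where(fluid[-1], _UNKNOWN, _VALUE)
    # faces buried between two solid cells act as wall mirrors for
    # tangential neighbours
    buried_u = np.zeros((nx + 1, ny), dtype=bool)
    buried_u[1:nx] = (~fluid[:-1]) & (~fluid[1:])

    v_state = np.full((nx, ny + 1), _VALUE, dtype=np.int8)
    v_val = np.zeros((nx, ny + 1))
    v_state[:, 1:ny] = np.where(fluid[:, :-1] & fluid[:, 1:], _UNKNOWN, _VALUE)
    buried_v = np.zeros((nx, ny + 1), dtype=bool)
    buried_v[:, 1:ny] = (~fluid[:, :-1]) & (~fluid[:, 1:])

    u_idx = -np.ones((nx + 1, ny), dtype=np.int64)
    v_idx = -np.ones((nx, ny + 1), dtype=np.int64)
    p_idx = -np.ones((nx, ny), dtype=np.int64)
    n = 0
    iu, ju = np.nonzero(u_state == _UNKNOWN)
    u_idx[iu, ju] = np.arange(n, n + len(iu)); n += len(iu)
    iv, jv = np.nonzero(v_state == _UNKNOWN)
    v_idx[iv, jv] = np.arange(n, n + len(iv)); n += len(iv)
    ip, jp = np.nonzero(fluid)
    p_idx[ip, jp] = np.arange(n, n + len(ip)); n += len(ip)
    return (u_state, u_idx, u_val, buried_u,
            v_state, v_idx, v_val, buried_v, p_idx, n)


def solve_flow(
    grid: Grid,
    tfr_ml_h: float,
    frr: float,
    mu: float = 1.0e-3,
    rho: float = 1000.0,
    advection: bool = False,
    max_picard: int = 30,
    picard_tol: float = 1.0e-6,
    relax: float = 0.7,
) -> FlowField:
    """Solve steady flow at the given total flow rate and flow-rate ratio.

    ``mu``/``rho`` are the (reference-composition) fluid properties in SI
    units.  With ``advection=True`` the convective term is Picard-iterated
    from the Stokes solution; failure to converge raises
    :class:`NonConvergenceError` carrying the residual history.
    """
    if grid.ny % 2:
        raise ValueError("need an even number of cells across for the two arms")
    nx, ny, h = grid.nx, grid.ny, grid.h
    u_in = _inlet_profile(grid, tfr_ml_h, frr)
    (u_state, u_idx, u_val, buried_u,
     v_state, v_idx, v_val, buried_v, p_idx, n_unk) = _face_states(grid, u_in)
    # momentum rows are scaled by h^2/mu and the pressure unknown is
    # p_hat = p * h / mu, so every block of the saddle matrix is O(1);
    # this keeps the direct solve's mass-conservation error near machine
    # precision.  a is the scaled viscous coefficient, cf the scaled
    # convective prefactor (a cell Reynolds number per unit velocity).
    a = 1.0
    cf = rho * h / mu

    def build(u_star: np.ndarray | None, v_star: np.ndarray | None):
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        rhs = np.zeros(n_unk)

        def add(r, c, v):
            rows.append(r); cols.append(c); vals.append(v)

        def u_face(i, j):
            """State lookup with ghost conventions for u tangential walls."""
            if j < 0 or j >= ny:
                return _MIRROR_NEG, 0.0, -1
            if i > nx:
                return _MIRROR_POS, 0.0, -1
            if u_state[i, j] == _UNKNOWN:
                return _UNKNOWN, 0.0, u_idx[i, j]
            if buried_u[i, j]:
                return _MIRROR_NEG, 0.0, -1
            return _VALUE, u_val[i, j], -1

        def v_face(i, j):
            if i < 0:
                return _MIRROR_NEG, 0.0, -1   # inlet plane: v = 0
            if i >= nx:
                return _MIRROR_POS, 0.0, -1   # outlet: zero gradient
            if v_state[i, j] == _UNKNOWN:
                return _UNKNOWN, 0.0, v_idx[i, j]
            if buried_v[i, j]:
                return _MIRROR_NEG, 0.0, -1
            return _VALUE, v_val[i, j], -1

        def couple(row, state, val, idx, coeff, diag_ref):
            """Add ``coeff * neighbour`` to a momentum row."""
            if state == _UNKNOWN:
                add(row, idx, coeff)
            elif state == _VALUE:
                rhs[row] -= coeff * val
            elif state == _MIRROR_NEG:
                add(row, diag_ref, -coeff)
            else:  # zero-gradient ghost
                add(row, diag_ref, coeff)

        # u-momentum
        iu, ju = np.nonzero(u_state == _UNKNOWN)
        for i, j in zip(iu, ju):
            r = u_idx[i, j]
            add(r, r, -4.0 * a)
            for st in (u_face(i - 1, j), u_face(i + 1, j),
                       u_face(i, j - 1), u_face(i, j + 1)):
                couple(r, st[0], st[1], st[2], a, r)
            # pressure gradient
            if i < nx:
                add(r, p_idx[i, j], -1.0)
            if i > 0 and p_idx[i - 1, j] >= 0:
                add(r, p_idx[i - 1, j], 1.0)
            if u_star is not None:
                ua = u_star[i, j]
                va = 0.25 * (v_star[min(i, nx - 1), j] + v_star[min(i, nx - 1), j + 1]
                             + v_star[max(i - 1, 0), j] + v_star[max(i - 1, 0), j + 1])
                # upwind d(u)/dx
                if ua >= 0:
                    stL = u_face(i - 1, j)
                    add(r, r, -cf * ua)
                    couple(r, stL[0], stL[1], stL[2], cf * ua, r)
                else:
                    stR = u_face(i + 1, j)
                    add(r, r, cf * ua)
                    couple(r, stR[0], stR[1], stR[2], -cf * ua, r)
                if va >= 0:
                    stB = u_face(i, j - 1)
                    add(r, r, -cf * va)
                    couple(r, stB[0], stB[1], stB[2], cf * va, r)
                else:
                    stT = u_face(i, j + 1)
                    add(r, r, cf * va)
                    couple(r, stT[0], stT[1], stT[2], -cf * va, r)

        # v-momentum
        iv, jv = np.nonzero(v_state == _UNKNOWN)
        for i, j in zip(iv, jv):
            r = v_idx[i, j]
            add(r, r, -4.0 * a)
            for st in (v_face(i - 1, j), v_face(i + 1, j),
                       v_face(i, j - 1), v_face(i, j + 1)):
                couple(r, st[0], st[1], st[2], a, r)
            add(r, p_idx[i, j], -1.0)
            if p_idx[i, j - 1] >= 0:
                add(r, p_idx[i, j - 1], 1.0)
            if u_star is not None:
                va = v_star[i, j]
                ua = 0.25 * (u_star[i, min(j, ny - 1)] + u_star[i + 1, min(j, ny - 1)]
                             + u_star[i, max(j - 1, 0)] + u_star[i + 1, max(j - 1, 0)])
                if ua >= 0:
                    stL = v_face(i - 1, j)
                    add(r, r, -cf * ua)
                    couple(r, stL[0], stL[1], stL[2], cf * ua, r)
                else:
                    stR = v_face(i + 1, j)
                    add(r, r, cf * ua)
                    couple(r, stR[0], stR[1], stR[2], -cf * ua, r)
                if va >= 0:
                    stB = v_face(i, j - 1)
                    add(r, r, -cf * va)
                    couple(r, stB[0], stB[1], stB[2], cf * va, r)
                else:
                    stT = v_face(i, j + 1)
                    add(r, r, cf * va)
                    couple(r, stT[0], stT[1], stT[2], -cf * va, r)

        # continuity
        ip, jp = np.nonzero(grid.fluid)
        for i, j in zip(ip, jp):
            r = p_idx[i, j]
            for sgn, (st, val, idx) in (
                (1.0, u_face(i + 1, j)), (-1.0, u_face(i, j)),
            ):
                if st == _UNKNOWN:
                    add(r, idx, sgn)
                elif st == _VALUE:
                    rhs[r] -= sgn * val
            for sgn, jj in ((1.0, j + 1), (-1.0, j)):
                if v_state[i, jj] == _UNKNOWN:
                    add(r, v_idx[i, jj], sgn)
                else:
                    rhs[r] -= sgn * v_val[i, jj]
        A = csc_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))
        return A, rhs

    def unpack(sol: np.ndarray):
        u = np.where(u_idx >= 0, sol[np.clip(u_idx, 0, None)], u_val)
        v = np.where(v_idx >= 0, sol[np.clip(v_idx, 0, None)], v_val)
        p = np.where(p_idx >= 0, sol[np.clip(p_idx, 0, None)], np.nan) * (mu / h)
        return u, v, p

    A, rhs = build(None, None)
    sol = spsolve(A, rhs)
    u, v, p = unpack(sol)
    residuals: list[float] = []
    converged = True
    if advection:
        converged = False
        for _ in range(max_picard):
            u_old = u.copy()
            A, rhs = build(u, v)
            sol = spsolve(A, rhs)
            u_new, v_new, p = unpack(sol)
            u = relax * u_new + (1 - relax) * u
            v = relax * v_new + (1 - relax) * v
            scale = max(np.max(np.abs(u)), 1e-300)
            res = float(np.max(np.abs(u - u_old)) / scale)
            residuals.append(res)
            if res < picard_tol:
                converged = True
                break
        if not converged:
            raise NonConvergenceError(
                f"Picard convection loop stalled at residual {residuals[-1]:.2e}",
                residuals,
            )
    depth = grid.geom.depth_um * 1e-6
    q_in = float(np.sum(u[0] * h) * depth)
    q_out = float(np.sum(u[nx] * h) * depth)
    return FlowField(
        grid=grid, u=u, v=v, p=p, tfr_ml_h=tfr_ml_h, frr=frr,
        q_in=q_in, q_out=q_out,
        meta={"mu": mu, "rho": rho, "advection": advection,
              "picard_residuals": residuals, "converged": converged},
    )
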