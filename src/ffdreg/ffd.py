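"""Trivariate Bernstein free-form deformation (FFD) and its inverse problem.

A deformation is parameterised by a lattice of control points spanning a
parallelepiped.  Any embedded point is written as a tensor-product Bernstein
combination of the control points; stacking the weight rows for a point set S
gives the deformation matrix B with S = B·P.  Moving the control points to P*
deforms the embedded set to S* = B·P*.  The *inverse* problem — recover P*
from observed deformed points S* — is an overdetermined linear least-squares
problem solved either by pseudoinverse or by damped (Levenberg–Marquardt)
iteration, optionally ridge-regularised toward the rest lattice so that
control points without surface support stay put.

Flat control-point index layout: ``flat = (i*(m+1) + j)*(n+1) + k`` — k varies
fastest, then j, then i.  This layout is fixed; every matrix and serialised
array in the package uses it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .errors import OutOfSupportError, SolverError

__all__ = [
    "FFDGrid",
    "DeformationMatrix",
    "ControlDisplacementSolution",
    "init_grid",
    "local_coords",
    "bernstein_row",
    "build_deformation_matrix",
    "forward_deform",
    "inverse_solve",
    "interpolate_displacement",
    "displacement_jacobian",
]

_SUPPORT_TOL = 1e-9


@dataclass
class FFDGrid:
    """Control lattice of an FFD.

    Fields
    ------
    x0 : (3,) world mm — origin of the local frame.
    S, T, U : (3,) axis vectors in mm spanning the grid box (need not be
        orthogonal, must be linearly independent).
    l, m, n : subdivision counts per axis; the lattice has
        (l+1)(m+1)(n+1) control points.
    P : ((l+1)(m+1)(n+1), 3) control-point positions.  At rest,
        ``p_ijk = x0 + (i/l)S + (j/m)T + (k/n)U``.
    """

    x0: np.ndarray
    S: np.ndarray
    T: np.ndarray
    U: np.ndarray
    l: int
    m: int
    n: int
    P: np.ndarray = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float).reshape(3)
        self.S = np.asarray(self.S, dtype=float).reshape(3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        self.U = np.asarray(self.U, dtype=float).reshape(3)
        if min(self.l, self.m, self.n) < 1:
            raise ValueError("grid subdivisions l, m, n must all be >= 1")
        M = np.column_stack([self.S, self.T, self.U])
        if abs(np.linalg.det(M)) < 1e-12:
            raise np.linalg.LinAlgError("grid axis vectors are linearly dependent")
        if self.P is None:
            self.P = self.rest_points()
        else:
            self.P = np.asarray(self.P, dtype=float).reshape(self.n_controls, 3)

    @property
    def n_controls(self) -> int:
        return (self.l + 1) * (self.m + 1) * (self.n + 1)

    def rest_points(self) -> np.ndarray:
        """Rest lattice p_ijk = x0 + (i/l)S + (j/m)T + (k/n)U, flat k-fastest."""
        i, j, k = np.meshgrid(
            np.arange(self.l + 1), np.arange(self.m + 1), np.arange(self.n + 1),
            indexing="ij",
        )
        pts = (
            self.x0
            + (i.ravel()[:, None] / self.l) * self.S
            + (j.ravel()[:, None] / self.m) * self.T
            + (k.ravel()[:, None] / self.n) * self.U
        )
        return pts

    def flat_index(self, i, j, k) -> int:
        return (i * (self.m + 1) + j) * (self.n + 1) + k

    def to_json(self, path) -> None:
        obj = {
            "x0": self.x0.tolist(), "S": self.S.tolist(), "T": self.T.tolist(),
            "U": self.U.tolist(), "l": self.l, "m": self.m, "n": self.n,
            "P": self.P.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FFDGrid":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["x0"], obj["S"], obj["T"], obj["U"],
                   obj["l"], obj["m"], obj["n"], np.array(obj["P"]))


@dataclass
class DeformationMatrix:
    """Bernstein weight matrix B, one row per embedded point.

    Rows are partitions of unity (sum to 1) for points inside the grid and all
    entries lie in [0, 1].  Column layout matches :meth:`FFDGrid.flat_index`.
    """

    B: np.ndarray
    grid: FFDGrid = None

    @property
    def shape(self):
        return self.B.shape


@dataclass
class ControlDisplacementSolution:
    """Result of the inverse FFD solve."""

    P_star: np.ndarray
    residual_rms: float
    method: str
    regularization: float
    n_iter: int = 0
    converged: bool = True
    trace: list = field(default_factory=list)


def init_grid(lower, upper, l: int, m: int, n: int, margin: float = 0.1) -> FFDGrid:
    """Axis-aligned grid over a bounding box inflated by ``margin`` per axis.

    ``margin`` is a fraction of the box extent added on *each* side, so the
    grid extent is ``(1 + 2*margin)`` times the box extent per axis.
    """
    lower = np.asarray(lower, dtype=float).reshape(3)
    upper = np.asarray(upper, dtype=float).reshape(3)
    extent = upper - lower
    if np.any(extent <= 0):
        raise ValueError(f"degenerate bounding box: extent {extent}")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    pad = margin * extent
    x0 = lower - pad
    span = extent + 2 * pad
    return FFDGrid(x0, [span[0], 0, 0], [0, span[1], 0], [0, 0, span[2]], l, m, n)


def local_coords(grid: FFDGrid, x) -> np.ndarray:
    """Local coordinates (chi, psi, omega) of world points x (…, 3).

    chi = T×U·(x−x0) / T×U·S, and cyclically; values outside [0, 1]^3 indicate
    points outside the grid support.
    """
    x = np.asarray(x, dtype=float)
    d = x - grid.x0
    txu = np.cross(grid.T, grid.U)
    sxu = np.cross(grid.S, grid.U)
    sxt = np.cross(grid.S, grid.T)
    chi = d @ txu / (txu @ grid.S)
    psi = d @ sxu / (sxu @ grid.T)
    omega = d @ sxt / (sxt @ grid.U)
    return np.stack([chi, psi, omega], axis=-1)


def _bernstein_basis(deg: int, t: np.ndarray) -> np.ndarray:
    """All Bernstein polynomials of degree ``deg`` at parameters t -> (len(t), deg+1)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
    i = np.arange(deg + 1)[None, :]
    return comb(deg, i) * t ** i * (1.0 - t) ** (deg - i)


def _bernstein_basis_deriv(deg: int, t: np.ndarray) -> np.ndarray:
    """d/dt of the Bernstein basis: deg*(B_{deg-1,i-1} - B_{deg-1,i})."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lower = _bernstein_basis(deg - 1, t) if deg >= 1 else np.zeros((t.size, 1))
    out = np.zeros((t.size, deg + 1))
    out[:, 1:] += deg * lower
    out[:, :-1] -= deg * lower
    return out


def _rows(grid: FFDGrid, x, check_support: bool = True):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    loc = local_coords(grid, x)
    if check_support:
        bad = np.any((loc < -_SUPPORT_TOL) | (loc > 1 + _SUPPORT_TOL), axis=1)
        if bad.any():
            raise OutOfSupportError(
                f"{bad.sum()} point(s) outside the FFD grid support",
                offenders=np.nonzero(bad)[0],
            )
    loc = np.clip(loc, 0.0, 1.0)
    Bi = _bernstein_basis(grid.l, loc[:, 0])
    Bj = _bernstein_basis(grid.m, loc[:, 1])
    Bk = _bernstein_basis(grid.n, loc[:, 2])
    rows = np.einsum("pi,pj,pk->pijk", Bi, Bj, Bk).reshape(x.shape[0], -1)
    return rows, loc


def bernstein_row(grid: FFDGrid, x) -> np.ndarray:
    """Tensor-product Bernstein weight row(s) for world point(s) x.

    Weight of control (i, j, k) is
    ``C(l,i)C(m,j)C(n,k) (1−chi)^{l−i} chi^i (1−psi)^{m−j} psi^j (1−omega)^{n−k} omega^k``;
    each row sums to 1.  Raises :class:`OutOfSupportError` for points outside
    the grid.
    """
    rows, _ = _rows(grid, x)
    return rows[0] if np.asarray(x).ndim == 1 else rows


def build_deformation_matrix(grid: FFDGrid, points: np.ndarray) -> DeformationMatrix:
    """Stack Bernstein rows for an N×3 point set into the N×K matrix B."""
    rows, _ = _rows(grid, points)
    return DeformationMatrix(rows, grid)


def forward_deform(B: DeformationMatrix | np.ndarray, P_star: np.ndarray) -> np.ndarray:
    """Deformed point set S* = B·P*."""
    mat = B.B if isinstance(B, DeformationMatrix) else np.asarray(B)
    P_star = np.asarray(P_star, dtype=float)
    if mat.shape[1] != P_star.shape[0]:
        raise ValueError(f"shape mismatch: B is {mat.shape}, P* is {P_star.shape}")
    return mat @ P_star


def inverse_solve(
    B: DeformationMatrix | np.ndarray,
    S_target: np.ndarray,
    P_rest: np.ndarray | None = None,
    method: str = "lm",
    lam: float | None = None,
    max_iter: int = 200,
) -> ControlDisplacementSolution:
    """Recover displaced control points P* from deformed surface points.

    Minimises ``||B·P − S*||^2 + lam ||P − P_rest||^2``.  The ridge term pins
    control points with little surface support (near-zero B columns) to the
    rest lattice; ``lam`` defaults to ``1e-6 * N`` where N is the number of
    surface points, and to plain least squares when ``P_rest`` is None.

    method="pinv" solves the (regularised) normal equations directly —
    minimum-norm least squares when lam = 0; method="lm" runs damped
    Levenberg–Marquardt iteration on the same objective with adaptive damping
    (×10 on a rejected step, ÷10 on an accepted one).  The two agree on
    well-conditioned instances as lam → 0.
    """
    mat = np.asarray(B.B if isinstance(B, DeformationMatrix) else B, dtype=float)
    S_target = np.asarray(S_target, dtype=float)
    N, K = mat.shape
    if lam is None:
        lam = 1e-6 * N if P_rest is not None else 0.0
    if lam < 0:
        raise ValueError("regularization weight must be >= 0")
    if lam > 0 and P_rest is None:
        raise ValueError("P_rest is required for a regularized solve")

    if method == "pinv":
        if lam == 0:
            if N < K:
                warnings.warn(
                    f"underdetermined system ({N} points, {K} controls): "
                    "returning the minimum-norm solution"
                )
            P_star, _, rank, _ = np.linalg.lstsq(mat, S_target, rcond=None)
            if rank < K:
                warnings.warn(
                    f"rank-deficient deformation matrix (rank {rank} < {K}): "
                    "returning the minimum-norm least-squares solution"
                )
        else:
            A = mat.T @ mat + lam * np.eye(K)
            rhs = mat.T @ S_target + lam * P_rest
            P_star = np.linalg.solve(A, rhs)
        res = mat @ P_star - S_target
        rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
        return ControlDisplacementSolution(P_star, rms, "pinv", lam)

    if method != "lm":
        raise ValueError(f"unknown method {method!r}")

    # Damped least squares on r(P) = [B·P − S*; sqrt(lam)(P − P_rest)].
    P = P_rest.copy() if P_rest is not None else np.zeros((K, 3))
    A = mat.T @ mat + (lam * np.eye(K) if lam > 0 else 0.0)
    diagA = np.diag(A).copy()
    diagA[diagA == 0] = 1.0

    def cost(P):
        r = mat @ P - S_target
        c = np.sum(r ** 2)
        if lam > 0:
            c += lam * np.sum((P - P_rest) ** 2)
        return c

    mu = 1e-3
    c = cost(P)
    trace = [c]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = mat.T @ (mat @ P - S_target)
        if lam > 0:
            g = g + lam * (P - P_rest)
        gnorm = np.sqrt(np.sum(g ** 2))
        if gnorm < 1e-10:
            converged = True
            break
        accepted = False
        for _ in range(50):
            try:
                step = np.linalg.solve(A + mu * np.diag(diagA), -g)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            if np.sqrt(np.sum(step ** 2)) < 1e-12:
                converged = True
                accepted = True
                break
            c_new = cost(P + step)
            if c_new < c:
                P = P + step
                c = c_new
                mu = max(mu / 10, 1e-12)
                accepted = True
                break
            mu *= 10
        trace.append(c)
        if not accepted or converged:
            if not accepted:
                raise SolverError(
                    f"Levenberg–Marquardt failed to find a descent step at iteration {it}",
                    trace=trace,
                )
            break
    else:
        raise SolverError(f"Levenberg–Marquardt did not converge in {max_iter} iterations",
                          trace=trace)
    res = mat @ P - S_target
    rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    return ControlDisplacementSolution(P, rms, "lm", lam, n_iter=it,
                                       converged=True, trace=trace)


def interpolate_displacement(grid: FFDGrid, P_star: np.ndarray, x) -> np.ndarray:
    """Deformed position(s) x' = B(x)·P* for world point(s) inside the grid."""
    rows, _ = _rows(grid, x)
    out = rows @ np.asarray(P_star, dtype=float)
    return out[0] if np.asarray(x).ndim == 1 else out


def displacement_jacobian(grid: FFDGrid, P_star: np.ndarray, x) -> np.ndarray:
    """Jacobian dx'/dx of the FFD map at world point(s) x -> (…, 3, 3)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, loc = _rows(grid, x)
    Bi = _bernstein_basis(grid.l, loc[:, 0])
    Bj = _bernstein_basis(grid.m, loc[:, 1])
    Bk = _bernstein_basis(grid.n, loc[:, 2])
    dBi = _bernstein_basis_deriv(grid.l, loc[:, 0])
    dBj = _bernstein_basis_deriv(grid.m, loc[:, 1])
    dBk = _bernstein_basis_deriv(grid.n, loc[:, 2])
    P = np.asarray(P_star, dtype=float)
    # d x' / d local
    d_chi = np.einsum("pi,pj,pk->pijk", dBi, Bj, Bk).reshape(x.shape[0], -1) @ P
    d_psi = np.einsum("pi,pj,pk->pijk", Bi, dBj, Bk).reshape(x.shape[0], -1) @ P
    d_omega = np.einsum("pi,pj,pk->pijk", Bi, Bj, dBk).reshape(x.shape[0], -1) @ P
    d_local = np.stack([d_chi, d_psi, d_omega], axis=-1)  # (p, 3 world, 3 local)
    M_inv = np.linalg.inv(np.column_stack([grid.S, grid.T, grid.U]))  # d local / d x
    return d_local @ M_inv
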