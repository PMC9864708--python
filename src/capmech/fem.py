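"""Generalized plane-strain hyperelastic finite elements for vessel slices.

The 0.5 mm thin-slice vessel model is solved as a 2-D cross-section with a
prescribed uniform out-of-plane stretch (the in-vivo axial stretch
1/(1 - 0.05) for 5% axial shrinkage), lumen pressure applied as a follower
load, and the modified Mooney-Rivlin materials of :mod:`capmech.materials`.
Linear triangles, total-Lagrangian formulation, Newton iteration with
incremental loading and adaptive step halving.

Rigid-body modes of the free-floating annulus are removed by three Lagrange
multiplier constraints (zero mean translation and zero mean rotation); the
pressure load is self-equilibrated, so the constraint reactions vanish at
equilibrium and serve as a global-equilibrium diagnostic.

The scalar stress/strain predictors are the maximum principal Cauchy stress
and maximum principal Green-Lagrange strain, recovered at each lumen sample
point by a local least-squares fit of the element fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contours import CapSamples
from .materials import MaterialParams
from .mesh import Mesh, TISSUE_NAMES

__all__ = [
    "Kinematics",
    "SolutionField",
    "strain_energy",
    "stress_from_kinematics",
    "solve",
    "mesh_convergence",
    "extract_cap_mechanics",
    "cap_mechanics_record",
    "green_lagrange",
]

AXIAL_SHRINK_DEFAULT = 0.05
DEFAULT_AXIAL_STRETCH = 1.0 / (1.0 - AXIAL_SHRINK_DEFAULT)


# ---------------------------------------------------------------------------
# constitutive law (vectorized over leading axes)
# ---------------------------------------------------------------------------

def _invariants(F: np.ndarray, nc: np.ndarray):
    """Invariants of C = F^T F; nc is the reference fiber direction."""
    C = np.einsum("...ki,...kj->...ij", F, F)
    J = np.linalg.det(F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    CC = np.einsum("...ij,...ij->...", C, C)
    I2 = 0.5 * (I1**2 - CC)
    I4 = np.einsum("...i,...ij,...j->...", nc, C, nc)
    return C, J, I1, I2, I4


def _energy_terms(mat: MaterialParams, I1b, I2b, I4b):
    W = (
        mat.c1 * (I1b - 3.0)
        + mat.c2 * (I2b - 3.0)
        + mat.D1 * np.expm1(mat.D2 * (I1b - 3.0))
    )
    if mat.anisotropic:
        W = W + (mat.K1 / mat.K2) * np.expm1(mat.K2 * (I4b - 1.0) ** 2)
    return W


@dataclass(frozen=True)
class Kinematics:
    """Deformation state at a material point.

    F maps reference to current position; nc is the unit circumferential
    fiber direction in the reference configuration.
    """

    F: np.ndarray  # (3, 3)
    nc: np.ndarray  # (3,)

    def __post_init__(self):
        if np.linalg.det(self.F) <= 0:
            raise ValueError("non-positive volume ratio J")

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))


def strain_energy(kin: Kinematics, mat: MaterialParams) -> float:
    """Strain-energy density (kPa) with isochoric split and volumetric penalty."""
    _, J, I1, I2, I4 = _invariants(kin.F, kin.nc)
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    I4b = J ** (-2.0 / 3.0) * I4
    W = _energy_terms(mat, I1b, I2b, I4b) + 0.5 * mat.kappa * (J - 1.0) ** 2
    return float(W)


def _pk2_stress(F: np.ndarray, nc: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress 2 dW/dC, vectorized (..., 3, 3).

    Intermediate Newton states may carry inverted elements (J <= 0); the
    resulting NaNs are deliberate and trigger step halving in the solver.
    """
    with np.errstate(all="ignore"):
        C, J, I1, I2, I4 = _invariants(F, nc)
        Cinv = np.linalg.inv(C)
        Jm23 = J ** (-2.0 / 3.0)
        Jm43 = J ** (-4.0 / 3.0)
        I1b = Jm23 * I1
        I2b = Jm43 * I2
        I4b = Jm23 * I4
        eye = np.broadcast_to(np.eye(3), C.shape)

        W1 = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (I1b - 3.0))
        W2 = mat.c2

        dI1b = Jm23[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
        dI2b = Jm43[..., None, None] * (
            I1[..., None, None] * eye - C - (2.0 * I2 / 3.0)[..., None, None] * Cinv
        )
        S = 2.0 * (W1[..., None, None] * dI1b + W2 * dI2b)
        if mat.anisotropic:
            W4 = 2.0 * mat.K1 * (I4b - 1.0) * np.exp(
                np.minimum(mat.K2 * (I4b - 1.0) ** 2, 700.0)
            )
            M = np.einsum("...i,...j->...ij", nc, nc)
            dI4b = Jm23[..., None, None] * (M - (I4 / 3.0)[..., None, None] * Cinv)
            S = S + 2.0 * W4[..., None, None] * dI4b
        S = S + (mat.kappa * (J - 1.0) * J)[..., None, None] * Cinv
    return S


def stress_from_kinematics(kin: Kinematics, mat: MaterialParams) -> np.ndarray:
    """Cauchy stress tensor (kPa): push-forward sigma = J^-1 F S F^T."""
    S = _pk2_stress(kin.F, kin.nc, mat)
    return (kin.F @ S @ kin.F.T) / kin.J


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2, vectorized."""
    C = np.einsum("...ki,...kj->...ij", F, F)
    return 0.5 * (C - np.eye(3))


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

def _pk2_inplane(F2: np.ndarray, nc: np.ndarray, lam_z: float,
                 mat: MaterialParams):
    """Block-diagonal fast path of the constitutive law.

    Generalized plane strain makes F = diag-block(F2, lam_z) with the fiber
    in-plane, so C, C^-1 and S are block diagonal; everything reduces to
    scalar component arrays.  Returns (S11, S12, S22, S33, J) with the
    same convention as `_pk2_stress` (verified against it in the tests).
    """
    with np.errstate(all="ignore"):
        f11, f12 = F2[..., 0, 0], F2[..., 0, 1]
        f21, f22 = F2[..., 1, 0], F2[..., 1, 1]
        C11 = f11 * f11 + f21 * f21
        C12 = f11 * f12 + f21 * f22
        C22 = f12 * f12 + f22 * f22
        c33 = lam_z * lam_z
        detF2 = f11 * f22 - f12 * f21
        detC2 = detF2 * detF2
        J = detF2 * lam_z
        I1 = C11 + C22 + c33
        CC = C11 * C11 + 2 * C12 * C12 + C22 * C22 + c33 * c33
        I2 = 0.5 * (I1 * I1 - CC)
        n1, n2 = nc[..., 0], nc[..., 1]
        I4 = C11 * n1 * n1 + 2 * C12 * n1 * n2 + C22 * n2 * n2

        Ci11 = C22 / detC2
        Ci22 = C11 / detC2
        Ci12 = -C12 / detC2
        Ci33 = 1.0 / c33

        Jm23 = J ** (-2.0 / 3.0)
        Jm43 = Jm23 * Jm23
        I1b = Jm23 * I1
        I4b = Jm23 * I4
        W1 = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (I1b - 3.0))
        W2 = mat.c2
        a1 = 2.0 * W1 * Jm23
        a2 = 2.0 * W2 * Jm43
        vol = mat.kappa * (J - 1.0) * J

        t1 = I1 / 3.0
        S11 = a1 * (1.0 - t1 * Ci11) + a2 * (I1 - C11 - (2 * I2 / 3.0) * Ci11)
        S12 = a1 * (-t1 * Ci12) + a2 * (-C12 - (2 * I2 / 3.0) * Ci12)
        S22 = a1 * (1.0 - t1 * Ci22) + a2 * (I1 - C22 - (2 * I2 / 3.0) * Ci22)
        S33 = a1 * (1.0 - t1 * Ci33) + a2 * (I1 - c33 - (2 * I2 / 3.0) * Ci33)
        if mat.anisotropic:
            W4 = 2.0 * mat.K1 * (I4b - 1.0) * np.exp(
                np.minimum(mat.K2 * (I4b - 1.0) ** 2, 700.0)
            )
            a4 = 2.0 * W4 * Jm23
            t4 = I4 / 3.0
            S11 += a4 * (n1 * n1 - t4 * Ci11)
            S12 += a4 * (n1 * n2 - t4 * Ci12)
            S22 += a4 * (n2 * n2 - t4 * Ci22)
            S33 += a4 * (-t4 * Ci33)
        S11 += vol * Ci11
        S12 += vol * Ci12
        S22 += vol * Ci22
        S33 += vol * Ci33
    return S11, S12, S22, S33, J


@dataclass
class SolutionField:
    """Equilibrium fields of one slice solve."""

    mesh: Mesh
    displacement: np.ndarray  # (N, 2) mm
    cauchy_stress: np.ndarray  # (M, 3, 3) kPa
    gl_strain: np.ndarray  # (M, 3, 3)
    converged: bool
    residual_norm: float
    load_fraction: float
    pressure: float
    axial_stretch: float

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacement

    def lumen_area(self) -> float:
        """Area enclosed by the deformed lumen boundary."""
        ring = self.deformed_nodes[self.mesh.lumen_edges[:, 0]]
        x, y = ring[:, 0], ring[:, 1]
        return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------

class _Assembler:
    def __init__(self, mesh: Mesh, materials: dict[str, MaterialParams], axial_stretch: float):
        self.mesh = mesh
        self.lam_z = axial_stretch
        p = mesh.nodes[mesh.elements]  # (M, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        self.area0 = 0.5 * det
        # gradients of linear shape functions, (M, 3 nodes, 2)
        Jinv = np.empty((len(det), 2, 2))
        Jinv[:, 0, 0] = v2[:, 1] / det
        Jinv[:, 0, 1] = -v2[:, 0] / det
        Jinv[:, 1, 0] = -v1[:, 1] / det
        Jinv[:, 1, 1] = v1[:, 0] / det
        dN_ref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
        self.gradN = np.einsum("ak,mkj->maj", dN_ref, Jinv)
        # fiber directions embedded in 3D
        self.nc3 = np.zeros((mesh.n_elements, 3))
        self.nc3[:, :2] = mesh.nc
        # group elements by material for vectorized constitutive calls
        self.groups = []
        for code in np.unique(mesh.tissue):
            name = TISSUE_NAMES[int(code)]
            if name not in materials:
                raise KeyError(f"no material for tissue {name!r}")
            self.groups.append((np.where(mesh.tissue == code)[0], materials[name]))

    def deformation_gradients(self, u_elem: np.ndarray) -> np.ndarray:
        """F (M, 3, 3) from element nodal displacements (M, 3, 2)."""
        M = len(self.area0)
        F = np.zeros((M, 3, 3))
        F[:, :2, :2] = np.eye(2) + np.einsum("mai,maj->mij", u_elem, self.gradN)
        F[:, 2, 2] = self.lam_z
        return F

    def _inplane_gradients(self, u_elem: np.ndarray) -> np.ndarray:
        F2 = np.empty((len(self.area0), 2, 2))
        F2[:] = np.eye(2)
        F2 += np.einsum("mai,maj->mij", u_elem, self.gradN)
        return F2

    def element_internal_forces(self, u_elem: np.ndarray) -> np.ndarray:
        """Nodal internal forces per element (M, 3, 2)."""
        F2 = self._inplane_gradients(u_elem)
        M = len(self.area0)
        P2 = np.empty((M, 2, 2))
        for idx, mat in self.groups:
            s11, s12, s22, _, _ = _pk2_inplane(
                F2[idx], self.mesh.nc[idx], self.lam_z, mat
            )
            f11, f12 = F2[idx, 0, 0], F2[idx, 0, 1]
            f21, f22 = F2[idx, 1, 0], F2[idx, 1, 1]
            P2[idx, 0, 0] = f11 * s11 + f12 * s12
            P2[idx, 0, 1] = f11 * s12 + f12 * s22
            P2[idx, 1, 0] = f21 * s11 + f22 * s12
            P2[idx, 1, 1] = f21 * s12 + f22 * s22
        f = self.area0[:, None, None] * np.einsum("mij,maj->mai", P2, self.gradN)
        return f

    def cauchy_and_strain(self, u_elem: np.ndarray):
        F = self.deformation_gradients(u_elem)
        sigma = np.empty_like(F)
        for idx, mat in self.groups:
            S = _pk2_stress(F[idx], self.nc3[idx], mat)
            sigma[idx] = np.einsum(
                "mik,mkl,mjl->mij", F[idx], S, F[idx]
            ) / np.linalg.det(F[idx])[:, None, None]
        E = green_lagrange(F)
        # symmetrize against roundoff
        sigma = 0.5 * (sigma + np.swapaxes(sigma, -1, -2))
        return sigma, E


def _pressure_forces(
    deformed: np.ndarray, edges: np.ndarray, pressure: float, lam_z: float
) -> np.ndarray:
    """Follower pressure nodal forces (N, 2) on the lumen boundary.

    Edge traversal is CCW around the lumen, interior on the left; the
    outward (into-wall) normal times edge length is (dy, -dx).  The deformed
    slab thickness scales with the axial stretch.
    """
    f = np.zeros_like(deformed)
    xa = deformed[edges[:, 0]]
    xb = deformed[edges[:, 1]]
    d = xb - xa
    n_ds = np.stack([d[:, 1], -d[:, 0]], axis=1)
    fe = 0.5 * pressure * lam_z * n_ds
    np.add.at(f, edges[:, 0], fe)
    np.add.at(f, edges[:, 1], fe)
    return f


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------

class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, load_fraction: float):
        super().__init__(f"{msg} (last converged load fraction {load_fraction:.3f})")
        self.load_fraction = load_fraction


def _constraint_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Rows: mean x-translation, mean y-translation, mean rotation."""
    N = mesh.n_nodes
    Xc = mesh.nodes - mesh.nodes.mean(axis=0)
    C = np.zeros((3, 2 * N))
    C[0, 0::2] = 1.0
    C[1, 1::2] = 1.0
    C[2, 0::2] = -Xc[:, 1]
    C[2, 1::2] = Xc[:, 0]
    return sp.csr_matrix(C / N)


def _residual(asm: _Assembler, mesh: Mesh, u: np.ndarray, pressure: float) -> np.ndarray:
    u_elem = u[mesh.elements]
    f_el = asm.element_internal_forces(u_elem)
    r = np.zeros_like(u)
    np.add.at(r, mesh.elements.ravel(), f_el.reshape(-1, 2))
    r -= _pressure_forces(mesh.nodes + u, mesh.lumen_edges, pressure, asm.lam_z)
    return r


def _tangent(asm: _Assembler, mesh: Mesh, u: np.ndarray, pressure: float, h: float = 1e-7):
    """Global tangent by central differencing of element/edge residuals."""
    M = mesh.n_elements
    u_elem = u[mesh.elements]  # (M, 3, 2)
    Ke = np.zeros((M, 6, 6))
    for k in range(6):
        a, i = divmod(k, 2)
        up = u_elem.copy()
        up[:, a, i] += h
        fp = asm.element_internal_forces(up)
        up[:, a, i] -= 2 * h
        fm = asm.element_internal_forces(up)
        Ke[:, :, k] = (fp - fm).reshape(M, 6) / (2 * h)

    dofs = (2 * mesh.elements[:, :, None] + np.arange(2)[None, None, :]).reshape(M, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes,) * 2)

    # follower-pressure load stiffness (exact: linear in deformed coords)
    E = len(mesh.lumen_edges)
    deformed = mesh.nodes + u
    Kp = np.zeros((E, 4, 4))
    c = 0.5 * pressure * asm.lam_z
    # d/d(xb - xa) of (dy, -dx): force on both nodes = c*(dy, -dx)
    # columns: [xa_x, xa_y, xb_x, xb_y]; residual contribution is -f_ext
    for node_row in range(2):  # same force added to both edge nodes
        r0 = 2 * node_row
        Kp[:, r0 + 0, 1] += c   # d(-fx)/d(ya): fx = c*dy = c*(yb-ya) -> -d = +c
        Kp[:, r0 + 0, 3] += -c
        Kp[:, r0 + 1, 0] += -c  # fy = -c*dx = -c*(xb-xa)
        Kp[:, r0 + 1, 2] += c
    edofs = (2 * mesh.lumen_edges[:, :, None] + np.arange(2)[None, None, :]).reshape(E, 4)
    prow = np.repeat(edofs, 4, axis=1).ravel()
    pcol = np.tile(edofs, (1, 4)).ravel()
    K = K + sp.coo_matrix((Kp.ravel(), (prow, pcol)), shape=K.shape)
    return K.tocsr()


def solve(
    mesh: Mesh,
    materials: dict[str, MaterialParams],
    pressure: float,
    axial_stretch: float = DEFAULT_AXIAL_STRETCH,
    n_increments: int = 10,
    rtol: float = 1e-8,
    max_newton: int = 30,
    max_halvings: int = 5,
) -> SolutionField:
    """Solve the slice at the given lumen pressure (kPa) and axial stretch.

    Pressure is ramped in ``n_increments`` steps with Newton iteration per
    step (residual tolerance relative to the applied load); on divergence
    the increment is halved, up to ``max_halvings`` times.  The prescribed
    axial stretch is normally applied from the first increment (fast); if
    that diverges the solve restarts with the stretch ramped alongside the
    pressure so step halving softens the out-of-plane loading too.
    """
    try:
        return _solve_once(mesh, materials, pressure, axial_stretch,
                           n_increments, rtol, max_newton, max_halvings,
                           ramp_axial=False)
    except NonConvergenceError:
        return _solve_once(mesh, materials, pressure, axial_stretch,
                           max(n_increments, 8), rtol, max_newton,
                           max_halvings, ramp_axial=True)


def _solve_once(
    mesh: Mesh,
    materials: dict[str, MaterialParams],
    pressure: float,
    axial_stretch: float,
    n_increments: int,
    rtol: float,
    max_newton: int,
    max_halvings: int,
    ramp_axial: bool,
) -> SolutionField:
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    if axial_stretch <= 0:
        raise ValueError("axial_stretch must be positive")
    asm = _Assembler(mesh, materials, axial_stretch)
    Cmat = _constraint_matrix(mesh)
    n = 2 * mesh.n_nodes
    u = np.zeros(n)
    lam = np.zeros(3)  # constraint multipliers

    # reference force scale for the relative tolerance
    lumen_len = float(
        np.sum(
            np.linalg.norm(
                mesh.nodes[mesh.lumen_edges[:, 1]] - mesh.nodes[mesh.lumen_edges[:, 0]],
                axis=1,
            )
        )
    )
    load_scale = pressure * lumen_len * axial_stretch
    tol = max(rtol * load_scale, 1e-10)  # absolute floor for zero-load solves

    target = 1.0
    loaded = 0.0
    step = target / n_increments
    halvings = 0
    res_norm = np.inf
    while loaded < target - 1e-12:
        frac = min(loaded + step, target)
        p = frac * pressure
        if ramp_axial:
            asm.lam_z = 1.0 + frac * (axial_stretch - 1.0)
        u_trial, lam_trial = u.copy(), lam.copy()
        ok = False
        for _ in range(max_newton):
            with np.errstate(all="ignore"):
                try:
                    r = _residual(asm, mesh, u_trial.reshape(-1, 2), p).ravel()
                except np.linalg.LinAlgError:
                    break  # inverted elements with NaN metric: halve the step
                r_aug = np.concatenate([r + Cmat.T @ lam_trial, Cmat @ u_trial])
                res_norm = float(np.linalg.norm(r_aug))
                if not np.isfinite(res_norm):
                    break
                if res_norm <= tol:
                    ok = True
                    break
                try:
                    K = _tangent(asm, mesh, u_trial.reshape(-1, 2), p)
                    KKT = sp.bmat([[K, Cmat.T], [Cmat, None]], format="csc")
                    d = spla.spsolve(KKT, -r_aug)
                except (RuntimeError, np.linalg.LinAlgError):
                    break
            if not np.all(np.isfinite(d)):
                break
            u_trial += d[:n]
            lam_trial += d[n:]
        if ok:
            u, lam = u_trial, lam_trial
            loaded = frac
        else:
            halvings += 1
            step *= 0.5
            if halvings > max_halvings:
                raise NonConvergenceError("Newton diverged", loaded)

    sigma, E = asm.cauchy_and_strain(u.reshape(-1, 2)[mesh.elements])
    return SolutionField(
        mesh=mesh,
        displacement=u.reshape(-1, 2),
        cauchy_stress=sigma,
        gl_strain=E,
        converged=True,
        residual_norm=res_norm,
        load_fraction=loaded,
        pressure=pressure,
        axial_stretch=axial_stretch,
    )


# ---------------------------------------------------------------------------
# predictor extraction and mesh convergence
# ---------------------------------------------------------------------------

def _lumen_adjacent_elements(mesh: Mesh) -> np.ndarray:
    lumen_nodes = set(mesh.lumen_edges[:, 0]) | set(mesh.lumen_edges[:, 1])
    mask = np.array(
        [sum(v in lumen_nodes for v in el) >= 2 for el in mesh.elements]
    )
    return np.where(mask)[0]


def _principal_scalars(solution: SolutionField, elem_idx: np.ndarray):
    sig = np.linalg.eigvalsh(solution.cauchy_stress[elem_idx])[:, -1]
    eps = np.linalg.eigvalsh(
        0.5 * (solution.gl_strain[elem_idx] + np.swapaxes(solution.gl_strain[elem_idx], -1, -2))
    )[:, -1]
    return sig, eps


def _recover_scalars_at(
    points: np.ndarray, solution: SolutionField, k: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-least-squares recovery of principal stress/strain at points.

    Element fields of linear triangles are piecewise constant and carry a
    pressure checkerboard from the volumetric penalty; a distance-weighted
    quadratic fit of the (rotation-invariant) maximum-principal scalars
    over the k nearest element centroids (deformed coordinates) smooths the
    oscillation and extrapolates the steep lumen boundary layer.
    """
    from scipy.spatial import cKDTree

    mesh = solution.mesh
    cen = solution.deformed_nodes[mesh.elements].mean(axis=1)
    k = min(k, mesh.n_elements)
    sig_el, eps_el = _principal_scalars(solution, np.arange(mesh.n_elements))
    tree = cKDTree(cen)
    d, idx = tree.query(points, k=k)
    if k == 1:
        return sig_el[idx], eps_el[idx]
    scale = np.maximum(d[:, min(int(0.7 * k), k - 1)][:, None], 1e-9)
    w = np.exp(-((d / scale) ** 2))
    dx = cen[idx] - points[:, None, :]  # (P, k, 2)
    cols = [np.ones_like(dx[..., :1]), dx]
    if k >= 12:  # quadratic terms need a rich enough patch
        cols.append(
            np.stack([dx[..., 0] ** 2, dx[..., 0] * dx[..., 1], dx[..., 1] ** 2], -1)
        )
    A = np.concatenate(cols, axis=-1)
    Aw = A * w[..., None]
    AtA = np.einsum("pki,pkj->pij", Aw, Aw)
    AtA_inv = np.linalg.inv(AtA + 1e-12 * np.eye(A.shape[-1]))

    def fit(vals: np.ndarray) -> np.ndarray:
        rhs = np.einsum("pki,pk->pi", Aw, w * vals)
        coef = np.einsum("pij,pj->pi", AtA_inv, rhs)
        return coef[:, 0]

    return fit(sig_el[idx]), fit(eps_el[idx])


def extract_cap_mechanics(solution: SolutionField, samples: CapSamples) -> CapSamples:
    """Fill per-point stress/strain scalars at the lumen sample points.

    Stress is the maximum principal Cauchy stress (kPa), strain the maximum
    principal Green-Lagrange strain, both recovered at the sample position
    by a local least-squares fit of the lumen-adjacent element fields in
    deformed coordinates (sample points are digitized on the in-vivo, i.e.
    pressurized, geometry).
    """
    if not solution.converged:
        raise ValueError("solution not converged")
    sig, eps = _recover_scalars_at(samples.points, solution)
    return CapSamples(
        points=samples.points,
        quarter=samples.quarter,
        in_cap=samples.in_cap,
        cap_thickness=samples.cap_thickness,
        stress=sig,
        strain=eps,
    )


def cap_mechanics_record(samples: CapSamples) -> dict[str, float | None]:
    """Aggregate MaxCapS/MeanCapS/MaxCapSn/MeanCapSn over in-cap points."""
    if samples.stress is None or samples.strain is None:
        raise ValueError("samples carry no mechanics; run extract_cap_mechanics")
    if not np.any(samples.in_cap):
        return {"MaxCapS": None, "MeanCapS": None, "MaxCapSn": None, "MeanCapSn": None}
    s = samples.stress[samples.in_cap]
    e = samples.strain[samples.in_cap]
    return {
        "MaxCapS": float(np.max(s)),
        "MeanCapS": float(np.mean(s)),
        "MaxCapSn": float(np.max(e)),
        "MeanCapSn": float(np.mean(e)),
    }


def _convergence_metric(solution: SolutionField, samples: CapSamples | None) -> float:
    """MaxCapS when a cap exists, else peak lumen-adjacent principal stress."""
    if samples is not None and np.any(samples.in_cap):
        filled = extract_cap_mechanics(solution, samples)
        return float(np.max(filled.stress[filled.in_cap]))
    adj = _lumen_adjacent_elements(solution.mesh)
    sig, _ = _principal_scalars(solution, adj)
    return float(np.max(sig))


def mesh_convergence(
    slc,
    materials: dict[str, MaterialParams],
    pressure: float,
    axial_stretch: float = DEFAULT_AXIAL_STRETCH,
    start_size: float = 0.3,
    samples: CapSamples | None = None,
    rel_change: float = 0.02,
    max_refinements: int = 15,
) -> tuple[SolutionField, Mesh, list[float]]:
    """Refine mesh density by 10% until the peak cap stress changes < 2%.

    Returns the converged solution, its mesh, and the metric history.
    """
    from .mesh import build_mesh

    size = start_size
    history: list[float] = []
    prev = None
    solution = None
    mesh = None
    for _ in range(max_refinements):
        mesh = build_mesh(slc, size, boundary_layer=True)
        solution = solve(mesh, materials, pressure, axial_stretch)
        metric = _convergence_metric(solution, samples)
        history.append(metric)
        if prev is not None and abs(metric - prev) <= rel_change * abs(prev):
            return solution, mesh, history
        prev = metric
        size /= np.sqrt(1.1)  # +10% element density per pass
    raise NonConvergenceError(
        f"mesh not converged after {max_refinements} refinements: {history}", 1.0
    )
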