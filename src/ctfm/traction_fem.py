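"""Nonlinear finite-element reconstruction of Cauchy surface tractions.

The measured displacement field is turned into tractions by a *forward*
finite-strain boundary-value problem - no inverse regularization is
needed because displacements are known at every marker with nanometre
precision:

I.   A cuboid section of the substrate (actual thickness, in-plane extent
     of the marker patch) is meshed with graded linear tetrahedra: element
     size about ``L0/5`` where the measured displacement is large, growing
     to about ``L0`` elsewhere and towards the bottom.
II.  The per-disc displacements are interpolated to every top-surface
     node with exact thin-plate-spline radial basis functions (affine
     part included, so rigid motions and uniform strains are reproduced
     exactly).  Bottom and lateral faces are fixed, representing bonding
     to the coverslip and embedding in the surrounding substrate.
III. The nearly incompressible two-term Ogden equilibrium is solved by
     Newton iteration (consistent tangent by per-element numerical
     differentiation of the exact stress, load stepping on stall), and
     the reaction forces at the constrained surface nodes divided by the
     deformed tributary areas give the Cauchy traction field.

Units: lengths um, stresses kPa internally; tractions are reported in Pa
and forces in nN (1 kPa um^2 = 1 nN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional
import logging

import numpy as np
from scipy import sparse
from scipy.interpolate import RBFInterpolator
from scipy.sparse.linalg import splu


def _factorize(K):
    """Sparse LU with an ordering that suits symmetric elastic stiffness."""
    return splu(K.tocsc(), permc_spec="MMD_AT_PLUS_A",
                options=dict(SymmetricMode=True))

from .material import OgdenMaterial, SUBSTRATE_9_10
from .reference_recovery import DisplacementField

logger = logging.getLogger(__name__)


class FEMError(RuntimeError):
    pass


class NewtonDivergence(FEMError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg + "; consider enabling more load steps")
        self.residual_history = residual_history


@dataclass
class SubstrateModel:
    """Cuboid substrate section with Ogden material and mesh sizing."""

    height: float = 30.0
    L0: float = 1.5
    material: OgdenMaterial = field(default_factory=lambda: SUBSTRATE_9_10)
    fine: Optional[float] = None     # default L0/5
    coarse: Optional[float] = None   # default L0
    coarse_z: Optional[float] = None  # vertical size away from the surface
    surface_band: Optional[float] = None  # depth meshed at `fine` below the top
    refine_threshold: float = 0.1    # um of |u| marking "high displacement"
    grade_ratio: float = 1.35

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("substrate height must be positive")
        if self.fine is None:
            self.fine = self.L0 / 5.0
        if self.coarse is None:
            self.coarse = self.L0
        if self.coarse_z is None:
            # the solution decays over ~ the surface feature size towards
            # the bottom; depth resolution can relax well beyond `coarse`
            self.coarse_z = max(self.coarse, self.height / 8.0)
        if self.surface_band is None:
            # resolve the decay depth of the smallest lateral feature the
            # markers can carry (~ one disc spacing) below the surface
            self.surface_band = max(2.0 * self.fine, self.L0)
        if not self.fine < self.coarse:
            raise ValueError("fine element size must be smaller than coarse")


@dataclass
class TetMesh:
    nodes: np.ndarray          # (n, 3) reference coordinates
    tets: np.ndarray           # (m, 4)
    top: np.ndarray            # node indices on z = h
    bottom: np.ndarray         # node indices on z = 0
    lateral: np.ndarray        # node indices on lateral faces
    top_tris: np.ndarray       # (q, 3) surface triangles on z = h

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def volume(self) -> float:
        d = self.nodes[self.tets]
        v = np.einsum("mi,mi->m",
                      np.cross(d[:, 1] - d[:, 0], d[:, 2] - d[:, 0]),
                      d[:, 3] - d[:, 0]) / 6.0
        return float(np.abs(v).sum())


@dataclass
class TractionField:
    """Cauchy tractions at the (deformed) top surface nodes."""

    points: np.ndarray         # (n, 3) deformed surface coordinates, um
    traction: np.ndarray       # (n, 3) Pa
    area: np.ndarray           # (n,) deformed tributary area, um^2
    node_ids: np.ndarray       # indices into the FE mesh

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.traction)):
            raise ValueError("tractions must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.traction, axis=1)

    @property
    def in_plane(self) -> np.ndarray:
        return np.linalg.norm(self.traction[:, :2], axis=1)

    def rms(self, region: Optional[np.ndarray] = None) -> float:
        """RMS traction magnitude, optionally over a boolean node mask."""
        m = self.magnitude if region is None else self.magnitude[region]
        return float(np.sqrt(np.mean(m ** 2)))

    def central_mask(self, inset: float) -> np.ndarray:
        """Nodes at least ``inset`` um from the lateral domain boundary."""
        lo = self.points[:, :2].min(axis=0)
        hi = self.points[:, :2].max(axis=0)
        p = self.points[:, :2]
        return np.all((p >= lo + inset) & (p <= hi - inset), axis=1)

    def interpolator(self):
        """Linear interpolator of the traction field over the surface (Pa)."""
        from scipy.interpolate import LinearNDInterpolator
        return LinearNDInterpolator(self.points[:, :2], self.traction,
                                    fill_value=np.nan)


# ---------------------------------------------------------------------------
# Step II: thin-plate-spline boundary conditions
# ---------------------------------------------------------------------------

def interpolate_bc(disc_xy: np.ndarray, disc_u: np.ndarray,
                   surface_xy: np.ndarray) -> np.ndarray:
    """Exact TPS interpolation of disc displacements to surface nodes.

    ``r^2 log r`` kernel plus affine polynomial; each displacement
    component is interpolated independently.  Values at disc positions
    are reproduced exactly; affine fields are reproduced everywhere.
    """
    xy = np.asarray(disc_xy, dtype=float)
    u = np.asarray(disc_u, dtype=float)
    if len(xy) < 3:
        raise FEMError("TPS interpolation needs at least 3 disc positions")
    if len(np.unique(xy.round(9), axis=0)) != len(xy):
        raise FEMError("duplicate disc positions in displacement field")
    rbf = RBFInterpolator(xy, u, kernel="thin_plate_spline", degree=1)
    return rbf(np.asarray(surface_xy, dtype=float))


# ---------------------------------------------------------------------------
# Step I: graded tetrahedral meshing of the cuboid
# ---------------------------------------------------------------------------

def _graded_axis(lo: float, hi: float, band: Optional[tuple[float, float]],
                 fine: float, coarse: float, ratio: float) -> np.ndarray:
    """1D node coordinates: spacing ``fine`` inside ``band``, growing
    geometrically to ``coarse`` outside."""
    if band is None:
        n = max(1, int(np.ceil((hi - lo) / coarse)))
        return np.linspace(lo, hi, n + 1)
    b0, b1 = max(band[0], lo), min(band[1], hi)
    xs = [b0]
    # fine region
    nf = max(1, int(np.ceil((b1 - b0) / fine)))
    xs = list(np.linspace(b0, b1, nf + 1))
    # grade down towards hi
    x, s = xs[-1], fine
    while x < hi - 1e-9:
        s = min(s * ratio, coarse)
        x = min(x + s, hi)
        xs.append(x)
    # grade up towards lo
    pre, x, s = [], xs[0], fine
    while x > lo + 1e-9:
        s = min(s * ratio, coarse)
        x = max(x - s, lo)
        pre.append(x)
    return np.array(pre[::-1] + xs)


_HEX_TETS = [(0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
             (1, 2, 3, 7), (1, 6, 2, 7), (1, 5, 6, 7)]
# mirrored split (x -> 1-x relabelling: 0<->1, 3<->2, 4<->5, 7<->6), used on
# a checkerboard so the triangulation is mirror-symmetric and face-conforming
_HEX_TETS_M = [(1, 0, 6, 2), (1, 0, 4, 6), (1, 4, 5, 6),
               (0, 3, 6, 2), (0, 7, 6, 3), (0, 4, 6, 7)]
# local corner order: 0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
#                     4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)


def build_mesh(model: SubstrateModel, disp: Optional[DisplacementField] = None,
               extent: Optional[tuple] = None,
               refined_box: Optional[tuple] = None) -> TetMesh:
    """Graded conforming tetrahedral mesh of the substrate cuboid.

    The in-plane extent defaults to the bounding box of the disc
    positions; the refined (fine) in-plane band defaults to the bounding
    box of discs with ``|u| > refine_threshold``, or the whole extent if
    no such discs exist but a displacement field was given with large
    motion anywhere.  Vertical spacing is ``fine`` at the top surface
    grading to ``coarse`` at the bottom (surface gradients dominate the
    traction solution).
    """
    if extent is None:
        if disp is None:
            raise FEMError("either a displacement field or an explicit "
                           "extent is required")
        lo = disp.reference[:, :2].min(axis=0)
        hi = disp.reference[:, :2].max(axis=0)
        extent = (lo[0], hi[0], lo[1], hi[1])
    x0, x1, y0, y1 = extent
    if refined_box is None and disp is not None:
        big = np.linalg.norm(disp.u[:, :2], axis=1) > model.refine_threshold
        if np.any(big):
            p = disp.reference[big][:, :2]
            pad = model.L0
            refined_box = (p[:, 0].min() - pad, p[:, 0].max() + pad,
                           p[:, 1].min() - pad, p[:, 1].max() + pad)
    bx = None if refined_box is None else (refined_box[0], refined_box[1])
    by = None if refined_box is None else (refined_box[2], refined_box[3])
    xs = _graded_axis(x0, x1, bx, model.fine, model.coarse, model.grade_ratio)
    ys = _graded_axis(y0, y1, by, model.fine, model.coarse, model.grade_ratio)
    # vertical axis: fine at top (z = h), coarse at bottom
    zs = _graded_axis(0.0, model.height,
                      (model.height - model.surface_band, model.height),
                      model.fine, model.coarse_z, max(model.grade_ratio, 1.5))

    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    I, J, K = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = np.empty((len(I), 8), dtype=np.int64)
    offs = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
            (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    for c, (di, dj, dk) in enumerate(offs):
        corner[:, c] = nid(I + di, J + dj, K + dk)
    parity = (I + J + K) % 2 == 0
    tets = np.concatenate(
        [corner[parity][:, t] for t in _HEX_TETS]
        + [corner[~parity][:, t] for t in _HEX_TETS_M], axis=0)

    eps = 1e-9
    top = np.flatnonzero(np.abs(nodes[:, 2] - model.height) < eps)
    bottom = np.flatnonzero(np.abs(nodes[:, 2]) < eps)
    lateral = np.flatnonzero((np.abs(nodes[:, 0] - x0) < eps)
                             | (np.abs(nodes[:, 0] - x1) < eps)
                             | (np.abs(nodes[:, 1] - y0) < eps)
                             | (np.abs(nodes[:, 1] - y1) < eps))
    # surface triangulation of the top face (from tet faces lying on z = h)
    on_top = np.isin(tets, top)
    rows = np.flatnonzero(on_top.sum(axis=1) == 3)
    tris = np.array([tets[r][on_top[r]] for r in rows], dtype=np.int64) \
        if len(rows) else np.empty((0, 3), dtype=np.int64)
    mesh = TetMesh(nodes=nodes, tets=tets, top=top, bottom=bottom,
                   lateral=lateral, top_tris=tris)
    if mesh.n_nodes > 25_000:
        import warnings
        warnings.warn(f"large FE mesh ({mesh.n_nodes} nodes): the direct "
                      "factorization may need several GB; consider a larger "
                      "fine element size or a smaller domain", stacklevel=2)
    _check_volumes(mesh)
    return mesh


def _tet_geometry(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (m, 4, 3) and volumes (m,) of linear tets."""
    x = nodes[tets]
    e = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]],
                 axis=1)                       # (m, 3, 3) rows are edges
    detJ = np.linalg.det(e)
    vol = detJ / 6.0
    inv = np.linalg.inv(e)                     # columns: grads of N1..N3
    g = np.transpose(inv, (0, 2, 1))           # (m, 3edge, 3) -> grads
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = g
    grads[:, 0, :] = -g.sum(axis=1)
    return grads, vol


def _check_volumes(mesh: TetMesh) -> None:
    _, vol = _tet_geometry(mesh.nodes, mesh.tets)
    if np.any(vol <= 0):
        raise FEMError(f"{int((vol <= 0).sum())} degenerate or inverted "
                       "elements in the reference mesh")


# ---------------------------------------------------------------------------
# Step III: Ogden stress and the Newton solve
# ---------------------------------------------------------------------------

def first_pk_deviatoric(F: np.ndarray, mat: OgdenMaterial) -> np.ndarray:
    """Batched deviatoric first Piola-Kirchhoff stress of the Ogden model.

    ``F`` is (..., 3, 3).  Principal-stretch spectral evaluation: the
    deviatoric principal Kirchhoff stresses are
    ``tau_i = sum_p 2 mu_p/alpha_p (lb_i^alpha_p - mean_j lb_j^alpha_p)``
    with isochoric stretches ``lb``; then ``P = F S`` with ``S`` assembled
    from ``tau_i / lambda_i^2`` on the right Cauchy-Green eigenbasis.
    """
    C = np.einsum("...ji,...jk->...ik", F, F)
    lam2, N = np.linalg.eigh(C)
    lam2 = np.maximum(lam2, 1e-12)
    lam = np.sqrt(lam2)
    J = lam.prod(axis=-1)
    lb = lam * J[..., None] ** (-1.0 / 3.0)
    tau = np.zeros_like(lam)
    for mu, al in ((mat.mu1, mat.alpha1), (mat.mu2, mat.alpha2)):
        if mu == 0.0:
            continue
        p = lb ** al
        tau = tau + 2.0 * mu / al * (p - p.mean(axis=-1, keepdims=True))
    S_princ = tau / lam2
    S = np.einsum("...ai,...i,...bi->...ab", N, S_princ, N)
    return F @ S


def first_pk_stress(F: np.ndarray, mat: OgdenMaterial) -> np.ndarray:
    """Deviatoric Ogden stress plus the pointwise volumetric penalty.

    Used for single-point evaluations and verification; inside the FE
    assembly the volumetric term is evaluated on nodal-patch-averaged
    volume changes instead (see :class:`_Assembler`).
    """
    P = first_pk_deviatoric(F, mat)
    J = np.linalg.det(F)
    cof = J[..., None, None] * np.linalg.inv(F).swapaxes(-1, -2)
    return P + (mat.kappa * (J - 1.0))[..., None, None] * cof


def cauchy_stress(F: np.ndarray, mat: OgdenMaterial) -> np.ndarray:
    P = first_pk_stress(F, mat)
    J = np.linalg.det(F)
    return np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]


class _Assembler:
    """Vectorized residual/tangent assembly over all elements.

    Linear tetrahedra with the deviatoric Ogden stress evaluated per
    element and the volumetric penalty evaluated on *nodal-patch-averaged*
    volume changes (average-nodal-pressure formulation): each element
    donates a quarter of its reference volume to each node; the nodal
    Jacobian is the volume-weighted mean over the incident elements, the
    nodal pressure ``kappa (Jbar_n - 1)`` acts back on the element through
    the mean of its four nodal pressures.  Pointwise volumetric penalties
    make constant-strain tetrahedra lock severely at nu = 0.49 (spurious
    stiffening by ~2x was measured on a layered-elasticity benchmark);
    patch averaging removes the locking while keeping the element linear.
    """

    def __init__(self, mesh: TetMesh, mat: OgdenMaterial):
        self.mesh = mesh
        self.mat = mat
        self.grads, self.vol = _tet_geometry(mesh.nodes, mesh.tets)
        t = mesh.tets
        dof = (3 * t[:, :, None] + np.arange(3)[None, None, :]).reshape(len(t), 12)
        self.edof = dof
        self.rows = np.repeat(dof, 12, axis=1).ravel().astype(np.int32)
        self.cols = np.tile(dof, (1, 12)).ravel().astype(np.int32)
        # nodal patch volumes (quarter of each incident tet)
        self.node_vol = np.zeros(mesh.n_nodes)
        np.add.at(self.node_vol, t.ravel(), np.repeat(self.vol / 4.0, 4))
        self._Kvol0 = None

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.tets]          # (m, 4, 3)
        F = np.eye(3)[None] + np.einsum("mai,maj->mij", ue, self.grads)
        return F

    def nodal_jacobians(self, J: np.ndarray) -> np.ndarray:
        Jbar = np.zeros(self.mesh.n_nodes)
        np.add.at(Jbar, self.mesh.tets.ravel(),
                  np.repeat(self.vol / 4.0 * J, 4))
        return Jbar / self.node_vol

    def _element_pressure(self, F: np.ndarray) -> np.ndarray:
        J = np.linalg.det(F)
        pbar_n = self.mat.kappa * (self.nodal_jacobians(J) - 1.0)
        return pbar_n[self.mesh.tets].mean(axis=1), J

    def internal_force_elements(self, F: np.ndarray,
                                pbar: Optional[np.ndarray] = None,
                                J: Optional[np.ndarray] = None) -> np.ndarray:
        P = first_pk_deviatoric(F, self.mat)
        if pbar is not None:
            cof = J[..., None, None] * np.linalg.inv(F).swapaxes(-1, -2)
            P = P + pbar[:, None, None] * cof
        fe = np.einsum("m,mij,maj->mai", self.vol, P, self.grads)
        return fe.reshape(len(self.mesh.tets), 12)

    def residual(self, u: np.ndarray) -> np.ndarray:
        F = self.deformation_gradients(u)
        pbar, J = self._element_pressure(F)
        fe = self.internal_force_elements(F, pbar, J)
        r = np.zeros(3 * self.mesh.n_nodes)
        np.add.at(r, self.edof.ravel(), fe.ravel())
        return r

    def _volumetric_stiffness0(self) -> sparse.csr_matrix:
        """Exact tangent of the patch-averaged penalty at u = 0.

        ``E_vol = sum_n kappa/(2 V_n) (G u)_n^2`` with the linearized
        nodal volume-change operator ``G``: ``G[n, dof(b, i)] =
        sum_(e in n) V_e/4 * grad N_b^e[i]``.
        """
        if self._Kvol0 is not None:
            return self._Kvol0
        m = len(self.mesh.tets)
        rows = np.repeat(self.mesh.tets.ravel(), 12)
        cols = np.tile(self.edof, (1, 4)).ravel()
        vals = np.tile((self.vol[:, None] / 4.0)
                       * self.grads.reshape(m, 12), (1, 4)).ravel()
        G = sparse.coo_matrix((vals, (rows, cols)),
                              shape=(self.mesh.n_nodes, 3 * self.mesh.n_nodes)
                              ).tocsr()
        D = sparse.diags(self.mat.kappa / self.node_vol)
        self._Kvol0 = (G.T @ D @ G).tocsr()
        return self._Kvol0

    def tangent(self, u: np.ndarray, eps: float = 1e-7) -> sparse.csr_matrix:
        """Tangent: element-FD of the deviatoric forces (with the element
        pressure frozen) plus the exact volumetric patch stiffness at u=0.
        Exact at u = 0; an effective quasi-Newton operator elsewhere."""
        F0 = self.deformation_gradients(u)
        f0 = self.internal_force_elements(F0)
        m = len(self.mesh.tets)
        Ke = np.empty((m, 12, 12))
        for a in range(4):
            for i in range(3):
                Fp = F0.copy()
                Fp[:, i, :] += eps * self.grads[:, a, :]
                fp = self.internal_force_elements(Fp)
                Ke[:, :, 3 * a + i] = (fp - f0) / eps
        Ke = 0.5 * (Ke + np.transpose(Ke, (0, 2, 1)))
        K = sparse.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                              shape=(3 * self.mesh.n_nodes,) * 2).tocsr()
        return K + self._volumetric_stiffness0()


def _deformed_tributary_areas(mesh: TetMesh, u: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-top-node area of adjacent deformed surface-facet thirds."""
    x = mesh.nodes + u.reshape(-1, 3)
    tri = mesh.top_tris
    v = np.cross(x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]])
    a = 0.5 * np.linalg.norm(v, axis=1)
    area = np.zeros(mesh.n_nodes)
    np.add.at(area, tri.ravel(), np.repeat(a / 3.0, 3))
    return area[mesh.top], x[mesh.top]


class FEASolver:
    """Reusable finite-strain solver bound to one mesh and material.

    The tangent stiffness at the undeformed state is assembled and
    LU-factorized once and reused as a quasi-Newton operator for every
    subsequent solve on the same mesh (the exact residual is always used,
    so converged solutions are exact equilibria).  If the constant-
    stiffness iteration stalls - large strains - the solver falls back to
    consistently re-linearized Newton steps, with load stepping as the
    last resort.
    """

    def __init__(self, model: SubstrateModel, mesh: TetMesh):
        self.model = model
        self.mesh = mesh
        self.asm = _Assembler(mesh, model.material)
        self._lu_cache: dict[bytes, object] = {}
        self._K0 = None

    def _factor0(self, free: np.ndarray):
        key = free.tobytes()
        if key not in self._lu_cache:
            if self._K0 is None:
                self._K0 = self.asm.tangent(np.zeros(3 * self.mesh.n_nodes))
            self._lu_cache[key] = _factorize(self._K0[free][:, free])
        return self._lu_cache[key]

    def solve(self, bc_top: np.ndarray,
              bc_lateral: Optional[Callable[[np.ndarray], np.ndarray]] = None,
              external_force: Optional[np.ndarray] = None,
              max_newton: int = 80, tol_rel: float = 1e-8,
              max_load_steps: int = 10) -> tuple[TractionField, np.ndarray]:
        """Solve for prescribed top displacements (and/or surface loads).

        ``bc_top`` is the prescribed displacement (n_top, 3) at top-surface
        nodes (ordered like ``mesh.top``); NaN rows leave the node free
        (forward problems driven by ``external_force``, a 3*n_nodes vector
        in nN).  Bottom and lateral nodes are fixed unless ``bc_lateral``
        supplies a displacement function of position (patch tests).
        Returns the Cauchy traction field at constrained top nodes
        (reaction force / deformed tributary area, Pa) and the full
        displacement vector.
        """
        mesh, asm, model = self.mesh, self.asm, self.model
        ndof = 3 * mesh.n_nodes
        g = np.zeros(ndof)
        prescribed = np.zeros(ndof, dtype=bool)

        bc_top = np.asarray(bc_top, dtype=float)
        top_mask = ~np.any(np.isnan(bc_top), axis=1)
        idx = 3 * mesh.top[top_mask]
        for c in range(3):
            g[idx + c] = bc_top[top_mask, c]
            prescribed[idx + c] = True
        for node in mesh.bottom:
            prescribed[3 * node:3 * node + 3] = True
        for node in mesh.lateral:
            sl = slice(3 * node, 3 * node + 3)
            if bc_lateral is not None:
                g[sl] = bc_lateral(mesh.nodes[node])
            prescribed[sl] = True
        free = ~prescribed

        fext = (np.zeros(ndof) if external_force is None
                else np.asarray(external_force, dtype=float))
        history: list[float] = []
        scale = max(float(model.material.mu0 * model.L0 ** 2), 1e-12)
        lu0 = self._factor0(free)

        lu_exact = [None]  # cached consistent tangent factorization

        def run(u0, lf):
            """Iterate to equilibrium at load factor lf; None on failure."""
            u = u0.copy()
            u[prescribed] = lf * g[prescribed]
            if np.any(np.linalg.det(asm.deformation_gradients(u)) <= 0):
                return None  # increment too large: starting state inverted
            r = asm.residual(u) - lf * fext
            rn = float(np.linalg.norm(r[free]))
            tol = max(tol_rel * min(rn, scale), 1e-13 * scale)
            slow = 0
            use_exact = False
            for it in range(max_newton):
                history.append(rn)
                if rn < tol:
                    return u
                if use_exact:
                    if lu_exact[0] is None:
                        try:
                            K = asm.tangent(u)
                            lu_exact[0] = _factorize(K[free][:, free])
                        except RuntimeError:
                            return None
                    du = lu_exact[0].solve(-r[free])
                else:
                    du = lu0.solve(-r[free])
                if not np.all(np.isfinite(du)):
                    return None
                # backtracking line search: halve the step until no element
                # inverts and the residual does not blow up (the constant-
                # stiffness predictor overshoots locally at large strains)
                s = 1.0
                u_new = None
                for _ in range(10):
                    cand = u.copy()
                    cand[free] += s * du
                    F = asm.deformation_gradients(cand)
                    if np.all(np.linalg.det(F) > 0):
                        r_cand = asm.residual(cand) - lf * fext
                        rn_cand = float(np.linalg.norm(r_cand[free]))
                        if rn_cand < 2.0 * rn or s < 0.26:
                            u_new, r_new, rn_new = cand, r_cand, rn_cand
                            break
                    s *= 0.5
                if u_new is None:
                    return None
                # slow contraction: re-linearize consistently at this state
                slow = slow + 1 if rn_new > 0.55 * rn else 0
                if slow >= 12 and not use_exact:
                    use_exact = True
                    slow = 0
                if rn_new > 10 * rn and it > 2:
                    return None
                u, r, rn = u_new, r_new, rn_new
            return None

        # incremental load marching with adaptive step control
        u = np.zeros(ndof)
        current, inc = 0.0, 1.0
        min_inc = 1.0 / max(2 ** 14, max_load_steps)
        while current < 1.0 - 1e-12:
            lf = min(current + inc, 1.0)
            lu_exact[0] = None
            u_try = run(u, lf)
            if u_try is None:
                inc *= 0.5
                if inc < min_inc:
                    raise NewtonDivergence(
                        f"Newton did not converge (load increment below "
                        f"{min_inc:g})", history)
                logger.info("load step to %.3f failed; increment -> %.4f",
                            lf, inc)
                continue
            u, current = u_try, lf
            inc = min(inc * 1.5, 1.0 - current) if current < 1.0 else inc

        # reactions at constrained top nodes = assembled internal forces
        r_full = asm.residual(u) - fext
        area, xdef = _deformed_tributary_areas(mesh, u)
        keep = top_mask & (area > 0)
        t = np.zeros((len(mesh.top), 3))
        nz = np.flatnonzero(keep)
        for local in nz:
            node = mesh.top[local]
            t[local] = r_full[3 * node:3 * node + 3] / area[local]
        return (TractionField(points=xdef[keep], traction=t[keep] * 1e3,
                              area=area[keep], node_ids=mesh.top[keep]),
                u)


def solve(model: SubstrateModel, mesh: TetMesh, bc_top: np.ndarray,
          **kw) -> tuple[TractionField, np.ndarray]:
    """One-shot convenience wrapper around :class:`FEASolver`."""
    return FEASolver(model, mesh).solve(bc_top, **kw)


def reconstruct_tractions(disp: DisplacementField, model: SubstrateModel,
                          mesh: Optional[TetMesh] = None,
                          solver: Optional[FEASolver] = None
                          ) -> tuple[TractionField, TetMesh]:
    """Full steps I-III for a measured displacement field.

    Pass a prebuilt :class:`FEASolver` to amortize meshing and stiffness
    factorization over repeated reconstructions on the same domain.
    """
    if solver is not None:
        mesh = solver.mesh
    elif mesh is None:
        mesh = build_mesh(model, disp)
    if solver is None:
        solver = FEASolver(model, mesh)
    u3 = np.zeros((len(disp.u), 3))
    u3[:, : disp.u.shape[1]] = disp.u
    bc = interpolate_bc(disp.reference[:, :2], u3,
                        mesh.nodes[mesh.top][:, :2])
    tf, _ = solver.solve(bc)
    return tf, mesh


def forward_surface_displacement(model: SubstrateModel, mesh: TetMesh,
                                 traction_fn: Callable[[np.ndarray], np.ndarray],
                                 solver: Optional["FEASolver"] = None):
    """Forward problem: apply surface tractions, return surface displacements.

    ``traction_fn`` maps (n, 2) surface xy to (n, 3) tractions in Pa.
    The top surface is free; the load vector integrates the traction over
    the reference surface triangles.  Returns a linear interpolator of the
    top-surface displacement (um) and the solved displacement vector.
    """
    ndof = 3 * mesh.n_nodes
    fext = np.zeros(ndof)
    tri = mesh.top_tris
    x = mesh.nodes
    v = np.cross(x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]])
    a = 0.5 * np.linalg.norm(v, axis=1)
    centroids = x[tri].mean(axis=1)[:, :2]
    t_c = np.asarray(traction_fn(centroids)) * 1e-3   # Pa -> kPa
    load = (a[:, None] * t_c) / 3.0                   # nN per vertex
    for c in range(3):
        np.add.at(fext, 3 * tri[:, c][:, None] + np.arange(3), load)
    bc = np.full((len(mesh.top), 3), np.nan)
    if solver is None:
        solver = FEASolver(model, mesh)
    _, u = solver.solve(bc, external_force=fext)
    from scipy.interpolate import LinearNDInterpolator
    interp = LinearNDInterpolator(mesh.nodes[mesh.top][:, :2],
                                  u.reshape(-1, 3)[mesh.top],
                                  fill_value=0.0)
    return interp, u


def read_material_json_or_default(path) -> OgdenMaterial:
    """Material from a JSON file, or the calibrated 9:10 substrate."""
    if path is None:
        return SUBSTRATE_9_10
    from .material import read_material_json
    return read_material_json(path)


def sensitivity_analysis(**kw):
    """Minimum detectable traction from a forward-inverse sweep.

    Thin delegate to :func:`ctfm.pipeline.sensitivity_analysis`, which
    orchestrates the full render/detect/mesh/relax/solve loop.
    """
    from .pipeline import sensitivity_analysis as _impl
    return _impl(**kw)


def write_traction_vtk(path, mesh: TetMesh, tf: TractionField) -> None:
    """ASCII legacy-VTK point cloud of surface tractions (visualizers)."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nctfm surface tractions\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {len(tf.points)} double\n")
        for p in tf.points:
            f.write(f"{p[0]} {p[1]} {p[2]}\n")
        f.write(f"POINT_DATA {len(tf.points)}\n"
                "VECTORS traction_Pa double\n")
        for t in tf.traction:
            f.write(f"{t[0]} {t[1]} {t[2]}\n")
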