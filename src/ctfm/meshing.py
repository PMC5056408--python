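"""Triangular-mesh reconstruction of a deformed nanodisc array.

The printed array is a triangular lattice with spacing ``L0``; under a
cell the observed point pattern is a deformed copy of it.  Connectivity is
recovered in two steps:

1. *Regular regions*: a disc is accepted as locally undeformed when it has
   exactly six neighbours at distance ``L0`` within ``dist_tol`` (250 nm
   default) whose consecutive polar-angle gaps are 60 deg within
   ``angle_tol`` (10 deg default).  Accepted discs are placed on integer
   axial lattice coordinates by breadth-first propagation; regions of the
   pattern that fail the test remain unmeshed *voids*.

2. *Void filling*: the vacant lattice sites enclosed by (or rimming) the
   regular region are enumerated, and the unmeshed discs are assigned to
   them one-to-one by minimizing mesh distortion - a linear assignment on
   squared distance to the ideal site positions, refined by 2-swap descent
   on the spring energy ``sum_edges (len - L0)^2``, with exhaustive
   enumeration for voids of up to 8 discs.

The final mesh is graph-isomorphic to the pristine printed lattice, which
is exactly what the spring-relaxation step downstream requires.

Axial coordinates ``(i, j)`` map to the plane as ``x = (i + j/2) L0``,
``y = j sqrt(3)/2 L0`` (before the global rotation/translation fitted from
the data), with the six lattice steps at multiples of 60 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional
import json
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .lattice_sim import NanodiscArray

AXIAL_STEPS = np.array([(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)])


class MeshingError(RuntimeError):
    pass


class UnfillableVoidError(MeshingError):
    pass


@dataclass(frozen=True)
class MeshingParams:
    """Tolerances of the local six-neighbour test."""

    L0: float
    dist_tol: float = 0.25
    angle_tol: float = 10.0
    max_displacement: float = 2.0  # um; search radius guard for void filling

    def __post_init__(self) -> None:
        if not (0 < self.dist_tol < self.L0 / 2):
            raise ValueError("dist_tol must lie in (0, L0/2)")
        if not (0 < self.angle_tol < 30):
            raise ValueError("angle_tol must lie in (0, 30) degrees")


@dataclass
class TriMesh:
    """Triangle connectivity over a nanodisc array.

    ``axial`` holds the integer lattice coordinate of every node (row i of
    ``axial`` for node i); ``assigned`` flags nodes that have one.  Nodes
    without coordinates (only before void filling) belong to ``voids``,
    each a dict with the disc indices and the boundary node loop.
    """

    n_nodes: int
    axial: np.ndarray                       # (n, 2) int, valid where assigned
    assigned: np.ndarray                    # (n,) bool
    triangles: np.ndarray = field(default=None)  # type: ignore[assignment]
    voids: list = field(default_factory=list)
    frame: tuple[float, float, float] = (0.0, 0.0, 0.0)  # theta, tx, ty

    def __post_init__(self) -> None:
        if self.triangles is None:
            self.triangles = _triangles_from_axial(self.axial, self.assigned)

    @property
    def edges(self) -> np.ndarray:
        e = set()
        for t in self.triangles:
            a, b, c = int(t[0]), int(t[1]), int(t[2])
            e.update({(min(a, b), max(a, b)), (min(b, c), max(b, c)),
                      (min(a, c), max(a, c))})
        return np.array(sorted(e), dtype=int).reshape(-1, 2)

    def neighbour_lists(self) -> list[list[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for a, b in self.edges:
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
        return [sorted(s) for s in nbrs]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def _triangles_from_axial(axial: np.ndarray, assigned: np.ndarray) -> np.ndarray:
    """Up/down lattice triangles whose three sites are all assigned."""
    site_to_node = {tuple(axial[i]): i for i in np.flatnonzero(assigned)}
    tris = []
    for (i, j), a in site_to_node.items():
        b = site_to_node.get((i + 1, j))
        c = site_to_node.get((i, j + 1))
        e = site_to_node.get((i - 1, j + 1))
        if b is not None and c is not None:
            tris.append((a, b, c))        # up-triangle
        if e is not None and c is not None:
            tris.append((a, e, c))        # down-triangle
    return np.array(sorted(set(map(tuple, map(sorted, tris)))), dtype=int
                    ).reshape(-1, 3)


def axial_to_xy(axial: np.ndarray, L0: float,
                frame: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Ideal plane positions of axial sites under rotation/translation ``frame``."""
    ij = np.asarray(axial, dtype=float)
    base = np.column_stack([(ij[:, 0] + ij[:, 1] / 2.0) * L0,
                            ij[:, 1] * np.sqrt(3.0) / 2.0 * L0])
    th, tx, ty = frame
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return base @ R.T + np.array([tx, ty])


def _fit_frame(axial: np.ndarray, xy: np.ndarray, L0: float
               ) -> tuple[float, float, float]:
    """Least-squares rotation + translation mapping axial sites onto xy."""
    base = axial_to_xy(axial, L0)
    mb, mx = base.mean(axis=0), xy.mean(axis=0)
    b, x = base - mb, xy - mx
    # Procrustes with fixed scale
    s = (b[:, 0] * x[:, 1] - b[:, 1] * x[:, 0]).sum()
    c = (b * x).sum()
    th = float(np.arctan2(s, c))
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = mx - R @ mb
    return th, float(t[0]), float(t[1])


def _regular_nodes(pos: np.ndarray, params: MeshingParams
                   ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Six-neighbour local-regularity test; returns flags and neighbour ids."""
    tree = cKDTree(pos)
    lo, hi = params.L0 - params.dist_tol, params.L0 + params.dist_tol
    candidates = tree.query_ball_point(pos, r=hi)
    regular = np.zeros(len(pos), dtype=bool)
    nbrs: list[np.ndarray] = [np.empty(0, dtype=int)] * len(pos)
    for i, cand in enumerate(candidates):
        cand = [j for j in cand if j != i
                and lo <= np.linalg.norm(pos[j] - pos[i]) <= hi]
        if len(cand) != 6:
            continue
        d = pos[cand] - pos[i]
        ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        order = np.argsort(ang)
        ang_sorted = ang[order]
        gaps = np.diff(np.append(ang_sorted, ang_sorted[0] + 360.0))
        if np.max(np.abs(gaps - 60.0)) <= params.angle_tol:
            regular[i] = True
            nbrs[i] = np.asarray(cand)[order]
    return regular, nbrs


def mesh_regular_regions(arr: NanodiscArray, params: MeshingParams) -> TriMesh:
    """Mesh locally-regular regions; leave strongly deformed regions as voids.

    Regular nodes receive axial lattice coordinates by BFS from a seed
    near the centroid; directions are classified against the global
    lattice orientation estimated from the seed's neighbour fan (the test
    tolerances guarantee an unambiguous nearest multiple of 60 deg).
    """
    pos = np.asarray(arr.xy, dtype=float)
    n = len(pos)
    if n < 7:
        raise MeshingError("need at least 7 nanodiscs to mesh")
    regular, nbrs = _regular_nodes(pos, params)
    axial = np.zeros((n, 2), dtype=int)
    assigned = np.zeros(n, dtype=bool)
    if not np.any(regular):
        warnings.warn("no locally regular node found: whole field is one void",
                      stacklevel=2)
        mesh = TriMesh(n_nodes=n, axial=axial, assigned=assigned)
        mesh.voids = [{"discs": list(range(n)), "boundary": []}]
        return mesh

    # seed inside the largest connected component of the regular graph so
    # the BFS frame propagates as far as possible
    comp = np.full(n, -1)
    ncomp = 0
    for s in np.flatnonzero(regular):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = ncomp
        while stack:
            a = stack.pop()
            for b in nbrs[a]:
                if regular[b] and comp[b] < 0:
                    comp[b] = ncomp
                    stack.append(b)
        ncomp += 1
    sizes = np.bincount(comp[comp >= 0].astype(int), minlength=ncomp)
    main = int(np.argmax(sizes))
    members = np.flatnonzero((comp == main) & regular)
    centroid = pos[members].mean(axis=0)
    seed = int(members[np.argmin(np.linalg.norm(pos[members] - centroid, axis=1))])
    d = pos[nbrs[seed]] - pos[seed]
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    theta0 = float(np.radians(_mean_mod60(ang)))

    step_angles = np.arange(6) * 60.0
    axial[seed] = (0, 0)
    assigned[seed] = True
    queue = [seed]
    while queue:
        i = queue.pop()
        for j in nbrs[i]:
            if not regular[j]:
                continue
            v = pos[j] - pos[i]
            phi = (np.degrees(np.arctan2(v[1], v[0])) - np.degrees(theta0)) % 360.0
            k = int(np.argmin(np.minimum(np.abs(step_angles - phi),
                                         360.0 - np.abs(step_angles - phi))))
            cand = axial[i] + AXIAL_STEPS[k]
            if assigned[j]:
                continue  # first assignment wins; conflicts impossible within tol
            axial[j] = cand
            assigned[j] = True
            queue.append(j)

    if not np.all(assigned[regular]):
        # secondary regular components disconnected from the seed's: leave
        # them for the assignment stage rather than guessing a frame
        regular = regular & assigned

    frame = _fit_frame(axial[assigned], pos[assigned], params.L0)
    mesh = TriMesh(n_nodes=n, axial=axial, assigned=assigned, frame=frame)
    mesh.voids = _find_voids(mesh, pos, params)
    return mesh


def _mean_mod60(angles_deg: np.ndarray) -> float:
    """Circular mean of angles folded to a 60-degree period."""
    a = np.radians(np.asarray(angles_deg) * 6.0)
    return float(np.degrees(np.arctan2(np.sin(a).sum(), np.cos(a).sum())) / 6.0)


def _find_voids(mesh: TriMesh, pos: np.ndarray, params: MeshingParams) -> list:
    """Group unassigned discs into voids with their regular boundary nodes."""
    un = np.flatnonzero(~mesh.assigned)
    if un.size == 0:
        return []
    tree = cKDTree(pos)
    # unmeshed discs are connected if within 1.5 L0 of each other
    adj = {i: set() for i in un}
    for i in un:
        for j in tree.query_ball_point(pos[i], r=1.5 * params.L0):
            if j != i and not mesh.assigned[j]:
                adj[i].add(j)
    comps, seen = [], set()
    for i in un:
        if i in seen:
            continue
        comp, stack = [], [i]
        seen.add(i)
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        comps.append(sorted(comp))
    voids = []
    for comp in comps:
        boundary = set()
        for i in comp:
            for j in tree.query_ball_point(pos[i], r=1.5 * params.L0):
                if mesh.assigned[j]:
                    boundary.add(int(j))
        voids.append({"discs": comp, "boundary": sorted(boundary)})
    return voids


def _vacant_sites(mesh: TriMesh) -> set[tuple[int, int]]:
    """Lattice sites inside the row-wise hull of assigned sites, not taken."""
    taken = {tuple(mesh.axial[i]) for i in np.flatnonzero(mesh.assigned)}
    by_j: dict[int, list[int]] = {}
    for (i, j) in taken:
        by_j.setdefault(j, []).append(i)
    vacant = set()
    for j, iis in by_j.items():
        for i in range(min(iis), max(iis) + 1):
            if (i, j) not in taken:
                vacant.add((i, j))
    return vacant


def mesh_distortion(site_of: dict[int, tuple[int, int]], pos: np.ndarray,
                    L0: float,
                    pred_of: Optional[dict[tuple[int, int], np.ndarray]] = None
                    ) -> float:
    """Distortion of a candidate site assignment.

    Two contributions per the package's distortion model:

    * edge terms ``(len - len_pred)^2`` over all lattice edges among the
      given nodes, where ``len`` is the observed inter-disc distance and
      ``len_pred`` the edge length predicted by the interpolated
      displacement field (falling back to the rest length ``L0``, i.e.
      spring energy, when no prediction is available - the two coincide as
      deformation vanishes);
    * node terms ``|x_i - x_pred(site_i)|^2`` penalizing discs far from
      the predicted position of their site (zero without a prediction).

    The node terms resolve the near-degeneracy of purely edge-based costs
    in strongly compressed regions, where swapping two nearby discs
    changes edge lengths by less than the printing jitter.
    """
    node_of = {s: i for i, s in site_of.items()}
    cost = 0.0
    for s, i in node_of.items():
        if pred_of is not None and s in pred_of:
            cost += float(np.sum((pos[i] - pred_of[s]) ** 2))
        for di, dj in AXIAL_STEPS[:3]:  # each undirected edge once
            t = (s[0] + di, s[1] + dj)
            j = node_of.get(t)
            if j is None:
                continue
            target = L0
            if pred_of is not None and s in pred_of and t in pred_of:
                target = float(np.linalg.norm(pred_of[s] - pred_of[t]))
            cost += (np.linalg.norm(pos[i] - pos[j]) - target) ** 2
    return cost


def fill_voids(mesh: TriMesh, arr: NanodiscArray,
               params: Optional[MeshingParams] = None) -> TriMesh:
    """Assign every unmeshed disc to a vacant lattice site; complete the mesh.

    Rim discs (outer lattice boundary, which can never pass the
    six-neighbour test) are first placed greedily on their unique nearby
    site, extending the assigned region outward.  Remaining (deformed-void)
    discs are matched to the enclosed vacant sites by linear assignment on
    squared distance to the ideal site positions, then refined: exhaustive
    enumeration for voids of <= 8 discs, otherwise 2-swap descent on the
    spring distortion cost.  Ties break towards the lowest-label ordering
    (``linear_sum_assignment`` is deterministic; enumeration scans
    assignments in lexicographic order and keeps the first optimum).
    """
    if params is None:
        params = MeshingParams(L0=arr.L0)
    pos = np.asarray(arr.xy, dtype=float)
    axial = mesh.axial.copy()
    assigned = mesh.assigned.copy()
    if not np.any(assigned):
        raise UnfillableVoidError("no meshed region to anchor void filling")

    frame = _fit_frame(axial[assigned], pos[assigned], arr.L0)

    # --- stage A: greedy rim extension -----------------------------------
    # The outer rim of the printed array can never pass the six-neighbour
    # test; those discs are placed on ring sites *outside* the row-wise
    # hull of the regular region, leaving hull-interior vacancies (the true
    # deformation voids) strictly to the optimal-assignment stage.
    changed = True
    while changed:
        changed = False
        un = np.flatnonzero(~assigned)
        if un.size == 0:
            break
        taken = {tuple(axial[i]) for i in np.flatnonzero(assigned)}
        interior = _vacant_sites(TriMesh(n_nodes=mesh.n_nodes, axial=axial,
                                         assigned=assigned,
                                         triangles=np.empty((0, 3), dtype=int)))
        # candidate sites: ring around the assigned set, hull-exterior only
        ring = set()
        for i in np.flatnonzero(assigned):
            for st in AXIAL_STEPS:
                s = (axial[i, 0] + st[0], axial[i, 1] + st[1])
                if s not in taken and s not in interior:
                    ring.add(s)
        if not ring:
            break
        ring_list = sorted(ring)
        ring_xy = axial_to_xy(np.array(ring_list), arr.L0, frame)
        tree = cKDTree(ring_xy)
        d, k = tree.query(pos[un])
        # accept unambiguous, close placements only
        order = np.argsort(d)
        used_sites: set[int] = set()
        for o in order:
            if d[o] > 0.45 * arr.L0 or int(k[o]) in used_sites:
                continue
            i = int(un[o])
            axial[i] = ring_list[int(k[o])]
            assigned[i] = True
            used_sites.add(int(k[o]))
            changed = True
        if changed:
            frame = _fit_frame(axial[assigned], pos[assigned], arr.L0)

    # --- stage B: optimal assignment for the remaining voids --------------
    un = np.flatnonzero(~assigned)
    if un.size > 0:
        tmp = TriMesh(n_nodes=mesh.n_nodes, axial=axial, assigned=assigned,
                      triangles=np.empty((0, 3), dtype=int))
        vacant = sorted(_vacant_sites(tmp))
        if len(vacant) != len(un):
            raise UnfillableVoidError(
                f"void with {len(un)} unmeshed discs but {len(vacant)} vacant "
                f"lattice sites; cannot complete the mesh (discs {list(un)})")
        from scipy.interpolate import RBFInterpolator
        ideal_sites = axial_to_xy(np.array(vacant), arr.L0, frame)
        anchors = np.flatnonzero(assigned)
        anchor_ideal = axial_to_xy(axial[anchors], arr.L0, frame)
        big = params.max_displacement + params.L0

        def assign(predicted_sites: np.ndarray) -> dict[int, tuple[int, int]]:
            cost = ((pos[un][:, None, :]
                     - predicted_sites[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(np.sqrt(cost) > big, cost + 1e6, cost)
            ri, ci = linear_sum_assignment(cost)
            return {int(un[a]): vacant[int(b)] for a, b in zip(ri, ci)}

        # predict the deformed position of each vacant site by thin-plate
        # spline interpolation of the displacement known at assigned nodes
        # (smooth continuum fields extend well from the void boundary into
        # its interior), then match discs to sites by linear assignment
        pred_sites = ideal_sites
        try:
            rbf = RBFInterpolator(anchor_ideal, pos[anchors] - anchor_ideal,
                                  kernel="thin_plate_spline")
            pred_sites = ideal_sites + rbf(ideal_sites)
        except Exception:  # degenerate anchor geometry: plain ideal sites
            rbf = None
        placement = assign(pred_sites)
        pred_of = {s: p for s, p in zip(vacant, pred_sites)}
        pred_of.update({tuple(axial[i]): pos[i] for i in anchors})
        placement = _refine_assignment(placement, axial, assigned, pos,
                                       arr.L0, pred_of)
        for i, s in placement.items():
            axial[i] = s
            assigned[i] = True

    out = TriMesh(n_nodes=mesh.n_nodes, axial=axial, assigned=assigned,
                  frame=_fit_frame(axial[assigned], pos[assigned], arr.L0))
    out.voids = mesh.voids
    return out


def _context_cost(placement: dict[int, tuple[int, int]], axial: np.ndarray,
                  assigned: np.ndarray, pos: np.ndarray, L0: float,
                  pred_of=None) -> float:
    """Distortion of a void placement including edges to the fixed boundary."""
    site_of = {i: tuple(axial[i]) for i in np.flatnonzero(assigned)}
    site_of.update(placement)
    return mesh_distortion(site_of, pos, L0, pred_of)


def _refine_assignment(placement: dict[int, tuple[int, int]], axial: np.ndarray,
                       assigned: np.ndarray, pos: np.ndarray, L0: float,
                       pred_of=None) -> dict[int, tuple[int, int]]:
    """Polish the assignment on the true edge-distortion cost.

    Exhaustive enumeration (lexicographic scan, first optimum kept) for
    voids of <= 8 discs; 2-swap descent otherwise.
    """
    discs = sorted(placement)
    if len(discs) <= 1:
        return placement
    if len(discs) <= 8:
        sites = [placement[i] for i in discs]
        best, best_cost = None, np.inf
        for perm in permutations(sites):
            cand = dict(zip(discs, perm))
            c = _context_cost(cand, axial, assigned, pos, L0, pred_of)
            if c < best_cost - 1e-12:
                best, best_cost = cand, c
        if best is not None and best_cost < _context_cost(
                placement, axial, assigned, pos, L0, pred_of) - 1e-12:
            warnings.warn("void assignment refined by exhaustive enumeration",
                          stacklevel=3)
            return best
        return placement
    # 2-swap descent on the true edge cost, with incremental cost updates
    # (a swap only changes edges incident to the two swapped discs)
    cur = dict(placement)
    node_of: dict[tuple[int, int], int] = {
        tuple(axial[i]): int(i) for i in np.flatnonzero(assigned)}
    node_of.update({s: i for i, s in cur.items()})

    def edge_target(s, t):
        if pred_of is not None and s in pred_of and t in pred_of:
            return float(np.linalg.norm(pred_of[s] - pred_of[t]))
        return L0

    def local_cost(site, node, skip=None):
        c = 0.0
        if pred_of is not None and site in pred_of:
            c += float(np.sum((pos[node] - pred_of[site]) ** 2))
        for di, dj in AXIAL_STEPS:
            t = (site[0] + di, site[1] + dj)
            j = node_of.get(t)
            if j is None or j == skip:
                continue
            c += (np.linalg.norm(pos[node] - pos[j]) - edge_target(site, t)) ** 2
        return c

    improved = True
    while improved:
        improved = False
        for a_idx in range(len(discs)):
            for b_idx in range(a_idx + 1, len(discs)):
                a, b = discs[a_idx], discs[b_idx]
                sa, sb = cur[a], cur[b]
                before = local_cost(sa, a) + local_cost(sb, b, skip=a)
                node_of[sa], node_of[sb] = b, a
                after = local_cost(sa, b) + local_cost(sb, a, skip=b)
                if after < before - 1e-12:
                    cur[a], cur[b] = sb, sa
                    improved = True
                else:
                    node_of[sa], node_of[sb] = a, b
    return cur


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_mesh(path, arr: NanodiscArray, mesh: TriMesh) -> None:
    """ASCII legacy-VTK unstructured grid (triangles) of the meshed array."""
    pos = arr.positions
    z = pos[:, 2] if pos.shape[1] > 2 else np.zeros(len(pos))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nctfm triangular mesh\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pos)} double\n")
        for p, zz in zip(pos[:, :2], z):
            f.write(f"{p[0]} {p[1]} {zz}\n")
        tris = mesh.triangles
        f.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {len(tris)}\n")
        f.write("\n".join(["5"] * len(tris)) + "\n")


def write_edge_list(path, mesh: TriMesh) -> None:
    np.savetxt(path, mesh.edges, fmt="%d", delimiter=",", header="a,b",
               comments="")


def write_void_report(path, mesh: TriMesh) -> None:
    with open(path, "w") as f:
        json.dump({"n_voids": len(mesh.voids),
                   "voids": [{"discs": [int(i) for i in v["discs"]],
                              "boundary": [int(i) for i in v["boundary"]]}
                             for v in mesh.voids]},
                  f, indent=2)
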