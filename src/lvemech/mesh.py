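"""Tetrahedral mesh container and low-level mesh utilities.

Meshes are stored in a minimal in-memory form: node coordinates, tetrahedral
connectivity (4-node linear or 10-node quadratic, VTK edge ordering), and
tagged boundary surfaces as oriented corner triangles (normals point out of
the tissue).  Structured generation from hexahedral grids uses the Kuhn
6-tetrahedra subdivision, which is face-conforming on translated grids and
degenerates gracefully when a hex face collapses to an edge (apex prisms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# VTK quadratic-tet edge ordering: midside node k sits on edge TET10_EDGES[k]
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

# Kuhn subdivision: the 6 permutations of unit steps from corner 000 to 111.
_KUHN_PERMS = (
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
)


@dataclass
class LVMesh:
    """Tetrahedral mesh with tagged boundary surfaces.

    Attributes
    ----------
    nodes : (n, 3) float array of coordinates.
    tets : (m, 4) or (m, 10) int connectivity; corners first.
    order : 1 (linear) or 2 (quadratic, midside nodes on straight edges).
    surfaces : mapping tag -> (k, 3) oriented corner triangles (outward).
    provenance : free label ("reference", "pre-P", "post-P", ...).
    spec : optional ellipsoid specification the mesh was generated from;
        kept so transmural position can be evaluated in closed form.
    """

    nodes: np.ndarray
    tets: np.ndarray
    order: int = 1
    surfaces: dict = field(default_factory=dict)
    provenance: str = "reference"
    spec: Optional[object] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def corners(self) -> np.ndarray:
        """Corner connectivity (m, 4) regardless of order."""
        return self.tets[:, :4]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.corners].mean(axis=1)

    def element_volumes(self, nodes: Optional[np.ndarray] = None) -> np.ndarray:
        pts = self.nodes if nodes is None else nodes
        return tet_volumes(pts, self.corners)

    def long_axis_length(self) -> float:
        """Base plane at max z of the base surface; apex at min z."""
        return float(self.nodes[:, 2].max() - self.nodes[:, 2].min())

    def copy_with_nodes(self, nodes: np.ndarray, provenance: Optional[str] = None) -> "LVMesh":
        return replace(
            self,
            nodes=np.asarray(nodes, dtype=float).copy(),
            provenance=self.provenance if provenance is None else provenance,
        )


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of linear tetrahedra."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vol = tet_volumes(nodes, tets)
    tets = tets.copy()
    flip = vol < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    return tets


def kuhn_tets_from_hexes(hex_corners: np.ndarray) -> np.ndarray:
    """Subdivide hexes into tetrahedra (Kuhn), dropping degenerate ones.

    ``hex_corners`` has shape (nh, 2, 2, 2): node id at local corner
    (dx, dy, dz).  Degenerate hexes (repeated node ids from collapsed faces)
    yield fewer than six tets.
    """
    hex_corners = np.asarray(hex_corners)
    tet_list = []
    for perm in _KUHN_PERMS:
        idx = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] = 1
            idx.append(tuple(cur))
        tet = np.stack([hex_corners[:, i, j, k] for (i, j, k) in idx], axis=1)
        tet_list.append(tet)
    tets = np.concatenate(tet_list, axis=0)
    # drop tets with repeated vertices (collapsed hexes)
    distinct = np.ones(len(tets), dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            distinct &= tets[:, i] != tets[:, j]
    return tets[distinct]


def five_tet_from_hexes(hex_corners: np.ndarray, parity: np.ndarray) -> np.ndarray:
    """Subdivide hexes into 5 tetrahedra with checkerboard-alternating
    diagonals (conforming on structured grids, no preferred diagonal).

    ``parity`` is a boolean per hex ((i+j+k) odd); odd cells use the
    x-mirrored template so shared faces carry matching diagonals.
    """
    h = np.asarray(hex_corners)
    p = {(dx, dy, dz): h[:, dx, dy, dz] for dx in (0, 1)
         for dy in (0, 1) for dz in (0, 1)}
    even_t = [((0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
              ((1, 0, 0), (0, 0, 0), (1, 1, 0), (1, 0, 1)),
              ((0, 1, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)),
              ((0, 0, 1), (0, 0, 0), (1, 0, 1), (0, 1, 1)),
              ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1))]
    mirror = lambda c: (1 - c[0], c[1], c[2])
    odd_t = [tuple(mirror(c) for c in tet) for tet in even_t]
    parity = np.asarray(parity, dtype=bool)
    out = []
    for tmpl, sel in ((even_t, ~parity), (odd_t, parity)):
        for tet in tmpl:
            conn = np.stack([p[c][sel] for c in tet], axis=1)
            out.append(conn)
    tets = np.concatenate(out, axis=0)
    distinct = np.ones(len(tets), dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            distinct &= tets[:, i] != tets[:, j]
    return tets[distinct]


_FACE_OF_TET = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))  # outward for +vol


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Oriented boundary triangles (corner ids) of a positively oriented mesh."""
    faces = np.concatenate([tets[:, f] for f in _FACE_OF_TET], axis=0)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def classify_boundary(faces: np.ndarray, masks: dict) -> dict:
    """Partition boundary faces by node masks (all 3 corners in the mask)."""
    out = {}
    claimed = np.zeros(len(faces), dtype=bool)
    for tag, mask in masks.items():
        sel = mask[faces].all(axis=1) & ~claimed
        out[tag] = faces[sel]
        claimed |= sel
    if not claimed.all():
        raise ValueError(f"{(~claimed).sum()} boundary faces match no surface tag")
    return out


# ---------------------------------------------------------------------------
# structured box (wedge fixture backbone)

def structured_box(nx: int, ny: int, nz: int, lengths=(1.0, 1.0, 1.0)) -> LVMesh:
    """Tetrahedralized box [0,Lx]x[0,Ly]x[0,Lz]; tags x0,x1,y0,y1,z0,z1."""
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    corners = np.empty((nx * ny * nz, 2, 2, 2), dtype=np.int64)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[:, di, dj, dk] = nid(ii + di, jj + dj, kk + dk).ravel()
    parity = ((ii + jj + kk) % 2 == 1).ravel()
    tets = _orient_positive(nodes, five_tet_from_hexes(corners, parity))
    faces = boundary_faces(tets)
    eps = 1e-12 * max(lx, ly, lz)
    masks = {
        "x0": nodes[:, 0] < eps, "x1": nodes[:, 0] > lx - eps,
        "y0": nodes[:, 1] < eps, "y1": nodes[:, 1] > ly - eps,
        "z0": nodes[:, 2] < eps, "z1": nodes[:, 2] > lz - eps,
    }
    surfaces = classify_boundary(faces, masks)
    return LVMesh(nodes=nodes, tets=tets, order=1, surfaces=surfaces, provenance="box")


# ---------------------------------------------------------------------------
# order conversion and refinement

def _edge_table(corners: np.ndarray):
    """Unique corner edges of the mesh. Returns (edges (ne,2) sorted, map)."""
    e = np.concatenate([corners[:, list(pair)] for pair in
                        ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))], axis=0)
    e = np.sort(e, axis=1)
    edges, inv = np.unique(e, axis=0, return_inverse=True)
    return edges, inv


def to_quadratic(mesh: LVMesh) -> LVMesh:
    """Insert midside nodes on every edge (straight edges, affine geometry)."""
    if mesh.order == 2:
        return mesh
    corners = mesh.corners
    nn = mesh.n_nodes
    edge_pairs = np.concatenate(
        [corners[:, list(pair)] for pair in TET10_EDGES], axis=0)
    key = np.sort(edge_pairs, axis=1)
    edges, inv = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
    nodes = np.vstack([mesh.nodes, mid])
    mid_ids = (nn + inv).reshape(6, -1).T  # (m, 6) in TET10 edge order
    tets = np.hstack([corners, mid_ids])
    return replace(mesh, nodes=nodes, tets=tets, order=2)


def edge_midpoint_map(mesh: LVMesh) -> dict:
    """For a quadratic mesh: dict (min_corner, max_corner) -> midside node id."""
    if mesh.order != 2:
        raise ValueError("edge midpoints only defined for quadratic meshes")
    out = {}
    for e, (i, j) in enumerate(TET10_EDGES):
        a = mesh.tets[:, i]
        b = mesh.tets[:, j]
        m = mesh.tets[:, 4 + e]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        out.update(zip(zip(lo.tolist(), hi.tolist()), m.tolist()))
    return out


def surface_triangles(mesh: LVMesh, tag: str) -> np.ndarray:
    """Flat triangles covering the tagged surface.

    Linear meshes return the stored corner triangles; quadratic meshes
    subtriangulate each curved face into 4 using its midside nodes.
    """
    faces = mesh.surfaces[tag]
    if mesh.order == 1:
        return faces
    mids = edge_midpoint_map(mesh)

    def mid(a, b):
        return mids[(min(a, b), max(a, b))]

    out = np.empty((4 * len(faces), 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
        out[4 * i:4 * i + 4] = [(a, mab, mca), (mab, b, mbc),
                                (mca, mbc, c), (mab, mbc, mca)]
    return out


def refine(mesh: LVMesh) -> LVMesh:
    """Uniform 1:8 refinement of a linear tetrahedral mesh."""
    if mesh.order != 1:
        raise ValueError("refine expects a linear mesh; linearize first")
    q = to_quadratic(mesh)
    c = q.tets  # (m, 10): corners 0-3, midsides 4-9 on TET10_EDGES
    n0, n1, n2, n3 = (c[:, i] for i in range(4))
    m01, m12, m20, m03, m13, m23 = (c[:, 4 + i] for i in range(6))
    children = [
        (n0, m01, m20, m03), (m01, n1, m12, m13),
        (m20, m12, n2, m23), (m03, m13, m23, n3),
        # interior octahedron split along diagonal m01-m23
        (m01, m12, m20, m23), (m01, m13, m12, m23),
        (m01, m20, m03, m23), (m01, m03, m13, m23),
    ]
    tets = np.concatenate([np.stack(ch, axis=1) for ch in children], axis=0)
    tets = _orient_positive(q.nodes, tets)
    # propagate surface tags: split each tagged face into 4
    mids = edge_midpoint_map(q)

    def mid(a, b):
        return mids[(min(a, b), max(a, b))]

    surfaces = {}
    for tag, faces in mesh.surfaces.items():
        out = np.empty((4 * len(faces), 3), dtype=np.int64)
        for i, (a, b, cc) in enumerate(faces):
            mab, mbc, mca = mid(a, b), mid(b, cc), mid(cc, a)
            out[4 * i:4 * i + 4] = [(a, mab, mca), (mab, b, mbc),
                                    (mca, mbc, cc), (mab, mbc, mca)]
        surfaces[tag] = out
    return LVMesh(nodes=q.nodes, tets=tets, order=1, surfaces=surfaces,
                  provenance=mesh.provenance, spec=mesh.spec)


def linearize(mesh: LVMesh) -> LVMesh:
    """Drop midside nodes, keeping corner connectivity and surface tags."""
    if mesh.order == 1:
        return mesh
    used = np.unique(mesh.corners)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(len(used))
    surfaces = {t: remap[f] for t, f in mesh.surfaces.items()}
    return LVMesh(nodes=mesh.nodes[used], tets=remap[mesh.corners], order=1,
                  surfaces=surfaces, provenance=mesh.provenance, spec=mesh.spec)


# ---------------------------------------------------------------------------
# enclosed (cavity) volume

def cavity_closure(mesh: LVMesh, endo_tag: str = "endocardium"):
    """Triangles closing the cavity: endocardial surface + base-plane cap fan.

    Returns (tris, rim, sign): flat endocardial triangles, rim edges (each
    appearing once in the patch, in patch orientation), and the sign that
    makes the signed enclosed volume positive for the reference nodes.
    The cap apex is the rim centroid in whatever coordinates are supplied to
    :func:`enclosed_volume`; with the base held on its plane the cap stays
    planar under deformation.
    """
    tris = surface_triangles(mesh, endo_tag)
    edges = np.concatenate([tris[:, (0, 1)], tris[:, (1, 2)], tris[:, (2, 0)]], axis=0)
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    rim = edges[counts[inv] == 1]
    v = _signed_enclosed(mesh.nodes, tris, rim)
    sign = 1.0 if v >= 0 else -1.0
    return tris, rim, sign


def _signed_enclosed(nodes, tris, rim):
    a, b, c = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
    v = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    if len(rim):
        apex = nodes[np.unique(rim)].mean(axis=0)
        # cap triangles (v1, v0, apex) close the patch with opposite edge use
        p, q = nodes[rim[:, 1]], nodes[rim[:, 0]]
        v += np.einsum("ij,ij->i", p, np.cross(q, apex[None, :].repeat(len(p), 0))).sum() / 6.0
    return v


def enclosed_volume(nodes: np.ndarray, tris: np.ndarray, rim: np.ndarray,
                    sign: float = 1.0) -> float:
    """Volume enclosed by the closed surface patch + cap (divergence theorem)."""
    return sign * _signed_enclosed(nodes, tris, rim)
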