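"""Truncated-ellipsoid left-ventricle geometry.

The LV is idealized as a thick-walled shell between two confocal-ish
ellipsoid surfaces, cut by a base plane perpendicular to the long axis.
Convention: the long axis is z, the base plane sits at z = z_base >= 0
(z_base = 0 truncates at the equator), and the apex points toward negative z.
Lengths default to cm, matching rat-heart dimensions of a few millimetres to
a centimetre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .mesh import (
    LVMesh, boundary_faces, classify_boundary, cavity_closure,
    enclosed_volume, kuhn_tets_from_hexes, surface_triangles, tet_volumes,
    to_quadratic, _orient_positive,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EllipsoidSpec:
    """Semi-axes of the epicardial / endocardial ellipsoids plus truncation.

    ``truncation_fraction`` positions the base plane along the long axis as a
    fraction of the epicardial long semi-axis above the equator (0 = equator).
    """

    epi_semiaxes: tuple = (0.34, 0.48, 0.95)
    endo_semiaxes: tuple = (0.16, 0.27, 0.79)
    truncation_fraction: float = 0.0
    unit: str = "cm"

    def __post_init__(self):
        epi = np.asarray(self.epi_semiaxes, dtype=float)
        endo = np.asarray(self.endo_semiaxes, dtype=float)
        if epi.shape != (3,) or endo.shape != (3,):
            raise ValueError("semi-axes must be length-3")
        if np.any(endo <= 0) or np.any(epi <= 0):
            raise ValueError("semi-axes must be positive")
        if np.any(epi <= endo):
            raise ValueError(f"each epicardial semi-axis must exceed the "
                             f"endocardial one: epi={epi}, endo={endo}")
        if not 0 <= self.truncation_fraction < 0.5:
            raise ValueError("truncation_fraction must lie in [0, 0.5)")

    @property
    def z_base(self) -> float:
        return self.truncation_fraction * self.epi_semiaxes[2]

    @property
    def min_wall_thickness(self) -> float:
        e = np.asarray(self.epi_semiaxes) - np.asarray(self.endo_semiaxes)
        return float(e.min())

    def cavity_volume_closed_form(self) -> float:
        """Volume of the endocardial ellipsoid below the base plane."""
        a, b, c = self.endo_semiaxes
        t = min(self.z_base / c, 1.0)
        return np.pi * a * b * c * (2.0 / 3.0 + t - t ** 3 / 3.0)

    def tissue_volume_closed_form(self) -> float:
        a, b, c = self.epi_semiaxes
        t = self.z_base / c
        epi = np.pi * a * b * c * (2.0 / 3.0 + t - t ** 3 / 3.0)
        return epi - self.cavity_volume_closed_form()


@dataclass
class MaterialFrame:
    """Per-element orthonormal material axes: radial r, circumferential c,
    longitudinal l, with det[r c l] = +1 (c = l x r)."""

    r: np.ndarray
    c: np.ndarray
    l: np.ndarray

    def __len__(self):
        return len(self.r)


def rat_pre_p_spec() -> EllipsoidSpec:
    """Geometry of the unloaded (pre-P) rat LV mesh."""
    return EllipsoidSpec((0.34, 0.48, 0.95), (0.16, 0.27, 0.79), 0.0)


def rat_post_p_spec() -> EllipsoidSpec:
    """Geometry of the passively pressurized (post-P) rat LV mesh."""
    return EllipsoidSpec((0.40, 0.48, 0.99), (0.26, 0.30, 0.84), 0.0)


# ---------------------------------------------------------------------------
# mesh generation

def _surface_point(semiaxes, theta, phi):
    a, b, c = semiaxes
    theta, phi = np.broadcast_arrays(np.asarray(theta, dtype=float), phi)
    st = np.sin(theta)
    return np.stack([a * st * np.cos(phi), b * st * np.sin(phi),
                     c * np.cos(theta)], axis=-1)


def _theta_base(semiaxes, z_base):
    # z = c cos(theta): base plane (z = z_base >= 0) at theta_base, apex
    # (z = -c) at theta = pi
    c = semiaxes[2]
    if z_base >= c:
        raise ValueError("base plane above the apex of a surface")
    return np.arccos(np.clip(z_base / c, -1.0, 1.0))


def build_lv_mesh(spec: EllipsoidSpec, target_edge_length: float = 0.06,
                  order: int = 1, divisions=None) -> LVMesh:
    """Build the truncated-ellipsoid shell mesh.

    Structured (transmural x azimuthal x apico-basal) hexahedral grid,
    Kuhn-subdivided into tetrahedra; the apex ring collapses to axis nodes.
    ``divisions=(nu, nphi, ns)`` overrides the resolution chosen from
    ``target_edge_length``.  Deterministic for fixed inputs.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    h = float(target_edge_length)
    if h >= spec.min_wall_thickness:
        raise ValueError(
            f"target_edge_length {h} must be below the smallest wall "
            f"thickness {spec.min_wall_thickness:.4g} (spec: {spec})")
    if divisions is None:
        a_ep, b_ep, c_ep = spec.epi_semiaxes
        nu = max(2, int(np.ceil(spec.min_wall_thickness / h)))
        nphi = max(8, int(np.ceil(2 * np.pi * np.sqrt((a_ep**2 + b_ep**2) / 2) / h)))
        arc = (np.pi - _theta_base(spec.epi_semiaxes, spec.z_base)) \
            * np.sqrt((b_ep**2 + c_ep**2) / 2)
        ns = max(4, int(np.ceil(arc / h)))
    else:
        nu, nphi, ns = divisions

    th_en = _theta_base(spec.endo_semiaxes, spec.z_base)
    th_ep = _theta_base(spec.epi_semiaxes, spec.z_base)
    phi = 2 * np.pi * np.arange(nphi) / nphi
    s = np.arange(ns + 1) / ns

    # node ids: rings (iu, is<ns, iphi), then axis nodes (apex) per iu
    def nid(iu, iphi, isv):
        return iu * (ns * nphi) + isv * nphi + (iphi % nphi)

    n_ring = (nu + 1) * ns * nphi

    def apex_id(iu):
        return n_ring + iu

    nodes = np.empty((n_ring + nu + 1, 3))
    for iu in range(nu + 1):
        u = iu / nu
        for isv in range(ns):
            t_en = th_en + (np.pi - th_en) * s[isv]
            t_ep = th_ep + (np.pi - th_ep) * s[isv]
            p = (1 - u) * _surface_point(spec.endo_semiaxes, t_en, phi) \
                + u * _surface_point(spec.epi_semiaxes, t_ep, phi)
            nodes[nid(iu, np.arange(nphi), isv)] = p
        apex = np.array([0.0, 0.0,
                         -((1 - u) * spec.endo_semiaxes[2] + u * spec.epi_semiaxes[2])])
        nodes[apex_id(iu)] = apex

    iu_g, ip_g, is_g = np.meshgrid(np.arange(nu), np.arange(nphi),
                                   np.arange(ns), indexing="ij")
    iu_g, ip_g, is_g = iu_g.ravel(), ip_g.ravel(), is_g.ravel()
    corners = np.empty((len(iu_g), 2, 2, 2), dtype=np.int64)
    for du in (0, 1):
        for dp in (0, 1):
            for ds in (0, 1):
                isv = is_g + ds
                cid = np.where(isv == ns, apex_id(iu_g + du),
                               nid(iu_g + du, ip_g + dp, np.minimum(isv, ns - 1)))
                corners[:, du, dp, ds] = cid
    tets = kuhn_tets_from_hexes(corners)
    tets = _orient_positive(nodes, tets)
    vols = tet_volumes(nodes, tets)
    if np.any(vols <= 0):
        raise RuntimeError(f"meshing produced non-positive element volumes "
                           f"for spec {spec}")

    n = len(nodes)
    endo_mask = np.zeros(n, dtype=bool)
    epi_mask = np.zeros(n, dtype=bool)
    base_mask = np.zeros(n, dtype=bool)
    for isv in range(ns):
        endo_mask[nid(0, np.arange(nphi), isv)] = True
        epi_mask[nid(nu, np.arange(nphi), isv)] = True
    endo_mask[apex_id(0)] = True
    epi_mask[apex_id(nu)] = True
    for iu in range(nu + 1):
        base_mask[nid(iu, np.arange(nphi), 0)] = True

    faces = boundary_faces(tets)
    surfaces = classify_boundary(
        faces, {"base": base_mask, "endocardium": endo_mask, "epicardium": epi_mask})
    mesh = LVMesh(nodes=nodes, tets=tets, order=1, surfaces=surfaces,
                  provenance="reference", spec=spec)
    if order == 2:
        mesh = to_quadratic(mesh)
    return mesh


# ---------------------------------------------------------------------------
# volumes

def mesh_volumes(mesh: LVMesh):
    """(cavity_volume, tissue_volume) of a tagged LV mesh.

    Cavity volume is enclosed by the endocardial surface plus the base-plane
    cap; tissue volume is the sum of element volumes.
    """
    if "endocardium" not in mesh.surfaces:
        raise ValueError("mesh has no tagged endocardium; cannot close cavity")
    tris, rim, sign = cavity_closure(mesh)
    cavity = enclosed_volume(mesh.nodes, tris, rim, sign)
    tissue = float(np.abs(mesh.element_volumes()).sum())
    return cavity, tissue


def cavity_volume(mesh: LVMesh, nodes=None) -> float:
    tris, rim, sign = cavity_closure(mesh)
    pts = mesh.nodes if nodes is None else nodes
    return enclosed_volume(pts, tris, rim, sign)


# ---------------------------------------------------------------------------
# transmural coordinate and material axes

def _ray_depth(points: np.ndarray, spec: EllipsoidSpec) -> np.ndarray:
    """Normalized transmural depth along the radial ray from the origin.

    q(x) = sqrt(sum (x_i/a_i)^2) is 1 on a surface and scales linearly along
    rays through the origin, so the ray hits the endocardium at t = 1/q_endo
    and the epicardium at t = 1/q_epi.
    """
    q_en = np.linalg.norm(points / np.asarray(spec.endo_semiaxes), axis=-1)
    q_ep = np.linalg.norm(points / np.asarray(spec.epi_semiaxes), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_en = 1.0 / q_en
        t_ep = 1.0 / q_ep
        w = (1.0 - t_en) / (t_ep - t_en)
    return w


def transmural_depth(mesh: LVMesh, clip_tol: float = 0.05) -> np.ndarray:
    """Per-element normalized wall depth: 0 at endocardium, 1 at epicardium.

    Uses the generating ellipsoid spec in closed form when available;
    otherwise falls back to relative distance to the tagged surfaces
    (coarser: accuracy is limited by surface facet size).
    """
    cent = mesh.element_centroids()
    if mesh.spec is not None:
        w = _ray_depth(cent, mesh.spec)
    else:
        if not {"endocardium", "epicardium"} <= set(mesh.surfaces):
            raise ValueError("untagged mesh and no generating spec: "
                             "transmural depth undefined")
        from scipy.spatial import cKDTree
        d = {}
        for tag in ("endocardium", "epicardium"):
            tris = surface_triangles(mesh, tag)
            pts = np.vstack([mesh.nodes[np.unique(tris)],
                             mesh.nodes[tris].mean(axis=1)])
            d[tag], _ = cKDTree(pts).query(cent)
        w = d["endocardium"] / (d["endocardium"] + d["epicardium"])
    n_out = int(np.sum((w < -clip_tol) | (w > 1 + clip_tol)))
    if n_out:
        logger.warning("transmural_depth: %d centroids outside shell, clamped", n_out)
    return np.clip(w, 0.0, 1.0)


def _depth_gradient(points: np.ndarray, spec: EllipsoidSpec,
                    h: float = 1e-6) -> np.ndarray:
    g = np.empty_like(points)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        g[:, k] = (_ray_depth(points + dp, spec) - _ray_depth(points - dp, spec)) / (2 * h)
    return g


def material_axes(mesh: LVMesh) -> MaterialFrame:
    """Per-element (r, c, l): outward radial, circumferential, longitudinal.

    r follows the gradient of the transmural depth; l is the long-axis
    direction projected orthogonal to r; c = l x r closes a right-handed
    triple.  Near the apex, where the long axis degenerates onto r, c falls
    back to the azimuthal direction.
    """
    cent = mesh.element_centroids()
    if mesh.spec is not None:
        g = _depth_gradient(cent, mesh.spec)
    else:
        # fall back: radial direction from surface-distance depth is not
        # available in closed form; use outward position in the slice plane
        # blended with z from a finite-difference of the fallback depth.
        raise ValueError("material_axes requires a generating ellipsoid spec")
    r = g / np.linalg.norm(g, axis=1, keepdims=True)
    z = np.array([0.0, 0.0, 1.0])
    l_raw = z - r * r[:, 2:3]
    nrm = np.linalg.norm(l_raw, axis=1)
    degen = nrm < 1e-3
    if degen.any():
        logger.info("material_axes: %d near-apex elements use azimuthal fallback",
                    int(degen.sum()))
        rho = cent[degen].copy()
        rho[:, 2] = 0.0
        rho /= np.maximum(np.linalg.norm(rho, axis=1, keepdims=True), 1e-300)
        c_f = np.cross(np.broadcast_to(z, rho.shape), rho)
        l_f = np.cross(c_f, r[degen])
        l_raw[degen] = l_f
        nrm = np.linalg.norm(l_raw, axis=1)
    l = l_raw / nrm[:, None]
    c = np.cross(l, r)
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    # re-orthogonalize l exactly
    l = np.cross(r, c)
    return MaterialFrame(r=r, c=c, l=l)


def scale_mesh(mesh: LVMesh, s: float) -> LVMesh:
    """Uniform scaling about the origin on the base plane."""
    if s <= 0:
        raise ValueError("scale factor must be positive")
    out = mesh.copy_with_nodes(mesh.nodes * s)
    if mesh.spec is not None:
        out = replace(out, spec=replace(
            mesh.spec,
            epi_semiaxes=tuple(np.asarray(mesh.spec.epi_semiaxes) * s),
            endo_semiaxes=tuple(np.asarray(mesh.spec.endo_semiaxes) * s)))
    return out


# ---------------------------------------------------------------------------
# wall thickness

def _ray_surface_hits(origin, direction, nodes, tris):
    """Moller-Trumbore distances of ray origin+t*direction to triangles."""
    v0 = nodes[tris[:, 0]]
    e1 = nodes[tris[:, 1]] - v0
    e2 = nodes[tris[:, 2]] - v0
    p = np.cross(np.broadcast_to(direction, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tv = origin - v0
    u = np.einsum("ij,ij->i", tv, p) * inv
    q = np.cross(tv, e1)
    v = np.einsum("j,ij->i", direction, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-12)
    return t[hit]


def wall_thickness(mesh: LVMesh, slice_fraction: float = 0.5, n_rays: int = 4,
                   phase_deg: float = 0.0) -> float:
    """Mean wall thickness on a short-axis slice.

    The slice sits at ``slice_fraction`` of the long-axis length below the
    base.  ``n_rays`` rays are cast symmetrically (default every 90 degrees,
    starting at ``phase_deg`` from +x) from the cavity centroid of the slice;
    thickness per ray = epicardial minus endocardial hit distance.
    """
    z_top = mesh.nodes[np.unique(mesh.surfaces["base"])][:, 2].mean() \
        if "base" in mesh.surfaces else mesh.nodes[:, 2].max()
    z_bot = mesh.nodes[:, 2].min()
    L = z_top - z_bot
    z0 = z_top - slice_fraction * L
    endo_nodes = mesh.nodes[np.unique(surface_triangles(mesh, "endocardium"))]
    band = L / 8
    near = endo_nodes[np.abs(endo_nodes[:, 2] - z0) < band]
    if len(near) == 0:
        raise ValueError("slice plane does not intersect the endocardium")
    origin = np.array([near[:, 0].mean(), near[:, 1].mean(), z0])

    endo_tris = surface_triangles(mesh, "endocardium")
    epi_tris = surface_triangles(mesh, "epicardium")
    thick = []
    for k in range(n_rays):
        ang = np.deg2rad(phase_deg + 360.0 * k / n_rays)
        d = np.array([np.cos(ang), np.sin(ang), 0.0])
        t_en = _ray_surface_hits(origin, d, mesh.nodes, endo_tris)
        t_ep = _ray_surface_hits(origin, d, mesh.nodes, epi_tris)
        if len(t_en) == 0 or len(t_ep) == 0:
            raise ValueError(f"wall-thickness ray {k} (azimuth "
                             f"{np.rad2deg(ang):.1f} deg) misses a surface")
        thick.append(t_ep.min() - t_en.min())
    return float(np.mean(thick))
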