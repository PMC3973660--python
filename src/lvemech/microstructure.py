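"""Fibre and sheet architecture models and regional fitting.

The fibre (helix) angle follows a Streeter-type transmural rule

    theta(w) = R * sgn(1 - 2w) * |1 - 2w|**n,

so theta = +R at the endocardium (w = 0), 0 at midwall and -R at the
epicardium; n = 1 gives a linear profile, n = 3 a cubic one.  The sheet
angle varies either linearly across the wall or as a sigmoidal ("bimodal")
step mimicking two sheet populations.  A subject-specific variant fits
(R, n) per region of a 16-region partition (the AHA 17-segment scheme with
the apex cap dropped) to axial fibre-direction observations such as DT-MRI
primary eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .geometry import MaterialFrame
from .mesh import LVMesh

DEFAULT_R_VALUES = (50.0, 60.0, 70.0, 80.0)  # degrees
DEFAULT_N_VALUES = (0.5, 1.0, 2.0, 3.0)


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class FibreModelSpec:
    """Rule-based fibre model: transmural rotation R (deg) and exponent n."""

    R: float = 70.0
    n: float = 1.0
    kind: str = "rule_based"

    def __post_init__(self):
        if not 0 < self.R <= 90:
            raise ValueError("R must lie in (0, 90] degrees")
        if self.n <= 0:
            raise ValueError("exponent n must be positive")

    @property
    def name(self) -> str:
        return f"Sn{_fmt(self.n)}R{_fmt(self.R)}"


def rule_based_models(R_values=DEFAULT_R_VALUES,
                      n_values=DEFAULT_N_VALUES) -> list[FibreModelSpec]:
    """The 4x4 grid of globally prescribed fibre models (Sn{n}R{R})."""
    return [FibreModelSpec(R=R, n=n) for R in R_values for n in n_values]


@dataclass(frozen=True)
class SheetModelSpec:
    """Transmural sheet-angle model: linear ramp or sigmoidal step."""

    kind: str = "linear"  # linear | bimodal
    beta_endo: float = 45.0
    beta_epi: float = -45.0
    k: float = 30.0  # sigmoid steepness (bimodal only)

    def __post_init__(self):
        if self.kind not in ("linear", "bimodal"):
            raise ValueError("sheet model kind must be 'linear' or 'bimodal'")
        if abs(self.beta_endo) > 90 or abs(self.beta_epi) > 90:
            raise ValueError("|beta| must not exceed 90 degrees")
        if self.k <= 0:
            raise ValueError("sigmoid steepness k must be positive")

    @property
    def name(self) -> str:
        return f"{self.kind}_b{_fmt(self.beta_endo)}_{_fmt(self.beta_epi)}"


@dataclass
class RegionalFibreModel:
    """Per-region (R, n) pairs over the 16-region partition."""

    R: np.ndarray  # (16,) degrees
    n: np.ndarray  # (16,)
    residual_deg: np.ndarray  # (16,) mean angular error of the fit
    boundary_flag: np.ndarray = field(default=None)  # (16,) bool
    kind: str = "regional"
    name: str = "regional"

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.R.shape != (16,) or self.n.shape != (16,):
            raise ValueError("regional model requires exactly 16 (R, n) pairs")
        if self.boundary_flag is None:
            self.boundary_flag = np.zeros(16, dtype=bool)


@dataclass
class StructureField:
    """Per-element orthonormal fibre / sheet / sheet-normal frame."""

    f: np.ndarray
    s: np.ndarray
    n_vec: np.ndarray
    provenance: str = ""

    def __len__(self):
        return len(self.f)

    def rotation_matrices(self) -> np.ndarray:
        """(ne, 3, 3) with columns (f, s, n_vec)."""
        return np.stack([self.f, self.s, self.n_vec], axis=-1)


@dataclass
class FibreObservationSet:
    """Axial (sign-free) unit-vector observations per element."""

    vectors: np.ndarray  # (ne, 3)
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        nrm = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(nrm - 1) > 1e-8):
            raise ValueError("observed fibre vectors must be unit norm")


# ---------------------------------------------------------------------------
# angle rules

def helix_angle(w, R: float, n: float):
    """Streeter-type helix angle (degrees) at normalized depth w in [0, 1]."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("transmural depth w must lie in [0, 1]")
    x = 1.0 - 2.0 * w
    return R * np.sign(x) * np.abs(x) ** n


def sheet_angle(w, spec: SheetModelSpec):
    """Sheet angle (degrees) at normalized depth w for a sheet model."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("transmural depth w must lie in [0, 1]")
    if spec.kind == "linear":
        return spec.beta_endo + (spec.beta_epi - spec.beta_endo) * w
    return spec.beta_endo + (spec.beta_epi - spec.beta_endo) \
        / (1.0 + np.exp(-spec.k * (w - 0.5)))


# ---------------------------------------------------------------------------
# frames

def _rotate_about(axis: np.ndarray, vec: np.ndarray, ang_rad: np.ndarray):
    """Rodrigues rotation of unit vectors about unit axes (vectorized)."""
    ca = np.cos(ang_rad)[:, None]
    sa = np.sin(ang_rad)[:, None]
    dot = np.einsum("ij,ij->i", axis, vec)[:, None]
    return vec * ca + np.cross(axis, vec) * sa + axis * dot * (1 - ca)


def build_structure_field(mesh: LVMesh, frame: MaterialFrame, w: np.ndarray,
                          fibre, sheet: SheetModelSpec,
                          regions: Optional[np.ndarray] = None) -> StructureField:
    """Rotate material axes into fibre/sheet/sheet-normal frames.

    The fibre f is the circumferential axis rotated about r by the helix
    angle; the sheet s is the radial axis rotated about f by the sheet
    angle; n_vec = f x s keeps the triple right-handed.  Regional models
    look up each element's (R, n) via ``regions`` labels in 1..16.
    """
    ne = len(frame)
    if len(w) != ne:
        raise ValueError("depth array and frame size mismatch")
    if isinstance(fibre, RegionalFibreModel):
        if regions is None:
            raise ValueError("regional fibre model requires region labels")
        if np.any((regions < 1) | (regions > 16)):
            raise ValueError("region labels must lie in 1..16")
        theta = helix_angle(w, 1.0, 1.0) * 0.0  # allocate
        for reg in range(1, 17):
            m = regions == reg
            if m.any():
                theta[m] = helix_angle(w[m], fibre.R[reg - 1], fibre.n[reg - 1])
        prov = f"{fibre.name}+{sheet.name}"
    else:
        theta = helix_angle(w, fibre.R, fibre.n)
        prov = f"{fibre.name}+{sheet.name}"
    beta = sheet_angle(w, sheet)

    th = np.deg2rad(theta)
    f = _rotate_about(frame.r, frame.c, th)
    be = np.deg2rad(np.broadcast_to(beta, (ne,)).copy())
    s = _rotate_about(f, frame.r, be)
    n_vec = np.cross(f, s)
    # numerical clean-up: renormalize
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    n_vec /= np.linalg.norm(n_vec, axis=1, keepdims=True)
    return StructureField(f=f, s=s, n_vec=n_vec, provenance=prov)


# ---------------------------------------------------------------------------
# regional partition

def partition_regions(mesh: LVMesh) -> np.ndarray:
    """Label elements 1..16: basal third 6 azimuthal sectors, mid third 6,
    apical third 4.  Azimuth origin at the +x meridian."""
    cent = mesh.element_centroids()
    z_top = mesh.nodes[:, 2].max()
    z_bot = mesh.nodes[:, 2].min()
    frac = (z_top - cent[:, 2]) / (z_top - z_bot)  # 0 at base, 1 at apex
    phi = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2 * np.pi)
    labels = np.empty(len(cent), dtype=np.int64)
    basal = frac < 1 / 3
    mid = (frac >= 1 / 3) & (frac < 2 / 3)
    apical = frac >= 2 / 3
    labels[basal] = 1 + np.floor(phi[basal] / (np.pi / 3)).astype(int) % 6
    labels[mid] = 7 + np.floor(phi[mid] / (np.pi / 3)).astype(int) % 6
    labels[apical] = 13 + np.floor(phi[apical] / (np.pi / 2)).astype(int) % 4
    return labels


# ---------------------------------------------------------------------------
# fitting

def angular_difference(u: np.ndarray, v: np.ndarray):
    """Axial angle between sign-free unit vectors, degrees in [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("zero vector passed to angular_difference")
    dot = np.abs(np.einsum("...i,...i->...", u, v) / (nu * nv))
    return np.rad2deg(np.arccos(np.clip(dot, 0.0, 1.0)))


def _region_cost_factory(frame, w, obs, weights):
    # f(theta) = cos(theta) c + sin(theta) l  (rotation about r of c)
    a = np.einsum("ij,ij->i", frame.c, obs)
    b = np.einsum("ij,ij->i", frame.l, obs)
    x = 1.0 - 2.0 * w
    sx = np.sign(x)
    ax = np.abs(x)
    wt = np.ones_like(a) if weights is None else weights

    def cost(R, n):
        theta = np.deg2rad(R * sx * ax ** n)
        dot = np.abs(np.cos(theta) * a + np.sin(theta) * b)
        ang = np.rad2deg(np.arccos(np.clip(dot, 0.0, 1.0)))
        return float(np.average(ang, weights=wt))

    return cost


def fit_regional_fibre_model(mesh: LVMesh, frame: MaterialFrame, w: np.ndarray,
                             observations: FibreObservationSet,
                             regions: np.ndarray,
                             R_grid=None, n_grid=None,
                             min_per_region: int = 10) -> RegionalFibreModel:
    """Fit (R, n) per region by minimizing the mean axial angular error.

    Deterministic coarse grid search (R in 1-degree steps over [30, 90],
    n log-spaced over [0.25, 4]) followed by Nelder-Mead refinement clipped
    to the grid bounds.  Ties on the grid break toward smaller n, then
    smaller R.  Exactly sign-flip invariant in the observations.
    """
    if R_grid is None:
        R_grid = np.arange(30.0, 90.0 + 1e-9, 1.0)
    if n_grid is None:
        n_grid = np.geomspace(0.25, 4.0, 17)
    n_grid = np.sort(np.asarray(n_grid, dtype=float))
    R_out = np.empty(16)
    n_out = np.empty(16)
    res_out = np.empty(16)
    flag = np.zeros(16, dtype=bool)
    for reg in range(1, 17):
        m = regions == reg
        if m.sum() == 0:
            raise ValueError(f"region {reg} contains no observed elements")
        if m.sum() < min_per_region:
            raise ValueError(f"region {reg} has only {int(m.sum())} observed "
                             f"elements (< {min_per_region})")
        sub = MaterialFrame(r=frame.r[m], c=frame.c[m], l=frame.l[m])
        wts = None if observations.weights is None else observations.weights[m]
        cost = _region_cost_factory(sub, w[m], observations.vectors[m], wts)
        # vectorized grid evaluation
        a = np.einsum("ij,ij->i", sub.c, observations.vectors[m])
        b = np.einsum("ij,ij->i", sub.l, observations.vectors[m])
        x = 1.0 - 2.0 * w[m]
        pow_n = np.sign(x)[None, :] * np.abs(x)[None, :] ** n_grid[:, None]
        theta = np.deg2rad(R_grid[None, :, None] * pow_n[:, None, :])
        dot = np.abs(np.cos(theta) * a + np.sin(theta) * b)
        ang = np.rad2deg(np.arccos(np.clip(dot, 0.0, 1.0)))
        wt = np.ones(int(m.sum())) if wts is None else wts
        grid_cost = (ang * wt).sum(axis=2) / wt.sum()  # (n, R)
        i_n, i_R = np.unravel_index(np.argmin(grid_cost), grid_cost.shape)
        R0, n0 = R_grid[i_R], n_grid[i_n]

        def obj(p):
            R = float(np.clip(p[0], R_grid[0], R_grid[-1]))
            n = float(np.clip(np.exp(p[1]), n_grid[0], n_grid[-1]))
            return cost(R, n)

        sol = minimize(obj, x0=[R0, np.log(n0)], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
        R_fit = float(np.clip(sol.x[0], R_grid[0], R_grid[-1]))
        n_fit = float(np.clip(np.exp(sol.x[1]), n_grid[0], n_grid[-1]))
        R_out[reg - 1] = R_fit
        n_out[reg - 1] = n_fit
        res_out[reg - 1] = cost(R_fit, n_fit)
        tol = 1e-6
        flag[reg - 1] = (abs(R_fit - R_grid[0]) < tol or abs(R_fit - R_grid[-1]) < tol
                         or abs(n_fit - n_grid[0]) < tol or abs(n_fit - n_grid[-1]) < tol)
    return RegionalFibreModel(R=R_out, n=n_out, residual_deg=res_out,
                              boundary_flag=flag)
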