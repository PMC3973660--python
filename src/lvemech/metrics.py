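"""Global and local deformation metrics.

Global: ejection fraction EF = (V(t0) - V(t1))/V(t0); wall thickening WT
(change of the four-ray mean wall thickness on a midventricular short-axis
slice); base-to-apex shortening SBA (change of the apico-basal length,
negative = shortening).  Local: Lagrangian strain in cylindrical
coordinates at element centroids — circumferential normal strain E_cc and
the circumferential-longitudinal / circumferential-radial shears E_cl and
E_cr — optionally averaged over basal/mid/apical thirds with the initial
(residual) value subtracted.

All operations work on any result object exposing ``mesh`` (reference),
``times``, ``u_samples``, ``F_samples`` and ``volumes`` — both the coupled
simulator and the analytic-motion generator produce these.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import wall_thickness as _wall_thickness

logger = logging.getLogger(__name__)


@dataclass
class GlobalMetrics:
    EF: float
    WT: float
    SBA: float
    t0: float
    t1: float


@dataclass
class StrainSeries:
    """Per-sample, per-element cylindrical strain components."""

    times: np.ndarray
    E_cc: np.ndarray  # (nt, ne)
    E_cl: np.ndarray
    E_cr: np.ndarray
    thirds: np.ndarray  # per element: 'basal' | 'mid' | 'apical'
    valid: np.ndarray  # per element bool (off-axis basis defined)
    residual_subtracted: bool = False


def _sample_index(times: np.ndarray, t: float) -> int:
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) > 1e-6 + 1e-3 * max(1.0, abs(t)):
        logger.info("using nearest sample t=%.3f for requested %.3f",
                    times[i], t)
    return i


def ejection_fraction(result, t0: Optional[float] = None,
                      t1: Optional[float] = None) -> float:
    """EF = (V(t0) - V(t1)) / V(t0); defaults to first and last samples."""
    times = np.asarray(result.times)
    t0 = times[0] if t0 is None else t0
    t1 = times[-1] if t1 is None else t1
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    v0 = result.volumes[_sample_index(times, t0)]
    v1 = result.volumes[_sample_index(times, t1)]
    if v0 <= 0:
        raise ValueError("non-positive cavity volume at t0")
    return float((v0 - v1) / v0)


def _deformed_mesh(result, i: int):
    return result.mesh.copy_with_nodes(result.mesh.nodes + result.u_samples[i])


def wall_thickening(result, slice_fraction: float = 0.5,
                    t0: Optional[float] = None,
                    t1: Optional[float] = None) -> float:
    """WT = thickness(t1) - thickness(t0) on the configured slice."""
    times = np.asarray(result.times)
    i0 = _sample_index(times, times[0] if t0 is None else t0)
    i1 = _sample_index(times, times[-1] if t1 is None else t1)
    th0 = _wall_thickness(_deformed_mesh(result, i0), slice_fraction)
    th1 = _wall_thickness(_deformed_mesh(result, i1), slice_fraction)
    return float(th1 - th0)


def apex_node(mesh) -> int:
    """Epicardial node at the long-axis extreme of the reference mesh."""
    if "epicardium" in mesh.surfaces:
        cand = np.unique(mesh.surfaces["epicardium"])
    else:
        cand = np.arange(mesh.n_nodes)
    return int(cand[np.argmin(mesh.nodes[cand, 2])])


def base_apex_shortening(result, t0: Optional[float] = None,
                         t1: Optional[float] = None) -> float:
    """Change in apico-basal length, tracked at the epicardial apex node.

    With the base held on its plane, SBA = z_apex(t0) - z_apex(t1)
    (apex at negative z): negative values mean the ventricle shortened.
    """
    times = np.asarray(result.times)
    i0 = _sample_index(times, times[0] if t0 is None else t0)
    i1 = _sample_index(times, times[-1] if t1 is None else t1)
    ap = apex_node(result.mesh)
    z0 = result.mesh.nodes[ap, 2] + result.u_samples[i0][ap, 2]
    z1 = result.mesh.nodes[ap, 2] + result.u_samples[i1][ap, 2]
    return float(z0 - z1)


def cylindrical_strains(result, axis_tol: float = 1e-8) -> StrainSeries:
    """Green-Lagrange strain components in the cylindrical basis.

    The basis is built at each reference element centroid: radial = in-plane
    position direction, longitudinal = long axis (z), circumferential =
    z x radial.  Elements whose centroid lies on the long axis are excluded.
    """
    mesh = result.mesh
    cent = mesh.element_centroids()
    rho = cent.copy()
    rho[:, 2] = 0.0
    rn = np.linalg.norm(rho, axis=1)
    valid = rn > axis_tol
    n_excl = int((~valid).sum())
    if n_excl:
        logger.info("cylindrical_strains: %d on-axis elements excluded", n_excl)
    e_r = np.zeros_like(rho)
    e_r[valid] = rho[valid] / rn[valid, None]
    e_z = np.broadcast_to([0.0, 0.0, 1.0], e_r.shape)
    e_c = np.cross(e_z, e_r)

    F = np.asarray(result.F_samples)  # (nt, ne, 3, 3)
    C = np.einsum("teki,tekj->teij", F, F)
    E = 0.5 * (C - np.eye(3))
    E_cc = np.einsum("ei,teij,ej->te", e_c, E, e_c)
    E_cl = np.einsum("ei,teij,ej->te", e_c, E, e_z)
    E_cr = np.einsum("ei,teij,ej->te", e_c, E, e_r)

    z_top = mesh.nodes[:, 2].max()
    z_bot = mesh.nodes[:, 2].min()
    frac = (z_top - cent[:, 2]) / (z_top - z_bot)
    thirds = np.where(frac < 1 / 3, "basal",
                      np.where(frac < 2 / 3, "mid", "apical"))
    return StrainSeries(times=np.asarray(result.times), E_cc=E_cc, E_cl=E_cl,
                        E_cr=E_cr, thirds=thirds, valid=valid)


def regional_average(series: StrainSeries,
                     subtract_residual: bool = False) -> pd.DataFrame:
    """Unweighted per-third mean traces of each strain component.

    With ``subtract_residual`` the value at the first sample is subtracted
    component-wise, so every trace starts at zero (removes the strain
    already present at the chosen reference time).
    """
    rows = []
    for third in ("basal", "mid", "apical"):
        m = (series.thirds == third) & series.valid
        if not m.any():
            raise ValueError(f"no elements in the {third} third")
        for comp, arr in (("E_cc", series.E_cc), ("E_cl", series.E_cl),
                          ("E_cr", series.E_cr)):
            trace = arr[:, m].mean(axis=1)
            if subtract_residual:
                trace = trace - trace[0]
            for t, v in zip(series.times, trace):
                rows.append({"time": t, "region": third,
                             "component": comp, "value": v})
    return pd.DataFrame(rows)


def global_metrics(result, slice_fraction: float = 0.5,
                   t0: Optional[float] = None,
                   t1: Optional[float] = None) -> GlobalMetrics:
    times = np.asarray(result.times)
    t0v = times[0] if t0 is None else t0
    t1v = times[-1] if t1 is None else t1
    return GlobalMetrics(
        EF=ejection_fraction(result, t0v, t1v),
        WT=wall_thickening(result, slice_fraction, t0v, t1v),
        SBA=base_apex_shortening(result, t0v, t1v),
        t0=float(t0v), t1=float(t1v))
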