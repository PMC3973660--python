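"""One-way coupled electromechanical simulation.

Pipeline: (1) estimate the unloaded (pre-P) geometry and its pressurized
(post-P) counterpart; (2) solve the monodomain equations on the refined
post-P mesh; (3) map nodal activation times onto the mechanics elements by
nearest centroid; (4) march the mechanics as a sequence of warm-started
quasi-static solves driven by the sigmoidal cavity-pressure trace and a
per-element active-tension twitch triggered at the local activation time;
(5) sample mesh state, deformation gradients and cavity volume.

Electrophysiology never sees mechanical deformation (one-way coupling via
the transmembrane voltage only, with geometry held fixed during EP).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import geometry, mechanics, ep as ep_mod
from .geometry import EllipsoidSpec, rat_pre_p_spec
from .mesh import LVMesh, linearize, refine
from .microstructure import (FibreModelSpec, SheetModelSpec, StructureField,
                             build_structure_field, partition_regions)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PressureTrace:
    """Sigmoidal cavity pressure: p(t) = p_end / (1 + exp(-(t - t_mid)/tau))."""

    p_end: float = 1.0  # kPa, plateau magnitude (applied inward)
    t_mid: float = 30.0  # ms
    tau: float = 6.0  # ms

    def __post_init__(self):
        if self.p_end < 0:
            raise ValueError("p_end must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def pressure_at(t: float, trace: PressureTrace):
    """Cavity pressure magnitude (kPa) at time t (ms)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return trace.p_end / (1.0 + np.exp(-(t - trace.t_mid) / trace.tau))


@dataclass(frozen=True)
class TwitchParams:
    """Active-tension twitch: T_a = T_max sin^2(pi (t - t_act)/t_twitch)."""

    T_max: float = 35.0  # kPa
    t_twitch: float = 90.0  # ms
    threshold_mV: float = -20.0

    def __post_init__(self):
        if self.T_max <= 0 or self.t_twitch <= 0:
            raise ValueError("twitch parameters must be positive")


def active_tension(t: float, t_act, params: TwitchParams):
    """Active fibre tension (kPa) at time t for activation time(s) t_act.

    Zero before activation and after one twitch duration; peaks at T_max
    half-way through the twitch.  Unactivated points (nan) stay at zero.
    """
    t_act = np.asarray(t_act, dtype=float)
    phase = (t - t_act) / params.t_twitch
    with np.errstate(invalid="ignore"):
        active = (phase >= 0.0) & (phase <= 1.0)
        Ta = np.where(active,
                      params.T_max * np.sin(np.pi * np.where(active, phase, 0.0)) ** 2,
                      0.0)
    return np.where(np.isnan(t_act), 0.0, Ta)


@dataclass
class SimulationConfig:
    """All knobs of the coupled run.

    Defaults give a desk-scale rat-LV contraction over 120 ms; geometry
    resolution is deliberately coarse so a full run completes in minutes.
    """

    spec: EllipsoidSpec = field(default_factory=rat_pre_p_spec)
    mesh_edge_length: float = 0.12
    mesh_divisions: Optional[tuple] = (2, 12, 6)  # overrides edge length
    fibre: object = field(default_factory=lambda: FibreModelSpec(R=70, n=1))
    sheet: SheetModelSpec = field(default_factory=SheetModelSpec)
    law: mechanics.MaterialLaw = field(
        default_factory=mechanics.MaterialLaw.transverse_isotropic)
    monodomain: ep_mod.MonodomainParams = field(
        default_factory=ep_mod.MonodomainParams)
    stimulus: ep_mod.StimulusProtocol = field(
        default_factory=ep_mod.StimulusProtocol)
    pressure: PressureTrace = field(default_factory=PressureTrace)
    twitch: TwitchParams = field(default_factory=TwitchParams)
    preload_pressure: float = 0.5  # kPa, pre-P/post-P estimation
    # duration approximates the time at which full contraction is achieved
    # for the default stimulus + twitch timing (apical activation within
    # ~25 ms, sin^2 twitch peaking ~45 ms later)
    duration: float = 70.0  # ms
    dt_mech: float = 1.0  # ms
    sample_interval: float = 2.0  # ms
    ep_refinements: int = 1
    skip_unloaded_estimation: bool = True
    # the electrophysiology geometry (post-P) is derived with a fixed
    # reference material law so activation maps are identical across the
    # mechanics configurations being compared (and EP stays strictly
    # independent of mechanics parameters); set to None to use `law`
    ep_reference_law: Optional[mechanics.MaterialLaw] = field(
        default_factory=mechanics.MaterialLaw.transverse_isotropic)
    seed: int = 0

    def provenance_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items()
                        if not callable(v)}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Sampled states of a coupled run."""

    mesh: LVMesh  # mechanics reference (pre-P) mesh
    times: np.ndarray
    u_samples: np.ndarray  # (nt, n_nodes, 3)
    F_samples: np.ndarray  # (nt, ne, 3, 3)
    volumes: np.ndarray  # cavity volume trace
    pressures: np.ndarray
    activation_times: np.ndarray  # per mechanics element, ms
    scale_factor: float
    structure: StructureField = None
    config: SimulationConfig = None
    provenance: str = ""


def _map_nearest(src_points: np.ndarray, src_values: np.ndarray,
                 dst_points: np.ndarray) -> np.ndarray:
    _, idx = cKDTree(src_points).query(dst_points)
    return src_values[idx]


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full one-way coupled electromechanical pipeline."""
    # ---- stage 1: geometry + structure ----------------------------------
    try:
        mesh = geometry.build_lv_mesh(config.spec, config.mesh_edge_length,
                                      order=2, divisions=config.mesh_divisions)
        w = geometry.transmural_depth(mesh)
        frame = geometry.material_axes(mesh)
        regions = partition_regions(mesh)
        structure = build_structure_field(mesh, frame, w, config.fibre,
                                          config.sheet, regions=regions)
    except Exception as exc:
        raise RuntimeError(f"stage geometry/structure failed: {exc}") from exc

    geom_law = config.ep_reference_law or config.law
    try:
        if config.skip_unloaded_estimation or config.preload_pressure == 0:
            s = 1.0
            pre_p = mesh.copy_with_nodes(mesh.nodes, provenance="pre-P")
            post_p = mechanics.inflate(pre_p, structure, geom_law,
                                       config.preload_pressure)
        else:
            s, pre_p, post_p = mechanics.estimate_unloaded(
                mesh, structure, geom_law, config.preload_pressure)
    except Exception as exc:
        raise RuntimeError(f"stage unloaded-geometry failed: {exc}") from exc

    # ---- stage 2: EP on the refined post-P mesh -------------------------
    try:
        ep_mesh = linearize(post_p)
        for _ in range(config.ep_refinements):
            ep_mesh = refine(ep_mesh)
        ep_structure = StructureField(
            f=_map_nearest(post_p.element_centroids(), structure.f,
                           ep_mesh.element_centroids()),
            s=_map_nearest(post_p.element_centroids(), structure.s,
                           ep_mesh.element_centroids()),
            n_vec=_map_nearest(post_p.element_centroids(), structure.n_vec,
                               ep_mesh.element_centroids()),
            provenance=structure.provenance + "+nearest")
        act = ep_mod.solve_monodomain(
            ep_mesh, ep_structure, config.monodomain, config.stimulus,
            duration=min(config.duration, 60.0),
            sample_interval=config.sample_interval)
    except Exception as exc:
        raise RuntimeError(f"stage electrophysiology failed: {exc}") from exc

    # ---- stage 3: activation map ----------------------------------------
    mech_centroids_post = post_p.element_centroids()
    t_act = _map_nearest(ep_mesh.nodes, act.t_act, mech_centroids_post)

    # ---- stage 4: mechanics march ---------------------------------------
    try:
        solver = mechanics.QuasiStaticSolver(
            pre_p, structure, config.law, mechanics.BoundarySpec())
        nsteps = int(round(config.duration / config.dt_mech))
        every = max(1, int(round(config.sample_interval / config.dt_mech)))
        u = np.zeros((pre_p.n_nodes, 3))
        times, volumes, pressures = [], [], []
        u_samples, F_samples = [], []

        def record(t, state):
            times.append(t)
            volumes.append(state.cavity_volume)
            pressures.append(float(pressure_at(t, config.pressure)))
            u_samples.append(state.u.copy())
            F_samples.append(state.F.copy())

        state = solver.solve(pressure=float(pressure_at(0.0, config.pressure)),
                             Ta=active_tension(0.0, t_act, config.twitch),
                             u0=u, n_load_steps=2)
        record(0.0, state)
        u = state.u
        for k in range(1, nsteps + 1):
            t = k * config.dt_mech
            p = float(pressure_at(t, config.pressure))
            Ta = active_tension(t, t_act, config.twitch)
            state = solver.solve(pressure=p, Ta=Ta, u0=u, n_load_steps=1)
            u = state.u
            if k % every == 0:
                record(t, state)
    except Exception as exc:
        raise RuntimeError(f"stage mechanics failed: {exc}") from exc

    return SimulationResult(
        mesh=pre_p, times=np.asarray(times), u_samples=np.asarray(u_samples),
        F_samples=np.asarray(F_samples), volumes=np.asarray(volumes),
        pressures=np.asarray(pressures), activation_times=t_act,
        scale_factor=s, structure=structure, config=config,
        provenance=config.provenance_hash())
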