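import numpy as np
import pytest

from lvemech import (EllipsoidSpec, FibreModelSpec, SheetModelSpec,
                     build_lv_mesh, build_structure_field, material_axes,
                     partition_regions, transmural_depth)
from lvemech.geometry import rat_pre_p_spec


@pytest.fixture(scope="session")
def rat_spec():
    return rat_pre_p_spec()


@pytest.fixture(scope="session")
def lv_mesh(rat_spec):
    """Moderately fine linear LV mesh (volume / depth / fitting tests)."""
    return build_lv_mesh(rat_spec, 0.06)


@pytest.fixture(scope="session")
def lv_frame(lv_mesh):
    return material_axes(lv_mesh)


@pytest.fixture(scope="session")
def lv_depth(lv_mesh):
    return transmural_depth(lv_mesh)


@pytest.fixture(scope="session")
def lv_regions(lv_mesh):
    return partition_regions(lv_mesh)


@pytest.fixture(scope="session")
def sphere_spec():
    return EllipsoidSpec((1.2, 1.2, 1.2), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def sphere_mesh(sphere_spec):
    return build_lv_mesh(sphere_spec, 0.1)


@pytest.fixture(scope="session")
def quad_mesh(rat_spec):
    """Small quadratic mesh with structure field for mechanics tests."""
    mesh = build_lv_mesh(rat_spec, 0.15, order=2, divisions=(1, 8, 4))
    w = transmural_depth(mesh)
    frame = material_axes(mesh)
    structure = build_structure_field(mesh, frame, w, FibreModelSpec(R=70, n=1),
                                      SheetModelSpec())
    return mesh, structure


@pytest.fixture(scope="session")
def coarse_sim_cache():
    """Cached coarse coupled simulations keyed by (fibre, law, sheet).

    Returns a callable producing summary metrics: ejection fraction and the
    largest regionally averaged strain-trace values (residual-subtracted).
    """
    from lvemech.coupling import SimulationConfig, run_simulation
    from lvemech.mechanics import MaterialLaw
    from lvemech.metrics import (cylindrical_strains, ejection_fraction,
                                 regional_average)

    cache = {}

    def run(fibre, law_name, sheet_kind):
        key = (fibre.name, law_name, sheet_kind)
        if key not in cache:
            cfg = SimulationConfig()
            cfg.mesh_divisions = (2, 10, 5)
            cfg.fibre = fibre
            cfg.law = getattr(MaterialLaw, law_name)()
            cfg.sheet = SheetModelSpec(kind=sheet_kind)
            res = run_simulation(cfg)
            strains = cylindrical_strains(res)
            df = regional_average(strains, subtract_residual=True)
            end = df[df.time == df.time.max()]

            def peak(component):
                vals = end[end.component == component].value
                return float(vals.iloc[np.argmax(np.abs(vals.to_numpy()))])

            cache[key] = {
                "EF": ejection_fraction(res),
                "E_cc": peak("E_cc"),
                "E_cr": peak("E_cr"),
                "E_cl": peak("E_cl"),
            }
        return cache[key]

    return run


@pytest.fixture(scope="session")
def quad_mesh_mid(rat_spec):
    """Default-resolution quadratic mesh (pressurized-J acceptance check)."""
    mesh = build_lv_mesh(rat_spec, 0.12, order=2, divisions=(2, 12, 6))
    w = transmural_depth(mesh)
    frame = material_axes(mesh)
    structure = build_structure_field(mesh, frame, w, FibreModelSpec(R=70, n=1),
                                      SheetModelSpec())
    return mesh, structure
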