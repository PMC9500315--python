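"""Synthetic spine generator: geometry contracts, sets, determinism."""

import numpy as np
import pytest

from cervifem.mesh import elliptic_cylinder, mesh_quality
from cervifem.phantom import (CONTACT_JUNCTIONS, GeometryError, InstrumentSpec,
                              PhantomSpec, ResolutionError, SpecificationError,
                              assemble_spine, disc_np_shares, generate_disc,
                              generate_vertebra)


def _shell_thicknesses(mesh, n_sample=100):
    """Inner-to-outer node distance of the cortical wedge layer."""
    ths = []
    for eid in mesh.elem_sets["cortical"][:n_sample]:
        kind, conn = mesh.element(int(eid))
        for i in range(3):
            ths.append(np.linalg.norm(mesh.nodes[conn[3 + i]] - mesh.nodes[conn[i]]))
    return np.array(ths)


@pytest.mark.parametrize("level,expected", [("C3", 0.28), ("T1", 0.24)])
def test_cortical_layer_thickness(level, expected):
    """The wedge shell sits at the prescribed normal offset (cervical 0.28 mm,
    thoracic 0.24 mm), within 1% at 100 sampled points."""
    vm = generate_vertebra(PhantomSpec(mesh_size=4.0), level)
    ths = _shell_thicknesses(vm)
    assert len(ths) >= 100 or len(ths) == 3 * len(vm.elem_sets["cortical"])
    assert np.abs(ths - expected).max() <= 0.01 * expected


def test_degenerate_dimensions_rejected():
    with pytest.raises(SpecificationError):
        PhantomSpec(body_dims={"C3": (16.0, 12.0, 0.0)})
    with pytest.raises(ResolutionError):
        PhantomSpec(mesh_size=40.0)


def test_trabecular_volume_matches_analytic_cylinder():
    """Summed tet volume of a fine elliptic body within 2% of pi*a*b*h."""
    m = elliptic_cylinder(8.0, 6.0, 10.0, 16, 10)
    assert m.element_volumes().sum() == pytest.approx(np.pi * 8 * 6 * 10, rel=0.02)


def test_vertebra_volume_via_sets():
    spec = PhantomSpec(mesh_size=2.0)
    vm = generate_vertebra(spec, "C4")
    vols = vm.element_volumes()
    w, d, h = spec.dims("C4")
    body = np.concatenate([vm.elem_sets["central_body"], vm.elem_sets["exterior_body"]])
    assert vols[body].sum() == pytest.approx(np.pi * (w / 2) * (d / 2) * h, rel=0.02)


def test_disc_np_shares_default():
    """Default disc: NP area share within the 25-50% band, volume share
    within the 40-50% band."""
    dm = generate_disc(PhantomSpec(), "C5-C6")
    fa, fv = disc_np_shares(dm)
    assert 0.25 <= fa <= 0.50
    assert 0.40 <= fv <= 0.50


def test_disc_np_area_follows_request():
    spec = PhantomSpec(np_area_fraction=0.25, np_volume_fraction=0.45, mesh_size=2.0)
    fa, fv = disc_np_shares(generate_disc(spec, "C5-C6"))
    assert fa == pytest.approx(0.25, abs=0.03)
    assert 0.40 <= fv <= 0.50


def test_out_of_band_np_fractions_rejected():
    with pytest.raises(SpecificationError):
        PhantomSpec(np_volume_fraction=0.60)
    with pytest.raises(SpecificationError):
        PhantomSpec(np_area_fraction=0.20)


def test_ligament_groups_per_junction(instrumented_model):
    """Six groups at free junctions; the anterior longitudinal ligament is
    resected across the instrumented span."""
    sets = instrumented_model.mesh.elem_sets
    groups = lambda j: sorted(n.split("_")[1] for n in sets
                              if n.startswith("lig_") and n.endswith(j))
    assert groups("C5-C6") == ["ALL", "ISL", "ITL", "LF", "PLL", "SSL"]
    assert groups("C3-C4") == ["ISL", "ITL", "LF", "PLL", "SSL"]
    assert groups("C2-C3") == ["ISL", "ITL", "LF", "PLL", "SSL"]
    # truss cross-section of the ALL card
    assert np.allclose(instrumented_model.area[sets["lig_ALL"]], 38.0)


def test_instrument_census(instrumented_model):
    sets = instrumented_model.mesh.elem_sets
    assert sum(1 for n in sets if n.startswith("screw_")) == 8
    assert sum(1 for n in sets if n.startswith("spacer_")) == 3
    assert "plate" in sets
    assert sum(1 for n in sets if n.startswith("trajectory_")) == 8


def test_spacer_heights(instrumented_model):
    """The C4-C5 spacer is the 7 mm unit; C2-C3/C3-C4 are 8 mm."""
    mesh = instrumented_model.mesh
    for junction, height in (("C2-C3", 8.0), ("C3-C4", 8.0), ("C4-C5", 7.0)):
        nodes = set()
        for eid in mesh.elem_sets[f"spacer_{junction}"]:
            _k, conn = mesh.element(int(eid))
            nodes.update(int(n) for n in conn)
        z = mesh.nodes[sorted(nodes)][:, 2]
        assert z.max() - z.min() == pytest.approx(height, abs=1e-9)


def test_plate_standoff_echo():
    spec = PhantomSpec(mesh_size=5.0)
    inst = InstrumentSpec(plate_standoff=1.0)
    model = assemble_spine(spec, inst)
    mesh = model.mesh
    plate_nodes = set()
    for eid in mesh.elem_sets["plate"]:
        _k, conn = mesh.element(int(eid))
        plate_nodes.update(int(n) for n in conn)
    y_plate = mesh.nodes[sorted(plate_nodes)][:, 1].max()
    bmax = max(spec.dims(lv)[1] for lv in inst.plate_span) / 2.0
    gap = -bmax - y_plate          # anterior-most bone wall at y = -bmax
    assert gap == pytest.approx(1.0, abs=0.05)


def test_screw_through_posterior_wall_rejected():
    with pytest.raises(GeometryError):
        assemble_spine(PhantomSpec(mesh_size=5.0), InstrumentSpec(screw_length=30.0))


def test_invalid_instrument_specs():
    with pytest.raises(SpecificationError):
        InstrumentSpec(plate_standoff=-0.5)
    with pytest.raises(SpecificationError):
        InstrumentSpec(plate_span=("C2", "C4"))
    with pytest.raises(SpecificationError):
        InstrumentSpec(spacer_heights=(8.0, 8.0))


def test_contact_pairs_and_friction(instrumented_model):
    names = [c.name for c in instrumented_model.contacts]
    assert names == list(CONTACT_JUNCTIONS)
    assert all(c.friction == 0.07 for c in instrumented_model.contacts)
    assert instrumented_model.meta["friction"] == 0.07


def test_required_sets_exist(instrumented_model):
    mesh = instrumented_model.mesh
    for es in ("central_body", "exterior_body", "trajectory_C2_left",
               "trajectory_C5_right", "endplate_contact_C2-C3"):
        assert es in mesh.elem_sets and len(mesh.elem_sets[es])
    for ns in ("c2_facet_left", "c2_facet_right", "spinous_C2", "base",
               "base_T1", "vert_C5"):
        assert ns in mesh.node_sets and len(mesh.node_sets[ns])
    for sf in ("facet_sup_C6", "facet_inf_C5"):
        assert sf in mesh.surfaces and len(mesh.surfaces[sf])


def test_assembly_deterministic():
    """Same seed -> bit-identical mesh content."""
    h = [assemble_spine(PhantomSpec(mesh_size=5.0),
                        InstrumentSpec()).mesh.content_hash() for _ in range(2)]
    assert h[0] == h[1]


def test_mesh_quality_report(instrumented_model):
    q = mesh_quality(instrumented_model.mesh)
    assert q["n_tets"] > 1000
    assert q["jacobian_min"] > 0.0            # no degenerate tets
    assert q["pct_collapse_poor"] < 5.0
    assert q["pct_skew_poor"] < 5.0
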