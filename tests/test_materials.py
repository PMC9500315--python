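"""Density-modulus law and material assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervifem.materials import (LIGAMENT_CARDS, MaterialCard, MaterialError,
                                RegionBmd, bmd_to_modulus)

# (BMD mg/cc, Young's modulus MPa) pairs of the reference trabecular card
TRABECULAR_TABLE = [
    (200.4, 403.10), (135.2, 182.75), (242.1, 589.43), (99.7, 99.08),
    (319.2, 1027.46), (185.9, 346.62), (301.3, 914.93), (251.5, 636.33),
    (262.6, 694.04), (141.8, 201.13), (229.1, 527.53), (124.7, 155.34),
    (165.7, 275.07), (55.1, 30.08), (187.4, 352.26), (140.4, 197.16),
]


@pytest.mark.parametrize("bmd,expected", TRABECULAR_TABLE)
def test_as_used_reproduces_reference_card(bmd, expected):
    """Every tabulated trabecular modulus follows the 2.01 power branch."""
    assert round(bmd_to_modulus(bmd, "as_used"), 2) == pytest.approx(expected, abs=0.011)


@pytest.mark.parametrize("bmd,expected", [
    (55.1, 57.641226824316185),     # 33900*(0.0551)**2.2 (low-density branch)
    (100.0, 213.89453977878543),
    (400.0, 2631.8),                # 5407*0.4 + 469 (linear mid branch)
    (700.0, 4980.205140070351),     # 10200*0.7**2.01 (high-density branch)
])
def test_as_printed_piecewise_branches(bmd, expected):
    assert bmd_to_modulus(bmd, "as_printed") == pytest.approx(expected, rel=1e-12)


def test_zero_density_sentinel():
    assert bmd_to_modulus(0.0, "as_used") == 0.001
    assert bmd_to_modulus(0.0, "as_printed") == 0.001


def test_negative_density_rejected():
    with pytest.raises(MaterialError):
        bmd_to_modulus(-1.0)


def test_modes_coincide_only_on_power_branch():
    """Above 600 mg/cc both modes share the 2.01 power law; at the card's
    low-density rows the printed piecewise form disagrees by far more than
    0.5%."""
    for bmd in (600.1, 750.0, 1200.0):
        assert bmd_to_modulus(bmd, "as_used") == pytest.approx(
            bmd_to_modulus(bmd, "as_printed"), rel=1e-12)
    for bmd, _ in TRABECULAR_TABLE:
        rel = abs(bmd_to_modulus(bmd, "as_printed") / bmd_to_modulus(bmd, "as_used") - 1)
        assert rel > 0.005


@settings(derandomize=True, max_examples=200)
@given(st.tuples(st.floats(0.0, 2000.0), st.floats(0.0, 2000.0)))
def test_as_used_monotone(pair):
    lo, hi = sorted(pair)
    assert bmd_to_modulus(lo, "as_used") <= bmd_to_modulus(hi, "as_used") + 1e-12


@settings(derandomize=True, max_examples=200)
@given(st.sampled_from([(1.0, 269.9), (270.1, 599.9), (600.1, 2000.0)]),
       st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_as_printed_monotone_within_branches(branch, f1, f2):
    a, b = branch
    x, y = sorted([a + f1 * (b - a), a + f2 * (b - a)])
    assert bmd_to_modulus(x, "as_printed") <= bmd_to_modulus(y, "as_printed") + 1e-9


def test_material_card_validation():
    with pytest.raises(MaterialError):
        MaterialCard("bad", -1.0, 0.3)
    with pytest.raises(MaterialError):
        MaterialCard("bad", 100.0, 0.6)
    with pytest.raises(MaterialError):
        RegionBmd("C4", "somewhere", 100.0)


def test_assignment_on_assembled_model(instrumented_model):
    """Constituent cards land on the right element sets."""
    model = instrumented_model
    E, sets = model.E, model.mesh.elem_sets
    assert np.allclose(E[sets["central_body_C4"]], 1027.46, atol=0.011)
    assert np.allclose(E[sets["spacer_C3-C4"]], 4000.0)
    assert np.allclose(E[sets["plate"]], 110000.0)
    assert np.allclose(E[sets["NP_C5-C6"]], 1.0)
    assert np.allclose(model.nu[sets["NP_C5-C6"]], 0.49)
    assert np.allclose(E[sets["AF_C6-C7"]], 3.4)
    assert np.allclose(E[sets["cortical_C3"]], 1000.0)
    assert np.allclose(E[sets["lig_ALL"]], 20.0)
    assert np.allclose(model.area[sets["lig_ALL"]], 38.0)
    # paired groups split their tabulated cross-section over the two trusses
    ligE, _nu, ligA = LIGAMENT_CARDS["ITL"]
    assert np.allclose(E[sets["lig_ITL"]], ligE)
    assert np.allclose(model.area[sets["lig_ITL"]].sum(),
                       ligA * len(sets["lig_ITL"]) / 2 / 1)


def test_missing_region_is_an_error():
    from cervifem.materials import assign_materials
    from cervifem.phantom import PhantomSpec, assemble_spine

    model = assemble_spine(PhantomSpec(levels=("C5", "C6"), mesh_size=5.0), None)
    with pytest.raises(MaterialError, match="missing RegionBmd"):
        assign_materials(model, [RegionBmd("C5", "central_body", 300.0)])
    with pytest.raises(MaterialError):
        assign_materials(model, [])
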