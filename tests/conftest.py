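import numpy as np
import pytest

from cervifem.fem import Coupling, Model
from cervifem.materials import RegionBmd, assign_materials
from cervifem.phantom import InstrumentSpec, PhantomSpec, assemble_spine


@pytest.fixture(scope="session")
def instrumented_model():
    """Full C2-T2 instrumented phantom with materials (coarse, no solve)."""
    spec = PhantomSpec(mesh_size=5.0)
    model = assemble_spine(spec, InstrumentSpec())
    from cervifem.materials import EXAMPLE_REGION_BMD

    assign_materials(model, EXAMPLE_REGION_BMD)
    return model


@pytest.fixture(scope="session")
def two_level_model():
    """C5-C6 pair with materials and a spinous coupling on C5 (for
    ROM/antisymmetry tests on a single soft junction)."""
    spec = PhantomSpec(levels=("C5", "C6"), mesh_size=4.5)
    model = assemble_spine(spec, None)
    bmd = [RegionBmd("C5", "central_body", 301.3),
           RegionBmd("C5", "exterior_body", 251.5),
           RegionBmd("C6", "central_body", 262.6),
           RegionBmd("C6", "exterior_body", 141.8)]
    assign_materials(model, bmd)
    spin = model.mesh.node_sets["spinous_C5"]
    model.couplings["c5_spinous"] = Coupling(
        ref_point=model.mesh.nodes[spin].mean(axis=0), node_set="spinous_C5")
    return model


class TorqueCase:
    """Minimal load case: pure torque at a coupling, fixed base."""

    def __init__(self, torque, coupling="c5_spinous", fixed_set="base"):
        self.torque = np.asarray(torque, dtype=float)
        self.coupling = coupling
        self.fixed_set = fixed_set

    def nodal_forces(self, model):
        return {}


class PointCase:
    """Minimal load case: nodal point forces, fixed node set, no coupling."""

    def __init__(self, forces, fixed_set):
        self.forces = {int(k): np.asarray(v, dtype=float) for k, v in forces.items()}
        self.fixed_set = fixed_set
        self.coupling = None
        self.torque = np.zeros(3)

    def nodal_forces(self, model):
        return self.forces


@pytest.fixture
def torque_case():
    return TorqueCase


@pytest.fixture
def point_case():
    return PointCase
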