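import numpy as np
import pytest

from mesobd import (ColourPair, ColourTable, GeomSpec, GestaltTemplate,
                    ProteinTemplate, SimulationBox, SystemBuilder)

FREE_BOX = SimulationBox((1e6, 1e6, 1e6), ("none", "none", "none"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def repulsive_table():
    return ColourTable({(0, 0): ColourPair(epsilon=1.0, sigma=0.25)})


@pytest.fixture
def free_bead():
    """Single massless unit-diffusivity gestalt without any shapes."""
    return ProteinTemplate("free", (GestaltTemplate(geom=GeomSpec(d_tr=1.0)),))


def make_free_system(template, replicas=1, box=FREE_BOX, colours=None,
                     position=(0.0, 0.0, 0.0)):
    builder = SystemBuilder(box, colours or ColourTable())
    builder.instantiate(template, position=position)
    system = builder.compile()
    return system, system.initial_state(replicas)
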