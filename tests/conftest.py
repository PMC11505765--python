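import numpy as np
import pytest

from rm3d.beam_model import BeamLine, RIGUR, bragg_curve, wet_of_slab
from rm3d.dose_engine import PROFILES, Scene
from rm3d.scenarios import StudyFixtures, run_reference
from rm3d.sobp_design import (WeightVector, optimize_sobp_weights,
                              weights_to_step_contour)


@pytest.fixture(scope="session")
def curve250():
    return bragg_curve(250.0)


@pytest.fixture(scope="session")
def beamline():
    return BeamLine()


@pytest.fixture(scope="session")
def reference_scene():
    return Scene()


@pytest.fixture(scope="session")
def sobp_interval(curve250, reference_scene):
    """Design interval of the 10 cm SOBP behind the 17 cm absorber."""
    distal = (curve250.range_80 - reference_scene.absorber_wet_mm
              - wet_of_slab(RIGUR, 8.0) - 0.5)
    return distal - 100.0, distal


@pytest.fixture(scope="session")
def sobp_weights(curve250, sobp_interval):
    prox, distal = sobp_interval
    return optimize_sobp_weights(curve250, prox, distal, 3.0)


@pytest.fixture(scope="session")
def step_pin(sobp_weights):
    return weights_to_step_contour(sobp_weights, 3.0, RIGUR)


@pytest.fixture(scope="session")
def four_level_weights():
    """A small, exactly representable pin design for geometry tests."""
    return WeightVector(np.arange(4) * 3.0,
                        np.array([0.4, 0.3, 0.2, 0.1]))


@pytest.fixture(scope="session")
def four_level_pin(four_level_weights):
    return weights_to_step_contour(four_level_weights, 3.0, RIGUR)


@pytest.fixture(scope="session")
def study():
    return StudyFixtures("desk")


@pytest.fixture(scope="session")
def reference_dose(study):
    return run_reference(study)
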