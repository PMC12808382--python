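import numpy as np
import pytest

import waterpet as wp
from waterpet.kinetics import _exp_conv_uniform, _frame_average_from_fine
from waterpet.tac import TimeActivityCurve


@pytest.fixture(scope="session")
def framing():
    return wp.protocol_framing()


@pytest.fixture(scope="session")
def aif():
    return wp.AIFModel()


@pytest.fixture(scope="session")
def small_phantom():
    """Compact lower-leg phantom for fast image-level tests."""
    return wp.LegPhantomConfig(
        shape=(32, 32, 40),
        cylinders={
            "tibia": wp.Cylinder((-7.0, -7.0), 5.0),
            "fibula": wp.Cylinder((10.0, -5.0), 3.0),
            "posterior": wp.Cylinder((1.0, 10.0), 10.0),
            "anterior": wp.Cylinder((0.0, -17.0), 5.0),
            "artery": wp.Cylinder((-9.0, 21.0), 3.0),
        },
        malleolus_z_mm=0.0,
        knee_z_mm=50.0,
        artery_bifurcation_z_mm=48.0,
    )


def make_noiseless_curves(k1, k2_per_min, delay_s, aif, framing, fine_step_s=0.01):
    """Frame-averaged input and 1TCM tissue curves for known parameters."""
    t_fine = np.arange(int(round(framing.total_duration_s / fine_step_s)) + 1) * fine_step_s
    idif_vals = _frame_average_from_fine(np.asarray(aif(t_fine)), fine_step_s, framing)
    conv = _exp_conv_uniform(np.asarray(aif(t_fine - delay_s)), k2_per_min / 60.0, fine_step_s)
    tissue_vals = _frame_average_from_fine((k1 / 100.0 / 60.0) * conv, fine_step_s, framing)
    idif = TimeActivityCurve(framing.mid_times_s, framing.durations_s, idif_vals, role="input")
    tissue = TimeActivityCurve(framing.mid_times_s, framing.durations_s, tissue_vals)
    return idif, tissue
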