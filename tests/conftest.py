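import warnings

import numpy as np
import pytest

from oomech.model import ForceSpec, ZenerParams
from oomech.simulate import SimulationConfig, generate_cohort, generate_curve, \
    render_frame_stack

warnings.filterwarnings("ignore", message="dropping zero-variance")


@pytest.fixture(scope="session")
def force_spec():
    return ForceSpec(suction_magnitude=0.1, inner_diameter_um=50.0)


@pytest.fixture(scope="session")
def default_params():
    # generator's default medians: jump ~8.5 um, tau = 60 ms
    return ZenerParams(k0=0.08, k1=0.08, eta0=0.0024, eta1=0.25)


@pytest.fixture(scope="session")
def noiseless_curve(default_params, force_spec):
    return generate_curve(default_params, force_spec.F0, frame_rate=70,
                          window=0.5, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def rendered(default_params, force_spec):
    """One rendered stack with its generating curve and ground truth."""
    curve = generate_curve(default_params, force_spec.F0, noise_sd=0.2, seed=3)
    stack, truth = render_frame_stack(curve, seed=3)
    return curve, stack, truth


@pytest.fixture(scope="session")
def separated_cohort():
    """Strong mechanics/outcome separation: classifier signal present."""
    return generate_cohort(SimulationConfig(seed=5, n_patients=40, class_effect=2.0))


@pytest.fixture(scope="session")
def null_cohort():
    """No mechanics/outcome association at all."""
    return generate_cohort(SimulationConfig(seed=11, n_patients=40, class_effect=1.0))


def true_fits(cohort):
    """Ground-truth parameters reshaped as a fits table (skips the
    fitting stage where a test only exercises downstream logic)."""
    df = cohort[(cohort["arm"] == "measured") & ~cohort["excluded"]]
    out = df[["oocyte_id", "true_k0", "true_k1", "true_eta0", "true_eta1"]].copy()
    out.columns = ["oocyte_id", "k0", "k1", "eta0", "eta1"]
    return out
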