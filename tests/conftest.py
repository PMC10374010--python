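import pytest

from popreach.analysis import AnalysisConfig, analyze_trajectories
from popreach.movement import SimParams, simulate_experiment
from popreach.selection import HistoryModelSpec
from popreach.synth import gen_trajectory_dataset, two_factor_spec


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def m3c_profiles(default_params):
    """Mean attraction profiles of the default inhibition-then-facilitation
    model, 21 noisy repetitions per condition."""
    spec = HistoryModelSpec("M3c")
    return simulate_experiment(spec, default_params, n_reps=21, seed=1)


@pytest.fixture(scope="session")
def planted_two_factor_profiles():
    """Analyzed synthetic dataset with the early-inhibition /
    late-facilitation factor plant."""
    table = gen_trajectory_dataset(two_factor_spec(seed=42))
    return analyze_trajectories(table, AnalysisConfig())
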