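import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def shared_panel():
    """One shared-scenario study panel at n=1000/group (no missingness)."""
    from panelnet.synthetic import default_truth, simulate_panel
    truth = default_truth("shared", 1000, seed=0)
    return simulate_panel(truth, seed=100), truth


@pytest.fixture(scope="session")
def benchmark_panel():
    """Unit-scale benchmark panel at n=1000 (group G1)."""
    from panelnet.synthetic import benchmark_truth, simulate_panel
    truth = benchmark_truth({"G1": 1000, "G2": 60, "G3": 60}, seed=0)
    panel = simulate_panel(truth, seed=7, clip=False)
    return panel, truth


@pytest.fixture(scope="session")
def g1_fit(shared_panel):
    from panelnet.gvar import fit_panel_gvar
    panel, truth = shared_panel
    sc = panel.scores[panel.scores.group == "G1"]
    return fit_panel_gvar(sc)
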