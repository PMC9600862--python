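import pytest
from hypothesis import HealthCheck, settings

from smassay import assay, build_scenario
from smassay.model import BENIGN_LABELS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The closed-loop scenario registry: all benign interaction types plus the
#: inhibitory-environment trio that reproduces the anomalous growth pattern.
REGISTRY = [(label, "benign") for label in BENIGN_LABELS] + [
    ("NS", "inhibitory"),
    ("NS+CF", "inhibitory"),
    ("NS+CD", "inhibitory"),
]


@pytest.fixture(scope="session")
def registry_assays():
    """Deterministic five-condition assay results for every registry scenario."""
    return {
        (label, env): assay.run_sm_assay(build_scenario(label, env))
        for label, env in REGISTRY
    }


@pytest.fixture(scope="session")
def relative_auc_grid(registry_assays):
    """Noise-free relative AUC (NC -> 0, MM -> 1) per scenario and condition."""
    from smassay.features import auc_curve, relative_auc

    grid = {}
    for key, result in registry_assays.items():
        aucs = {cond: auc_curve(sim.times, sim.biomass[1])
                for cond, sim in result.conditions.items()}
        grid[key] = {cond: relative_auc(aucs[cond], aucs["NC"], aucs["MM"])
                     for cond in assay.CONDITION_ORDER}
    return grid
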