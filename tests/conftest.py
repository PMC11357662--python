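import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_sim():
    """One mid-sized cohort under default study conditions, shared read-only."""
    from prsgre.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_participants=4000, seed=11))


@pytest.fixture(scope="session")
def analysis_frame(cohort_sim) -> pd.DataFrame:
    """The eligible, genotyped subset with PRS percentile/tertile columns."""
    from prsgre.cohort import apply_exclusions
    from prsgre.models import add_prs_scales

    kept = apply_exclusions(cohort_sim.phenotypes, require_genotyped=True).kept
    return add_prs_scales(kept, reference="cohort")
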