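import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from proxymed.assoc import AssociationPanel
from proxymed.synthcohort import SimulationConfig, simulate_multistudy

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_panel(metabolites, betas, ses, variant="rare_v", study="study1", n=1000, pvals=None):
    """Hand-built association panel for unit tests."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if pvals is None:
        from proxymed.assoc import _wald_p
        pvals = _wald_p(betas, ses)
    df = pd.DataFrame(
        {
            "metabolite_id": list(metabolites),
            "variant_id": variant,
            "study_id": study,
            "beta": betas,
            "se": ses,
            "p": pvals,
            "n": n,
            "transformed": True,
            "skipped_reason": "",
        }
    )
    return AssociationPanel(variant_id=variant, study_id=study, results=df)


@pytest.fixture(scope="session")
def small_sim():
    """Small three-study dataset with known truth, reused across tests."""
    cfg = SimulationConfig(
        n_per_study=(600, 600, 500),
        n_metabolites=20,
        maf_rare=0.05,
        maf_common=0.10,
        family_fraction=0.5,
        seed=42,
    )
    return simulate_multistudy(cfg)
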