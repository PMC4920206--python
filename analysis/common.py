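"""Shared locations and the demo study configuration for the analysis scripts.

The demo scale is chosen so the whole sequence runs in about a minute:
three cohorts of a few thousand individuals, a 60-measure metabolite
panel, the focal variant at MAF 2% (so carrier counts support per-study
estimates), the proxy at MAF 10%, a true mediation constant of -2, and
five metabolites given a genuine proxy-independent effect.
"""

from pathlib import Path

from proxymed.synthcohort import SimulationConfig, draw_truth

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
DATA_DIR = RESULTS / "data"

SEED = 2024


def demo_config() -> SimulationConfig:
    base = dict(
        n_per_study=(3000, 2500, 2000),
        n_metabolites=60,
        maf_rare=0.02,
        maf_common=0.10,
        k_true=-2.0,
        seed=SEED,
    )
    # pick the proxy-independent metabolites from the non-zero-inflated set
    # (the zero-inflation flags do not depend on which set is chosen)
    pilot = draw_truth(SimulationConfig(**base))
    candidates = pilot.loc[~pilot["zero_inflated"], "metabolite_id"].tolist()
    injected = tuple(candidates[::11][:5])
    return SimulationConfig(**base, independent_set=injected, delta_independent=0.5)
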