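"""Replicate simulation studies that calibrate the pipeline.

These are the scaled-down study conditions used throughout the test suite
and the acceptance analyses: three studies of n=2000, 100 metabolites, the
focal variant's MAF elevated to 5% so that carrier counts make recovery
studies stable, proxy MAF 10%, k_true = -2.  Rare-variant noise at the
real-data MAF (~0.25%) is a property of the data, not of the code, so the
calibration runs trade the real MAF for replicate stability.

Each replicate simulates the three cohorts, scans both variants in each,
combines the per-study panels by inverse-variance fixed-effects
meta-analysis for the headline k estimate, and runs the per-study
predict-then-combine mediation test for the overlap flags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synthcohort import SimulationConfig, simulate_multistudy, simulate_study, draw_truth
from .assoc import AssociationPanel, run_scan
from .metastat import meta_panels
from .proxytest import estimate_k, predict_effects, combine_predictions, correlate_profiles

__all__ = [
    "calibration_config",
    "meta_to_panel",
    "one_replicate",
    "recovery_study",
    "sensitivity_config",
    "null_pvalue_study",
    "profile_correlation_run",
]

_COVARIATES = ("age", "sex", "phase")


def calibration_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The scaled-down three-study configuration used for replicate studies."""
    base = dict(
        n_per_study=(2000, 2000, 2000),
        n_metabolites=100,
        maf_rare=0.05,
        maf_common=0.10,
        k_true=-2.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def meta_to_panel(meta: pd.DataFrame, study_id: str = "meta") -> AssociationPanel:
    """Wrap a meta-analysis table as an AssociationPanel for downstream reuse."""
    res = pd.DataFrame(
        {
            "metabolite_id": meta["metabolite_id"],
            "variant_id": meta["variant_id"],
            "study_id": study_id,
            "beta": meta["beta_pooled"],
            "se": meta["se_pooled"],
            "p": meta["p"],
            "n": meta["n_total"],
            "transformed": True,
            "skipped_reason": "",
        }
    )
    return AssociationPanel(variant_id=str(meta["variant_id"].iloc[0]), study_id=study_id, results=res)


@dataclass
class ReplicateResult:
    k_hat: float
    se_k: float
    k_per_study: list[float]
    predictions: pd.DataFrame  # combined predicted-vs-observed table
    truth: pd.DataFrame
    discovery_p: np.ndarray  # rare-variant p-values in the discovery study


def one_replicate(config: SimulationConfig, B: int = 1000, trim: float = 0.25) -> ReplicateResult:
    """Simulate one three-study dataset and run the full mediation analysis."""
    sim = simulate_multistudy(config)
    rare_panels, proxy_panels = [], []
    for cohort in sim.cohorts:
        rare_panels.append(run_scan(cohort, "rare", covariates=_COVARIATES, transform="always"))
        proxy_panels.append(run_scan(cohort, "proxy", covariates=_COVARIATES, transform="always"))

    # headline k: ratios from inverse-variance combined panels
    boot_seed = (config.seed * 7919 + 13) % 2**31
    rare_meta = meta_to_panel(meta_panels(rare_panels, "fixed"))
    proxy_meta = meta_to_panel(meta_panels(proxy_panels, "fixed"))
    k_est, _ = estimate_k(rare_meta, proxy_meta, trim_fraction=trim, B=B, seed=boot_seed)

    # per-study procedure, combined by sample size (the flag track)
    per_study_pred = []
    k_per_study = []
    for s, (pr, pp) in enumerate(zip(rare_panels, proxy_panels)):
        ks, _ = estimate_k(pr, pp, trim_fraction=trim, B=B, seed=(boot_seed + s + 1) % 2**31)
        k_per_study.append(ks.k_hat)
        per_study_pred.append(predict_effects(ks, pp, pr))
    combined = combine_predictions(per_study_pred)

    disc = rare_panels[0].ok()
    return ReplicateResult(
        k_hat=k_est.k_hat,
        se_k=k_est.se_k,
        k_per_study=k_per_study,
        predictions=combined,
        truth=sim.truth,
        discovery_p=disc["p"].to_numpy(float),
    )


def recovery_study(
    n_reps: int,
    base_seed: int = 0,
    config_overrides: dict | None = None,
    B: int = 1000,
) -> pd.DataFrame:
    """Replicate recovery/type-I/sensitivity study.

    One row per replicate: the k estimate, whether truth lies within
    +-3 se_k, the fraction of proportional (delta=0) metabolites flagged as
    proxy-independent, and (when an independent set exists) the fraction of
    injected metabolites flagged.
    """
    overrides = dict(config_overrides or {})
    rows = []
    for rep in range(n_reps):
        cfg = calibration_config(seed=(base_seed * 100003 + rep) % 2**31, **overrides)
        res = one_replicate(cfg, B=B)
        truth = res.truth.set_index("metabolite_id")
        pred = res.predictions.set_index("metabolite_id")
        shared = pred.index
        null_set = [m for m in shared if truth.loc[m, "delta"] == 0.0]
        inj_set = [m for m in shared if truth.loc[m, "delta"] != 0.0]
        frac_null_flagged = float(pred.loc[null_set, "lpl_independent"].mean()) if null_set else np.nan
        frac_inj_flagged = float(pred.loc[inj_set, "lpl_independent"].mean()) if inj_set else np.nan
        rows.append(
            {
                "rep": rep,
                "k_hat": res.k_hat,
                "se_k": res.se_k,
                "covered": bool(abs(res.k_hat - cfg.k_true) <= 3.0 * res.se_k),
                "frac_null_flagged": frac_null_flagged,
                "frac_injected_flagged": frac_inj_flagged,
                "n_null": len(null_set),
                "n_injected": len(inj_set),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_config(
    base_seed: int = 0,
    n_injected: int = 10,
    delta_multiple: float = 5.0,
    **overrides,
) -> tuple[dict, float]:
    """Configuration overrides for the sensitivity study.

    The injected proxy-independent effect is ``delta_multiple`` times the
    typical (median) combined observed-effect SE, measured on a pilot
    replicate under pure proportionality.  The focal variant is simulated
    at MAF 2% against a 30% proxy so the observed-effect SE dominates the
    predicted-effect SE, as it does when a rare variant is compared with a
    common proxy; the injected set is drawn from the non-zero-inflated
    metabolites so that the injected effect is not attenuated by the
    zero-truncation.
    """
    base = dict(maf_rare=0.02, maf_common=0.30)
    base.update(overrides)
    pilot_cfg = calibration_config(seed=(base_seed * 100003) % 2**31, **base)
    pilot = one_replicate(pilot_cfg, B=50)
    med_se = float(np.median(pilot.predictions["se_obs"]))
    delta = delta_multiple * med_se

    truth = pilot.truth
    candidates = truth.loc[~truth["zero_inflated"], "metabolite_id"].tolist()
    step = max(1, len(candidates) // n_injected)
    injected = tuple(candidates[::step][:n_injected])
    base.update(independent_set=injected, delta_independent=delta)
    return base, delta


def null_pvalue_study(
    n_reps: int,
    base_seed: int = 0,
    **overrides,
) -> tuple[np.ndarray, float]:
    """Discovery-scan p-values under the global null (k_true=0, delta=0).

    Returns the pooled p-values across replicates and the fraction below
    0.05 (the nominal hit rate, ~5% when the scan is calibrated).
    """
    pvals = []
    for rep in range(n_reps):
        cfg = calibration_config(
            seed=(base_seed * 99991 + rep) % 2**31, k_true=0.0, **overrides
        )
        cohort = simulate_study(cfg, study_index=0)
        panel = run_scan(cohort, "rare", covariates=_COVARIATES, transform="always")
        pvals.append(panel.ok()["p"].to_numpy(float))
    pooled = np.concatenate(pvals)
    return pooled, float((pooled < 0.05).mean())


def profile_correlation_run(
    seed: int = 0,
    n: int = 5000,
    n_metabolites: int = 225,
    align: bool = True,
) -> tuple[float, float]:
    """Pearson r and slope between the two variants' z-scaled effect profiles
    in a single pure-proportionality discovery cohort.

    Which allele of the proxy variant is counted is arbitrary; with
    ``align=True`` the proxy allele is oriented so that its profile runs in
    the same direction as the focal variant's (the convention under which
    profile correlations are reported), which flips the signs of r and the
    slope when the mediation constant is negative.
    """
    cfg = calibration_config(
        seed=seed, n_per_study=(n, 2, 2), n_metabolites=n_metabolites
    )
    cohort = simulate_study(cfg, study_index=0)
    rare = run_scan(cohort, "rare", covariates=_COVARIATES, transform="always")
    proxy = run_scan(cohort, "proxy", covariates=_COVARIATES, transform="always")
    r, slope = correlate_profiles(rare, proxy)
    if align and r < 0:
        r, slope = -r, -slope
    return r, slope
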