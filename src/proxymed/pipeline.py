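"""End-to-end orchestration: simulate/load -> scan -> pool/meta -> FDR -> proxy test.

A run executes, in order: association scans for both variants in every
study; a nominal discovery filter (p <= 0.05 in the discovery study); a
confirmation fixed-effects meta-analysis of the remaining studies with
Benjamini-Yekutieli adjustment of the discovery hits; an optional full
meta-analysis that first pools the two related studies with a
family-random-intercept mixed model; and the proxy-mediation test per
study and combined across studies.  All intermediates are persisted as
TSV, so every number in the summary is recomputable from the output tree,
and identical config + seeds give a byte-identical tree.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthcohort import SimulationConfig, CohortTable, simulate_multistudy
from .assoc import AssociationPanel, run_scan
from .metastat import meta_panels, pool_scan, by_fdr
from .proxytest import estimate_k, predict_effects, combine_predictions, correlate_profiles
from .calibration import meta_to_panel

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (a SimulationConfig) or ``cohort_paths`` (TSVs in
    the generator dialect) supplies the cohorts.  Discovery/confirmation
    roles are config-assigned; the shipped default mirrors the
    three-cohort layout (discovery in the young participants, confirmation
    in the mothers + independent women, with the first two sharing
    families).
    """

    simulation: SimulationConfig | None = None
    cohort_paths: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ("age", "sex", "phase")
    transform: str = "always"
    coding: str = "additive"
    discovery_study: str = "young"
    confirmation_studies: tuple[str, ...] = ("mothers", "women")
    related_studies: tuple[str, ...] = ("young", "mothers")
    alpha: float = 0.05
    discovery_p: float = 0.05
    trim_fraction: float = 0.25
    B: int = 1000
    level: float = 0.95
    seed: int = 0
    include_full_meta: bool = True
    fasting_sensitivity: bool = False
    outdir: str = "results/run"

    def validate(self) -> None:
        if self.discovery_study in self.confirmation_studies:
            raise ValueError("discovery study must not be in the confirmation set")
        if self.simulation is None and not self.cohort_paths:
            raise ValueError("either a simulation config or cohort paths required")
        if self.cohort_paths:
            missing = [p for p in self.cohort_paths if not Path(p).exists()]
            if missing:
                raise ValueError(f"cohort files not found: {missing}")
        if not (0 < self.level < 1):
            raise ValueError("confidence level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            for key in ("n_per_study", "study_ids", "beta_proxy_range", "independent_set"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (the output location is not one)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log_lines = [
        f"proxymed {__version__} (python {platform.python_version()}, "
        f"numpy {np.__version__}, pandas {pd.__version__})",
        f"config hash {config.config_hash()}",
        f"seed {config.seed}",
    ]

    def _register(name: str) -> Path:
        manifest.append(name)
        return outdir / name

    def _fail(stage: str, exc: Exception) -> None:
        (outdir / "MANIFEST").write_text(
            "\n".join([f"INCOMPLETE: failed at stage {stage}: {exc}"] + manifest) + "\n"
        )
        raise RuntimeError(f"[{stage}] {exc}") from exc

    # -- stage 1: cohorts ----------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": config.seed})
            sim = simulate_multistudy(sim_cfg)
            cohorts = sim.cohorts
            sim.truth.to_csv(_register("truth.tsv"), sep="\t", index=False, float_format="%.10g")
            sim_cfg.to_yaml(_register("sim_config.yaml"))
            for c in cohorts:
                c.to_tsv(_register(f"cohort_{c.study_id}.tsv"))
            log_lines.append(f"simulated {len(cohorts)} cohorts")
        else:
            cohorts = [CohortTable.from_tsv(p) for p in config.cohort_paths]
            log_lines.append(f"loaded {len(cohorts)} cohorts")
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        _fail("cohorts", exc)

    by_id = {c.study_id: c for c in cohorts}
    if config.discovery_study not in by_id:
        _fail("cohorts", ValueError(f"discovery study {config.discovery_study!r} not among cohorts"))

    # -- stage 2: scans -------------------------------------------------
    panels: dict[tuple[str, str], AssociationPanel] = {}
    try:
        for c in cohorts:
            for label in ("rare", "proxy"):
                panel = run_scan(
                    c, label, covariates=config.covariates,
                    transform=config.transform, coding=config.coding,
                )
                panels[(label, c.study_id)] = panel
                panel.to_tsv(_register(f"panel_{label}_{c.study_id}.tsv"))
        if config.fasting_sensitivity:
            for subset in ("fasted", "nonfasted"):
                p = run_scan(
                    by_id[config.discovery_study], "rare", covariates=config.covariates,
                    transform=config.transform, coding=config.coding, fasting=subset,
                )
                p.to_tsv(_register(f"panel_rare_{config.discovery_study}_{subset}.tsv"))
        log_lines.append(f"scanned {len(panels)} variant-study panels")
    except Exception as exc:  # noqa: BLE001
        _fail("scan", exc)

    # -- stage 3: discovery filter + confirmation meta + FDR ------------
    try:
        disc_panel = panels[("rare", config.discovery_study)].ok()
        hits = disc_panel[disc_panel["p"] <= config.discovery_p]
        hits.reset_index(drop=True).to_csv(
            _register("discovery_hits.tsv"), sep="\t", index=False, float_format="%.10g"
        )
        confirm_ids = [s for s in config.confirmation_studies if s in by_id]
        summary_conf: dict = {"n_discovery_nominal": int(len(hits))}
        if confirm_ids:
            conf_meta = meta_panels([panels[("rare", s)] for s in confirm_ids], "fixed")
            conf_meta.to_csv(_register("confirmation_meta.tsv"), sep="\t", index=False, float_format="%.10g")
            conf_on_hits = conf_meta[conf_meta["metabolite_id"].isin(hits["metabolite_id"])]
            if len(conf_on_hits):
                fdr = by_fdr(
                    conf_on_hits["p"].to_numpy(), alpha=config.alpha,
                    metabolite_ids=conf_on_hits["metabolite_id"].tolist(),
                )
                fdr.to_tsv(_register("confirmation_fdr.tsv"))
                summary_conf["n_confirmed_by"] = fdr.n_significant
            else:
                summary_conf["n_confirmed_by"] = 0
    except Exception as exc:  # noqa: BLE001
        _fail("confirmation", exc)

    # -- stage 4: full meta (pedigree pooling + fixed meta + FDR) -------
    summary_meta: dict = {}
    try:
        if config.include_full_meta:
            related = [by_id[s] for s in config.related_studies if s in by_id]
            others = [c for c in cohorts if c.study_id not in config.related_studies]
            if len(related) >= 2:
                pooled = pool_scan(related, "rare", covariates=config.covariates, transform=config.transform)
                pooled.to_tsv(_register("pooled_related_rare.tsv"))
                meta_inputs = [pooled] + [panels[("rare", c.study_id)] for c in others]
            else:
                meta_inputs = [panels[("rare", c.study_id)] for c in cohorts]
            full = meta_panels(meta_inputs, "fixed")
            full.to_csv(_register("full_meta.tsv"), sep="\t", index=False, float_format="%.10g")
            full_random = meta_panels(meta_inputs, "random")
            full_random.to_csv(_register("full_meta_random.tsv"), sep="\t", index=False, float_format="%.10g")
            fdr_full = by_fdr(
                full["p"].to_numpy(), alpha=config.alpha,
                metabolite_ids=full["metabolite_id"].tolist(),
            )
            fdr_full.to_tsv(_register("full_meta_fdr.tsv"))
            summary_meta["n_full_meta_by"] = fdr_full.n_significant
            log_lines.append("full meta-analysis complete")
    except Exception as exc:  # noqa: BLE001
        _fail("full_meta", exc)

    # -- stage 5: proxy-mediation test ----------------------------------
    try:
        per_study_pred = []
        k_summary = {}
        for s, c in enumerate(cohorts):
            pr, pp = panels[("rare", c.study_id)], panels[("proxy", c.study_id)]
            boot_seed = (config.seed * 7919 + 13 + s) % 2**31
            k_est, ratios = estimate_k(pr, pp, trim_fraction=config.trim_fraction, B=config.B, seed=boot_seed)
            ratios.to_csv(_register(f"ratios_{c.study_id}.tsv"), sep="\t", index=False, float_format="%.10g")
            k_est.to_tsv(_register(f"k_{c.study_id}.tsv"))
            pred = predict_effects(k_est, pp, pr, level=config.level)
            pred.to_csv(_register(f"pred_{c.study_id}.tsv"), sep="\t", index=False, float_format="%.10g")
            per_study_pred.append(pred)
            k_summary[c.study_id] = {"k_hat": k_est.k_hat, "se_k": k_est.se_k}
        combined = combine_predictions(per_study_pred)
        combined.to_csv(_register("pred_combined.tsv"), sep="\t", index=False, float_format="%.10g")

        # headline k from inverse-variance combined panels
        rare_meta = meta_to_panel(meta_panels([panels[("rare", c.study_id)] for c in cohorts], "fixed"))
        proxy_meta = meta_to_panel(meta_panels([panels[("proxy", c.study_id)] for c in cohorts], "fixed"))
        k_meta, _ = estimate_k(
            rare_meta, proxy_meta, trim_fraction=config.trim_fraction,
            B=config.B, seed=(config.seed * 7919 + 7) % 2**31,
        )
        k_meta.to_tsv(_register("k_combined.tsv"))
        r, slope = correlate_profiles(
            panels[("rare", config.discovery_study)], panels[("proxy", config.discovery_study)]
        )
        log_lines.append("proxy-mediation test complete")
    except Exception as exc:  # noqa: BLE001
        _fail("proxytest", exc)

    # -- summary --------------------------------------------------------
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_studies": len(cohorts),
        "n_metabolites": len(cohorts[0].metabolite_ids),
        **summary_conf,
        **summary_meta,
        "k_per_study": k_summary,
        "k_combined": {"k_hat": k_meta.k_hat, "se_k": k_meta.se_k},
        "n_flagged_per_study": {
            c.study_id: int(per_study_pred[i]["lpl_independent"].sum()) for i, c in enumerate(cohorts)
        },
        "n_flagged_combined": int(combined["lpl_independent"].sum()),
        "profile_r_discovery": r,
        "profile_slope_discovery": slope,
    }
    _write_json(_register("summary.json"), summary)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest.append("run.log")
    (outdir / "MANIFEST").write_text("\n".join(["COMPLETE"] + sorted(manifest)) + "\n")
    return summary


def write_report(run_dir: str | Path) -> pd.DataFrame:
    """Regenerate the per-metabolite report from persisted intermediates.

    Produces ``report.tsv`` (one row per metabolite: observed and
    predicted effects in beta/SE units, CI bounds, overlap flags, the
    discovery p-value) and ``report_long.tsv`` (plot-ready long format:
    metabolite, track, estimate, lo, hi).
    """
    run_dir = Path(run_dir)
    combined = pd.read_csv(run_dir / "pred_combined.tsv", sep="\t")
    report = combined.copy()
    report["z_obs"] = np.where(report["se_obs"] > 0, report["beta_obs"] / report["se_obs"], np.nan)
    report["z_pred"] = np.where(report["se_pred"] > 0, report["beta_pred"] / report["se_pred"], np.nan)

    disc_files = sorted(run_dir.glob("panel_rare_*.tsv"))
    if disc_files:
        disc = pd.read_csv(disc_files[0], sep="\t")[["metabolite_id", "p"]]
        disc = disc.rename(columns={"p": "p_discovery_file0"})
        report = report.merge(disc, on="metabolite_id", how="left")

    report.to_csv(run_dir / "report.tsv", sep="\t", index=False, float_format="%.10g")

    long_rows = []
    for _, row in combined.iterrows():
        long_rows.append((row["metabolite_id"], "observed", row["beta_obs"], row["obs_lo"], row["obs_hi"]))
        long_rows.append((row["metabolite_id"], "predicted", row["beta_pred"], row["pred_lo"], row["pred_hi"]))
    long = pd.DataFrame(long_rows, columns=["metabolite_id", "track", "estimate", "lo", "hi"])
    long.to_csv(run_dir / "report_long.tsv", sep="\t", index=False, float_format="%.10g")
    return report
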