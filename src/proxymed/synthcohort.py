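"""Synthetic multi-study cohort generator with known ground truth.

Emulates a three-cohort metabolomics design: a discovery cohort of young
participants (mixed sex, three measurement phases, a nonfasting fraction),
their mothers (all female, overlapping families with the discovery cohort),
and an independent cohort of older women.  Two biallelic variants are
simulated: a rare focal variant and a common proxy variant whose
per-metabolite effects are proportional up to a global constant ``k_true``,
with an optional subset of metabolites carrying an additional
proxy-independent effect ``delta``.

Metabolites are generated on the log1p scale,

    y*_im = a_m + beta_proxy[m] * g_proxy,i
                + (k_true * beta_proxy[m] + delta[m]) * g_rare,i
                + covariate effects + u_family(i),m + eps_im,

then stored on the raw scale as ``max(exp(y*) - 1, 0)``, so the downstream
``ln(x + 1)`` transform recovers the linear model exactly.  Zero-inflated
metabolites receive low intercepts, producing exact zeros through the
truncation; all other metabolites receive intercepts far enough above zero
that truncation is effectively never triggered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "CohortTable",
    "SimulatedData",
    "simulate_genotypes",
    "simulate_study",
    "simulate_multistudy",
    "draw_truth",
]

#: column order of the non-metabolite part of a cohort TSV
_META_COLS = [
    "study_id",
    "individual_id",
    "family_id",
    "genotype_rare",
    "genotype_proxy",
    "age",
    "sex",
    "phase",
    "fasted",
]

# per-study (age mean, age sd); study 1 mixed-sex with three phases and a
# nonfasting fraction, studies 2 and 3 all-female, single phase, fasted
_STUDY_AGE = {0: (15.5, 2.5), 1: (48.0, 4.4), 2: (69.0, 5.5)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-study cohort.

    Defaults mirror the scale of the motivating three-cohort design:
    ~7100 / 4530 / 3780 individuals, 225 metabolic measures, a rare focal
    variant at MAF 0.25% and a common proxy variant at MAF 10%, 37.5%
    nonfasting samples in the discovery cohort, and a mother-child family
    overlap between the first two cohorts.
    """

    n_per_study: tuple[int, int, int] = (7100, 4530, 3780)
    study_ids: tuple[str, str, str] = ("young", "mothers", "women")
    maf_rare: float = 0.0025
    maf_common: float = 0.10
    k_true: float = -2.0
    n_metabolites: int = 225
    #: explicit per-metabolite proxy effects; drawn from beta_proxy_range if None
    beta_proxy: tuple[float, ...] | None = None
    #: magnitude range for drawn proxy effects (sign random)
    beta_proxy_range: tuple[float, float] = (0.2, 0.6)
    #: metabolite IDs carrying a proxy-independent rare-variant effect
    independent_set: tuple[str, ...] = ()
    #: additional rare-variant-only effect applied to the independent set
    delta_independent: float = 0.0
    noise_sd: float = 1.0
    #: fraction of metabolites with exact zeros in the raw panel
    zero_inflation: float = 0.1
    #: fraction of individuals (of the smaller of studies 1/2) paired into
    #: mother-child families shared across the two pooled studies
    family_fraction: float = 0.44
    #: SD of the per-family random intercept (transformed-metabolite units)
    family_sd: float = 0.5
    nonfasting_fraction: float = 0.375
    geno_missing_rate: float = 0.01
    #: equicorrelation of residuals across metabolites (0 = independent)
    resid_equicorr: float = 0.0
    age_effect: float = 0.01
    sex_effect: float = 0.1
    phase_effect: float = 0.05
    seed: int = 0

    def metabolite_ids(self) -> list[str]:
        return [f"met{i + 1:03d}" for i in range(self.n_metabolites)]

    def validate(self) -> None:
        for name, maf in (("maf_rare", self.maf_rare), ("maf_common", self.maf_common)):
            if not (0.0 < maf <= 0.5):
                raise ValueError(f"{name} must be in (0, 0.5], got {maf}")
        if any(n < 1 for n in self.n_per_study):
            raise ValueError("n_per_study entries must be >= 1")
        if len(self.n_per_study) != len(self.study_ids):
            raise ValueError("n_per_study and study_ids must have equal length")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0, 1]")
        if not (0.0 <= self.family_fraction <= 1.0):
            raise ValueError("family_fraction must be in [0, 1]")
        if not (0.0 <= self.nonfasting_fraction <= 1.0):
            raise ValueError("nonfasting_fraction must be in [0, 1]")
        if not (0.0 <= self.geno_missing_rate < 1.0):
            raise ValueError("geno_missing_rate must be in [0, 1)")
        if not (0.0 <= self.resid_equicorr < 1.0):
            raise ValueError("resid_equicorr must be in [0, 1)")
        if self.noise_sd < 0 or self.family_sd < 0:
            raise ValueError("noise_sd and family_sd must be >= 0")
        unknown = set(self.independent_set) - set(self.metabolite_ids())
        if unknown:
            raise ValueError(
                f"independent_set references unknown metabolite IDs: {sorted(unknown)}"
            )
        if self.beta_proxy is not None and len(self.beta_proxy) != self.n_metabolites:
            raise ValueError("beta_proxy length must equal n_metabolites")

    # -- persistence ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_per_study", "study_ids", "beta_proxy_range", "independent_set"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("beta_proxy") is not None:
            raw["beta_proxy"] = tuple(raw["beta_proxy"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class CohortTable:
    """One study's individuals x {genotypes, covariates, metabolite panel}."""

    study_id: str
    data: pd.DataFrame
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        if self.data["individual_id"].duplicated().any():
            raise ValueError("individual_id must be unique within a study")
        for col in ("genotype_rare", "genotype_proxy"):
            vals = self.data[col].dropna().unique()
            if not np.isin(vals, [0, 1, 2]).all():
                raise ValueError(f"{col} contains dosages outside {{0,1,2,missing}}")

    @property
    def n(self) -> int:
        return len(self.data)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "study_id", self.study_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort TSV missing required columns: {missing}")
        study_id = str(df["study_id"].iloc[0])
        mets = [c for c in df.columns if c not in _META_COLS]
        return cls(study_id=study_id, data=df.drop(columns=["study_id"]), metabolite_ids=mets)


@dataclass
class SimulatedData:
    """Cohorts plus the ground-truth effect table used to generate them."""

    cohorts: list[CohortTable]
    truth: pd.DataFrame  # metabolite_id, beta_proxy, delta, beta_rare, zero_inflated
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cohort in self.cohorts:
            cohort.to_tsv(outdir / f"cohort_{cohort.study_id}.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
        self.config.to_yaml(outdir / "sim_config.yaml")


def simulate_genotypes(
    n: int,
    maf: float,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw additive dosages (0/1/2, NaN for missing) under Hardy-Weinberg.

    Each individual's dosage is the sum of two independent Bernoulli(maf)
    allele draws, so the empirical MAF converges to ``maf`` as n grows.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = rng.binomial(2, maf, size=n).astype(float)
    if missing_rate > 0:
        dosages[rng.random(n) < missing_rate] = np.nan
    return dosages


def draw_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth effect table, deterministic given the config.

    Columns: metabolite_id, beta_proxy, delta, beta_rare (= k_true*beta_proxy
    + delta), zero_inflated, intercept.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    m = config.n_metabolites
    ids = config.metabolite_ids()
    if config.beta_proxy is not None:
        beta_proxy = np.asarray(config.beta_proxy, dtype=float)
    else:
        lo, hi = config.beta_proxy_range
        beta_proxy = rng.uniform(lo, hi, size=m) * rng.choice([-1.0, 1.0], size=m)
    delta = np.zeros(m)
    indep = np.isin(ids, list(config.independent_set))
    delta[indep] = config.delta_independent
    beta_rare = config.k_true * beta_proxy + delta

    n_zi = int(round(config.zero_inflation * m))
    zero_inflated = np.zeros(m, dtype=bool)
    zero_inflated[rng.choice(m, size=n_zi, replace=False)] = True

    # intercepts: zero-inflated measures sit near zero so truncation creates
    # exact zeros; all others are pushed >5 noise SDs above the worst-case
    # negative genotype contribution so truncation is effectively impossible
    guard = 2.0 * (np.abs(beta_proxy) + np.abs(beta_rare)) + 1.0 + 5.0 * config.noise_sd
    intercept = np.where(
        zero_inflated,
        rng.uniform(0.2, 0.8, size=m) * max(config.noise_sd, 0.1),
        guard + rng.uniform(0.0, 1.0, size=m),
    )
    return pd.DataFrame(
        {
            "metabolite_id": ids,
            "beta_proxy": beta_proxy,
            "delta": delta,
            "beta_rare": beta_rare,
            "zero_inflated": zero_inflated,
            "intercept": intercept,
        }
    )


def _study_frame(
    config: SimulationConfig,
    study_index: int,
    study_id: str,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    family_ids: Sequence[str] | None = None,
    family_effects: dict[str, np.ndarray] | None = None,
) -> CohortTable:
    """Build one study; family ids/effects may be injected for shared families."""
    n = config.n_per_study[study_index]
    m = config.n_metabolites

    g_rare = rng.binomial(2, config.maf_rare, size=n).astype(float)
    g_proxy = rng.binomial(2, config.maf_common, size=n).astype(float)

    age_mean, age_sd = _STUDY_AGE.get(study_index, (50.0, 5.0))
    age = rng.normal(age_mean, age_sd, size=n).clip(min=1.0)
    if study_index == 0:
        sex = rng.integers(0, 2, size=n).astype(float)
        # phase 0 = early nonfasted assessment; phases 1/2 fasted
        nonfast = rng.random(n) < config.nonfasting_fraction
        phase = np.where(nonfast, 0, rng.integers(1, 3, size=n))
        fasted = (~nonfast).astype(int)
    else:
        sex = np.ones(n)
        phase = np.zeros(n, dtype=int)
        fasted = np.ones(n, dtype=int)

    if family_ids is None:
        family_ids = [f"{study_id}_f{i + 1:06d}" for i in range(n)]
    family_ids = list(family_ids)

    beta_proxy = truth["beta_proxy"].to_numpy()
    beta_rare = truth["beta_rare"].to_numpy()
    intercept = truth["intercept"].to_numpy()

    y = (
        intercept[None, :]
        + np.outer(g_proxy, beta_proxy)
        + np.outer(g_rare, beta_rare)
        + (config.age_effect * age + config.sex_effect * sex)[:, None]
        + (config.phase_effect * phase)[:, None]
    )
    if config.family_sd > 0:
        fam_arr = np.empty((n, m))
        effects = family_effects if family_effects is not None else {}
        for i, fid in enumerate(family_ids):
            if fid not in effects:
                effects[fid] = rng.normal(0.0, config.family_sd, size=m)
            fam_arr[i] = effects[fid]
        y += fam_arr
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=(n, m))
        if config.resid_equicorr > 0:
            shared = rng.normal(0.0, config.noise_sd, size=n)
            rho = config.resid_equicorr
            eps = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
        y += eps

    raw = np.maximum(np.expm1(y), 0.0)

    # genotype missingness is observational: applied after the phenotypes
    if config.geno_missing_rate > 0:
        g_rare[rng.random(n) < config.geno_missing_rate] = np.nan
        g_proxy[rng.random(n) < config.geno_missing_rate] = np.nan

    df = pd.DataFrame(
        {
            "individual_id": [f"{study_id}_i{i + 1:06d}" for i in range(n)],
            "family_id": family_ids,
            "genotype_rare": g_rare,
            "genotype_proxy": g_proxy,
            "age": age,
            "sex": sex,
            "phase": phase,
            "fasted": fasted,
        }
    )
    mets = pd.DataFrame(raw, columns=truth["metabolite_id"].tolist())
    return CohortTable(study_id=study_id, data=pd.concat([df, mets], axis=1), metabolite_ids=truth["metabolite_id"].tolist())


def simulate_study(config: SimulationConfig, study_id: str | None = None, study_index: int = 0) -> CohortTable:
    """Generate a single study; every individual forms their own family."""
    config.validate()
    truth = draw_truth(config)
    children = np.random.SeedSequence(config.seed).spawn(2 + study_index)
    rng = np.random.default_rng(children[1 + study_index])
    sid = study_id if study_id is not None else config.study_ids[study_index]
    return _study_frame(config, study_index, sid, truth, rng)


def simulate_multistudy(config: SimulationConfig) -> SimulatedData:
    """Generate the three-study design.

    Studies 1 and 2 share mother-child families for ``family_fraction`` of
    the smaller study's individuals: paired rows carry the same family_id
    and the same per-family random intercept in their metabolite values.
    Study 3 is unrelated.
    """
    config.validate()
    truth = draw_truth(config)
    n_studies = len(config.n_per_study)
    children = np.random.SeedSequence(config.seed).spawn(1 + n_studies)

    n_shared = 0
    shared_ids: list[str] = []
    if n_studies >= 2:
        n_shared = int(round(config.family_fraction * min(config.n_per_study[0], config.n_per_study[1])))
        shared_ids = [f"shared_f{i + 1:06d}" for i in range(n_shared)]
    shared_effects: dict[str, np.ndarray] = {}

    cohorts = []
    for s in range(n_studies):
        rng = np.random.default_rng(children[1 + s])
        sid = config.study_ids[s]
        fam = None
        if s in (0, 1) and n_shared > 0:
            n = config.n_per_study[s]
            fam = shared_ids + [f"{sid}_f{i + 1:06d}" for i in range(n - n_shared)]
        cohorts.append(
            _study_frame(
                config, s, sid, truth, rng,
                family_ids=fam,
                family_effects=shared_effects if s in (0, 1) else None,
            )
        )
    return SimulatedData(cohorts=cohorts, truth=truth, config=config)
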