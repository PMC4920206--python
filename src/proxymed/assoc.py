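"""Genotype QC, metabolite transformation, and the per-metabolite association scan.

Effects are estimated by ordinary least squares of the (optionally
log1p-transformed) metabolite on allele dosage plus covariates, with
complete-case deletion and Wald inference against the normal reference.
The scan is vectorized: metabolites sharing a missingness pattern are fit
in one multi-response solve, which is what makes the replicate calibration
studies (tens of thousands of regressions) run in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .synthcohort import CohortTable

__all__ = [
    "QCThresholds",
    "QCReport",
    "AssociationResult",
    "AssociationPanel",
    "hwe_exact_test",
    "qc_variant",
    "transform_metabolite",
    "fit_association",
    "run_scan",
]

_VARIANT_ALIASES = {"rare": "genotype_rare", "proxy": "genotype_proxy"}


# ---------------------------------------------------------------------------
# genotype QC


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC thresholds.

    Defaults follow standard array-QC practice: missingness <= 3%, call
    rate >= 95%, MAF >= 1%, HWE exact p >= 5e-7.  The MAF filter can be
    disabled because the rare focal variant (MAF ~0.25%) is deliberately
    exempt from it.
    """

    max_missingness: float = 0.03
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 5e-7
    apply_maf_filter: bool = True


@dataclass
class QCReport:
    variant_id: str
    missingness: float
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int, midp: bool = False) -> float:
    """Exact Hardy-Weinberg test p-value, conditional on allele counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (two-sided, Wigginton-style).  ``midp=True`` counts the
    observed configuration with half weight.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:  # monomorphic: single possible configuration
        return 1.0 if not midp else 0.5

    # possible het counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    valid = hom_major >= 0
    hets, hom_minor, hom_major = hets[valid], hom_minor[valid], hom_major[valid]

    logp = (
        hets * math.log(2.0)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:
        raise ValueError("observed genotype counts incompatible with allele counts")
    p_obs = prob[obs[0]]
    # tolerance guards against ties lost to floating point
    mask = prob <= p_obs * (1.0 + 1e-12)
    p = prob[mask].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(p, 1.0))


def qc_variant(
    dosages: Sequence[float] | np.ndarray,
    thresholds: QCThresholds | None = None,
    variant_id: str = "variant",
) -> QCReport:
    """Compute missingness, MAF and exact HWE p for a dosage vector."""
    thresholds = thresholds or QCThresholds()
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all dosages missing")
    if not np.isin(obs, [0.0, 1.0, 2.0]).all():
        raise ValueError("dosages must be in {0, 1, 2} or missing")

    missingness = 1.0 - obs.size / d.size
    call_rate = 1.0 - missingness
    counts = [int((obs == g).sum()) for g in (0.0, 1.0, 2.0)]
    n_minor = counts[1] + 2 * counts[2]
    maf = n_minor / (2 * obs.size)
    maf = min(maf, 1.0 - maf)
    hwe_p = hwe_exact_test(counts[0], counts[1], counts[2])
    passed = (
        missingness <= thresholds.max_missingness
        and call_rate >= thresholds.min_call_rate
        and hwe_p >= thresholds.min_hwe_p
        and (not thresholds.apply_maf_filter or maf >= thresholds.min_maf)
    )
    return QCReport(
        variant_id=variant_id,
        missingness=float(missingness),
        call_rate=float(call_rate),
        maf=float(maf),
        hwe_p=hwe_p,
        passed=bool(passed),
    )


# ---------------------------------------------------------------------------
# metabolite transformation


def transform_metabolite(
    values: Sequence[float] | np.ndarray,
    mode: str = "auto",
    skew_threshold: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Apply the ln(x+1) transform when warranted.

    ``mode='always'`` transforms unconditionally (the consistent choice for
    pipeline runs, since some measures contain exact zeros); ``'never'``
    leaves values untouched; ``'auto'`` transforms when the non-missing
    sample is right-skewed (skewness > ``skew_threshold``) or contains
    exact zeros.  Missing values propagate; negative values are rejected
    because the raw metabolite scale is non-negative.
    """
    if mode not in ("auto", "always", "never"):
        raise ValueError(f"unknown transform mode: {mode!r}")
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size and obs.min() < 0:
        raise ValueError("negative metabolite value on the raw (non-negative) scale")
    if mode == "never":
        return v.copy(), False
    if mode == "always":
        return np.log1p(v), True
    if obs.size == 0:
        return v.copy(), False
    has_zero = bool((obs == 0).any())
    skew = stats.skew(obs) if obs.size >= 3 and np.ptp(obs) > 0 else 0.0
    if has_zero or (np.isfinite(skew) and skew > skew_threshold):
        return np.log1p(v), True
    return v.copy(), False


# ---------------------------------------------------------------------------
# association fitting


@dataclass
class AssociationResult:
    metabolite_id: str
    variant_id: str
    study_id: str
    beta: float
    se: float
    p: float
    n: int
    transformed: bool


@dataclass
class AssociationPanel:
    """Per-metabolite association results for one variant in one study.

    ``results`` has one row per requested metabolite with columns
    metabolite_id, variant_id, study_id, beta, se, p, n, transformed,
    skipped_reason (empty string for fitted rows).
    """

    variant_id: str
    study_id: str
    results: pd.DataFrame

    _COLUMNS = [
        "metabolite_id", "variant_id", "study_id",
        "beta", "se", "p", "n", "transformed", "skipped_reason",
    ]

    def ok(self) -> pd.DataFrame:
        """Rows with a fitted estimate, indexed by metabolite."""
        out = self.results[self.results["skipped_reason"] == ""]
        return out.set_index("metabolite_id", drop=False)

    @property
    def n_skipped(self) -> int:
        return int((self.results["skipped_reason"] != "").sum())

    def to_tsv(self, path: str | Path) -> None:
        self.results[self._COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationPanel":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        df["skipped_reason"] = df["skipped_reason"].fillna("")
        return cls(
            variant_id=str(df["variant_id"].iloc[0]),
            study_id=str(df["study_id"].iloc[0]),
            results=df,
        )

    def get(self, metabolite_id: str) -> AssociationResult:
        row = self.results[self.results["metabolite_id"] == metabolite_id]
        if row.empty:
            raise KeyError(metabolite_id)
        r = row.iloc[0]
        if r["skipped_reason"]:
            raise ValueError(f"{metabolite_id} was skipped: {r['skipped_reason']}")
        return AssociationResult(
            metabolite_id=r["metabolite_id"], variant_id=r["variant_id"],
            study_id=r["study_id"], beta=float(r["beta"]), se=float(r["se"]),
            p=float(r["p"]), n=int(r["n"]), transformed=bool(r["transformed"]),
        )


def load_vcf_dosages(vcf_path: str | Path, variant_id: str) -> tuple[np.ndarray, list[str]]:
    """Extract additive dosages for one variant from a VCF (GT field).

    Returns (dosages with NaN for missing genotypes, sample names).  The
    variant is selected by its ID column entry.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for rec in vcf:
        if rec.ID == variant_id:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            return gt.sum(axis=1), samples
    raise KeyError(f"variant {variant_id!r} not found in {vcf_path}")


def attach_vcf_genotypes(
    cohort: CohortTable,
    vcf_path: str | Path,
    variant_id: str,
    target: str = "genotype_rare",
) -> CohortTable:
    """Replace a cohort's genotype column with dosages read from a VCF.

    Samples are matched to individuals by name; cohort individuals absent
    from the VCF get a missing dosage.
    """
    target = _VARIANT_ALIASES.get(target, target)
    dosages, samples = load_vcf_dosages(vcf_path, variant_id)
    lookup = dict(zip(samples, dosages))
    data = cohort.data.copy()
    data[target] = [lookup.get(i, np.nan) for i in data["individual_id"]]
    return CohortTable(cohort.study_id, data, list(cohort.metabolite_ids))


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided Wald p against the normal reference; exact fits get p=0."""
    beta = np.atleast_1d(np.asarray(beta, float))
    se = np.atleast_1d(np.asarray(se, float))
    p = np.ones_like(beta)
    pos = se > 0
    p[pos] = 2.0 * stats.norm.sf(np.abs(beta[pos]) / se[pos])
    exact = ~pos
    p[exact] = np.where(np.abs(beta[exact]) > 0, 0.0, 1.0)
    return p


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of each column of Y on X; returns (coef (p,k), se (p,k), dof)."""
    n, p = X.shape
    dof = n - p
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design matrix") from exc
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    if dof > 0:
        sigma2 = rss / dof
        # exactly-fit columns can go slightly negative through cancellation
        sigma2 = np.maximum(sigma2, 0.0)
    else:
        sigma2 = np.full(Y.shape[1], np.nan)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return coef, se, dof


def _resolve_variant(cohort: CohortTable, variant: str) -> str:
    col = _VARIANT_ALIASES.get(variant, variant)
    if col not in cohort.data.columns:
        raise KeyError(f"variant column {variant!r} not found in cohort")
    return col


def _design_matrix(
    df: pd.DataFrame,
    dosage_col: str,
    covariates: Sequence[str],
    coding: str,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dosage + covariates; phase expands to indicator contrasts.

    Constant covariate columns (e.g. sex in an all-female study) are
    dropped automatically.
    """
    dosage = df[dosage_col].to_numpy(float)
    if coding == "carrier":
        dosage = (dosage > 0).astype(float)
    elif coding != "additive":
        raise ValueError(f"unknown genotype coding: {coding!r}")
    cols = [np.ones(len(df)), dosage]
    names = ["intercept", "dosage"]
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate column {cov!r} not found")
        if cov == "phase":
            dummies = pd.get_dummies(df[cov].astype("category"), prefix="phase", drop_first=True)
            for c in dummies.columns:
                col = dummies[c].to_numpy(float)
                if np.ptp(col) > 0:
                    cols.append(col)
                    names.append(c)
        else:
            col = df[cov].to_numpy(float)
            if np.ptp(col) > 0:
                cols.append(col)
                names.append(cov)
    return np.column_stack(cols), names


def fit_association(
    cohort: CohortTable,
    metabolite_id: str,
    variant: str,
    covariates: Sequence[str] = ("age", "sex", "phase"),
    transform: str = "always",
    coding: str = "additive",
) -> AssociationResult:
    """OLS association of one transformed metabolite with one variant's dosage."""
    col = _resolve_variant(cohort, variant)
    if metabolite_id not in cohort.data.columns:
        raise KeyError(f"metabolite {metabolite_id!r} not found in cohort")
    df = cohort.data
    tvals, flag = transform_metabolite(df[metabolite_id].to_numpy(float), mode=transform)

    base = ~df[col].isna().to_numpy()
    for cov in covariates:
        base &= ~df[cov].isna().to_numpy()
    mask = base & ~np.isnan(tvals)
    sub = df.loc[mask]
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no complete cases")
    X, names = _design_matrix(sub, col, covariates, coding)
    if np.ptp(X[:, 1]) == 0:
        raise ValueError("monomorphic in analysis sample")
    if n <= X.shape[1]:
        raise ValueError(f"n={n} does not exceed parameter count {X.shape[1]}")
    coef, se, _ = _ols_multi(X, tvals[mask][:, None])
    beta, sebeta = float(coef[1, 0]), float(se[1, 0])
    p = float(_wald_p(np.array([beta]), np.array([sebeta]))[0])
    return AssociationResult(
        metabolite_id=metabolite_id,
        variant_id=col,
        study_id=cohort.study_id,
        beta=beta,
        se=sebeta,
        p=p,
        n=n,
        transformed=flag,
    )


def run_scan(
    cohort: CohortTable,
    variant: str,
    metabolite_ids: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "sex", "phase"),
    transform: str = "always",
    coding: str = "additive",
    fasting: str = "all",
) -> AssociationPanel:
    """Association scan of one variant across the metabolite panel.

    Metabolites failing preconditions (monomorphic dosage in their
    complete-case set, too few cases) are recorded as skipped with a
    reason, never silently dropped.  ``fasting`` restricts the analysis
    sample ('fasted' / 'nonfasted') for sensitivity analyses.
    """
    col = _resolve_variant(cohort, variant)
    ids = list(metabolite_ids) if metabolite_ids is not None else list(cohort.metabolite_ids)
    if not ids:
        raise ValueError("empty metabolite list")
    if fasting not in ("all", "fasted", "nonfasted"):
        raise ValueError(f"unknown fasting subset: {fasting!r}")

    df = cohort.data
    if fasting != "all":
        want = 1 if fasting == "fasted" else 0
        df = df[df["fasted"] == want]

    base = ~df[col].isna().to_numpy()
    for cov in covariates:
        base &= ~df[cov].isna().to_numpy()

    transformed: dict[str, tuple[np.ndarray, bool]] = {}
    for mid in ids:
        if mid not in df.columns:
            raise KeyError(f"metabolite {mid!r} not found in cohort")
        transformed[mid] = transform_metabolite(df[mid].to_numpy(float), mode=transform)

    # group metabolites by complete-case pattern so each group is one solve
    groups: dict[bytes, list[str]] = {}
    masks: dict[bytes, np.ndarray] = {}
    for mid in ids:
        mask = base & ~np.isnan(transformed[mid][0])
        key = np.packbits(mask).tobytes()
        groups.setdefault(key, []).append(mid)
        masks[key] = mask

    rows = []
    for key, mids in groups.items():
        mask = masks[key]
        n = int(mask.sum())
        sub = df.loc[mask]

        def _skip(reason: str) -> None:
            for mid in mids:
                rows.append((mid, col, cohort.study_id, np.nan, np.nan, np.nan,
                             n, transformed[mid][1], reason))

        if n == 0:
            _skip("no complete cases")
            continue
        X, _ = _design_matrix(sub, col, covariates, coding)
        if np.ptp(X[:, 1]) == 0:
            _skip("monomorphic in analysis sample")
            continue
        if n <= X.shape[1]:
            _skip("insufficient sample size")
            continue
        Y = np.column_stack([transformed[mid][0][mask] for mid in mids])
        const = np.ptp(Y, axis=0) == 0
        try:
            coef, se, _ = _ols_multi(X, Y)
        except ValueError:
            _skip("singular design matrix")
            continue
        beta, sebeta = coef[1], se[1]
        pvals = _wald_p(beta, sebeta)
        for j, mid in enumerate(mids):
            if const[j]:
                rows.append((mid, col, cohort.study_id, np.nan, np.nan, np.nan,
                             n, transformed[mid][1], "constant metabolite"))
            else:
                rows.append((mid, col, cohort.study_id, float(beta[j]), float(sebeta[j]),
                             float(pvals[j]), n, transformed[mid][1], ""))

    res = pd.DataFrame(rows, columns=AssociationPanel._COLUMNS)
    # restore the requested metabolite order
    res = res.set_index("metabolite_id").loc[ids].reset_index()
    return AssociationPanel(variant_id=col, study_id=cohort.study_id, results=res)
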