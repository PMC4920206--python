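"""The proxy-mediation test: trimmed-mean effect-ratio estimation, bootstrap
standard errors, predicted effects under pure mediation, and the CI-overlap
verdict.

The construction: if the rare focal variant acts on the metabolite panel
exclusively through the pathway indexed by the common proxy variant, its
per-metabolite effects are a constant multiple k of the proxy's effects.
The per-metabolite ratios r_m = beta_rare,m / beta_proxy,m then share the
value k, up to sampling noise and up to metabolites violating the model.
A 25% trimmed mean of the ratios estimates k robustly; its standard error
comes from bootstrapping the ratio list (1000 replicates by default).  The
predicted effect of the rare variant on metabolite m under pure mediation
is k_hat * beta_proxy,m, with a delta-method confidence interval; absence
of overlap between the predicted and observed intervals flags a
proxy-independent effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationPanel

__all__ = [
    "RatioEstimate",
    "compute_ratios",
    "trimmed_mean",
    "bootstrap_se",
    "predict_effects",
    "combine_predictions",
    "correlate_profiles",
]


@dataclass
class RatioEstimate:
    """Global mediation scaling factor: trimmed mean of effect ratios."""

    k_hat: float
    se_k: float
    trim_fraction: float
    n_ratios_total: int
    n_ratios_used: int
    B: int
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([vars(self)]).to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_ratios(
    panel_rare: AssociationPanel,
    panel_proxy: AssociationPanel,
    min_proxy_z: float = 0.0,
) -> pd.DataFrame:
    """Per-metabolite effect ratios r_m = beta_rare,m / beta_proxy,m.

    The metabolite intersection of the two panels is used; metabolites with
    an exactly zero proxy effect are recorded as excluded ("zero
    denominator") rather than mapped to infinity.  ``min_proxy_z`` > 0
    additionally excludes metabolites whose proxy effect is weaker than
    that many SEs (off by default; trimming is normally sufficient).

    Returns a frame with columns metabolite_id, beta_rare, se_rare,
    beta_proxy, se_proxy, ratio, excluded_reason.
    """
    rare = panel_rare.ok()
    proxy = panel_proxy.ok()
    shared = [m for m in rare["metabolite_id"] if m in set(proxy["metabolite_id"])]
    if not shared:
        raise ValueError("no shared metabolites between the two panels")
    rows = []
    for mid in shared:
        br, sr = float(rare.loc[mid, "beta"]), float(rare.loc[mid, "se"])
        bp, sp = float(proxy.loc[mid, "beta"]), float(proxy.loc[mid, "se"])
        reason = ""
        ratio = np.nan
        if bp == 0.0:
            reason = "zero denominator"
        elif min_proxy_z > 0 and sp > 0 and abs(bp) / sp < min_proxy_z:
            reason = "weak proxy effect"
        else:
            ratio = br / bp
        rows.append((mid, br, sr, bp, sp, ratio, reason))
    return pd.DataFrame(
        rows,
        columns=["metabolite_id", "beta_rare", "se_rare", "beta_proxy", "se_proxy", "ratio", "excluded_reason"],
    )


def trimmed_mean(values: Sequence[float] | np.ndarray, trim_fraction: float = 0.25) -> float:
    """Mean after removing floor(trim_fraction * n) values from each tail.

    The default 0.25 removes a quarter of the sorted ratios from each end
    (the midmean), rejecting metabolites that do not follow the
    proportional-effects model symmetrically.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if np.isnan(v).any():
        raise ValueError("values must not contain NaN")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cut = int(math.floor(trim_fraction * v.size))
    kept = np.sort(v)[cut: v.size - cut]
    if kept.size == 0:
        raise ValueError("trimming removed all values")
    return float(kept.mean())


def _trimmed_mean_rows(sorted_rows: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Row-wise trimmed mean of an already-sorted (B, n) matrix."""
    n = sorted_rows.shape[1]
    cut = int(math.floor(trim_fraction * n))
    if n - 2 * cut <= 0:
        raise ValueError("trimming removed all values")
    return sorted_rows[:, cut: n - cut].mean(axis=1)


def bootstrap_se(
    ratios: Sequence[float] | np.ndarray,
    B: int = 1000,
    trim_fraction: float = 0.25,
    seed: int = 0,
    trim_total: bool = False,
) -> RatioEstimate:
    """Trimmed-mean ratio estimate with a bootstrap standard error.

    The resampling unit is the per-metabolite ratio: each of the B
    replicates resamples the ratio list with replacement and recomputes the
    trimmed mean; se_k is the sample SD across replicates.  ``trim_total``
    interprets the trim fraction as the total fraction removed (split
    across the two tails) instead of per-tail.
    """
    v = np.asarray(ratios, dtype=float)
    if v.size == 0:
        raise ValueError("empty ratio list")
    if B < 2:
        raise ValueError("B must be >= 2")
    frac = trim_fraction / 2.0 if trim_total else trim_fraction
    k_hat = trimmed_mean(v, frac)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(B, v.size))
    boot = _trimmed_mean_rows(np.sort(v[idx], axis=1), frac)
    se_k = float(boot.std(ddof=1))
    cut = int(math.floor(frac * v.size))
    return RatioEstimate(
        k_hat=k_hat,
        se_k=se_k,
        trim_fraction=frac,
        n_ratios_total=int(v.size),
        n_ratios_used=int(v.size - 2 * cut),
        B=B,
        seed=seed,
    )


def estimate_k(
    panel_rare: AssociationPanel,
    panel_proxy: AssociationPanel,
    trim_fraction: float = 0.25,
    B: int = 1000,
    seed: int = 0,
    min_proxy_z: float = 0.0,
) -> tuple[RatioEstimate, pd.DataFrame]:
    """Convenience: ratios + trimmed-mean + bootstrap SE in one call."""
    ratios = compute_ratios(panel_rare, panel_proxy, min_proxy_z=min_proxy_z)
    usable = ratios.loc[ratios["excluded_reason"] == "", "ratio"].to_numpy()
    if usable.size == 0:
        raise ValueError("no usable ratios after exclusions")
    est = bootstrap_se(usable, B=B, trim_fraction=trim_fraction, seed=seed)
    return est, ratios


_PRED_COLUMNS = [
    "metabolite_id", "beta_pred", "pred_lo", "pred_hi", "se_pred",
    "beta_obs", "obs_lo", "obs_hi", "se_obs", "n_obs", "n_proxy",
    "overlap", "lpl_independent",
]


def predict_effects(
    k: RatioEstimate,
    panel_proxy: AssociationPanel,
    panel_rare: AssociationPanel,
    level: float = 0.95,
    cross_term: bool = False,
) -> pd.DataFrame:
    """Predicted pure-mediation effects vs observed effects, with overlap flags.

    beta_pred,m = k_hat * beta_proxy,m; its variance takes into account the
    standard errors of both the proxy estimate and the ratio mean
    (first-order delta method, Var = k^2 se_proxy^2 + beta_proxy^2 se_k^2;
    ``cross_term`` adds the exact-product term se_k^2 se_proxy^2).
    Intervals are normal-quantile based; a shared endpoint counts as
    overlap, so ``lpl_independent`` requires strictly disjoint intervals.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rare = panel_rare.ok()
    proxy = panel_proxy.ok()
    shared = [m for m in proxy["metabolite_id"] if m in set(rare["metabolite_id"])]
    if not shared:
        raise ValueError("no shared metabolites between the two panels")
    rows = []
    for mid in shared:
        bp, sp = float(proxy.loc[mid, "beta"]), float(proxy.loc[mid, "se"])
        bo, so = float(rare.loc[mid, "beta"]), float(rare.loc[mid, "se"])
        pred = k.k_hat * bp
        var = k.k_hat**2 * sp**2 + bp**2 * k.se_k**2
        if cross_term:
            var += k.se_k**2 * sp**2
        se_pred = math.sqrt(var)
        lo_p, hi_p = pred - z * se_pred, pred + z * se_pred
        lo_o, hi_o = bo - z * so, bo + z * so
        overlap = (lo_p <= hi_o) and (lo_o <= hi_p)
        rows.append((mid, pred, lo_p, hi_p, se_pred, bo, lo_o, hi_o, so,
                     int(rare.loc[mid, "n"]), int(proxy.loc[mid, "n"]),
                     overlap, not overlap))
    return pd.DataFrame(rows, columns=_PRED_COLUMNS)


def combine_predictions(per_study: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size-weighted fixed-effects combination of per-study predictions.

    Both the observed and the predicted tracks are pooled with weights
    proportional to each study's own analysis n: pooled beta =
    sum(n_s b_s)/sum(n_s), pooled SE = sqrt(sum(n_s^2 se_s^2))/sum(n_s).
    The overlap verdict is re-evaluated on the pooled intervals at the
    width implied by the input intervals (the per-study z is recovered
    from the first frame).
    """
    if len(per_study) == 0:
        raise ValueError("no study predictions to combine")
    frames = [df.set_index("metabolite_id") for df in per_study]
    shared = set(frames[0].index)
    for f in frames[1:]:
        shared &= set(f.index)
    if not shared:
        raise ValueError("no shared metabolites across studies")
    # recover the z used for the input intervals
    f0 = frames[0].iloc[0]
    z = (f0["obs_hi"] - f0["beta_obs"]) / f0["se_obs"] if f0["se_obs"] > 0 else stats.norm.ppf(0.975)

    rows = []
    for mid in sorted(shared):
        n_obs = np.array([float(f.loc[mid, "n_obs"]) for f in frames])
        n_prx = np.array([float(f.loc[mid, "n_proxy"]) for f in frames])
        if (n_obs <= 0).any() or (n_prx <= 0).any():
            raise ValueError("study sample sizes must be positive")

        def _pool(b_col: str, se_col: str, n: np.ndarray) -> tuple[float, float]:
            b = np.array([float(f.loc[mid, b_col]) for f in frames])
            se = np.array([float(f.loc[mid, se_col]) for f in frames])
            bp = float(np.sum(n * b) / np.sum(n))
            sep = float(np.sqrt(np.sum(n**2 * se**2)) / np.sum(n))
            return bp, sep

        bo, so = _pool("beta_obs", "se_obs", n_obs)
        bp, sp = _pool("beta_pred", "se_pred", n_prx)
        lo_o, hi_o = bo - z * so, bo + z * so
        lo_p, hi_p = bp - z * sp, bp + z * sp
        overlap = (lo_p <= hi_o) and (lo_o <= hi_p)
        rows.append((mid, bp, lo_p, hi_p, sp, bo, lo_o, hi_o, so,
                     int(n_obs.sum()), int(n_prx.sum()), overlap, not overlap))
    return pd.DataFrame(rows, columns=_PRED_COLUMNS)


def correlate_profiles(
    panel_a: AssociationPanel,
    panel_b: AssociationPanel,
) -> tuple[float, float]:
    """Pearson r and least-squares slope between two z-scaled effect profiles.

    Each panel's effects are scaled by their standard error (beta/se); the
    slope is from the regression of panel_a's z-profile on panel_b's.
    """
    a = panel_a.ok()
    b = panel_b.ok()
    shared = [m for m in a["metabolite_id"] if m in set(b["metabolite_id"])]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared metabolites")
    if (a.loc[shared, "se"] <= 0).any() or (b.loc[shared, "se"] <= 0).any():
        raise ValueError("all standard errors must be positive")
    za = (a.loc[shared, "beta"] / a.loc[shared, "se"]).to_numpy()
    zb = (b.loc[shared, "beta"] / b.loc[shared, "se"]).to_numpy()
    r = float(stats.pearsonr(za, zb).statistic)
    slope = float(np.polyfit(zb, za, 1)[0])
    return r, slope
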