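"""Meta-analysis closed forms, DerSimonian-Laird tau2, BY adjustment against
the direct min-over-ranks formula, and mixed-model pedigree pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from proxymed.assoc import AssociationResult
from proxymed.metastat import (
    fixed_effects_meta,
    random_effects_meta,
    meta_panels,
    pool_related_studies,
    by_fdr,
)
from proxymed.synthcohort import SimulationConfig, simulate_multistudy

from conftest import make_panel


def _res(beta, se, met="met001", study="s1", n=100):
    return AssociationResult(
        metabolite_id=met, variant_id="v", study_id=study,
        beta=beta, se=se, p=0.5, n=n, transformed=True,
    )


class TestFixedEffects:
    def test_single_study_identity(self):
        m = fixed_effects_meta([_res(1.5, 0.3)])
        assert m.beta_pooled == pytest.approx(1.5)
        assert m.se_pooled == pytest.approx(0.3)

    def test_two_identical_studies_shrink_se_by_sqrt2(self):
        m = fixed_effects_meta([_res(0.8, 0.2, study="a"), _res(0.8, 0.2, study="b")])
        assert m.beta_pooled == pytest.approx(0.8)
        assert m.se_pooled == pytest.approx(0.2 / np.sqrt(2))
        assert m.q_stat == pytest.approx(0.0)

    def test_equal_weight_closed_form(self):
        m = fixed_effects_meta([_res(1.0, 1.0, study="a"), _res(3.0, 1.0, study="b")])
        assert m.beta_pooled == pytest.approx(2.0)
        assert m.se_pooled == pytest.approx(1.0 / np.sqrt(2))

    def test_k_identical_studies_se_scaling(self):
        for k in (1, 2, 5, 9):
            m = fixed_effects_meta([_res(0.4, 0.15, study=f"s{i}") for i in range(k)])
            assert m.se_pooled == pytest.approx(0.15 / np.sqrt(k))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mixed metabolite"):
            fixed_effects_meta([_res(1, 0.1, met="a"), _res(1, 0.1, met="b")])
        with pytest.raises(ValueError, match="positive"):
            fixed_effects_meta([_res(1, 0.0)])
        with pytest.raises(ValueError):
            fixed_effects_meta([])

    def test_matches_statsmodels_combine_effects(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 1, 6)
        se = rng.uniform(0.1, 0.5, 6)
        mine = fixed_effects_meta([_res(b, s, study=f"s{i}") for i, (b, s) in enumerate(zip(beta, se))])
        ref = combine_effects(beta, se**2).summary_frame()
        assert mine.beta_pooled == pytest.approx(ref.loc["fixed effect", "eff"], rel=1e-8)
        assert mine.se_pooled == pytest.approx(ref.loc["fixed effect", "sd_eff"], rel=1e-8)


class TestRandomEffects:
    def test_identical_studies_reduce_to_fixed(self):
        m = random_effects_meta([_res(0.8, 0.2, study="a"), _res(0.8, 0.2, study="b")])
        assert m.tau2 == 0.0
        assert m.se_pooled == pytest.approx(0.2 / np.sqrt(2))

    def test_dersimonian_laird_closed_form(self):
        # beta = 0,1,2 with se = 0.1: w = 100 each, Q = 200,
        # denom = 300 - 30000/300 = 200, tau2 = (200-2)/200 = 0.99
        m = random_effects_meta([_res(b, 0.1, study=f"s{b}") for b in (0.0, 1.0, 2.0)])
        assert m.tau2 == pytest.approx(0.99, abs=1e-10)
        assert m.beta_pooled == pytest.approx(1.0, abs=1e-10)
        assert m.se_pooled == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-10)

    def test_single_study_identity(self):
        m = random_effects_meta([_res(1.5, 0.3)])
        assert m.tau2 == 0.0
        assert m.beta_pooled == pytest.approx(1.5)

    def test_matches_statsmodels_dl(self):
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 1, 5)
        se = rng.uniform(0.1, 0.4, 5)
        mine = random_effects_meta([_res(b, s, study=f"s{i}") for i, (b, s) in enumerate(zip(beta, se))])
        ref = combine_effects(beta, se**2, method_re="chi2").summary_frame()
        assert mine.beta_pooled == pytest.approx(ref.loc["random effect", "eff"], rel=1e-6)


class TestMetaPanels:
    def test_panel_alignment(self):
        a = make_panel(["m1", "m2", "m3"], [1, 2, 3], [0.1, 0.1, 0.1], study="a")
        b = make_panel(["m2", "m3", "m4"], [2, 2, 2], [0.1, 0.1, 0.1], study="b")
        out = meta_panels([a, b], "fixed")
        assert set(out["metabolite_id"]) == {"m2", "m3"}

    def test_no_overlap_rejected(self):
        a = make_panel(["m1"], [1], [0.1], study="a")
        b = make_panel(["m2"], [1], [0.1], study="b")
        with pytest.raises(ValueError, match="shared"):
            meta_panels([a, b], "fixed")


@pytest.fixture(scope="module")
def zero_variance_sim():
    cfg = SimulationConfig(
        n_per_study=(500, 500, 2), n_metabolites=4, maf_rare=0.05,
        maf_common=0.10, family_fraction=0.5, family_sd=0.0, seed=17,
    )
    return simulate_multistudy(cfg)


class TestPedigreePooling:
    def test_zero_family_variance_agrees_with_ols(self, zero_variance_sim):
        """REML variance hits the zero boundary and the fit equals pooled OLS."""
        import statsmodels.api as sm
        from proxymed.assoc import transform_metabolite

        cohorts = zero_variance_sim.cohorts[:2]
        r = pool_related_studies(cohorts, "met001", "rare")
        assert r.sigma2_family == 0.0

        frames = []
        for c in cohorts:
            s = c.data[["family_id", "genotype_rare", "age", "sex", "phase", "met001"]].copy()
            s["study"] = c.study_id
            frames.append(s)
        df = pd.concat(frames, ignore_index=True)
        y, _ = transform_metabolite(df["met001"].to_numpy(float), "always")
        keep = (~df["genotype_rare"].isna()).to_numpy() & ~np.isnan(y)
        df, y = df.loc[keep], y[keep]
        X = pd.get_dummies(df[["genotype_rare", "age", "sex"]].assign(
            phase=df["phase"].astype("category"), study=df["study"]), drop_first=True)
        fit = sm.OLS(y, sm.add_constant(X.astype(float))).fit()
        assert r.beta == pytest.approx(fit.params["genotype_rare"], rel=1e-6)
        assert r.se == pytest.approx(fit.bse["genotype_rare"], rel=1e-6)

    def test_variance_fraction_recovery(self):
        """ICC 0.5 (family SD = noise SD) recovered within +-0.1 at 2000 pairs."""
        cfg = SimulationConfig(
            n_per_study=(2000, 2000, 2), n_metabolites=3, maf_rare=0.05,
            maf_common=0.10, family_fraction=1.0, family_sd=1.0, noise_sd=1.0, seed=19,
        )
        sim = simulate_multistudy(cfg)
        r = pool_related_studies(sim.cohorts[:2], "met002", "rare")
        assert abs(r.icc - 0.5) <= 0.1

    def test_matches_mixedlm_oracle(self):
        """The profiled-REML solver agrees with statsmodels MixedLM (the
        generic mixed-model route) on data with a real family variance."""
        import warnings
        from statsmodels.regression.mixed_linear_model import MixedLM
        from proxymed.assoc import transform_metabolite, _design_matrix

        cfg = SimulationConfig(
            n_per_study=(400, 400, 2), n_metabolites=3, maf_rare=0.05,
            maf_common=0.10, family_fraction=0.8, family_sd=0.8, seed=29,
        )
        sim = simulate_multistudy(cfg)
        r = pool_related_studies(sim.cohorts[:2], "met001", "rare")

        frames = []
        for c in sim.cohorts[:2]:
            s = c.data[["family_id", "genotype_rare", "age", "sex", "phase", "met001"]].copy()
            s = s.rename(columns={"genotype_rare": "dosage"})
            s["study"] = c.study_id
            frames.append(s)
        df = pd.concat(frames, ignore_index=True)
        y, _ = transform_metabolite(df["met001"].to_numpy(float), "always")
        keep = (~df["dosage"].isna()).to_numpy() & ~np.isnan(y)
        df, y = df.loc[keep].reset_index(drop=True), y[keep]
        X, _ = _design_matrix(df, "dosage", ("age", "sex", "phase"), "additive")
        sd = pd.get_dummies(df["study"], prefix="study", drop_first=True)
        X = np.column_stack([X, sd.to_numpy(float)])
        for j in range(2, X.shape[1]):
            X[:, j] = X[:, j] - X[:, j].mean()
            s = X[:, j].std()
            if s > 0:
                X[:, j] = X[:, j] / s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=df["family_id"].to_numpy()).fit(reml=True)
        assert r.beta == pytest.approx(float(fit.fe_params[1]), rel=1e-4)
        # MixedLM's bse_fe comes from the joint observed information, ours is
        # the model-based GLS covariance (X' V^-1 X)^-1 at the REML optimum;
        # they agree to ~0.2% at this size
        assert r.se == pytest.approx(float(fit.bse_fe[1]), rel=2e-3)
        assert r.sigma2_family == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), rel=1e-3)
        assert r.sigma2_resid == pytest.approx(float(fit.scale), rel=1e-3)

    def test_singleton_families_equal_ols_exactly(self, zero_variance_sim):
        """With every family a singleton, V is proportional to I for any
        variance split, so the pooled fit equals OLS to machine precision."""
        import statsmodels.api as sm
        from proxymed.assoc import transform_metabolite
        from proxymed.synthcohort import CohortTable

        cohorts = []
        for c in zero_variance_sim.cohorts[:2]:
            data = c.data.copy()
            data["family_id"] = [f"{c.study_id}_solo{i}" for i in range(len(data))]
            cohorts.append(CohortTable(c.study_id, data, c.metabolite_ids))
        r = pool_related_studies(cohorts, "met002", "rare")
        assert r.sigma2_family == 0.0

        frames = []
        for c in cohorts:
            s = c.data[["genotype_rare", "age", "sex", "phase", "met002"]].copy()
            s["study"] = c.study_id
            frames.append(s)
        df = pd.concat(frames, ignore_index=True)
        y, _ = transform_metabolite(df["met002"].to_numpy(float), "always")
        keep = (~df["genotype_rare"].isna()).to_numpy() & ~np.isnan(y)
        df, y = df.loc[keep], y[keep]
        X = pd.get_dummies(df[["genotype_rare", "age", "sex"]].assign(
            phase=df["phase"].astype("category"), study=df["study"]), drop_first=True)
        fit = sm.OLS(y, sm.add_constant(X.astype(float))).fit()
        assert r.beta == pytest.approx(fit.params["genotype_rare"], rel=1e-10)
        assert r.se == pytest.approx(fit.bse["genotype_rare"], rel=1e-10)

    def test_requires_multiple_families(self, zero_variance_sim):
        c = zero_variance_sim.cohorts[0]
        single = c.data.head(20).copy()
        single["family_id"] = "same"
        from proxymed.synthcohort import CohortTable
        mutated = CohortTable("s", single, c.metabolite_ids)
        with pytest.raises(ValueError, match="families"):
            pool_related_studies([mutated], "met001", "rare")


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli


def _by_oracle(p):
    """Direct min-over-ranks formula."""
    p = np.asarray(p, float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        val = m * c_m / rank * p[order[rank - 1]]
        running = min(running, val)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBYFDR:
    def test_worked_example_all_equal(self):
        # p = j/100 for j=1..5: every m*c(m)/j * p_(j) equals 0.01*5*137/60
        out = by_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        expect = 0.01 * 5 * (137 / 60)
        np.testing.assert_allclose(out.table["p_adjusted"], expect, atol=1e-12)

    def test_single_p_identity(self):
        out = by_fdr([0.03])
        assert out.table["p_adjusted"].iloc[0] == pytest.approx(0.03)

    def test_cap_at_one(self):
        out = by_fdr([1.0, 1.0, 1.0])
        np.testing.assert_array_equal(out.table["p_adjusted"], 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            by_fdr([])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_direct_formula_and_dominates_bh(self, pvals):
        from statsmodels.stats.multitest import multipletests

        out = by_fdr(pvals)
        np.testing.assert_allclose(out.table["p_adjusted"], _by_oracle(pvals), atol=1e-10)
        # BY is uniformly more conservative than BH
        _, bh, _, _ = multipletests(pvals, method="fdr_bh")
        assert (out.table["p_adjusted"].to_numpy() >= bh - 1e-12).all()
        # monotone in the raw p ordering
        tab = out.table.sort_values("p_raw")
        assert tab["p_adjusted"].is_monotonic_increasing
        assert (out.table["p_adjusted"] >= out.table["p_raw"] - 1e-12).all()
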