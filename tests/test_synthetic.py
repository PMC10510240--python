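import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlkit.ewas import fit_ewas
from meqtlkit.mr import mr_ivw, mr_presso
from meqtlkit.synthetic import (
    SimConfig,
    SyntheticTruth,
    balding_nichols_freqs,
    simulate_admixed_cohort,
    simulate_bundle,
    simulate_catalog,
    simulate_exposure,
    simulate_reference_panel,
    _block_ids,
    _variant_table,
)

from conftest import small_config


def test_balding_nichols_no_drift_limit(rng):
    """As Fst -> 0 every population's frequency collapses onto p0."""
    cfg = small_config(fst=1e-4, n_snps=200)
    variants = _variant_table(cfg, rng)
    blocks = _block_ids(cfg, variants)
    freqs = balding_nichols_freqs(cfg, blocks, rng)
    spread = freqs.max(axis=0) - freqs.min(axis=0)
    assert spread.max() < 0.02


def test_reference_panel_population_structure():
    """Fst=0.1 populations separate into 4 PCA clusters (silhouette > 0.5)."""
    from sklearn.metrics import silhouette_score

    from meqtlkit.ancestry import genotype_pca

    cfg = SimConfig(seed=5, fst=0.1, n_ref_per_pop=200, n_snps=2000)
    G, labels, _ = simulate_reference_panel(cfg)
    scores, _, _ = genotype_pca(G, None, n_pc=2)
    assert silhouette_score(scores, labels) > 0.5


def test_reference_panel_deterministic():
    cfg = small_config(seed=9)
    G1, _, _ = simulate_reference_panel(cfg)
    G2, _, _ = simulate_reference_panel(cfg)
    np.testing.assert_array_equal(G1.dosages, G2.dosages)


class TestAdmixedCohort:
    def setup_method(self):
        self.cfg = small_config(n_snps=400, ld_r=0.0)
        self.rng = np.random.default_rng(0)
        self.variants = _variant_table(self.cfg, self.rng)
        self.blocks = _block_ids(self.cfg, self.variants)
        self.freqs = balding_nichols_freqs(self.cfg, self.blocks, self.rng)

    def test_degenerate_mixture_matches_source_population(self):
        n = 800
        props = np.tile([1.0, 0, 0, 0], (n, 1))
        G = simulate_admixed_cohort(self.freqs, props, self.cfg, self.rng,
                                    self.variants, self.blocks)
        af = G.dosages.mean(axis=0) / 2
        se = np.sqrt(self.freqs[0] * (1 - self.freqs[0]) / (2 * n))
        assert (np.abs(af - self.freqs[0]) < 3 * se + 1e-9).mean() > 0.98

    def test_expected_dosage_linear_in_proportions(self):
        n = 2000
        props = np.tile([0.5, 0.5, 0, 0], (n, 1))
        G = simulate_admixed_cohort(self.freqs, props, self.cfg, self.rng,
                                    self.variants, self.blocks)
        expected = self.freqs[0] + self.freqs[1]  # 2 * (p1+p2)/2
        se = np.sqrt(2 * 0.25 / n) * 2  # loose bound on dosage-mean SE
        assert (np.abs(G.dosages.mean(axis=0) - expected) < 4 * se + 0.05).all()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_admixed_cohort(self.freqs, np.array([[0.5, 0.4, 0, 0]]),
                                    self.cfg, self.rng, self.variants, self.blocks)

    def test_within_block_dosage_correlation_matches_config(self):
        cfg = small_config(n_snps=400, ld_r=0.4)
        rng = np.random.default_rng(3)
        props = np.tile([1.0, 0, 0, 0], (500, 1))
        G = simulate_admixed_cohort(self.freqs, props, cfg, rng,
                                    self.variants, self.blocks)
        rs = []
        for b in range(20):
            cols = np.flatnonzero(self.blocks == b)
            C = np.corrcoef(G.dosages[:, cols], rowvar=False)
            rs.append(C[np.triu_indices_from(C, k=1)].mean())
        assert abs(np.mean(rs) - 0.4) < 0.1


class TestExposure:
    def test_null_model_prevalence(self):
        cfg = small_config()
        rng = np.random.default_rng(1)
        variants = _variant_table(cfg, rng)
        blocks = _block_ids(cfg, variants)
        freqs = balding_nichols_freqs(cfg, blocks, rng)
        G = simulate_admixed_cohort(freqs, np.tile([1, 0, 0, 0], (3000, 1)),
                                    cfg, rng, variants, blocks)
        y = simulate_exposure(G, SyntheticTruth(), cfg, rng)
        se = np.sqrt(cfg.exposure_prevalence * (1 - cfg.exposure_prevalence) / 3000)
        assert abs(y.mean() - cfg.exposure_prevalence) < 3 * se

    def test_logistic_effect_recovery(self):
        import statsmodels.api as sm

        cfg = small_config()
        rng = np.random.default_rng(2)
        variants = _variant_table(cfg, rng)
        blocks = _block_ids(cfg, variants)
        freqs = balding_nichols_freqs(cfg, blocks, rng)
        G = simulate_admixed_cohort(freqs, np.tile([1, 0, 0, 0], (2000, 1)),
                                    cfg, rng, variants, blocks, ld=False)
        v = G.variants["id"].iloc[5]
        truth = SyntheticTruth(exposure_snp_effects={v: 0.5})
        y = simulate_exposure(G, truth, cfg, rng)
        X = sm.add_constant(G.dosages[:, 5])
        fit = sm.Logit(y, X).fit(disp=False)
        assert abs(fit.params[1] - 0.5) < 3 * fit.bse[1]

    def test_seeded_determinism(self):
        cfg = small_config()
        rng = np.random.default_rng(1)
        variants = _variant_table(cfg, rng)
        blocks = _block_ids(cfg, variants)
        freqs = balding_nichols_freqs(cfg, blocks, rng)
        G = simulate_admixed_cohort(freqs, np.tile([1, 0, 0, 0], (100, 1)),
                                    cfg, rng, variants, blocks)
        y1 = simulate_exposure(G, SyntheticTruth(), cfg, np.random.default_rng(5))
        y2 = simulate_exposure(G, SyntheticTruth(), cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(y1, y2)


class TestMethylome:
    def test_noise_free_methylome_is_mixture_exactly(self):
        from meqtlkit.synthetic import simulate_methylome, _cpg_table

        cfg = small_config(noise_sd=0.0, batch_shift_sd=0.0,
                           technical_loading_sd=0.0, n_hidden_factors=0,
                           covariate_cpg_fraction=0.0, n_450k=30, n_epic=30,
                           n_cpgs=50, n_cell_ref_cpgs=20)
        rng = np.random.default_rng(4)
        variants = _variant_table(cfg, rng)
        blocks = _block_ids(cfg, variants)
        freqs = balding_nichols_freqs(cfg, blocks, rng)
        G = simulate_admixed_cohort(freqs, np.tile([1, 0, 0, 0], (60, 1)),
                                    cfg, rng, variants, blocks)
        cpgs = _cpg_table(cfg, rng)
        cov = pd.DataFrame({"sample": G.samples,
                            "cohort": ["450K"] * 30 + ["EPIC"] * 30,
                            "age": np.full(60, 50.0),
                            "tobacco": np.zeros(60, dtype=int)})
        out = simulate_methylome(G, np.zeros(60), SyntheticTruth(), cfg, rng,
                                 cpgs, cov)
        # with every effect and noise term zeroed M is the pure cell mixture
        w = out["cell_proportions"].to_numpy()
        # reconstruct profiles from the reference block (first 20 CpGs)
        M450 = out["methylation"]["450K"].values
        P_ref = out["cell_reference"].to_numpy()
        np.testing.assert_allclose(M450[:, :20], (w @ P_ref.T)[:30], atol=1e-10)

    def test_planted_cis_effect_recovery(self, small_bundle):
        b = small_bundle
        (v, c), beta = next(iter(b.truth.meqtl_effects.items()))
        gi = list(b.cohort.variants["id"]).index(v)
        M = b.methylome["methylation"]["450K"]
        ci = list(M.probes["id"]).index(c)
        rows = [b.cohort.samples.index(s) for s in M.samples]
        x = b.cohort.dosages[rows, gi]
        y = M.values[:, ci]
        slope, _, _, _, se = stats.linregress(x, y)[:5]
        assert abs(slope - beta) < 3 * se + 0.15  # nuisance structure adds noise

    def test_null_exposure_gives_uniform_ewas_p(self):
        # shared latent structure is disabled: the KS test assumes the 2000
        # null p-values are independent draws
        cfg = small_config(seed=21, n_true_exposure_cpgs=1, n_true_meqtls=1,
                           n_exposure_snps=0, n_cpgs=2000, n_snps=200,
                           exposure_cpg_effect=0.0, meqtl_effect=0.0,
                           n_hidden_factors=0, technical_loading_sd=0.0,
                           covariate_cpg_fraction=0.0, cell_profile_sd=0.0,
                           cell_profile_bg_sd=0.0)
        b = simulate_bundle(cfg)
        M = b.methylome["methylation"]["450K"]
        cov = b.covariates[b.covariates.cohort == "450K"]
        res = fit_ewas(M, cov["exposure"].to_numpy(float),
                       cov[["age", "wbc"]].reset_index(drop=True))
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def gwas_setup():
    cfg = small_config(outcome_gwas_n=5000, n_snps=400, ld_r=0.0)
    rng = np.random.default_rng(8)
    variants = _variant_table(cfg, rng)
    blocks = _block_ids(cfg, variants)
    freqs = balding_nichols_freqs(cfg, blocks, rng)
    return cfg, rng, variants, blocks, freqs


class TestOutcomeGwas:
    def _mr_input(self, cfg, rng, variants, blocks, freqs, gamma, outlier=None):
        from meqtlkit.synthetic import simulate_outcome_gwas

        ivs = list(variants["id"].iloc[::13][:30])
        truth = SyntheticTruth(
            exposure_snp_effects={v: 0.4 for v in ivs},
            causal_gamma={"t": gamma},
            pleiotropic_variants={"t": outlier or {}})
        gwas = simulate_outcome_gwas(
            freqs, lambda m, r: np.tile([1, 0, 0, 0], (m, 1)), truth, cfg,
            rng, variants, blocks, "t").set_index("variant")
        # exposure-side betas from an independent discovery cohort
        G = simulate_admixed_cohort(freqs, np.tile([1, 0, 0, 0], (2000, 1)),
                                    cfg, rng, variants, blocks)
        y = simulate_exposure(G, truth, cfg, rng)
        rows = []
        for v in ivs:
            i = list(G.variants["id"]).index(v)
            slope, _, _, _, se = stats.linregress(G.dosages[:, i], y)[:5]
            rows.append({"variant": v, "beta_exposure": slope,
                         "se_exposure": se,
                         "beta_outcome": gwas.loc[v, "beta"],
                         "se_outcome": gwas.loc[v, "se"]})
        return pd.DataFrame(rows)

    def test_null_causal_effect(self, gwas_setup):
        data = self._mr_input(*gwas_setup, gamma=0.0)
        res = mr_ivw(data)
        assert abs(res.estimate) < 3 * res.se

    def test_causal_effect_recovery(self, gwas_setup):
        data = self._mr_input(*gwas_setup, gamma=0.3)
        res = mr_ivw(data)
        assert abs(res.estimate - 0.3) < 3 * res.se

    def test_pleiotropic_outlier_flagged(self, gwas_setup):
        cfg, rng, variants, blocks, freqs = gwas_setup
        bad = variants["id"].iloc[0]
        data = self._mr_input(cfg, rng, variants, blocks, freqs, gamma=0.3,
                              outlier={bad: 1.0})
        # n_sim must exceed n_variants/sig for the Bonferroni outlier test
        # to be attainable (minimum empirical p is 1/(n_sim+1))
        res = mr_presso(data, n_sim=2000, seed=1)
        assert bad in res.outliers
        assert abs(res.estimate - 0.3) < 3 * res.se


class TestCatalog:
    def test_power_under_strong_enrichment(self):
        cfg = small_config(n_enriched_traits=1, n_null_traits=0,
                           enrichment_factor=5.0, risk_variants_per_trait=40)
        universe = [f"rs{i}" for i in range(2000)]
        meqtls = universe[:120]
        from meqtlkit.pleiotropy import trait_enrichment

        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = SyntheticTruth(enriched_traits=["t0"])
            cat = simulate_catalog(truth, cfg, rng, meqtls, universe)
            enr = trait_enrichment(set(meqtls), cat, universe)
            ps.append(enr.set_index("trait").loc["t0", "p_one_sided"])
        assert np.median(ps) < 0.05

    def test_enrichment_factor_below_one_rejected(self, rng):
        cfg = small_config()
        with pytest.raises(ValueError, match="enrichment_factor"):
            simulate_catalog(SyntheticTruth(), cfg, rng, ["rs1"], ["rs1", "rs2"],
                             enrichment_factor=0.5)


def test_bundle_truth_round_trip(small_bundle, tmp_path):
    small_bundle.truth.to_json(tmp_path / "truth.json")
    t2 = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert t2.meqtl_effects == small_bundle.truth.meqtl_effects
    assert t2.causal_gamma == small_bundle.truth.causal_gamma


def test_bundle_betas_and_dosages_in_range(small_bundle):
    from meqtlkit.io_formats import m_to_beta

    b = small_bundle
    d = b.cohort.dosages
    assert np.nanmin(d) >= 0 and np.nanmax(d) <= 2
    betas = m_to_beta(b.methylome["methylation"]["450K"].values)
    assert betas.min() >= 0 and betas.max() <= 1
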