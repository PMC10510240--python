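import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlkit.io_formats import GenotypeMatrix, MethylationMatrix
from meqtlkit.meqtl import (
    bh_fdr,
    cis_pairs,
    clump,
    fit_meqtl,
    genotype_qc,
    hwe_test,
    nearest_gene,
)


def _gm(dosages, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": [chrom] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m, "alt": ["G"] * m})
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], variants)


class TestHwe:
    def test_perfect_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # p_hat=0.5 gives expected (25,50,25); chi2 = 25+50+25 = 100
        expected = stats.chi2.sf(100, 1)
        assert hwe_test(50, 0, 50) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.52e-23, rel=0.01)

    def test_monomorphic_convention(self):
        assert hwe_test(40, 0, 0) == 1.0
        assert hwe_test(0, 0, 40) == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestGenotypeQc:
    def test_maf_boundary_keep_at_equality(self):
        n = 100
        # column frequencies 0.04 and 0.05 built exactly from dosage counts
        col_low = np.r_[np.ones(8), np.zeros(92)]     # AF = 0.04
        col_keep = np.r_[np.ones(10), np.zeros(90)]   # AF = 0.05
        G = _gm(np.column_stack([col_low, col_keep]))
        out = genotype_qc(G, hwe_p_min=0.0)
        assert list(out.variants["id"]) == ["v1"]

    def test_missingness_filter(self):
        col = np.full(100, 1.0)
        col_miss = col.copy()
        col_miss[:6] = np.nan  # 6% missing
        G = _gm(np.column_stack([col, col_miss]))
        out = genotype_qc(G, maf_min=0.0, hwe_p_min=0.0)
        assert list(out.variants["id"]) == ["v0"]

    def test_hwe_filter(self, rng):
        hw = np.repeat([0, 1, 2], [25, 50, 25]).astype(float)
        bad = np.repeat([0, 2], [50, 50]).astype(float)  # no heterozygotes
        G = _gm(np.column_stack([hw, bad]))
        out = genotype_qc(G, maf_min=0.0, miss_max=1.0)
        assert list(out.variants["id"]) == ["v0"]


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        cpgs = pd.DataFrame({"id": ["cg0"], "chrom": ["chr1"], "pos": [1_000_000]})
        variants = pd.DataFrame({"id": ["a", "b"], "chrom": ["chr1"] * 2,
                                 "pos": [1_500_000, 1_500_001]})
        pairs = cis_pairs(cpgs, variants, window=500_000)
        assert list(pairs["variant"]) == ["a"]

    def test_cross_chromosome_never_paired(self):
        cpgs = pd.DataFrame({"id": ["cg0"], "chrom": ["chr1"], "pos": [100]})
        variants = pd.DataFrame({"id": ["a"], "chrom": ["chr2"], "pos": [100]})
        assert cis_pairs(cpgs, variants).empty


class TestFitMeqtl:
    def _pairs(self, m):
        return pd.DataFrame({"variant": [f"v{j}" for j in range(m)],
                             "cpg": [f"cg{j}" for j in range(m)]})

    def _mm(self, values):
        values = np.asarray(values, float)
        n, m = values.shape
        probes = pd.DataFrame({"id": [f"cg{j}" for j in range(m)],
                               "chrom": ["chr1"] * m,
                               "pos": np.arange(1, m + 1) * 1000})
        return MethylationMatrix(values, [f"s{i}" for i in range(n)], probes)

    def test_planted_effect_recovery(self, rng):
        n = 400
        G = _gm(rng.binomial(2, 0.3, size=(n, 3)))
        C = pd.DataFrame({"age": rng.normal(size=n)})
        M = self._mm(0.4 * G.dosages + rng.normal(0, 1, size=(n, 3)))
        res = fit_meqtl(M, G, C, self._pairs(3))
        assert (np.abs(res["beta"] - 0.4) < 3 * res["se"]).all()

    def test_matches_joint_ols(self, rng):
        import statsmodels.api as sm

        n = 30
        G = _gm(rng.binomial(2, 0.4, size=(n, 2)))
        C = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        M = self._mm(rng.normal(size=(n, 2)))
        res = fit_meqtl(M, G, C, self._pairs(2))
        for j in range(2):
            X = sm.add_constant(np.column_stack([G.dosages[:, j], C]))
            fit = sm.OLS(M.values[:, j], X).fit()
            assert res.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_monomorphic_variant_degenerate_record(self, rng):
        n = 50
        dos = np.column_stack([np.full(n, 2.0), rng.binomial(2, 0.5, n)])
        G = _gm(dos)
        M = self._mm(rng.normal(size=(n, 2)))
        res = fit_meqtl(M, G, pd.DataFrame(index=range(n)), self._pairs(2))
        assert res.loc[0, "degenerate"] and res.loc[0, "p"] == 1.0
        assert not res.loc[1, "degenerate"]

    def test_se_scaling_with_duplicated_samples(self, rng):
        n = 1000
        G1 = _gm(rng.binomial(2, 0.5, size=(n, 1)))
        M1 = self._mm(0.2 * G1.dosages + rng.normal(0, 1, size=(n, 1)))
        res1 = fit_meqtl(M1, G1, pd.DataFrame(index=range(n)), self._pairs(1))
        G2 = _gm(np.vstack([G1.dosages] * 2))
        M2 = self._mm(np.vstack([M1.values] * 2))
        res2 = fit_meqtl(M2, G2, pd.DataFrame(index=range(2 * n)), self._pairs(1))
        assert res2.loc[0, "se"] == pytest.approx(res1.loc[0, "se"] / np.sqrt(2),
                                                  rel=0.05)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        # p*(m/rank) = (.04, .04, .04, .04) after the running minimum
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 200))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), q, atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def brute_force_clump(pvals, positions, r2, r2_min):
    """Oracle: explicit greedy clumping over a precomputed r^2 matrix."""
    k = len(pvals)
    order = sorted(range(k), key=lambda i: (pvals[i], positions[i]))
    clump_id = [-1] * k
    index = [False] * k
    cid = 0
    for i in order:
        if clump_id[i] >= 0:
            continue
        clump_id[i] = cid
        index[i] = True
        for j in range(k):
            if clump_id[j] < 0 and r2[i][j] > r2_min:
                clump_id[j] = cid
        cid += 1
    return clump_id, index


class TestClump:
    def _records(self, pvals):
        return pd.DataFrame({"variant": [f"v{j}" for j in range(len(pvals))],
                             "cpg": "cg0", "p": pvals})

    def test_uncorrelated_all_index(self, rng):
        G = _gm(rng.binomial(2, 0.5, size=(500, 4)).astype(float))
        out = clump(self._records([0.01, 0.02, 0.03, 0.04]), G, r2_min=0.5)
        assert out["is_index"].all()
        assert out["clump_id"].nunique() == 4

    def test_perfect_ld_single_clump(self, rng):
        x = rng.binomial(2, 0.5, size=300).astype(float)
        G = _gm(np.column_stack([x, x]))
        out = clump(self._records([1e-10, 1e-5]), G, r2_min=0.1)
        assert out["clump_id"].nunique() == 1
        assert list(out["is_index"]) == [True, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 300, 15
        base = rng.binomial(2, 0.5, size=(n, k)).astype(float)
        for j in range(1, k, 3):  # create LD blocks of three
            mask = rng.random(n) < 0.8
            base[mask, j] = base[mask, j - 1]
        G = _gm(base)
        pvals = rng.uniform(1e-12, 0.05, size=k)
        out = clump(self._records(pvals), G, r2_min=0.1)
        r2 = np.corrcoef(base, rowvar=False) ** 2
        cid, idx = brute_force_clump(pvals, G.variants["pos"].tolist(), r2, 0.1)
        assert list(out["is_index"]) == idx
        # partitions agree up to clump relabelling
        mapping = {}
        for got, want in zip(out["clump_id"], cid):
            mapping.setdefault(got, want)
            assert mapping[got] == want

    def test_partition_covers_all_exactly_once(self, rng):
        G = _gm(rng.binomial(2, 0.4, size=(200, 10)).astype(float))
        out = clump(self._records(list(rng.uniform(size=10))), G, r2_min=0.1)
        assert (out["clump_id"] >= 0).all()
        assert out.groupby("clump_id")["is_index"].sum().eq(1).all()


class TestNearestGene:
    GENES = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                          "start": [100, 1000, 50],
                          "end": [200, 1100, 500],
                          "name": ["G1", "G2", "G3"]})

    def test_inside_gene(self):
        out = nearest_gene(pd.DataFrame({"chrom": ["chr1"], "pos": [150]}),
                           self.GENES)
        assert out.loc[0, "gene"] == "G1" and out.loc[0, "region_class"] == "genic"

    def test_equidistant_tie_prefers_lower_coordinate(self):
        out = nearest_gene(pd.DataFrame({"chrom": ["chr1"], "pos": [600]}),
                           self.GENES)
        assert out.loc[0, "gene"] == "G1"

    def test_absent_chromosome_gives_na(self):
        out = nearest_gene(pd.DataFrame({"chrom": ["chrX"], "pos": [1]}),
                           self.GENES)
        assert out.loc[0, "gene"] == "NA"

    def test_matches_linear_scan_oracle(self, rng):
        genes = pd.DataFrame({
            "chrom": ["chr1"] * 10,
            "start": np.sort(rng.choice(100_000, 10, replace=False)) + 1,
            "name": [f"G{i}" for i in range(10)]})
        genes["end"] = genes["start"] + 500
        pos = rng.integers(1, 100_000, size=100)
        out = nearest_gene(pd.DataFrame({"chrom": ["chr1"] * 100, "pos": pos}),
                           genes)
        for i, p in enumerate(pos):
            dists = [max(s - p, p - e, 0) for s, e in zip(genes["start"], genes["end"])]
            best = min(dists)
            cands = [g for g, d in zip(genes["name"], dists) if d == best]
            assert out.loc[i, "gene"] in cands
            assert out.loc[i, "gene"] == sorted(
                cands, key=lambda g: genes.set_index("name").loc[g, "start"])[0]


def test_meqtl_recovery_on_study_bundle(study_run):
    """Planted cis pairs are FDR-detected and their index is in-block."""
    bundle = study_run["bundle"]
    res = study_run["results"]["meqtl"]
    planted = bundle.truth.meqtl_effects
    sig = res.significant.set_index(["variant", "cpg"])
    hits = [pair for pair in planted if pair in sig.index]
    assert len(hits) >= 0.9 * len(planted)
    # recovered effects lie within 3 SE of the planted value
    betas = sig.loc[hits, "beta"]
    ses = sig.loc[hits, "se"]
    assert ((betas - 0.5).abs() < 3 * ses).mean() > 0.9
    # each planted pair's clump index shares the planted variant's LD block
    block_of = bundle.truth.ld_block_of
    ok = 0
    for v, c in hits:
        clump_id = sig.loc[(v, c), "clump_id"]
        idx_members = res.significant.loc[
            (res.significant["clump_id"] == clump_id)
            & res.significant["is_index"], "variant"]
        ok += any(block_of[i] == block_of[v] for i in idx_members)
    assert ok >= 0.9 * len(hits)


from hypothesis import given, settings, strategies as st


@given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1,
                max_size=60))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_fdr_properties(p):
    """q-values are valid probabilities, bounded below by p/m-scaling, and
    invariant to input order."""
    p = np.asarray(p)
    q = bh_fdr(p)
    assert ((q > 0) & (q <= 1)).all()
    assert (q >= p - 1e-15).all()  # q_(i) >= p_(i) since m/j >= 1
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-15)
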