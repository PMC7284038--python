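import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldlprs.io import ScoreDefinition, ScoreVariant, load_canonical_36snp_score
from ldlprs.scoring import (
    Orientation,
    align_alleles,
    compute_prs,
    default_threshold_grid,
    impute_missing_dosages,
    incremental_r2,
    scan_thresholds,
    score_from_sumstats,
)


def make_score(entries, name="toy"):
    return ScoreDefinition(
        name,
        tuple(
            ScoreVariant(vid, chrom, pos, oa, ea, w)
            for vid, chrom, pos, oa, ea, w in entries
        ),
    )


class TestAlignAlleles:
    def test_effect_allele_matching_alt_is_direct(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0], [1.0]]), ids=["rs1"], ref="G", alt="T")
        sd = make_score([("rs1", "1", 1000, "G", "T", 0.2)])
        aligned = align_alleles(sd, geno)
        assert aligned.variants[0].orientation is Orientation.DIRECT

    def test_effect_allele_matching_ref_is_flipped(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0], [1.0]]), ids=["rs1"], ref="G", alt="T")
        sd = make_score([("rs1", "1", 1000, "T", "G", 0.2)])
        aligned = align_alleles(sd, geno)
        assert aligned.variants[0].orientation is Orientation.FLIPPED

    def test_ambiguous_palindromic_dropped_under_default_policy(self, genotypes_factory):
        # A/T variant at in-sample frequency 0.5
        geno = genotypes_factory(
            np.array([[0.0], [2.0], [1.0], [1.0]]), ids=["rs1"], ref="A", alt="T"
        )
        sd = make_score([("rs1", "1", 1000, "A", "T", 0.2), ("rs2", "1", 2000, "A", "G", 0.1)])
        geno2 = genotypes_factory(
            np.hstack([geno.dosages, np.array([[0.0], [1.0], [2.0], [1.0]])]),
            ids=["rs1", "rs2"],
        )
        geno2.variants.loc[0, ["ref", "alt"]] = ["A", "T"]
        aligned = align_alleles(sd, geno2)
        dropped = {v.variant_id: v.reason for v in aligned.dropped}
        assert dropped == {"rs1": "ambiguous palindromic"}

    def test_unmatched_variant_dropped_with_reason(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0], [1.0]]), ids=["rs1"])
        sd = make_score([("rs1", "1", 1000, "A", "G", 0.2), ("rsX", "9", 99, "A", "G", 0.1)])
        aligned = align_alleles(sd, geno)
        assert [v.variant_id for v in aligned.dropped] == ["rsX"]
        assert aligned.dropped[0].reason == "unmatched"

    def test_position_fallback_match(self, genotypes_factory):
        geno = genotypes_factory(np.array([[1.0]]), ids=["chr_anon"], positions=[1234])
        sd = make_score([("rs1", "1", 1234, "A", "G", 0.2)])
        aligned = align_alleles(sd, geno)
        assert aligned.used[0].genotype_column == 0

    def test_fully_unmatched_score_is_error(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0], [1.0]]), ids=["rs1"])
        sd = make_score([("rsX", "9", 99, "A", "G", 0.1)])
        with pytest.raises(ValueError, match="no variant"):
            align_alleles(sd, geno)


class TestImputation:
    def test_missing_cell_gets_twice_allele_frequency(self, genotypes_factory):
        geno = genotypes_factory(
            np.array([[0.0], [1.0], [0.0], [np.nan]]), ids=["rs1"]
        )  # observed freq 0.5/2 -> impute 2*0.25/... freq = mean/2 = 1/6? use explicit
        geno = genotypes_factory(np.array([[0.0], [1.0], [np.nan], [1.0]]), ids=["rs1"])
        sd = make_score([("rs1", "1", 1000, "A", "G", 0.2)])
        aligned = align_alleles(sd, geno)
        # observed dosages (0, 1, 1): freq = 2/6 = 1/3 -> imputed 2/3
        out = impute_missing_dosages(geno, aligned)
        assert out.dosages[2, 0] == pytest.approx(2.0 / 3.0)

    def test_frequency_quarter_imputes_half(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0], [1.0], [0.0], [1.0], [np.nan]]), ids=["rs1"])
        sd = make_score([("rs1", "1", 1000, "A", "G", 0.2)])
        out = impute_missing_dosages(geno, align_alleles(sd, geno))
        assert out.dosages[4, 0] == pytest.approx(0.5)  # 2 x 0.25

    def test_no_missing_is_identity(self, genotypes_factory):
        geno = genotypes_factory(np.array([[0.0, 1.0], [2.0, 1.0]]))
        sd = make_score([("v0", "1", 1000, "A", "G", 0.2), ("v1", "1", 2000, "A", "G", 0.3)])
        out = impute_missing_dosages(geno, align_alleles(sd, geno))
        assert np.array_equal(out.dosages, geno.dosages)

    def test_all_missing_variant_errors(self, genotypes_factory):
        geno = genotypes_factory(np.array([[np.nan], [np.nan]]), ids=["rs1"])
        sd = make_score([("rs1", "1", 1000, "A", "G", 0.2)])
        with pytest.raises(ValueError, match="all dosages missing"):
            impute_missing_dosages(geno, align_alleles(sd, geno))


class TestComputePrs:
    def test_zero_dosages_zero_score(self, genotypes_factory):
        geno = genotypes_factory(np.zeros((3, 2)))
        sd = make_score([("v0", "1", 1000, "A", "G", 0.2), ("v1", "1", 2000, "A", "G", 0.5)])
        prs = compute_prs(geno, align_alleles(sd, geno))
        assert np.allclose(prs.values, 0.0)

    def test_hand_weighted_sum(self, genotypes_factory):
        geno = genotypes_factory(np.array([[1.0, 2.0]]))
        sd = make_score([("v0", "1", 1000, "A", "G", 0.2), ("v1", "1", 2000, "A", "G", 0.5)])
        prs = compute_prs(geno, align_alleles(sd, geno))
        assert prs.values.iloc[0] == pytest.approx(1.2)

    def test_canonical_single_dosage(self, genotypes_factory):
        sd = load_canonical_36snp_score()
        ids = sd.variant_ids
        X = np.zeros((1, 36))
        X[0, ids.index("rs629301")] = 2.0
        geno = genotypes_factory(
            X,
            ids=ids,
            chroms=[v.chrom for v in sd.variants],
            positions=[v.pos for v in sd.variants],
        )
        geno.variants["ref"] = [v.other_allele for v in sd.variants]
        geno.variants["alt"] = [v.effect_allele for v in sd.variants]
        prs = compute_prs(geno, align_alleles(sd, geno, palindromic_policy="keep"))
        assert prs.values.iloc[0] == pytest.approx(0.3472)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_linearity_and_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        from tests.conftest import make_genotypes  # reuse factory outside fixture

        X1 = rng.integers(0, 2, size=(8, 3)).astype(float)
        X2 = rng.integers(0, 2, size=(8, 3)).astype(float)
        sd = make_score(
            [(f"v{j}", "1", 1000 * (j + 1), "A", "G", w) for j, w in enumerate(rng.normal(size=3))]
        )
        g1, g2, g12 = make_genotypes(X1), make_genotypes(X2), make_genotypes(X1 + X2)
        a = align_alleles(sd, g1)
        s1 = compute_prs(g1, a).values.to_numpy()
        s2 = compute_prs(g2, a).values.to_numpy()
        s12 = compute_prs(g12, a).values.to_numpy()
        assert np.allclose(s12, s1 + s2, atol=1e-12)
        perm = rng.permutation(8)
        gp = make_genotypes(X1[perm])
        assert np.allclose(compute_prs(gp, a).values.to_numpy(), s1[perm], atol=1e-12)

    def test_flip_equivalence(self, genotypes_factory):
        rng = np.random.default_rng(42)
        X = rng.integers(0, 3, size=(20, 2)).astype(float)
        sd = make_score(
            [("v0", "1", 1000, "A", "G", 0.3), ("v1", "1", 2000, "C", "T", -0.4)]
        )
        geno = genotypes_factory(X.copy())
        geno.variants.loc[1, ["ref", "alt"]] = ["C", "T"]
        s_direct = compute_prs(geno, align_alleles(sd, geno)).values
        # recode v1 to count the opposite allele: dosage 2-x, swapped ref/alt
        Xr = X.copy()
        Xr[:, 1] = 2 - Xr[:, 1]
        geno_r = genotypes_factory(Xr)
        geno_r.variants.loc[1, ["ref", "alt"]] = ["T", "C"]
        s_flipped = compute_prs(geno_r, align_alleles(sd, geno_r)).values
        assert np.allclose(s_direct, s_flipped, atol=1e-12)

    def test_missing_dosages_rejected(self, genotypes_factory):
        geno = genotypes_factory(np.array([[np.nan], [1.0]]), ids=["rs1"])
        sd = make_score([("rs1", "1", 1000, "A", "G", 0.2)])
        with pytest.raises(ValueError, match="impute"):
            compute_prs(geno, align_alleles(sd, geno))


def pheno_frame(ldl, **covars):
    n = len(ldl)
    df = pd.DataFrame({"ldl_c": ldl, **covars}, index=[f"S{i}" for i in range(n)])
    df.index.name = "sample_id"
    return df


class TestIncrementalR2:
    def test_phenotype_equal_to_prs_explains_everything(self):
        rng = np.random.default_rng(0)
        prs = pd.Series(rng.normal(size=50), index=[f"S{i}" for i in range(50)])
        fit = incremental_r2(prs, pheno_frame(prs.to_numpy()), covariate_names=[])
        assert fit.incremental == pytest.approx(1.0)

    def test_covariate_determined_phenotype_gives_zero_increment(self):
        rng = np.random.default_rng(1)
        age = rng.normal(60, 10, 80)
        prs = pd.Series(rng.normal(size=80), index=[f"S{i}" for i in range(80)])
        fit = incremental_r2(prs, pheno_frame(2 + 0.05 * age, age=age), ["age"])
        assert fit.r2_null == pytest.approx(1.0)
        assert fit.incremental == pytest.approx(0.0, abs=1e-9)

    def test_nested_models_bound_increment(self):
        rng = np.random.default_rng(2)
        age = rng.normal(60, 10, 100)
        prs = pd.Series(rng.normal(size=100), index=[f"S{i}" for i in range(100)])
        y = 1 + 0.3 * prs.to_numpy() + 0.02 * age + rng.normal(0, 1, 100)
        fit = incremental_r2(prs, pheno_frame(y, age=age), ["age"])
        assert 0.0 <= fit.incremental <= 1.0
        assert fit.r2_full >= fit.r2_null

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        age = rng.normal(60, 10, 50)
        prs = pd.Series(rng.normal(size=50), index=[f"S{i}" for i in range(50)])
        ph = pheno_frame(rng.normal(size=50), age=age, age2=2 * age)
        with pytest.raises(ValueError, match="rank deficient"):
            incremental_r2(prs, ph, ["age", "age2"])


class TestThresholdScan:
    def test_default_grid_endpoints(self):
        grid = default_threshold_grid()
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e-100)
        assert len(grid) == 98

    def test_score_from_sumstats_uses_strict_inequality(self):
        ss = pd.DataFrame(
            {
                "rsid": ["a", "b"],
                "chrom": "1",
                "pos": [1, 2],
                "allele_a": "A",
                "allele_b": "G",
                "beta": [0.1, 0.2],
                "pvalue": [1e-3, 1e-4],
            }
        )
        assert score_from_sumstats(ss, 1e-3).n == 1

    def test_scan_table_counts_monotone_and_best_is_argmax(self, genotypes_factory):
        rng = np.random.default_rng(4)
        n, m = 400, 8
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        betas = np.array([0.4, 0.35, 0.3, 0.25, 0, 0, 0, 0])
        y = X @ betas + rng.normal(0, 1.0, n)
        geno = genotypes_factory(X, positions=[10_000_000 * (j + 1) for j in range(m)])
        pvals = [1e-30, 1e-25, 1e-22, 1e-21, 1e-5, 1e-5, 1e-4, 1e-4]
        ss = pd.DataFrame(
            {
                "rsid": [f"v{j}" for j in range(m)],
                "chrom": "1",
                "pos": geno.variants["pos"],
                "allele_a": "A",
                "allele_b": "G",
                "beta": betas,
                "pvalue": pvals,
            }
        )
        ph = pheno_frame(y)
        res = scan_thresholds(ss, geno, ph, covariate_names=[], grid=default_threshold_grid(3, 40))
        tab = res.table.sort_values("threshold")
        assert (tab["n_snps"].diff().dropna() >= 0).all()
        at_best = res.table.loc[
            res.table["threshold"] == res.best_threshold, "incremental_r2"
        ].iloc[0]
        assert at_best == res.table["incremental_r2"].max()

    def test_planted_signal_selects_causal_thresholds(self, genotypes_factory):
        # causal SNPs have p < 1e-20; decoys sit at p ~ 1e-4 with no effect
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 1500
            Xc = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
            Xn = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
            X = np.hstack([Xc, Xn])
            y = Xc @ np.full(4, 0.5) + rng.normal(0, 1, n)
            geno = genotypes_factory(X, positions=[10_000_000 * (j + 1) for j in range(10)])
            ss = pd.DataFrame(
                {
                    "rsid": [f"v{j}" for j in range(10)],
                    "chrom": "1",
                    "pos": geno.variants["pos"],
                    "allele_a": "A",
                    "allele_b": "G",
                    "beta": [0.5] * 4 + list(rng.normal(0, 0.3, 6)),
                    "pvalue": list(10.0 ** -rng.uniform(21, 40, 4))
                    + list(10.0 ** -rng.uniform(3.1, 5, 6)),
                }
            )
            res = scan_thresholds(
                ss, geno, pheno_frame(y), covariate_names=[], grid=default_threshold_grid(3, 50)
            )
            causal_only = set(res.best_score.variant_ids) <= {"v0", "v1", "v2", "v3"}
            if res.best_threshold <= 1e-20 and causal_only:
                hits += 1
        assert hits >= 9  # >= 90% of seeds

    def test_zero_snp_thresholds_recorded_not_fatal(self, genotypes_factory):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.4, size=(200, 2)).astype(float)
        geno = genotypes_factory(X)
        ss = pd.DataFrame(
            {
                "rsid": ["v0", "v1"],
                "chrom": "1",
                "pos": [1000, 2000],
                "allele_a": "A",
                "allele_b": "G",
                "beta": [0.3, 0.2],
                "pvalue": [1e-8, 1e-9],
            }
        )
        y = X @ np.array([0.3, 0.2]) + rng.normal(0, 0.5, 200)
        res = scan_thresholds(
            ss, geno, pheno_frame(y), covariate_names=[], grid=default_threshold_grid(3, 30)
        )
        empty = res.table[res.table["n_snps"] == 0]
        assert len(empty) > 0
        assert empty["incremental_r2"].isna().all()
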