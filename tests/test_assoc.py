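"""Mixed-model association: Henderson-III oracle equivalences, permutation
thresholds, Gibbs estimation and heritability partitioning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fullgen as fg
from fullgen.assoc import HendersonScan
from tests.conftest import make_pheno


def _single_locus_design(codes, y, env=None):
    """Design for one locus from explicit integer codes and responses."""
    n = len(codes)
    geno = fg.GenotypeMatrix(np.asarray(codes, dtype=np.int8)[:, None],
                             [f"L{i}" for i in range(n)], ["F0"] * n,
                             ["S1_100"])
    pheno = make_pheno(y, env=env)
    return fg.build_design(geno, pheno, gxe=False), geno


class TestHendersonF:
    def test_two_group_f_equals_classical_anova(self):
        rng = np.random.default_rng(0)
        codes = [2] * 12 + [0] * 12
        y = rng.normal(size=24) + 0.8 * (np.array(codes) - 1)
        dm, _ = _single_locus_design(codes, y)
        f, df1, df2, p = HendersonScan(dm).henderson_f("a@S1_100")
        f_ref, p_ref = stats.f_oneway(y[:12], y[12:])
        assert df1 == 1 and df2 == 22
        assert math.isclose(f, f_ref, rel_tol=0, abs_tol=1e-10)
        assert math.isclose(p, p_ref, rel_tol=1e-9)

    def test_three_group_joint_term_equals_classical_anova(self):
        rng = np.random.default_rng(1)
        codes = [2] * 10 + [1] * 10 + [0] * 10
        y = rng.normal(size=30)
        dm, _ = _single_locus_design(codes, y)
        f, df1, df2, _ = HendersonScan(dm).f_for_columns(
            ["a@S1_100", "d@S1_100"])
        f_ref, _ = stats.f_oneway(y[:10], y[10:20], y[20:])
        assert (df1, df2) == (2, 27)
        assert math.isclose(f, f_ref, rel_tol=0, abs_tol=1e-10)

    def test_zero_coefficient_term_gives_f_zero(self):
        rng = np.random.default_rng(2)
        codes = [0] * 20  # monomorphic: a column collinear with intercept
        dm, _ = _single_locus_design(codes, rng.normal(size=20))
        f, df1, _, p = HendersonScan(dm).henderson_f("a@S1_100")
        assert f == 0.0 and df1 == 0 and p == 1.0

    def test_unknown_term_raises(self):
        dm, _ = _single_locus_design([2, 0, 2, 0], [1, 2, 3, 4])
        with pytest.raises(KeyError):
            HendersonScan(dm).henderson_f("a@S9_9")

    def test_saturated_design_is_undefined(self):
        dm, _ = _single_locus_design([2, 0], [1.0, 2.0])
        with pytest.raises(ValueError, match="df2"):
            HendersonScan(dm).henderson_f("a@S1_100")

    def test_null_pointwise_p_is_uniform(self):
        rng = np.random.default_rng(3)
        geno = fg.simulate_nam_genotypes(25, 16, 250, 0.05, 0.0, seed=51)
        arch = fg.GeneticArchitecture(mu=0.0, residual_sd=1.0)
        pheno = fg.simulate_phenotypes(geno, arch, 1, seed=52)
        pvals = []
        for s in geno.snp_ids:
            dm = fg.build_design(geno, pheno, loci=[s], gxe=False)
            pvals.append(HendersonScan(dm).henderson_f(f"a@{s}")[3])
        stat = stats.kstest(pvals, "uniform")
        assert stat.statistic < 0.08
        assert stat.pvalue > 0.01


def _ols_f_oracle(X_full, X_reduced, y):
    """Textbook reduction-in-SS F for the columns dropped from X_full."""
    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ beta
        return fit @ fit
    r_full, r_red = ssr(X_full), ssr(X_reduced)
    df1 = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    df2 = len(y) - np.linalg.matrix_rank(X_full)
    sse = y @ y - r_full
    return ((r_full - r_red) / df1) / (sse / df2)


class TestPermutationThreshold:
    def test_exhaustive_enumeration_matches_independent_oracle(self):
        codes = [2, 0, 1, 2, 0, 1]
        env = [1, 1, 1, 2, 2, 2]
        y = np.array([3.0, -1.0, 0.5, 2.0, 4.0, -2.0])
        dm, _ = _single_locus_design(codes, y, env=env)
        res = fg.permutation_threshold(dm, alpha=0.25, exhaustive=True,
                                       include=("main",))
        # oracle: enumerate all within-env permutations, max F over a and d
        n = len(y)
        base = np.column_stack([np.ones(n), (np.array(env) == 2) * 1.0])
        xa = np.array(codes) - 1.0
        xd = (np.array(codes) == 1) * 1.0
        max_fs = []
        for p1 in itertools.permutations(range(3)):
            for p2 in itertools.permutations(range(3)):
                yp = np.r_[y[:3][list(p1)], y[3:][list(p2)]]
                full = np.column_stack([base, xa, xd])
                f_a = _ols_f_oracle(full,
                                    np.column_stack([base, xd]), yp)
                f_d = _ols_f_oracle(full,
                                    np.column_stack([base, xa]), yp)
                max_fs.append(max(f_a, f_d))
        expected = np.quantile(max_fs, 0.75, method="higher")
        assert res.n_perm == 36
        assert math.isclose(res.critical_f["experiment"], expected,
                            rel_tol=1e-9)

    def test_alpha_one_critical_is_minimum_max_f(self, null_data):
        geno, pheno = null_data
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:3])
        res = fg.permutation_threshold(dm, n_perm=100, alpha=1.0, seed=0)
        assert math.isclose(res.critical_f["experiment"],
                            res.max_f["experiment"].min())

    def test_small_n_perm_refused_unless_forced(self, null_data):
        geno, pheno = null_data
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:2])
        with pytest.raises(ValueError, match="force"):
            fg.permutation_threshold(dm, n_perm=50, seed=0)
        res = fg.permutation_threshold(dm, n_perm=50, seed=0, force=True)
        assert res.n_perm == 50

    def test_reported_families_split_terms(self, null_data):
        geno, pheno = null_data
        i, j = geno.snp_ids[:2]
        dm = fg.build_design(geno, pheno, loci=[i, j], pairs=[(i, j)])
        res = fg.permutation_threshold(dm, n_perm=100, seed=0,
                                       families="reported")
        assert set(res.critical_f) == {"main", "epistasis", "interaction"}

    def test_permutation_is_seed_deterministic(self, null_data):
        geno, pheno = null_data
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:5])
        a = fg.permutation_threshold(dm, n_perm=120, seed=9)
        b = fg.permutation_threshold(dm, n_perm=120, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestFullGeneticModel:
    def test_noiseless_additive_effect_recovered_exactly(self):
        codes = [2] * 10 + [0] * 10 + [1] * 5
        y = 5.0 + 2.0 * (np.array(codes) - 1.0) - 0.5 * (np.array(codes) == 1)
        dm, _ = _single_locus_design(codes, y)
        m = fg.FullGeneticModel().fit(dm)
        assert math.isclose(m.fixed_effects_["a@S1_100"], 2.0,
                            abs_tol=1e-9)
        assert math.isclose(m.fixed_effects_["d@S1_100"], -0.5,
                            abs_tol=1e-9)

    def test_empty_fixed_block_reduces_to_environment_means(self, null_data):
        geno, pheno = null_data
        dm = fg.build_design(geno, pheno, loci=[])
        m = fg.FullGeneticModel().fit(dm)
        mu = m.fixed_effects_["(intercept)"]
        env_effects = [m.random_effects_.get(f"e@{h}", 0.0) for h in (1, 2)]
        df = pheno.df
        for h, e in zip((1, 2), env_effects):
            observed = df.loc[df.env == h, "value"].mean()
            assert abs((mu + e) - observed) < 0.05  # BLUP shrinkage only

    def test_ae_only_architecture_loads_on_interaction_component(self):
        geno = fg.simulate_nam_genotypes(25, 40, 2, 0.03, 0.0, seed=61)
        snp = geno.snp_ids[0]
        arch = fg.GeneticArchitecture(
            mu=0.0, additive={snp: 0.0},
            gxe_loci={(snp, 1): {"ae": 2.0}, (snp, 2): {"ae": -2.0}},
            residual_sd=1.0)
        pheno = fg.simulate_phenotypes(geno, arch, 2, seed=62)
        dm = fg.build_design(geno, pheno, loci=[snp])
        m = fg.FullGeneticModel().fit(dm)
        assert m.variance_components_["ae"] > 0.5
        assert abs(m.fixed_effects_[f"a@{snp}"]) < 0.3
        # realized interaction effects carry the sign pattern
        assert m.random_effects_[f"ae@{snp}:1"] > 1.0
        assert m.random_effects_[f"ae@{snp}:2"] < -1.0

    def test_misaligned_response_rejected(self, null_data):
        geno, pheno = null_data
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:1])
        with pytest.raises(ValueError):
            fg.FullGeneticModel().fit(dm, y=np.ones(3))


class TestGibbs:
    def test_noiseless_posterior_mean_equals_ols(self):
        codes = [2] * 8 + [0] * 8
        y = 1.0 + 0.7 * (np.array(codes) - 1.0)
        dm, _ = _single_locus_design(codes, y)
        m = fg.FullGeneticModel().fit(dm)
        post = m.gibbs(n_iter=500, burn_in=100, seed=0).set_index("term")
        assert abs(post.loc["a@S1_100", "estimate"] - 0.7) < 1e-3

    def test_same_seed_same_posterior(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2], size=60)
        y = 0.5 * (codes - 1.0) + rng.normal(scale=0.5, size=60)
        dm, _ = _single_locus_design(codes, y)
        m = fg.FullGeneticModel().fit(dm)
        a = m.gibbs(n_iter=400, burn_in=100, seed=7)
        b = m.gibbs(n_iter=400, burn_in=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_credible_interval_covers_null_effect(self):
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            geno = fg.simulate_nam_genotypes(10, 50, 2, 0.05, 0.0,
                                             seed=300 + rep)
            causal, null_snp = geno.snp_ids
            arch = fg.GeneticArchitecture(mu=0.0,
                                          additive={causal: 0.5},
                                          residual_sd=1.0)
            pheno = fg.simulate_phenotypes(geno, arch, 1, seed=400 + rep)
            dm = fg.build_design(geno, pheno, gxe=False)
            m = fg.FullGeneticModel().fit(dm)
            post = m.gibbs(n_iter=700, burn_in=200, thin=2,
                           seed=rep).set_index("term")
            est = post.loc[f"a@{null_snp}", "estimate"]
            sd = post.loc[f"a@{null_snp}", "sd"]
            covered += abs(est) <= 1.96 * sd
        assert covered >= 24  # ~95% nominal, binomial slack at n=30

    def test_iteration_budget_validated(self):
        dm, _ = _single_locus_design([2, 0, 2, 0, 1, 1],
                                     [1, 2, 3, 4, 5, 6])
        m = fg.FullGeneticModel().fit(dm)
        with pytest.raises(ValueError):
            m.gibbs(n_iter=100, burn_in=100)


class TestHeritability:
    def test_single_locus_closed_form(self):
        geno = fg.simulate_nam_genotypes(25, 80, 1, 0.03, 0.0, seed=71)
        snp = geno.snp_ids[0]
        a, sd = 0.8, 1.0
        arch = fg.GeneticArchitecture(mu=0.0, additive={snp: a},
                                      residual_sd=sd)
        pheno = fg.simulate_phenotypes(geno, arch, 1, seed=72)
        dm = fg.build_design(geno, pheno, gxe=False)
        m = fg.FullGeneticModel().fit(dm)
        h = m.heritability(use_posterior=False)
        xa = (geno.codes[:, 0] - 1.0)
        expected = 100 * a ** 2 * xa.var() / (a ** 2 * xa.var() + sd ** 2)
        assert abs(h.components["A"] - expected) < 2.0

    def test_all_zero_components_aggregate_to_zero(self):
        agg = fg.aggregate_heritability({k: 0.0 for k in
                                         ("A", "D", "AA", "AE")})
        assert agg == {"h2_T": 0.0, "h2_Dplus": 0.0, "h2_GE": 0.0}

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            fg.aggregate_heritability({"XX": 1.0})

    def test_zero_variance_is_undefined(self):
        dm, _ = _single_locus_design([2, 0, 2, 0, 1, 1], [2.0] * 6)
        m = fg.FullGeneticModel().fit(dm)
        with pytest.raises(ValueError):
            m.heritability()
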