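"""Breeding optimization: genotypic values, exact enumeration, stepwise
tuning and the prediction table."""

import itertools

import numpy as np
import pytest

import fullgen as fg
from fullgen.coding import encode_epistasis, encode_locus


def _random_arch(rng, n_loci=6, n_pairs=2, with_dd=True):
    loci = [f"S{k + 1}_1000" for k in range(n_loci)]
    arch = fg.GeneticArchitecture(
        mu=0.0,
        additive={s: float(rng.normal()) for s in loci},
        dominance={s: float(rng.normal()) for s in loci},
        residual_sd=1.0)
    pairs = list(itertools.combinations(loci, 2))[:n_pairs]
    for p in pairs:
        arch.epistasis[p] = {
            "aa": float(rng.normal()), "ad": float(rng.normal()),
            "da": float(rng.normal()),
            "dd": float(rng.normal()) if with_dd else 0.0}
    return fg.GeneticArchitecture(
        mu=arch.mu, additive=arch.additive, dominance=arch.dominance,
        epistasis=arch.epistasis, residual_sd=1.0)


def _oracle_value(genotype, arch, env=None):
    """Independent evaluation through the scalar coding functions."""
    v = 0.0
    for s, a in arch.additive.items():
        v += a * encode_locus(genotype[s])[0]
    for s, d in arch.dominance.items():
        v += d * encode_locus(genotype[s])[1]
    for (i, j), eff in arch.epistasis.items():
        aa, ad, da, dd = encode_epistasis(genotype[i], genotype[j])
        v += (eff.get("aa", 0) * aa + eff.get("ad", 0) * ad
              + eff.get("da", 0) * da + eff.get("dd", 0) * dd)
    if env is not None:
        for (s, h), eff in arch.gxe_loci.items():
            if h == env:
                xa, xd = encode_locus(genotype[s])
                v += eff.get("ae", 0) * xa + eff.get("de", 0) * xd
    return v


class TestGenotypicValue:
    def test_hand_evaluated_two_locus_example(self):
        arch = fg.GeneticArchitecture(
            mu=0.0, additive={"S1_1": 1.0, "S2_1": 2.0},
            epistasis={("S1_1", "S2_1"): {"aa": 0.5}})
        # 1*1 + 2*(-1) + 0.5*(-1) = -1.5
        assert fg.genotypic_value({"S1_1": "QQ", "S2_1": "qq"},
                                  arch) == -1.5

    def test_all_zero_effects_give_zero(self):
        arch = fg.GeneticArchitecture(mu=99.0, additive={"S1_1": 0.0})
        assert fg.genotypic_value({"S1_1": "QQ"}, arch) == 0.0

    def test_additive_negation_symmetry(self):
        rng = np.random.default_rng(0)
        loci = [f"S{k + 1}_5" for k in range(5)]
        arch = fg.GeneticArchitecture(
            mu=3.0, additive={s: float(rng.normal()) for s in loci})
        all_qq = {s: "qq" for s in loci}
        all_alt = {s: "QQ" for s in loci}
        assert fg.genotypic_value(all_qq, arch) == \
            -fg.genotypic_value(all_alt, arch)

    def test_matches_scalar_coding_oracle(self):
        rng = np.random.default_rng(1)
        arch = _random_arch(rng)
        for _ in range(20):
            geno = {s: rng.choice(["QQ", "Qq", "qq"]) for s in arch.loci}
            assert np.isclose(fg.genotypic_value(geno, arch),
                              _oracle_value(geno, arch))

    def test_missing_locus_raises(self):
        arch = fg.GeneticArchitecture(additive={"S1_1": 1.0, "S2_1": 1.0})
        with pytest.raises(KeyError):
            fg.genotypic_value({"S1_1": "QQ"}, arch)


class TestEnumerateOptimum:
    def test_single_additive_locus(self):
        arch = fg.GeneticArchitecture(additive={"S1_1": 2.0})
        geno, val = fg.enumerate_optimum(arch, ("QQ", "qq"))
        assert geno == {"S1_1": "QQ"} and val == 2.0

    def test_dominance_beats_additive_forces_heterozygote(self):
        arch = fg.GeneticArchitecture(additive={"S1_1": 1.0},
                                      dominance={"S1_1": 3.0})
        geno, val = fg.enumerate_optimum(arch, ("QQ", "Qq", "qq"))
        assert geno == {"S1_1": "Qq"} and val == 3.0

    def test_matches_exhaustive_scalar_oracle(self):
        rng = np.random.default_rng(11)
        arch = _random_arch(rng, n_loci=6)
        best_val = max(
            _oracle_value(dict(zip(arch.loci, combo)), arch)
            for combo in itertools.product(["QQ", "Qq", "qq"],
                                           repeat=len(arch.loci)))
        geno, val = fg.enumerate_optimum(arch, ("QQ", "Qq", "qq"))
        assert np.isclose(val, best_val)
        assert np.isclose(_oracle_value(geno, arch), val)

    def test_too_many_loci_refused(self):
        loci = {f"S1_{k + 1}": 1.0 for k in range(16)}
        arch = fg.GeneticArchitecture(additive=loci)
        with pytest.raises(ValueError, match="stepwise"):
            fg.enumerate_optimum(arch)


class TestStepwiseTune:
    def test_additive_objective_converges_to_enumeration(self):
        rng = np.random.default_rng(2)
        loci = [f"S{k + 1}_9" for k in range(8)]
        arch = fg.GeneticArchitecture(
            additive={s: float(rng.normal()) for s in loci})
        g1, v1 = fg.stepwise_tune(arch, ("QQ", "qq"))
        g2, v2 = fg.enumerate_optimum(arch, ("QQ", "qq"))
        assert g1 == g2 and np.isclose(v1, v2)

    def test_never_exceeds_enumeration(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            arch = _random_arch(rng, n_loci=5)
            _, v_enum = fg.enumerate_optimum(arch, ("QQ", "Qq", "qq"))
            _, v_tune = fg.stepwise_tune(arch, ("QQ", "Qq", "qq"))
            assert v_tune <= v_enum + 1e-12

    def test_optimum_is_a_fixed_point(self):
        rng = np.random.default_rng(3)
        arch = _random_arch(rng, n_loci=5)
        g_opt, v_opt = fg.enumerate_optimum(arch, ("QQ", "Qq", "qq"))
        g2, v2 = fg.stepwise_tune(arch, ("QQ", "Qq", "qq"),
                                  start_vector=g_opt)
        assert g2 == g_opt and v2 == v_opt

    def test_start_outside_allowed_codes_rejected(self):
        arch = fg.GeneticArchitecture(additive={"S1_1": 1.0})
        with pytest.raises(ValueError):
            fg.stepwise_tune(arch, ("QQ", "qq"), start_vector={"S1_1": "Qq"})


class TestBestExistingLine:
    def test_single_line_population(self):
        g = fg.simulate_nam_genotypes(1, 1, 3, 0.0, 0.0, seed=1)
        arch = fg.GeneticArchitecture(additive={g.snp_ids[0]: 1.0})
        best = fg.best_existing_line(g, arch)
        assert best["overall"][0] == g.line_ids[0]

    def test_planted_optimum_recovered(self):
        g = fg.simulate_nam_genotypes(5, 40, 4, 0.0, 0.0, seed=2)
        arch = fg.GeneticArchitecture(
            additive={s: 1.0 for s in g.snp_ids})
        g.codes[7, :] = 2  # plant the all-QQ optimum at line 7
        best = fg.best_existing_line(g, arch)
        assert best["overall"] == (g.line_ids[7], 4.0)

    def test_environment_sign_flip_changes_best_line(self):
        codes = np.array([[2], [0]], dtype=np.int8)
        g = fg.GenotypeMatrix(codes, ["L0", "L1"], ["F0", "F0"], ["S1_1"])
        arch = fg.GeneticArchitecture(
            additive={"S1_1": 0.0},
            gxe_loci={("S1_1", 1): {"ae": 1.0}, ("S1_1", 2): {"ae": -1.0}})
        best = fg.best_existing_line(g, arch, [1, 2])
        assert best[1][0] == "L0" and best[2][0] == "L1"


class TestBreedingTable:
    def test_additive_only_line_equals_hybrid(self):
        g = fg.simulate_nam_genotypes(2, 30, 2, 0.0, 0.0, seed=3)
        arch = fg.GeneticArchitecture(
            mu=5.0, additive={s: 1.0 for s in g.snp_ids})
        pred = fg.predict_breeding_table(arch, g, [1])
        t = pred.to_frame()
        assert np.isclose(t.loc["superior_line", "overall"],
                          t.loc["superior_hybrid", "overall"])
        assert "Qq" not in pred.superior_line_genotypes["overall"].values()

    def test_large_dd_effects_make_hybrid_strictly_better(self):
        g = fg.simulate_nam_genotypes(2, 30, 2, 0.1, 0.0, seed=4)
        i, j = g.snp_ids
        arch = fg.GeneticArchitecture(
            mu=0.0, additive={i: 0.2, j: 0.2},
            epistasis={(i, j): {"dd": 5.0}})
        pred = fg.predict_breeding_table(arch, g, [1])
        t = pred.to_frame()
        assert t.loc["superior_hybrid", "overall"] > \
            t.loc["superior_line", "overall"]

    def test_nestedness_invariant_on_homozygous_population(self):
        rng = np.random.default_rng(5)
        g = fg.simulate_nam_genotypes(5, 40, 5, 0.0, 0.0, seed=6)
        arch = fg.GeneticArchitecture(
            mu=0.0,
            additive={s: float(rng.normal()) for s in g.snp_ids},
            dominance={s: float(rng.normal()) for s in g.snp_ids})
        pred = fg.predict_breeding_table(arch, g, [1])
        t = pred.to_frame()
        for col in t.columns:
            assert t.loc["superior_hybrid", col] >= \
                t.loc["superior_line", col] - 1e-12
            assert t.loc["superior_line", col] >= \
                t.loc["best_line", col] - 1e-12

    def test_no_interactions_means_identical_env_columns(self):
        g = fg.simulate_nam_genotypes(2, 20, 2, 0.0, 0.0, seed=7)
        arch = fg.GeneticArchitecture(
            mu=1.0, additive={s: 0.5 for s in g.snp_ids})
        pred = fg.predict_breeding_table(arch, g, [1, 2])
        t = pred.to_frame().drop(index="mu")
        assert np.allclose(t["env1"].astype(float),
                           t["env2"].astype(float))

    def test_f1_row_is_all_heterozygote_value(self):
        g = fg.simulate_nam_genotypes(2, 10, 2, 0.1, 0.0, seed=8)
        arch = fg.GeneticArchitecture(
            mu=0.0, dominance={s: 1.5 for s in g.snp_ids})
        pred = fg.predict_breeding_table(arch, g, [1])
        assert pred.to_frame().loc["F1", "overall"] == 3.0

    def test_empty_effect_set_rejected(self):
        g = fg.simulate_nam_genotypes(1, 5, 2, 0.0, 0.0, seed=9)
        with pytest.raises(ValueError):
            fg.predict_breeding_table(fg.GeneticArchitecture(), g, [1])


class TestArchitectureFromModel:
    def test_roundtrip_from_noiseless_fit(self):
        g = fg.simulate_nam_genotypes(4, 50, 2, 0.1, 0.0, seed=10)
        i, j = g.snp_ids
        truth = fg.GeneticArchitecture(
            mu=4.0, additive={i: 1.0, j: -0.5}, dominance={i: 0.8, j: 0.0},
            residual_sd=0.0)
        pheno = fg.simulate_phenotypes(g, truth, 1, seed=11)
        dm = fg.build_design(g, pheno, gxe=False)
        m = fg.FullGeneticModel().fit(dm)
        arch_hat = fg.architecture_from_model(m)
        assert np.isclose(arch_hat.mu, 4.0)
        assert np.isclose(arch_hat.additive[i], 1.0)
        assert np.isclose(arch_hat.dominance[i], 0.8)

    def test_keep_terms_filters_effects(self):
        g = fg.simulate_nam_genotypes(4, 50, 2, 0.1, 0.0, seed=12)
        i, j = g.snp_ids
        truth = fg.GeneticArchitecture(mu=0.0, additive={i: 1.0, j: 0.5},
                                       residual_sd=0.1)
        pheno = fg.simulate_phenotypes(g, truth, 1, seed=13)
        dm = fg.build_design(g, pheno, gxe=False)
        m = fg.FullGeneticModel().fit(dm)
        arch_hat = fg.architecture_from_model(m, keep_terms=[f"a@{i}"])
        assert list(arch_hat.additive) == [i]
        assert not arch_hat.dominance
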