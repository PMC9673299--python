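"""Coefficient coding: the exact contrast tables, design assembly, and
population-structure cofactors."""

import numpy as np
import pandas as pd
import pytest

import fullgen as fg
from tests.conftest import make_pheno

# the canonical single-locus contrasts: QQ -> (1, 0), Qq -> (0, 1),
# qq -> (-1, 0)
LOCUS_TABLE = {"QQ": (1.0, 0.0), "Qq": (0.0, 1.0), "qq": (-1.0, 0.0)}

# all 9 ordered genotype pairs -> (x_AA, x_AD, x_DA, x_DD)
EPISTASIS_TABLE = {
    ("QQ", "QQ"): (1, 0, 0, 0), ("QQ", "Qq"): (0, 1, 0, 0),
    ("QQ", "qq"): (-1, 0, 0, 0),
    ("Qq", "QQ"): (0, 0, 1, 0), ("Qq", "Qq"): (0, 0, 0, 1),
    ("Qq", "qq"): (0, 0, -1, 0),
    ("qq", "QQ"): (-1, 0, 0, 0), ("qq", "Qq"): (0, -1, 0, 0),
    ("qq", "qq"): (1, 0, 0, 0),
}


class TestContrastTables:
    @pytest.mark.parametrize("code,expected", LOCUS_TABLE.items())
    def test_single_locus_contrasts(self, code, expected):
        assert fg.encode_locus(code) == expected

    @pytest.mark.parametrize("pair,expected", EPISTASIS_TABLE.items())
    def test_epistasis_contrasts_all_nine_pairs(self, pair, expected):
        got = fg.encode_epistasis(*pair)
        assert np.allclose(got, expected)

    def test_missing_code_gives_nan(self):
        xa, xd = fg.encode_locus("NN")
        assert np.isnan(xa) and np.isnan(xd)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            fg.encode_locus("XY")
        with pytest.raises(ValueError):
            fg.encode_epistasis("QQ", "ZZ")


def _design_fixture(seed=3, n_envs=2):
    geno = fg.simulate_nam_genotypes(2, 25, 4, het_rate=0.1,
                                     missing_rate=0.0, seed=seed)
    arch = fg.GeneticArchitecture(mu=0.0, residual_sd=1.0)
    pheno = fg.simulate_phenotypes(geno, arch, n_envs, seed=seed + 1)
    return geno, pheno


class TestBuildDesign:
    def test_shapes_one_locus_two_envs(self):
        geno, pheno = _design_fixture()
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:1])
        n = len(pheno)
        assert dm.fixed.shape == (n, 2)            # a@ and d@ columns
        assert dm.random["ae"].shape == (n, 2)     # one locus x two envs
        assert dm.env_block.shape == (n, 2)

    def test_constant_locus_codes_constant_columns(self):
        geno, pheno = _design_fixture()
        geno.codes[:, 0] = 2  # force all-QQ
        dm = fg.build_design(geno, pheno, loci=geno.snp_ids[:1])
        assert np.allclose(dm.fixed.iloc[:, 0], 1.0)
        assert np.allclose(dm.fixed.iloc[:, 1], 0.0)

    def test_interaction_columns_are_masked_contrasts(self):
        geno, pheno = _design_fixture(seed=9)
        snp = geno.snp_ids[0]
        dm = fg.build_design(geno, pheno, loci=[snp])
        xa = dm.fixed[f"a@{snp}"].to_numpy()
        for h in (1, 2):
            u = dm.random["ae"][f"ae@{snp}:{h}"].to_numpy()
            assert np.array_equal(u, np.where(dm.env == h, xa, 0.0))

    def test_epistasis_columns_are_products(self):
        geno, pheno = _design_fixture(seed=15)
        i, j = geno.snp_ids[:2]
        dm = fg.build_design(geno, pheno, loci=[i, j], pairs=[(i, j)])
        aa = dm.fixed[f"aa@{i}:{j}"].to_numpy()
        assert np.allclose(aa, dm.fixed[f"a@{i}"] * dm.fixed[f"a@{j}"])
        dd = dm.fixed[f"dd@{i}:{j}"].to_numpy()
        assert np.allclose(dd, dm.fixed[f"d@{i}"] * dm.fixed[f"d@{j}"])

    def test_family_mean_of_additive_contrast(self):
        geno, _ = _design_fixture(seed=21)
        fam = np.asarray(geno.family_ids)
        for f in np.unique(fam):
            block = geno.codes[fam == f]
            xa_mean = (block - 1.0).mean(axis=0)
            expected = (block == 2).mean(axis=0) - (block == 0).mean(axis=0)
            assert np.allclose(xa_mean, expected)

    def test_missing_call_imputed_with_family_mean(self):
        geno, pheno = _design_fixture(seed=27)
        snp = geno.snp_ids[0]
        geno.codes[0, 0] = -1
        fam0 = np.asarray(geno.family_ids) == geno.family_ids[0]
        fam0[0] = False
        expected = (geno.codes[fam0, 0] - 1.0).mean()
        dm = fg.build_design(geno, pheno, loci=[snp])
        rows = dm.lines == geno.line_ids[0]
        assert np.allclose(dm.fixed.loc[rows, f"a@{snp}"], expected)

    def test_unknown_phenotype_line_raises(self):
        geno, pheno = _design_fixture()
        bad = pheno.df.copy()
        bad.loc[0, "line"] = "ZZZ"
        with pytest.raises(KeyError):
            fg.build_design(geno, fg.PhenotypeTable(bad))

    def test_base_model_equals_adjusted_with_k0(self):
        geno, pheno = _design_fixture(seed=33)
        base = fg.build_design(geno, pheno)
        adj = fg.build_design(geno, pheno, n_pcs=3)
        assert base.cofactors.shape[1] == 0
        assert adj.cofactors.shape == (len(pheno), 3)
        pd.testing.assert_frame_equal(base.fixed, adj.fixed)
        pd.testing.assert_frame_equal(base.env_block, adj.env_block)
        for fam in base.random:
            pd.testing.assert_frame_equal(base.random[fam], adj.random[fam])


class TestPrincipalComponents:
    def test_pc1_separates_divergent_families(self):
        # two families fixed for opposite alleles at most SNPs
        rng = np.random.default_rng(0)
        n, m = 60, 40
        codes = np.zeros((2 * n, m), dtype=np.int8)
        codes[:n] = rng.choice([0, 2], size=(n, m), p=[0.9, 0.1])
        codes[n:] = rng.choice([0, 2], size=(n, m), p=[0.1, 0.9])
        geno = fg.GenotypeMatrix(
            codes, [f"Z001E{i:04d}" for i in range(n)]
            + [f"Z002E{i:04d}" for i in range(n)],
            ["Z001"] * n + ["Z002"] * n,
            [f"S1_{1000 + k}" for k in range(m)])
        pcs = fg.compute_pcs(geno, 2)
        label = np.r_[np.zeros(n), np.ones(n)]
        r = np.corrcoef(pcs["pc1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_k0_gives_empty_block_and_k_too_large_rejected(self, small_geno):
        assert fg.compute_pcs(small_geno, 0).shape[1] == 0
        with pytest.raises(ValueError):
            fg.compute_pcs(small_geno, small_geno.n_snps)

    def test_duplicated_lines_share_scores(self, small_geno):
        codes = np.vstack([small_geno.codes, small_geno.codes[:1]])
        geno = fg.GenotypeMatrix(
            codes, list(small_geno.line_ids) + ["Z099E0001"],
            list(small_geno.family_ids) + ["Z099"],
            list(small_geno.snp_ids))
        pcs = fg.compute_pcs(geno, 2)
        assert np.allclose(pcs.iloc[-1], pcs.iloc[0])

    def test_sign_convention_is_deterministic(self, small_geno):
        a = fg.compute_pcs(small_geno, 3)
        b = fg.compute_pcs(small_geno, 3)
        pd.testing.assert_frame_equal(a, b)


class TestGenotypeEncoder:
    def test_transformer_roundtrip(self):
        geno, pheno = _design_fixture()
        enc = fg.GenotypeEncoder(loci=geno.snp_ids[:2], n_pcs=2)
        dm = enc.fit(geno).transform(pheno)
        direct = fg.build_design(geno, pheno, loci=geno.snp_ids[:2], n_pcs=2)
        pd.testing.assert_frame_equal(dm.fixed, direct.fixed)
        assert enc.get_params()["n_pcs"] == 2
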