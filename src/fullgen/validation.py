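"""Calibration experiments for the association machinery.

These run the whole stack on simulated data with known truth and measure
its operating characteristics: the experiment-wise type-I error of the
permutation-thresholded Henderson-III scan under the null, and
parameter/heritability recovery of the Gibbs-refined mixed model under a
fully specified architecture.
"""

from __future__ import annotations

import numpy as np

from .assoc import FullGeneticModel, permutation_threshold
from .coding import build_design
from .datatypes import GeneticArchitecture
from .simdata import (make_architecture, realized_h2, simulate_nam_genotypes,
                      simulate_phenotypes)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(n)]


def experimentwise_type1_rate(n_datasets: int = 200, n_lines: int = 500,
                              n_envs: int = 2, n_snps: int = 50,
                              n_perm: int = 200, alpha: float = 0.05,
                              seed: int = 0, n_families: int = 25
                              ) -> dict:
    """Fraction of null datasets where any term beats its critical F.

    Each replicate simulates a population with every genetic effect zero
    (residual noise only), scans all candidate SNPs (main and
    gene-by-environment terms) with within-environment permutation
    thresholds at ``alpha``, and records whether anything is declared
    significant.  Under exchangeability the rejection fraction should not
    exceed ``alpha`` beyond Monte-Carlo error.
    """
    lines_per_family = max(n_lines // n_families, 1)
    rejections = 0
    for ds_seed in _spawn_seeds(seed, n_datasets):
        s_geno, s_pheno, s_perm = _spawn_seeds(ds_seed, 3)
        geno = simulate_nam_genotypes(n_families, lines_per_family, n_snps,
                                      het_rate=0.03, missing_rate=0.0,
                                      seed=s_geno)
        arch = GeneticArchitecture(mu=0.0, residual_sd=1.0)
        pheno = simulate_phenotypes(geno, arch, n_envs, seed=s_pheno)
        dm = build_design(geno, pheno)
        res = permutation_threshold(dm, n_perm=n_perm, alpha=alpha,
                                    seed=s_perm)
        rejections += int(res.any_significant)
    rate = rejections / n_datasets
    se = float(np.sqrt(alpha * (1 - alpha) / n_datasets))
    return {"rate": rate, "n_datasets": n_datasets, "alpha": alpha,
            "mc_se": se}


def parameter_recovery_experiment(seed: int = 0, n_lines: int = 2000,
                                  n_envs: int = 4, n_iter: int = 6000,
                                  burn_in: int = 1500, thin: int = 3
                                  ) -> dict:
    """Recovery of a 6-locus / 2-pair architecture with G x E on 2 loci.

    The reference population uses a heterozygote rate of 0.2 so that every
    coefficient class (including Qq x Qq cells behind the dd terms) is
    populated at this sample size; with NAM-level residual heterozygosity
    the dominance-related classes are empty at n = 2000 and those effects
    are unidentifiable by construction.  Returns the fraction of a/d/aa/
    dd/ae terms whose posterior mean lies within 3 posterior standard
    deviations of truth, and the largest absolute error (percent points)
    between estimated and realized component heritabilities.
    """
    s_geno, s_arch, s_pheno, s_gibbs = _spawn_seeds(seed, 4)
    lines_per_family = max(n_lines // 25, 1)
    geno = simulate_nam_genotypes(25, lines_per_family, 6, het_rate=0.2,
                                  missing_rate=0.0, seed=s_geno)
    targets = {"A": 0.15, "D": 0.05, "AA": 0.05, "DD": 0.05,
               "AE": 0.08, "DE": 0.03}
    arch = make_architecture(6, 2, targets, seed=s_arch, reference=geno,
                             n_envs=n_envs)
    gxe_loci = arch.loci[:2]
    arch = GeneticArchitecture(
        mu=arch.mu, additive=arch.additive, dominance=arch.dominance,
        epistasis=arch.epistasis, env_effects=arch.env_effects,
        env_sd=arch.env_sd,
        gxe_loci={k: v for k, v in arch.gxe_loci.items()
                  if k[0] in gxe_loci},
        gxe_pairs=arch.gxe_pairs, residual_sd=arch.residual_sd,
        trait=arch.trait)
    truth_h2 = realized_h2(geno, arch, n_envs)
    pheno = simulate_phenotypes(geno, arch, n_envs, seed=s_pheno)
    dm = build_design(geno, pheno, loci=arch.loci, pairs=arch.pairs)
    model = FullGeneticModel().fit(dm)
    post = model.gibbs(n_iter=n_iter, burn_in=burn_in, thin=thin,
                       seed=s_gibbs).set_index("term")

    true_vals: dict[str, float] = {}
    for s in arch.loci:
        true_vals[f"a@{s}"] = arch.additive.get(s, 0.0)
        true_vals[f"d@{s}"] = arch.dominance.get(s, 0.0)
    for (i, j), eff in arch.epistasis.items():
        true_vals[f"aa@{i}:{j}"] = eff.get("aa", 0.0)
        true_vals[f"dd@{i}:{j}"] = eff.get("dd", 0.0)
    for (s, h), eff in arch.gxe_loci.items():
        true_vals[f"ae@{s}:{h}"] = eff.get("ae", 0.0)

    n_cov = n_tot = 0
    misses = []
    for term, truth in true_vals.items():
        if term not in post.index:
            continue
        est = float(post.loc[term, "estimate"])
        sd = float(post.loc[term, "sd"])
        n_tot += 1
        if abs(est - truth) <= 3 * max(sd, 1e-12):
            n_cov += 1
        else:
            misses.append(term)
    herit = model.heritability()
    h2_err = {k: herit.components[k] - 100 * truth_h2[k]
              for k in herit.components}
    return {"coverage": n_cov / n_tot, "n_terms": n_tot, "misses": misses,
            "h2_max_abs_err": max(abs(v) for v in h2_err.values()),
            "h2_err": h2_err,
            "h2_estimated": herit.components,
            "h2_true": {k: 100 * v for k, v in truth_h2.items()}}
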