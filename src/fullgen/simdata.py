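"""NAM-like genotype and multi-environment phenotype simulation.

The generator emulates the structure of a nested association mapping
population: ~25 half-sib recombinant-inbred families sharing the common
parent B73.  Within a family a SNP either segregates (the founder carried
the non-B73 allele) and the inbred lines are QQ or qq with probability 1/2
each, or is fixed qq (founder identical to B73).  Residual heterozygosity
left by selfing is injected as a per-cell Bernoulli overwrite.  Loci are
drawn independently (no linkage map): linkage disequilibrium is irrelevant
to every downstream formula this package implements, and is a documented
non-goal.

Phenotypes follow the full genetic model: for line k in environment h,

    y_hk = mu + sum_i a_i x_Aik + sum_i d_i x_Dik
         + sum_{i<j} (aa, ad, da, dd) epistasis terms
         + e_h + environment-specific (ae, de, aae, ade, dae, dde) terms
         + eps_hk,   eps ~ N(0, residual_sd^2)
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import _contrast_matrices, _impute_by_family
from .datatypes import (GeneticArchitecture, GenotypeMatrix, PhenotypeTable,
                        HET, MISSING, QQ_HOM_ALT, QQ_HOM_B73)

H2_COMPONENTS = ("A", "D", "AA", "AD", "DA", "DD",
                 "AE", "DE", "AAE", "ADE", "DAE", "DDE")


def _snp_ids(n_snps: int) -> list[str]:
    """Synthetic S<chrom>_<pos> ids spread over the 10 maize chromosomes."""
    ids = []
    for k in range(n_snps):
        chrom = 1 + k % 10
        pos = 10_000 * (1 + k // 10)
        ids.append(f"S{chrom}_{pos}")
    return ids


def simulate_nam_genotypes(n_families: int, lines_per_family: int,
                           n_snps: int, het_rate: float = 0.03,
                           missing_rate: float = 0.0, seed: int = 0,
                           segregating_fraction: float = 0.5
                           ) -> GenotypeMatrix:
    """Simulate a half-sib RIL population with B73 as common parent.

    ``segregating_fraction`` is the chance that a given founder carries the
    non-B73 allele at a given SNP; non-segregating (family, SNP) cells are
    fixed qq.  Among homozygotes at a segregating SNP the expected non-B73
    allele frequency is 1/2 within each family.
    """
    if n_families < 1 or lines_per_family < 1 or n_snps < 1:
        raise ValueError("all counts must be >= 1")
    if not (0 <= het_rate < 1) or not (0 <= missing_rate < 1):
        raise ValueError("het_rate and missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_lines = n_families * lines_per_family
    codes = np.empty((n_lines, n_snps), dtype=np.int8)
    line_ids, family_ids = [], []
    for f in range(n_families):
        fam = f"Z{f + 1:03d}"
        seg = rng.random(n_snps) < segregating_fraction
        homs = rng.choice(np.array([QQ_HOM_B73, QQ_HOM_ALT], dtype=np.int8),
                          size=(lines_per_family, n_snps))
        block = np.where(seg[None, :], homs, np.int8(QQ_HOM_B73))
        rows = slice(f * lines_per_family, (f + 1) * lines_per_family)
        codes[rows] = block
        line_ids += [f"{fam}E{k + 1:04d}" for k in range(lines_per_family)]
        family_ids += [fam] * lines_per_family
    if het_rate > 0:
        codes[rng.random(codes.shape) < het_rate] = HET
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    return GenotypeMatrix(codes, line_ids, family_ids, _snp_ids(n_snps))


def _line_contrasts(geno: GenotypeMatrix, loci: Sequence[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    sub = geno.subset_snps(list(loci))
    xa, xd = _contrast_matrices(sub.codes)
    xa = _impute_by_family(xa, sub.family_ids)
    xd = _impute_by_family(xd, sub.family_ids)
    return xa, xd


def genetic_values(geno: GenotypeMatrix, arch: GeneticArchitecture
                   ) -> np.ndarray:
    """Per-line main + epistasis genetic value (no mu, env or noise)."""
    loci = arch.loci
    for s in loci:
        geno.snp_index(s)  # KeyError if the architecture references unknowns
    xa, xd = _line_contrasts(geno, loci)
    col = {s: k for k, s in enumerate(loci)}
    g = np.zeros(geno.n_lines)
    for s, a in arch.additive.items():
        g += a * xa[:, col[s]]
    for s, d in arch.dominance.items():
        g += d * xd[:, col[s]]
    for (i, j), eff in arch.epistasis.items():
        ai, di = xa[:, col[i]], xd[:, col[i]]
        aj, dj = xa[:, col[j]], xd[:, col[j]]
        g += (eff.get("aa", 0.0) * ai * aj + eff.get("ad", 0.0) * ai * dj
              + eff.get("da", 0.0) * di * aj + eff.get("dd", 0.0) * di * dj)
    return g


def gxe_values(geno: GenotypeMatrix, arch: GeneticArchitecture, env: int
               ) -> np.ndarray:
    """Per-line environment-specific interaction value for environment env."""
    loci = arch.loci
    xa, xd = _line_contrasts(geno, loci)
    col = {s: k for k, s in enumerate(loci)}
    g = np.zeros(geno.n_lines)
    for (s, h), eff in arch.gxe_loci.items():
        if h != env:
            continue
        g += (eff.get("ae", 0.0) * xa[:, col[s]]
              + eff.get("de", 0.0) * xd[:, col[s]])
    for (i, j, h), eff in arch.gxe_pairs.items():
        if h != env:
            continue
        ai, di = xa[:, col[i]], xd[:, col[i]]
        aj, dj = xa[:, col[j]], xd[:, col[j]]
        g += (eff.get("aae", 0.0) * ai * aj + eff.get("ade", 0.0) * ai * dj
              + eff.get("dae", 0.0) * di * aj + eff.get("dde", 0.0) * di * dj)
    return g


def simulate_phenotypes(geno: GenotypeMatrix, arch: GeneticArchitecture,
                        n_envs: int, seed: int = 0) -> PhenotypeTable:
    """Phenotypes for every line in every environment under the full model."""
    if n_envs < 1:
        raise ValueError("n_envs must be >= 1")
    rng = np.random.default_rng(seed)
    g = genetic_values(geno, arch)
    if arch.env_effects is not None:
        missing_envs = [h for h in range(1, n_envs + 1)
                        if h not in arch.env_effects]
        if missing_envs:
            raise ValueError(f"env_effects missing environments "
                             f"{missing_envs}")
        e = np.array([arch.env_effects[h] for h in range(1, n_envs + 1)])
    else:
        e = rng.normal(0.0, arch.env_sd, size=n_envs)
    frames = []
    for h in range(1, n_envs + 1):
        ge = gxe_values(geno, arch, h)
        eps = rng.normal(0.0, arch.residual_sd, size=geno.n_lines)
        frames.append(pd.DataFrame({
            "line": geno.line_ids, "family": geno.family_ids, "env": h,
            "trait": arch.trait, "value": arch.mu + g + e[h - 1] + ge + eps}))
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def make_architecture(n_loci: int, n_pairs: int,
                      target_h2: Mapping[str, float], seed: int = 0,
                      reference: GenotypeMatrix | None = None,
                      n_envs: int = 4, residual_sd: float = 1.0,
                      mu: float = 0.0, trait: str = "trait"
                      ) -> GeneticArchitecture:
    """Effect set whose realized variance shares hit ``target_h2``.

    Raw effects are drawn from N(0, 1) and each component block is rescaled
    so that the variance of its contribution across the records of a
    reference population (simulated here if not supplied) equals exactly
    ``target * total_variance`` with ``total = residual_sd^2 / (1 - sum)``.
    On an independently simulated population the realized shares then match
    the targets up to Monte-Carlo error.
    """
    bad = [k for k in target_h2 if k not in H2_COMPONENTS]
    if bad:
        raise ValueError(f"unknown heritability components: {bad}")
    t = {k: float(target_h2.get(k, 0.0)) for k in H2_COMPONENTS}
    if any(v < 0 for v in t.values()):
        raise ValueError("component fractions must be >= 0")
    if sum(t.values()) >= 1:
        raise ValueError(f"component fractions sum to {sum(t.values()):.3f}"
                         " >= 1: infeasible")
    if n_loci < 1 or n_pairs < 0:
        raise ValueError("n_loci must be >= 1 and n_pairs >= 0")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = simulate_nam_genotypes(
            25, 200, n_snps=n_loci, het_rate=0.03, missing_rate=0.0,
            seed=int(rng.integers(2 ** 31)))
    if reference.n_snps < n_loci:
        raise ValueError("reference population has fewer SNPs than n_loci")
    loci = list(reference.snp_ids[:n_loci])
    all_pairs = list(itertools.combinations(loci, 2))
    if n_pairs > len(all_pairs):
        raise ValueError("n_pairs exceeds available locus pairs")
    # prefer disjoint pairs so pair components stay near-orthogonal
    disjoint = [(loci[2 * k], loci[2 * k + 1])
                for k in range(min(n_pairs, n_loci // 2))]
    pairs = disjoint + [p for p in all_pairs if p not in disjoint]
    pairs = pairs[:n_pairs]

    total_var = residual_sd ** 2 / (1.0 - sum(t.values()))
    xa, xd = _line_contrasts(reference, loci)
    col = {s: k for k, s in enumerate(loci)}
    # balanced records: every line in every environment
    n_lines = reference.n_lines
    env_rec = np.repeat(np.arange(1, n_envs + 1), n_lines)
    ridx = np.tile(np.arange(n_lines), n_envs)

    def scaled(raw: np.ndarray, contrib: np.ndarray, target: float,
               label: str) -> np.ndarray:
        v = contrib.var()
        if v <= 0:
            raise ValueError(f"reference population carries no variance for "
                             f"component {label}")
        return raw * np.sqrt(target * total_var / v)

    arch = GeneticArchitecture(mu=mu, residual_sd=residual_sd, trait=trait)
    pair_basis = {}
    for (i, j) in pairs:
        ai, di = xa[:, col[i]], xd[:, col[i]]
        aj, dj = xa[:, col[j]], xd[:, col[j]]
        pair_basis[(i, j)] = {"aa": ai * aj, "ad": ai * dj,
                              "da": di * aj, "dd": di * dj}

    # --- main and epistasis components (per-line, identical across envs) ---
    line_basis = {"A": xa, "D": xd}
    for comp, kind in (("A", "a"), ("D", "d")):
        if t[comp] > 0:
            raw = rng.normal(size=n_loci)
            contrib = (line_basis[comp] @ raw)[ridx]
            eff = scaled(raw, contrib, t[comp], comp)
            target_map = arch.additive if comp == "A" else arch.dominance
            for s, v in zip(loci, eff):
                target_map[s] = float(v)
    for comp, kind in (("AA", "aa"), ("AD", "ad"), ("DA", "da"),
                       ("DD", "dd")):
        if t[comp] > 0:
            if not pairs:
                raise ValueError(f"component {comp} requested with n_pairs=0")
            raw = rng.normal(size=len(pairs))
            contrib = sum(w * pair_basis[p][kind]
                          for w, p in zip(raw, pairs))[ridx]
            eff = scaled(raw, contrib, t[comp], comp)
            for p, v in zip(pairs, eff):
                arch.epistasis.setdefault(p, {})[kind] = float(v)

    # --- environment-interaction components (effects vary with h) ----------
    def gxe_block(basis_cols: list[np.ndarray], target: float, label: str):
        """Draw per-(unit, env) effects, centered over envs per unit."""
        raw = rng.normal(size=(len(basis_cols), n_envs))
        raw -= raw.mean(axis=1, keepdims=True)
        contrib = np.zeros(len(ridx))
        for u, basis in enumerate(basis_cols):
            contrib += raw[u, env_rec - 1] * basis[ridx]
        v = contrib.var()
        if v <= 0:
            raise ValueError(f"no variance available for component {label}")
        return raw * np.sqrt(target * total_var / v)

    if t["AE"] > 0:
        eff = gxe_block([xa[:, col[s]] for s in loci], t["AE"], "AE")
        for k, s in enumerate(loci):
            for h in range(1, n_envs + 1):
                arch.gxe_loci.setdefault((s, h), {})["ae"] = float(eff[k, h - 1])
    if t["DE"] > 0:
        eff = gxe_block([xd[:, col[s]] for s in loci], t["DE"], "DE")
        for k, s in enumerate(loci):
            for h in range(1, n_envs + 1):
                arch.gxe_loci.setdefault((s, h), {})["de"] = float(eff[k, h - 1])
    for comp, kind in (("AAE", "aa"), ("ADE", "ad"), ("DAE", "da"),
                       ("DDE", "dd")):
        if t[comp] > 0:
            if not pairs:
                raise ValueError(f"component {comp} requested with n_pairs=0")
            eff = gxe_block([pair_basis[p][kind] for p in pairs], t[comp],
                            comp)
            key = kind + "e"
            for k, (i, j) in enumerate(pairs):
                for h in range(1, n_envs + 1):
                    arch.gxe_pairs.setdefault((i, j, h), {})[key] = \
                        float(eff[k, h - 1])
    # make sure every pair with interaction effects is a declared pair
    for (i, j, h) in list(arch.gxe_pairs):
        arch.epistasis.setdefault((i, j), {})
    return GeneticArchitecture(
        mu=arch.mu, additive=arch.additive, dominance=arch.dominance,
        epistasis=arch.epistasis, env_effects=None, env_sd=0.0,
        gxe_loci=arch.gxe_loci, gxe_pairs=arch.gxe_pairs,
        residual_sd=residual_sd, trait=trait)


def realized_h2(geno: GenotypeMatrix, arch: GeneticArchitecture,
                n_envs: int) -> dict[str, float]:
    """Realized variance share of every component on a balanced layout.

    The share of a component is the variance, across line x environment
    records, of that component's contribution alone, divided by the total
    (sum of component variances plus residual).  Used as the independent
    oracle for effect-size calibration and parameter-recovery tests.
    """
    xa, xd = _line_contrasts(geno, arch.loci)
    col = {s: k for k, s in enumerate(arch.loci)}
    n_lines = geno.n_lines
    env_rec = np.repeat(np.arange(1, n_envs + 1), n_lines)
    ridx = np.tile(np.arange(n_lines), n_envs)

    contribs: dict[str, np.ndarray] = {
        k: np.zeros(len(ridx)) for k in H2_COMPONENTS}
    for s, a in arch.additive.items():
        contribs["A"] += a * xa[ridx, col[s]]
    for s, d in arch.dominance.items():
        contribs["D"] += d * xd[ridx, col[s]]
    for (i, j), eff in arch.epistasis.items():
        basis = {"AA": xa[:, col[i]] * xa[:, col[j]],
                 "AD": xa[:, col[i]] * xd[:, col[j]],
                 "DA": xd[:, col[i]] * xa[:, col[j]],
                 "DD": xd[:, col[i]] * xd[:, col[j]]}
        for comp, kind in (("AA", "aa"), ("AD", "ad"), ("DA", "da"),
                           ("DD", "dd")):
            contribs[comp] += eff.get(kind, 0.0) * basis[comp][ridx]
    for (s, h), eff in arch.gxe_loci.items():
        mask = env_rec == h
        contribs["AE"][mask] += eff.get("ae", 0.0) * xa[ridx[mask], col[s]]
        contribs["DE"][mask] += eff.get("de", 0.0) * xd[ridx[mask], col[s]]
    for (i, j, h), eff in arch.gxe_pairs.items():
        mask = env_rec == h
        ai, di = xa[:, col[i]], xd[:, col[i]]
        aj, dj = xa[:, col[j]], xd[:, col[j]]
        basis = {"AAE": ("aae", ai * aj), "ADE": ("ade", ai * dj),
                 "DAE": ("dae", di * aj), "DDE": ("dde", di * dj)}
        for comp, (kind, b) in basis.items():
            contribs[comp][mask] += eff.get(kind, 0.0) * b[ridx[mask]]

    comp_var = {k: float(v.var()) for k, v in contribs.items()}
    total = sum(comp_var.values()) + arch.residual_sd ** 2
    return {k: v / total for k, v in comp_var.items()}
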