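"""Config-driven orchestration of the full analysis pipeline.

Stages run in order: data (simulate or ingest) -> QC -> prescreen ->
association (permutation-thresholded Henderson-III scan, then REML + Gibbs
on the candidate model) -> heritability -> breeding.  Every output table
carries the config hash and seed in a comment header; deterministic stages
are bit-identical under a fixed config.

A single run-level seed fans out to the stochastic stages through
``numpy.random.SeedSequence.spawn`` in a fixed order (simulation,
prescreen, permutation, Gibbs), so per-stage seeds are reproducible and
independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, breed, io, prescreen, qc, simdata
from .coding import build_design
from .datatypes import GeneticArchitecture, GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)

STAGES = ("data", "qc", "prescreen", "scan", "herit", "breed")

FIXTURES = ("null", "additive", "epistatic", "gxe", "table1-like")


def make_fixture(name: str, seed: int = 0, n_families: int = 25,
                 lines_per_family: int = 20, n_snps: int = 50,
                 n_envs: int = 2
                 ) -> tuple[GenotypeMatrix, PhenotypeTable,
                            GeneticArchitecture]:
    """Seeded demo dataset (genotypes, phenotypes, true architecture).

    ``null``        every genetic effect zero, pure residual noise;
    ``additive``    five additive loci at moderate heritability;
    ``epistatic``   additive plus dominance-by-dominance pairs;
    ``gxe``         additive-by-environment effects with opposite signs in
                    two environments (location-flip pattern);
    ``table1-like`` component profile shaped like a strongly dominant /
                    epistatic trait (large DD, moderate A and DAE shares).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    ss = np.random.SeedSequence(seed)
    s_geno, s_arch, s_pheno = (int(s.generate_state(1)[0] % 2 ** 31)
                               for s in ss.spawn(3))
    geno = simdata.simulate_nam_genotypes(
        n_families, lines_per_family, n_snps, het_rate=0.03,
        missing_rate=0.0, seed=s_geno)
    if name == "null":
        arch = GeneticArchitecture(mu=10.0, residual_sd=1.0)
    elif name == "additive":
        arch = simdata.make_architecture(
            5, 0, {"A": 0.3}, seed=s_arch, reference=geno, n_envs=n_envs)
        arch.mu = 10.0
    elif name == "epistatic":
        arch = simdata.make_architecture(
            6, 2, {"A": 0.15, "DD": 0.15}, seed=s_arch, reference=geno,
            n_envs=n_envs)
        arch.mu = 10.0
    elif name == "gxe":
        loci = geno.snp_ids[:2]
        arch = GeneticArchitecture(
            mu=10.0, additive={loci[0]: 0.5, loci[1]: 0.0},
            gxe_loci={(loci[0], 1): {"ae": 1.5}, (loci[0], 2): {"ae": -1.5},
                      (loci[1], 1): {"ae": -1.0}, (loci[1], 2): {"ae": 1.0}},
            residual_sd=1.0)
    else:  # table1-like: Row-Number-shaped component profile
        targets = {"A": 0.098, "D": 0.087, "AA": 0.006, "AD": 0.016,
                   "DA": 0.075, "DD": 0.238, "AE": 0.027, "DE": 0.012,
                   "DAE": 0.066}
        arch = simdata.make_architecture(
            6, 2, targets, seed=s_arch, reference=geno, n_envs=max(n_envs, 2))
        arch.mu = 15.0
    pheno = simdata.simulate_phenotypes(geno, arch, n_envs, seed=s_pheno)
    return geno, pheno, arch


@dataclass
class RunConfig:
    """Declarative run configuration; defaults mirror the study settings
    (MAF 0.05, call rate 0.90, alpha 0.05, 2000 permutations, 20000 Gibbs
    iterations)."""

    seed: int
    # input: either files or a simulation spec
    genotypes: str | None = None
    genotype_format: str = "hapmap"
    phenotypes: str | None = None
    trait: str | None = None
    simulate: dict | None = None
    # QC thresholds
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    iqr_k: float = 1.5
    resid_k: float = 3.0
    # prescreen
    dims: tuple = (1, 2)
    top_k: int = 10
    n_folds: int = 5
    n_1d_survivors: int = 20
    # model
    n_pcs: int = 0
    n_perm: int = 2000
    alpha: float = 0.05
    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 5
    # breeding
    max_enum_loci: int = 15

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0 <= self.call_rate_min <= 1):
            raise ValueError("call_rate_min must lie in [0, 1]")
        if self.iqr_k < 0 or self.resid_k < 0:
            raise ValueError("outlier multipliers must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha={self.alpha} must lie in (0, 1]")
        if self.n_perm < 1 or self.n_iter <= self.burn_in:
            raise ValueError("invalid permutation / Gibbs iteration counts")
        if self.simulate is None and (self.genotypes is None
                                      or self.phenotypes is None):
            raise ValueError("provide input files or a simulation spec")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, outdir, until: str = "breed") -> dict:
    """Run the pipeline up to (and including) stage ``until``.

    Returns a dict of in-memory stage results; tables are written as TSV
    under ``outdir``.
    """
    config.validate()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    root = logging.getLogger("fullgen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        ss = np.random.SeedSequence(config.seed)
        seeds = {k: int(s.generate_state(1)[0] % 2 ** 31) for k, s in
                 zip(("sim", "prescreen", "perm", "gibbs"), ss.spawn(4))}
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        # -- data ------------------------------------------------------
        stage_limit = STAGES.index(until)
        if config.simulate is not None:
            spec = dict(config.simulate)
            fixture = spec.pop("fixture", "additive")
            spec.setdefault("seed", seeds["sim"])
            geno, pheno, truth = make_fixture(fixture, **spec)
            results["truth"] = truth
        else:
            geno = io.read_genotypes(config.genotypes,
                                     format=config.genotype_format)
            pheno = io.read_phenotypes(config.phenotypes)
        if config.trait is not None:
            pheno = pheno.for_trait(config.trait)
        if len(pheno.traits) != 1:
            raise ValueError("select a single trait via the config")
        log.info("data: %d lines, %d SNPs, %d records", geno.n_lines,
                 geno.n_snps, len(pheno))
        results["geno"], results["pheno"] = geno, pheno
        if stage_limit < 1:
            return results

        # -- QC --------------------------------------------------------
        geno, snp_report = qc.filter_snps(geno, config.maf_min,
                                          config.call_rate_min)
        pheno, iqr_report = qc.remove_phenotype_outliers_iqr(pheno,
                                                             config.iqr_k)
        pheno, resid_report = qc.remove_residual_outliers(pheno,
                                                          config.resid_k)
        qc_frame = pd.concat([
            snp_report.to_frame().assign(step="snp_filter"),
            iqr_report.to_frame().assign(step="iqr"),
            resid_report.to_frame().assign(step="residual")])
        _write_table(qc_frame, outdir / "qc_report.tsv", config)
        results["geno"], results["pheno"] = geno, pheno
        results["qc"] = (snp_report, iqr_report, resid_report)
        if stage_limit < 2:
            return results

        # -- prescreen -------------------------------------------------
        cand = prescreen.gmdr_scan(
            pheno, geno, dims=config.dims, top_k=config.top_k,
            seed=seeds["prescreen"], n_folds=config.n_folds,
            n_1d_survivors=config.n_1d_survivors)
        cand_frames = [f for f in (cand.loci.assign(dim=1),
                                   cand.pairs.assign(dim=2),
                                   cand.triples.assign(dim=3))
                       if len(f)]
        _write_table(pd.concat(cand_frames, ignore_index=True)
                     if cand_frames else cand.loci.assign(dim=1),
                     outdir / "candidates.tsv", config)
        results["candidates"] = cand
        if stage_limit < 3:
            return results

        # -- association scan ------------------------------------------
        dm = build_design(geno, pheno, loci=cand.candidate_loci,
                          pairs=cand.candidate_pairs, n_pcs=config.n_pcs)
        perm = assoc.permutation_threshold(
            dm, n_perm=config.n_perm, alpha=config.alpha,
            seed=seeds["perm"])
        model = assoc.FullGeneticModel().fit(dm)
        posterior = model.gibbs(n_iter=config.n_iter,
                                burn_in=config.burn_in, thin=config.thin,
                                seed=seeds["gibbs"])
        effects = posterior.merge(
            perm.table[["term", "F", "p", "p_ew", "significant"]],
            on="term", how="left")
        effects["neg_log10_p"] = -np.log10(effects["p"].clip(1e-300))
        effects["highly_significant"] = effects["neg_log10_p"] > 5
        _write_table(effects, outdir / "effects.tsv", config)
        _write_table(model.per_env_effects(), outdir / "per_env_effects.tsv",
                     config, index=True)
        results.update(dm=dm, model=model, perm=perm, effects=effects)
        if stage_limit < 4:
            return results

        # -- heritability ----------------------------------------------
        trait = pheno.traits[0]
        herit = model.heritability(trait=trait)
        _write_table(herit.to_frame(), outdir / "heritability.tsv", config,
                     index=True)
        results["heritability"] = herit
        if stage_limit < 5:
            return results

        # -- breeding ---------------------------------------------------
        sig_terms = perm.significant_terms()
        if not sig_terms:
            log.info("breed: no experiment-wise significant terms; "
                     "skipping breeding prediction")
            return results
        arch_hat = breed.architecture_from_model(model, keep_terms=sig_terms)
        if not arch_hat.loci:
            log.info("breed: significant set carries no genetic loci")
            return results
        pred = breed.predict_breeding_table(
            arch_hat, geno, env_list=pheno.envs,
            max_enum_loci=config.max_enum_loci)
        _write_table(pred.to_frame(), outdir / "breeding.tsv", config,
                     index=True)
        sl = pd.DataFrame(pred.superior_line_genotypes)
        sh = pd.DataFrame(pred.superior_hybrid_genotypes)
        _write_table(pd.concat([sl.add_prefix("SL_"), sh.add_prefix("SH_")],
                               axis=1),
                     outdir / "superior_genotypes.tsv", config, index=True)
        results["breeding"] = pred
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
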