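"""Quality control for genotypes and phenotypes.

Filtering rules follow the strict-inequality convention throughout: a SNP
is discarded when MAF < ``maf_min`` or call rate < ``call_rate_min`` (the
boundary value is kept); a phenotype record is removed when it lies
strictly outside the IQR fences or when its standardized residual strictly
exceeds ``k``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeTable, QCReport

log = logging.getLogger(__name__)


def filter_snps(geno: GenotypeMatrix, maf_min: float = 0.05,
                call_rate_min: float = 0.90
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with MAF < maf_min or call rate < call_rate_min.

    MAF counts the heterozygote as one copy of each allele.  An empty
    result is allowed.
    """
    if geno.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    maf = geno.maf()
    cr = geno.call_rate()
    fail_maf = maf < maf_min
    fail_cr = cr < call_rate_min
    keep = ~(fail_maf | fail_cr)
    reasons = np.where(fail_maf, "maf", "call_rate")
    removed = pd.DataFrame({
        "snp": [s for s, k in zip(geno.snp_ids, keep) if not k],
        "reason": [r for r, k in zip(reasons, keep) if not k]})
    kept_ids = [s for s, k in zip(geno.snp_ids, keep) if k]
    out = GenotypeMatrix(geno.codes[:, keep], list(geno.line_ids),
                         list(geno.family_ids), kept_ids)
    report = QCReport(n_snps_in=geno.n_snps, n_snps_out=out.n_snps,
                      removed_snps=removed)
    return out, report


def _group_iter(pheno: PhenotypeTable):
    for (trait, env), idx in pheno.df.groupby(["trait", "env"]).groups.items():
        yield trait, env, np.asarray(idx)


def remove_phenotype_outliers_iqr(pheno: PhenotypeTable, k: float = 1.5
                                  ) -> tuple[PhenotypeTable, QCReport]:
    """Remove values outside [Q1 - k*IQR, Q3 + k*IQR] per trait x environment.

    Quartiles use linear interpolation between order statistics (the numpy
    default).  Groups with fewer than 4 values are skipped with a warning.
    """
    df = pheno.df
    drop = np.zeros(len(df), dtype=bool)
    for trait, env, idx in _group_iter(pheno):
        vals = df.loc[idx, "value"].to_numpy()
        if len(vals) < 4:
            log.warning("IQR filter: group (%s, env %s) has %d < 4 values; "
                        "skipped", trait, env, len(vals))
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        drop[df.index.get_indexer(idx)] = (vals < lo) | (vals > hi)
    removed = df[drop].copy()
    removed["reason"] = "iqr"
    out = PhenotypeTable(df[~drop])
    report = QCReport(n_records_in=len(df), n_records_out=len(out),
                      removed_records=removed)
    return out, report


def remove_residual_outliers(pheno: PhenotypeTable, k: float = 3.0
                             ) -> tuple[PhenotypeTable, QCReport]:
    """Remove records with |eps - mu_eps| / sigma_eps > k.

    Residuals come from the simplest defensible baseline: the trait x
    environment mean.  mu_eps and sigma_eps are the pooled moments of those
    residuals per trait.  sigma_eps = 0 removes nothing (warning).
    """
    df = pheno.df
    resid = np.full(len(df), np.nan)
    for trait, env, idx in _group_iter(pheno):
        pos = df.index.get_indexer(idx)
        vals = df.loc[idx, "value"].to_numpy()
        resid[pos] = vals - vals.mean()
    drop = np.zeros(len(df), dtype=bool)
    for trait in pheno.traits:
        mask = (df["trait"] == trait).to_numpy()
        eps = resid[mask]
        mu, sigma = eps.mean(), eps.std()
        if sigma == 0:
            log.warning("residual filter: sigma_eps = 0 for trait %s; "
                        "nothing removed", trait)
            continue
        drop[mask] = np.abs(eps - mu) / sigma > k
    removed = df[drop].copy()
    removed["reason"] = "residual"
    out = PhenotypeTable(df[~drop])
    report = QCReport(n_records_in=len(df), n_records_out=len(out),
                      removed_records=removed)
    return out, report
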