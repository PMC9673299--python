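"""Fixed-effect coefficient columns and random-effect incidence blocks.

The full genetic model codes each biallelic locus with an additive contrast
``x_A`` (1 for QQ, 0 for Qq, -1 for qq; Q = non-B73 allele) and a dominance
indicator ``x_D`` (1 for Qq, 0 otherwise).  Digenic epistasis coefficients
are the products of the constituent contrasts, which reproduces the
conventional table: ``x_AA`` is 1 for QQxQQ and qqxqq, -1 for QQxqq and
qqxQQ, 0 otherwise; ``x_AD`` is 1 for QQxQq and -1 for qqxQq; ``x_DA``
mirrors it; ``x_DD`` is 1 only for QqxQq.

Environment-interaction incidence columns ``u_*`` equal the corresponding
fixed coefficient on records belonging to that environment and 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (GenotypeMatrix, PhenotypeTable, MISSING,
                        STR_TO_CODE)

FIXED_FAMILIES = ("a", "d", "aa", "ad", "da", "dd")
RANDOM_FAMILIES = ("ae", "de", "aae", "ade", "dae", "dde")
MAIN_FAMILY = ("a", "d")
EPISTASIS_FAMILY = ("aa", "ad", "da", "dd")


def _as_code(code) -> int:
    if isinstance(code, str):
        if code not in STR_TO_CODE:
            raise ValueError(f"unknown genotype code {code!r}")
        return STR_TO_CODE[code]
    code = int(code)
    if code not in (-1, 0, 1, 2):
        raise ValueError(f"unknown genotype code {code!r}")
    return code


def encode_locus(code) -> tuple[float, float]:
    """(x_A, x_D) for one genotype code; NaNs for a missing call."""
    c = _as_code(code)
    if c == MISSING:
        return (np.nan, np.nan)
    return (float(c - 1), float(c == 1))


def encode_epistasis(code_i, code_j) -> tuple[float, float, float, float]:
    """(x_AA, x_AD, x_DA, x_DD) for a pair of genotype codes."""
    xa_i, xd_i = encode_locus(code_i)
    xa_j, xd_j = encode_locus(code_j)
    return (xa_i * xa_j, xa_i * xd_j, xd_i * xa_j, xd_i * xd_j)


def _contrast_matrices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized x_A / x_D with NaN at missing calls."""
    xa = (codes - 1).astype(float)
    xd = (codes == 1).astype(float)
    miss = codes == MISSING
    xa[miss] = np.nan
    xd[miss] = np.nan
    return xa, xd


def _impute_by_family(mat: np.ndarray, family_ids: Sequence[str]) -> np.ndarray:
    """Replace NaNs by the within-family column mean (column mean fallback).

    Keeps every phenotype record in the design; a post-QC missing call is
    rare, so the mean coefficient is a neutral, variance-preserving choice.
    """
    out = mat.copy()
    fam = np.asarray(family_ids)
    for f in np.unique(fam):
        rows = fam == f
        block = out[rows]
        nan_cols = np.isnan(block).any(axis=0)
        for j in np.flatnonzero(nan_cols):
            col = block[:, j]
            m = np.nanmean(col) if not np.all(np.isnan(col)) else np.nan
            col[np.isnan(col)] = m
            block[:, j] = col
        out[rows] = block
    # families entirely missing at a locus: overall column mean, then 0
    nan_cols = np.isnan(out).any(axis=0)
    for j in np.flatnonzero(nan_cols):
        col = out[:, j]
        m = np.nanmean(col) if not np.all(np.isnan(col)) else 0.0
        col[np.isnan(col)] = m
        out[:, j] = col
    return out


def compute_pcs(geno: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal component scores of the centered additive contrasts.

    Deterministic up to sign; the sign is fixed by making the
    largest-magnitude SNP loading of each component positive.
    """
    if k == 0:
        return pd.DataFrame(index=geno.line_ids)
    if k < 0 or k >= min(geno.n_lines, geno.n_snps):
        raise ValueError(f"k={k} must satisfy 0 <= k < min(lines, SNPs)")
    xa, _ = _contrast_matrices(geno.codes)
    # column-mean imputation of missing calls prior to the SVD
    col_mean = np.nanmean(np.where(np.isnan(xa), np.nan, xa), axis=0)
    col_mean = np.nan_to_num(col_mean)
    inds = np.where(np.isnan(xa))
    xa[inds] = col_mean[inds[1]]
    xa -= xa.mean(axis=0)
    u, s, vt = np.linalg.svd(xa, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=geno.line_ids,
                        columns=[f"pc{j + 1}" for j in range(k)])


@dataclass
class DesignMatrices:
    """Row-aligned design for one trait: one row per phenotype record."""

    fixed: pd.DataFrame                  # a@, d@, aa@, ad@, da@, dd@ columns
    cofactors: pd.DataFrame              # pc1..pck (may be empty)
    env_block: pd.DataFrame              # e@h indicator columns
    random: dict[str, pd.DataFrame]      # family -> u-columns (term@snp:h)
    y: np.ndarray
    env: np.ndarray                      # environment id per record
    lines: np.ndarray                    # line id per record
    loci: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.y)

    def terms(self) -> dict[str, tuple[str, list[str]]]:
        """Map term id -> (family, column names).

        Fixed terms are single columns (``a@snp``); each random genetic term
        groups its per-environment incidence columns (``ae@snp`` spans
        ``ae@snp:h`` for every h).
        """
        out: dict[str, tuple[str, list[str]]] = {}
        for col in self.fixed.columns:
            kind = col.split("@", 1)[0]
            fam = "main" if kind in MAIN_FAMILY else "epistasis"
            out[col] = (fam, [col])
        for fam_name, block in self.random.items():
            groups: dict[str, list[str]] = {}
            for col in block.columns:
                term = col.rsplit(":", 1)[0]
                groups.setdefault(term, []).append(col)
            for term, cols in groups.items():
                out[term] = ("interaction", cols)
        return out


def build_design(geno: GenotypeMatrix, pheno: PhenotypeTable,
                 loci: Sequence[str] | None = None,
                 pairs: Sequence[tuple[str, str]] | None = None,
                 n_pcs: int = 0, gxe: bool = True) -> DesignMatrices:
    """Assemble fixed/cofactor/random blocks aligned to phenotype records.

    ``gxe=False`` omits the interaction incidence blocks (fixed-only
    model, e.g. single-environment fits).
    """
    traits = pheno.traits
    if len(traits) != 1:
        raise ValueError(f"build_design expects a single trait, got {traits}")
    loci = list(loci) if loci is not None else list(geno.snp_ids)
    pairs = [tuple(p) for p in pairs] if pairs else []
    for i, j in pairs:
        if i not in loci or j not in loci:
            raise KeyError(f"pair ({i}, {j}) references loci outside the set")

    line_pos = {l: k for k, l in enumerate(geno.line_ids)}
    missing_lines = sorted(set(pheno.df["line"]) - set(line_pos))
    if missing_lines:
        raise KeyError(f"phenotype lines absent from genotypes: "
                       f"{missing_lines[:10]}")

    sub = geno.subset_snps(loci)
    xa, xd = _contrast_matrices(sub.codes)
    xa = _impute_by_family(xa, sub.family_ids)
    xd = _impute_by_family(xd, sub.family_ids)

    ridx = pheno.df["line"].map(line_pos).to_numpy()
    env = pheno.df["env"].to_numpy()
    envs = sorted(np.unique(env))
    y = pheno.values()

    col_of = {s: k for k, s in enumerate(loci)}
    fixed_cols: dict[str, np.ndarray] = {}
    for s in loci:
        fixed_cols[f"a@{s}"] = xa[ridx, col_of[s]]
    for s in loci:
        fixed_cols[f"d@{s}"] = xd[ridx, col_of[s]]
    pair_vals: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for i, j in pairs:
        ai, di = xa[:, col_of[i]], xd[:, col_of[i]]
        aj, dj = xa[:, col_of[j]], xd[:, col_of[j]]
        pv = {"aa": ai * aj, "ad": ai * dj, "da": di * aj, "dd": di * dj}
        pair_vals[(i, j)] = pv
        for kind, v in pv.items():
            fixed_cols[f"{kind}@{i}:{j}"] = v[ridx]
    fixed = pd.DataFrame(fixed_cols, index=range(len(y)))

    env_block = pd.DataFrame(
        {f"e@{h}": (env == h).astype(float) for h in envs})

    random: dict[str, pd.DataFrame] = {}
    if not gxe:
        pcs_line = compute_pcs(geno, n_pcs)
        cof = (pcs_line.to_numpy()[ridx]
               if n_pcs else np.empty((len(y), 0)))
        return DesignMatrices(
            fixed=fixed, cofactors=pd.DataFrame(cof,
                                                columns=list(pcs_line.columns)),
            env_block=env_block, random=random, y=y, env=env,
            lines=pheno.df["line"].to_numpy(), loci=loci, pairs=pairs)
    ae_cols: dict[str, np.ndarray] = {}
    de_cols: dict[str, np.ndarray] = {}
    for s in loci:
        a_rec = xa[ridx, col_of[s]]
        d_rec = xd[ridx, col_of[s]]
        for h in envs:
            mask = env == h
            ae_cols[f"ae@{s}:{h}"] = np.where(mask, a_rec, 0.0)
            de_cols[f"de@{s}:{h}"] = np.where(mask, d_rec, 0.0)
    random["ae"] = pd.DataFrame(ae_cols, index=range(len(y)))
    random["de"] = pd.DataFrame(de_cols, index=range(len(y)))
    if pairs:
        for fam, kind in zip(("aae", "ade", "dae", "dde"),
                             ("aa", "ad", "da", "dd")):
            cols: dict[str, np.ndarray] = {}
            for (i, j) in pairs:
                v = pair_vals[(i, j)][kind][ridx]
                for h in envs:
                    cols[f"{fam}@{i}:{j}:{h}"] = np.where(env == h, v, 0.0)
            random[fam] = pd.DataFrame(cols, index=range(len(y)))

    pcs_line = compute_pcs(geno, n_pcs)
    cof = (pcs_line.to_numpy()[ridx]
           if n_pcs else np.empty((len(y), 0)))
    cofactors = pd.DataFrame(cof, columns=list(pcs_line.columns))

    return DesignMatrices(fixed=fixed, cofactors=cofactors,
                          env_block=env_block, random=random, y=y, env=env,
                          lines=pheno.df["line"].to_numpy(),
                          loci=loci, pairs=pairs)


class GenotypeEncoder(TransformerMixin, BaseEstimator):
    """Transformer view of :func:`build_design`.

    ``fit`` binds the genotype matrix (and computes the population-structure
    PCs); ``transform`` maps a phenotype table to row-aligned design
    matrices.  Composes with sklearn pipelines that carry the phenotype
    table as X.
    """

    def __init__(self, loci=None, pairs=None, n_pcs: int = 0):
        self.loci = loci
        self.pairs = pairs
        self.n_pcs = n_pcs

    def fit(self, geno: GenotypeMatrix, y=None):
        self.geno_ = geno
        self.pcs_ = compute_pcs(geno, self.n_pcs)
        return self

    def transform(self, pheno: PhenotypeTable) -> DesignMatrices:
        if not hasattr(self, "geno_"):
            raise RuntimeError("GenotypeEncoder is not fitted")
        return build_design(self.geno_, pheno, loci=self.loci,
                            pairs=self.pairs, n_pcs=self.n_pcs)
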