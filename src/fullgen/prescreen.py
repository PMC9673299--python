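"""GMDR-style prescreen of loci and locus tuples.

Generalized multifactor dimensionality reduction labels each multi-locus
genotype cell high- or low-risk according to whether the cell's mean score
statistic exceeds the overall mean, then measures how well that labeling
classifies held-out individuals.  For quantitative traits the score
statistic is the residual from a mean + environment model, and the
cross-validated balanced accuracy of the high/low classification is the
tuple's score: ~0.5 for a null locus, 1.0 under perfect separation.

The exhaustive 1D scan ranks every SNP; 2D/3D scans are restricted to the
top 1D survivors, which trades the original GPU-scale exhaustiveness for
desk-scale tractability (the survivor count is configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, PhenotypeTable, parse_snp_id


def env_residuals(pheno: PhenotypeTable) -> pd.Series:
    """Residuals from the trait x environment mean model, indexed by line."""
    df = pheno.df
    if len(pheno.traits) != 1:
        raise ValueError("prescreen expects a single trait")
    resid = df["value"] - df.groupby("env")["value"].transform("mean")
    return pd.Series(resid.to_numpy(), index=df["line"].to_numpy())


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % n_folds
    rng.shuffle(folds)
    return folds


def _score_cells(resid: np.ndarray, cells: np.ndarray, n_cells: int,
                 folds: np.ndarray, n_folds: int) -> float:
    """Pooled-over-folds balanced accuracy of the high/low cell labeling."""
    tp = fp = tn = fn = 0
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if not train.any() or not test.any():
            continue
        overall = resid[train].mean()
        counts = np.bincount(cells[train], minlength=n_cells)
        sums = np.bincount(cells[train], weights=resid[train],
                           minlength=n_cells)
        with np.errstate(invalid="ignore"):
            cell_mean = np.where(counts > 0, sums / np.maximum(counts, 1),
                                 np.nan)
        high = cell_mean > overall           # NaN -> False, but we also
        classified = counts > 0              # skip unclassified cells
        ok = classified[cells[test]]
        pred = high[cells[test]][ok]
        true = (resid[test] > overall)[ok]
        tp += int(np.sum(pred & true))
        fp += int(np.sum(pred & ~true))
        tn += int(np.sum(~pred & ~true))
        fn += int(np.sum(~pred & true))
    sens = tp / (tp + fn) if (tp + fn) else 0.5
    spec = tn / (tn + fp) if (tn + fp) else 0.5
    return 0.5 * (sens + spec)


def _cells_for(geno: GenotypeMatrix, line_rows: np.ndarray,
               loci_idx: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Cell index per record; records with a missing call are masked out."""
    codes = geno.codes[np.ix_(line_rows, list(loci_idx))]
    valid = (codes >= 0).all(axis=1)
    cells = np.zeros(len(line_rows), dtype=np.int64)
    for k in range(codes.shape[1]):
        cells = cells * 3 + np.maximum(codes[:, k], 0)
    return cells, valid


def gmdr_score(pheno_residuals: pd.Series, geno: GenotypeMatrix,
               tuple_of_loci, n_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated GMDR score of a 1-, 2- or 3-locus tuple in [0, 1].

    ``pheno_residuals`` is a Series of score statistics indexed by line id
    (lines repeat across environments).
    """
    loci = (tuple_of_loci,) if isinstance(tuple_of_loci, str) \
        else tuple(tuple_of_loci)
    if not 1 <= len(loci) <= 3:
        raise ValueError("tuple size must be 1, 2 or 3")
    line_pos = {l: k for k, l in enumerate(geno.line_ids)}
    rows = np.array([line_pos[l] for l in pheno_residuals.index])
    idx = tuple(geno.snp_index(s) for s in loci)
    cells, valid = _cells_for(geno, rows, idx)
    resid = pheno_residuals.to_numpy()
    folds = _fold_assignment(len(resid), n_folds, seed)
    m = valid
    return _score_cells(resid[m], cells[m], 3 ** len(loci), folds[m],
                        n_folds)


@dataclass
class CandidateSet:
    """Ranked prescreen output feeding the association stage."""

    loci: pd.DataFrame                       # columns: snp, score
    pairs: pd.DataFrame                      # snp_i, snp_j, score
    triples: pd.DataFrame                    # snp_i, snp_j, snp_k, score
    params: dict = field(default_factory=dict)

    @property
    def candidate_loci(self) -> list[str]:
        """Top loci plus every constituent of a selected pair/triple."""
        seen: dict[str, None] = {}
        for s in self.loci["snp"]:
            seen.setdefault(s)
        for _, row in self.pairs.iterrows():
            seen.setdefault(row["snp_i"])
            seen.setdefault(row["snp_j"])
        for _, row in self.triples.iterrows():
            for c in ("snp_i", "snp_j", "snp_k"):
                seen.setdefault(row[c])
        return list(seen)

    @property
    def candidate_pairs(self) -> list[tuple[str, str]]:
        """Selected pairs; triples expand to their three constituent pairs."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.pairs.iterrows():
            seen.setdefault((row["snp_i"], row["snp_j"]))
        for _, row in self.triples.iterrows():
            trio = [row["snp_i"], row["snp_j"], row["snp_k"]]
            for p in itertools.combinations(trio, 2):
                seen.setdefault(tuple(p))
        return list(seen)


def _rank_key(geno: GenotypeMatrix):
    meta = {s: parse_snp_id(s) for s in geno.snp_ids}

    def key(snps: tuple[str, ...]):
        return tuple(meta[s] for s in snps)
    return key


def gmdr_scan(pheno: PhenotypeTable, geno: GenotypeMatrix,
              dims=(1, 2), top_k=20, seed: int = 0, n_folds: int = 5,
              n_1d_survivors: int = 50) -> CandidateSet:
    """Scan SNPs (1D exhaustively, 2D/3D over 1D survivors) and rank tuples.

    ``top_k`` is an int applied per dimension or a {dim: k} mapping.
    Ranking is by descending score with ties broken by (chromosome,
    position) order for determinism.
    """
    dims = set(int(d) for d in dims)
    if not dims or not dims <= {1, 2, 3}:
        raise ValueError(f"dims must be a non-empty subset of {{1,2,3}}, "
                         f"got {sorted(dims)}")
    if isinstance(top_k, int):
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        top_k = {d: top_k for d in (1, 2, 3)}
    resid = env_residuals(pheno)
    key = _rank_key(geno)

    def ranked(tuples, scores):
        order = sorted(range(len(tuples)),
                       key=lambda i: (-scores[i], key(tuples[i])))
        return [tuples[i] for i in order], [scores[i] for i in order]

    snps = [(s,) for s in geno.snp_ids]
    scores_1d = [gmdr_score(resid, geno, t, n_folds, seed) for t in snps]
    snps, scores_1d = ranked(snps, scores_1d)
    survivors = [t[0] for t in snps[:n_1d_survivors]]

    loci_df = pd.DataFrame({"snp": [t[0] for t in snps],
                            "score": scores_1d})
    if 1 in dims:
        loci_df = loci_df.head(top_k[1]).reset_index(drop=True)
    else:
        loci_df = loci_df.iloc[0:0]

    pairs_df = pd.DataFrame(columns=["snp_i", "snp_j", "score"])
    if 2 in dims and len(survivors) >= 2:
        tuples = list(itertools.combinations(survivors, 2))
        scores = [gmdr_score(resid, geno, t, n_folds, seed) for t in tuples]
        tuples, scores = ranked(tuples, scores)
        tuples = tuples[:top_k[2]]
        pairs_df = pd.DataFrame(
            {"snp_i": [t[0] for t in tuples],
             "snp_j": [t[1] for t in tuples],
             "score": scores[:len(tuples)]})

    triples_df = pd.DataFrame(columns=["snp_i", "snp_j", "snp_k", "score"])
    if 3 in dims and len(survivors) >= 3:
        tuples = list(itertools.combinations(survivors, 3))
        scores = [gmdr_score(resid, geno, t, n_folds, seed) for t in tuples]
        tuples, scores = ranked(tuples, scores)
        tuples = tuples[:top_k[3]]
        triples_df = pd.DataFrame(
            {"snp_i": [t[0] for t in tuples],
             "snp_j": [t[1] for t in tuples],
             "snp_k": [t[2] for t in tuples],
             "score": scores[:len(tuples)]})

    return CandidateSet(loci=loci_df, pairs=pairs_df, triples=triples_df,
                        params={"dims": sorted(dims), "top_k": top_k,
                                "folds": n_folds, "seed": seed,
                                "n_1d_survivors": n_1d_survivors})


class GMDRScreen(BaseEstimator):
    """sklearn-style wrapper: ``fit(geno, pheno)`` ranks candidate tuples.

    ``transform(geno)`` subsets a genotype matrix to the selected loci.
    """

    def __init__(self, dims=(1, 2), top_k=20, n_folds: int = 5,
                 n_1d_survivors: int = 50, seed: int = 0):
        self.dims = dims
        self.top_k = top_k
        self.n_folds = n_folds
        self.n_1d_survivors = n_1d_survivors
        self.seed = seed

    def fit(self, geno: GenotypeMatrix, pheno: PhenotypeTable):
        self.candidates_ = gmdr_scan(
            pheno, geno, dims=self.dims, top_k=self.top_k, seed=self.seed,
            n_folds=self.n_folds, n_1d_survivors=self.n_1d_survivors)
        return self

    def transform(self, geno: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "candidates_"):
            raise RuntimeError("GMDRScreen is not fitted")
        return geno.subset_snps(self.candidates_.candidate_loci)
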