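"""Core containers shared by every pipeline stage.

Genotypes are stored as a compact integer matrix (lines x SNPs) with the
coding ``qq=0, Qq=1, QQ=2, missing=-1`` where *Q* is always the non-reference
(non-B73) allele.  With this coding the additive contrast is ``code - 1`` and
the dominance indicator is ``code == 1``, which the design-matrix builder
exploits directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# integer genotype codes
QQ_HOM_B73 = 0  # qq : homozygous for the reference (B73) allele
HET = 1         # Qq
QQ_HOM_ALT = 2  # QQ : homozygous for the non-B73 allele
MISSING = -1

CODE_TO_STR = {0: "qq", 1: "Qq", 2: "QQ", -1: "NN"}
STR_TO_CODE = {"qq": 0, "Qq": 1, "QQ": 2, "NN": -1, "NA": -1, "--": -1, "": -1}

SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def parse_snp_id(snp_id: str) -> tuple[int, int]:
    """Split an ``S<chrom>_<pos>`` identifier into (chromosome, position)."""
    m = SNP_ID_RE.match(snp_id)
    if m is None:
        raise ParseError(f"SNP id {snp_id!r} does not match S<chrom>_<pos>")
    return int(m.group(1)), int(m.group(2))


@dataclass
class GenotypeMatrix:
    """Lines x SNPs genotype codes with family labels and SNP metadata."""

    codes: np.ndarray               # int8, shape (n_lines, n_snps)
    line_ids: list[str]
    family_ids: list[str]           # one family per line
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (lines x SNPs)")
        n_lines, n_snps = self.codes.shape
        if len(self.line_ids) != n_lines or len(self.family_ids) != n_lines:
            raise ValueError("line/family labels do not match codes rows")
        if len(self.snp_ids) != n_snps:
            raise ValueError("snp_ids do not match codes columns")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError(f"invalid genotype codes present: "
                             f"{np.unique(self.codes[bad])}")
        for sid in self.snp_ids:
            parse_snp_id(sid)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def chrom(self) -> np.ndarray:
        return np.array([parse_snp_id(s)[0] for s in self.snp_ids])

    @property
    def pos(self) -> np.ndarray:
        return np.array([parse_snp_id(s)[1] for s in self.snp_ids])

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise KeyError(f"line {line_id!r} not in genotype matrix") from None

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(self.codes[:, idx], list(self.line_ids),
                              list(self.family_ids), list(snp_ids))

    def to_frame(self) -> pd.DataFrame:
        """String-coded DataFrame (lines x SNPs), for display and export."""
        arr = np.vectorize(CODE_TO_STR.get)(self.codes)
        return pd.DataFrame(arr, index=self.line_ids, columns=self.snp_ids)

    # -- allele summaries ---------------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes >= 0).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (heterozygote adds one of each)."""
        obs = self.codes >= 0
        n_alleles = 2 * obs.sum(axis=0)
        q_count = np.where(obs, self.codes, 0).sum(axis=0)  # Q allele dosage
        minor = np.minimum(q_count, n_alleles - q_count)  # integer-exact
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, minor / n_alleles, 0.0)


PHENO_COLUMNS = ["line", "family", "env", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Long-format phenotype records (line, family, env, trait, value)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParseError(f"phenotype table missing columns: {missing}")
        df = self.df[PHENO_COLUMNS].copy()
        df["env"] = df["env"].astype(int)
        if (df["env"] < 1).any():
            raise ParseError("environment ids must be positive integers")
        df["value"] = df["value"].astype(float)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def envs(self) -> list[int]:
        return sorted(self.df["env"].unique())

    def for_trait(self, trait: str) -> "PhenotypeTable":
        return PhenotypeTable(self.df[self.df["trait"] == trait])

    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()


@dataclass
class GeneticArchitecture:
    """Ground-truth or estimated effect set for the full genetic model.

    ``additive``/``dominance`` map locus -> effect (trait units);
    ``epistasis`` maps an ordered pair (i, j) -> {aa, ad, da, dd};
    ``env_effects`` maps environment h -> e_h (drawn from N(0, env_sd^2) at
    simulation time when absent); ``gxe_loci`` maps (locus, h) -> {ae, de};
    ``gxe_pairs`` maps (i, j, h) -> {aae, ade, dae, dde}.
    """

    mu: float = 0.0
    additive: dict[str, float] = field(default_factory=dict)
    dominance: dict[str, float] = field(default_factory=dict)
    epistasis: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    env_effects: dict[int, float] | None = None
    env_sd: float = 0.0
    gxe_loci: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    gxe_pairs: dict[tuple[str, str, int], dict[str, float]] = field(default_factory=dict)
    residual_sd: float = 1.0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for (i, j, h) in self.gxe_pairs:
            if (i, j) not in self.epistasis:
                raise ValueError(f"G x E pair effect references undeclared "
                                 f"pair ({i}, {j})")

    @property
    def loci(self) -> list[str]:
        """Every locus carrying any effect, in first-mention order."""
        seen: dict[str, None] = {}
        for s in list(self.additive) + list(self.dominance):
            seen.setdefault(s)
        for i, j in self.epistasis:
            seen.setdefault(i)
            seen.setdefault(j)
        for s, _h in self.gxe_loci:
            seen.setdefault(s)
        return list(seen)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.epistasis)


@dataclass
class QCReport:
    """Bookkeeping for one QC step; ``in = out + removed`` on both axes."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_records_in: int = 0
    n_records_out: int = 0
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"]))
    removed_records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=PHENO_COLUMNS + ["reason"]))

    def __post_init__(self) -> None:
        if self.n_snps_in != self.n_snps_out + len(self.removed_snps):
            raise ValueError("SNP accounting does not balance")
        if self.n_records_in != self.n_records_out + len(self.removed_records):
            raise ValueError("record accounting does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("snps_in", self.n_snps_in), ("snps_out", self.n_snps_out),
            ("records_in", self.n_records_in),
            ("records_out", self.n_records_out),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])
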