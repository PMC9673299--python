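"""Readers and writers for genotype and phenotype files.

Two genotype dialects are supported:

* ``hapmap`` — tab-delimited with columns ``rs, alleles, chrom, pos`` then
  one column per line.  Cells are two-letter genotypes (``AA``, ``AT`` ...,
  ``NN`` for missing).  The first allele listed in ``alleles`` is the
  reference (B73) allele, so ``AA`` maps to qq, the alternate homozygote to
  QQ and the mixed call to Qq.
* ``matrix`` — tab-delimited lines x SNPs with ``line`` and ``family``
  columns followed by one column per SNP carrying QQ/Qq/qq/NA codes.

Phenotypes travel as CSV with columns ``line, family, env, trait, value``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CODE_TO_STR, GenotypeMatrix, ParseError,
                        PhenotypeTable, PHENO_COLUMNS, STR_TO_CODE,
                        parse_snp_id)

log = logging.getLogger(__name__)

_LINE_ID_RE = re.compile(r"^(Z\d+)E\d+$")


def _family_of(line_id: str) -> str:
    m = _LINE_ID_RE.match(line_id)
    return m.group(1) if m else "F0"


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[:4] != ["rs", "alleles", "chrom", "pos"]:
            raise ParseError(f"{path}:1: malformed header {cols[:4]!r}, "
                             "expected rs/alleles/chrom/pos")
        line_ids = cols[4:]
        if not line_ids:
            raise ParseError(f"{path}:1: no line columns")
        snp_ids, code_rows = [], []
        for ln, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ParseError(f"{path}:{ln}: expected {len(cols)} fields, "
                                 f"got {len(parts)}")
            rs, alleles = parts[0], parts[1]
            try:
                parse_snp_id(rs)
            except ParseError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            allele_pair = alleles.split("/")
            if len(allele_pair) != 2:
                raise ParseError(f"{path}:{ln}: malformed alleles "
                                 f"{alleles!r}")
            ref, alt = allele_pair  # ref = B73 allele = q
            row = np.empty(len(line_ids), dtype=np.int8)
            for k, cell in enumerate(parts[4:]):
                if cell in ("NN", "--", "NA", ""):
                    row[k] = -1
                elif cell == ref + ref:
                    row[k] = 0
                elif cell == alt + alt:
                    row[k] = 2
                elif set(cell) == {ref, alt}:
                    row[k] = 1
                else:
                    raise ParseError(f"{path}:{ln}: unknown genotype "
                                     f"{cell!r} for alleles {alleles!r}")
            snp_ids.append(rs)
            code_rows.append(row)
    if not snp_ids:
        raise ParseError(f"{path}: no SNP rows")
    codes = np.stack(code_rows, axis=1)  # lines x SNPs
    families = [_family_of(l) for l in line_ids]
    return GenotypeMatrix(codes, line_ids, families, snp_ids)


def _read_matrix(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.columns[0] != "line":
        raise ParseError(f"{path}:1: first column must be 'line'")
    has_family = len(df.columns) > 1 and df.columns[1] == "family"
    snp_cols = list(df.columns[2 if has_family else 1:])
    if not snp_cols:
        raise ParseError(f"{path}:1: no SNP columns")
    for s in snp_cols:
        parse_snp_id(s)
    line_ids = df["line"].tolist()
    families = (df["family"].tolist() if has_family
                else [_family_of(l) for l in line_ids])
    codes = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, s in enumerate(snp_cols):
        for i, cell in enumerate(df[s].fillna("NA")):
            if cell not in STR_TO_CODE:
                raise ParseError(f"{path}:{i + 2}: unknown code {cell!r} "
                                 f"at SNP {s}")
            codes[i, j] = STR_TO_CODE[cell]
    return GenotypeMatrix(codes, line_ids, families, snp_cols)


def read_genotypes(path, format: str = "hapmap") -> GenotypeMatrix:
    """Read a genotype file; ``format`` is ``hapmap`` or ``matrix``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path, format: str = "hapmap"
                    ) -> None:
    path = Path(path)
    if format == "hapmap":
        with open(path, "w") as fh:
            fh.write("\t".join(["rs", "alleles", "chrom", "pos"]
                               + list(geno.line_ids)) + "\n")
            chrom, pos = geno.chrom, geno.pos
            cell = {0: "AA", 1: "AT", 2: "TT", -1: "NN"}  # A = B73 allele
            for j, sid in enumerate(geno.snp_ids):
                row = [sid, "A/T", str(chrom[j]), str(pos[j])]
                row += [cell[int(c)] for c in geno.codes[:, j]]
                fh.write("\t".join(row) + "\n")
    elif format == "matrix":
        df = geno.to_frame().replace("NN", "NA")
        df.insert(0, "family", geno.family_ids)
        df.insert(0, "line", geno.line_ids)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(path) -> PhenotypeTable:
    """Read the long-format phenotype CSV.

    Rows whose value does not parse as a number are dropped; the count is
    available as ``table.n_dropped`` and logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    keep = values.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%s: dropped %d rows with unparseable values",
                    path, n_dropped)
    df = df.loc[keep].copy()
    df["value"] = values[keep]
    env = pd.to_numeric(df["env"], errors="coerce")
    if env.isna().any():
        bad = df.loc[env.isna(), "env"].unique()
        raise ParseError(f"{path}: non-integer environment labels {bad}")
    df["env"] = env.astype(int)
    table = PhenotypeTable(df)
    table.n_dropped = n_dropped
    return table


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False)
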