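"""Genotype-combination optimization for breeding prediction.

Given an effect set (true or estimated), the total genotypic value of a
multi-locus genotype is the full-model sum of additive, dominance and
digenic epistasis terms, plus the environment-specific interaction terms
when a target environment is given; the population mean mu is reported
separately.  The best existing line maximizes this value over observed
lines; the superior line is the exact or greedily tuned optimum over
homozygous combinations {QQ, qq}; the superior hybrid also admits the
heterozygote Qq.  Small instances are solved by exhaustive enumeration;
larger ones by coordinate-wise stepwise tuning, whose sweeps are
monotonically non-decreasing and which enumeration bounds from above on
every instance small enough to check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (GeneticArchitecture, GenotypeMatrix, STR_TO_CODE,
                        CODE_TO_STR)

_CODE_INTS = {"QQ": 2, "Qq": 1, "qq": 0}


class _EffectArrays:
    """Dense views of an architecture's effects for fast evaluation."""

    def __init__(self, arch: GeneticArchitecture, env: int | None = None):
        self.loci = arch.loci
        self.index = {s: k for k, s in enumerate(self.loci)}
        L = len(self.loci)
        self.a = np.zeros(L)
        self.d = np.zeros(L)
        for s, v in arch.additive.items():
            self.a[self.index[s]] = v
        for s, v in arch.dominance.items():
            self.d[self.index[s]] = v
        if env is not None:
            for (s, h), eff in arch.gxe_loci.items():
                if h == env:
                    self.a[self.index[s]] += eff.get("ae", 0.0)
                    self.d[self.index[s]] += eff.get("de", 0.0)
        self.pairs: list[tuple[int, int, float, float, float, float]] = []
        pair_eff: dict[tuple[str, str], dict[str, float]] = {
            p: dict(e) for p, e in arch.epistasis.items()}
        if env is not None:
            for (i, j, h), eff in arch.gxe_pairs.items():
                if h != env:
                    continue
                tgt = pair_eff.setdefault((i, j), {})
                for kind in ("aa", "ad", "da", "dd"):
                    tgt[kind] = tgt.get(kind, 0.0) + eff.get(kind + "e", 0.0)
        for (i, j), eff in pair_eff.items():
            self.pairs.append((self.index[i], self.index[j],
                               eff.get("aa", 0.0), eff.get("ad", 0.0),
                               eff.get("da", 0.0), eff.get("dd", 0.0)))

    def value(self, codes: np.ndarray) -> np.ndarray:
        """Genotypic value(s); codes is (..., L) of ints in {0, 1, 2}."""
        xa = codes - 1.0
        xd = (codes == 1).astype(float)
        v = xa @ self.a + xd @ self.d
        for i, j, aa, ad, da, dd in self.pairs:
            v = v + (aa * xa[..., i] * xa[..., j]
                     + ad * xa[..., i] * xd[..., j]
                     + da * xd[..., i] * xa[..., j]
                     + dd * xd[..., i] * xd[..., j])
        return v


def _codes_from_vector(vector, loci: Sequence[str]) -> np.ndarray:
    if isinstance(vector, Mapping):
        missing = [s for s in loci if s not in vector]
        if missing:
            raise KeyError(f"genotype vector missing loci {missing}")
        seq = [vector[s] for s in loci]
    else:
        seq = list(vector)
        if len(seq) != len(loci):
            raise KeyError(f"genotype vector has {len(seq)} codes for "
                           f"{len(loci)} loci")
    out = np.empty(len(loci), dtype=np.int8)
    for k, c in enumerate(seq):
        c = _CODE_INTS.get(c, c) if isinstance(c, str) else int(c)
        if c not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {seq[k]!r}")
        out[k] = c
    return out


def genotypic_value(genotype_vector, arch: GeneticArchitecture,
                    env: int | None = None) -> float:
    """Total genotypic value of a genotype vector, relative to mu."""
    eff = _EffectArrays(arch, env=env)
    codes = _codes_from_vector(genotype_vector, eff.loci)
    return float(eff.value(codes))


def best_existing_line(geno: GenotypeMatrix, arch: GeneticArchitecture,
                       env_list: Sequence[int] | None = None
                       ) -> dict[str | int, tuple[str, float]]:
    """Per-environment and overall (line id, value) argmax over lines.

    Ties break by line-id order.  Missing calls at an effect locus
    contribute nothing (coefficient 0) for that line.
    """
    if geno.n_lines == 0:
        raise ValueError("no lines in the genotype matrix")
    out: dict[str | int, tuple[str, float]] = {}
    sub = geno.subset_snps(arch.loci)
    for key in ["overall"] + list(env_list or []):
        env = None if key == "overall" else int(key)
        eff = _EffectArrays(arch, env=env)
        codes = sub.codes.astype(float)
        # missing calls contribute nothing: x_A = 0 and x_D = 0
        xa = np.where(sub.codes >= 0, codes - 1.0, 0.0)
        xd = np.where(sub.codes >= 0, (sub.codes == 1).astype(float), 0.0)
        v = xa @ eff.a + xd @ eff.d
        for i, j, aa, ad, da, dd in eff.pairs:
            v += (aa * xa[:, i] * xa[:, j] + ad * xa[:, i] * xd[:, j]
                  + da * xd[:, i] * xa[:, j] + dd * xd[:, i] * xd[:, j])
        order = np.lexsort((np.array(geno.line_ids), -v))
        best = order[0]
        out[key] = (geno.line_ids[best], float(v[best]))
    return out


def enumerate_optimum(arch: GeneticArchitecture,
                      allowed_codes: Sequence[str] = ("QQ", "qq"),
                      env: int | None = None, max_loci: int = 15
                      ) -> tuple[dict[str, str], float]:
    """Exact argmax over |allowed|^n_loci genotype combinations.

    Refuses instances above ``max_loci`` (use :func:`stepwise_tune`).
    Ties break by enumeration order, so the result is deterministic.
    """
    eff = _EffectArrays(arch, env=env)
    n = len(eff.loci)
    if n == 0:
        return {}, 0.0
    if n > max_loci:
        raise ValueError(f"{n} loci exceeds max_loci={max_loci}; use "
                         "stepwise_tune for larger instances")
    allowed = [_CODE_INTS[c] for c in allowed_codes]
    best_val, best_combo = -np.inf, None
    chunk = 1 << 16
    combos = itertools.product(allowed, repeat=n)
    while True:
        block = np.array(list(itertools.islice(combos, chunk)), dtype=np.int8)
        if block.size == 0:
            break
        vals = eff.value(block)
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_combo = block[k].copy()
    genotype = {s: CODE_TO_STR[int(c)] for s, c in zip(eff.loci, best_combo)}
    return genotype, best_val


def _marginal_start(eff: _EffectArrays, allowed: list[int]) -> np.ndarray:
    """Per-locus argmax of a*x_A + d*x_D ignoring interactions."""
    start = np.empty(len(eff.loci), dtype=np.int8)
    for k in range(len(eff.loci)):
        vals = [eff.a[k] * (c - 1) + eff.d[k] * (c == 1) for c in allowed]
        start[k] = allowed[int(np.argmax(vals))]
    return start


def stepwise_tune(arch: GeneticArchitecture,
                  allowed_codes: Sequence[str] = ("QQ", "qq"),
                  env: int | None = None, start_vector=None,
                  max_sweeps: int = 100, n_restarts: int = 8,
                  restart_seed: int = 0) -> tuple[dict[str, str], float]:
    """Coordinate-wise greedy improvement of the genotype combination.

    Sweeps loci in descending |a| + |d| order (ties by locus id), changing
    one locus at a time only when the value strictly increases; stops at a
    fixed point or after ``max_sweeps``.  Deterministic given the start.
    When no start is supplied the search runs from the per-locus marginal
    optimum, the three uniform vectors and ``n_restarts`` seeded random
    starts, returning the best fixed point found; epistatic landscapes are
    multimodal and a single start can stall on a local optimum.
    """
    eff = _EffectArrays(arch, env=env)
    allowed = [_CODE_INTS[c] for c in allowed_codes]
    if start_vector is None:
        starts = [_marginal_start(eff, allowed)]
        for c in allowed:
            starts.append(np.full(len(eff.loci), c, dtype=np.int8))
        rng = np.random.default_rng(restart_seed)
        for _ in range(n_restarts):
            starts.append(np.array(rng.choice(allowed, size=len(eff.loci)),
                                   dtype=np.int8))
        best: tuple[dict[str, str], float] | None = None
        for s in starts:
            cand = stepwise_tune(arch, allowed_codes, env=env,
                                 start_vector=s, max_sweeps=max_sweeps)
            if best is None or cand[1] > best[1]:
                best = cand
        return best
    current = _codes_from_vector(start_vector, eff.loci)
    if any(int(c) not in allowed for c in current):
        raise ValueError("start vector uses codes outside allowed_codes")
    order = sorted(range(len(eff.loci)),
                   key=lambda k: (-(abs(eff.a[k]) + abs(eff.d[k])),
                                  eff.loci[k]))
    value = float(eff.value(current))
    for _ in range(max_sweeps):
        improved = False
        for k in order:
            trial = np.tile(current, (len(allowed), 1))
            trial[:, k] = allowed
            vals = eff.value(trial)
            j = int(np.argmax(vals))
            if vals[j] > value:
                current = trial[j]
                value = float(vals[j])
                improved = True
        if not improved:
            break
    genotype = {s: CODE_TO_STR[int(c)] for s, c in zip(eff.loci, current)}
    return genotype, value


def _optimum(arch, allowed_codes, env, max_loci, extra_starts=()):
    """Enumeration when feasible, otherwise best of stepwise starts."""
    n = len(arch.loci)
    if n <= max_loci:
        return enumerate_optimum(arch, allowed_codes, env, max_loci)
    best = stepwise_tune(arch, allowed_codes, env=env)
    for start in extra_starts:
        cand = stepwise_tune(arch, allowed_codes, env=env,
                             start_vector=start)
        if cand[1] > best[1]:
            best = cand
    return best


@dataclass
class BreedingPrediction:
    """Table-3-style summary: mu, fixed combinations, best/superior values."""

    trait: str
    mu: dict[str, float]
    values: pd.DataFrame                  # rows x columns of genetic values
    best_line_ids: dict[str, str]
    superior_line_genotypes: dict[str, dict[str, str]]
    superior_hybrid_genotypes: dict[str, dict[str, str]]

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.loc["mu"] = pd.Series(self.mu)
        return out.reindex(["mu", "QQ", "qq", "F1", "best_line",
                            "superior_line", "superior_hybrid"])


def predict_breeding_table(arch: GeneticArchitecture, geno: GenotypeMatrix,
                           env_list: Sequence[int] | None = None,
                           max_enum_loci: int = 15) -> BreedingPrediction:
    """Assemble mu, QQ/qq/F1 rows and best/superior line and hybrid values.

    The "overall" column uses main + epistasis effects only; per-environment
    columns add the realized interaction effects of that environment.  The
    superior line searches {QQ, qq}; the superior hybrid searches
    {QQ, Qq, qq} and is seeded with the superior line, so its value can
    never fall below it.
    """
    if not arch.loci:
        raise ValueError("effect set is empty")
    env_list = list(env_list or [])
    cols = ["overall"] + [f"env{h}" for h in env_list]
    envs = [None] + env_list
    rows = ["QQ", "qq", "F1", "best_line", "superior_line",
            "superior_hybrid"]
    values = pd.DataFrame(index=rows, columns=cols, dtype=float)
    mu: dict[str, float] = {}
    best_ids: dict[str, str] = {}
    sl_geno: dict[str, dict[str, str]] = {}
    sh_geno: dict[str, dict[str, str]] = {}
    best = best_existing_line(geno, arch, env_list)
    L = len(arch.loci)
    for col, env in zip(cols, envs):
        e_h = 0.0
        if env is not None and arch.env_effects is not None:
            e_h = arch.env_effects.get(env, 0.0)
        mu[col] = arch.mu + e_h
        eff = _EffectArrays(arch, env=env)
        values.loc["QQ", col] = float(eff.value(np.full(L, 2, dtype=np.int8)))
        values.loc["qq", col] = float(eff.value(np.full(L, 0, dtype=np.int8)))
        values.loc["F1", col] = float(eff.value(np.full(L, 1, dtype=np.int8)))
        key = "overall" if env is None else env
        best_ids[col], values.loc["best_line", col] = best[key]
        sl, sl_val = _optimum(arch, ("QQ", "qq"), env, max_enum_loci)
        values.loc["superior_line", col] = sl_val
        sl_geno[col] = sl
        sh, sh_val = _optimum(arch, ("QQ", "Qq", "qq"), env, max_enum_loci,
                              extra_starts=(sl,))
        if sh_val < sl_val:  # only possible via independent stepwise starts
            sh, sh_val = sl, sl_val
        values.loc["superior_hybrid", col] = sh_val
        sh_geno[col] = sh
    return BreedingPrediction(trait=arch.trait, mu=mu, values=values,
                              best_line_ids=best_ids,
                              superior_line_genotypes=sl_geno,
                              superior_hybrid_genotypes=sh_geno)


def architecture_from_model(model, keep_terms=None) -> GeneticArchitecture:
    """Convert fitted-model estimates into an effect set for breeding.

    ``keep_terms`` optionally restricts genetic effects to the given term
    ids (e.g. the experiment-wise significant ones); mu and environment
    effects are always carried over.
    """
    est = (model.posterior_.set_index("term")["estimate"]
           if hasattr(model, "posterior_")
           else pd.concat([model.fixed_effects_, model.random_effects_]))
    keep = set(keep_terms) if keep_terms is not None else None

    def kept(term: str) -> bool:
        return keep is None or term in keep

    arch = GeneticArchitecture(mu=float(est.get("(intercept)", 0.0)),
                               residual_sd=float(
                                   np.sqrt(max(model.resid_variance_, 0.0))),
                               env_effects={})
    for term, v in est.items():
        if "@" not in term:
            continue
        kind, rest = term.split("@", 1)
        if kind == "e":
            arch.env_effects[int(rest)] = float(v)
        elif kind in ("a", "d"):
            if kept(term):
                (arch.additive if kind == "a" else arch.dominance)[rest] = \
                    float(v)
        elif kind in ("aa", "ad", "da", "dd"):
            if kept(term):
                i, j = rest.split(":")
                arch.epistasis.setdefault((i, j), {})[kind] = float(v)
        elif kind in ("ae", "de"):
            snp, h = rest.rsplit(":", 1)
            if kept(f"{kind}@{snp}"):
                arch.gxe_loci.setdefault((snp, int(h)), {})[kind] = float(v)
        elif kind in ("aae", "ade", "dae", "dde"):
            pair, h = rest.rsplit(":", 1)
            if kept(f"{kind}@{pair}"):
                i, j = pair.split(":")
                arch.epistasis.setdefault((i, j), {})
                arch.gxe_pairs.setdefault((i, j, int(h)), {})[kind] = float(v)
    if not arch.env_effects:
        arch.env_effects = None
    return GeneticArchitecture(
        mu=arch.mu, additive=arch.additive, dominance=arch.dominance,
        epistasis=arch.epistasis, env_effects=arch.env_effects,
        gxe_loci=arch.gxe_loci, gxe_pairs=arch.gxe_pairs,
        residual_sd=arch.residual_sd, trait=arch.trait)
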