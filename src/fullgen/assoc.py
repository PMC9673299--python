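"""Full genetic model association: mixed-model fit, Henderson-III F tests,
permutation experiment-wise thresholds, Gibbs effect estimation and
heritability partition.

Model
-----
Genetic main effects (a, d) and digenic epistasis (aa, ad, da, dd) are
fixed; environment (e) and every gene x environment interaction family
(ae, de, aae, ade, dae, dde) are random, each family with its own iid
variance component:

    y = X beta + sum_f Z_f u_f + eps,   u_f ~ N(0, s2_f I),
                                        eps ~ N(0, s2_e I).

Variance components are estimated by restricted maximum likelihood with a
Woodbury-factored profile likelihood (random-column count q stays small at
desk scale, so every evaluation is O(q^3) after one pass over the data).
Hypothesis tests use Henderson's method III: the F statistic for a term is
built from the difference in reductions in sums of squares between the
model with every effect column present and the model with that term's
columns dropped, scaled by the full-model residual mean square.  The
experiment-wise critical F is the (1 - alpha) quantile of the maximum F
over a term family across phenotype permutations performed within
environment.  Effect estimates and their uncertainties come from a Gibbs
sampler with flat priors on fixed effects and inverse-gamma(0.001, 0.001)
priors on variance components.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .coding import DesignMatrices

log = logging.getLogger(__name__)

DOMINANCE_RELATED = ("D", "AD", "DA", "DD", "DE", "ADE", "DAE", "DDE")
GXE_COMPONENTS = ("AE", "DE", "AAE", "ADE", "DAE", "DDE")
ALL_COMPONENTS = ("A", "D", "AA", "AD", "DA", "DD") + GXE_COMPONENTS


# ---------------------------------------------------------------------------
# heritability aggregation (Table-1 style identities)
# ---------------------------------------------------------------------------

def aggregate_heritability(components: Mapping[str, float]) -> dict[str, float]:
    """Aggregate component heritabilities.

    ``h2_T`` is the sum of all components; ``h2_Dplus`` sums every
    dominance-containing component (D, AD, DA, DD, DE, ADE, DAE, DDE);
    ``h2_GE`` sums every environment-interaction component.  Input and
    output share whatever scale (fraction or percent) the caller uses.
    """
    bad = [k for k in components if k not in ALL_COMPONENTS]
    if bad:
        raise ValueError(f"unknown components: {bad}")
    get = lambda k: float(components.get(k, 0.0))
    return {
        "h2_T": sum(get(k) for k in ALL_COMPONENTS),
        "h2_Dplus": sum(get(k) for k in DOMINANCE_RELATED),
        "h2_GE": sum(get(k) for k in GXE_COMPONENTS),
    }


@dataclass
class HeritabilityTable:
    """Per-trait component heritabilities (percent) plus aggregates."""

    trait: str
    components: dict[str, float]

    @property
    def aggregates(self) -> dict[str, float]:
        return aggregate_heritability(self.components)

    def to_frame(self) -> pd.DataFrame:
        row = {f"h2_{k}": self.components.get(k, 0.0)
               for k in ALL_COMPONENTS}
        row.update(self.aggregates)
        return pd.DataFrame([row], index=[self.trait])


# ---------------------------------------------------------------------------
# all-effects-fixed representation for Henderson method III
# ---------------------------------------------------------------------------

def _greedy_full_rank(gram: np.ndarray, rtol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent column subset (in order)."""
    p = gram.shape[0]
    keep: list[int] = []
    diag = np.diag(gram)
    scale = diag.max() if p else 1.0
    chol = np.zeros((p, p))
    for j in range(p):
        if diag[j] <= rtol * max(scale, 1.0):
            continue
        k = len(keep)
        if k == 0:
            chol[0, 0] = math.sqrt(diag[j])
            keep.append(j)
            continue
        b = gram[np.ix_(keep, [j])].ravel()
        w = np.linalg.solve(np.tril(chol[:k, :k]), b)
        res = diag[j] - w @ w
        if res > rtol * max(diag[j], rtol * scale):
            chol[k, :k] = w
            chol[k, k] = math.sqrt(res)
            keep.append(j)
    return keep


class HendersonScan:
    """Henderson-III F tests over the all-effects-fixed representation.

    Builds one design with intercept, cofactors, the environment block and
    every genetic term column, prunes it to full rank (dropped columns are
    logged), and computes per-term F statistics from reduction-in-SS
    differences.  Permutation thresholds reuse the same cross-products, so
    thousands of permutations cost one matrix product each.
    """

    def __init__(self, dm: DesignMatrices,
                 include: Sequence[str] = ("main", "epistasis",
                                           "interaction")):
        self.dm = dm
        y = np.asarray(dm.y, dtype=float)
        blocks = [np.ones((len(y), 1)), dm.cofactors.to_numpy(float),
                  dm.env_block.to_numpy(float)]
        names = (["(intercept)"] + list(dm.cofactors.columns)
                 + list(dm.env_block.columns))
        term_cols: dict[str, tuple[str, list[int]]] = {}
        col_cursor = len(names)
        all_terms = dm.terms()
        for term, (family, cols) in all_terms.items():
            if family not in include:
                continue
            src = dm.fixed if cols[0] in dm.fixed.columns else None
            arrs = []
            for c in cols:
                if src is not None:
                    arrs.append(dm.fixed[c].to_numpy(float))
                else:
                    fam_name = c.split("@", 1)[0]
                    arrs.append(dm.random[fam_name][c].to_numpy(float))
            blocks.append(np.column_stack(arrs))
            names += cols
            term_cols[term] = (family,
                               list(range(col_cursor, col_cursor + len(cols))))
            col_cursor += len(cols)
        X = np.hstack(blocks)
        gram = X.T @ X
        keep = _greedy_full_rank(gram)
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        if dropped:
            log.info("Henderson scan: pruned %d collinear columns: %s",
                     len(dropped), [names[j] for j in dropped[:20]])
        pos = {j: k for k, j in enumerate(keep)}
        self.names = [names[j] for j in keep]
        self.X = X[:, keep]
        self.y = y
        self.n, self.p = self.X.shape
        self.gram = gram[np.ix_(keep, keep)]
        self.C = np.linalg.inv(self.gram)
        self.terms: dict[str, tuple[str, list[int]]] = {}
        self._Ctt_inv: dict[str, np.ndarray] = {}
        for term, (family, cols) in term_cols.items():
            kept_cols = [pos[j] for j in cols if j in pos]
            self.terms[term] = (family, kept_cols)
            if kept_cols:
                self._Ctt_inv[term] = np.linalg.inv(
                    self.C[np.ix_(kept_cols, kept_cols)])
        self.yty = float(y @ y)
        self.Xty = self.X.T @ y

    # -- single response ----------------------------------------------------
    def _f_for(self, Xty: np.ndarray, yty: float
               ) -> tuple[pd.DataFrame, float]:
        beta = self.C @ Xty
        r_full = float(beta @ Xty)
        df2 = self.n - self.p
        if df2 <= 0:
            raise ValueError("no residual degrees of freedom: the test is "
                             "undefined (df2 <= 0)")
        mse = max(yty - r_full, 0.0) / df2
        rows = []
        for term, (family, cols) in self.terms.items():
            if not cols:
                rows.append((term, family, 0.0, 0, df2, 1.0))
                continue
            bt = beta[cols]
            num = float(bt @ self._Ctt_inv[term] @ bt)
            df1 = len(cols)
            f = (num / df1) / mse if mse > 0 else np.inf
            pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
            rows.append((term, family, f, df1, df2, pval))
        df = pd.DataFrame(rows, columns=["term", "family", "F", "df1",
                                         "df2", "p"])
        return df, mse

    def f_tests(self) -> pd.DataFrame:
        """Observed Henderson-III F and pointwise P for every term."""
        table, _ = self._f_for(self.Xty, self.yty)
        return table

    def f_for_columns(self, cols: Sequence[str]
                      ) -> tuple[float, int, int, float]:
        """Henderson-III F for an ad-hoc group of design columns."""
        idx = [self.names.index(c) for c in cols if c in self.names]
        beta = self.C @ self.Xty
        df2 = self.n - self.p
        if df2 <= 0:
            raise ValueError("no residual degrees of freedom: the test is "
                             "undefined (df2 <= 0)")
        mse = max(self.yty - float(beta @ self.Xty), 0.0) / df2
        if not idx:
            return (0.0, 0, df2, 1.0)
        bt = beta[idx]
        num = float(bt @ np.linalg.solve(self.C[np.ix_(idx, idx)], bt))
        df1 = len(idx)
        f = (num / df1) / mse if mse > 0 else np.inf
        pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return (f, df1, df2, pval)

    def henderson_f(self, term: str) -> tuple[float, int, int, float]:
        """(F, df1, df2, pointwise P) for one term."""
        if term not in self.terms:
            raise KeyError(f"term {term!r} not in model")
        table = self.f_tests().set_index("term")
        row = table.loc[term]
        return (float(row["F"]), int(row["df1"]), int(row["df2"]),
                float(row["p"]))

    # -- permutation --------------------------------------------------------
    def _within_env_permutations(self, n_perm: int, seed: int
                                 ) -> np.ndarray:
        rng = np.random.default_rng(seed)
        env = self.dm.env
        Y = np.tile(self.y[:, None], (1, n_perm))
        for h in np.unique(env):
            rows = np.flatnonzero(env == h)
            for c in range(n_perm):
                Y[rows, c] = self.y[rows][rng.permutation(len(rows))]
        return Y

    def _exhaustive_permutations(self, limit: int = 200_000) -> np.ndarray:
        env = self.dm.env
        groups = [np.flatnonzero(env == h) for h in np.unique(env)]
        total = 1
        for g in groups:
            total *= math.factorial(len(g))
            if total > limit:
                raise ValueError(f"exhaustive enumeration infeasible "
                                 f"(> {limit} permutations)")
        cols = []
        per_group = [list(itertools.permutations(range(len(g))))
                     for g in groups]
        for combo in itertools.product(*per_group):
            y = self.y.copy()
            for g, perm in zip(groups, combo):
                y[g] = self.y[g][list(perm)]
            cols.append(y)
        return np.column_stack(cols)

    def permutation_threshold(self, n_perm: int = 2000, alpha: float = 0.05,
                              seed: int = 0, families=None,
                              exhaustive: bool = False, force: bool = False
                              ) -> "PermutationResult":
        """Experiment-wise critical F and P_EW from within-env permutations.

        ``families`` partitions terms for the max-F statistic.  The default
        is a single experiment-wise family over every tested term, which
        controls the probability that *any* term rejects at alpha; pass
        ``"reported"`` for the {main, epistasis, interaction} split used in
        per-table reporting.
        """
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if n_perm < 100 and not exhaustive:
            if not force:
                raise ValueError(f"n_perm={n_perm} < 100 gives an unstable "
                                 "threshold; pass force=True to override")
            log.warning("permutation threshold with n_perm=%d < 100", n_perm)
        if families is None or families == "experiment":
            fam_of = {t: "experiment" for t in self.terms}
        elif families == "reported":
            fam_of = {t: f for t, (f, _) in self.terms.items()}
        else:
            fam_of = dict(families)
        Y = (self._exhaustive_permutations() if exhaustive
             else self._within_env_permutations(n_perm, seed))
        n_perm = Y.shape[1]
        XtY = self.X.T @ Y                         # p x P
        Beta = self.C @ XtY
        r_full = np.einsum("ij,ij->j", Beta, XtY)
        df2 = self.n - self.p
        mse = np.maximum(self.yty - r_full, 0.0) / df2

        obs, obs_mse = self._f_for(self.Xty, self.yty)
        obs = obs.set_index("term")
        fam_names = sorted(set(fam_of.values()))
        fam_max = {f: np.zeros(n_perm) for f in fam_names}
        f_perm: dict[str, np.ndarray] = {}
        for term, (_, cols) in self.terms.items():
            if not cols:
                f_perm[term] = np.zeros(n_perm)
                continue
            Bt = Beta[cols]
            num = np.einsum("ij,ik,kj->j", Bt, self._Ctt_inv[term], Bt)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(mse > 0, (num / len(cols)) / mse, np.inf)
            f_perm[term] = f
            fam = fam_of[term]
            np.maximum(fam_max[fam], f, out=fam_max[fam])
        critical = {f: float(np.quantile(fam_max[f], 1 - alpha,
                                         method="higher"))
                    for f in fam_names}
        rows = []
        for term, (family, cols) in self.terms.items():
            fam = fam_of[term]
            f_obs = float(obs.loc[term, "F"])
            p_ew = float((1 + np.sum(fam_max[fam] >= f_obs))
                         / (n_perm + 1))
            rows.append((term, family, fam, f_obs,
                         float(obs.loc[term, "p"]), p_ew,
                         f_obs > critical[fam]))
        table = pd.DataFrame(rows, columns=[
            "term", "family", "threshold_family", "F", "p", "p_ew",
            "significant"])
        return PermutationResult(critical_f=critical, table=table,
                                 n_perm=n_perm, alpha=alpha,
                                 max_f=fam_max)


@dataclass
class PermutationResult:
    critical_f: dict[str, float]
    table: pd.DataFrame
    n_perm: int
    alpha: float
    max_f: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())

    def significant_terms(self) -> list[str]:
        return self.table.loc[self.table["significant"], "term"].tolist()


# ---------------------------------------------------------------------------
# REML + Gibbs mixed model
# ---------------------------------------------------------------------------

class FullGeneticModel(BaseEstimator):
    """Mixed linear full genetic model estimator (sklearn style).

    ``fit(dm)`` estimates fixed effects (BLUE), realized random effects
    (BLUP) and one variance component per random family by REML.
    ``gibbs()`` refines effect estimates and uncertainties by MCMC.
    Fitted attributes carry a trailing underscore.
    """

    def __init__(self, max_iter: int = 200, var_floor: float = 1e-10,
                 random_env: bool = True):
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_env = random_env

    # -- REML ---------------------------------------------------------------
    def fit(self, dm: DesignMatrices, y=None):
        self.dm_ = dm
        y = np.asarray(dm.y if y is None else y, dtype=float)
        if len(y) != dm.n_records:
            raise ValueError("response length does not match design rows")
        X = np.hstack([np.ones((len(y), 1)), dm.cofactors.to_numpy(float),
                       dm.fixed.to_numpy(float)])
        x_names = (["(intercept)"] + list(dm.cofactors.columns)
                   + list(dm.fixed.columns))
        keep = _greedy_full_rank(X.T @ X)
        self.pruned_fixed_ = [x_names[j] for j in range(X.shape[1])
                              if j not in keep]
        if self.pruned_fixed_:
            log.info("fit: pruned collinear fixed columns %s",
                     self.pruned_fixed_)
        X = X[:, keep]
        x_names = [x_names[j] for j in keep]

        z_blocks: list[np.ndarray] = []
        self.random_names_: list[str] = []
        self.random_slices_: dict[str, slice] = {}
        cursor = 0
        fam_order = []
        if self.random_env and dm.env_block.shape[1] > 1:
            fam_order.append(("env", dm.env_block))
        for fam, block in dm.random.items():
            if block.shape[1] > 0:
                fam_order.append((fam, block))
        for fam, block in fam_order:
            arr = block.to_numpy(float)
            z_blocks.append(arr)
            self.random_slices_[fam] = slice(cursor, cursor + arr.shape[1])
            self.random_names_ += list(block.columns)
            cursor += arr.shape[1]
        Z = (np.hstack(z_blocks) if z_blocks
             else np.empty((len(y), 0)))
        n, p = X.shape
        q = Z.shape[1]
        self.n_obs_, self.x_names_ = n, x_names
        self._X, self._Z, self._y = X, Z, y

        var_y = y.var() if y.var() > 0 else 1.0
        if q == 0:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = max(n - p, 1)
            self.fixed_effects_ = pd.Series(beta, index=x_names)
            self.random_effects_ = pd.Series(dtype=float)
            self.variance_components_ = {}
            self.resid_variance_ = float(resid @ resid / df)
            self.converged_ = True
            return self

        fams = [f for f, _ in fam_order]
        Gzz, Gzx, Gzy = Z.T @ Z, Z.T @ X, Z.T @ y
        Gxx, Gxy, yty = X.T @ X, X.T @ y, float(y @ y)
        q_f = {f: self.random_slices_[f].stop - self.random_slices_[f].start
               for f in fams}

        def unpack(theta):
            s2 = np.exp(theta)
            return s2[:-1], s2[-1]

        def neg_reml(theta):
            s2_fam, s2_e = unpack(theta)
            d = np.concatenate([np.full(q_f[f], s2_fam[k])
                                for k, f in enumerate(fams)])
            A = Gzz + np.diag(s2_e / d)
            try:
                cA = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return 1e12
            logdet_v = ((n - q) * math.log(s2_e) + np.sum(np.log(d))
                        + 2 * np.sum(np.log(np.diag(cA))))
            Ai = lambda M: np.linalg.solve(cA.T, np.linalg.solve(cA, M))
            xvx = (Gxx - Gzx.T @ Ai(Gzx)) / s2_e
            xvy = (Gxy - Gzx.T @ Ai(Gzy)) / s2_e
            yvy = (yty - Gzy @ Ai(Gzy)) / s2_e
            sign, logdet_xvx = np.linalg.slogdet(xvx)
            if sign <= 0:
                return 1e12
            try:
                b = np.linalg.solve(xvx, xvy)
            except np.linalg.LinAlgError:
                return 1e12
            ypy = yvy - xvy @ b
            return 0.5 * (logdet_v + logdet_xvx + max(ypy, 0.0))

        theta0 = np.log(np.full(len(fams) + 1, var_y / (len(fams) + 1)))
        bounds = [(math.log(var_y) - 25, math.log(var_y) + 6)] * len(theta0)
        res = optimize.minimize(neg_reml, theta0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": self.max_iter})
        if not res.success:
            # polish with a derivative-free pass; L-BFGS-B on log-variance
            # surfaces often stalls at the boundary with ABNORMAL status
            res2 = optimize.minimize(
                neg_reml, res.x, method="Nelder-Mead",
                options={"maxiter": 200 * len(theta0), "fatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
        self.converged_ = bool(res.success)
        if not res.success:
            log.warning("REML optimizer did not report convergence: %s",
                        res.message)
        s2_fam, s2_e = unpack(res.x)
        self.variance_components_ = {
            f: float(max(s2_fam[k], 0.0)) for k, f in enumerate(fams)}
        self.resid_variance_ = float(s2_e)
        self.loglik_ = -float(res.fun)

        d = np.concatenate([np.full(q_f[f], s2_fam[k])
                            for k, f in enumerate(fams)])
        A = Gzz + np.diag(s2_e / d)
        cA = np.linalg.cholesky(A)
        Ai = lambda M: np.linalg.solve(cA.T, np.linalg.solve(cA, M))
        xvx = (Gxx - Gzx.T @ Ai(Gzx)) / s2_e
        xvy = (Gxy - Gzx.T @ Ai(Gzy)) / s2_e
        beta = np.linalg.solve(xvx, xvy)
        zr = Gzy - Gzx @ beta
        u = d * ((zr - Gzz @ Ai(zr)) / s2_e)
        self.fixed_effects_ = pd.Series(beta, index=x_names)
        self.random_effects_ = pd.Series(u, index=self.random_names_)
        return self

    # -- predictions and tests ----------------------------------------------
    def predict(self, dm: DesignMatrices | None = None) -> np.ndarray:
        """Fitted values (fixed plus realized random effects)."""
        self._check_fitted()
        dm = self.dm_ if dm is None else dm
        yhat = np.zeros(dm.n_records)
        X = np.hstack([np.ones((dm.n_records, 1)),
                       dm.cofactors.to_numpy(float),
                       dm.fixed.to_numpy(float)])
        names = (["(intercept)"] + list(dm.cofactors.columns)
                 + list(dm.fixed.columns))
        b = self.fixed_effects_.reindex(names).fillna(0.0).to_numpy()
        yhat += X @ b
        for fam, block in list(dm.random.items()) + [("env", dm.env_block)]:
            if fam == "env" and "env" not in self.random_slices_:
                continue
            cols = [c for c in block.columns if c in self.random_effects_]
            if cols:
                yhat += block[cols].to_numpy(float) @ \
                    self.random_effects_[cols].to_numpy()
        return yhat

    def _check_fitted(self):
        if not hasattr(self, "fixed_effects_"):
            raise RuntimeError("FullGeneticModel is not fitted")

    def henderson_scan(self, include=("main", "epistasis", "interaction")
                       ) -> HendersonScan:
        self._check_fitted()
        return HendersonScan(self.dm_, include=include)

    # -- Gibbs --------------------------------------------------------------
    def gibbs(self, n_iter: int = 20000, burn_in: int = 2000,
              thin: int = 5, seed: int = 0,
              prior_a: float = 0.001, prior_b: float = 0.001
              ) -> pd.DataFrame:
        """Gibbs-sample effects; returns a posterior summary table.

        Flat priors on fixed effects; inverse-gamma(prior_a, prior_b) on
        each variance component.  Deterministic under ``seed``.  A
        split-half convergence ratio is computed per parameter and a
        warning logged when it exceeds 1.1.  A (near-)zero residual
        variance degenerates the posterior, in which case the exact
        REML/BLUE solution is returned with zero spread (logged).
        """
        self._check_fitted()
        if n_iter <= burn_in:
            raise ValueError("n_iter must exceed burn_in")
        X, Z, y = self._X, self._Z, self._y
        n, p = X.shape
        q = Z.shape[1]
        var_y = y.var() if y.var() > 0 else 1.0
        if self.resid_variance_ < 1e-10 * var_y or (q == 0 and n <= p):
            log.info("gibbs: degenerate residual posterior; returning the "
                     "exact solution")
            est = pd.concat([self.fixed_effects_, self.random_effects_])
            return self._summary_frame(est, pd.Series(0.0, index=est.index))

        rng = np.random.default_rng(seed)
        W = np.hstack([X, Z]) if q else X
        G = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)
        fams = list(self.random_slices_)
        sl = {f: slice(self.random_slices_[f].start + p,
                       self.random_slices_[f].stop + p) for f in fams}
        Gxx = G[:p, :p]
        cxx = np.linalg.cholesky(Gxx + 1e-12 * np.eye(p) * np.trace(Gxx))
        theta = np.concatenate([
            self.fixed_effects_.to_numpy(),
            self.random_effects_.to_numpy() if q else np.empty(0)])
        s2_f = {f: max(self.variance_components_[f], 1e-8 * var_y)
                for f in fams}
        s2_e = max(self.resid_variance_, 1e-8 * var_y)

        n_kept = (n_iter - burn_in) // thin
        draws = np.empty((n_kept, p + q))
        var_draws = np.empty((n_kept, len(fams) + 1))
        kept = 0
        for it in range(n_iter):
            # fixed block
            rhs = Wty[:p] - G[:p, p:] @ theta[p:] if q else Wty[:p]
            mean = np.linalg.solve(cxx.T, np.linalg.solve(cxx, rhs))
            z = rng.standard_normal(p)
            theta[:p] = mean + math.sqrt(s2_e) * \
                np.linalg.solve(cxx.T, z)
            # random families
            for f in fams:
                s = sl[f]
                qf = s.stop - s.start
                Af = G[s, s] + (s2_e / s2_f[f]) * np.eye(qf)
                cf = np.linalg.cholesky(Af)
                others = np.r_[0:s.start, s.stop:p + q]
                rhs = Wty[s] - G[s][:, others] @ theta[others]
                mean = np.linalg.solve(cf.T, np.linalg.solve(cf, rhs))
                z = rng.standard_normal(qf)
                theta[s] = mean + math.sqrt(s2_e) * \
                    np.linalg.solve(cf.T, z)
                ssq = float(theta[s] @ theta[s])
                s2_f[f] = 1.0 / rng.gamma(prior_a + qf / 2.0,
                                          1.0 / (prior_b + ssq / 2.0))
            sse = max(yty - 2 * theta @ Wty + theta @ G @ theta, 1e-30)
            s2_e = 1.0 / rng.gamma(prior_a + n / 2.0,
                                   1.0 / (prior_b + sse / 2.0))
            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_kept:
                draws[kept] = theta
                var_draws[kept] = [s2_f[f] for f in fams] + [s2_e]
                kept += 1
        draws = draws[:kept]
        var_draws = var_draws[:kept]

        half = kept // 2
        if half >= 10:
            m1, m2 = draws[:half].mean(0), draws[half:].mean(0)
            sd = draws.std(0)
            drift = np.abs(m1 - m2) / np.where(sd > 0, sd, np.inf)
            if np.nanmax(drift) > 0.5:
                log.warning("gibbs: split-half mean drift up to %.2f sd; "
                            "chains may not have converged",
                            float(np.nanmax(drift)))
        names = list(self.fixed_effects_.index) + self.random_names_
        est = pd.Series(draws.mean(0), index=names)
        sd = pd.Series(draws.std(0, ddof=1), index=names)
        self.posterior_variances_ = dict(
            zip(fams + ["residual"], var_draws.mean(0)))
        self.posterior_ = self._summary_frame(est, sd)
        return self.posterior_

    def _summary_frame(self, est: pd.Series, sd: pd.Series) -> pd.DataFrame:
        fam_of = []
        for t in est.index:
            if t == "(intercept)":
                fam_of.append("mu")
            elif t.startswith("pc"):
                fam_of.append("cofactor")
            elif t.startswith("e@"):
                fam_of.append("env")
            else:
                fam_of.append(t.split("@", 1)[0])
        return pd.DataFrame({"term": est.index, "family": fam_of,
                             "estimate": est.to_numpy(),
                             "sd": sd.reindex(est.index).to_numpy()}
                            ).reset_index(drop=True)

    # -- heritability --------------------------------------------------------
    def heritability(self, use_posterior: bool = True,
                     trait: str = "trait") -> HeritabilityTable:
        """Partition phenotypic variance into the 12 component shares.

        Each share is the variance, across the observed records, of the
        term family's predicted contribution, divided by the observed
        phenotypic variance; reported in percent.
        """
        self._check_fitted()
        dm = self.dm_
        total = float(np.var(self._y))
        if total <= 0:
            raise ValueError("total phenotypic variance is zero")
        if use_posterior and hasattr(self, "posterior_"):
            est = self.posterior_.set_index("term")["estimate"]
        else:
            est = pd.concat([self.fixed_effects_, self.random_effects_])
        comps: dict[str, float] = {}
        fixed_map = {"A": "a", "D": "d", "AA": "aa", "AD": "ad",
                     "DA": "da", "DD": "dd"}
        for comp, prefix in fixed_map.items():
            cols = [c for c in dm.fixed.columns
                    if c.split("@", 1)[0] == prefix and c in est.index]
            contrib = (dm.fixed[cols].to_numpy(float)
                       @ est[cols].to_numpy()) if cols else np.zeros(1)
            comps[comp] = 100.0 * float(np.var(contrib)) / total
        rand_map = {"AE": "ae", "DE": "de", "AAE": "aae", "ADE": "ade",
                    "DAE": "dae", "DDE": "dde"}
        for comp, fam in rand_map.items():
            block = dm.random.get(fam)
            if block is None or block.shape[1] == 0:
                comps[comp] = 0.0
                continue
            cols = [c for c in block.columns if c in est.index]
            contrib = (block[cols].to_numpy(float) @ est[cols].to_numpy()) \
                if cols else np.zeros(1)
            comps[comp] = 100.0 * float(np.var(contrib)) / total
        return HeritabilityTable(trait=trait, components=comps)

    # -- per-environment effect export (heat-map style table) ---------------
    def per_env_effects(self) -> pd.DataFrame:
        """Locus x environment total effect matrix (a + ae_h per locus)."""
        self._check_fitted()
        est = (self.posterior_.set_index("term")["estimate"]
               if hasattr(self, "posterior_")
               else pd.concat([self.fixed_effects_, self.random_effects_]))
        envs = sorted(np.unique(self.dm_.env))
        rows = {}
        for s in self.dm_.loci:
            a = float(est.get(f"a@{s}", 0.0))
            rows[s] = [a + float(est.get(f"ae@{s}:{h}", 0.0))
                       for h in envs]
        return pd.DataFrame(rows, index=[f"env{h}" for h in envs]).T


# ---------------------------------------------------------------------------
# thin functional wrappers (spec-level operation names)
# ---------------------------------------------------------------------------

def fit_full_model(dm: DesignMatrices, y=None, **params) -> FullGeneticModel:
    return FullGeneticModel(**params).fit(dm, y=y)


def henderson_f(fitted: FullGeneticModel | HendersonScan, term: str
                ) -> tuple[float, int, int, float]:
    scan = fitted if isinstance(fitted, HendersonScan) \
        else fitted.henderson_scan()
    return scan.henderson_f(term)


def permutation_threshold(dm: DesignMatrices, n_perm: int = 2000,
                          alpha: float = 0.05, seed: int = 0,
                          families=None, exhaustive: bool = False,
                          force: bool = False,
                          include=("main", "epistasis", "interaction")
                          ) -> PermutationResult:
    scan = HendersonScan(dm, include=include)
    return scan.permutation_threshold(n_perm=n_perm, alpha=alpha, seed=seed,
                                      families=families,
                                      exhaustive=exhaustive, force=force)


def gibbs_estimate(fitted: FullGeneticModel, n_iter: int = 20000,
                   burn_in: int = 2000, thin: int = 5, seed: int = 0
                   ) -> pd.DataFrame:
    return fitted.gibbs(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)


def heritability(fitted: FullGeneticModel, trait: str = "trait"
                 ) -> HeritabilityTable:
    return fitted.heritability(trait=trait)
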