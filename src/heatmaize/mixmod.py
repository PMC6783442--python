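"""REML machinery for the trial mixed models.

The engine fits y = X beta + sum_k Z_k u_k + e with independent random
factors u_k ~ N(0, sigma2_k I) and e ~ N(0, sigma2_e I) by average-
information (AI) REML with an EM fallback, working throughout on the
Henderson mixed-model equations so the cost scales with the number of
effect levels rather than the number of observations.  Fixed effects are
the generalized least squares solution at the converged variances.

Model wrappers cover the three trial models: the two-heat-level model with
a fixed condition effect (condition test), the single-condition model with
fixed genotypes (adjusted entry means), and the genotype-as-random variants
used for variance components and heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Model formula for a long-format phenotype table.

    Factors are column names, or ':'-joined column names for nested /
    interaction terms (e.g. ``"block:replicate"`` is block within
    replicate).  A factor may appear as fixed or random, not both.
    """

    response: str = "value"
    fixed: Sequence[str] = field(default_factory=list)
    random: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.fixed) & set(self.random)
        if overlap:
            raise ValueError(f"factors cannot be fixed and random: {sorted(overlap)}")


@dataclass
class VarianceComponents:
    """Named non-negative REML variance estimates with fit diagnostics."""

    variances: Mapping[str, float]
    loglik: float
    converged: bool
    n_iter: int = 0

    def __getitem__(self, key):
        return self.variances[key]


@dataclass
class REMLResult:
    varcomp: VarianceComponents
    beta: pd.Series
    beta_cov: pd.DataFrame
    blups: Mapping[str, pd.Series]
    spec: ModelSpec
    n_obs: int


def _factor_levels(data: pd.DataFrame, term: str):
    cols = term.split(":")
    if len(cols) == 1:
        codes, levels = pd.factorize(data[cols[0]], sort=True)
        return codes, [str(v) for v in levels]
    key = data[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "\x1f" + data[c].astype(str)
    codes, levels = pd.factorize(key, sort=True)
    return codes, [lv.replace("\x1f", ":") for lv in levels]


def _fixed_design(data: pd.DataFrame, fixed: Sequence[str]):
    """Intercept + drop-last dummy coding; aliased columns dropped
    deterministically (later columns first)."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in fixed:
        codes, levels = _factor_levels(data, term)
        for j, lv in enumerate(levels[:-1]):  # last-level drop
            cols.append((codes == j).astype(float))
            names.append(f"{term}[{lv}]")
    X = np.column_stack(cols)
    # rank check: drop columns linearly dependent on earlier ones
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * max(diag.max(), 1.0)
    if X.shape[1] > len(diag):  # more columns than rows
        keep = np.concatenate([keep, np.zeros(X.shape[1] - len(diag), bool)])
    if not keep.all():
        dropped = [names[j] for j in np.where(~keep)[0]]
        logger.warning("dropping aliased fixed-effect columns: %s", dropped)
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    return X, names


def _random_design(data: pd.DataFrame, term: str):
    codes, levels = _factor_levels(data, term)
    n = len(data)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return Z, levels


def reml_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> REMLResult:
    """Fit the mixed model by MME-based AI-REML with EM fallback.

    Negative variance estimates are clamped at zero (the component is
    pinned and removed from the working model).  Convergence is declared
    when the relative REML log-likelihood change drops below ``tol``;
    non-convergence is flagged on the result, not raised.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        data = data.loc[keep]
        y = y[keep]
    n = len(y)
    X, xnames = _fixed_design(data, spec.fixed)
    p = X.shape[1]
    if n - p < 1:
        raise ValueError("design leaves no residual degree of freedom")

    Zs, levels = [], {}
    for term in spec.random:
        Z, lv = _random_design(data, term)
        Zs.append(Z)
        levels[term] = lv

    vy = float(np.var(y))
    if vy < 1e-14 * (1.0 + float(np.mean(y)) ** 2):
        # constant response: all variances zero, mean = the constant
        beta = np.zeros(p)
        beta[0] = y[0] if n else 0.0
        vc = VarianceComponents(
            {**{t: 0.0 for t in spec.random}, "residual": 0.0}, 0.0, True, 0
        )
        return REMLResult(
            vc,
            pd.Series(beta, index=xnames),
            pd.DataFrame(np.zeros((p, p)), index=xnames, columns=xnames),
            {t: pd.Series(0.0, index=levels[t]) for t in spec.random},
            spec,
            n,
        )

    engine = _MMEngine(y, X, Zs)
    theta, loglik, converged, n_iter = engine.estimate(vy, max_iter, tol)
    beta, beta_cov, u_list = engine.solve_effects(theta)

    variances = {term: float(theta[k]) for k, term in enumerate(spec.random)}
    variances["residual"] = float(theta[-1])
    blups = {
        term: pd.Series(u_list[k], index=levels[term]) for k, term in enumerate(spec.random)
    }
    return REMLResult(
        VarianceComponents(variances, float(loglik), converged, n_iter),
        pd.Series(beta, index=xnames),
        pd.DataFrame(beta_cov, index=xnames, columns=xnames),
        blups,
        spec,
        n,
    )


class _MMEngine:
    """Mixed-model-equation workhorse for i.i.d. random factors."""

    def __init__(self, y, X, Zs):
        self.y = y
        self.X = X
        self.Zs =Zs
        self.n, self.p = X.shape
        self.q = [Z.shape[1] for Z in Zs]
        self.K = len(Zs)
        W = sparse.hstack([sparse.csr_matrix(X)] + Zs, format="csr") if Zs else sparse.csr_matrix(X)
        self.W = W
        self.WtW = np.asarray((W.T @ W).todense())
        self.Wty = np.asarray(W.T @ y).ravel()
        self.yty = float(y @ y)

    def _assemble(self, gammas, s2, active):
        """Cholesky of the MME matrix for the active components."""
        idx = list(range(self.p))
        off = self.p
        dvals = []
        for k in range(self.K):
            if active[k]:
                idx.extend(range(off, off + self.q[k]))
                dvals.extend([1.0 / gammas[k]] * self.q[k])
            off += self.q[k]
        idx = np.array(idx)
        C = self.WtW[np.ix_(idx, idx)] / s2
        d = np.concatenate([np.zeros(self.p), np.array(dvals)]) if dvals else np.zeros(self.p)
        C[np.arange(len(idx)), np.arange(len(idx))] += d
        return cho_factor(C, lower=True), idx

    def _loglik(self, gammas, s2, active):
        cf, idx = self._assemble(gammas, s2, active)
        rhs = self.Wty[idx] / s2
        sol = cho_solve(cf, rhs)
        yPy = (self.yty - sol @ self.Wty[idx]) / s2
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (
            self.n * np.log(s2)
            + sum(self.q[k] * np.log(gammas[k]) for k in range(self.K) if active[k])
            + logdetC
            + yPy
        )
        return ll, (cf, idx, sol)

    def _derivatives(self, gammas, s2, active, state):
        """Scores and AI matrix for active components + residual."""
        cf, idx, sol = state
        Wact = self.W[:, idx]
        e_hat = self.y - Wact @ sol
        Py = e_hat / s2
        Cinv = cho_solve(cf, np.eye(len(idx)))

        act = [k for k in range(self.K) if active[k]]
        scores = []
        fvecs = []
        # offsets of each active u-block inside the active system
        off = self.p
        block = {}
        for k in act:
            block[k] = (off, off + self.q[k])
            off += self.q[k]

        tr_sum = 0.0
        for k in act:
            a, b = block[k]
            u_k = sol[a:b]
            g = gammas[k]
            trCkk = float(np.trace(Cinv[a:b, a:b]))
            trPZZ = self.q[k] / g - trCkk / g**2
            yPVPy = float(u_k @ u_k) / g**2
            scores.append(-0.5 * (trPZZ - yPVPy))
            Zk = self.Zs[k]
            fvecs.append(np.asarray(Zk @ (Zk.T @ Py)).ravel())
            tr_sum += g * trPZZ
        trP = ((self.n - self.p) - tr_sum) / s2
        yPPy = float(Py @ Py)
        scores.append(-0.5 * (trP - yPPy))
        fvecs.append(Py)

        # AI_{kl} = 0.5 f_k' P f_l via an MME solve for each f
        m = len(fvecs)
        Pf = []
        for f in fvecs:
            rhs = np.asarray(Wact.T @ f).ravel() / s2
            sol_f = cho_solve(cf, rhs)
            Pf.append((f - Wact @ sol_f) / s2)
        AI = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                AI[i, j] = AI[j, i] = 0.5 * float(fvecs[i] @ Pf[j])
        return np.array(scores), AI, act, trP, yPPy, block, sol

    def estimate(self, vy, max_iter, tol):
        K = self.K
        gammas = np.full(K, vy / (K + 1.0)) if K else np.empty(0)
        s2 = vy / (K + 1.0) if K else vy
        active = [True] * K
        floor = 1e-10 * vy
        s2_floor = 1e-12 * vy

        ll, state = self._loglik(gammas, s2, active)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            scores, AI, act, trP, yPPy, block, sol = self._derivatives(
                gammas, s2, active, state
            )
            theta_act = np.array([gammas[k] for k in act] + [s2])

            # EM proposal (guaranteed uphill)
            em = theta_act.copy()
            for pos, k in enumerate(act):
                g = gammas[k]
                a, b = block[k]
                u_k = sol[a:b]
                yPVPy = float(u_k @ u_k) / g**2
                trPZZ = yPVPy - 2.0 * scores[pos]  # score = -(tr - yPVPy)/2
                em[pos] = g + g**2 * (yPVPy - trPZZ) / self.q[k]
            em[-1] = s2 + s2**2 * (yPPy - trP) / self.n
            em = np.maximum(em, floor)

            # AI proposal with step halving into the feasible region
            proposal = None
            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(len(AI)), scores)
                step = 1.0
                for _ in range(12):
                    cand = theta_act + step * delta
                    if (cand[:-1] > -floor).all() and cand[-1] > s2_floor:
                        proposal = np.maximum(cand, floor)
                        proposal[-1] = max(cand[-1], s2_floor)
                        break
                    step /= 2.0
            except np.linalg.LinAlgError:
                pass

            best = None
            for cand in ([proposal] if proposal is not None else []) + [em]:
                g_new = gammas.copy()
                for pos, k in enumerate(act):
                    g_new[k] = cand[pos]
                s2_new = cand[-1]
                ll_new, state_new = self._loglik(g_new, s2_new, active)
                if np.isfinite(ll_new) and (best is None or ll_new > best[0]):
                    best = (ll_new, g_new, s2_new, state_new)
                if best is not None and best[0] >= ll - 1e-10:
                    break  # AI step already uphill; skip EM evaluation
            ll_new, gammas, s2, state = best

            # pin components collapsing onto the zero boundary
            pinned = False
            for k in list(act):
                if active[k] and gammas[k] <= 2.0 * floor:
                    gammas[k] = 0.0
                    active[k] = False
                    pinned = True
            if pinned:
                ll_new, state = self._loglik(gammas, s2, active)

            if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        return np.concatenate([gammas, [s2]]), ll, converged, it

    def solve_effects(self, theta):
        gammas, s2 = theta[:-1], theta[-1]
        active = [g > 0 for g in gammas]
        if s2 <= 0:
            s2 = 1e-12
        cf, idx = self._assemble(gammas, s2, active)
        sol = cho_solve(cf, self.Wty[idx] / s2)
        Cinv_beta = cho_solve(cf, np.eye(len(idx)))[: self.p, : self.p]
        beta = sol[: self.p]
        u_list = []
        off = self.p
        for k in range(self.K):
            if active[k]:
                u_list.append(sol[off : off + self.q[k]])
                off += self.q[k]
            else:
                u_list.append(np.zeros(self.q[k]))
        return beta, Cinv_beta, u_list


# ---------------------------------------------------------------------------
# closed forms and model wrappers
# ---------------------------------------------------------------------------

def oneway_balanced_reml(y_wide: np.ndarray):
    """Exact REML variance components for a balanced one-way random layout.

    ``y_wide`` is genotypes x replicates.  On balanced data REML equals the
    ANOVA method-of-moments estimators truncated at zero.
    """
    g, r = y_wide.shape
    gm = y_wide.mean(axis=1)
    grand = y_wide.mean()
    ms_g = r * np.sum((gm - grand) ** 2) / (g - 1)
    ms_e = np.sum((y_wide - gm[:, None]) ** 2) / (g * (r - 1))
    s2g = (ms_g - ms_e) / r
    if s2g >= 0:
        return float(s2g), float(ms_e)
    # genotype variance pinned at zero: residual is the pooled variance
    return 0.0, float(np.sum((y_wide - grand) ** 2) / (g * r - 1))


def condition_effect_test(data: pd.DataFrame, trait: str) -> float:
    """Wald F p-value for the heat-level fixed effect in the two-condition
    model (random genotype, genotype x condition, replicate and block
    within condition).  Denominator degrees of freedom follow the
    containment rule: number of replicate-within-condition levels minus 2.
    """
    sub = data[data["trait"] == trait]
    conds = sub["condition"].unique()
    if len(conds) < 2:
        raise ValueError("condition test needs both heat levels")
    spec = ModelSpec(
        response="value",
        fixed=["condition"],
        random=["genotype", "genotype:condition", "replicate:condition", "block:replicate:condition"],
    )
    res = reml_fit(sub, spec)
    cname = [c for c in res.beta.index if c.startswith("condition[")]
    b = res.beta[cname].to_numpy()
    V = res.beta_cov.loc[cname, cname].to_numpy()
    if np.allclose(b, 0.0):
        return 1.0
    df1 = len(cname)
    df2 = sub.groupby(["condition", "replicate"]).ngroups - 2
    F = float(b @ np.linalg.solve(V, b)) / df1
    return float(f_dist.sf(F, df1, max(df2, 1)))


@dataclass
class AEMTable:
    """Adjusted entry means per genotype and condition."""

    table: pd.DataFrame  # columns: genotype, condition, trait, aem

    def across(self, condition: str, trait: str) -> float:
        sel = self.table[(self.table["condition"] == condition) & (self.table["trait"] == trait)]
        return float(sel["aem"].mean())

    def wide(self, trait: str) -> pd.DataFrame:
        sel = self.table[self.table["trait"] == trait]
        return sel.pivot(index="genotype", columns="condition", values="aem")


def adjusted_entry_means(data: pd.DataFrame, condition: str, trait: str) -> pd.DataFrame:
    """AEM for one condition: genotype and replicate fixed, block random.

    Returns a DataFrame (genotype, condition, trait, aem) where the AEM is
    the estimated marginal mean: intercept + genotype effect averaged over
    replicate effects.
    """
    sub = data[(data["condition"] == condition) & (data["trait"] == trait)]
    if sub.empty:
        raise ValueError(f"no data for condition {condition!r}, trait {trait!r}")
    spec = ModelSpec(response="value", fixed=["genotype", "replicate"], random=["block:replicate"])
    res = reml_fit(sub, spec)
    genos = sorted(sub["genotype"].unique(), key=str)
    reps = sorted(sub["replicate"].unique(), key=str)
    beta = res.beta
    rep_cols = [c for c in beta.index if c.startswith("replicate[")]
    rep_avg = float(beta[rep_cols].sum()) / len(reps) if reps else 0.0
    rows = []
    for g in genos:
        cname = f"genotype[{g}]"
        eff = float(beta[cname]) if cname in beta.index else 0.0
        rows.append((g, condition, trait, float(beta["(Intercept)"]) + eff + rep_avg))
    return pd.DataFrame(rows, columns=["genotype", "condition", "trait", "aem"])


def aem_table(data: pd.DataFrame, traits: Sequence[str] | None = None) -> AEMTable:
    """Adjusted entry means for every trait under both conditions."""
    if traits is None:
        traits = list(dict.fromkeys(data["trait"]))
    parts = []
    for t in traits:
        for cond in dict.fromkeys(data["condition"]):
            parts.append(adjusted_entry_means(data, cond, t))
    return AEMTable(pd.concat(parts, ignore_index=True))


def genotype_variance_components(
    data: pd.DataFrame, condition: str, trait: str
) -> VarianceComponents:
    """Variance components with genotype random (single-condition model)."""
    sub = data[(data["condition"] == condition) & (data["trait"] == trait)]
    spec = ModelSpec(
        response="value", fixed=["replicate"], random=["genotype", "block:replicate"]
    )
    res = reml_fit(sub, spec)
    v = dict(res.varcomp.variances)
    v["sigma2_g"] = v.pop("genotype")
    v["sigma2_e"] = v.pop("residual")
    return VarianceComponents(v, res.varcomp.loglik, res.varcomp.converged, res.varcomp.n_iter)


def heritability(vc: VarianceComponents, n_replicates: int) -> float:
    """Entry-mean broad-sense heritability sigma2_g / (sigma2_g + sigma2_e/r)."""
    s2g = vc.variances.get("sigma2_g", vc.variances.get("genotype"))
    s2e = vc.variances.get("sigma2_e", vc.variances.get("residual"))
    if s2g is None or s2e is None:
        raise ValueError("need sigma2_g and sigma2_e")
    denom = s2g + s2e / n_replicates
    if denom <= 0:
        return float("nan")
    return float(s2g / denom)
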