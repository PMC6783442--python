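"""GBLUP genome-wide prediction and training-set resampling schemes.

The genetic model is y = 1 mu + u + e with u ~ N(0, K sigma2_u) for a
realised kinship K (additive only, M_A, or additive plus an independent
dominance component, M_AD) and e ~ N(0, I sigma2).  Variances are REML
estimates; validation genotypes are predicted through their genomic
relationship with the training set.  Prediction ability is the Pearson
correlation r(y, y_hat) in the validation set; medians are used to
aggregate over resampling rounds throughout.

Resampling schemes: stratified five-fold cross-validation (r_a,cv and
r_pop,cv), a within-population training-size bootstrap (r_pop,BSPw), the
between-population training-composition scenarios TS1/TS2/TS3 with their
sub-scenarios (r_pop,BSPb), and a marker-number subsampling curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .datatypes import CrossingScheme, GenotypeMatrix
from .diversity import KinshipMatrix, additive_kinship

logger = logging.getLogger(__name__)


@dataclass
class GBLUPFit:
    """Converged GBLUP fit with predictions for every individual in K."""

    mu: float
    variances: Mapping[str, float]
    genetic_values: pd.Series  # BLUP of the total genetic effect, all ids
    predictions: pd.Series  # mu + genetic value
    train_ids: list
    converged: bool


@dataclass
class ScenarioSpec:
    """One between-population training-composition scenario."""

    name: str
    validation: str
    constituents: Sequence[str]
    size: int = 50
    rounds: int = 500


@dataclass
class PredictionSummary:
    """Per-round prediction abilities and their median."""

    label: str
    per_round: pd.DataFrame
    median: float
    meta: dict = field(default_factory=dict)


def _check_psd(k: KinshipMatrix):
    if getattr(k, "_psd_ok", False):
        return
    if k.min_eigenvalue() < -1e-6:
        raise ValueError(f"{k.flavor} kinship matrix is not positive semidefinite")
    k._psd_ok = True


def fit_gblup(
    y: pd.Series,
    kinships: Sequence[KinshipMatrix],
    train_ids: Sequence[str] | None = None,
    weights: pd.Series | None = None,
    fixed_variances: Mapping[str, float] | None = None,
) -> GBLUPFit:
    """Fit GBLUP on the training genotypes and predict all individuals.

    ``y`` holds phenotypes for (at least) the training ids; ``kinships``
    is one (M_A) or two (M_AD) relationship matrices covering training and
    validation ids alike.  ``weights`` gives per-training-record weights
    (residual variance sigma2/w, used for collapsed bootstrap duplicates).
    ``fixed_variances`` skips REML (keys: flavors plus 'residual').
    """
    if not kinships:
        raise ValueError("need at least one kinship matrix")
    ids = kinships[0].ids
    for k in kinships[1:]:
        if k.ids != ids:
            raise ValueError("kinship matrices must share the same individuals")
    for k in kinships:
        _check_psd(k)
    if train_ids is None:
        train_ids = [i for i in ids if i in y.index and np.isfinite(y[i])]
    train_ids = list(train_ids)
    pos = {g: j for j, g in enumerate(ids)}
    t = np.array([pos[g] for g in train_ids])
    yt = y.loc[train_ids].to_numpy(dtype=float)
    if len(yt) < 3:
        raise ValueError("need at least three training genotypes")
    if np.var(yt) < 1e-14:
        raise ValueError("zero phenotypic variance in the training set")
    w = (
        weights.loc[train_ids].to_numpy(dtype=float)
        if weights is not None
        else np.ones(len(t))
    )
    Ks_tt = [k.to_numpy()[np.ix_(t, t)] for k in kinships]

    if fixed_variances is not None:
        sigmas = [float(fixed_variances[k.flavor]) for k in kinships]
        s2e = float(fixed_variances["residual"])
        converged = True
    elif len(kinships) == 1:
        sigmas, s2e, converged = _reml_single(yt, Ks_tt[0], w)
        sigmas = [sigmas]
    else:
        sigmas, s2e, converged = _reml_multi(yt, Ks_tt, w)

    V = s2e * np.diag(1.0 / w)
    for s, Ktt in zip(sigmas, Ks_tt):
        V += s * Ktt
    cf = cho_factor(V, lower=True)
    one = np.ones(len(t))
    Vi1 = cho_solve(cf, one)
    mu = float(one @ cho_solve(cf, yt) / (one @ Vi1))
    alpha = cho_solve(cf, yt - mu)
    gv = np.zeros(len(ids))
    variances = {}
    for s, k in zip(sigmas, kinships):
        gv += s * (k.to_numpy()[:, t] @ alpha)
        variances[k.flavor] = float(s)
    variances["residual"] = float(s2e)
    gv = pd.Series(gv, index=ids)
    return GBLUPFit(mu, variances, gv, mu + gv, train_ids, converged)


def _reml_single(y, K, w):
    """Exact profile REML for one kinship via eigendecomposition.

    Works in the whitened space sqrt(w)-scaled so the residual is iid; the
    variance ratio lambda = sigma2_u / sigma2_e is optimised on a log grid
    refined by bounded scalar minimisation.
    """
    s = np.sqrt(w)
    Kt = K * np.outer(s, s)
    yt = y * s
    xt = s.copy()  # transformed intercept column
    d, U = eigh(Kt)
    d = np.clip(d, 0.0, None)
    yr = U.T @ yt
    xr = U.T @ xt
    n = len(y)

    def neg_profile(log_lam):
        lam = 10.0**log_lam
        m = lam * d + 1.0
        xvx = np.sum(xr**2 / m)
        beta = np.sum(xr * yr / m) / xvx
        r = yr - beta * xr
        ypy = np.sum(r**2 / m)
        s2e = ypy / (n - 1)
        ll = -0.5 * (np.sum(np.log(m)) + np.log(xvx) + (n - 1) * np.log(s2e))
        return -ll

    grid = np.linspace(-4, 4, 17)
    best = min(grid, key=neg_profile)
    res = minimize_scalar(
        neg_profile, bounds=(best - 1.0, best + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = 10.0**res.x
    m = lam * d + 1.0
    xvx = np.sum(xr**2 / m)
    beta = np.sum(xr * yr / m) / xvx
    ypy = np.sum((yr - beta * xr) ** 2 / m)
    s2e = float(ypy / (n - 1))
    return float(lam * s2e), s2e, True


def _reml_multi(y, Ks, w, max_iter=100, tol=1e-8):
    """Dense AI-REML with EM fallback for several covariance structures."""
    n = len(y)
    X = np.ones((n, 1))
    Gs = [K for K in Ks] + [np.diag(1.0 / w)]
    vy = float(np.var(y))
    theta = np.full(len(Gs), vy / len(Gs))
    floor = 1e-8 * vy

    def loglik(th):
        V = sum(t * G for t, G in zip(th, Gs))
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None
        Vi = cho_solve(cf, np.eye(n))
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XVX, X.T @ Vi)
        ll = -0.5 * (
            2.0 * np.sum(np.log(np.diag(cf[0])))
            + np.log(XVX[0, 0])
            + float(y @ P @ y)
        )
        return ll, P

    ll, P = loglik(theta)
    converged = False
    for _ in range(max_iter):
        Py = P @ y
        scores = np.empty(len(Gs))
        fv = []
        for k, G in enumerate(Gs):
            GPy = G @ Py
            scores[k] = -0.5 * (np.sum(P * G) - float(Py @ GPy))
            fv.append(GPy)
        AI = np.empty((len(Gs), len(Gs)))
        Pf = [P @ f for f in fv]
        for i in range(len(Gs)):
            for j in range(i, len(Gs)):
                AI[i, j] = AI[j, i] = 0.5 * float(fv[i] @ Pf[j])
        # EM proposal
        em = theta.copy()
        for k in range(len(Gs)):
            q_eff = n
            em[k] = theta[k] + theta[k] ** 2 * (2.0 * scores[k]) / q_eff
        em = np.maximum(em, floor)
        proposal = None
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(len(Gs)), scores)
            step = 1.0
            for _ in range(10):
                cand = theta + step * delta
                if (cand > 0).all():
                    proposal = cand
                    break
                step /= 2.0
        except np.linalg.LinAlgError:
            pass
        best = None
        for cand in ([proposal] if proposal is not None else []) + [em]:
            ll_new, P_new = loglik(cand)
            if np.isfinite(ll_new) and (best is None or ll_new > best[0]):
                best = (ll_new, cand, P_new)
            if best is not None and best[0] >= ll - 1e-10:
                break
        ll_new, theta, P = best
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return list(theta[:-1]), float(theta[-1]), converged


def genomic_heritability(fit: GBLUPFit, kinship: KinshipMatrix) -> float:
    """Genomic heritability on the population scale.

    The kinship variance sigma2_u refers to a relationship matrix whose
    diagonal mean differs from 1 in structured or partially inbred
    material, so the genetic variance realised in the training set is
    sigma2_u * mean(diag K); h2 = that over itself plus the residual."""
    pos = {g: j for j, g in enumerate(kinship.ids)}
    t = np.array([pos[g] for g in fit.train_ids])
    md = float(np.diag(kinship.to_numpy())[t].mean())
    s2u = fit.variances[kinship.flavor] * md
    s2e = fit.variances["residual"]
    if s2u + s2e <= 0:
        return float("nan")
    return float(s2u / (s2u + s2e))


def prediction_ability(observed, predicted) -> float:
    """Pearson correlation of observed and predicted phenotypes."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if len(obs) < 3:
        raise ValueError("need at least three observed/predicted pairs")
    if np.std(obs) < 1e-14 or np.std(pred) < 1e-14:
        logger.warning("constant vector in prediction-ability computation")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def fit_and_ability(
    y: pd.Series, kinships: Sequence[KinshipMatrix], populations: pd.Series
):
    """Non-cross-validated abilities r_a / r_pop: correlation of observed
    values with the model's fitted genomic values on the full data."""
    fit = fit_gblup(y, kinships)
    ids = [i for i in kinships[0].ids if i in y.index]
    obs = y.loc[ids]
    pred = fit.predictions.loc[ids]
    r_a = prediction_ability(obs, pred)
    r_pop = {}
    for pop in dict.fromkeys(populations.loc[ids]):
        sel = [i for i in ids if populations[i] == pop]
        r_pop[pop] = prediction_ability(obs.loc[sel], pred.loc[sel])
    return r_a, pd.Series(r_pop), fit


def _stratified_folds(ids, populations, folds, rng):
    """Fold labels keeping each population's proportions equal across folds."""
    lab = np.empty(len(ids), dtype=int)
    idx = pd.Index(ids)
    for pop in dict.fromkeys(populations.loc[ids]):
        members = np.where(populations.loc[ids].to_numpy() == pop)[0]
        if len(members) < folds:
            raise ValueError(f"population {pop!r} smaller than the number of folds")
        rng.shuffle(members)
        lab[members] = np.arange(len(members)) % folds
    return lab


def cross_validate(
    y: pd.Series,
    kinships: Sequence[KinshipMatrix],
    populations: pd.Series,
    folds: int = 5,
    reps: int = 20,
    seed: int = 0,
):
    """Replicated stratified k-fold cross-validation.

    Returns ``(r_a_cv, r_pop_cv, per_round)``: the median pooled
    validation-set correlation over rep x fold, the per-population medians
    of within-population validation correlations, and the per-round table.
    """
    rng = np.random.default_rng(seed)
    ids = [i for i in kinships[0].ids if i in y.index and np.isfinite(y[i])]
    rows = []
    for rep in range(reps):
        lab = _stratified_folds(ids, populations, folds, rng)
        for f in range(folds):
            vs = [g for g, l in zip(ids, lab) if l == f]
            ts = [g for g, l in zip(ids, lab) if l != f]
            fit = fit_gblup(y, kinships, train_ids=ts)
            obs, pred = y.loc[vs], fit.predictions.loc[vs]
            r_all = prediction_ability(obs, pred)
            rows.append((rep, f, "__all__", r_all))
            for pop in dict.fromkeys(populations.loc[vs]):
                sel = [g for g in vs if populations[g] == pop]
                try:
                    r = prediction_ability(obs.loc[sel], pred.loc[sel])
                except ValueError:
                    r = np.nan
                rows.append((rep, f, pop, r))
    per_round = pd.DataFrame(rows, columns=["rep", "fold", "population", "r"])
    r_a_cv = float(per_round.loc[per_round["population"] == "__all__", "r"].median())
    r_pop_cv = (
        per_round[per_round["population"] != "__all__"]
        .groupby("population")["r"]
        .median()
    )
    return r_a_cv, r_pop_cv, per_round


def within_population_bootstrap(
    y: pd.Series,
    kinships: Sequence[KinshipMatrix],
    population: str,
    populations: pd.Series,
    sizes: Sequence[int] = tuple(range(10, 101, 10)),
    rounds: int = 500,
    seed: int = 0,
) -> PredictionSummary:
    """Within-population prediction ability r_pop,BSPw versus training size.

    Per round, N member genotypes are drawn with replacement as the
    training set (duplicates collapse to weighted records); the validation
    set is the out-of-bag remainder.  Rounds whose validation set has
    fewer than three genotypes are skipped and logged.
    """
    rng = np.random.default_rng(seed)
    members = [
        i for i in kinships[0].ids
        if populations.get(i) == population and i in y.index and np.isfinite(y[i])
    ]
    rows = []
    for n in sizes:
        skipped = 0
        for b in range(rounds):
            draw = rng.choice(len(members), size=n, replace=True)
            uniq, counts = np.unique(draw, return_counts=True)
            ts = [members[j] for j in uniq]
            vs = [m for m in members if m not in set(ts)]
            if len(vs) < 3:
                skipped += 1
                continue
            wts = pd.Series(counts.astype(float), index=ts)
            try:
                fit = fit_gblup(y, kinships, train_ids=ts, weights=wts)
            except ValueError:
                skipped += 1
                continue
            r = prediction_ability(y.loc[vs], fit.predictions.loc[vs])
            rows.append((n, b, r))
        if skipped:
            logger.warning(
                "population %s, N=%d: skipped %d/%d rounds (validation set too small)",
                population, n, skipped, rounds,
            )
    per_round = pd.DataFrame(rows, columns=["size", "round", "r"])
    medians = per_round.groupby("size")["r"].median()
    return PredictionSummary(
        "r_pop,BSPw",
        per_round,
        float(medians.iloc[-1]) if len(medians) else float("nan"),
        {"population": population, "medians": medians},
    )


def resolve_scenarios(
    scheme: CrossingScheme,
    validation: str,
    ts2s_choice: str | None = None,
    size: int = 50,
    rounds: int = 500,
) -> list:
    """Training-set composition scenarios for one validation population.

    For an intra-pool validation population (DxD or FxF): TS1 = the other
    population(s) of the same pool; TS2s / TS2c = one / both opposite-pool
    populations; TS3sr / TS3su = the inter-pool population sharing / not
    sharing a parent with the validation set; TS3c = both inter-pool
    populations.  For an inter-pool (DxF) validation population: TS1 = the
    other DxF population; TS2 = the combined intra-pool populations with no
    shared parent; TS3 = those sharing a parent.
    """
    parents = scheme.population_parents()
    if validation not in parents:
        raise ValueError(f"unknown validation population {validation!r}")
    vs_parents = set(parents[validation])
    vs_type = scheme.population_type(validation)
    intra = [p for p in parents if scheme.population_type(p) in ("DxD", "FxF")]
    mixed = [p for p in parents if scheme.population_type(p) not in ("DxD", "FxF")]

    def spec(name, pops):
        if not pops:
            raise ValueError(f"scenario {name} has no constituent populations")
        if validation in pops:
            raise ValueError(f"scenario {name} overlaps the validation set")
        return ScenarioSpec(name, validation, list(pops), size, rounds)

    out = []
    if vs_type in ("DxD", "FxF"):
        same_pool = [p for p in intra if p != validation and scheme.population_type(p) == vs_type]
        opp_pool = [p for p in intra if scheme.population_type(p) != vs_type]
        sharing = [p for p in mixed if vs_parents & set(parents[p])]
        unrelated = [p for p in mixed if not (vs_parents & set(parents[p]))]
        out.append(spec("TS1", same_pool))
        chosen = ts2s_choice or (opp_pool[0] if opp_pool else None)
        out.append(spec("TS2s", [chosen] if chosen else []))
        out.append(spec("TS2c", opp_pool))
        out.append(spec("TS3sr", sharing))
        out.append(spec("TS3su", unrelated))
        out.append(spec("TS3c", mixed))
    else:
        other_mixed = [p for p in mixed if p != validation]
        sharing = [p for p in intra if vs_parents & set(parents[p])]
        unrelated = [p for p in intra if not (vs_parents & set(parents[p]))]
        out.append(spec("TS1", other_mixed))
        out.append(spec("TS2", unrelated))
        out.append(spec("TS3", sharing))
    return out


def _proportional_counts(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over groups."""
    share = sizes / sizes.sum() * total
    counts = np.floor(share).astype(int)
    rem = share - counts
    for j in np.argsort(-rem):
        if counts.sum() >= total:
            break
        counts[j] += 1
    return counts


def between_population_scenarios(
    y: pd.Series,
    kinships: Sequence[KinshipMatrix],
    populations: pd.Series,
    scenarios: Sequence[ScenarioSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Between-population prediction abilities r_pop,BSPb per scenario.

    Per round the training set is subsampled to the scenario size with the
    constituent-population proportions preserved; the whole validation
    population is predicted.  Returns a DataFrame with one row per
    scenario (median r, rounds) plus per-round values in ``attrs``.
    """
    rng = np.random.default_rng(seed)
    rows, per_round = [], []
    for sc in scenarios:
        if sc.validation in sc.constituents:
            raise ValueError(
                f"scenario {sc.name}: training and validation sets must be disjoint"
            )
        vs = [i for i in kinships[0].ids if populations.get(i) == sc.validation and i in y.index]
        groups = [
            [i for i in kinships[0].ids if populations.get(i) == pop and i in y.index]
            for pop in sc.constituents
        ]
        sizes = np.array([len(g) for g in groups])
        if (sizes == 0).any():
            raise ValueError(f"scenario {sc.name}: empty constituent population")
        counts = _proportional_counts(sizes, min(sc.size, int(sizes.sum())))
        rs = []
        for b in range(sc.rounds):
            ts = []
            for g, c in zip(groups, counts):
                take = rng.choice(len(g), size=min(c, len(g)), replace=False)
                ts.extend([g[j] for j in take])
            fit = fit_gblup(y, kinships, train_ids=ts)
            r = prediction_ability(y.loc[vs], fit.predictions.loc[vs])
            rs.append(r)
            per_round.append((sc.name, sc.validation, b, r))
        rows.append((sc.name, sc.validation, float(np.nanmedian(rs)), sc.rounds))
    out = pd.DataFrame(rows, columns=["scenario", "validation", "median_r", "rounds"])
    out.attrs["per_round"] = pd.DataFrame(
        per_round, columns=["scenario", "validation", "round", "r"]
    )
    return out


def marker_subsample_curve(
    y: pd.Series,
    imputed: pd.DataFrame,
    populations: pd.Series,
    sizes: Sequence[int] | None = None,
    reps: int = 100,
    seed: int = 0,
    base: int = 170,
) -> pd.DataFrame:
    """Median non-CV prediction ability r_a versus marker number.

    Sizes default to base, 2*base, 4*base, ... up to the full marker set
    (which is evaluated once, without sampling variance).
    """
    n_total = imputed.shape[0]
    if sizes is None:
        sizes = []
        s = base
        while s < n_total:
            sizes.append(s)
            s *= 2
        sizes.append(n_total)
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        if s >= n_total:
            ka = additive_kinship(imputed)
            r_a, _, _ = fit_and_ability(y, [ka], populations)
            rows.append((n_total, float(r_a), 0.0, 1))
            continue
        rs = []
        for _ in range(reps):
            take = rng.choice(n_total, size=s, replace=False)
            ka = additive_kinship(imputed.iloc[take])
            r_a, _, _ = fit_and_ability(y, [ka], populations)
            rs.append(r_a)
        rows.append((s, float(np.median(rs)), float(np.std(rs)), reps))
    return pd.DataFrame(rows, columns=["n_markers", "median_r_a", "sd", "reps"])
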