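"""Heat susceptibility index (HSI), its resampled heritability, and the
among/within-population partition (Q_ST).

For a genotype i with adjusted entry means AEM_iS (standard) and AEM_iH
(heat), and across-genotype means AEM_S and AEM_H,

    HSI_i = (1 - AEM_iH / AEM_iS) / (1 - AEM_H / AEM_S),

so 0 marks an unaffected genotype and 1 average susceptibility.  Because
the HSI is computed from means it has no replicates of its own; an
approximate heritability is obtained by pairing replicate-level
observations (corrected for replicate and block effects) across the two
heat levels at random, which yields three HSI replicates per genotype per
resampling round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixmod import AEMTable, ModelSpec, oneway_balanced_reml, reml_fit

logger = logging.getLogger(__name__)


@dataclass
class QstResult:
    """Median among/within variance components and the Q_ST scalar."""

    sigma2_among: float
    sigma2_within: float
    qst: float
    c: float
    per_round: pd.DataFrame


def compute_hsi(aem: AEMTable, populations: dict | None = None) -> pd.DataFrame:
    """Per-genotype HSI for every trait in an adjusted-entry-mean table.

    Returns a DataFrame (genotype, population, trait, hsi); the population
    column is filled from ``populations`` (genotype -> label) when given.
    """
    rows = []
    for trait in dict.fromkeys(aem.table["trait"]):
        wide = aem.wide(trait)
        if "standard" not in wide or "heat" not in wide:
            raise ValueError(f"trait {trait!r} lacks one of the two conditions")
        aem_s = float(wide["standard"].mean())
        aem_h = float(wide["heat"].mean())
        denom = 1.0 - aem_h / aem_s if aem_s != 0 else 0.0
        if abs(aem_s) < 1e-12 or abs(denom) < 1e-12:
            raise ZeroDivisionError(
                f"HSI undefined for trait {trait!r}: across-genotype AEM ratio is 1"
            )
        if (wide["standard"].abs() < 1e-12).any():
            bad = wide.index[wide["standard"].abs() < 1e-12][0]
            raise ZeroDivisionError(
                f"HSI undefined for trait {trait!r}: AEM_S of genotype {bad!r} is 0"
            )
        hsi = (1.0 - wide["heat"] / wide["standard"]) / denom
        for g, v in hsi.items():
            rows.append((g, populations.get(g) if populations else None, trait, float(v)))
    return pd.DataFrame(rows, columns=["genotype", "population", "trait", "hsi"])


# ---------------------------------------------------------------------------
# replicate-level resampling machinery
# ---------------------------------------------------------------------------

def adjusted_replicates(data: pd.DataFrame, trait: str) -> dict:
    """Observations corrected for fixed replicate and block effects.

    Per condition, the single-condition trial model is fitted with genotype,
    replicate and block-within-replicate all fixed; the estimated replicate
    and block effects (centred to mean zero so condition means are
    preserved) are subtracted.  Returns
    ``{condition: DataFrame genotypes x replicates}``.
    """
    out = {}
    for cond in dict.fromkeys(data["condition"]):
        sub = data[(data["condition"] == cond) & (data["trait"] == trait)].copy()
        spec = ModelSpec(
            response="value", fixed=["genotype", "replicate", "block:replicate"], random=[]
        )
        res = reml_fit(sub, spec)
        beta = res.beta

        def effect(term, level):
            name = f"{term}[{level}]"
            return float(beta[name]) if name in beta.index else 0.0

        reps = sorted(sub["replicate"].unique(), key=str)
        rep_eff = {r: effect("replicate", r) for r in reps}
        rep_mean = np.mean(list(rep_eff.values()))
        blocks = sub[["block", "replicate"]].drop_duplicates()
        blk_eff = {
            (b, r): effect("block:replicate", f"{b}:{r}") for b, r in blocks.itertuples(index=False)
        }
        blk_mean = np.mean(list(blk_eff.values()))
        sub["adj"] = [
            v - (rep_eff[r] - rep_mean) - (blk_eff[(b, r)] - blk_mean)
            for v, r, b in zip(sub["value"], sub["replicate"], sub["block"])
        ]
        out[cond] = sub.pivot_table(index="genotype", columns="replicate", values="adj")
    return out


def hsi_replicate_rounds(
    data: pd.DataFrame,
    trait: str,
    n_rounds: int = 100,
    seed: int = 0,
):
    """Yield per-round HSI replicate tables.

    Each round pairs, independently per genotype, a random permutation of
    the three heat replicates with the three standard replicates, and
    computes the HSI of each pair using the across-genotype means of the
    adjusted data.  Genotypes with missing replicates are dropped (logged
    once).  Yields DataFrames (genotype, population, replicate, hsi).
    """
    adj = adjusted_replicates(data, trait)
    if set(adj) != {"standard", "heat"}:
        raise ValueError("need adjusted data for both conditions")
    std, heat = adj["standard"], adj["heat"]
    common = std.dropna().index.intersection(heat.dropna().index)
    dropped = len(set(std.index) | set(heat.index)) - len(common)
    if dropped:
        logger.warning("dropping %d genotypes with incomplete replicates", dropped)
    std = std.loc[common].to_numpy()
    heat = heat.loc[common].to_numpy()
    n_g, n_r = std.shape
    pops = (
        data.drop_duplicates("genotype").set_index("genotype")["population"].reindex(common)
    )
    mean_s, mean_h = float(std.mean()), float(heat.mean())
    denom = 1.0 - mean_h / mean_s
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(f"HSI undefined for trait {trait!r}: mean ratio is 1")
    rng = np.random.default_rng(seed)
    for _ in range(n_rounds):
        perm = np.argsort(rng.random((n_g, n_r)), axis=1)
        heat_p = np.take_along_axis(heat, perm, axis=1)
        hsi = (1.0 - heat_p / std) / denom
        yield pd.DataFrame(
            {
                "genotype": np.repeat(common.to_numpy(), n_r),
                "population": np.repeat(pops.to_numpy(), n_r),
                "replicate": np.tile(np.arange(1, n_r + 1), n_g),
                "hsi": hsi.ravel(),
            }
        )


def hsi_heritability(
    data: pd.DataFrame,
    trait: str,
    n_rounds: int = 100,
    seed: int = 0,
):
    """Median resampled heritability of the HSI of one trait.

    Per round the paired HSI replicates are analysed with the genotype-
    as-random one-way model and h2 = sigma2_g / (sigma2_g + sigma2_e / r).
    Returns ``(median, per-round ndarray)``.
    """
    vals = []
    for round_df in hsi_replicate_rounds(data, trait, n_rounds, seed):
        wide = round_df.pivot(index="genotype", columns="replicate", values="hsi").to_numpy()
        s2g, s2e = oneway_balanced_reml(wide)
        r = wide.shape[1]
        denom = s2g + s2e / r
        vals.append(s2g / denom if denom > 0 else np.nan)
    vals = np.asarray(vals)
    return float(np.nanmedian(vals)), vals


def qst(
    rounds,
    c: float = 2.0,
) -> QstResult:
    """Q_ST from per-round HSI replicate tables.

    Each round is fitted with population and genotype-within-population as
    independent random factors; the medians of the among- and within-
    population variances over rounds give
    Q_ST = sigma2_among / (sigma2_among + c * sigma2_within), with c = 2
    for the outbred convention (configurable for partially inbred lines).
    """
    rows = []
    for round_df in rounds:
        if round_df["population"].nunique() < 2:
            raise ValueError("Q_ST requires at least two populations")
        spec = ModelSpec(response="hsi", fixed=[], random=["population", "genotype"])
        res = reml_fit(round_df, spec)
        rows.append(
            (res.varcomp["population"], res.varcomp["genotype"], res.varcomp["residual"])
        )
    per_round = pd.DataFrame(rows, columns=["sigma2_among", "sigma2_within", "sigma2_e"])
    among = float(per_round["sigma2_among"].median())
    within = float(per_round["sigma2_within"].median())
    denom = among + c * within
    return QstResult(among, within, among / denom if denom > 0 else np.nan, c, per_round)


def qst_from_phenotypes(
    data: pd.DataFrame,
    trait: str,
    n_rounds: int = 100,
    seed: int = 0,
    c: float = 2.0,
) -> QstResult:
    """Q_ST of one trait's HSI via the replicate-pairing resampling."""
    return qst(hsi_replicate_rounds(data, trait, n_rounds, seed), c=c)


def hsi_correlations(hsi_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between the HSI of all traits."""
    wide = hsi_table.pivot(index="genotype", columns="trait", values="hsi")
    if len(wide) < 3:
        raise ValueError("need at least three genotypes")
    zero_var = wide.columns[wide.std() < 1e-14]
    for t in zero_var:
        logger.warning("trait %s has zero HSI variance; correlations undefined", t)
        wide = wide.drop(columns=t)
    corr = wide.corr(method="pearson", min_periods=2)
    return corr
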