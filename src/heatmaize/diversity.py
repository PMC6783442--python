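"""Molecular diversity and relationship statistics.

Gene diversity D, population differentiation G_ST, modified Rogers distance
(MRD), classical-scaling principal coordinates, and the realised additive
(K_A) and dominance (K_D) relationship matrices used by GBLUP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric realised relationship matrix (individuals x individuals)."""

    values: pd.DataFrame
    flavor: str  # 'additive' or 'dominance'
    n_markers: int

    def __post_init__(self):
        if self.flavor not in ("additive", "dominance"):
            raise ValueError("flavor must be 'additive' or 'dominance'")
        a = self.values.to_numpy()
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def ids(self) -> list:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values.to_numpy()).min())


def _allele_freqs(calls: np.ndarray) -> float:
    """Alternate-allele frequency of one marker's non-missing calls."""
    called = calls[calls != MISSING]
    if len(called) == 0:
        return np.nan
    return float(called.sum()) / (2.0 * len(called))


def gene_diversity(genotypes: GenotypeMatrix, grouping=None) -> pd.Series:
    """Nei gene diversity D = 1 - p^2 - q^2 per group, averaged over markers.

    ``grouping`` defaults to the population labels; pass a single label for
    all individuals to obtain a pooled estimate.  Markers without calls in
    a group are skipped for that group.
    """
    if grouping is None:
        grouping = genotypes.populations
    grouping = np.asarray(grouping, dtype=object)
    g = genotypes.genotypes
    out = {}
    for grp in dict.fromkeys(grouping):
        sub = g[:, grouping == grp].astype(float)
        sub[sub == MISSING] = np.nan
        n_called = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=1) / (2.0 * n_called)
        d = 1.0 - p**2 - (1.0 - p) ** 2
        out[grp] = float(np.nanmean(d[n_called > 0]))
    return pd.Series(out, name="D")


def gst(genotypes: GenotypeMatrix, populations=None) -> float:
    """Nei population differentiation G_ST = (H_T - H_S) / H_T.

    H components are summed over markers before the ratio.  H_S is the mean
    within-population diversity, H_T the diversity of the pooled (mean)
    allele frequencies.  Returns NaN when all markers are monomorphic.
    """
    if populations is None:
        populations = genotypes.populations
    populations = np.asarray(populations, dtype=object)
    pops = list(dict.fromkeys(populations))
    if len(pops) < 2:
        raise ValueError("G_ST requires at least two populations")
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    h_s_sum = 0.0
    h_t_sum = 0.0
    for m in range(genotypes.n_markers):
        freqs = []
        for pop in pops:
            calls = g[m, populations == pop]
            calls = calls[~np.isnan(calls)]
            if len(calls):
                freqs.append(calls.sum() / (2.0 * len(calls)))
        if not freqs:
            continue
        freqs = np.asarray(freqs)
        h_s = np.mean(1.0 - freqs**2 - (1.0 - freqs) ** 2)
        p_bar = freqs.mean()
        h_t = 1.0 - p_bar**2 - (1.0 - p_bar) ** 2
        h_s_sum += h_s
        h_t_sum += h_t
    if h_t_sum <= 0:
        logger.warning("all markers monomorphic; G_ST undefined")
        return float("nan")
    return float((h_t_sum - h_s_sum) / h_t_sum)


def mrd(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Modified Rogers distance between individuals, in [0, 1].

    MRD(a, b) = sqrt( sum_markers sum_alleles (p_a - p_b)^2 / (2 m) ) with
    individual allele "frequencies" in {0, 0.5, 1}.  Missing calls are
    excluded pairwise with per-pair renormalisation of the marker count;
    a pair with no shared markers gets NaN.
    """
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    p = (g / 2.0).T  # individuals x markers
    n = p.shape[0]
    obs = ~np.isnan(p)
    pz = np.nan_to_num(p)
    # for biallelic markers sum over the two alleles of (pa-pb)^2 = 2 (pa-pb)^2
    sq = pz**2
    cross = pz @ pz.T
    d2 = sq @ obs.T + obs @ sq.T - 2.0 * cross  # sum of (pa-pb)^2 over shared markers
    shared = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.clip(2.0 * d2 / (2.0 * shared), 0.0, None))
    dist[shared == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    ids = list(genotypes.individuals)
    return pd.DataFrame(dist, index=ids, columns=ids)


def mrd_population_summary(dist: pd.DataFrame, populations) -> pd.DataFrame:
    """Average pairwise MRD between (off-diagonal) and within populations."""
    populations = np.asarray(populations, dtype=object)
    pops = list(dict.fromkeys(populations))
    d = dist.to_numpy()
    out = pd.DataFrame(index=pops, columns=pops, dtype=float)
    for i, a in enumerate(pops):
        ia = np.where(populations == a)[0]
        for b in pops[i:]:
            ib = np.where(populations == b)[0]
            block = d[np.ix_(ia, ib)]
            if a == b:
                iu = np.triu_indices(len(ia), k=1)
                val = float(np.nanmean(block[iu])) if len(ia) > 1 else np.nan
            else:
                val = float(np.nanmean(block))
            out.loc[a, b] = out.loc[b, a] = val
    return out


def pcoa(distances: pd.DataFrame, n_axes: int = 2):
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and keeps the top ``n_axes``
    axes with positive eigenvalues.  Returns ``(coordinates, percent)``
    where percent is the variance explained per axis (eigenvalue over the
    sum of positive eigenvalues, x100).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("need a square symmetric distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(vals.max(), 1.0)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    percent = vals[:n_axes] / vals[pos].sum() * 100.0
    ids = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(n))
    coords = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{k + 1}" for k in range(n_axes)]
    )
    return coords, percent


def additive_kinship(imputed: pd.DataFrame) -> KinshipMatrix:
    """Realised additive relationship K_A = WW' / (2 sum p(1-p)).

    ``imputed`` is a numeric markers x individuals table (mean-imputed
    allele counts).  Marker codes are centred by twice the sample allele
    frequency; monomorphic markers are removed.
    """
    m = imputed.to_numpy(dtype=float)
    p = m.mean(axis=1) / 2.0
    keep = (p > 0) & (p < 1)
    if keep.sum() < 1:
        raise ValueError("no polymorphic markers")
    m = m[keep]
    p = p[keep]
    w = (m - 2.0 * p[:, None]).T  # individuals x markers
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = w @ w.T / denom
    ids = list(imputed.columns)
    return KinshipMatrix(pd.DataFrame(k, index=ids, columns=ids), "additive", int(keep.sum()))


def dominance_kinship(imputed: pd.DataFrame) -> KinshipMatrix:
    """Dominance relationship K_D = VV' / sum (2pq)^2.

    Uses the classical orthogonal dominance coding per marker:
    -2q^2 / 2pq / -2p^2 for genotypes 0 / 1 / 2 (p the alternate-allele
    frequency, q = 1 - p); fractional (imputed) genotypes are linearly
    interpolated between the three codes.
    """
    m = imputed.to_numpy(dtype=float)
    p = m.mean(axis=1) / 2.0
    keep = (p > 0) & (p < 1)
    if keep.sum() < 1:
        raise ValueError("no polymorphic markers")
    m = m[keep]
    p = p[keep][:, None]
    q = 1.0 - p
    # piecewise-linear orthogonal codes through (-2q^2, 2pq, -2p^2)
    low = -2.0 * q**2 + (2.0 * p * q + 2.0 * q**2) * np.clip(m, 0.0, 1.0)
    high = 2.0 * p * q + (-2.0 * p**2 - 2.0 * p * q) * (np.clip(m, 1.0, 2.0) - 1.0)
    v = np.where(m <= 1.0, low, high).T  # individuals x markers
    denom = float(np.sum((2.0 * p * q) ** 2))
    k = v @ v.T / denom
    ids = list(imputed.columns)
    return KinshipMatrix(pd.DataFrame(k, index=ids, columns=ids), "dominance", int(keep.sum()))
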