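"""Genotype quality control: probability-cutoff calling, mean imputation,
segregation-distortion filtering, and sparse assay marker selection.

The probability cutoffs mirror the three post-imputation calling policies
used for posterior genotype probabilities: accept a call only when its
probability exceeds 1 (within floating-point tolerance) or 0.98, or always
accept the maximum-probability class (MAX).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .datatypes import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

_GP_MODES = {"GP1": 1.0 - 1e-9, "GP098": 0.98, "MAX": None}


@dataclass(frozen=True)
class GPCutoffPolicy:
    """Genotype-probability calling policy: 'GP1', 'GP098' or 'MAX'."""

    mode: str

    def __post_init__(self):
        if self.mode not in _GP_MODES:
            raise ValueError(f"mode must be one of {sorted(_GP_MODES)}")

    @property
    def threshold(self):
        return _GP_MODES[self.mode]


def gp_cutoff_filter(
    gprobs: np.ndarray, policy: GPCutoffPolicy, template: GenotypeMatrix
) -> GenotypeMatrix:
    """Convert a (markers x individuals x 3) probability tensor into calls.

    For GP1/GP098 a call is emitted only when the maximum probability
    exceeds the threshold, otherwise the call is set missing.  MAX always
    emits the argmax class; ties are broken toward the heterozygous class
    and then toward the lower code.
    """
    gprobs = np.asarray(gprobs, dtype=float)
    if gprobs.ndim != 3 or gprobs.shape[2] != 3:
        raise ValueError("gprobs must be markers x individuals x 3")
    sums = gprobs.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("probability triples must sum to 1")
    if (gprobs < -1e-12).any():
        raise ValueError("negative probabilities")

    # tie-break: prefer heterozygote, then lower code -> order classes 1,0,2
    order = np.array([1, 0, 2])
    reordered = gprobs[..., order]
    best = order[np.argmax(reordered, axis=2)]
    pmax = gprobs.max(axis=2)

    if policy.mode == "MAX":
        calls = best
    else:
        calls = np.where(pmax > policy.threshold, best, MISSING)
    return GenotypeMatrix(
        calls.astype(np.int8),
        list(template.individuals),
        template.populations.copy(),
        template.gmap,
    )


def mean_impute(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Replace missing calls by the marker mean over non-missing calls.

    Markers without a single call are dropped with a warning.  Returns a
    float markers x individuals DataFrame (marker ids as index).
    """
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    n_called = np.sum(~np.isnan(g), axis=1)
    keep = n_called > 0
    if not keep.any():
        raise ValueError("all markers are entirely missing; nothing to impute")
    if (~keep).any():
        logger.warning("dropping %d all-missing markers during imputation", int((~keep).sum()))
    g = g[keep]
    means = np.nanmean(g, axis=1)
    filled = np.where(np.isnan(g), means[:, None], g)
    return pd.DataFrame(filled, index=genotypes.markers[keep], columns=genotypes.individuals)


def segregation_filter(
    genotypes: GenotypeMatrix,
    expected_allele_freq: float = 0.5,
    alpha: float = 0.001,
) -> list:
    """Markers retained after a per-population exact binomial test of the
    observed alternate-allele count against the expected frequency.

    A marker is removed as soon as it is significantly distorted
    (two-sided P < alpha) in any population in which it is called.
    Markers with zero calls in every population are removed and logged.
    """
    if not 0.0 < expected_allele_freq < 1.0:
        raise ValueError("expected_allele_freq must be in (0, 1)")
    g = genotypes.genotypes
    pops = genotypes.populations
    retained = []
    for m, marker in enumerate(genotypes.markers):
        any_called = False
        distorted = False
        for pop in dict.fromkeys(pops):
            calls = g[m, pops == pop]
            calls = calls[calls != MISSING]
            if len(calls) == 0:
                continue
            any_called = True
            alt = int(calls.sum())
            total = 2 * len(calls)
            p = binomtest(alt, total, expected_allele_freq, alternative="two-sided").pvalue
            if p < alpha:
                distorted = True
                break
        if not any_called:
            logger.warning("marker %s has zero called genotypes; removed", marker)
            continue
        if not distorted:
            retained.append(marker)
    return retained


def select_kasp_subset(
    parents: GenotypeMatrix,
    gmap: GeneticMap,
    crosses: dict,
    per_population_target: int,
) -> dict:
    """Per-population marker panels emulating sparse-assay selection.

    For each population (pair of parent ids) the candidate set contains
    markers at which both parents are homozygous for different alleles.
    Markers already chosen for another population are preferred, then a
    greedy rule maximises the minimum pairwise map distance until the
    target count is reached.

    Parameters
    ----------
    parents:
        genotype matrix of the parental inbreds (columns = parent ids).
    crosses:
        mapping population id -> (parentA id, parentB id).
    """
    if per_population_target < 1:
        raise ValueError("target must be positive")
    col = {p: j for j, p in enumerate(parents.individuals)}
    table = gmap.table.set_index("marker")
    # global position on a concatenated axis so distances are comparable
    offsets, off = {}, 0.0
    for chrom, sub in gmap.table.groupby("chrom", sort=False):
        offsets[chrom] = off
        off += float(sub["pos_cM"].max()) + 50.0  # gap so chromosomes never look adjacent
    gpos = {
        m: offsets[row["chrom"]] + row["pos_cM"] for m, row in table.iterrows()
    }

    chosen_global: set = set()
    result = {}
    for pop, (pa, pb) in crosses.items():
        ga = parents.genotypes[:, col[pa]]
        gb = parents.genotypes[:, col[pb]]
        cand_mask = (
            np.isin(ga, [0, 2]) & np.isin(gb, [0, 2]) & (ga != gb)
        )
        candidates = list(np.asarray(gmap.markers)[cand_mask])
        if len(candidates) <= per_population_target:
            if len(candidates) < per_population_target:
                logger.warning(
                    "population %s: only %d candidate markers for target %d",
                    pop, len(candidates), per_population_target,
                )
            result[pop] = candidates
            chosen_global.update(candidates)
            continue
        selected = _greedy_spread(candidates, gpos, per_population_target, chosen_global)
        result[pop] = selected
        chosen_global.update(selected)
    return result


def _greedy_spread(candidates, gpos, target, preferred):
    """Greedy max-min-distance selection, seeding with the two outermost
    candidates and preferring markers already used elsewhere on ties."""
    cand = sorted(candidates, key=lambda m: gpos[m])
    if target == 1:
        return [cand[0]]
    selected = [cand[0], cand[-1]]
    remaining = [m for m in cand if m not in selected]
    while len(selected) < target and remaining:
        sel_pos = np.array([gpos[m] for m in selected])
        best_m, best_key = None, None
        for m in remaining:
            d = np.min(np.abs(sel_pos - gpos[m]))
            key = (d, 1 if m in preferred else 0)
            if best_key is None or key > best_key:
                best_key, best_m = key, m
        selected.append(best_m)
        remaining.remove(best_m)
    return sorted(selected, key=lambda m: gpos[m])
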