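"""Simulation of connected bi-parental populations and trial phenotypes.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome length in Morgan and crossover positions are uniform,
i.e. no interference.  An F1 between two inbreds is selfed for a configurable
number of generations (default two, giving F3 genotypes with an expected 25%
heterozygosity at segregating loci).  Phenotypes are generated for a
replicated incomplete-block (lattice-style) trial at two heat levels with
known variance components and QTL effects, so that every downstream
statistic can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    MISSING,
    CrossingScheme,
    GeneticMap,
    GenotypeMatrix,
    SimTruth,
    TraitTruth,
    TrialDesign,
    default_crossing_scheme,
)

TRAIT_NAMES = ("LL", "PH", "NL", "SC", "SN", "SD", "DW", "WC", "LR")


# ---------------------------------------------------------------------------
# genome and crossing
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chromosomes: int,
    chrom_lengths_cm: Sequence[float],
    n_markers: int,
    n_parents: int,
    seed: int,
):
    """Random biallelic marker map plus fully homozygous parent haplotypes.

    Markers are allocated to chromosomes proportionally to map length (at
    least one per chromosome), placed uniformly at random and sorted.  Each
    parent is an inbred represented by a single haplotype of 0/1 alleles;
    monomorphic markers are perturbed so every marker segregates somewhere
    in the parent set.

    Returns
    -------
    (GeneticMap, ndarray of shape (n_parents, n_markers))
    """
    if n_chromosomes < 1 or n_markers < n_chromosomes or n_parents < 2:
        raise ValueError("need >=1 chromosome, >=1 marker per chromosome, >=2 parents")
    chrom_lengths_cm = np.asarray(chrom_lengths_cm, dtype=float)
    if len(chrom_lengths_cm) != n_chromosomes or (chrom_lengths_cm <= 0).any():
        raise ValueError("chromosome lengths must be positive, one per chromosome")
    rng = np.random.default_rng(seed)

    # largest-remainder allocation proportional to length, min one marker
    share = chrom_lengths_cm / chrom_lengths_cm.sum() * n_markers
    alloc = np.maximum(np.floor(share).astype(int), 1)
    while alloc.sum() < n_markers:
        alloc[np.argmax(share - alloc)] += 1
    while alloc.sum() > n_markers:
        over = np.where(alloc > 1)[0]
        alloc[over[np.argmin((share - alloc)[over])]] -= 1

    rows = []
    width = len(str(n_markers))
    m_id = 0
    for c in range(n_chromosomes):
        pos = np.sort(rng.uniform(0.0, chrom_lengths_cm[c], size=alloc[c]))
        for p in pos:
            m_id += 1
            rows.append((f"chr{c + 1}", f"M{m_id:0{width}d}", float(p)))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["chrom", "marker", "pos_cM"]))

    haps = rng.integers(0, 2, size=(n_parents, n_markers)).astype(np.int8)
    mono = np.where(haps.min(axis=0) == haps.max(axis=0))[0]
    for m in mono:
        haps[rng.integers(0, n_parents), m] ^= 1
    return gmap, haps


def _gamete(gmap_pos: Mapping, h1: np.ndarray, h2: np.ndarray, rng) -> np.ndarray:
    """One meiotic product of the diploid (h1, h2) under the Haldane model."""
    out = np.empty_like(h1)
    for chrom, (idx, pos, length) in gmap_pos.items():
        n_x = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(0.0, length, size=n_x))
        strand = (rng.integers(0, 2) + np.searchsorted(cuts, pos)) % 2
        out[idx] = np.where(strand == 0, h1[idx], h2[idx])
    return out


def _chrom_pos_index(gmap: GeneticMap) -> dict:
    out = {}
    for chrom, idx in gmap.chrom_slices().items():
        pos = gmap.table["pos_cM"].to_numpy()[idx]
        out[chrom] = (idx, pos, max(float(pos.max()), 1e-9))
    return out


def simulate_cross(
    gmap: GeneticMap,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    n_progeny: int,
    selfing_generations: int,
    seed: int,
    population: str = "pop",
    individual_prefix: str | None = None,
    coding: str = "parentB",
) -> GenotypeMatrix:
    """Progeny genotypes of an inbred x inbred cross after selfing.

    Parents are given as single haplotypes (they must be homozygous, i.e.
    1-D; passing a 2-row haplotype pair with differing rows is rejected).
    The F1 carries one chromosome set from each parent; each selfing
    generation replaces the genotype by the union of two independent gametes
    of itself.  ``coding='parentB'`` counts copies of the parent-B allele,
    ``coding='alt'`` counts the globally designated alternate allele (1).
    """
    hap_a, hap_b = _require_homozygous(hap_a), _require_homozygous(hap_b)
    if selfing_generations < 0 or n_progeny < 1:
        raise ValueError("n_progeny >= 1 and selfing_generations >= 0 required")
    rng = np.random.default_rng(seed)
    gpos = _chrom_pos_index(gmap)
    n_m = gmap.n_markers

    genos = np.empty((n_m, n_progeny), dtype=np.int8)
    for j in range(n_progeny):
        h1, h2 = hap_a, hap_b  # the F1
        for _ in range(selfing_generations):
            h1, h2 = _gamete(gpos, h1, h2, rng), _gamete(gpos, h1, h2, rng)
        if coding == "alt":
            genos[:, j] = h1 + h2
        else:
            genos[:, j] = (h1 == hap_b).astype(np.int8) + (h2 == hap_b).astype(np.int8)
    prefix = individual_prefix or population
    ids = [f"{prefix}_{j + 1:03d}" for j in range(n_progeny)]
    return GenotypeMatrix(genos, ids, np.repeat(population, n_progeny), gmap)


def _require_homozygous(hap: np.ndarray) -> np.ndarray:
    hap = np.asarray(hap, dtype=np.int8)
    if hap.ndim == 2:
        if not np.array_equal(hap[0], hap[1]):
            raise ValueError("parents must be homozygous inbreds")
        hap = hap[0]
    return hap


# ---------------------------------------------------------------------------
# trial design and phenotypes
# ---------------------------------------------------------------------------

def lattice_design(
    genotype_ids: Sequence[str],
    condition: str,
    n_replicates: int = 3,
    n_blocks: int = 32,
    seed: int = 0,
) -> TrialDesign:
    """Randomised incomplete-block layout: per replicate the genotypes are
    shuffled and split into ``n_blocks`` near-equal blocks."""
    rng = np.random.default_rng(seed)
    n_blocks = min(n_blocks, len(genotype_ids))
    rows = []
    for r in range(1, n_replicates + 1):
        order = rng.permutation(len(genotype_ids))
        splits = np.array_split(order, n_blocks)
        for b, blk in enumerate(splits, start=1):
            for g in blk:
                rows.append((genotype_ids[g], r, b))
    return TrialDesign(condition, pd.DataFrame(rows, columns=["genotype", "replicate", "block"]), n_blocks)


def genetic_values(genotypes: GenotypeMatrix, truth: TraitTruth) -> dict:
    """True genetic value per individual for both heat levels."""
    midx = pd.Index(genotypes.gmap.table["marker"]).get_indexer(truth.qtl_markers)
    if (midx < 0).any():
        raise ValueError("QTL marker id missing from the genotype matrix")
    x = genotypes.genotypes[midx].astype(float)  # q x n
    if (x < 0).any():
        raise ValueError("missing genotype calls at QTL markers")
    het = (x == 1.0).astype(float)
    add = np.asarray(truth.additive, dtype=float)
    dom = np.asarray(truth.dominance, dtype=float)
    mult = np.asarray(truth.heat_multiplier, dtype=float)
    out = {}
    for cond in CONDITIONS:
        m = mult if cond == "heat" else np.ones_like(mult)
        out[cond] = (add * m) @ x + (dom * m) @ het
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    designs: Mapping[str, TrialDesign],
    seed: int,
) -> pd.DataFrame:
    """Long-format phenotype records for every trait in ``truth``.

    observation = mu + genetic value + condition effect + replicate effect
    + block effect + Normal(0, sigma2_e[condition]) residual.  The replicate
    and block draws are recorded back into ``truth`` so parameter-recovery
    tests can subtract them.
    """
    rng = np.random.default_rng(seed)
    id_set = set(genotypes.individuals)
    pop_of = dict(zip(genotypes.individuals, genotypes.populations))
    col = {ind: j for j, ind in enumerate(genotypes.individuals)}
    rows = []
    for trait, tt in truth.traits.items():
        gvals = genetic_values(genotypes, tt)
        for cond, design in designs.items():
            tab = design.table
            if not set(tab["genotype"]).issubset(id_set):
                raise ValueError("design contains genotypes absent from the genotype matrix")
            reps = design.replicates
            rep_eff = rng.normal(0.0, np.sqrt(tt.sigma2_rep), size=len(reps))
            blk_eff = {}
            for r in reps:
                for b in sorted(tab.loc[tab["replicate"] == r, "block"].unique()):
                    blk_eff[(r, b)] = rng.normal(0.0, np.sqrt(tt.sigma2_block))
            truth.rep_effects[f"{trait}:{cond}"] = rep_eff
            truth.block_effects[f"{trait}:{cond}"] = [
                (r, b, e) for (r, b), e in blk_eff.items()
            ]
            g = gvals[cond]
            sd_e = np.sqrt(tt.sigma2_e[cond])
            for gen, r, b in tab.itertuples(index=False):
                val = (
                    tt.mu
                    + g[col[gen]]
                    + tt.condition_effect[cond]
                    + rep_eff[reps.index(r)]
                    + blk_eff[(r, b)]
                    + rng.normal(0.0, sd_e)
                )
                rows.append((gen, pop_of[gen], cond, r, b, trait, val))
    return pd.DataFrame(
        rows,
        columns=["genotype", "population", "condition", "replicate", "block", "trait", "value"],
    )


# ---------------------------------------------------------------------------
# genotype probabilities (posterior-call emulation)
# ---------------------------------------------------------------------------

def add_genotype_probabilities(
    genotypes: GenotypeMatrix,
    error_rate: float,
    missing_rate: float,
    seed: int,
) -> np.ndarray:
    """Posterior probability triples over {0,1,2} for every call.

    With probability ``1 - error_rate`` the true class receives mass
    >= 0.98; otherwise most of the mass lands on a wrong class.  A
    ``missing_rate`` fraction of calls (and every truly missing call)
    receives a near-uniform triple, which downstream probability-cutoff
    filtering turns back into a missing call.
    """
    for r in (error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m, n = genotypes.genotypes.shape
    gp = np.empty((m, n, 3), dtype=float)
    u = rng.random((m, n))
    is_uniformish = (u < missing_rate) | (genotypes.genotypes == MISSING)
    is_error = (~is_uniformish) & (rng.random((m, n)) < error_rate)

    # accurate calls: mass in [0.985, 1) on truth, remainder split at random
    top = rng.uniform(0.985, 0.999999, size=(m, n))
    split = rng.random((m, n))
    truthful = np.clip(genotypes.genotypes, 0, 2)
    rest = 1.0 - top
    for k in range(3):
        gp[..., k] = np.where(truthful == k, top, 0.0)
    others = [(1, 2), (0, 2), (0, 1)]
    for k in range(3):
        a, b = others[k]
        sel = truthful == k
        gp[..., a] = np.where(sel, rest * split, gp[..., a])
        gp[..., b] = np.where(sel, rest * (1.0 - split), gp[..., b])

    # erroneous calls: mass in [0.5, 0.9] on a random wrong class
    err_idx = np.argwhere(is_error)
    for i, j in err_idx:
        wrong = [k for k in range(3) if k != truthful[i, j]]
        k = wrong[rng.integers(0, 2)]
        p = rng.uniform(0.5, 0.9)
        q = rng.random()
        triple = np.full(3, 0.0)
        triple[k] = p
        rem = [c for c in range(3) if c != k]
        triple[rem[0]] = (1 - p) * q
        triple[rem[1]] = (1 - p) * (1 - q)
        gp[i, j] = triple

    # near-uniform triples
    uni_idx = np.argwhere(is_uniformish)
    if len(uni_idx):
        noise = rng.uniform(-0.05, 0.05, size=(len(uni_idx), 3))
        tri = 1.0 / 3.0 + noise
        tri /= tri.sum(axis=1, keepdims=True)
        gp[uni_idx[:, 0], uni_idx[:, 1]] = tri
    return gp


# ---------------------------------------------------------------------------
# the full connected-population study
# ---------------------------------------------------------------------------

@dataclass
class StudySim:
    """All artefacts of one simulated two-heat-level experiment."""

    scheme: CrossingScheme
    gmap: GeneticMap
    parent_haplotypes: np.ndarray
    parents: GenotypeMatrix
    geno_dense: GenotypeMatrix
    geno_sparse: GenotypeMatrix
    truth: SimTruth
    designs: Mapping[str, TrialDesign]
    phenotypes: pd.DataFrame


def make_trait_truth(
    gmap: GeneticMap,
    rng,
    n_qtl: int = 40,
    mu: float = 60.0,
    condition_effect: Mapping[str, float] | None = None,
    sigma2_e: Mapping[str, float] | None = None,
    sigma2_rep: float = 0.2,
    sigma2_block: float | None = None,
) -> TraitTruth:
    """Draw a polygenic architecture with condition-specific effect
    multipliers (the source of genetic HSI variance)."""
    if condition_effect is None:
        condition_effect = {"standard": 0.0, "heat": -15.0}
    if sigma2_e is None:
        s = float(rng.uniform(0.8, 2.0))
        sigma2_e = {"standard": s, "heat": s * float(rng.uniform(0.9, 1.3))}
    if sigma2_block is None:
        sigma2_block = 0.25 * sigma2_e["standard"]
    qtl = rng.choice(gmap.n_markers, size=min(n_qtl, gmap.n_markers), replace=False)
    qtl.sort()
    sigma_a = np.sqrt(1.0 / (len(qtl) * 0.75 * 0.5))
    add = rng.normal(0.0, sigma_a, size=len(qtl))
    dom = rng.normal(0.0, 0.1 * sigma_a, size=len(qtl))
    mult = np.abs(rng.normal(1.4, 0.5, size=len(qtl)))
    return TraitTruth(
        qtl_markers=list(gmap.markers[qtl]),
        additive=add,
        dominance=dom,
        heat_multiplier=mult,
        mu=mu,
        condition_effect=dict(condition_effect),
        sigma2_e=dict(sigma2_e),
        sigma2_rep=sigma2_rep,
        sigma2_block=sigma2_block,
    )


def simulate_study(
    seed: int,
    n_progeny: int = 100,
    n_markers_dense: int = 5440,
    n_markers_sparse: int = 170,
    n_chromosomes: int = 10,
    total_length_cm: float = 1823.5,
    n_traits: int = 9,
    n_qtl: int = 40,
    n_replicates: int = 3,
    n_blocks: int = 32,
    scheme: CrossingScheme | None = None,
) -> StudySim:
    """Simulate the default experiment: six connected F3:4 populations from
    four Dent and four Flint inbreds, genotyped at a dense ("RAD-like") and
    a sparse ("KASP-like") marker set, phenotyped for up to nine traits in a
    three-replicate incomplete-block trial under standard and heat
    conditions."""
    rng = np.random.default_rng(seed)
    if scheme is None:
        scheme = default_crossing_scheme(n_progeny=n_progeny)
    lengths = np.full(n_chromosomes, total_length_cm / n_chromosomes)
    gmap, haps = simulate_genome(
        n_chromosomes, lengths, n_markers_dense, len(scheme.pools), int(rng.integers(2**31))
    )
    parent_ids = list(scheme.pools)
    parents = GenotypeMatrix(
        (2 * haps.T).astype(np.int8),
        parent_ids,
        np.repeat("parents", len(parent_ids)),
        gmap,
    )
    hap_of = dict(zip(parent_ids, haps))

    pops = []
    for pa, pb, n in scheme.crosses:
        name = scheme.population_name(pa, pb)
        pops.append(
            simulate_cross(
                gmap,
                hap_of[pa],
                hap_of[pb],
                n,
                scheme.selfing_generations,
                int(rng.integers(2**31)),
                population=name,
                coding="alt",
            )
        )
    geno = pops[0]
    for p in pops[1:]:
        geno = geno.concat(p)

    sparse_idx = np.unique(
        np.linspace(0, n_markers_dense - 1, min(n_markers_sparse, n_markers_dense)).astype(int)
    )
    geno_sparse = geno.subset_markers(gmap.markers[sparse_idx])

    traits = {}
    for t in range(n_traits):
        traits[TRAIT_NAMES[t % len(TRAIT_NAMES)]] = make_trait_truth(gmap, rng, n_qtl=n_qtl)
    truth = SimTruth(traits=traits, seed=seed)

    designs = {
        cond: lattice_design(
            list(geno.individuals), cond, n_replicates, n_blocks, int(rng.integers(2**31))
        )
        for cond in CONDITIONS
    }
    pheno = simulate_phenotypes(geno, truth, designs, int(rng.integers(2**31)))
    return StudySim(scheme, gmap, haps, parents, geno, geno_sparse, truth, designs, pheno)
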