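"""Shared containers for maps, genotypes, designs and simulation ground truth.

Genotypes are stored as an int8 markers x individuals array of alternate-allele
counts (0, 1, 2) with ``MISSING = -1`` as the sentinel for no-calls.  Genetic
map positions are in centiMorgan; they are converted to Morgan only inside
meiosis simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

CONDITIONS = ("standard", "heat")


class GeneticMap:
    """Marker positions (cM) on one or more chromosomes.

    Parameters
    ----------
    table:
        DataFrame with columns ``chrom``, ``marker``, ``pos_cM``.  Positions
        must be non-negative and non-decreasing within a chromosome and
        marker ids unique genome-wide.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "marker", "pos_cM"}
        if not required.issubset(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        table = table.reset_index(drop=True)
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r} in genetic map")
        if (table["pos_cM"] < 0).any():
            raise ValueError("negative map position")
        for _, sub in table.groupby("chrom", sort=False):
            if (np.diff(sub["pos_cM"].to_numpy()) < 0).any():
                raise ValueError("positions must be non-decreasing within a chromosome")
        self.table = table

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slices(self) -> dict:
        """Contiguous index ranges per chromosome (markers sorted by position)."""
        out = {}
        idx = np.arange(self.n_markers)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            out[chrom] = idx[sub.index.to_numpy()]
        return out

    def length_cm(self) -> float:
        return float(
            sum(sub["pos_cM"].max() for _, sub in self.table.groupby("chrom", sort=False))
        )

    def length_morgan(self) -> float:
        """Genome size L in Morgan (total map length / 100)."""
        return self.length_cm() / 100.0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_markers


@dataclass
class GenotypeMatrix:
    """Allele-count genotype calls for markers x individuals.

    ``genotypes[m, i]`` is the number of copies (0/1/2) of the arbitrarily
    designated alternate allele carried by individual ``i`` at marker ``m``,
    or :data:`MISSING`.
    """

    genotypes: np.ndarray
    individuals: list
    populations: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be markers x individuals")
        if self.genotypes.shape[0] != self.gmap.n_markers:
            raise ValueError("marker dimension does not match the genetic map")
        if self.genotypes.shape[1] != len(self.individuals):
            raise ValueError("individual dimension does not match ids")
        if len(self.populations) != len(self.individuals):
            raise ValueError("every individual needs a population label")
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def markers(self) -> np.ndarray:
        return self.gmap.markers

    def population_ids(self) -> list:
        return list(dict.fromkeys(self.populations))

    def subset_markers(self, marker_ids: Sequence) -> "GenotypeMatrix":
        keep = pd.Index(self.gmap.table["marker"]).get_indexer(list(marker_ids))
        if (keep < 0).any():
            raise KeyError("unknown marker id in subset")
        return GenotypeMatrix(
            self.genotypes[keep],
            list(self.individuals),
            self.populations.copy(),
            GeneticMap(self.gmap.table.iloc[keep]),
        )

    def subset_individuals(self, ids: Sequence) -> "GenotypeMatrix":
        pos = {ind: j for j, ind in enumerate(self.individuals)}
        cols = np.array([pos[i] for i in ids])
        return GenotypeMatrix(
            self.genotypes[:, cols],
            list(ids),
            self.populations[cols],
            self.gmap,
        )

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if not np.array_equal(self.gmap.markers, other.gmap.markers):
            raise ValueError("marker sets differ")
        return GenotypeMatrix(
            np.concatenate([self.genotypes, other.genotypes], axis=1),
            list(self.individuals) + list(other.individuals),
            np.concatenate([self.populations, other.populations]),
            self.gmap,
        )


@dataclass
class CrossingScheme:
    """Parent pool membership and the crosses that generate each population."""

    pools: Mapping[str, str]
    crosses: list  # (parentA, parentB, n_progeny)
    selfing_generations: int = 2

    def population_name(self, pa: str, pb: str) -> str:
        return f"P_{pa}{pb}"

    def population_parents(self) -> dict:
        return {self.population_name(a, b): (a, b) for a, b, _ in self.crosses}

    def population_type(self, pop: str) -> str:
        """'DxD', 'FxF' or 'DxF' according to parental pool membership."""
        pa, pb = self.population_parents()[pop]
        pools = sorted((self.pools[pa], self.pools[pb]))
        if pools[0] == pools[1]:
            return f"{pools[0]}x{pools[0]}"
        return f"{pools[0]}x{pools[1]}"


def default_crossing_scheme(n_progeny: int = 100, selfing_generations: int = 2) -> CrossingScheme:
    """The six-population connected design: two intra-Dent, two intra-Flint
    and two inter-pool (Dent x Flint) crosses from eight inbred parents."""
    pools = {f"D{i}": "D" for i in range(1, 5)}
    pools.update({f"F{i}": "F" for i in range(1, 5)})
    crosses = [
        ("D1", "D2", n_progeny),
        ("D3", "D4", n_progeny),
        ("F1", "F2", n_progeny),
        ("F3", "F4", n_progeny),
        ("D1", "F1", n_progeny),
        ("D4", "F4", n_progeny),
    ]
    return CrossingScheme(pools, crosses, selfing_generations)


@dataclass
class TrialDesign:
    """Assignment of genotypes to incomplete blocks, one row per plot.

    ``table`` has columns genotype, replicate, block; each genotype appears
    once per replicate and the blocks of a replicate partition the genotypes.
    """

    condition: str
    table: pd.DataFrame
    n_blocks: int

    def __post_init__(self):
        counts = self.table.groupby(["genotype", "replicate"]).size()
        if (counts != 1).any():
            raise ValueError("each genotype must appear exactly once per replicate")

    @property
    def replicates(self) -> list:
        return sorted(self.table["replicate"].unique())


@dataclass
class TraitTruth:
    """Ground-truth genetic architecture of one simulated trait."""

    qtl_markers: list
    additive: np.ndarray
    dominance: np.ndarray
    heat_multiplier: np.ndarray  # per-QTL effect multiplier under heat
    mu: float
    condition_effect: Mapping[str, float]
    sigma2_e: Mapping[str, float]
    sigma2_rep: float
    sigma2_block: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("additive", "dominance", "heat_multiplier"):
            d[k] = np.asarray(d[k]).tolist()
        d["condition_effect"] = dict(self.condition_effect)
        d["sigma2_e"] = dict(self.sigma2_e)
        return d


@dataclass
class SimTruth:
    """Everything the phenotype simulator drew, recorded exactly as used."""

    traits: Mapping[str, TraitTruth]
    seed: int
    rep_effects: dict = field(default_factory=dict)
    block_effects: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "traits": {t: tt.to_dict() for t, tt in self.traits.items()},
            "rep_effects": {k: [float(x) for x in v] for k, v in self.rep_effects.items()},
            "block_effects": {
                k: [[int(r), int(b), float(e)] for r, b, e in v]
                for k, v in self.block_effects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
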