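"""Deterministic expectations for genomic prediction.

Effective population size (harmonic mean over generations), effective
number of chromosome segments M_e = 2 N_e L, the expected within-population
prediction ability r = sqrt(N h2 / (N h2 + M_e)), and the relative merit of
genome-wide versus phenotypic selection expressed as the maximum relative
cycle length 100 * r / h2 at equal selection gain.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def effective_population_size(generation_sizes: Sequence[float]) -> float:
    """Harmonic-mean effective size N_e = t / sum(1/N_i)."""
    sizes = np.asarray(generation_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one generation size")
    if (sizes < 1).any():
        raise ValueError("generation sizes must be >= 1")
    return float(len(sizes) / np.sum(1.0 / sizes))


def effective_number_of_segments(n_e: float, genome_length_morgan: float) -> float:
    """M_e = 2 N_e L with L the genome size in Morgan."""
    if n_e <= 0 or genome_length_morgan <= 0:
        raise ValueError("N_e and L must be positive")
    return 2.0 * n_e * genome_length_morgan


def expected_ability(n_ts: float, h2: float, m_e: float) -> float:
    """Expected within-population prediction ability,
    r = sqrt(N h2 / (N h2 + M_e))."""
    if n_ts < 1:
        raise ValueError("training-set size must be >= 1")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    if m_e <= 0:
        raise ValueError("M_e must be positive")
    return float(np.sqrt(n_ts * h2 / (n_ts * h2 + m_e)))


def relative_cycle_length(r: float, h2: float) -> float:
    """Maximum relative cycle length (%) of genome-wide vs phenotypic
    selection at equal gain: 100 * r / h2."""
    if h2 <= 0:
        raise ValueError("relative cycle length undefined for h2 <= 0")
    return 100.0 * r / h2


def expectation_table(
    observed: pd.DataFrame,
    n_e: dict,
    genome_length_morgan: float,
    n_ts: dict,
    h2: dict,
) -> pd.DataFrame:
    """Observed vs expected within-population prediction abilities.

    ``observed`` has columns population, trait, r_obs; ``n_e``, ``n_ts``
    are per-population, ``h2`` per (population, trait) or per trait.
    """
    rows = []
    for pop, trait, r_obs in observed[["population", "trait", "r_obs"]].itertuples(index=False):
        m_e = effective_number_of_segments(n_e[pop], genome_length_morgan)
        h = h2.get((pop, trait), h2.get(trait))
        r_exp = expected_ability(n_ts[pop], h, m_e)
        rows.append((pop, trait, float(r_obs), r_exp, m_e))
    return pd.DataFrame(rows, columns=["population", "trait", "r_obs", "r_exp", "m_e"])
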