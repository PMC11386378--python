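"""Cross-analysis summary: membership matrix and VFA consumption math.

Collates the taxon sets returned by each analytical stage (top-25
abundance, resilient/susceptible response, stable ensemble, core, niche
specialists) into a single boolean membership matrix, and provides the
small amount of arithmetic needed for volatile-fatty-acid consumption
summaries and their group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("Top-25", "Resilient", "Susceptible", "Stable", "Core", "Specialist")


@dataclass
class VfaSeries:
    """One acid's concentration trajectory over a 48-h incubation cycle."""

    acid: str                  # acetic | propionic | butyric
    times_h: np.ndarray
    concentrations: np.ndarray  # mg per litre
    replicate: int = 1

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.times_h) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")
        if (np.diff(self.times_h) <= 0).any():
            raise ValueError("time points must be strictly increasing")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be non-negative")


def build_membership_matrix(
    top25, resilient, susceptible, stable, core, specialist
) -> pd.DataFrame:
    """Boolean taxon × category matrix over the union of the input sets.

    Rows are sorted by number of categories (descending) then
    lexicographically. A taxon in both the resilient and susceptible sets
    violates the sign rule and is an error.
    """
    sets = dict(zip(CATEGORIES, (set(map(str, s)) for s in
                                 (top25, resilient, susceptible, stable, core,
                                  specialist))))
    both = sets["Resilient"] & sets["Susceptible"]
    if both:
        raise ValueError(
            f"taxa cannot be both resilient and susceptible: {sorted(both)}"
        )
    union = sorted(set().union(*sets.values()))
    df = pd.DataFrame(
        {cat: [t in sets[cat] for t in union] for cat in CATEGORIES},
        index=pd.Index(union, name="taxon"),
    )
    order = sorted(union, key=lambda t: (-int(df.loc[t].sum()), t))
    return df.loc[order]


def vfa_consumption(series: VfaSeries) -> float:
    """Fraction of the acid consumed over the cycle: (C_first − C_last)/C_first.

    Negative values indicate net production. NaN when the initial
    concentration is zero.
    """
    if len(series.times_h) < 2:
        raise ValueError("need at least two time points")
    c0, c1 = series.concentrations[0], series.concentrations[-1]
    if c0 == 0:
        import warnings

        warnings.warn("initial concentration is zero; consumption undefined")
        return float("nan")
    return min((c0 - c1) / c0, 1.0)


def compare_consumption(
    group_a, group_b, n_perm: int = 9999, seed: int = 0
) -> float:
    """Two-sided permutation test on the difference of mean consumption.

    p = (#{|permuted difference| ≥ |observed|} + 1) / (n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    hits = 0
    n_a = len(a)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
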