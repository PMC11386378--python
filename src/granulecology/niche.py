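"""Levins niche breadth, permutation null, and asymmetric niche overlap.

A genus's niche breadth over R condition states is B = 1/Σ_j q_j², where
q_j is the genus's share of mean relative abundance in state j; B_N = B/R
lies in [1/R, 1]. Generalists approach B_N = 1 (uniform use of all
states); specialists approach 1/R (all abundance in one state).
Significance comes from a seeded permutation null that shuffles
sample-to-state assignments, with Benjamini–Hochberg adjustment across
genera per tail. Levins overlap LO_{1,2} = Σ_j q_{1j} q_{2j} / Σ_j q_{2j}²
is deliberately asymmetric: LO_{1,2} = 1 means genus 1 covers every state
where genus 2 occurs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_model import GROUPS, RelativeAbundanceMatrix, SampleFrame


def _state_mean_matrix(frame: SampleFrame, sample_ids) -> tuple[np.ndarray, list]:
    """Samples × states matrix averaging within each design group."""
    groups = frame.groups_of(sample_ids)
    states = [g for g in GROUPS if g in set(groups)]
    G = np.zeros((len(sample_ids), len(states)))
    for j, s in enumerate(states):
        cols = groups == s
        G[cols, j] = 1.0 / cols.sum()
    return G, states


def _breadth_from_means(means: np.ndarray, R: int) -> tuple[np.ndarray, np.ndarray]:
    """(B, B_N) per genus from a genus × state mean-abundance matrix."""
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = means / totals
        B = 1.0 / (q**2).sum(axis=1)
    B = np.where(totals[:, 0] > 0, B, np.nan)
    return B, B / R


def niche_breadth(
    r: RelativeAbundanceMatrix, frame: SampleFrame
) -> pd.DataFrame:
    """Levins B and normalised B_N per genus over the design's states."""
    G, states = _state_mean_matrix(frame, r.sample_ids)
    R = len(states)
    means = r.values @ G
    B, BN = _breadth_from_means(means, R)
    if np.isnan(B).any():
        warnings.warn(
            f"{int(np.isnan(B).sum())} genera absent everywhere; breadth NA"
        )
    return pd.DataFrame(
        dict(B=B, B_N=BN, R=R),
        index=pd.Index(r.taxon_ids, name="genus"),
    )


def condition_shares(
    r: RelativeAbundanceMatrix, frame: SampleFrame
) -> pd.DataFrame:
    """Per-genus share vector q over condition states (rows sum to 1)."""
    G, states = _state_mean_matrix(frame, r.sample_ids)
    means = r.values @ G
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(totals > 0, means / totals, np.nan)
    return pd.DataFrame(q, index=pd.Index(r.taxon_ids, name="genus"),
                        columns=states)


def niche_null_test(
    r: RelativeAbundanceMatrix,
    frame: SampleFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values per genus for both niche tails.

    Sample-to-state labels are shuffled ``n_perm`` times; the
    specialist-tail p is (#{null B_N ≤ observed} + 1)/(n_perm + 1), the
    generalist tail the analogous upper-tail count. BH adjustment is
    applied across genera separately per tail.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    G, states = _state_mean_matrix(frame, r.sample_ids)
    R = len(states)
    obs = _breadth_from_means(r.values @ G, R)[1]
    rng = np.random.default_rng(seed)
    n = len(r.sample_ids)
    le = np.zeros(r.n_taxa)
    ge = np.zeros(r.n_taxa)
    for _ in range(n_perm):
        null = _breadth_from_means(r.values @ G[rng.permutation(n)], R)[1]
        le += null <= obs + 1e-12
        ge += null >= obs - 1e-12
    p_spec = (le + 1) / (n_perm + 1)
    p_gen = (ge + 1) / (n_perm + 1)
    ok = ~np.isnan(obs)
    adj_spec = np.full(r.n_taxa, np.nan)
    adj_gen = np.full(r.n_taxa, np.nan)
    adj_spec[ok] = multipletests(p_spec[ok], method="fdr_bh")[1]
    adj_gen[ok] = multipletests(p_gen[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        dict(B_N=obs, p_specialist=p_spec, p_adj_specialist=adj_spec,
             p_generalist=p_gen, p_adj_generalist=adj_gen),
        index=pd.Index(r.taxon_ids, name="genus"),
    )


def classify_niche(
    profiles: pd.DataFrame,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Specialist / generalist / neither from empirical B_N quantiles.

    Specialist: B_N below the ``lower_q`` quantile of all recovered genera
    AND adjusted specialist-tail p < alpha. Generalist: mirrored at the
    upper quantile. ``profiles`` must carry B_N, p_adj_specialist and
    p_adj_generalist columns (as from :func:`niche_null_test`).
    """
    bn = profiles["B_N"].to_numpy(dtype=float)
    ok = ~np.isnan(bn)
    if ok.sum() < 20:
        warnings.warn("fewer than 20 genera; quantile thresholds unstable")
    lo = float(np.quantile(bn[ok], lower_q))
    hi = float(np.quantile(bn[ok], upper_q))
    cls = []
    for _, row in profiles.iterrows():
        if np.isnan(row["B_N"]):
            cls.append("neither")
        elif row["B_N"] < lo and row["p_adj_specialist"] < alpha:
            cls.append("specialist")
        elif row["B_N"] > hi and row["p_adj_generalist"] < alpha:
            cls.append("generalist")
        else:
            cls.append("neither")
    out = profiles.copy()
    out["class"] = cls
    out.attrs["lower_threshold"] = lo
    out.attrs["upper_threshold"] = hi
    return out


def levins_overlap(
    r: RelativeAbundanceMatrix, frame: SampleFrame, genera
) -> pd.DataFrame:
    """Asymmetric Levins overlap matrix over ordered genus pairs.

    LO_{1,2} = Σ_j q_{1j} q_{2j} / Σ_j q_{2j}²; the diagonal is 1.
    Genera with all-zero shares get an NA row and column.
    """
    genera = list(genera)
    shares = condition_shares(r, frame)
    missing = [g for g in genera if g not in shares.index]
    if missing:
        raise KeyError(f"genera without share vectors: {missing}")
    q = shares.loc[genera].to_numpy(dtype=float)
    num = q @ q.T                        # num[a, b] = Σ_j q_a q_b
    den = (q**2).sum(axis=1)             # den[b] = Σ_j q_b²
    with np.errstate(invalid="ignore", divide="ignore"):
        lo = num / den[None, :]
    valid = den > 0
    lo[:, ~valid] = np.nan
    lo[~valid, :] = np.nan
    np.fill_diagonal(lo, np.where(valid, 1.0, np.nan))
    return pd.DataFrame(lo, index=pd.Index(genera, name="genus_1"),
                        columns=pd.Index(genera, name="genus_2"))
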