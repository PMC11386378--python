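"""Alpha and beta diversity with group tests.

Chao1 richness and Shannon entropy (natural log) per sample with one-way
ANOVA group tests and pairwise Welch comparisons; Bray–Curtis distances,
principal-coordinates analysis (classical scaling of the Gower-centred
distance matrix) and a seeded permutation PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _skbio_alpha
from statsmodels.stats.multitest import multipletests

from .io_model import CountMatrix, RelativeAbundanceMatrix, to_relative

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    distances: np.ndarray       # square, symmetric, zero diagonal
    coordinates: np.ndarray     # samples × retained axes, scaled by √eigenvalue
    eigenvalues: np.ndarray     # all eigenvalues, descending (negatives reported)
    permanova_f: float | None = None
    permanova_p: float | None = None


def rarefy(m: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep, cols = [], []
    for j, s in enumerate(m.sample_ids):
        total = int(m.counts[:, j].sum())
        if total < depth:
            warnings.warn(f"sample {s!r} has only {total} reads; dropped")
            continue
        keep.append(s)
        cols.append(rng.multivariate_hypergeometric(m.counts[:, j], depth))
    if not keep:
        raise ValueError("no sample reaches the rarefaction depth")
    return CountMatrix(list(m.taxon_ids), keep, np.column_stack(cols))


def chao1(col) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1−1) / (2(F2+1))."""
    c = np.asarray(col)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return float(_skbio_alpha.chao1(c.astype(int), bias_corrected=True))


def shannon(col) -> float:
    """Shannon entropy in nats: −Σ p ln p over nonzero proportions."""
    c = np.asarray(col, dtype=float)
    if c.sum() <= 0:
        raise ValueError("sample has zero total count")
    return float(_skbio_alpha.shannon(c, base=np.e))


def alpha_diversity_table(m: CountMatrix) -> pd.DataFrame:
    rows = []
    for j, s in enumerate(m.sample_ids):
        col = m.counts[:, j]
        rows.append(dict(sample_id=s, S_obs=int((col > 0).sum()),
                         chao1=chao1(col), shannon=shannon(col)))
    return pd.DataFrame(rows).set_index("sample_id")


def group_anova(values, groups) -> tuple[float, pd.DataFrame]:
    """Omnibus one-way ANOVA plus pairwise Welch tests with BH adjustment.

    Returns the omnibus p-value and a table of pairwise comparisons with
    raw p, BH-adjusted p, and significance stars.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    per_group = {g: values[groups == g] for g in levels}
    if len(levels) < 2 or any(len(v) < 2 for v in per_group.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_omnibus = stats.f_oneway(*per_group.values())
    if np.isnan(p_omnibus):  # zero variance everywhere
        p_omnibus = 1.0
    pairs, praw = [], []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            va, vb = per_group[a], per_group[b]
            if np.ptp(np.concatenate([va, vb])) == 0:
                p = 1.0
            else:
                _, p = stats.ttest_ind(va, vb, equal_var=False)
            pairs.append((a, b))
            praw.append(float(p))
    padj = multipletests(praw, method="fdr_bh")[1] if praw else np.array([])
    table = pd.DataFrame(
        dict(group_a=[a for a, _ in pairs], group_b=[b for _, b in pairs],
             p=praw, p_adj=padj, stars=[stars(p) for p in padj]),
    )
    return float(p_omnibus), table


def bray_curtis(r: RelativeAbundanceMatrix) -> np.ndarray:
    """Pairwise Bray–Curtis distances: d(j,k) = 1 − Σ_i min(r_ij, r_ik)."""
    return squareform(pdist(r.values.T, metric="braycurtis"))


def pcoa(d: np.ndarray, sample_ids=None) -> OrdinationResult:
    """Classical scaling: eigendecomposition of the Gower-centred −½d².

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalue; axes with negative eigenvalues are reported in the
    eigenvalue vector but dropped from the coordinates.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n)]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return OrdinationResult(list(sample_ids), d, coords, eigval)


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F from the squared-distance partition (Anderson's PERMANOVA)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        n_groups += 1
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within <= 0:
        return np.inf
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    d: np.ndarray, groups, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation PERMANOVA: p = (#{F_perm ≥ F_obs} + 1) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if (sizes == 1).all():
        raise ValueError("all groups are singletons")
    if (sizes == 1).any():
        warnings.warn("some groups have a single sample")
    d2 = np.asarray(d, dtype=float) ** 2
    f_obs = _permanova_f(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(groups)) >= f_obs - 1e-12:
            hits += 1
    return float(f_obs), (hits + 1) / (n_perm + 1)


def beta_diversity(
    m: CountMatrix, groups, n_perm: int = 999, seed: int = 0
) -> OrdinationResult:
    """Bray–Curtis distances, PCoA and PERMANOVA in one pass."""
    d = bray_curtis(to_relative(m))
    res = pcoa(d, list(m.sample_ids))
    res.permanova_f, res.permanova_p = permanova(d, groups, n_perm, seed)
    return res
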