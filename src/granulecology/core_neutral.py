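"""Core-microbiome ranking and Sloan neutral-assembly partitioning.

ASVs are ranked by an occupancy index combining overall occupancy with
mean within-group (replicate-consistency) occupancy. Walking down the
ranking, the cumulative percent of total Bray–Curtis similarity explained
by the top-ranked set defines a contribution curve; the core is the
smallest prefix after which every marginal gain falls below a threshold
(the "last 2% decrease" rule).

Independently, the Sloan neutral community model predicts each ASV's
occupancy from its mean relative abundance and a single migration
parameter Nm; ASVs whose observed occupancy falls above the 95% band were
plausibly selected by the environment, those below assembled under
dispersal limitation, and those inside are indistinguishable from neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln
from statsmodels.stats.proportion import proportion_confint

from .io_model import CountMatrix, SampleFrame, to_relative


@dataclass
class SloanFit:
    taxon_ids: list[str]
    mean_abundance: np.ndarray   # metacommunity estimate p_i
    occupancy: np.ndarray        # observed detection fraction o_i
    predicted: np.ndarray        # fitted occupancy under neutrality
    ci_low: np.ndarray
    ci_high: np.ndarray
    Nm: float
    m: float                     # Nm × detection limit (migration probability)
    r_squared: float
    detection_limit: float
    n_samples: int
    occupancy_model: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(mean_abundance=self.mean_abundance, occupancy=self.occupancy,
                 predicted=self.predicted, ci_low=self.ci_low,
                 ci_high=self.ci_high),
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )


def occupancy_index(
    m: CountMatrix, frame: SampleFrame, w_all: float = 0.5
) -> pd.DataFrame:
    """Rank ASVs by w·occ_all + (1−w)·mean within-group occupancy.

    Ties break by total abundance (descending) then taxon id. Returns a
    frame indexed by taxon with columns occ_all, occ_group, index, rank.
    """
    groups = frame.groups_of(m.sample_ids)
    levels = sorted(pd.unique(groups))  # fixed order: exact float summation
    if len(levels) < 2:
        raise ValueError("need at least 2 design groups")
    present = m.counts > 0
    occ_all = present.mean(axis=1)
    occ_group = np.zeros(m.n_taxa)
    for g in levels:
        cols = groups == g
        if cols.sum() == 0:
            raise ValueError(f"group {g} is empty")
        occ_group += present[:, cols].mean(axis=1)
    occ_group /= len(levels)
    index = w_all * occ_all + (1 - w_all) * occ_group
    totals = m.counts.sum(axis=1)
    order = sorted(
        range(m.n_taxa), key=lambda i: (-index[i], -totals[i], m.taxon_ids[i])
    )
    df = pd.DataFrame(
        dict(occ_all=occ_all, occ_group=occ_group, index=index,
             total_count=totals),
        index=pd.Index(m.taxon_ids, name="taxon_id"),
    ).iloc[order]
    df["rank"] = np.arange(1, m.n_taxa + 1)
    return df


def bc_contribution_curve(ranking, m: CountMatrix) -> np.ndarray:
    """Cumulative percent contribution of top-ranked sets to BC similarity.

    For each sample pair, the similarity share of set K is
    Σ_{i∈K} 2·min(r_ij, r_ik) / (Σ_i r_ij + Σ_i r_ik); the curve value at
    rank r is the mean over pairs of share / total similarity × 100.
    """
    ranking = list(ranking)
    if set(ranking) != set(m.taxon_ids):
        raise ValueError("ranking must cover exactly the ASVs of the matrix")
    rel = to_relative(m)
    idx = {t: i for i, t in enumerate(rel.taxon_ids)}
    rows = [idx[t] for t in ranking]
    v = rel.values[rows]  # taxa (ranked order) × samples
    n = v.shape[1]
    pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]
    mins = np.minimum(v[:, [j for j, _ in pairs]], v[:, [k for _, k in pairs]])
    totals = mins.sum(axis=0)  # total similarity per pair (denominators are 2)
    ok = totals > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} sample pair(s) share no taxa; skipped")
    if not ok.any():
        raise ValueError("no sample pair with nonzero similarity")
    shares = np.cumsum(mins[:, ok], axis=0) / totals[ok]
    return shares.mean(axis=1) * 100.0


def select_core(curve, ranking=None, threshold: float = 2.0):
    """Core prefix under the "last ≥threshold% gain" rule.

    The core ends at the smallest rank r* after which every marginal gain
    of the contribution curve is below ``threshold`` percentage points.
    Returns the core size, or the top-r* taxa when ``ranking`` is given.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    curve = np.asarray(curve, dtype=float)
    if (np.diff(curve) < -1e-9).any():
        raise ValueError("contribution curve must be non-decreasing")
    gains = np.diff(curve)
    big = np.flatnonzero(gains >= threshold)
    r_star = int(big[-1]) + 2 if len(big) else 1  # gains[i] is rank i+1 → i+2
    r_star = min(r_star, len(curve))
    if ranking is None:
        return r_star
    return list(ranking)[:r_star]


def _predicted_occupancy(pm, Nm, d, n_reads, model):
    a = Nm * pm
    b = Nm * (1.0 - pm)
    if model == "exact":
        # probability of ≥1 read in a multinomial sample of size n_reads
        # whose composition is Beta(a, b): 1 − B(a, b+N)/B(a, b)
        return 1.0 - np.exp(betaln(a, b + n_reads) - betaln(a, b))
    if model == "threshold":
        return 1.0 - stats.beta.cdf(d, a, b)
    raise ValueError(f"unknown occupancy model {model!r}")


def fit_neutral_model(
    m: CountMatrix,
    detection_limit: float | None = None,
    occupancy_model: str = "exact",
) -> SloanFit:
    """Fit the Sloan neutral model by least squares over taxa.

    ``detection_limit`` defaults to 1/(mean sample depth). The default
    occupancy model computes the exact probability of detecting at least
    one read at that depth under the fitted beta composition; the
    classical threshold approximation 1 − BetaCDF(d; Nm·p, Nm(1−p)) is
    available as ``occupancy_model="threshold"``. The 95% band is a Wilson
    binomial interval around the predicted occupancy at n = #samples.
    """
    depths = m.counts.sum(axis=0)
    if (depths == 0).any():
        raise ValueError("samples with zero total count")
    d = detection_limit if detection_limit is not None else 1.0 / depths.mean()
    if d <= 0:
        raise ValueError("detection limit must be positive")
    n_reads = max(int(round(1.0 / d)), 1)
    rel = m.counts / depths
    pm = rel.mean(axis=1)
    occ = (m.counts > 0).mean(axis=1)
    keep = pm > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} never-observed taxa excluded from fit")
    taxa = [t for t, k in zip(m.taxon_ids, keep) if k]
    pm, occ = pm[keep], occ[keep]
    n_partial = int(((occ > 0) & (occ < 1)).sum())
    if n_partial < 10:
        warnings.warn(
            f"only {n_partial} taxa with intermediate occupancy; fit unstable"
        )

    def sse(log_nm):
        pred = _predicted_occupancy(pm, np.exp(log_nm), d, n_reads,
                                    occupancy_model)
        return float(((occ - pred) ** 2).sum())

    lo, hi = np.log(1e-3), np.log(1e9)
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    if res.x < lo + 1e-3 or res.x > hi - 1e-3:
        warnings.warn("Nm optimiser at bound; fit may be degenerate")
    Nm = float(np.exp(res.x))
    pred = _predicted_occupancy(pm, Nm, d, n_reads, occupancy_model)
    ss_tot = float(((occ - occ.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / ss_tot if ss_tot > 0 else np.nan
    n = m.n_samples
    ci_low, ci_high = proportion_confint(
        pred * n, n, alpha=0.05, method="wilson"
    )
    return SloanFit(
        taxon_ids=taxa, mean_abundance=pm, occupancy=occ, predicted=pred,
        ci_low=np.asarray(ci_low), ci_high=np.asarray(ci_high), Nm=Nm,
        m=Nm * d, r_squared=r2, detection_limit=d, n_samples=n,
        occupancy_model=occupancy_model,
    )


def classify_neutrality(fit: SloanFit, subset=None) -> pd.Series:
    """Partition ASVs into above / neutral / below the 95% neutral band.

    Above the band: occupancy higher than neutral assembly predicts —
    selected by the environment. Below: dispersal limited.
    """
    subset = list(subset) if subset is not None else list(fit.taxon_ids)
    idx = {t: i for i, t in enumerate(fit.taxon_ids)}
    missing = [t for t in subset if t not in idx]
    if missing:
        raise KeyError(f"ASVs absent from fit: {missing}")
    out = {}
    for t in subset:
        i = idx[t]
        if fit.occupancy[i] > fit.ci_high[i]:
            out[t] = "above"
        elif fit.occupancy[i] < fit.ci_low[i]:
            out[t] = "below"
        else:
            out[t] = "neutral"
    return pd.Series(out, name="class")
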