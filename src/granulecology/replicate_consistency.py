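"""CLR-based replicate-consistency screening.

Tests whether a group of replicate granules forms one homogeneous
community: samples are centred-log-ratio transformed, each sample's share
of the group's total sum of squares is computed, and samples contributing
more than the median plus twice the interquartile range of the
contributions are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import CountMatrix


@dataclass
class ClrMatrix:
    """Centred-log-ratio transformed counts; columns sum to zero."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        colsums = np.abs(self.values.sum(axis=0))
        if colsums.size and colsums.max() > 1e-8:
            raise ValueError("CLR columns must sum to zero")


@dataclass
class OutlierReport:
    sample_ids: list[str]
    contributions: np.ndarray  # fractions of total group SS, sum to 1
    median: float
    iqr: float
    cutoff: float              # median + 2·IQR
    outliers: list[str]        # samples strictly above the cutoff


def clr_transform(m: CountMatrix, pseudocount: float = 0.5) -> ClrMatrix:
    """CLR per sample: x_ij = ln((c_ij + pc) / geometric mean_i(c_ij + pc))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(m.counts + pseudocount)
    centred = logged - logged.mean(axis=0, keepdims=True)
    return ClrMatrix(list(m.taxon_ids), list(m.sample_ids), centred, pseudocount)


def variance_contributions(x: ClrMatrix) -> np.ndarray:
    """Per-sample share of the group's total sum of squares.

    SS_j = Σ_i (x_ij − x̄_i·)² with x̄_i· the per-taxon mean across samples;
    contributions are SS_j normalised to sum to one.
    """
    if x.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    dev = x.values - x.values.mean(axis=1, keepdims=True)
    ss = (dev**2).sum(axis=0)
    total = ss.sum()
    if total == 0:
        raise ValueError("no variance in group")
    return ss / total


def detect_outliers(contributions, sample_ids=None) -> OutlierReport:
    """Flag samples contributing more than median + 2·IQR of the shares.

    The inequality is strict, matching an outlier defined as contributing
    *greater than* the cutoff. Quantiles use linear interpolation.
    """
    c = np.asarray(contributions, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 samples for a meaningful IQR")
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(len(c))]
    med = float(np.median(c))
    q1, q3 = np.quantile(c, [0.25, 0.75])
    iqr = float(q3 - q1)
    cutoff = med + 2.0 * iqr
    flags = [s for s, v in zip(sample_ids, c) if v > cutoff]
    return OutlierReport(list(sample_ids), c, med, iqr, cutoff, flags)


def screen_group(m: CountMatrix, pseudocount: float = 0.5) -> OutlierReport:
    """Full screen of one replicate group: CLR → contributions → outliers."""
    contrib = variance_contributions(clr_transform(m, pseudocount))
    return detect_outliers(contrib, list(m.sample_ids))
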