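"""Per-genus condition-response modelling and resilient/susceptible calls.

Counts of the most abundant genera are regressed on the nine incubation
conditions with the untreated (ORIGINAL) granules as reference, using a
negative-binomial model with the log sample total as offset:

    log μ_ij = log s_i + α_j + β_{j,c(i)}  (+ u_iᵀ λ_j for latent rank > 0)

A genus whose nine condition coefficients are all positive is *resilient*;
all negative, *susceptible*; otherwise *mixed*. Optional latent factors
(rank d > 0) absorb residual sample-level covariance and are estimated by
alternating conditional maximisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_model import CONDITIONS, ORIGINAL, CountMatrix, SampleFrame

MIN_DISPERSION = 1e-8
Z95 = 1.959963984540054


@dataclass
class ResponseModel:
    taxa: list[str]
    intercepts: pd.Series            # α_j
    beta: pd.DataFrame               # taxon × 9 conditions, natural-log scale
    se: pd.DataFrame                 # Wald standard errors of β
    dispersion: pd.Series            # NB dispersion φ_j (NB2 alpha)
    converged: pd.Series             # per-taxon fit flag
    rank: int = 0
    loadings: pd.DataFrame | None = None   # taxon × rank
    scores: pd.DataFrame | None = None     # sample × rank
    labels: pd.Series | None = None

    def wald_ci(self, level: float = 0.95):
        z = Z95 if level == 0.95 else float(
            -np.sqrt(2) * _erfcinv(1 - level)
        )
        return self.beta - z * self.se, self.beta + z * self.se


def _erfcinv(x):
    from scipy.special import erfcinv

    return erfcinv(x)


def _design(frame: SampleFrame, sample_ids) -> tuple[np.ndarray, list[str]]:
    groups = frame.groups_of(sample_ids)
    cols = [np.ones(len(sample_ids))]
    for c in CONDITIONS:
        cols.append((groups == c).astype(float))
    return np.column_stack(cols), ["intercept"] + list(CONDITIONS)


def _moment_alpha(y, mu) -> float:
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu**2).sum()
    return max(num / den if den > 0 else 0.0, MIN_DISPERSION)


def _fit_taxon(y, X, offset):
    """ML negative-binomial fit; GLM fallback when the ML fit fails.

    Returns (params, se, alpha, converged)."""
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(y, X, offset=offset).fit(
                disp=0, maxiter=200, method="bfgs"
            )
        params, bse = res.params, res.bse
        conv = bool(res.mle_retvals.get("converged", False))
        if np.all(np.isfinite(params[:k])):
            alpha = max(float(params[-1]), MIN_DISPERSION)
            se = np.where(np.isfinite(bse[:k]), bse[:k], np.inf)
            return params[:k], se, alpha, conv
    except Exception:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _moment_alpha(y, pois.fittedvalues)
        nb = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
    se = np.where(np.isfinite(nb.bse), nb.bse, np.inf)
    return nb.params, se, alpha, False


def fit_response_model(
    m: CountMatrix,
    frame: SampleFrame,
    rank: int = 0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ResponseModel:
    """Fit the per-taxon condition-response model.

    ``m`` is expected to be restricted to the genera of interest (the
    study used the top-100 most abundant). The ORIGINAL group must have at
    least two samples and every condition at least one.
    """
    groups = frame.groups_of(m.sample_ids)
    if (groups == ORIGINAL).sum() < 2:
        raise ValueError("ORIGINAL group needs at least 2 samples")
    for c in CONDITIONS:
        if (groups == c).sum() < 1:
            raise ValueError(f"condition {c} has no samples")
    X, names = _design(frame, m.sample_ids)
    offset = np.log(m.counts.sum(axis=0).astype(float))
    k = X.shape[1]

    params = np.full((m.n_taxa, k), np.nan)
    ses = np.full((m.n_taxa, k), np.nan)
    alphas = np.full(m.n_taxa, np.nan)
    conv = np.zeros(m.n_taxa, dtype=bool)
    for i, t in enumerate(m.taxon_ids):
        y = m.counts[i].astype(float)
        if y.sum() == 0:
            warnings.warn(f"taxon {t!r} has all-zero counts; coefficients NA")
            continue
        params[i], ses[i], alphas[i], conv[i] = _fit_taxon(y, X, offset)
        if not conv[i]:
            warnings.warn(f"taxon {t!r}: fit did not fully converge")

    loadings = scores = None
    if rank > 0:
        params, ses, loadings, scores = _fit_latent(
            m, X, offset, params, alphas, rank, seed, max_iter, tol
        )

    idx = pd.Index(m.taxon_ids, name="taxon")
    model = ResponseModel(
        taxa=list(m.taxon_ids),
        intercepts=pd.Series(params[:, 0], index=idx),
        beta=pd.DataFrame(params[:, 1:], index=idx, columns=list(CONDITIONS)),
        se=pd.DataFrame(ses[:, 1:], index=idx, columns=list(CONDITIONS)),
        dispersion=pd.Series(alphas, index=idx),
        converged=pd.Series(conv, index=idx),
        rank=rank,
        loadings=loadings,
        scores=scores,
    )
    model.labels = classify_response(model)
    return model


def _nb_loglik(y, mu, alpha):
    from scipy.special import gammaln

    a = 1.0 / alpha
    return (
        gammaln(y + a) - gammaln(a) - gammaln(y + 1)
        + a * np.log(a / (a + mu)) + y * np.log(mu / (a + mu))
    ).sum()


def _fit_latent(m, X, offset, params0, alphas, rank, seed, max_iter, tol):
    """Alternating conditional maximisation for latent scores and loadings.

    Per-taxon dispersions are held at their rank-0 ML estimates; the taxon
    step is an NB GLM on [design | scores], the sample step a Fisher-scoring
    update of each score vector.
    """
    rng = np.random.default_rng(seed)
    n_taxa, n_samples = m.counts.shape
    k = X.shape[1]
    fitted = np.flatnonzero(m.counts.sum(axis=1) > 0)
    U = rng.normal(0.0, 0.1, (n_samples, rank))
    L = np.zeros((n_taxa, rank))
    params = params0.copy()
    ses = np.full((n_taxa, k), np.nan)
    alphas = np.where(np.isfinite(alphas), np.maximum(alphas, MIN_DISPERSION), 1.0)
    last_ll = -np.inf
    for _ in range(max_iter):
        # taxon step
        Xfull = np.column_stack([X, U])
        for i in fitted:
            y = m.counts[i].astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(
                        y, Xfull,
                        family=sm.families.NegativeBinomial(alpha=alphas[i]),
                        offset=offset,
                    ).fit()
                except Exception:
                    continue
            params[i] = res.params[:k]
            L[i] = res.params[k:]
            ses[i] = np.where(np.isfinite(res.bse[:k]), res.bse[:k], np.inf)
        # sample step: one Fisher-scoring update per score vector
        eta_fixed = offset[None, :] + (X @ params[fitted].T).T  # taxa × samples
        for j in range(n_samples):
            lam = L[fitted]
            y = m.counts[fitted, j].astype(float)
            mu = np.exp(eta_fixed[:, j] + lam @ U[j])
            w = mu / (1.0 + alphas[fitted] * mu)
            grad = lam.T @ ((y - mu) / (1.0 + alphas[fitted] * mu))
            hess = (lam * w[:, None]).T @ lam + 1e-8 * np.eye(rank)
            U[j] = U[j] + np.linalg.solve(hess, grad)
        U -= U.mean(axis=0)  # identification: centred scores
        ll = 0.0
        for i in fitted:
            mu = np.exp(offset + X @ params[i] + U @ L[i])
            ll += _nb_loglik(m.counts[i].astype(float), mu, alphas[i])
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    idx = pd.Index(m.taxon_ids, name="taxon")
    cols = [f"LV{r + 1}" for r in range(rank)]
    return params, ses, pd.DataFrame(L, index=idx, columns=cols), pd.DataFrame(
        U, index=pd.Index(m.sample_ids, name="sample"), columns=cols
    )


def classify_response(model: ResponseModel, require_ci: bool = False) -> pd.Series:
    """Label each taxon resilient / susceptible / mixed by coefficient signs.

    With ``require_ci``, a condition counts as positive (negative) only
    when its 95% Wald interval lies entirely above (below) zero.
    """
    labels = {}
    lo, hi = model.wald_ci()
    for t in model.taxa:
        b = model.beta.loc[t].to_numpy()
        if np.isnan(b).any():
            warnings.warn(f"taxon {t!r} has NA coefficients; labelled mixed")
            labels[t] = "mixed"
            continue
        if require_ci:
            pos = (lo.loc[t].to_numpy() > 0).all()
            neg = (hi.loc[t].to_numpy() < 0).all()
        else:
            pos = (b > 0).all()
            neg = (b < 0).all()
        labels[t] = "resilient" if pos else "susceptible" if neg else "mixed"
    return pd.Series(labels, name="label")
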