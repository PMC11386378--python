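"""Synthetic granule-community generator with planted ground truth.

Emulates the study design — 16 untreated ("ORIGINAL") replicate granules
plus nine incubation conditions with 3 replicate granules each (43 samples)
— as a compositional count model: each sample's expected composition is the
softmax of per-taxon base log-abundances plus condition-specific log-fold
effects, and counts are drawn Dirichlet-multinomial at a sampled sequencing
depth. Planted taxon sets give every downstream stage a recoverable truth:

* resilient / susceptible genera: log-fold effect +δ / −δ in all nine
  conditions relative to ORIGINAL;
* stable-ensemble genera: per-condition effects rescaled so the subset's
  summed (unnormalised) abundance is preserved, realising a low-CV subset;
* core ASVs: abundance boosted so they are detected in every sample;
* neutral-block ASVs: per-sample abundance fluctuation drawn from the
  gamma construction of a Dirichlet(N·m·p) local community;
* specialist genera: abundance concentrated in k ≤ 2 "home" conditions.

A single global seed fans out to per-stage child seeds by fixed offsets so
stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    CONDITIONS,
    ORIGINAL,
    RANKS,
    UNKNOWN_GENUS,
    CountMatrix,
    SampleFrame,
    TaxonomyTable,
)
from .integration import VfaSeries

_STAGE_OFFSETS = dict(
    taxonomy=1, base=2, effects=3, depths=4, counts=5, neutral=6, posthoc=7
)

#: Default time grid of the 48-h incubation cycle (hours).
VFA_TIMEPOINTS = (0, 4, 8, 12, 20, 24, 28, 32, 36, 40, 42, 48)


class SimConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study-design conditions."""

    n_taxa: int = 300
    n_genera: int = 120
    n_original: int = 16
    n_replicates_per_condition: int = 3
    depth_mean: float = 20_000.0
    depth_sigma: float = 0.1           # lognormal sigma of sequencing depth
    base_mu: float = 0.0               # base log-abundance location
    base_sigma: float = 2.0            # base log-abundance spread
    theta: float = 2000.0              # Dirichlet-multinomial concentration
    frac_unassigned: float = 0.1       # ASVs with no genus ("unknowns")
    # planted sets (counts of genera unless noted) and effect sizes
    n_resilient: int = 8
    n_susceptible: int = 8
    n_stable: int = 10
    n_core: int = 10                   # ASVs
    n_neutral: int = 30                # ASVs
    n_specialist: int = 6
    n_selected: int = 0                # ASVs, occupancy boosted post hoc
    n_dispersal_limited: int = 0       # ASVs, occupancy suppressed post hoc
    delta_effect: float = 1.0          # |log-fold effect| for resilient/susceptible
    specialist_effect: float = 4.0     # home-condition log-fold boost
    specialist_k: int = 1              # number of home conditions (≤ 2)
    stable_effect_sd: float = 0.5      # pre-rescaling stable-member effect spread
    background_effect_sd: float = 0.5  # condition effects on background taxa
    planted_boost: float = 1.0         # mean base log-abundance, planted genera
    core_boost: float = 3.0            # mean base log-abundance, core ASVs
    neutral_m: float = 0.1             # migration parameter of the neutral block
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.neutral_m <= 1):
            raise SimConfigError("neutral_m must be in (0, 1]")
        if not (0 <= self.frac_unassigned < 1):
            raise SimConfigError("frac_unassigned must be in [0, 1)")
        if self.specialist_k not in (1, 2):
            raise SimConfigError("specialist_k must be 1 or 2")
        for name in ("delta_effect", "specialist_effect", "stable_effect_sd",
                     "background_effect_sd"):
            if not np.isfinite(getattr(self, name)):
                raise SimConfigError(f"{name} must be finite")
        if self.n_taxa < self.n_core + self.n_neutral + self.n_selected + \
                self.n_dispersal_limited:
            raise SimConfigError("ASV-level planted sets exceed n_taxa")


@dataclass
class PlantedTruth:
    """Ground-truth labels and parameters of a simulated experiment."""

    labels: pd.DataFrame        # index taxon_id; columns label, genus
    genus_labels: pd.DataFrame  # index genus; column label
    m: float                    # neutral-block migration parameter
    delta: pd.DataFrame         # taxon × condition true log-fold effects

    def taxa_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels["label"] == label])

    def genera_with(self, label: str) -> list[str]:
        return list(
            self.genus_labels.index[self.genus_labels["label"] == label]
        )


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) + _STAGE_OFFSETS[stage])


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleFrame, TaxonomyTable, PlantedTruth]:
    """Simulate the full 43-sample design with planted ground truth."""
    cfg.validate()
    frame = SampleFrame.default_design(
        cfg.n_original, cfg.n_replicates_per_condition
    )
    taxa = [f"ASV_{i + 1:04d}" for i in range(cfg.n_taxa)]

    # --- taxonomy: ASVs collated into genera, a fraction unassigned -------
    rng_tax = _rng(cfg.seed, "taxonomy")
    genus_pool = [f"Genus_{g + 1:03d}" for g in range(cfg.n_genera)]
    assignment = []
    for i in range(cfg.n_taxa):
        if i < cfg.n_genera:
            assignment.append(genus_pool[i])  # every genus gets ≥ 1 ASV
        elif rng_tax.random() < cfg.frac_unassigned:
            assignment.append("")
        else:
            assignment.append(genus_pool[rng_tax.integers(cfg.n_genera)])
    rng_tax.shuffle(assignment)
    tax_df = pd.DataFrame(
        {r: ["" for _ in taxa] for r in RANKS},
        index=pd.Index(taxa, name="taxon_id"),
    )
    tax_df["domain"] = "Bacteria"
    tax_df["genus"] = assignment
    taxonomy = TaxonomyTable(tax_df)

    # --- planted sets ------------------------------------------------------
    genus_of = dict(zip(taxa, assignment))
    members: dict[str, list[str]] = {}
    for t, g in genus_of.items():
        if g:
            members.setdefault(g, []).append(t)
    assigned_genera = sorted(members)
    # specialists are planted on single-ASV genera so that their strong
    # home-condition boost stays a small share of the community
    singles = [g for g in assigned_genera if len(members[g]) == 1]
    if cfg.n_specialist > len(singles):
        raise SimConfigError("not enough single-ASV genera for specialists")
    specialist_g = list(
        rng_tax.choice(singles, size=cfg.n_specialist, replace=False)
    )
    rest = [g for g in assigned_genera if g not in set(specialist_g)]
    n_genus_planted = cfg.n_resilient + cfg.n_susceptible + cfg.n_stable
    if n_genus_planted > len(rest):
        raise SimConfigError("genus-level planted sets exceed available genera")
    picked = list(rng_tax.choice(rest, size=n_genus_planted, replace=False))
    resilient_g = picked[: cfg.n_resilient]
    picked = picked[cfg.n_resilient:]
    susceptible_g = picked[: cfg.n_susceptible]
    stable_g = picked[cfg.n_susceptible:]

    planted_genus_taxa = {
        t for g in resilient_g + susceptible_g + stable_g + specialist_g
        for t in members[g]
    }
    free = [t for t in taxa if t not in planted_genus_taxa]
    rng_tax.shuffle(free)
    if len(free) < cfg.n_core + cfg.n_neutral + cfg.n_selected + \
            cfg.n_dispersal_limited:
        raise SimConfigError("not enough unplanted ASVs for ASV-level sets")
    core_t = free[: cfg.n_core]
    free = free[cfg.n_core:]
    neutral_t = free[: cfg.n_neutral]
    free = free[cfg.n_neutral:]
    selected_t = free[: cfg.n_selected]
    free = free[cfg.n_selected:]
    displim_t = free[: cfg.n_dispersal_limited]

    # --- base log-abundances ----------------------------------------------
    rng_base = _rng(cfg.seed, "base")
    base = rng_base.normal(cfg.base_mu, cfg.base_sigma, cfg.n_taxa)
    t_index = {t: i for i, t in enumerate(taxa)}
    for g in resilient_g + susceptible_g + stable_g:
        for t in members[g]:
            base[t_index[t]] = rng_base.normal(cfg.planted_boost, 1.0)
    for g in specialist_g:
        base[t_index[members[g][0]]] = rng_base.normal(0.0, 0.5)
    for t in core_t:
        base[t_index[t]] = rng_base.normal(cfg.core_boost, 0.5)

    # --- condition effects delta (taxa × 9) --------------------------------
    rng_eff = _rng(cfg.seed, "effects")
    n_cond = len(CONDITIONS)
    delta = np.zeros((cfg.n_taxa, n_cond))
    special = planted_genus_taxa | set(core_t) | set(neutral_t)
    for i, t in enumerate(taxa):
        if t not in special:
            delta[i] = rng_eff.normal(0.0, cfg.background_effect_sd, n_cond)
    for g in resilient_g:
        for t in members[g]:
            delta[t_index[t]] = cfg.delta_effect
    for g in susceptible_g:
        for t in members[g]:
            delta[t_index[t]] = -cfg.delta_effect
    home_of: dict[str, tuple[int, ...]] = {}
    for g in specialist_g:
        home = tuple(
            sorted(rng_eff.choice(n_cond, size=cfg.specialist_k, replace=False))
        )
        home_of[g] = home
        for t in members[g]:
            delta[t_index[t], list(home)] = cfg.specialist_effect
    # stable members: per-condition effects rescaled so the subset's total
    # unnormalised abundance is preserved exactly
    stable_rows = [t_index[t] for g in stable_g for t in members[g]]
    if stable_rows:
        w = np.exp(base[stable_rows])
        raw = rng_eff.normal(0.0, cfg.stable_effect_sd, (len(stable_rows), n_cond))
        for c in range(n_cond):
            shift = np.log((w * np.exp(raw[:, c])).sum() / w.sum())
            delta[stable_rows, c] = raw[:, c] - shift

    # --- neutral block fluctuations ----------------------------------------
    rng_neu = _rng(cfg.seed, "neutral")
    n_samples = len(frame.sample_ids)
    log_mult = np.zeros((cfg.n_taxa, n_samples))
    if neutral_t:
        rows = [t_index[t] for t in neutral_t]
        p_base = np.exp(base) / np.exp(base).sum()
        shapes = cfg.depth_mean * cfg.neutral_m * p_base[rows]
        draws = rng_neu.gamma(
            np.tile(shapes[:, None], (1, n_samples)), 1.0
        )
        with np.errstate(divide="ignore"):
            log_mult[rows] = np.log(np.maximum(draws, 1e-300)) - np.log(shapes)[:, None]

    # --- depths and Dirichlet-multinomial counts ---------------------------
    rng_dep = _rng(cfg.seed, "depths")
    mu_log = np.log(cfg.depth_mean) - cfg.depth_sigma**2 / 2
    depths = np.maximum(
        rng_dep.lognormal(mu_log, cfg.depth_sigma, n_samples).round().astype(int), 1
    )
    rng_cnt = _rng(cfg.seed, "counts")
    groups = frame.groups_of(frame.sample_ids)
    cond_index = {c: k for k, c in enumerate(CONDITIONS)}
    counts = np.zeros((cfg.n_taxa, n_samples), dtype=np.int64)
    # planted condition effects act directly on the relative-abundance
    # scale (the estimand of the response model): planted taxa get
    # π_i·e^δ and only the background block renormalises, so the true
    # log-fold change of a planted taxon's proportion is exactly δ
    pi_base = np.exp(base - base.max())
    pi_base /= pi_base.sum()
    planted_rows = np.array(
        sorted(t_index[t] for t in planted_genus_taxa), dtype=int
    )
    bg_rows = np.array(
        [i for i in range(cfg.n_taxa) if i not in set(planted_rows)], dtype=int
    )
    for j, g in enumerate(groups):
        d_j = np.zeros(cfg.n_taxa) if g == ORIGINAL else delta[:, cond_index[g]]
        target = pi_base[planted_rows] * np.exp(d_j[planted_rows])
        share = target.sum()
        if share >= 0.9:
            raise SimConfigError(
                "planted effects occupy >=90% of the community; reduce "
                "effect sizes or planted-set abundance"
            )
        u = pi_base[bg_rows] * np.exp(d_j[bg_rows] + log_mult[bg_rows, j])
        pi = np.empty(cfg.n_taxa)
        pi[planted_rows] = target
        pi[bg_rows] = u * (1.0 - share) / u.sum()
        x = rng_cnt.dirichlet(cfg.theta * pi)
        counts[:, j] = rng_cnt.multinomial(depths[j], x)
    # guard against an all-zero sample at tiny configured depths
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[np.argmax(np.exp(base)), j] = 1

    # --- post-hoc occupancy manipulation (selection / dispersal limitation)
    rng_post = _rng(cfg.seed, "posthoc")
    for t in selected_t:
        row = counts[t_index[t]]
        row[row == 0] = 1
    for t in displim_t:
        drop = rng_post.random(n_samples) < 0.5
        counts[t_index[t], drop] = 0

    # --- truth tables -------------------------------------------------------
    label = pd.Series("background", index=pd.Index(taxa, name="taxon_id"))
    glabel = pd.Series(
        "background", index=pd.Index(assigned_genera + [UNKNOWN_GENUS], name="genus")
    )
    for gset, name in [
        (resilient_g, "resilient"), (susceptible_g, "susceptible"),
        (stable_g, "stable_member"), (specialist_g, "specialist"),
    ]:
        for g in gset:
            glabel[g] = name
            for t in members[g]:
                label[t] = name
    for tset, name in [
        (core_t, "core"), (neutral_t, "neutral"),
        (selected_t, "selected"), (displim_t, "dispersal_limited"),
    ]:
        for t in tset:
            label[t] = name
    truth = PlantedTruth(
        labels=pd.DataFrame({"label": label, "genus": [genus_of[t] or UNKNOWN_GENUS
                                                       for t in taxa]}),
        genus_labels=pd.DataFrame({"label": glabel}),
        m=cfg.neutral_m,
        delta=pd.DataFrame(delta, index=pd.Index(taxa, name="taxon_id"),
                           columns=list(CONDITIONS)),
    )
    return CountMatrix(taxa, frame.sample_ids, counts), frame, taxonomy, truth


def simulate_neutral_community(
    p: np.ndarray, m: float, n_samples: int, depth: int, seed: int,
    taxon_ids: list[str] | None = None,
) -> CountMatrix:
    """Simulate samples under the neutral assembly model.

    Each sample's composition is drawn from Dirichlet(N·m·p) with N the
    sequencing depth, then counts from a multinomial at that depth — the
    sampling assumptions under which taxon occupancy depends only on
    metacommunity abundance p_i and migration m.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("metacommunity abundances p must sum to 1")
    if (p < 0).any():
        raise ValueError("metacommunity abundances must be non-negative")
    if not (0 < m <= 1):
        raise ValueError("migration probability m must be in (0, 1]")
    if depth < 1 or n_samples < 1:
        raise ValueError("depth and n_samples must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.maximum(depth * m * p, 1e-12)
    counts = np.empty((len(p), n_samples), dtype=np.int64)
    for j in range(n_samples):
        x = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(depth, x)
    if taxon_ids is None:
        taxon_ids = [f"ASV_{i + 1:04d}" for i in range(len(p))]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    return CountMatrix(taxon_ids, samples, counts)


def simulate_vfa_series(
    initial_mg_per_l: float,
    consumption_fraction: float,
    n_timepoints: int = len(VFA_TIMEPOINTS),
    noise_sd: float = 0.0,
    seed: int = 0,
    acid: str = "acetic",
    replicate: int = 1,
) -> VfaSeries:
    """Seeded monotone-trend decay of a VFA concentration over a 48-h cycle.

    The trend decays exponentially from the initial concentration to
    ``initial × (1 − consumption_fraction)`` across the sampled time points,
    with additive Gaussian noise (clipped at zero).
    """
    if initial_mg_per_l < 0:
        raise ValueError("initial concentration must be non-negative")
    if not (0 <= consumption_fraction <= 1):
        raise ValueError("consumption_fraction must be in [0, 1]")
    times = np.asarray(VFA_TIMEPOINTS[:n_timepoints], dtype=float)
    if len(times) < n_timepoints:  # extend past the standard grid if asked
        extra = np.arange(len(times), n_timepoints) * 4.0 + times[-1]
        times = np.concatenate([times, extra])
    span = times[-1] - times[0] if len(times) > 1 else 1.0
    frac = (times - times[0]) / span
    remaining = 1.0 - consumption_fraction
    if remaining > 0:
        trend = initial_mg_per_l * remaining ** frac  # exponential decay
    else:
        trend = initial_mg_per_l * (1.0 - frac)       # linear to zero
    rng = np.random.default_rng(seed)
    conc = trend + (rng.normal(0.0, noise_sd, len(times)) if noise_sd > 0 else 0.0)
    return VfaSeries(
        acid=acid, times_h=times, concentrations=np.maximum(conc, 0.0),
        replicate=replicate,
    )
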