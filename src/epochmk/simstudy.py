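"""Null-simulation study: how much epoch-model support does tree shape and
tree error generate when the truth is constant-rate evolution?

Per replicate: draw simulating parameters from a pool of empirical-style Mk
fits, simulate a constant-rate trait on one tree from a pooled pseudo-
posterior sample, re-fit constant and epoch models on a *different* tree, and
record the inferred shift age, direction and magnitude.  Summaries report the
fraction of upward shifts inside an old-age window, the mean likelihood
profile, and a 2-D kernel density of (shift age, log10 magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .epoch import EpochFitResult, fit_epoch, profile_scan, shift_grid
from .mk_core import FitSettings, MkError, MkRates, fit_mk
from .simstudy_io import replicates_to_frame  # noqa: F401  (re-export)
from .synthetic_data import simulate_trait
from .treeio import Chronogram, TraitMatrix, TreeSet


@dataclass
class SimStudyConfig:
    tree_pool: list[TreeSet]
    n_replicates: int = 200
    seed: int = 0
    boundary_old: tuple[float, float] = (1.6, 1.8)
    profile_grid: int = 38
    match_trees: bool = False  # force estimation tree == simulation tree
    run_profiles: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.tree_pool or not any(len(s) for s in self.tree_pool):
            raise ValueError("empty tree pool")


@dataclass
class SimReplicate:
    replicate: int
    source_tree_id: str
    sim_tree_id: str
    est_tree_id: str
    true_rates: MkRates
    est: EpochFitResult
    shift_direction_01: str  # up | down
    shift_direction_10: str
    argmax_age: float
    log10_magnitude: float  # mean of the two log10 multipliers
    profile_delta_lnL: np.ndarray | None = None


@dataclass
class SimStudySummary:
    n_ok: int
    n_failed: int
    prop_up_in_window: float
    prop_epoch_favored: float
    mean_profile: np.ndarray | None
    profile_grid_ages: np.ndarray | None
    boundary_old: tuple[float, float]
    magnitude_density: pd.DataFrame | None = None


def harvest_parameter_pool(tree_pool: list[TreeSet], traits: TraitMatrix,
                           settings: FitSettings | None = None,
                           max_fits: int | None = None) -> list[MkRates]:
    """Constant-rate Mk2 fits over every (trait, tree) pairing.

    Returns the fitted rate pairs; boundary (monomorphic) fits are kept but
    failures are excluded.  ``max_fits`` caps the number of pairings (taken
    in order) to bound runtime.
    """
    settings = settings or FitSettings()
    names = [c for c in traits.traits
             if traits.column_types.get(c, "binary") == "binary"]
    pool: list[MkRates] = []
    n_done = 0
    for ts in tree_pool:
        for tree in ts:
            for nm in names:
                if max_fits is not None and n_done >= max_fits:
                    break
                try:
                    fit = fit_mk(tree, traits.binary_column(nm), "Mk2",
                                 settings)
                    pool.append(fit.rates)
                except MkError:
                    continue
                finally:
                    n_done += 1
    if not pool:
        raise MkError("parameter pool is empty after failures")
    return pool


def _pooled_trees(tree_pool: list[TreeSet]) -> list[tuple[str, Chronogram]]:
    out = []
    for ts in tree_pool:
        for k, tree in enumerate(ts):
            out.append((f"{ts.set_id}:{k}", tree))
    return out


def run_null_study(config: SimStudyConfig,
                   settings: FitSettings | None = None,
                   parameter_pool: list[MkRates] | None = None,
                   traits: TraitMatrix | None = None
                   ) -> tuple[list[SimReplicate], SimStudySummary]:
    """Run the constant-rate null study.

    Per-replicate seeds derive deterministically from ``config.seed`` so any
    single replicate can be replayed.  Replicate-level failures are recorded
    and skipped; the study fails only if more than 10% of replicates fail.
    """
    settings = settings or FitSettings()
    if parameter_pool is None:
        if traits is None:
            raise MkError("need a parameter pool or a trait matrix")
        parameter_pool = harvest_parameter_pool(config.tree_pool, traits,
                                                settings)
    trees = _pooled_trees(config.tree_pool)
    replicates: list[SimReplicate] = []
    n_failed = 0
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, 4177, rep])
        try:
            replicates.append(
                _one_replicate(rep, rng, trees, parameter_pool, config,
                               settings))
        except MkError:
            n_failed += 1
    if n_failed > 0.1 * config.n_replicates:
        raise MkError(f"{n_failed}/{config.n_replicates} replicates failed")
    return replicates, summarize_study(replicates, config, n_failed=n_failed)


def _one_replicate(rep, rng, trees, pool, config, settings) -> SimReplicate:
    src_idx = int(rng.integers(len(pool)))
    true_rates = pool[src_idx]
    sim_idx = int(rng.integers(len(trees)))
    sim_id, sim_tree = trees[sim_idx]
    if config.match_trees or len(trees) == 1:
        est_id, est_tree = sim_id, sim_tree
    else:
        while True:
            est_idx = int(rng.integers(len(trees)))
            if est_idx != sim_idx:
                break
        est_id, est_tree = trees[est_idx]

    tip_states = simulate_trait(sim_tree, true_rates,
                                seed=int(rng.integers(2 ** 31)))
    if len(set(tip_states.values())) < 2:
        raise MkError("monomorphic simulated trait")
    # tip sets can differ between pseudo-posterior sets; evaluate on shared taxa
    shared = set(est_tree.tip_labels) & set(tip_states)
    if len(shared) < est_tree.n_tips:
        est_tree = est_tree.prune_to(shared)
    est_states = {t: tip_states[t] for t in est_tree.tip_labels}

    const = fit_mk(est_tree, est_states, "Mk2", settings)
    est = fit_epoch(est_tree, est_states, settings, "free",
                    n_grid=config.profile_grid, constant_fit=const)
    profile = None
    if config.run_profiles:
        prof = profile_scan(est_tree, est_states, settings,
                            n_grid=config.profile_grid, constant_fit=const)
        profile = prof.delta_lnL
    mag = 0.5 * (est.log10_r01 + est.log10_r10)
    return SimReplicate(
        replicate=rep, source_tree_id=f"pool:{src_idx}", sim_tree_id=sim_id,
        est_tree_id=est_id, true_rates=true_rates, est=est,
        shift_direction_01="up" if est.log10_r01 > 0 else "down",
        shift_direction_10="up" if est.log10_r10 > 0 else "down",
        argmax_age=est.params.t_shift, log10_magnitude=mag,
        profile_delta_lnL=profile)


def summarize_study(replicates: list[SimReplicate], config: SimStudyConfig,
                    n_failed: int = 0, kde_bandwidth: float | None = None
                    ) -> SimStudySummary:
    """Aggregate a replicate list (pure function; recomputable from CSV)."""
    if not replicates:
        raise MkError("no successful replicates")
    lo, hi = config.boundary_old
    in_win_up = [r for r in replicates
                 if lo <= r.argmax_age <= hi and r.log10_magnitude > 0]
    favored = [r for r in replicates if r.est.delta_AIC_vs_constant > 0]
    profiles = [r.profile_delta_lnL for r in replicates
                if r.profile_delta_lnL is not None]
    mean_profile = np.mean(profiles, axis=0) if profiles else None
    grid = shift_grid(_root_age_of(config), config.profile_grid)         if profiles else None
    density = None
    if len(replicates) >= 2:
        try:
            density = shift_magnitude_density(replicates, kde_bandwidth,
                                              root_age=_root_age_of(config))
        except MkError:
            density = None
    return SimStudySummary(
        n_ok=len(replicates), n_failed=n_failed,
        prop_up_in_window=len(in_win_up) / len(replicates),
        prop_epoch_favored=len(favored) / len(replicates),
        mean_profile=mean_profile, profile_grid_ages=grid,
        boundary_old=config.boundary_old, magnitude_density=density)


def _root_age_of(config: SimStudyConfig) -> float:
    return config.tree_pool[0].trees[0].root_age


def shift_magnitude_density(replicates: list[SimReplicate],
                            bandwidth: float | None = None,
                            root_age: float | None = None,
                            n_grid: int = 40) -> pd.DataFrame:
    """2-D Gaussian KDE over (shift age, log10 magnitude).

    Returns a long-format table (age, log10_magnitude, density) on a regular
    grid; the density integrates to ~1 over the grid.  A magnitude of 0 means
    no rate shift.
    """
    if len(replicates) < 2:
        raise MkError("need at least 2 replicates for a density")
    ages = np.array([r.argmax_age for r in replicates])
    mags = np.array([r.log10_magnitude for r in replicates])
    if np.ptp(ages) < 1e-12 or np.ptp(mags) < 1e-12:
        raise MkError("degenerate inputs: KDE needs spread in both the "
                      "shift ages and the magnitudes; supply more varied "
                      "data or use a histogram")
    data = np.vstack([ages, mags])
    kde = stats.gaussian_kde(data, bw_method=bandwidth)
    a_max = root_age if root_age is not None else float(ages.max()) * 1.2
    m_span = max(float(np.abs(mags).max()) * 1.5, 0.5)
    a_grid = np.linspace(0.0, a_max, n_grid)
    m_grid = np.linspace(-m_span, m_span, n_grid)
    aa, mm = np.meshgrid(a_grid, m_grid, indexing="ij")
    dens = kde(np.vstack([aa.ravel(), mm.ravel()])).reshape(aa.shape)
    return pd.DataFrame({"age": aa.ravel(), "log10_magnitude": mm.ravel(),
                         "density": dens.ravel()})
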