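"""Time-shifted ("epoch") Mk models.

A single phylogeny-wide shift age ``t_shift`` splits the chronogram into an
old epoch (ages > t_shift) evolving under base rates (q01, q10) and a young
epoch (ages < t_shift) evolving under multiplied rates (q01*r01, q10*r10).
Because ages run backward, the multipliers apply *after* the shift in forward
time.  Branches spanning the shift use the forward-ordered product of the two
epoch transition matrices.

Provides per-trait fits, fixed-grid likelihood profiles, cross-trait
cumulative support, the joint multi-trait shift model, and epoch-model
ancestral state reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mk_core import (FitSettings, MkError, MkFitResult, MkRates,
                      _apply_missing_policy, _lhs_starts, _marginals_given_mats,
                      _multistart_minimize, _pmat, _pmat_mul, _prune_lnL,
                      _tip_partials, fit_mk)
from .treeio import Chronogram, TraitMatrix

LOG10_MULT_BOUNDS = (-3.0, 3.0)

_IDENTITY = (1.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class EpochParams:
    """Base rates (old epoch), shift age, and post-shift rate multipliers."""

    base: MkRates
    t_shift: float
    r01: float
    r10: float

    def __post_init__(self):
        if not (self.t_shift > 0 and math.isfinite(self.t_shift)):
            raise MkError("t_shift must be positive and finite")
        if self.r01 <= 0 or self.r10 <= 0:
            raise MkError("rate multipliers must be positive")

    @property
    def post(self) -> MkRates:
        return MkRates(self.base.q01 * self.r01, self.base.q10 * self.r10)


@dataclass
class EpochFitResult:
    params: EpochParams
    lnL: float
    n_params: int
    AIC: float
    delta_lnL_vs_constant: float
    delta_AIC_vs_constant: float
    log10_r01: float
    log10_r10: float
    converged: bool = True
    constant_fit: MkFitResult | None = None
    equal_rates: bool = False


@dataclass
class LikelihoodProfile:
    grid: np.ndarray
    delta_lnL: np.ndarray
    argmax_age: float
    lnL_constant: float = float("nan")
    errors: dict[int, str] = field(default_factory=dict)
    tied_ages: list[float] = field(default_factory=list)


@dataclass
class CumulativeProfile:
    grid: np.ndarray
    summed_support: np.ndarray
    thresholded_support: np.ndarray
    threshold: float


@dataclass
class JointFitResult:
    shared_t_shift: float
    shared_r01: float
    shared_r10: float
    per_trait_base: dict[str, MkRates]
    lnL_total: float
    n_params: int
    AIC: float
    lnL_no_shift: float
    n_params_no_shift: int
    delta_AIC_vs_no_shift: float
    multiplier_mode: str


# ---------------------------------------------------------------------------
# likelihood


def shift_grid(root_age: float, n_grid: int = 38) -> np.ndarray:
    """``n_grid`` candidate shift ages evenly spaced strictly inside
    (0, root_age)."""
    if n_grid < 2:
        raise MkError("n_grid must be >= 2")
    return np.linspace(0.0, root_age, n_grid + 2)[1:-1]


def _split_durations(tree: Chronogram, t_shift: float):
    """Per non-root node: (node, duration older than shift, duration younger)."""
    segs = []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        a_p, a_c = tree.age[p], tree.age[i]
        dt_old = max(0.0, a_p - max(a_c, t_shift))
        dt_young = max(0.0, min(a_p, t_shift) - a_c)
        segs.append((i, dt_old, dt_young))
    return segs


def _epoch_mats(tree: Chronogram, segs, q01: float, q10: float,
                r01: float, r10: float) -> list:
    p01, p10 = q01 * r01, q10 * r10
    mats = [_IDENTITY] * tree.n_nodes
    if r01 == 1.0 and r10 == 1.0:
        # nesting identity: reuse the constant-rate code path bit-for-bit
        for i, _, _ in segs:
            mats[i] = _pmat(q01, q10, tree.length[i])
        return mats
    for i, dt_old, dt_young in segs:
        if dt_old == 0.0:
            mats[i] = _pmat(p01, p10, dt_young)
        elif dt_young == 0.0:
            mats[i] = _pmat(q01, q10, dt_old)
        else:
            mats[i] = _pmat_mul(_pmat(q01, q10, dt_old),
                                _pmat(p01, p10, dt_young))
    return mats


def _epoch_prior(settings: FitSettings, base: MkRates):
    # the root lives in the old epoch, so a stationary prior uses base rates
    if settings.root_prior == "stationary":
        return settings.prior_vector(base)
    return settings.prior_vector()


def epoch_lnL(tree: Chronogram, tip_states: dict, params: EpochParams,
              settings: FitSettings | None = None) -> float:
    """Log-likelihood of a binary trait under the single-shift epoch model."""
    settings = settings or FitSettings()
    if not 0.0 < params.t_shift < tree.root_age:
        raise MkError(
            f"t_shift {params.t_shift} outside (0, {tree.root_age})")
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    segs = _split_durations(tree, params.t_shift)
    mats = _epoch_mats(tree, segs, params.base.q01, params.base.q10,
                       params.r01, params.r10)
    return _prune_lnL(tree, partials, mats,
                      _epoch_prior(settings, params.base))


# ---------------------------------------------------------------------------
# fitting


def _rate_log_bounds(settings: FitSettings):
    return math.log10(settings.rate_bounds[0]), math.log10(settings.rate_bounds[1])


def _nll_factory(tree, partials, segs, settings):
    stationary = settings.root_prior == "stationary"
    fixed_prior = None if stationary else settings.prior_vector()

    def nll(x):
        q01, q10 = 10.0 ** x[0], 10.0 ** x[1]
        r01, r10 = 10.0 ** x[2], 10.0 ** x[3]
        prior = settings.prior_vector(MkRates(q01, q10)) if stationary \
            else fixed_prior
        mats = _epoch_mats(tree, segs, q01, q10, r01, r10)
        val = _prune_lnL(tree, partials, mats, prior)
        return -val if math.isfinite(val) else 1e12
    return nll


def _expander(equal_rates: bool):
    if equal_rates:
        return lambda x: (x[0], x[0], x[1], x[1])
    return lambda x: tuple(x[:4])


def fit_epoch(tree: Chronogram, tip_states: dict,
              settings: FitSettings | None = None,
              shift_mode: str | tuple[str, float] = "free",
              n_grid: int = 38,
              constant_fit: MkFitResult | None = None,
              equal_rates: bool = False) -> EpochFitResult:
    """ML fit of the epoch model.

    ``shift_mode='free'`` searches the shift age over a coarse grid of
    ``n_grid`` candidate ages and then refines locally (the likelihood is
    piecewise smooth in t_shift with kinks at node ages).
    ``shift_mode=('fixed', t)`` optimises the rate parameters at a given
    shift age.  ``equal_rates=True`` ties q01 == q10 and r01 == r10 (the
    Mk1-based epoch variant, 3 parameters in free mode) — much better
    identified on symmetric data.  ``delta_*_vs_constant`` compare against
    the matching constant fit (Mk2, or Mk1 when rates are tied).
    """
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    if constant_fit is None:
        constant_fit = fit_mk(tree, tip_states,
                              "Mk1" if equal_rates else "Mk2", settings)

    lo, hi = _rate_log_bounds(settings)
    mlo, mhi = LOG10_MULT_BOUNDS
    expand = _expander(equal_rates)
    ndim = 2 if equal_rates else 4
    bounds = ([(lo, hi), (mlo, mhi)] if equal_rates
              else [(lo, hi), (lo, hi), (mlo, mhi), (mlo, mhi)])
    if equal_rates:
        base_start = np.array([
            np.clip(math.log10(max(constant_fit.rates.q01, 1e-12)), lo, hi),
            0.0])
        start_lo = [max(lo, -4), -1.5]
        start_hi = [min(hi, 1.5), 1.5]
    else:
        base_start = np.array([
            np.clip(math.log10(max(constant_fit.rates.q01, 1e-12)), lo, hi),
            np.clip(math.log10(max(constant_fit.rates.q10, 1e-12)), lo, hi),
            0.0, 0.0])
        start_lo = [max(lo, -4), max(lo, -4), -1.5, -1.5]
        start_hi = [min(hi, 1.5), min(hi, 1.5), 1.5, 1.5]
    rng = np.random.default_rng(settings.seed)

    def fit_at(t, extra_starts=()):
        segs = _split_durations(tree, t)
        nll4 = _nll_factory(tree, partials, segs, settings)
        nll = (lambda x: nll4(expand(x))) if equal_rates else nll4
        starts = [base_start] + [np.asarray(s) for s in extra_starts]
        return _multistart_minimize(nll, starts, bounds)

    n_free = ndim + 1  # + shift age
    if isinstance(shift_mode, tuple) and shift_mode[0] == "fixed":
        t = float(shift_mode[1])
        if not 0.0 < t < tree.root_age:
            raise MkError(f"t_shift {t} outside (0, {tree.root_age})")
        extras = list(_lhs_starts(max(settings.n_restarts - 1, 0), ndim,
                                  start_lo, start_hi, rng))
        best = fit_at(t, extras)
        return _package_epoch(best, t, constant_fit, n_params=ndim,
                              equal_rates=equal_rates)

    if shift_mode != "free":
        raise MkError(f"unknown shift_mode {shift_mode!r}")

    grid = shift_grid(tree.root_age, n_grid)
    best_t, best_res, prev_x = None, None, None
    for t in grid:
        extras = [prev_x] if prev_x is not None else list(
            _lhs_starts(max(settings.n_restarts - 1, 0), ndim,
                        start_lo, start_hi, rng))
        res = fit_at(t, extras)
        prev_x = res.x
        if best_res is None or res.fun < best_res.fun - 1e-12:
            best_t, best_res = t, res

    # local refinement of the shift age around the best grid point
    j = int(np.searchsorted(grid, best_t))
    t_lo = grid[j - 1] if j > 0 else 1e-9 * tree.root_age
    t_hi = grid[j + 1] if j < len(grid) - 1 else (1 - 1e-9) * tree.root_age

    def nll_t(x):
        t = float(np.clip(x[ndim], t_lo, t_hi))
        segs = _split_durations(tree, t)
        nll4 = _nll_factory(tree, partials, segs, settings)
        return nll4(expand(x[:ndim]))

    from scipy import optimize
    x0 = np.append(best_res.x, best_t)
    res_t = optimize.minimize(nll_t, x0, method="L-BFGS-B",
                              bounds=bounds + [(t_lo, t_hi)])
    if res_t.fun < best_res.fun:
        return _package_epoch(res_t, float(np.clip(res_t.x[ndim], t_lo, t_hi)),
                              constant_fit, n_params=n_free,
                              x=res_t.x[:ndim], equal_rates=equal_rates)
    return _package_epoch(best_res, best_t, constant_fit, n_params=n_free,
                          equal_rates=equal_rates)


def _package_epoch(res, t, constant_fit, n_params, x=None,
                   equal_rates: bool = False) -> EpochFitResult:
    x = res.x if x is None else x
    x4 = _expander(equal_rates)(x)
    params = EpochParams(base=MkRates(10.0 ** x4[0], 10.0 ** x4[1]),
                         t_shift=t, r01=10.0 ** x4[2], r10=10.0 ** x4[3])
    lnL = -res.fun
    d_lnL = lnL - constant_fit.lnL
    aic = 2 * n_params - 2 * lnL
    return EpochFitResult(
        params=params, lnL=lnL, n_params=n_params, AIC=aic,
        delta_lnL_vs_constant=d_lnL,
        delta_AIC_vs_constant=constant_fit.AIC - aic,
        log10_r01=float(x4[2]), log10_r10=float(x4[3]),
        converged=bool(res.success), constant_fit=constant_fit,
        equal_rates=equal_rates)


def profile_scan(tree: Chronogram, tip_states: dict,
                 settings: FitSettings | None = None,
                 n_grid: int = 38,
                 constant_fit: MkFitResult | None = None,
                 equal_rates: bool = False) -> LikelihoodProfile:
    """Fixed-shift likelihood profile over a grid of candidate shift ages.

    Each grid point gets a rates-plus-multipliers fit (four parameters, or
    two with ``equal_rates=True``); the profile reports the lnL gain over the
    matching constant-rate fit.  Per-point failures are recorded, not fatal.
    Ties at the maximum resolve to the youngest age.
    """
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    if constant_fit is None:
        constant_fit = fit_mk(tree, tip_states,
                              "Mk1" if equal_rates else "Mk2", settings)

    lo, hi = _rate_log_bounds(settings)
    mlo, mhi = LOG10_MULT_BOUNDS
    expand = _expander(equal_rates)
    ndim = 2 if equal_rates else 4
    if equal_rates:
        bounds = [(lo, hi), (mlo, mhi)]
        base_start = np.array([
            np.clip(math.log10(max(constant_fit.rates.q01, 1e-12)), lo, hi),
            0.0])
        start_lo, start_hi = [max(lo, -4), -1.5], [min(hi, 1.5), 1.5]
    else:
        bounds = [(lo, hi), (lo, hi), (mlo, mhi), (mlo, mhi)]
        base_start = np.array([
            np.clip(math.log10(max(constant_fit.rates.q01, 1e-12)), lo, hi),
            np.clip(math.log10(max(constant_fit.rates.q10, 1e-12)), lo, hi),
            0.0, 0.0])
        start_lo = [max(lo, -4), max(lo, -4), -1.5, -1.5]
        start_hi = [min(hi, 1.5), min(hi, 1.5), 1.5, 1.5]
    rng = np.random.default_rng(settings.seed)
    extras0 = list(_lhs_starts(max(settings.n_restarts - 1, 0), ndim,
                               start_lo, start_hi, rng))

    grid = shift_grid(tree.root_age, n_grid)
    delta = np.full(len(grid), np.nan)
    errors: dict[int, str] = {}
    prev_x = None
    for k, t in enumerate(grid):
        try:
            segs = _split_durations(tree, t)
            nll4 = _nll_factory(tree, partials, segs, settings)
            nll = (lambda x: nll4(expand(x))) if equal_rates else nll4
            starts = [base_start] + ([prev_x] if prev_x is not None else extras0)
            res = _multistart_minimize(nll, starts, bounds)
            prev_x = res.x
            delta[k] = -res.fun - constant_fit.lnL
        except Exception as exc:  # pragma: no cover - defensive
            errors[k] = str(exc)

    finite = np.where(np.isfinite(delta))[0]
    if finite.size == 0:
        raise MkError("profile scan failed at every grid point")
    dmax = np.nanmax(delta)
    tied = [float(grid[k]) for k in finite if delta[k] >= dmax - 1e-9]
    return LikelihoodProfile(grid=grid, delta_lnL=delta,
                             argmax_age=min(tied),
                             lnL_constant=constant_fit.lnL,
                             errors=errors, tied_ages=tied)


def cumulative_support(profiles: list[LikelihoodProfile],
                       threshold: float = 6.0) -> CumulativeProfile:
    """Pointwise sum of per-trait profiles; values more than ``threshold``
    likelihood units below the maximum are zeroed."""
    if not profiles:
        raise MkError("no profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if len(p.grid) != len(grid) or not np.allclose(p.grid, grid,
                                                       atol=1e-12):
            raise MkError("profiles have mismatched grids")
    summed = np.sum([p.delta_lnL for p in profiles], axis=0)
    cut = np.nanmax(summed) - threshold
    thresholded = np.where(summed >= cut, summed, 0.0)
    return CumulativeProfile(grid=grid, summed_support=summed,
                             thresholded_support=thresholded,
                             threshold=threshold)


# ---------------------------------------------------------------------------
# joint multi-trait model


def fit_joint(tree: Chronogram, traits: TraitMatrix,
              settings: FitSettings | None = None,
              multiplier_mode: str = "shared_pair",
              n_grid: int = 38,
              trait_names: list[str] | None = None) -> JointFitResult:
    """Joint epoch fit: one shift age and shared multipliers across traits,
    independent base rates per trait.

    Fitted by block-coordinate ascent: a grid search over the shift age with
    shared multipliers optimised at per-trait Mk2 base rates, then alternating
    optimisation of per-trait bases and shared (t, multipliers) until the
    total lnL stabilises.  Compared by AIC to independent no-shift Mk2 fits
    (positive ``delta_AIC_vs_no_shift`` favours the shift model).
    """
    settings = settings or FitSettings()
    if multiplier_mode not in ("shared_pair", "shared_scalar"):
        raise MkError(f"unknown multiplier_mode {multiplier_mode!r}")
    names = trait_names or [c for c in traits.traits
                            if traits.column_types.get(c, "binary") == "binary"]
    if not names:
        raise MkError("no binary traits to fit")
    k = len(names)

    cols = {nm: traits.binary_column(nm) for nm in names}
    const_fits = {nm: fit_mk(tree, cols[nm], "Mk2", settings)
                  for nm in names}
    lnL_no_shift = sum(f.lnL for f in const_fits.values())
    n_no_shift = 2 * k

    if k == 1 and multiplier_mode == "shared_pair":
        # identical model to the single-trait epoch fit
        nm = names[0]
        ef = fit_epoch(tree, cols[nm], settings, "free", n_grid,
                       constant_fit=const_fits[nm])
        aic = 2 * 5 - 2 * ef.lnL
        return JointFitResult(
            shared_t_shift=ef.params.t_shift, shared_r01=ef.params.r01,
            shared_r10=ef.params.r10, per_trait_base={nm: ef.params.base},
            lnL_total=ef.lnL, n_params=5, AIC=aic,
            lnL_no_shift=lnL_no_shift, n_params_no_shift=n_no_shift,
            delta_AIC_vs_no_shift=(2 * n_no_shift - 2 * lnL_no_shift) - aic,
            multiplier_mode=multiplier_mode)

    lo, hi = _rate_log_bounds(settings)
    mlo, mhi = LOG10_MULT_BOUNDS
    n_mult = 2 if multiplier_mode == "shared_pair" else 1
    prior_flat = settings.root_prior != "stationary"

    # per-trait cached structures
    tdata = {}
    for nm in names:
        tr, ts = _apply_missing_policy(tree, cols[nm], settings)
        tdata[nm] = (tr, _tip_partials(tr, ts))

    bases = {nm: [np.clip(math.log10(max(const_fits[nm].rates.q01, 1e-12)),
                          lo, hi),
                  np.clip(math.log10(max(const_fits[nm].rates.q10, 1e-12)),
                          lo, hi)] for nm in names}

    def trait_lnL(nm, segs_map, lb01, lb10, lr01, lr10):
        tr, partials = tdata[nm]
        q01, q10 = 10.0 ** lb01, 10.0 ** lb10
        r01, r10 = 10.0 ** lr01, 10.0 ** lr10
        prior = ((0.5, 0.5) if prior_flat and settings.root_prior == "flat"
                 else (settings.prior_vector() if prior_flat
                       else settings.prior_vector(MkRates(q01, q10))))
        mats = _epoch_mats(tr, segs_map[nm], q01, q10, r01, r10)
        val = _prune_lnL(tr, partials, mats, prior)
        return val if math.isfinite(val) else -1e12

    def segs_for(t):
        return {nm: _split_durations(tdata[nm][0], t) for nm in names}

    from scipy import optimize

    def opt_multipliers(segs_map, m0):
        def nll(m):
            lr01 = m[0]
            lr10 = m[1] if n_mult == 2 else m[0]
            return -sum(trait_lnL(nm, segs_map, bases[nm][0], bases[nm][1],
                                  lr01, lr10) for nm in names)
        res = optimize.minimize(nll, m0, method="L-BFGS-B",
                                bounds=[(mlo, mhi)] * n_mult)
        return res.x, -res.fun

    def opt_bases(segs_map, lr01, lr10):
        total = 0.0
        for nm in names:
            def nll(b, nm=nm):
                return -trait_lnL(nm, segs_map, b[0], b[1], lr01, lr10)
            res = optimize.minimize(nll, np.asarray(bases[nm]),
                                    method="L-BFGS-B",
                                    bounds=[(lo, hi), (lo, hi)])
            bases[nm] = list(res.x)
            total += -res.fun
        return total

    # stage A: shift-age grid with multipliers optimised at Mk2 bases
    grid = shift_grid(tree.root_age, n_grid)
    m_prev = np.zeros(n_mult)
    best_t, best_val, best_m = None, -math.inf, m_prev
    for t in grid:
        segs_map = segs_for(t)
        m_opt, val = opt_multipliers(segs_map, m_prev)
        m_prev = m_opt
        if val > best_val + 1e-12:
            best_t, best_val, best_m = float(t), val, m_opt

    # stage B: block-coordinate refinement at the best shift age
    t_cur, m_cur = best_t, np.asarray(best_m, float)
    j = int(np.searchsorted(grid, t_cur))
    t_lo = grid[j - 1] if j > 0 else 1e-9 * tree.root_age
    t_hi = grid[j + 1] if j < len(grid) - 1 else (1 - 1e-9) * tree.root_age
    lnL_cur = -math.inf
    for _ in range(15):
        segs_map = segs_for(t_cur)
        lr01 = m_cur[0]
        lr10 = m_cur[1] if n_mult == 2 else m_cur[0]
        opt_bases(segs_map, lr01, lr10)

        def nll_tm(x):
            t = float(np.clip(x[0], t_lo, t_hi))
            sm = segs_for(t)
            a01 = x[1]
            a10 = x[2] if n_mult == 2 else x[1]
            return -sum(trait_lnL(nm, sm, bases[nm][0], bases[nm][1],
                                  a01, a10) for nm in names)
        res = optimize.minimize(
            nll_tm, np.concatenate([[t_cur], m_cur]), method="L-BFGS-B",
            bounds=[(t_lo, t_hi)] + [(mlo, mhi)] * n_mult)
        t_cur = float(np.clip(res.x[0], t_lo, t_hi))
        m_cur = res.x[1:]
        if -res.fun - lnL_cur < 1e-5:
            lnL_cur = -res.fun
            break
        lnL_cur = -res.fun

    lr01 = float(m_cur[0])
    lr10 = float(m_cur[1]) if n_mult == 2 else float(m_cur[0])
    segs_map = segs_for(t_cur)
    lnL_total = sum(trait_lnL(nm, segs_map, bases[nm][0], bases[nm][1],
                              lr01, lr10) for nm in names)
    n_params = 2 * k + 1 + n_mult
    aic = 2 * n_params - 2 * lnL_total
    aic_null = 2 * n_no_shift - 2 * lnL_no_shift
    return JointFitResult(
        shared_t_shift=t_cur, shared_r01=10.0 ** lr01, shared_r10=10.0 ** lr10,
        per_trait_base={nm: MkRates(10.0 ** bases[nm][0], 10.0 ** bases[nm][1])
                        for nm in names},
        lnL_total=lnL_total, n_params=n_params, AIC=aic,
        lnL_no_shift=lnL_no_shift, n_params_no_shift=n_no_shift,
        delta_AIC_vs_no_shift=aic_null - aic, multiplier_mode=multiplier_mode)


# ---------------------------------------------------------------------------
# epoch-model ASR


def epoch_asr(tree: Chronogram, tip_states: dict, best_fit: EpochFitResult,
              settings: FitSettings | None = None) -> dict[int, tuple]:
    """Marginal ancestral states under a fitted epoch model."""
    settings = settings or FitSettings()
    params = best_fit.params if isinstance(best_fit, EpochFitResult) \
        else best_fit
    if not 0.0 < params.t_shift < tree.root_age:
        raise MkError(
            f"t_shift {params.t_shift} outside (0, {tree.root_age})")
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    segs = _split_durations(tree, params.t_shift)
    mats = _epoch_mats(tree, segs, params.base.q01, params.base.q10,
                       params.r01, params.r10)
    return _marginals_given_mats(tree, partials, mats,
                                 _epoch_prior(settings, params.base))
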