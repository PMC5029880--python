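"""Constant-rate two-state Mk machinery.

Closed-form transition probabilities, Felsenstein pruning, ML fitting of the
one-rate (Mk1) and two-rate (Mk2) models, Pagel's lambda transform with its
likelihood-ratio signal test, and marginal ancestral state reconstruction.

Rates are per Ga.  The likelihood kernel works on per-edge 2x2 matrices given
as flat ``(P00, P01, P10, P11)`` tuples so that the epoch model can reuse it
with piecewise matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .treeio import MISSING, Chronogram

LOG10_RATE_BOUNDS = (-6.0, 3.0)  # rates span 1e-6 .. 1e3 per Ga


class MkError(ValueError):
    pass


@dataclass(frozen=True)
class MkRates:
    """Gain (0->1) and loss (1->0) rates per Ga."""

    q01: float
    q10: float

    def __post_init__(self):
        if not (math.isfinite(self.q01) and math.isfinite(self.q10)):
            raise MkError("rates must be finite")
        if self.q01 < 0 or self.q10 < 0:
            raise MkError("rates must be non-negative")

    @property
    def stationary(self) -> tuple[float, float]:
        s = self.q01 + self.q10
        if s <= 0:
            raise MkError("stationary distribution undefined for zero rates")
        return self.q10 / s, self.q01 / s


@dataclass
class FitSettings:
    root_prior: str | tuple[float, float] = "flat"
    rate_bounds: tuple[float, float] = tuple(10.0 ** b for b in LOG10_RATE_BOUNDS)
    n_restarts: int = 5
    seed: int = 0
    missing_policy: str = "marginalize"  # or "drop_taxon"

    def __post_init__(self):
        lo, hi = self.rate_bounds
        if not (lo > 0 and hi >= lo):
            raise MkError("rate bounds must satisfy 0 < lo <= hi")
        if self.n_restarts < 1:
            raise MkError("n_restarts must be >= 1")
        if self.missing_policy not in ("marginalize", "drop_taxon"):
            raise MkError(f"unknown missing policy {self.missing_policy!r}")

    def prior_vector(self, rates: MkRates | None = None) -> tuple[float, float]:
        if self.root_prior == "flat":
            return 0.5, 0.5
        if self.root_prior == "stationary":
            if rates is None:
                raise MkError("stationary prior needs rates")
            return rates.stationary
        p0, p1 = self.root_prior
        if abs(p0 + p1 - 1.0) > 1e-9 or p0 < 0 or p1 < 0:
            raise MkError("root prior must be a probability vector")
        return float(p0), float(p1)


@dataclass
class MkFitResult:
    rates: MkRates
    lnL: float
    n_params: int
    AIC: float
    converged: bool
    model: str
    warning: str | None = None


@dataclass
class LambdaFit:
    lambda_hat: float
    lnL_hat: float
    lnL_lambda0: float
    LR_stat: float
    p_value: float
    rates: MkRates | None = None
    warning: str | None = None


# ---------------------------------------------------------------------------
# transition probabilities


def transition_matrix(rates: MkRates, t: float) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix for elapsed time ``t``."""
    if t < 0:
        raise MkError("negative elapsed time")
    return np.array(_pmat(rates.q01, rates.q10, t)).reshape(2, 2)


def _pmat(q01: float, q10: float, t: float) -> tuple[float, float, float, float]:
    s = q01 + q10
    if s <= 0.0 or t == 0.0:
        return 1.0, 0.0, 0.0, 1.0
    e = math.exp(-s * t)
    pi1 = q01 / s
    pi0 = 1.0 - pi1
    return pi0 + pi1 * e, pi1 * (1.0 - e), pi0 * (1.0 - e), pi1 + pi0 * e


def _pmat_mul(a, b):
    # (a @ b) for the flat 2x2 representation
    a00, a01, a10, a11 = a
    b00, b01, b10, b11 = b
    return (a00 * b00 + a01 * b10, a00 * b01 + a01 * b11,
            a10 * b00 + a11 * b10, a10 * b01 + a11 * b11)


# ---------------------------------------------------------------------------
# pruning kernel


def _tip_partials(tree: Chronogram, tip_states: dict) -> list:
    """Per-node (f0, f1) partials for tips; None placeholders for internals."""
    partials = [None] * tree.n_nodes
    tips = tree.tips()
    labels = {tree.label[i]: i for i in tips}
    unknown = set(tip_states) - set(labels)
    if unknown:
        raise MkError(f"taxa not in tree: {sorted(unknown)}")
    n_obs = 0
    for i in tips:
        lb = tree.label[i]
        if lb not in tip_states:
            raise MkError(f"tip {lb!r} has no entry in tip_states")
        st = tip_states[lb]
        if st is MISSING:
            partials[i] = (1.0, 1.0)
        elif st == 0:
            partials[i] = (1.0, 0.0)
            n_obs += 1
        elif st == 1:
            partials[i] = (0.0, 1.0)
            n_obs += 1
        else:
            raise MkError(f"invalid state {st!r} for tip {lb!r}")
    if n_obs == 0:
        raise MkError("all tips missing")
    return partials


def _prune_lnL(tree: Chronogram, partials: list, mats: list,
               prior: tuple[float, float]) -> float:
    """Log-likelihood given per-node edge matrices (flat 2x2 tuples)."""
    f = list(partials)
    log_scale = 0.0
    for i in tree.postorder():
        kids = tree.children[i]
        if not kids:
            continue
        g0 = g1 = 1.0
        for c in kids:
            p00, p01, p10, p11 = mats[c]
            c0, c1 = f[c]
            g0 *= p00 * c0 + p01 * c1
            g1 *= p10 * c0 + p11 * c1
        tot = g0 + g1
        if tot <= 0.0:
            return -math.inf
        f[i] = (g0 / tot, g1 / tot)
        log_scale += math.log(tot)
    r0, r1 = f[tree.root]
    like = prior[0] * r0 + prior[1] * r1
    if like <= 0.0:
        return -math.inf
    return math.log(like) + log_scale


def _constant_mats(tree: Chronogram, q01: float, q10: float,
                   lengths: list | None = None) -> list:
    lengths = lengths if lengths is not None else tree.length
    return [_pmat(q01, q10, lengths[i]) for i in range(tree.n_nodes)]


def _apply_missing_policy(tree: Chronogram, tip_states: dict,
                          settings: FitSettings):
    if settings.missing_policy == "drop_taxon":
        keep = [lb for lb in tree.tip_labels
                if tip_states.get(lb) is not MISSING]
        if len(keep) < len(tree.tip_labels):
            tree = tree.prune_to(keep)
            tip_states = {lb: tip_states[lb] for lb in keep}
    return tree, tip_states


def pruning_lnL(tree: Chronogram, tip_states: dict, rates: MkRates,
                settings: FitSettings | None = None) -> float:
    """Felsenstein-pruning log-likelihood of a binary trait under Mk."""
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    mats = _constant_mats(tree, rates.q01, rates.q10)
    return _prune_lnL(tree, partials, mats, settings.prior_vector(rates))


# ---------------------------------------------------------------------------
# optimisation helpers


def _lhs_starts(n: int, dims: int, lo, hi, rng) -> np.ndarray:
    """Latin-hypercube starting points in box [lo, hi]^dims."""
    lo = np.broadcast_to(np.asarray(lo, float), (dims,))
    hi = np.broadcast_to(np.asarray(hi, float), (dims,))
    u = (np.stack([rng.permutation(n) for _ in range(dims)], axis=1)
         + rng.random((n, dims))) / n
    return lo + u * (hi - lo)


def _multistart_minimize(fun, starts, bounds):
    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_mk(tree: Chronogram, tip_states: dict, model: str = "Mk2",
           settings: FitSettings | None = None) -> MkFitResult:
    """Maximum-likelihood fit of the constant-rate Mk model.

    Mk1 constrains q01 == q10; Mk2 fits both rates.  Optimisation runs on the
    log10-rate scale with multi-start L-BFGS-B.
    """
    if model not in ("Mk1", "Mk2"):
        raise MkError(f"unknown model {model!r}")
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)

    observed = [s for s in tip_states.values() if s is not MISSING]
    warning = None
    if len(set(observed)) < 2:
        warning = "monomorphic trait: boundary fit"

    lo, hi = (math.log10(b) for b in settings.rate_bounds)
    dims = 1 if model == "Mk1" else 2

    def prior_for(q01, q10):
        return settings.prior_vector(MkRates(q01, q10)
                                     if q01 + q10 > 0 else None) \
            if settings.root_prior == "stationary" \
            else settings.prior_vector()

    def nll(x):
        q01 = 10.0 ** x[0]
        q10 = 10.0 ** x[-1]
        mats = _constant_mats(tree, q01, q10)
        val = _prune_lnL(tree, partials, mats, prior_for(q01, q10))
        return -val if math.isfinite(val) else 1e12

    rng = np.random.default_rng(settings.seed)
    guess = max(min(math.log10(1.0 / max(tree.root_age, 1e-12)), hi), lo)
    starts = [np.full(dims, guess)]
    if settings.n_restarts > 1:
        starts += list(_lhs_starts(settings.n_restarts - 1, dims,
                                   max(lo, -4.0), min(hi, 1.5), rng))
    best = _multistart_minimize(nll, starts, [(lo, hi)] * dims)
    q01 = 10.0 ** best.x[0]
    q10 = 10.0 ** best.x[-1]
    lnL = -best.fun
    n_params = dims
    return MkFitResult(rates=MkRates(q01, q10), lnL=lnL, n_params=n_params,
                       AIC=2 * n_params - 2 * lnL, converged=bool(best.success),
                       model=model, warning=warning)


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_edge_lengths(tree: Chronogram, lam: float) -> list[float]:
    """Edge durations after the lambda transform (tip heights preserved)."""
    H = tree.root_age
    new_age = [0.0] * tree.n_nodes
    for i in range(tree.n_nodes):
        if tree.children[i]:
            new_age[i] = (1.0 - lam) * H + lam * tree.age[i]
    lengths = [0.0] * tree.n_nodes
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            lengths[i] = new_age[p] - new_age[i]
    return lengths


def lambda_transform(tree: Chronogram, lam: float) -> Chronogram:
    """Pagel's lambda branch-length transform.

    Internal branches are scaled by ``lam``; terminal branches are stretched
    so every tip keeps its root-to-tip height.  The root age is unchanged and
    the result is ultrametric.
    """
    if not 0.0 <= lam <= 1.0:
        raise MkError("lambda must lie in [0, 1]")
    out = tree.copy()
    out.length = _lambda_edge_lengths(tree, lam)
    H = tree.root_age
    out.age = [(1.0 - lam) * H + lam * tree.age[i] if tree.children[i] else 0.0
               for i in range(tree.n_nodes)]
    return out


def phylo_signal_test(tree: Chronogram, tip_states: dict,
                      settings: FitSettings | None = None,
                      p_mixture: bool = False) -> LambdaFit:
    """Likelihood-ratio test of phylogenetic signal via Pagel's lambda.

    Jointly maximises the Mk2 likelihood over (q01, q10, lambda) and compares
    against the model with lambda fixed at 0 (rates re-optimised), using a
    chi-square(1) reference distribution by default.  Because the null pins
    lambda to the boundary of [0, 1], the plain chi-square test is
    conservative; ``p_mixture=True`` uses the 50:50 point-mass/chi-square(1)
    mixture instead, which restores nominal type-I error.
    """
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    observed = [s for s in tip_states.values() if s is not MISSING]
    if len(set(observed)) < 2:
        return LambdaFit(lambda_hat=0.0, lnL_hat=0.0, lnL_lambda0=0.0,
                         LR_stat=0.0, p_value=1.0,
                         warning="monomorphic trait: no signal test")

    lo, hi = (math.log10(b) for b in settings.rate_bounds)
    prior_flat = settings.root_prior == "flat" or isinstance(
        settings.root_prior, tuple)

    def nll_at(lengths, x):
        q01, q10 = 10.0 ** x[0], 10.0 ** x[1]
        prior = (settings.prior_vector() if prior_flat
                 else settings.prior_vector(MkRates(q01, q10)))
        mats = _constant_mats(tree, q01, q10, lengths)
        val = _prune_lnL(tree, partials, mats, prior)
        return -val if math.isfinite(val) else 1e12

    cache: dict[float, list[float]] = {}

    def lengths_for(lam):
        key = round(lam, 12)
        if key not in cache:
            cache[key] = _lambda_edge_lengths(tree, lam)
        return cache[key]

    def nll_full(x):
        return nll_at(lengths_for(float(np.clip(x[2], 0.0, 1.0))), x[:2])

    rng = np.random.default_rng(settings.seed)
    guess = max(min(math.log10(1.0 / max(tree.root_age, 1e-12)), hi), lo)
    starts = [np.array([guess, guess, 1.0]), np.array([guess, guess, 0.2])]
    if settings.n_restarts > 2:
        extra = _lhs_starts(settings.n_restarts - 2, 3,
                            [max(lo, -4.0), max(lo, -4.0), 0.0],
                            [min(hi, 1.5), min(hi, 1.5), 1.0], rng)
        starts += list(extra)
    bounds = [(lo, hi), (lo, hi), (0.0, 1.0)]
    best = _multistart_minimize(nll_full, starts, bounds)

    starts0 = [s[:2] for s in starts]
    best0 = _multistart_minimize(lambda x: nll_at(lengths_for(0.0), x),
                                 starts0, bounds[:2])

    lnL_hat = -best.fun
    lnL0 = -best0.fun
    lam_hat = float(np.clip(best.x[2], 0.0, 1.0))
    if lnL0 > lnL_hat:  # lambda=0 is inside the full model's domain
        lnL_hat, lam_hat = lnL0, 0.0
        best = best0
    elif lam_hat < 1e-9:  # models coincide at the boundary
        lam_hat = 0.0
        lnL0 = lnL_hat
        best0 = best
    LR = max(2.0 * (lnL_hat - lnL0), 0.0)
    if LR <= 0:
        p = 1.0
    elif p_mixture:
        p = float(0.5 * stats.chi2.sf(LR, df=1))
    else:
        p = float(stats.chi2.sf(LR, df=1))
    return LambdaFit(lambda_hat=lam_hat, lnL_hat=lnL_hat, lnL_lambda0=lnL0,
                     LR_stat=LR, p_value=p,
                     rates=MkRates(10.0 ** best.x[0], 10.0 ** best.x[1]))


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction


def _marginals_given_mats(tree: Chronogram, partials: list, mats: list,
                          prior: tuple[float, float]) -> dict[int, tuple]:
    """Two-pass (down/up) marginals with per-node normalisation."""
    down = list(partials)
    lifted = [None] * tree.n_nodes  # P_edge @ down, per child edge
    for i in tree.postorder():
        kids = tree.children[i]
        if not kids:
            continue
        g0 = g1 = 1.0
        for c in kids:
            p00, p01, p10, p11 = mats[c]
            c0, c1 = down[c]
            l0 = p00 * c0 + p01 * c1
            l1 = p10 * c0 + p11 * c1
            lifted[c] = (l0, l1)
            g0 *= l0
            g1 *= l1
        tot = g0 + g1
        if tot <= 0:
            raise MkError("zero likelihood during ASR")
        down[i] = (g0 / tot, g1 / tot)

    up = [None] * tree.n_nodes
    up[tree.root] = prior
    marginals: dict[int, tuple] = {}
    for i in tree.preorder():
        u0, u1 = up[i]
        d0, d1 = down[i]
        m0, m1 = u0 * d0, u1 * d1
        tot = m0 + m1
        marginals[i] = (m0 / tot, m1 / tot)
        kids = tree.children[i]
        for c in kids:
            l0, l1 = lifted[c]
            # message to c excludes c's own lifted contribution
            e0 = u0 * d0 / l0 if l0 > 0 else 0.0
            e1 = u1 * d1 / l1 if l1 > 0 else 0.0
            # guard divide-by-zero via direct recomputation when needed
            if l0 <= 0.0 or l1 <= 0.0:
                e0, e1 = u0, u1
                for s in kids:
                    if s == c:
                        continue
                    s0, s1 = lifted[s]
                    e0 *= s0
                    e1 *= s1
            p00, p01, p10, p11 = mats[c]
            v0 = e0 * p00 + e1 * p10
            v1 = e0 * p01 + e1 * p11
            tot = v0 + v1
            up[c] = (v0 / tot, v1 / tot) if tot > 0 else (0.5, 0.5)
    return marginals


def marginal_asr(tree: Chronogram, tip_states: dict, rates: MkRates,
                 settings: FitSettings | None = None) -> dict[int, tuple]:
    """Marginal ancestral state probabilities per node under constant Mk.

    Returns a map node-id -> (P(state 0), P(state 1)); observed tips carry
    point-mass marginals.
    """
    settings = settings or FitSettings()
    tree, tip_states = _apply_missing_policy(tree, tip_states, settings)
    partials = _tip_partials(tree, tip_states)
    mats = _constant_mats(tree, rates.q01, rates.q10)
    return _marginals_given_mats(tree, partials, mats,
                                 settings.prior_vector(rates))
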