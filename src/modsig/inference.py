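"""Maximum-likelihood fitting of activities and the modulatory process.

Signatures are always treated as given; inference alternates between two
block maximizations of the same Poisson log-likelihood:

* ``fit_activities`` — per-sample bound-constrained (a >= 0) refit of the
  additive activities, with the modulation factors held fixed.  Each
  sample's problem is concave (the rate is linear in a), so a single
  warm-started run of a projected quasi-Newton method suffices.
* ``fit_modulatory`` — joint fit of the global profile r (box-constrained
  to [-1, 1]) and the per-sample activities c >= 0, with the additive
  reconstruction held fixed.  This block is not concave; failed
  convergences are retried from random initial values, up to
  ``max_restarts`` attempts, keeping the best likelihood seen.

The alternating loop runs a fixed small number of rounds (three by
default), re-gauging r and c after every optimizer run.  Coordinate
ascent guarantees a non-decreasing likelihood trace, and because c = 0
is always feasible, the extended model's likelihood can never fall below
the additive one beyond optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls

from .catalogs import ActivityMatrix, MutationCatalog, SignatureSet
from .model import (
    ModulatoryFit,
    P_FLOOR,
    additive_reconstruction,
    gauge_fix,
    log_likelihood,
)

_TINY = 1e-300


@dataclass
class FitConfig:
    """Knobs of the alternating maximum-likelihood fit.

    ``gradient_tolerance`` is relative: an attempt counts as converged
    when the optimizer reports success or the infinity norm of the
    projected gradient falls below ``gradient_tolerance * max(1,
    sqrt(total observed count))`` — gradient components of a Poisson
    log-likelihood scale like the square root of the counts, so the
    criterion does not tighten or loosen with the mutation burden.
    """

    max_restarts: int = 100
    n_alternations: int = 3
    gradient_tolerance: float = 1e-6
    seed: int = 0
    init_scheme: str = "warm"  # "warm" (NNLS / residual-based) or "random"
    outer_tolerance: float = 1e-4  # early stop when a round improves less
    maxiter: int = 2000
    optimizer: str = "L-BFGS-B"  # any bound-constrained quasi-Newton ("TNC" too)

    def __post_init__(self) -> None:
        if self.max_restarts < 1 or self.n_alternations < 1:
            raise ValueError("max_restarts and n_alternations must be >= 1")
        if self.optimizer not in ("L-BFGS-B", "TNC"):
            raise ValueError("optimizer must be 'L-BFGS-B' or 'TNC'")


@dataclass
class FitResult:
    """Outcome of :func:`alternating_fit`."""

    activities: ActivityMatrix            # under the extended model
    additive_activities: ActivityMatrix   # additive-only refit (c = 0)
    modulatory: ModulatoryFit
    log_likelihood: float
    additive_log_likelihood: float
    gain: float
    converged: bool
    n_restarts_used: int
    trace: list[float] = field(default_factory=list)


@dataclass
class ModelComparison:
    """BIC comparison of the additive model and its modulatory extension."""

    gain: float
    n_extra_parameters: int
    n_observations: int
    delta_bic: float
    gain_per_mutation: float | None


def _optimizer_options(method: str, maxiter: int, pgtol: float) -> dict:
    if method == "TNC":
        return {"maxfun": max(maxiter, 5000), "xtol": 1e-12, "ftol": 1e-12, "gtol": pgtol}
    return {"maxiter": maxiter, "maxfun": 50 * maxiter, "ftol": 1e-12, "gtol": pgtol}


def _projected_gradient_inf(
    theta: np.ndarray, grad: np.ndarray, bounds: list[tuple[float, float | None]]
) -> float:
    """Infinity norm of the gradient projected onto the feasible box."""
    pg = grad.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[i] <= lo + 1e-12 and pg[i] > 0:
            pg[i] = 0.0
        if hi is not None and theta[i] >= hi - 1e-12 and pg[i] < 0:
            pg[i] = 0.0
    return float(np.max(np.abs(pg)))


def _fit_one_sample_activities(
    x: np.ndarray,
    M: np.ndarray,
    p_row: np.ndarray,
    a0: np.ndarray,
    config: FitConfig,
) -> np.ndarray:
    """Maximize the Poisson log-likelihood of one sample over a >= 0."""
    if x.sum() == 0:
        # zero counts: likelihood -sum(p * a@M) is maximized at a = 0
        return np.zeros(M.shape[0])

    def neg_ll_and_grad(a: np.ndarray) -> tuple[float, np.ndarray]:
        xhat = a @ M
        rate = np.maximum(p_row * xhat, _TINY)
        ll = -rate.sum() + np.sum(x * np.log(rate), where=x > 0)
        grad = M @ (x / np.maximum(xhat, _TINY) - p_row)
        return -ll, -grad

    pgtol = config.gradient_tolerance * max(1.0, float(np.sqrt(x.sum())))
    res = minimize(
        neg_ll_and_grad,
        np.maximum(a0, 1e-6),
        jac=True,
        method=config.optimizer,
        bounds=[(0.0, None)] * M.shape[0],
        options=_optimizer_options(config.optimizer, config.maxiter, pgtol),
    )
    return np.maximum(res.x, 0.0)


def _warm_start_activities(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Non-negative least-squares fit of each (pseudo-counted) sample."""
    A = np.empty((X.shape[0], M.shape[0]))
    MT = M.T  # (96, n_sig)
    for k in range(X.shape[0]):
        A[k], _ = nnls(MT, X[k] + 1.0)
    return A


def fit_activities(
    observed: MutationCatalog,
    signatures: SignatureSet,
    fixed_modulatory: ModulatoryFit | None = None,
    config: FitConfig | None = None,
    init: ActivityMatrix | None = None,
) -> ActivityMatrix:
    """Refit the additive activities, optionally under fixed modulation.

    With ``fixed_modulatory=None`` this is the plain additive refit.
    Samples are independent and fitted one at a time.
    """
    config = config or FitConfig()
    X = observed.counts
    M = signatures.profiles
    if fixed_modulatory is None:
        P = np.ones_like(X)
    else:
        P = np.clip(1.0 + np.outer(fixed_modulatory.c, fixed_modulatory.r), P_FLOOR, None)
    A0 = init.activities if init is not None else _warm_start_activities(X, M)
    A = np.empty((X.shape[0], M.shape[0]))
    for k in range(X.shape[0]):
        A[k] = _fit_one_sample_activities(X[k], M, P[k], A0[k], config)
    return ActivityMatrix(list(observed.sample_ids), list(signatures.signature_ids), A)


def _modulatory_objective(theta, X, Xhat, n_channels):
    """Negative log-likelihood and gradient in theta = [r, c].

    Modulation factors are floored at P_FLOOR inside the rates so the
    log stays finite; a quadratic penalty Xhat * min(p, 0)^2 makes the
    infeasible region (1 + c*r < 0, where the floored likelihood would
    be flat) strictly unprofitable, keeping iterates feasible.
    """
    r = theta[:n_channels]
    c = theta[n_channels:]
    p = 1.0 + np.outer(c, r)
    clamped = p < P_FLOOR
    pc = np.where(clamped, P_FLOOR, p)
    rate = np.maximum(pc * Xhat, _TINY)
    ll = -rate.sum() + np.sum(X * np.log(rate), where=X > 0)
    active = ~clamped  # floored cells contribute no likelihood gradient
    common = np.where(active, X / pc - Xhat, 0.0)
    neg = np.minimum(p, 0.0)
    ll -= float(np.sum(Xhat * neg**2))
    pen = 2.0 * Xhat * neg  # d penalty / d p, nonzero only where p < 0
    g_r = np.sum(c[:, None] * (common - pen), axis=0)
    g_c = np.sum(r[None, :] * (common - pen), axis=1)
    return -ll, -np.concatenate([g_r, g_c])


def _project_feasible(fit: ModulatoryFit) -> ModulatoryFit:
    """Cap each c so that min_j (1 + c*r_j) >= 0 exactly.

    The optimizer's penalty keeps iterates only approximately feasible;
    this final projection moves c by at most O(penalty tolerance).
    """
    r_min = float(fit.r.min())
    if r_min >= 0.0:
        return fit
    return ModulatoryFit(fit.r, np.minimum(fit.c, 1.0 / (-r_min)))


def _mean_multiplicative_residual_init(X: np.ndarray, Xhat: np.ndarray) -> np.ndarray:
    """Centred mean multiplicative residual, gauged: a cheap guess for r."""
    ratio = (X + 1.0) / (Xhat + 1.0)
    r0 = ratio.mean(axis=0) - 1.0
    scale = np.max(np.abs(r0))
    return r0 / scale if scale > 0 else r0


def fit_modulatory(
    observed: MutationCatalog,
    signatures: SignatureSet,
    activities: ActivityMatrix,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    init: ModulatoryFit | None = None,
) -> tuple[ModulatoryFit, bool, int]:
    """Fit (r, c) jointly with the additive reconstruction fixed.

    Returns the gauged fit, a convergence flag, and the number of
    restarts consumed.  The first attempt starts from ``init`` (or the
    centred mean multiplicative residual with c = 0.5); subsequent
    attempts use uniform random initial values.
    """
    config = config or FitConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = observed.counts
    Xhat = additive_reconstruction(activities, signatures)
    n_s, n_c = X.shape
    bounds = [(-1.0, 1.0)] * n_c + [(0.0, None)] * n_s

    if init is not None and np.any(init.r != 0):
        theta0 = np.concatenate([init.r, init.c])
    elif config.init_scheme == "warm":
        theta0 = np.concatenate(
            [_mean_multiplicative_residual_init(X, Xhat), np.full(n_s, 0.5)]
        )
    else:
        theta0 = np.concatenate([rng.uniform(-1, 1, n_c), rng.uniform(0, 1, n_s)])

    pgtol = config.gradient_tolerance * max(1.0, float(np.sqrt(X.sum())))
    best: ModulatoryFit | None = None
    best_ll = -np.inf
    converged = False
    attempts = 0
    for attempt in range(config.max_restarts):
        attempts = attempt + 1
        res = minimize(
            _modulatory_objective,
            theta0,
            args=(X, Xhat, n_c),
            jac=True,
            method=config.optimizer,
            bounds=bounds,
            options=_optimizer_options(config.optimizer, config.maxiter, pgtol),
        )
        fit = gauge_fix(ModulatoryFit(res.x[:n_c], np.maximum(res.x[n_c:], 0.0)))
        fit = _project_feasible(fit)
        try:
            ll = log_likelihood(X, Xhat, fit)
        except ValueError:
            ll = -np.inf
        if ll > best_ll:
            best, best_ll = fit, ll
        ok = bool(res.success) or _projected_gradient_inf(res.x, res.jac, bounds) <= pgtol
        if ok:
            converged = True
            break
        theta0 = np.concatenate([rng.uniform(-1, 1, n_c), rng.uniform(0, 1, n_s)])
    assert best is not None
    return best, converged, attempts


def alternating_fit(
    observed: MutationCatalog,
    signatures: SignatureSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Alternate activity and modulatory-process fits (three rounds by default).

    Round 0 is the plain additive refit, which also provides the
    baseline likelihood for the gain.  Each subsequent round refits
    (r, c) given the activities and then the activities given (r, c),
    warm-starting every block from its current value so the likelihood
    trace is non-decreasing up to optimizer tolerance.  Deterministic
    for a fixed config seed.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    X = observed.counts

    A_add = fit_activities(observed, signatures, None, config)
    Xhat = additive_reconstruction(A_add, signatures)
    ll_add = log_likelihood(X, Xhat, None)

    A = A_add
    mod = ModulatoryFit.inactive(observed.n_samples, X.shape[1])
    ll_best = ll_add
    best_A, best_mod = A, mod
    trace = [ll_add]
    converged = True
    restarts_total = 0

    for _ in range(config.n_alternations):
        mod, ok, used = fit_modulatory(observed, signatures, A, config, rng, init=mod)
        restarts_total += used
        converged = converged and ok
        trace.append(log_likelihood(X, additive_reconstruction(A, signatures), mod))
        A = fit_activities(observed, signatures, mod, config, init=A)
        ll = log_likelihood(X, additive_reconstruction(A, signatures), mod)
        trace.append(ll)
        if ll > ll_best:
            improvement = ll - ll_best
            ll_best, best_A, best_mod = ll, A, mod
        else:
            improvement = 0.0
        if improvement < config.outer_tolerance:
            break

    gain = ll_best - ll_add
    return FitResult(
        activities=best_A,
        additive_activities=A_add,
        modulatory=best_mod,
        log_likelihood=ll_best,
        additive_log_likelihood=ll_add,
        gain=gain,
        converged=converged,
        n_restarts_used=restarts_total,
        trace=trace,
    )


def model_comparison(
    result: FitResult,
    n_samples: int,
    n_channels: int = 96,
    total_mutations: float | None = None,
) -> ModelComparison:
    """BIC-style comparison of the extended model against the additive one.

    The extension adds one 96-channel profile plus one activity per
    sample; the number of observations is the number of catalogue cells
    (samples x channels).  Positive delta_bic favours the extension.
    """
    k_extra = n_channels + n_samples
    n_obs = n_samples * n_channels
    delta_bic = 2.0 * result.gain - k_extra * np.log(n_obs)
    per_mut = result.gain / total_mutations if total_mutations else None
    return ModelComparison(
        gain=result.gain,
        n_extra_parameters=k_extra,
        n_observations=n_obs,
        delta_bic=float(delta_bic),
        gain_per_mutation=per_mut,
    )
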