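"""Core model: additive reconstruction, multiplicative modulation, Poisson
log-likelihood, its analytic gradients, and gauge fixing.

The additive part reconstructs the expected catalogue of sample ``k`` as

    Xhat[k, j] = sum_i a[k, i] * mu[i, j]

with non-negative activities ``a`` and signature profiles ``mu`` (each a
probability distribution over the 96 channels).  A single global
modulatory process ``r`` (one real multiplier per channel) acts
multiplicatively with a per-sample activity ``c[k] >= 0``:

    X[k, j] ~ Poisson((1 + c[k] * r[j]) * Xhat[k, j])

so channels with r[j] > 0 are amplified and channels with r[j] < 0 are
depleted, which an additive mixture of non-negative signatures cannot
express.  Only the product of c and r is identified; the scale
degeneracy (r -> r/alpha, c -> alpha*c) is removed by the gauge
max|r| = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalogs import ActivityMatrix, MutationCatalog, SignatureSet

#: Modulation factors are clamped at this floor inside rates so the
#: log-likelihood stays finite at the feasibility boundary p = 0.
P_FLOOR = 1e-9

_TINY = 1e-300


class ZeroRateError(ValueError):
    """A channel with a positive observed count has model rate zero."""


@dataclass
class ModulatoryFit:
    """A modulatory process profile ``r`` with per-sample activities ``c``."""

    r: np.ndarray  # (96,)
    c: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.r.ndim != 1 or self.c.ndim != 1:
            raise ValueError("r and c must be one-dimensional")
        if np.any(self.c < 0):
            raise ValueError("modulatory activities c must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.c.shape[0]

    @classmethod
    def inactive(cls, n_samples: int, n_channels: int = 96) -> "ModulatoryFit":
        """The fit with no modulation: r = 0, c = 0 (plain additive model)."""
        return cls(np.zeros(n_channels), np.zeros(n_samples))

    def is_feasible(self, tol: float = 1e-12) -> bool:
        return bool(np.all(1.0 + np.outer(self.c, self.r) >= -tol))


def modulation_factors(fit: ModulatoryFit, tol: float = 1e-12) -> np.ndarray:
    """Per-sample, per-channel factors p[k, j] = 1 + c[k] * r[j] (all >= 0)."""
    p = 1.0 + np.outer(fit.c, fit.r)
    if np.any(p < -tol):
        raise ValueError("infeasible modulatory fit: some 1 + c*r < 0")
    return np.clip(p, 0.0, None)


def additive_reconstruction(
    activities: ActivityMatrix | np.ndarray, signatures: SignatureSet | np.ndarray
) -> np.ndarray:
    """Expected counts Xhat = A @ M of the plain additive model."""
    A = activities.activities if isinstance(activities, ActivityMatrix) else np.asarray(activities, float)
    M = signatures.profiles if isinstance(signatures, SignatureSet) else np.asarray(signatures, float)
    if A.ndim != 2 or M.ndim != 2 or A.shape[1] != M.shape[0]:
        raise ValueError(f"non-conformable shapes {A.shape} x {M.shape}")
    if np.any(A < 0):
        raise ValueError("activities must be non-negative")
    return A @ M


def _as_counts(observed: MutationCatalog | np.ndarray) -> np.ndarray:
    if isinstance(observed, MutationCatalog):
        return observed.counts
    return np.asarray(observed, dtype=float)


def log_likelihood(
    observed: MutationCatalog | np.ndarray,
    additive: np.ndarray,
    fit: ModulatoryFit | None = None,
) -> float:
    """Poisson log-likelihood of the (possibly modulated) reconstruction.

    Computes sum_kj [ -p*Xhat + X*log(p*Xhat) ]; the log(X!) term is a
    data-only constant and is dropped throughout, so values are
    comparable between fits of the same catalogue (and all likelihood
    gains are unaffected).  Cells with X = 0 contribute only -p*Xhat.

    Raises :class:`ZeroRateError` when a positive count meets a zero
    rate, where the likelihood is genuinely -infinity.
    """
    X = _as_counts(observed)
    additive = np.asarray(additive, dtype=float)
    if X.shape != additive.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {additive.shape}")
    if fit is None:
        rates = additive.copy()
    else:
        rates = np.clip(1.0 + np.outer(fit.c, fit.r), P_FLOOR, None) * additive
    pos = X > 0
    if np.any(rates[pos] <= 0):
        raise ZeroRateError("positive count with zero model rate: log-likelihood -inf")
    ll = -float(rates.sum())
    ll += float(np.sum(X[pos] * np.log(rates[pos])))
    return ll


def grad_activities(
    observed: MutationCatalog | np.ndarray,
    signatures: SignatureSet | np.ndarray,
    activities: ActivityMatrix | np.ndarray,
    fit: ModulatoryFit | None = None,
) -> np.ndarray:
    """d log L / d a[k, i] = sum_j mu[i, j] * (X[k, j]/Xhat[k, j] - p[k, j])."""
    X = _as_counts(observed)
    M = signatures.profiles if isinstance(signatures, SignatureSet) else np.asarray(signatures, float)
    Xhat = additive_reconstruction(activities, M)
    p = np.ones_like(X) if fit is None else np.clip(1.0 + np.outer(fit.c, fit.r), P_FLOOR, None)
    ratio = X / np.maximum(Xhat, _TINY)
    return (ratio - p) @ M.T


def grad_modulatory_profile(
    observed: MutationCatalog | np.ndarray,
    additive: np.ndarray,
    fit: ModulatoryFit,
) -> np.ndarray:
    """d log L / d r[j] = sum_k c[k] * (X[k, j]/p[k, j] - Xhat[k, j])."""
    X = _as_counts(observed)
    p = np.clip(1.0 + np.outer(fit.c, fit.r), P_FLOOR, None)
    return np.sum(fit.c[:, None] * (X / p - additive), axis=0)


def grad_modulatory_activity(
    observed: MutationCatalog | np.ndarray,
    additive: np.ndarray,
    fit: ModulatoryFit,
) -> np.ndarray:
    """d log L / d c[k] = sum_j r[j] * (X[k, j]/p[k, j] - Xhat[k, j])."""
    X = _as_counts(observed)
    p = np.clip(1.0 + np.outer(fit.c, fit.r), P_FLOOR, None)
    return np.sum(fit.r[None, :] * (X / p - additive), axis=1)


def gauge_fix(fit: ModulatoryFit) -> ModulatoryFit:
    """Rescale to the canonical gauge max|r| = 1.

    r is divided and c multiplied by max|r|, leaving every modulation
    factor 1 + c*r — and hence the likelihood — unchanged.  An
    identically zero r returns the inactive fit (c forced to 0, since c
    is then unidentified).
    """
    scale = float(np.max(np.abs(fit.r)))
    if scale == 0.0:
        return ModulatoryFit(fit.r.copy(), np.zeros_like(fit.c))
    return ModulatoryFit(fit.r / scale, fit.c * scale)
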