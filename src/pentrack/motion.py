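"""Stay-put motion model: an exponential mixture over inter-frame pose displacement.

At frame rates of a few fps, housed animals move very little between frames,
so the transition density over the pose displacement

    delta(a, b) = sqrt(|s_a - s_b|^2 + |t_a - t_b|^2)

(shoulder and tail displacements combined in quadrature) is concentrated at
zero.  A single exponential fits observed displacements poorly; a three
component mixture

    p(delta) = sum_k w_k * lambda_k * exp(-lambda_k * delta)

captures both the sharp stay-put peak and the heavy tail of fast movement.
The default coefficients, fitted upstream to ~1.7 million displacement
samples from overhead pig-pen video, are
(w, lambda) = (0.6, 9/10), (0.3, 1/6), (0.1, 1/30), in the pixel units of
the input coordinates.

:func:`fit_motion_model` re-estimates the mixture from displacement samples
by EM for deployments whose geometry (camera height, resolution, species)
differs from the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

DEFAULT_WEIGHTS = (0.6, 0.3, 0.1)
DEFAULT_RATES = (9.0 / 10.0, 1.0 / 6.0, 1.0 / 30.0)


@dataclass
class MotionModel:
    """Mixture of exponentials over the inter-frame pose displacement delta."""

    weights: np.ndarray = DEFAULT_WEIGHTS
    rates: np.ndarray = DEFAULT_RATES

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.weights.shape != self.rates.shape or self.weights.ndim != 1:
            raise ValueError("weights and rates must be 1-d arrays of equal length")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    @classmethod
    def default(cls) -> "MotionModel":
        return cls(np.array(DEFAULT_WEIGHTS), np.array(DEFAULT_RATES))

    def scaled(self, factor: float) -> "MotionModel":
        """Model whose displacements are ``factor`` times larger (rates / factor)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return MotionModel(self.weights.copy(), self.rates / factor)

    @property
    def mean(self) -> float:
        """Mean displacement, sum_k w_k / lambda_k."""
        return float(np.sum(self.weights / self.rates))

    def density(self, delta) -> np.ndarray | float:
        """Mixture density at displacement(s) ``delta`` (>= 0)."""
        d = np.asarray(delta, dtype=float)
        if np.any(d < 0):
            raise ValueError("displacement must be nonnegative")
        out = np.einsum(
            "k,k...->...",
            self.weights * self.rates,
            np.exp(-np.multiply.outer(self.rates, d)),
        )
        return float(out) if np.isscalar(delta) or d.ndim == 0 else out

    def log_density(self, delta) -> np.ndarray | float:
        """log p(delta), computed per component so huge displacements never
        underflow to log(0)."""
        d = np.asarray(delta, dtype=float)
        if np.any(d < 0):
            raise ValueError("displacement must be nonnegative")
        comp = (np.log(self.weights * self.rates)[:, None]
                - self.rates[:, None] * d.reshape(1, -1))
        out = logsumexp(comp, axis=0).reshape(d.shape)
        return float(out) if np.isscalar(delta) or d.ndim == 0 else out

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw displacement magnitudes from the mixture."""
        comp = rng.choice(self.weights.size, size=size, p=self.weights)
        return rng.exponential(1.0 / self.rates[comp])


def slot_distance(a, b) -> float:
    """Pose displacement delta between two (shoulder, tail) pairs."""
    sa, ta = a
    sb, tb = b
    ds = np.asarray(sa, dtype=float) - np.asarray(sb, dtype=float)
    dt = np.asarray(ta, dtype=float) - np.asarray(tb, dtype=float)
    return float(np.sqrt(ds @ ds + dt @ dt))


def transition_density(delta, model: MotionModel | None = None):
    """Stay-put transition density p(delta) under ``model`` (default mixture)."""
    model = model or MotionModel.default()
    return model.density(delta)


def fit_motion_model(
    samples,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> MotionModel:
    """Maximum-likelihood exponential-mixture fit by EM.

    Restarts from jittered quantile-based initializations and keeps the
    highest-likelihood solution; components are returned sorted by
    decreasing rate (stay-put component first).  Zero displacements are kept
    (the exponential density is finite at 0).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} samples to fit {n_components} components")
    if np.any(x < 0):
        raise ValueError("displacement samples must be nonnegative")
    rng = np.random.default_rng(seed)
    # quantile-based group means seed the rates across the observed scale
    qs = np.quantile(x, np.linspace(0, 1, n_components + 1))
    base_means = np.array([
        max(x[(x >= qs[k]) & (x <= qs[k + 1])].mean(), 1e-12)
        for k in range(n_components)
    ])

    best = None
    best_ll = -np.inf
    for restart in range(n_restarts):
        jitter = 1.0 if restart == 0 else rng.uniform(0.3, 3.0, size=n_components)
        rates = 1.0 / (base_means * jitter)
        weights = np.full(n_components, 1.0 / n_components)
        prev_ll = -np.inf
        for _ in range(max_iter):
            log_comp = (np.log(weights * rates)[:, None] - rates[:, None] * x[None, :])
            log_norm = logsumexp(log_comp, axis=0)
            ll = float(log_norm.sum())
            resp = np.exp(log_comp - log_norm[None, :])  # (K, n)
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            weights = nk / x.size
            rates = nk / np.maximum(resp @ x, 1e-300)
            rates = np.clip(rates, 1e-12, 1e12)
            if ll - prev_ll < tol * max(1.0, abs(ll)):
                break
            prev_ll = ll
        if ll > best_ll:
            best_ll = ll
            best = (weights.copy(), rates.copy())

    weights, rates = best
    order = np.argsort(-rates)
    weights = weights[order] / weights.sum()
    return MotionModel(weights, rates[order])
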