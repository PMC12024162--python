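"""Loss terms and schedules for LEM training.

The sparse loss has two parts, both sums of sigmoids of clamped scores:

* elimination loss — penalises *wrongly signed* extrema: a flagged maximum
  with a negative score contributes sigmoid(S), a flagged minimum with a
  positive score contributes sigmoid(-S).  Correctly signed extrema
  contribute the constant sigmoid(0) = 0.5 and no gradient.  Gradient
  descent therefore pushes a negative maximum further down (and a positive
  minimum further up) until it stops being an extremum — the wrong
  extremum is eliminated rather than sign-flipped.
* penalty loss — confines *all* scores to the band (-tau, tau): constant
  (zero gradient) inside the band, pushing |S| down outside it, which keeps
  non-salient regions flat and makes genuine extrema stand out.

The classification losses are plain binary cross-entropies on the GAP and
LEM probabilities, blended by alpha in the total objective:

    J = alpha * (mu * L_spa + L_lem) + (1 - alpha) * L_gap + lam/2 * ||theta||^2

alpha ramps from 0.1 to 1.0 during training (GAP-dominated warm-up, then
LEM-dominated), and the learning rate decays by a fixed factor every few
epochs.  Gradient helpers return dLoss/dS with the extremum indicator maps
treated as constants of the forward pass (they are piecewise constant in S).
"""

from __future__ import annotations

import numpy as np

from .extremum import ExtremumMaps
from .scoremap import sigmoid

__all__ = [
    "elimination_loss",
    "elimination_grad",
    "penalty_loss",
    "penalty_grad",
    "sparse_loss",
    "sparse_grad",
    "classification_loss",
    "total_objective",
    "alpha_schedule",
    "lr_schedule",
]

_EPS = 1e-7


def _dsigmoid(z: np.ndarray) -> np.ndarray:
    s = sigmoid(z)
    return s * (1.0 - s)


def elimination_loss(S: np.ndarray, E: ExtremumMaps) -> float:
    S = np.asarray(S, dtype=float)
    terms = E.smax * sigmoid(np.minimum(S, 0.0)) + E.smin * sigmoid(-np.maximum(S, 0.0))
    return float(terms.sum())


def elimination_grad(S: np.ndarray, E: ExtremumMaps) -> np.ndarray:
    """d(elimination loss)/dS; nonzero only at wrongly signed extrema."""
    S = np.asarray(S, dtype=float)
    g = np.zeros_like(S)
    neg = S < 0.0
    pos = S > 0.0
    g += E.smax * neg * _dsigmoid(np.minimum(S, 0.0))
    g -= E.smin * pos * _dsigmoid(-np.maximum(S, 0.0))
    return g


def penalty_loss(S: np.ndarray, tau: float) -> float:
    if tau <= 0:
        raise ValueError("tau must be > 0")
    S = np.asarray(S, dtype=float)
    terms = sigmoid(np.maximum(S, tau)) + sigmoid(-np.minimum(S, -tau))
    return float(terms.sum())


def penalty_grad(S: np.ndarray, tau: float) -> np.ndarray:
    """d(penalty loss)/dS; zero inside the band |S| <= tau."""
    S = np.asarray(S, dtype=float)
    g = np.zeros_like(S)
    above = S > tau
    below = S < -tau
    g += above * _dsigmoid(np.maximum(S, tau))
    g -= below * _dsigmoid(-np.minimum(S, -tau))
    return g


def sparse_loss(S: np.ndarray, E: ExtremumMaps, gamma: float, tau: float) -> float:
    return elimination_loss(S, E) + gamma * penalty_loss(S, tau)


def sparse_grad(S: np.ndarray, E: ExtremumMaps, gamma: float, tau: float) -> np.ndarray:
    return elimination_grad(S, E) + gamma * penalty_grad(S, tau)


def classification_loss(y: float, t: int) -> float:
    """Binary cross-entropy -(t log y + (1-t) log(1-y)), y clipped to [eps, 1-eps]."""
    y = float(np.clip(y, _EPS, 1.0 - _EPS))
    return float(-(t * np.log(y) + (1 - t) * np.log(1.0 - y)))


def total_objective(l_spa: float, l_lem: float, l_gap: float,
                    theta_norm_sq: float, alpha: float, mu: float,
                    lam: float) -> float:
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * (mu * l_spa + l_lem) + (1.0 - alpha) * l_gap + 0.5 * lam * theta_norm_sq


def alpha_schedule(epoch: int, max_epochs: int, alpha_start: float = 0.1,
                   alpha_end: float = 1.0, ramp_epochs: int | None = None) -> float:
    """Linear ramp from alpha_start (epoch 0) to alpha_end, then flat.

    The ramp spans ``ramp_epochs`` epochs (default: half of ``max_epochs``),
    so the schedule is monotone nondecreasing and reaches alpha_end exactly at
    the ramp end.
    """
    if not (0 <= epoch):
        raise ValueError("epoch must be >= 0")
    ramp = ramp_epochs if ramp_epochs is not None else max(1, max_epochs // 2)
    ramp = max(1, ramp)
    frac = min(1.0, epoch / ramp)
    return alpha_start + (alpha_end - alpha_start) * frac


def lr_schedule(epoch: int, lr0: float = 1e-4, decay: float = 0.98,
                every: int = 8) -> float:
    """Stepwise decay: lr0 * decay ** floor(epoch / every)."""
    return lr0 * decay ** (epoch // every)
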