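"""Score-map head: 1x1 projection of a feature map and the GAP probability.

A trained classifier head of the form "global average pooling followed by a
single linear unit" can be rewritten, without changing the output, as a 1x1
convolution followed by GAP: averaging the feature map and then projecting
equals projecting each position and then averaging.  The projected grid is
the *score map* S — the per-region class evidence that the extremum machinery
operates on.  No activation is applied to S.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["compute_score_map", "gap_probability", "sigmoid"]

sigmoid = expit


def _check(M: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    V = np.asarray(V, dtype=float)
    if M.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {M.shape}")
    if V.ndim != 1 or V.shape[0] != M.shape[0]:
        raise ValueError(
            f"projection weights of length {V.shape} do not match {M.shape[0]} channels"
        )
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(V))):
        raise ValueError("feature map and weights must be finite")
    return M, V


def compute_score_map(M: np.ndarray, V: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Per-position projection S[i, j] = sum_c M[c, i, j] * V[c] + bias."""
    M, V = _check(M, V)
    return np.tensordot(V, M, axes=([0], [0])) + bias


def gap_probability(M: np.ndarray, V: np.ndarray, bias: float = 0.0) -> float:
    """Classification probability via global average pooling of the score map.

    Computed as sigmoid(mean over channels-projected positions); by linearity
    this equals the conventional GAP-then-linear head.
    """
    S = compute_score_map(M, V, bias)
    return float(sigmoid(S.mean()))
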