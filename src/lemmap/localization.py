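"""Top-down importance propagation from selected extrema to pixels.

After classification, the extrema that support the predicted class are
selected (maxima with positive scores when the image is called malignant,
minima with negative scores otherwise) and each one is assigned unit
importance.  Importance is then redistributed layer by layer down to the
input pixels: at every neuron the incoming importance is split over its
children in proportion to ReLU(weight) * child_activation, normalised so the
fractions sum to one.  Negative weights are discarded; at the score layer,
positive projection weights feed maxima and negative ones (via their
magnitude) feed minima, since the score map carries no activation.

The result is a nonnegative pixel map whose total mass equals the number of
propagated extrema, minus any mass dropped at neurons whose normaliser is
zero (recorded in the result).  High-mass pixels are the ones that drove the
selected extrema — the lesion candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .extremum import Aggregates, ExtremumMaps, aggregate, detect_extrema

__all__ = [
    "ImportanceMap",
    "LocalizationResult",
    "CapabilityError",
    "select_extrema",
    "propagate_importance",
    "localize",
    "binarize_and_score",
    "dice",
    "recall",
]


class CapabilityError(RuntimeError):
    """Raised when the network contains a layer type propagation cannot handle."""


@dataclass
class ImportanceMap:
    values: np.ndarray  # (H, W) >= 0, image resolution
    source_extrema: list[tuple[int, int, str]] = field(default_factory=list)
    mass_delivered: float = 0.0  # == len(source_extrema) when nothing dropped
    status: str = "ok"  # "ok" | "empty-selection"


@dataclass
class LocalizationResult:
    binary_mask: np.ndarray  # (H, W) bool
    dsc: float | None = None
    recall: float | None = None


def select_extrema(S: np.ndarray, E: ExtremumMaps, aggregates: Aggregates,
                   threshold: float = 0.5) -> list[tuple[int, int, str]]:
    """Extrema supporting the predicted class.

    Malignant call (y_lem > threshold): all flagged maxima with positive
    scores; benign call: all flagged minima with negative scores.  May be
    empty (e.g. a constant-zero score map on the benign branch).
    """
    S = np.asarray(S, dtype=float)
    if aggregates.y_lem > threshold:
        keep = E.smax & (S > 0.0)
        kind = "max"
    else:
        keep = E.smin & (S < 0.0)
        kind = "min"
    return [(int(r), int(c), kind) for r, c in zip(*np.nonzero(keep))]


# ---------------------------------------------------------------------------
# propagation core


def _score_layer_init(net: nn.Network, extrema: list[tuple[int, int, str]],
                      weights: dict[str, float] | None = None
                      ) -> tuple[np.ndarray, float]:
    """Distribute each extremum's unit importance over feature channels.

    Positive projection weights feed maxima, magnitudes of negative weights
    feed minima; fractions are normalised per extremum.  Returns (P over the
    feature map, dropped mass).
    """
    M = net.proj.x
    if M is None:
        raise RuntimeError("run a forward pass before propagating importance")
    M = M[0]  # (C, h, w), batch of one
    V = net.proj.V
    P = np.zeros_like(M)
    dropped = 0.0
    for (r, c, kind) in extrema:
        w = np.maximum(V, 0.0) if kind == "max" else np.maximum(-V, 0.0)
        num = w * M[:, r, c]
        z = num.sum()
        mass = 1.0 if weights is None else weights[f"{r},{c},{kind}"]
        if z <= 0.0:
            dropped += mass
            continue
        P[:, r, c] += mass * num / z
    return P, dropped


def _propagate_feature_importance(net: nn.Network, P: np.ndarray
                                  ) -> tuple[np.ndarray, float]:
    """Push importance from the final feature map down to the input pixels."""
    dropped = 0.0
    P = P[None]  # (1, C, h, w)
    for layer in reversed(net.features):
        x = layer.x
        if x is None:
            raise RuntimeError("layer has no cached forward activation")
        if isinstance(layer, (nn.ReLU, nn.Scale)):
            # ReLU: a conv+ReLU pair is one neuron.  Scale: one child per
            # unit with a positive weight.  Importance passes through.
            continue
        if isinstance(layer, nn.Conv2D):
            wpos = np.maximum(layer.W, 0.0)
            Z = nn.conv2d(x, wpos, None, layer.pad, layer.pad_mode)
            ok = Z > 0.0
            dropped += float(P[~ok].sum())
            Q = np.where(ok, P / np.where(ok, Z, 1.0), 0.0)
            P = x * nn.conv2d_input_grad(Q, wpos, layer.pad, x.shape,
                                         layer.pad_mode)
        elif isinstance(layer, nn.MaxPool2D):
            s = layer.size
            n, c, h, w = x.shape
            xr = x.reshape(n, c, h // s, s, w // s, s)
            mx = xr.max(axis=(3, 5))
            ties = xr == mx[:, :, :, None, :, None]
            count = ties.sum(axis=(3, 5))
            share = (P / count)[:, :, :, None, :, None]
            P = (ties * share).reshape(n, c, h, w)
        elif isinstance(layer, nn.AvgPool2D):
            # uniform-weight convolution: Z_j = mean of the (nonnegative)
            # window, fraction for child i is x_i / (s*s*Z_j)
            s = layer.size
            n, c, h, w = x.shape
            xr = x.reshape(n, c, h // s, s, w // s, s)
            Z = xr.sum(axis=(3, 5))
            ok = Z > 0.0
            dropped += float(P[~ok].sum())
            Q = np.where(ok, P / np.where(ok, Z, 1.0), 0.0)
            P = (xr * Q[:, :, :, None, :, None]).reshape(n, c, h, w)
        else:
            raise CapabilityError(
                f"unsupported layer type for importance propagation: "
                f"{type(layer).__name__}"
            )
    return P[0].sum(axis=0), dropped  # sum over input channels -> (H, W)


def propagate_importance(net: nn.Network,
                         extremum: tuple[int, int, str]) -> ImportanceMap:
    """Propagate unit importance from one extremum down to the pixels.

    Requires that a forward pass (batch of one image) has already been run so
    that every layer's activations are cached.
    """
    P, _ = _score_layer_init(net, [extremum])
    values, _ = _propagate_feature_importance(net, P)
    # mass_delivered < 1 records importance dropped at zero normalisers
    return ImportanceMap(values=values, source_extrema=[extremum],
                         mass_delivered=float(values.sum()), status="ok")


def localize(net: nn.Network, image: np.ndarray, config=None,
             threshold: float | None = None) -> tuple[ImportanceMap, Aggregates]:
    """Full pipeline: forward pass, extremum detection, selection, propagation.

    The propagation is linear in the initial importance, so all selected
    extrema are pushed down in a single pass; the result equals the sum of
    per-extremum maps.
    """
    if threshold is None:
        threshold = getattr(config, "decision_threshold", 0.5)
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    _, S = net.forward(x)
    S0 = S[0]
    E = detect_extrema(S0)
    agg = aggregate(S0, E)
    selected = select_extrema(S0, E, agg, threshold)
    if not selected:
        return (ImportanceMap(values=np.zeros(x.shape[-2:]), source_extrema=[],
                              mass_delivered=0.0, status="empty-selection"), agg)
    P, _ = _score_layer_init(net, selected)
    values, _ = _propagate_feature_importance(net, P)
    return (ImportanceMap(values=values, source_extrema=selected,
                          mass_delivered=float(values.sum()), status="ok"), agg)


# ---------------------------------------------------------------------------
# scoring


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 0 when both empty."""
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def recall(pred: np.ndarray, truth: np.ndarray) -> float:
    """|A∩B| / |B|, the fraction of true lesion pixels recovered."""
    truth = truth.astype(bool)
    if truth.sum() == 0:
        return 0.0
    return float(np.logical_and(pred.astype(bool), truth).sum() / truth.sum())


def binarize_and_score(imap: ImportanceMap, truth: np.ndarray | None = None,
                       fraction: float = 0.2) -> LocalizationResult:
    """Threshold the importance map at ``fraction`` of its maximum.

    An all-zero map yields an empty mask (DSC 0 against a nonempty truth).
    """
    values = np.asarray(imap.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("importance map must be nonnegative")
    peak = values.max()
    mask = values >= fraction * peak if peak > 0 else np.zeros_like(values, dtype=bool)
    res = LocalizationResult(binary_mask=mask)
    if truth is not None:
        res.dsc = dice(mask, truth)
        res.recall = recall(mask, truth)
    return res
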