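"""Training loop: plain SGD on the blended GAP/LEM objective.

Each step runs the forward pass, detects score-map extrema (treated as
constants of the step), assembles the analytic gradient of the objective with
respect to the score map, and backpropagates it through the network:

    dJ/dS = alpha * (mu * dL_spa/dS + dL_lem/dS) + (1 - alpha) * dL_gap/dS

with dL_gap/dS = (y_gap - t) / (W*H) and dL_lem/dS = (y_lem - t) *
(smax * [S > 0] + smin * [S < 0]) / n_extrema.  The L2 term contributes
lam * theta (weights only, biases excluded) once per update.  Per-sample
objectives are summed within a mini-batch; the update is the vanilla rule
theta <- theta - lr * dJ/dtheta.

With alpha fixed at 0 the loop degenerates exactly — bit for bit — into
plain cross-entropy training of the GAP head (see ``train_gap_baseline``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn, objective
from .config import LemConfig
from .extremum import ExtremumMaps, aggregate, detect_extrema
from .scoremap import sigmoid
from .synthetic import LabeledImage, augment, sample_augment_params

__all__ = ["TrainState", "DataError", "build_tiny_backbone", "train",
           "train_gap_baseline", "predict"]


class DataError(ValueError):
    pass


@dataclass
class TrainState:
    epoch: int = 0
    lr: float = 0.0
    alpha: float = 0.0
    history: list[dict] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def build_tiny_backbone(config: LemConfig,
                        rng: np.random.Generator | None = None) -> nn.Network:
    """A small conv net: one conv+ReLU+maxpool block per entry of
    ``config.channels``, then the 1x1 score projection.  With the default
    three stride-2 pools a 64x64 image yields an 8x8 score map."""
    rng = rng or np.random.default_rng(config.seed)
    extent = config.image_size
    layers: list[nn.Layer] = [nn.Scale(config.input_scale)]
    c_in = 1
    for c_out in config.channels:
        layers += [nn.Conv2D(c_in, c_out, 3, rng=rng), nn.ReLU(), nn.MaxPool2D(2)]
        extent //= 2
        c_in = c_out
    if extent < 2:
        raise ValueError(
            f"config yields a {extent}x{extent} score map; need at least 2x2"
        )
    return nn.Network(layers, nn.ScoreProjection(c_in, rng=rng))


def calibrate_head(net: nn.Network, X: np.ndarray, target_std: float = 1.0) -> None:
    """Data-dependent initialisation of the score head.

    The half-normal projection init makes the raw score map an uncentred
    salience map whose mean offset (several units) could not be absorbed by
    the bias within a short run.  One forward pass on a calibration batch
    rescales V so the score map has roughly unit spread and sets the bias to
    centre it, so training starts calibrated (y of order 0.5) with scores
    inside the penalty band.
    """
    _, S = net.forward(X)
    sd = float(S.std())
    if sd > 0:
        net.proj.V *= target_std / sd
        S = S * (target_std / sd)
    net.proj.b -= float(S.mean())


def _dataset_arrays(dataset: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([im.pixels for im in dataset])[:, None, :, :].astype(float)
    t = np.array([im.label for im in dataset], dtype=float)
    return X, t


def _gap_grad(S: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(y_gap per sample, dL_gap/dS per sample) for a batch of score maps."""
    n, h, w = S.shape
    y = sigmoid(S.mean(axis=(1, 2)))
    dS = ((y - t) / (h * w))[:, None, None] * np.ones_like(S)
    return y, dS


def _run_epochs(net: nn.Network, X: np.ndarray, t: np.ndarray,
                config: LemConfig, lem: bool,
                dataset: list[LabeledImage] | None = None) -> TrainState:
    state = TrainState()
    n = X.shape[0]
    calibrate_head(net, X[:min(n, config.batch_size)])
    velocity: list[np.ndarray] | None = None
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    aug_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for epoch in range(config.max_epochs):
        lr = objective.lr_schedule(epoch, config.lr, config.lr_decay,
                                   config.lr_decay_every)
        alpha = objective.alpha_schedule(epoch, config.max_epochs,
                                         config.alpha_start, config.alpha_end,
                                         config.ramp_epochs)
        perm = shuffle_rng.permutation(n)
        sums = {k: 0.0 for k in ("l_eli", "l_pna", "l_spa", "l_lem", "l_gap",
                                 "total_j")}
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, tb = X[idx], t[idx]
            if config.augment and dataset is not None:
                imgs = [augment(dataset[i], params=sample_augment_params(aug_rng))
                        for i in idx]
                xb = np.stack([im.pixels for im in imgs])[:, None]
            _, S = net.forward(xb)
            y_gap, dS_gap = _gap_grad(S, tb)
            dS = np.empty_like(S)
            theta_sq = net.weight_sq_norm()
            for k, (s, tk, dg) in enumerate(zip(S, tb, dS_gap)):
                l_gap = objective.classification_loss(y_gap[k], tk)
                if lem:
                    E = detect_extrema(s)
                    agg = aggregate(s, E)
                    l_eli = objective.elimination_loss(s, E)
                    l_pna = objective.penalty_loss(s, config.tau)
                    l_spa = l_eli + config.gamma * l_pna
                    l_lem = objective.classification_loss(agg.y_lem, tk)
                    d_lem = (agg.y_lem - tk) / agg.n_extrema * (
                        E.smax * (s > 0) + E.smin * (s < 0))
                    d_spa = objective.sparse_grad(s, E, config.gamma, config.tau)
                    dS[k] = alpha * (config.mu * d_spa + d_lem) + (1.0 - alpha) * dg
                else:
                    l_eli = l_pna = l_spa = l_lem = 0.0
                    dS[k] = dg
                total = objective.total_objective(l_spa, l_lem, l_gap, theta_sq,
                                                 alpha, config.mu, config.lam)
                for key, val in (("l_eli", l_eli), ("l_pna", l_pna),
                                 ("l_spa", l_spa), ("l_lem", l_lem),
                                 ("l_gap", l_gap), ("total_j", total)):
                    sums[key] += val
            if config.batch_reduction == "mean":
                dS /= len(idx)
            net.zero_grads()
            net.backward_from_score(dS)
            net.add_weight_decay(config.lam)
            if config.momentum > 0.0:
                if velocity is None:
                    velocity = [np.zeros_like(v) for _, _, _, v, _ in net.parameters()]
                for vel, (_, _, _, value, grad) in zip(velocity, net.parameters()):
                    vel *= config.momentum
                    vel += grad
                    value -= lr * vel
            else:
                net.sgd_step(lr)
        row = {k: v / n for k, v in sums.items()}
        if not np.isfinite(row["total_j"]):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: {row}; aborting"
            )
        row.update(epoch=epoch, alpha=alpha, lr=lr)
        state.history.append(row)
        state.epoch = epoch + 1
        state.lr = lr
        state.alpha = alpha
    return state


def train(dataset: list[LabeledImage], config: LemConfig
          ) -> tuple[nn.Network, TrainState]:
    """Train the blended GAP/LEM objective on a labeled dataset."""
    if not dataset:
        raise DataError("empty dataset")
    labels = {im.label for im in dataset}
    if labels != {0, 1}:
        raise DataError(f"need both classes present, got labels {sorted(labels)}")
    X, t = _dataset_arrays(dataset)
    if X.shape[-1] != config.image_size or X.shape[-2] != config.image_size:
        raise DataError(
            f"images are {X.shape[-2]}x{X.shape[-1]} but config.image_size is "
            f"{config.image_size}"
        )
    net = build_tiny_backbone(config, np.random.default_rng(config.seed))
    state = _run_epochs(net, X, t, config, lem=True, dataset=dataset)
    return net, state


def train_gap_baseline(dataset: list[LabeledImage], config: LemConfig
                       ) -> tuple[nn.Network, TrainState]:
    """Plain GAP cross-entropy training (no extremum machinery at all).

    Uses the same initialisation, shuffling and update rule as :func:`train`,
    so a LEM run with alpha fixed at zero reproduces this trajectory exactly.
    """
    if not dataset:
        raise DataError("empty dataset")
    X, t = _dataset_arrays(dataset)
    net = build_tiny_backbone(config, np.random.default_rng(config.seed))
    state = _run_epochs(net, X, t, config, lem=False, dataset=dataset)
    return net, state


def predict(net: nn.Network, image: np.ndarray, mode: str = "lem"
            ) -> tuple[float, np.ndarray, ExtremumMaps]:
    """Probability for one image plus the score map and extremum maps."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    _, S = net.forward(x)
    S0 = S[0]
    E = detect_extrema(S0)
    if mode == "gap":
        prob = float(sigmoid(S0.mean()))
    elif mode == "lem":
        prob = aggregate(S0, E).y_lem
    else:
        raise ValueError(f"mode must be 'gap' or 'lem', got {mode!r}")
    return prob, S0, E
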