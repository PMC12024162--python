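"""Hyperparameter record for local extremum mapping (LEM).

All tunables of the method live in one validated dataclass so that a run is
fully described by a single config file plus a seed.  The defaults follow the
method's published operating point: penalty threshold ``tau = 3``, L2 weight
``lam = 1e-5``, initial learning rate ``1e-4`` decayed by 0.98 every 8 epochs,
batch size 32, blending weight ``alpha`` ramped from 0.1 to 1.0, decision
threshold 0.5.  ``gamma`` (penalty factor inside the sparse loss) and ``mu``
(sparse-loss weight in the total objective) have no published value; the
package defaults are gamma=0.1 and mu=0.05, chosen so the sparse-loss
gradient stays below the classification gradients at typical score scales,
and config files must state both explicitly.  The update rule is SGD with
heavy-ball momentum (default 0.9): from-scratch training of the small
bundled backbone at the published learning rate makes negligible progress
without it; set ``momentum=0`` for the plain vanilla update.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = ["LemConfig"]


@dataclass
class LemConfig:
    # sparse loss
    tau: float = 3.0
    gamma: float = 0.1
    mu: float = 0.05
    # objective
    lam: float = 1e-5
    alpha_start: float = 0.1
    alpha_end: float = 1.0
    #: epochs over which alpha ramps linearly from alpha_start to alpha_end;
    #: None means half of max_epochs.
    alpha_ramp_epochs: int | None = None
    # optimisation
    lr: float = 1e-4
    lr_decay: float = 0.98
    lr_decay_every: int = 8
    batch_size: int = 32
    max_epochs: int = 30
    momentum: float = 0.9
    #: "sum" adds per-sample objectives within a mini-batch (the default);
    #: "mean" averages them.
    batch_reduction: str = "sum"
    # decision / localization
    decision_threshold: float = 0.5
    binarize_fraction: float = 0.2
    # backbone
    channels: tuple[int, ...] = (8, 16, 32)
    image_size: int = 64
    #: fixed positive input rescaling applied before the first convolution
    #: (images in [0, 1] have pixel std far below one)
    input_scale: float = 8.0
    # data
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.gamma < 0 or self.mu < 0 or self.lam < 0:
            raise ValueError("gamma, mu and lam must be >= 0")
        if not (0.0 <= self.alpha_start <= self.alpha_end <= 1.0):
            raise ValueError("need 0 <= alpha_start <= alpha_end <= 1")
        if self.lr <= 0 or self.lr_decay <= 0:
            raise ValueError("learning rate and decay must be positive")
        if self.lr_decay_every < 1:
            raise ValueError("lr_decay_every must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("batch_size >= 1 and max_epochs >= 0 required")
        if self.batch_reduction not in ("sum", "mean"):
            raise ValueError("batch_reduction must be 'sum' or 'mean'")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must lie in (0, 1)")
        if not (0.0 < self.binarize_fraction <= 1.0):
            raise ValueError("binarize_fraction must lie in (0, 1]")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) < 1 or any(c < 1 for c in self.channels):
            raise ValueError("channels must be a nonempty tuple of positive ints")

    @property
    def ramp_epochs(self) -> int:
        if self.alpha_ramp_epochs is not None:
            return max(1, self.alpha_ramp_epochs)
        return max(1, self.max_epochs // 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict, *, require_explicit: bool = True) -> "LemConfig":
        """Build a config from a mapping.

        With ``require_explicit`` (the default for files), ``gamma`` and
        ``mu`` must be present: they have no published value, so silent
        defaults in a run config would hide an assumption.
        """
        if require_explicit:
            missing = [k for k in ("gamma", "mu") if k not in d]
            if missing:
                raise ValueError(
                    f"config must state {missing} explicitly (no published value)"
                )
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "LemConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
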