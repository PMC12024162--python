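"""Classification and localization metrics.

AUC is computed as the Mann-Whitney rank statistic with midrank tie handling
(equivalent to trapezoidal ROC integration, but directly testable against
exhaustive pair counting).  Accuracy is measured at the configured decision
threshold.  DSC and recall are unweighted means over the images that carry a
ground-truth mask (macro averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import nn
from .config import LemConfig
from .localization import binarize_and_score, localize
from .synthetic import LabeledImage
from .training import predict

__all__ = ["MetricReport", "compute_auc", "evaluate"]


@dataclass
class MetricReport:
    acc: float
    auc: float
    mean_dsc: float | None
    mean_recall: float | None
    n: int
    per_image: pd.DataFrame

    def to_dict(self) -> dict:
        return {"acc": self.acc, "auc": self.auc, "mean_dsc": self.mean_dsc,
                "mean_recall": self.mean_recall, "n": self.n}


def compute_auc(scores, labels) -> float:
    """Midrank Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(net: nn.Network, dataset: list[LabeledImage],
             config: LemConfig | None = None,
             with_localization: bool = True) -> MetricReport:
    """Score a dataset: LEM probabilities, accuracy, AUC, and (for images
    with masks) per-image DSC/recall from the localization pipeline."""
    config = config or LemConfig()
    rows = []
    for im in dataset:
        prob, _, _ = predict(net, im.pixels, mode="lem")
        row = {"id": im.id, "label": im.label, "y_lem": prob,
               "pred": int(prob > config.decision_threshold),
               "dsc": np.nan, "recall": np.nan, "n_extrema_used": 0,
               "mass_delivered": np.nan}
        if with_localization and im.mask is not None:
            imap, _ = localize(net, im.pixels, config)
            res = binarize_and_score(imap, im.mask, config.binarize_fraction)
            row.update(dsc=res.dsc, recall=res.recall,
                       n_extrema_used=len(imap.source_extrema),
                       mass_delivered=imap.mass_delivered)
        rows.append(row)
    per_image = pd.DataFrame(rows)
    acc = float((per_image["pred"] == per_image["label"]).mean())
    auc = compute_auc(per_image["y_lem"], per_image["label"])
    has_masks = per_image["dsc"].notna()
    mean_dsc = float(per_image.loc[has_masks, "dsc"].mean()) if has_masks.any() else None
    mean_recall = (float(per_image.loc[has_masks, "recall"].mean())
                   if has_masks.any() else None)
    return MetricReport(acc=acc, auc=auc, mean_dsc=mean_dsc,
                        mean_recall=mean_recall, n=len(dataset),
                        per_image=per_image)
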