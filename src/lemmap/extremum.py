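"""Local-extremum detection on score maps and aggregation to a probability.

A position is a local maximum (minimum) when its score equals the maximum
(minimum) of its neighbourhood, where the neighbourhood *includes the position
itself* and is clipped at the image boundary: a 2x2 block at corners, 2x3 at
non-corner boundary cells, 3x3 in the interior (4/6/9 cells).  Comparisons are
non-strict, so every cell of a tied plateau is flagged, and a cell may be
flagged as both a maximum and a minimum (e.g. on a constant map).

Aggregation keeps only correctly signed evidence: positive scores at maxima
count toward malignancy, negative scores at minima toward benignity, and the
malignancy probability is the sigmoid of their sum divided by the total number
of flags (a cell flagged both ways counts twice in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter, minimum_filter

from .scoremap import sigmoid

__all__ = ["ExtremumMaps", "Aggregates", "detect_extrema", "aggregate"]


@dataclass
class ExtremumMaps:
    """Binary maps flagging local maxima / minima of a score map."""

    smax: np.ndarray  # bool (H, W)
    smin: np.ndarray  # bool (H, W)

    @property
    def n_extrema(self) -> int:
        return int(self.smax.sum() + self.smin.sum())

    def to_frame(self, S: np.ndarray) -> pd.DataFrame:
        """Tabulate flagged positions as (row, col, kind, score)."""
        rows = []
        for kind, m in (("max", self.smax), ("min", self.smin)):
            for r, c in zip(*np.nonzero(m)):
                rows.append((int(r), int(c), kind, float(S[r, c])))
        return pd.DataFrame(rows, columns=["row", "col", "kind", "score"])


@dataclass
class Aggregates:
    """Extremum-only evidence sums and the resulting malignancy probability."""

    a_m: float  # >= 0, positive scores at maxima
    a_b: float  # <= 0, negative scores at minima
    n_extrema: int
    y_lem: float


def detect_extrema(S: np.ndarray) -> ExtremumMaps:
    """Flag every local maximum and minimum under the clipped neighbourhood rule."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError(f"score map must be 2-D with both sides >= 2, got {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("score map contains non-finite values")
    # 'nearest' edge handling replicates border values, which makes the 3x3
    # filter equal to the max/min over the boundary-clipped window.
    smax = S >= maximum_filter(S, size=3, mode="nearest")
    smin = S <= minimum_filter(S, size=3, mode="nearest")
    return ExtremumMaps(smax=smax, smin=smin)


def aggregate(S: np.ndarray, E: ExtremumMaps) -> Aggregates:
    S = np.asarray(S, dtype=float)
    if S.shape != E.smax.shape or S.shape != E.smin.shape:
        raise ValueError("score map and extremum maps have mismatched shapes")
    n = E.n_extrema
    if n < 1:  # unreachable for finite maps: global extrema always qualify
        raise RuntimeError("no extrema flagged; cannot aggregate")
    a_m = float(np.sum(E.smax * np.maximum(S, 0.0)))
    a_b = float(np.sum(E.smin * np.minimum(S, 0.0)))
    y = float(sigmoid((a_m + a_b) / n))
    return Aggregates(a_m=a_m, a_b=a_b, n_extrema=n, y_lem=y)
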