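"""Information-gain feature ranking and band selection.

Each real-valued feature is discretized (equal-width bins) and scored by its
information gain against the fold labels; features whose score falls in the
closed band [band_fraction * max_IG, max_IG] are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LabeledDataset

_EPS = 1e-12


def entropy(labels) -> float:
    """Shannon entropy of a discrete sequence, in bits (0*log0 = 0)."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    _, counts = np.unique(arr, return_counts=True)
    p = counts / arr.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(x, y) -> float:
    """H(X | Y) in bits from empirical joint frequencies."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("conditional entropy of empty sequences is undefined")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    total = 0.0
    for value in np.unique(y):
        sel = y == value
        total += sel.mean() * entropy(x[sel])
    return float(total)


def information_gain(x, y) -> float:
    """IG = H(X) - H(X|Y); tiny negative round-off is clipped to 0."""
    ig = entropy(x) - conditional_entropy(x, y)
    if -_EPS < ig < 0.0:
        return 0.0
    return ig


def discretize(values, n_bins: int) -> np.ndarray:
    """Equal-width binning over [min, max] with a right-closed top bin.

    Bins are (edge, edge] intervals except the lowest, which is closed on
    both sides.  A constant feature lands entirely in bin 0.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot discretize non-finite values")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return np.zeros(values.shape, dtype=int)
    edges = np.linspace(vmin, vmax, n_bins + 1)
    bins = np.searchsorted(edges, values, side="left") - 1
    return np.clip(bins, 0, n_bins - 1)


@dataclass
class IGRanking:
    """Per-feature information-gain scores and the selected band mask."""

    ig_scores: np.ndarray
    selected_mask: np.ndarray
    band: tuple[float, float]
    n_bins: int
    method: str = "equal_width"

    def __post_init__(self) -> None:
        self.ig_scores = np.asarray(self.ig_scores, dtype=float)
        self.selected_mask = np.asarray(self.selected_mask, dtype=bool)
        if self.ig_scores.shape != self.selected_mask.shape:
            raise ValueError("ig_scores and selected_mask must align")
        if np.any(self.ig_scores < -_EPS):
            raise ValueError("negative information gain")
        if not self.selected_mask.any():
            raise ValueError("selection must keep at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())

    def to_frame(self, feature_ids: list[str]) -> pd.DataFrame:
        """Ranking table sorted by descending IG."""
        df = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "ig_bits": self.ig_scores,
                "selected": self.selected_mask,
            }
        )
        return df.sort_values("ig_bits", ascending=False, kind="stable").reset_index(
            drop=True
        )


def rank_and_select(
    data: LabeledDataset,
    n_bins: int = 10,
    band_fraction: float = 0.5,
) -> IGRanking:
    """Score every feature by IG against the labels and keep the top band.

    The band is the closed interval [band_fraction * max_IG, max_IG], so
    boundary ties are included and the maximum always qualifies.
    """
    if not 0.0 <= band_fraction <= 1.0:
        raise ValueError(f"band_fraction must be in [0, 1], got {band_fraction}")
    labels = np.asarray(data.labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 distinct classes for IG selection")
    scores = np.empty(data.n_features)
    for j in range(data.n_features):
        binned = discretize(data.matrix[:, j], n_bins)
        scores[j] = information_gain(binned, labels)
    max_ig = float(scores.max())
    lower = band_fraction * max_ig
    mask = scores >= lower
    return IGRanking(
        ig_scores=scores,
        selected_mask=mask,
        band=(lower, max_ig),
        n_bins=n_bins,
    )
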