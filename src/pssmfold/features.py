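"""Fixed-length feature vectors from variable-length PSSM profiles.

Two families are extracted and fused:

* **ACC** — lagged auto-covariance (AC, same column with itself) and
  cross-covariance (CC, ordered pairs of distinct columns), mean-centered
  per column over the whole sequence.  20*LG AC values plus 380*LG CC
  values; 1600 total at the default lag bound LG=4.
* **SD** — separated-dimer sums: for every ordered column pair (m, n) the
  sum over positions of the *uncentered* product of scores k residues
  apart.  400 values per separation; k=4 by default.

Feature ordering is fixed and encoded in the feature ids (AC and CC are
lag-major; SD is m-major), so selections are portable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset
from .pssm_io import PSSMProfile, normalize_profile

DEFAULT_LG = 4
DEFAULT_K = 4


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction parameters: lag bound, dimer separation, normalization."""

    lg: int = DEFAULT_LG
    k: int = DEFAULT_K
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.lg < 1:
            raise ValueError(f"LG must be >= 1, got {self.lg}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def min_length(self) -> int:
        """Profiles must be strictly longer than the largest offset used."""
        return max(self.lg, self.k) + 1

    @property
    def n_features(self) -> int:
        return 400 * self.lg + 400


@dataclass
class FeatureVector:
    """Real vector with parallel stable feature identifiers."""

    values: np.ndarray
    feature_ids: list[str]
    source_protein: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be one-dimensional")
        if len(self.values) != len(self.feature_ids):
            raise ValueError("values and feature_ids must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite feature values for {self.source_protein!r}"
            )

    def __len__(self) -> int:
        return len(self.values)


def _check_length(p: PSSMProfile, offset: int, what: str) -> None:
    if p.length <= offset:
        raise ValueError(
            f"profile {p.protein_id!r} has length {p.length} <= {what}={offset}; "
            f"sequence must be strictly longer than the largest offset"
        )


def _lagged_covariances(p: PSSMProfile, lg: int) -> list[np.ndarray]:
    """Per lag 1..lg, the 20x20 matrix M[a, b] = cov-style sum of column a
    against column b shifted by the lag, divided by (L - lag)."""
    x = p.scores
    centered = x - x.mean(axis=0)
    out = []
    for lag in range(1, lg + 1):
        m = centered[:-lag].T @ centered[lag:] / (p.length - lag)
        out.append(m)
    return out


def ac_features(p: PSSMProfile, lg: int = DEFAULT_LG) -> FeatureVector:
    """Auto-covariance of each score column with itself at lags 1..lg.

    Lag-major ordering: all 20 columns at lag 1, then lag 2, ...  Length
    20*lg.
    """
    _check_length(p, lg, "LG")
    mats = _lagged_covariances(p, lg)
    values = np.concatenate([np.diagonal(m) for m in mats])
    ids = [
        f"AC:i={i}:lg={lag}"
        for lag in range(1, lg + 1)
        for i in range(1, 21)
    ]
    return FeatureVector(values, ids, p.protein_id)


def cc_features(p: PSSMProfile, lg: int = DEFAULT_LG) -> FeatureVector:
    """Cross-covariance of every ordered pair of distinct columns at lags
    1..lg.

    Both (i1, i2) and (i2, i1) are emitted — the transform is asymmetric.
    Lag-major, then (i1, i2) lexicographic.  Length 380*lg.
    """
    _check_length(p, lg, "LG")
    mats = _lagged_covariances(p, lg)
    off_diag = ~np.eye(20, dtype=bool)
    values = np.concatenate([m[off_diag] for m in mats])
    ids = [
        f"CC:i1={i1}:i2={i2}:lg={lag}"
        for lag in range(1, lg + 1)
        for i1 in range(1, 21)
        for i2 in range(1, 21)
        if i1 != i2
    ]
    return FeatureVector(values, ids, p.protein_id)


def acc_features(p: PSSMProfile, lg: int = DEFAULT_LG) -> FeatureVector:
    """AC block followed by CC block: 400*lg values (1600 at lg=4)."""
    ac = ac_features(p, lg)
    cc = cc_features(p, lg)
    return FeatureVector(
        np.concatenate([ac.values, cc.values]),
        ac.feature_ids + cc.feature_ids,
        p.protein_id,
    )


def sd_features(p: PSSMProfile, k: int = DEFAULT_K) -> FeatureVector:
    """Separated-dimer sums at one separation k.

    F[m, n] = sum over positions j = 1..L-k of score(j, m) * score(j+k, n);
    uncentered, so unlike ACC these respond to column-mean differences.
    m-major ordering: F(1,1), F(1,2), ..., F(20,20).  Length 400.
    """
    _check_length(p, k, "k")
    x = p.scores
    f = x[:-k].T @ x[k:]
    ids = [
        f"SD:m={m}:n={n}:k={k}"
        for m in range(1, 21)
        for n in range(1, 21)
    ]
    return FeatureVector(f.reshape(-1), ids, p.protein_id)


def fuse(acc: FeatureVector, sd: FeatureVector) -> FeatureVector:
    """Concatenate the ACC block and the SD block for one protein."""
    if acc.source_protein != sd.source_protein:
        raise ValueError(
            f"cannot fuse vectors from different proteins: "
            f"{acc.source_protein!r} vs {sd.source_protein!r}"
        )
    return FeatureVector(
        np.concatenate([acc.values, sd.values]),
        acc.feature_ids + sd.feature_ids,
        acc.source_protein,
    )


def extract_fused(p: PSSMProfile, cfg: FeatureConfig) -> FeatureVector:
    """Full per-protein feature vector under ``cfg`` (normalization applied)."""
    q = normalize_profile(p, cfg.normalization)
    return fuse(acc_features(q, cfg.lg), sd_features(q, cfg.k))


def build_feature_matrix(
    profiles: list[PSSMProfile],
    labels: list[str],
    cfg: FeatureConfig | None = None,
) -> LabeledDataset:
    """Extract fused vectors for every profile into a labeled N x D matrix.

    Fails fast, listing every profile shorter than the minimum length rather
    than silently dropping or zero-padding it.
    """
    cfg = cfg or FeatureConfig()
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must have equal length")
    too_short = [
        f"{p.protein_id} (L={p.length})"
        for p in profiles
        if p.length < cfg.min_length
    ]
    if too_short:
        raise ValueError(
            f"profiles too short for LG={cfg.lg}, k={cfg.k} "
            f"(need L >= {cfg.min_length}): {too_short}"
        )
    vectors = [extract_fused(p, cfg) for p in profiles]
    feature_ids = vectors[0].feature_ids
    return LabeledDataset(
        matrix=np.vstack([v.values for v in vectors]),
        protein_ids=[p.protein_id for p in profiles],
        labels=list(labels),
        feature_ids=feature_ids,
    )
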