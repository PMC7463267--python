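"""Labeled feature-matrix carrier shared by the selection and classifier stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_ID_COL = "protein_id"
_LABEL_COL = "fold_label"


@dataclass
class LabeledDataset:
    """N x D feature matrix with aligned protein ids, fold labels and feature ids."""

    matrix: np.ndarray
    protein_ids: list[str]
    labels: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, d = self.matrix.shape
        if len(self.protein_ids) != n or len(self.labels) != n:
            raise ValueError("protein_ids and labels must match matrix rows")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids must match matrix columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def class_labels(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        out: list[str] = []
        for lab in self.labels:
            if lab not in out:
                out.append(lab)
        return out

    def subset_features(self, mask_or_ids) -> "LabeledDataset":
        """Restrict to a boolean column mask or an explicit feature-id list."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = list(mask_or_ids)
            pos = {fid: i for i, fid in enumerate(self.feature_ids)}
            missing = [f for f in wanted if f not in pos]
            if missing:
                raise KeyError(f"unknown feature ids: {missing[:5]}")
            idx = np.asarray([pos[f] for f in wanted], dtype=int)
        return LabeledDataset(
            matrix=self.matrix[:, idx],
            protein_ids=list(self.protein_ids),
            labels=list(self.labels),
            feature_ids=[self.feature_ids[i] for i in idx],
        )

    def subset_rows(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            matrix=self.matrix[idx],
            protein_ids=[self.protein_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            feature_ids=list(self.feature_ids),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.feature_ids)
        df.insert(0, _ID_COL, self.protein_ids)
        df[_LABEL_COL] = self.labels
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        if _ID_COL not in df.columns or _LABEL_COL not in df.columns:
            raise ValueError(
                f"matrix file must have {_ID_COL!r} and {_LABEL_COL!r} columns"
            )
        feature_cols = [c for c in df.columns if c not in (_ID_COL, _LABEL_COL)]
        return cls(
            matrix=df[feature_cols].to_numpy(dtype=float),
            protein_ids=df[_ID_COL].astype(str).tolist(),
            labels=df[_LABEL_COL].astype(str).tolist(),
            feature_ids=feature_cols,
        )
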