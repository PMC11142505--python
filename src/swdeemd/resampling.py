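"""SMOTE: synthetic minority oversampling in feature space.

For each synthetic row, a minority base row is chosen round-robin, one of
its k nearest minority neighbours (Euclidean) is drawn uniformly, and the
new row is  x + u * (neighbour - x)  with a single u ~ Uniform(0,1) shared
across features (Chawla's original algorithm; an independent-u-per-feature
variant is available behind ``per_feature_u``).  Majority rows are never
created, modified or deleted; synthetic rows are flagged in provenance and
carry ``synthetic_<i>`` subject ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority/majority count after oversampling
    seed: int = 0
    per_feature_u: bool = False
    standardize_before_knn: bool = False

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must lie in (0, 1]")


@dataclass
class SmoteProvenance:
    """Parent bookkeeping for each synthetic row (in appended order)."""

    base_index: np.ndarray      # row index into the input matrix
    neighbor_index: np.ndarray  # row index into the input matrix
    u: np.ndarray               # interpolation weight(s) per synthetic row


def smote_oversample(
    matrix: FeatureMatrix,
    cfg: SmoteConfig | None = None,
    return_provenance: bool = False,
):
    """Append synthetic minority rows until
    minority count = round(target_ratio * majority count).

    Original rows are returned unchanged and first; synthetic rows follow,
    flagged via ``is_synthetic``.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SmoteConfig()
    cfg.validate()
    if matrix.n_rows == 0:
        raise ValueError("cannot oversample an empty matrix")
    counts = matrix.class_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly two classes, got {sorted(counts)}")
    minority_label = min(counts, key=lambda k: (counts[k], k))
    majority_label = next(k for k in counts if k != minority_label)
    n_min, n_maj = counts[minority_label], counts[majority_label]
    if n_min < 2:
        raise ValueError("minority class needs at least 2 rows for SMOTE")

    target = int(round(cfg.target_ratio * n_maj))
    n_new = max(0, target - n_min)
    min_idx = np.nonzero(matrix.labels == minority_label)[0]
    x_min = matrix.values[min_idx]

    k = cfg.k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds minority size - 1 ({n_min - 1}); clamping",
            stacklevel=2,
        )
        k = n_min - 1

    knn_space = x_min
    if cfg.standardize_before_knn:
        scale = x_min.std(axis=0)
        scale[scale == 0] = 1.0
        knn_space = (x_min - x_min.mean(axis=0)) / scale
    # +1 because each row's nearest neighbour is itself
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(knn_space)
    _, nbr_idx = nbrs.kneighbors(knn_space)
    nbr_idx = nbr_idx[:, 1:]  # drop self

    rng = np.random.default_rng(cfg.seed)
    new_rows = np.empty((n_new, matrix.n_columns))
    base_ids = np.empty(n_new, dtype=int)
    nbr_ids = np.empty(n_new, dtype=int)
    us = (
        np.empty((n_new, matrix.n_columns))
        if cfg.per_feature_u
        else np.empty(n_new)
    )
    for i in range(n_new):
        b = i % n_min  # round-robin base selection: exact, even coverage
        j = nbr_idx[b, rng.integers(k)]
        u = rng.random(matrix.n_columns) if cfg.per_feature_u else rng.random()
        new_rows[i] = x_min[b] + u * (x_min[j] - x_min[b])
        base_ids[i], nbr_ids[i] = min_idx[b], min_idx[j]
        us[i] = u

    out = FeatureMatrix(
        values=np.vstack([matrix.values, new_rows]),
        column_names=list(matrix.column_names),
        labels=np.concatenate(
            [matrix.labels, np.full(n_new, minority_label, dtype=matrix.labels.dtype)]
        ),
        subject_ids=np.concatenate(
            [
                matrix.subject_ids,
                np.array([f"synthetic_{i}" for i in range(n_new)], dtype=str),
            ]
        ),
        is_synthetic=np.concatenate(
            [matrix.is_synthetic, np.ones(n_new, dtype=bool)]
        ),
        degenerate=np.concatenate([matrix.degenerate, np.zeros(n_new, dtype=bool)]),
    )
    if return_provenance:
        return out, SmoteProvenance(base_ids, nbr_ids, us)
    return out
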