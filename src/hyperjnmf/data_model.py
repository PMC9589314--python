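"""Core domain types: modality matrices, diagnosis labels, cross-modality adjacency.

A *modality* is one feature table over the shared cohort (e.g. radiomic
texture features from abdominal films, or routine clinical laboratory
values). Both tables share sample ordering; features are columns. All
factorization inputs must be non-negative, and columns are l2-standardized
so that regularizers act on comparable feature scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModalityMatrix",
    "DiagnosisVector",
    "CrossAdjacency",
    "ValidationError",
    "standardize_columns",
    "build_cross_adjacency",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass
class ModalityMatrix:
    """Non-negative samples-by-features matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_features)``, all entries >= 0.
    sample_ids, feature_names
        Unique ordered identifiers for rows and columns.
    modality_tag
        Free-form label ("radiomics", "clinical", ...).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValidationError(f"need at least 2 samples and 2 features, got {n}x{p}")
        if not np.isfinite(self.values).all():
            raise ValidationError("values contain NaN or infinite entries")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(f"negative entry at ({i}, {j}); factorization inputs must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match row count")
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


@dataclass
class DiagnosisVector:
    """Per-sample surgery status: 1 = non-surgical, 2 = surgical.

    The coding is deliberate — used as a diagonal sample weight it up-weights
    the reconstruction of surgical patients, steering the factors toward
    features that separate the two diagnostic groups.
    """

    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a vector")
        if not np.isin(self.labels, (1, 2)).all():
            raise ValidationError("labels must contain only 1 (non-surgical) and 2 (surgical)")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != self.labels.size:
                raise ValidationError("sample_ids length does not match labels")

    def __len__(self) -> int:
        return self.labels.size

    def check_against(self, x: ModalityMatrix) -> None:
        if len(self) != x.n_samples:
            raise ValidationError(f"{len(self)} labels for {x.n_samples} samples")
        if self.sample_ids is not None and self.sample_ids != x.sample_ids:
            raise ValidationError("label sample ordering differs from matrix sample ordering")


@dataclass
class CrossAdjacency:
    """Feature-level adjacency linking the two modalities.

    ``weights[j, k]`` couples feature *j* of modality 1 with feature *k* of
    modality 2; entries lie in [0, 1]. Used as the network-regularization
    reward term in the factorization.
    """

    weights: np.ndarray
    build_threshold: float = 0.5
    binary_flag: bool = True
    feature_names_1: list[str] = field(default_factory=list)
    feature_names_2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValidationError("adjacency weights must be a matrix")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValidationError("adjacency entries must lie in [0, 1]")
        if not 0.0 <= self.build_threshold <= 1.0:
            raise ValidationError("threshold must lie in [0, 1]")


def standardize_columns(
    raw: np.ndarray | pd.DataFrame | ModalityMatrix,
    *,
    shift_to_nonnegative: bool = False,
    sample_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
    modality_tag: str = "",
) -> ModalityMatrix:
    """l2-standardize each feature column to unit Euclidean norm.

    Column-wise scaling keeps features on comparable scales, which is what
    the graph and sparsity regularizers need; all-zero columns are left at
    zero and reported via a warning. With ``shift_to_nonnegative`` a column
    containing negative values is first shifted by its minimum.
    """
    if isinstance(raw, ModalityMatrix):
        sample_ids = sample_ids or raw.sample_ids
        feature_names = feature_names or raw.feature_names
        modality_tag = modality_tag or raw.modality_tag
        raw = raw.values
    elif isinstance(raw, pd.DataFrame):
        sample_ids = sample_ids or [str(s) for s in raw.index]
        feature_names = feature_names or [str(c) for c in raw.columns]
        raw = raw.to_numpy(dtype=float)

    x = np.array(raw, dtype=float)
    if x.ndim != 2:
        raise ValidationError("input must be a 2-D matrix")
    if np.isnan(x).any():
        raise ValidationError("input contains NaN")
    if (x < 0).any():
        if not shift_to_nonnegative:
            i, j = np.argwhere(x < 0)[0]
            raise ValidationError(
                f"negative entry at row {i}, column {j}; pass shift_to_nonnegative=True to shift columns"
            )
        mins = x.min(axis=0)
        x = x - np.minimum(mins, 0.0)[None, :]

    norms = np.linalg.norm(x, axis=0)
    zero_cols = norms == 0.0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero column(s) left unscaled: "
            f"indices {np.flatnonzero(zero_cols).tolist()}",
            UserWarning,
            stacklevel=2,
        )
    scale = np.where(zero_cols, 1.0, norms)
    x = x / scale[None, :]

    n, p = x.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    return ModalityMatrix(x, sample_ids, feature_names, modality_tag)


def _column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of `a` and every column of `b`.

    Constant columns yield correlation 0 by convention (keeps the adjacency
    well-defined and non-negative instead of NaN).
    """
    const_a = np.ptp(a, axis=0) == 0
    const_b = np.ptp(b, axis=0) == 0
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.linalg.norm(a, axis=0)
    sb = np.linalg.norm(b, axis=0)
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / denom
    r[~np.isfinite(r)] = 0.0
    r[const_a, :] = 0.0
    r[:, const_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def build_cross_adjacency(
    x1: ModalityMatrix,
    x2: ModalityMatrix,
    threshold: float = 0.5,
    binary: bool = True,
) -> CrossAdjacency:
    """Link cross-modality feature pairs whose |Pearson r| reaches `threshold`.

    Entry (j, k) is |corr(x1 feature j, x2 feature k)| when that exceeds or
    equals the threshold, else 0; with ``binary`` the surviving entries are
    set to 1. Constant feature columns contribute zero rows/columns.
    """
    if x1.n_samples != x2.n_samples:
        raise ValidationError(
            f"modalities disagree on sample count: {x1.n_samples} vs {x2.n_samples}"
        )
    if x1.sample_ids != x2.sample_ids:
        raise ValidationError("modalities must share sample ordering")
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")

    r = np.abs(_column_correlations(x1.values, x2.values))
    a = np.where(r >= threshold, r, 0.0)
    if binary:
        a = (a > 0).astype(float)
    return CrossAdjacency(a, threshold, binary, list(x1.feature_names), list(x2.feature_names))
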