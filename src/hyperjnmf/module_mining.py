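"""Coexpression-module extraction from the fitted coefficient matrices.

Each factorization dimension m defines a module: column m of W plus the
features whose coefficient in row m of H_i stands out. Membership is
decided per row by z-score — z_ij = (h_ij - mean_i) / sd_i with the
population standard deviation — keeping feature j when z_ij > T. Modules
are then ranked by how well their rank-1 reconstruction W[:, m] H_i[m, members]
correlates (Pearson, on flattened entries) with the member submatrix of the
original data, averaged over the two modalities; the top-ranked module is
the one carried into downstream correlation and classification analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ModalityMatrix, ValidationError
from .factorization import FactorizationResult

__all__ = ["ModuleSet", "zscore_membership", "rank_modules", "module_heatmap_table"]


@dataclass
class ModuleSet:
    members1: list[np.ndarray]  # per module: member feature indices in modality 1
    members2: list[np.ndarray]
    scores: pd.DataFrame  # columns r1, r2, mean; one row per module
    z_threshold: float
    best_module: int  # argmax of mean score (NaN-aware)

    @property
    def n_modules(self) -> int:
        return len(self.members1)


def zscore_membership(h: np.ndarray, T: float = 1.0) -> list[np.ndarray]:
    """Member indices per module row: features with (h_ij - u_i)/sigma_i > T.

    sigma_i is the population (divide-by-p) standard deviation. Constant
    rows have no distinguishable features and yield empty sets with a
    warning. The rule is one-sided by construction: only coefficients
    above the row average can mark membership.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValidationError("coefficient matrix must be 2-D")
    if not np.isfinite(T):
        raise ValidationError("threshold T must be finite")
    means = h.mean(axis=1, keepdims=True)
    sds = h.std(axis=1, keepdims=True)  # population sd
    members: list[np.ndarray] = []
    degenerate = []
    for i in range(h.shape[0]):
        if sds[i, 0] == 0.0:
            degenerate.append(i)
            members.append(np.array([], dtype=int))
            continue
        z = (h[i] - means[i, 0]) / sds[i, 0]
        members.append(np.flatnonzero(z > T))
    if degenerate:
        warnings.warn(
            f"constant coefficient row(s) {degenerate}: no members selectable",
            UserWarning,
            stacklevel=2,
        )
    return members


def _flat_pearson(x_sub: np.ndarray, recon_sub: np.ndarray) -> float:
    """Pearson r between flattened member submatrix and its rank-1 reconstruction."""
    a, b = x_sub.ravel(), recon_sub.ravel()
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def rank_modules(
    x1: ModalityMatrix | np.ndarray,
    x2: ModalityMatrix | np.ndarray,
    result: FactorizationResult,
    members1: list[np.ndarray] | None = None,
    members2: list[np.ndarray] | None = None,
    T: float = 1.0,
) -> ModuleSet:
    """Score every module by member-submatrix reconstruction correlation.

    For module m and modality i the member columns of X_i are compared with
    the outer product W[:, m] * H_i[m, members]; r_im is the Pearson
    correlation of the flattened entries and the module score is the mean of
    r_1m and r_2m. A module empty on one side is scored on the other side
    only (flagged by the NaN in that column); modules empty on both sides
    are excluded from the ranking with a warning.
    """
    X1 = x1.values if isinstance(x1, ModalityMatrix) else np.asarray(x1, dtype=float)
    X2 = x2.values if isinstance(x2, ModalityMatrix) else np.asarray(x2, dtype=float)
    if members1 is None:
        members1 = zscore_membership(result.H1, T)
    if members2 is None:
        members2 = zscore_membership(result.H2, T)
    K = result.W.shape[1]
    if len(members1) != K or len(members2) != K:
        raise ValidationError("need one member set per module and modality")

    r1 = np.full(K, np.nan)
    r2 = np.full(K, np.nan)
    for m in range(K):
        idx1, idx2 = members1[m], members2[m]
        if idx1.size:
            recon = np.outer(result.W[:, m], result.H1[m, idx1])
            r1[m] = _flat_pearson(X1[:, idx1], recon)
        if idx2.size:
            recon = np.outer(result.W[:, m], result.H2[m, idx2])
            r2[m] = _flat_pearson(X2[:, idx2], recon)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(np.column_stack([r1, r2]), axis=1)
    scores = pd.DataFrame({"r1": r1, "r2": r2, "mean": mean})
    scores.index.name = "module"

    if np.isnan(mean).all():
        raise ValidationError("every module is empty on both sides; lower T")
    empty_both = np.flatnonzero(np.isnan(mean))
    if empty_both.size:
        warnings.warn(
            f"module(s) {empty_both.tolist()} empty on both sides; excluded from ranking",
            UserWarning,
            stacklevel=2,
        )
    best = int(np.nanargmax(mean))
    return ModuleSet(list(members1), list(members2), scores, T, best)


def module_heatmap_table(
    x1: ModalityMatrix,
    x2: ModalityMatrix,
    members1: np.ndarray,
    members2: np.ndarray,
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-modality correlation table of one module's members, plus top pairs.

    Returns the full member-by-member Pearson table (rows = modality-1
    members, columns = modality-2 members) and the ``top_n`` pairs ranked by
    |r| (all pairs if fewer). Ties in |r| resolve by (row, column) order.
    """
    from .data_model import _column_correlations

    idx1 = np.asarray(members1, dtype=int)
    idx2 = np.asarray(members2, dtype=int)
    if idx1.size == 0 or idx2.size == 0:
        raise ValidationError("both member sets must be non-empty for the correlation table")
    r = _column_correlations(x1.values[:, idx1], x2.values[:, idx2])
    names1 = [x1.feature_names[j] for j in idx1]
    names2 = [x2.feature_names[j] for j in idx2]
    table = pd.DataFrame(r, index=names1, columns=names2)

    pairs = [
        (names1[i], names2[j], r[i, j], abs(r[i, j]))
        for i in range(idx1.size)
        for j in range(idx2.size)
    ]
    top = (
        pd.DataFrame(pairs, columns=["feature_1", "feature_2", "r", "abs_r"])
        .sort_values("abs_r", ascending=False, kind="stable")
        .head(top_n)
        .reset_index(drop=True)
    )
    return table, top
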