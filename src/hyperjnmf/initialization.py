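"""SVD-based non-negative initialization of the shared basis and coefficients.

Multiplicative updates never revive an exactly-zero entry, so the starting
point matters twice over: it sets the basin of attraction and it must be
strictly positive to avoid zero-locking. The default is NNDSVDa
(non-negative double SVD with mean-fill) applied to the column-concatenated
matrix [X1 | X2], so both modalities shape the shared basis W from the
start; the right factors split back into the per-modality coefficient
blocks. A seeded uniform-random strategy is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .data_model import ModalityMatrix, ValidationError

__all__ = ["InitBundle", "svd_init", "random_init"]


@dataclass
class InitBundle:
    W0: np.ndarray  # (n, K), strictly positive
    H10: np.ndarray  # (K, p1)
    H20: np.ndarray  # (K, p2)
    strategy: Literal["svd", "random"] = "svd"


def _as_values(x: ModalityMatrix | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, ModalityMatrix) else np.asarray(x, dtype=float)


def _nndsvd(a: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Boutsidis-Gallopoulos non-negative double SVD of `a` at rank `k`."""
    u, s, vt = scipy.linalg.svd(a, full_matrices=False)
    n, m = a.shape
    w = np.zeros((n, k))
    h = np.zeros((k, m))

    # Leading pair: Perron-Frobenius makes it sign-consistent; take |.| to
    # absorb the SVD sign ambiguity.
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0, :] = np.sqrt(s[0]) * np.abs(vt[0, :])

    for j in range(1, k):
        uj, vj = u[:, j], vt[j, :]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        up_n, un_n = np.linalg.norm(up), np.linalg.norm(un)
        vp_n, vn_n = np.linalg.norm(vp), np.linalg.norm(vn)
        term_p, term_n = up_n * vp_n, un_n * vn_n
        if term_p >= term_n:
            sigma = s[j] * term_p
            if term_p > 0:
                w[:, j] = np.sqrt(sigma) * up / up_n
                h[j, :] = np.sqrt(sigma) * vp / vp_n
        else:
            sigma = s[j] * term_n
            w[:, j] = np.sqrt(sigma) * un / un_n
            h[j, :] = np.sqrt(sigma) * vn / vn_n
    return w, h


def svd_init(
    x1: ModalityMatrix | np.ndarray,
    x2: ModalityMatrix | np.ndarray,
    K: int,
    seed: int = 0,
) -> InitBundle:
    """NNDSVDa initialization from the concatenated matrix [X1 | X2].

    Zeros produced by the positive/negative split are replaced by a
    data-scale fill sqrt(mean([X1|X2]) / K) — the magnitude a well-scaled
    factor entry has, so the fill neither locks coordinates at zero under
    multiplicative updates nor inflates the initial reconstruction.
    Deterministic: `seed` is accepted for interface symmetry with the
    random strategy but unused.
    """
    a1, a2 = _as_values(x1), _as_values(x2)
    if a1.shape[0] != a2.shape[0]:
        raise ValidationError("modalities disagree on sample count")
    n, p1 = a1.shape
    p2 = a2.shape[1]
    if not 1 <= K <= min(n, p1 + p2):
        raise ValidationError(f"K must be in [1, {min(n, p1 + p2)}], got {K}")

    stacked = np.concatenate([a1, a2], axis=1)
    w, h = _nndsvd(stacked, K)
    fill = np.sqrt(max(stacked.mean(), 0.0) / K)
    if fill <= 0:
        fill = 1e-6
    w[w <= 0] = fill
    h[h <= 0] = fill
    return InitBundle(w, h[:, :p1].copy(), h[:, p1:].copy(), "svd")


def random_init(
    x1: ModalityMatrix | np.ndarray,
    x2: ModalityMatrix | np.ndarray,
    K: int,
    seed: int = 0,
) -> InitBundle:
    """Seeded uniform(0, s] initialization with s matched to the data scale."""
    a1, a2 = _as_values(x1), _as_values(x2)
    n, p1 = a1.shape
    p2 = a2.shape[1]
    if not 1 <= K <= min(n, p1 + p2):
        raise ValidationError(f"K must be in [1, {min(n, p1 + p2)}], got {K}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(np.concatenate([a1, a2], axis=1).mean(), 1e-12) / K)
    # uniform over (0, 2*scale]: strictly positive, mean = scale
    w0 = (1.0 - rng.random((n, K))) * 2 * scale
    h10 = (1.0 - rng.random((K, p1))) * 2 * scale
    h20 = (1.0 - rng.random((K, p2))) * 2 * scale
    return InitBundle(w0, h10, h20, "random")
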