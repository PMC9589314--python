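"""Multi-constraint joint NMF: objective, multiplicative updates, fitting.

Two non-negative matrices X1 (n x p1) and X2 (n x p2) over the same samples
are factorized as X_i ~ W H_i with one shared basis W >= 0 (n x K) and
modality-specific coefficients H_i >= 0 (K x p_i). The full objective adds
five constraint families to the joint reconstruction loss:

    F = sum_i ||X_i - W H_i||^2_Omega            (diagnosis-weighted fit)
        - alpha * tr(H1 A H2^T)                  (cross-modality adjacency reward)
        + sum_i lambda_i * tr(H_i B_i H_i^T)     (hypergraph smoothness)
        + sum_i beta_i * ||H_i H_i^T - I_K||^2_F (soft orthogonality)
        + gamma1 * ||W||_1 + gamma2 * (||H1||_1 + ||H2||_1)   (sparsity)

where ||R||^2_Omega = tr(R^T Omega R) weights samples by the squared
diagnosis code (surgical patients, coded 2, count 4:1 by default;
``sample_weighting="linear"`` gives 2:1), A is the cross-modality feature
adjacency and B_i the hypergraph Laplacians. Setting every extra weight to
zero recovers plain joint NMF.

Updates are the multiplicative KKT rules: each factor is multiplied
elementwise by the ratio of the negative to the positive part of its
gradient, which preserves non-negativity exactly and decreases F
monotonically. The Laplacian enters through its split B = B_pos - B_neg
(vertex degrees minus the non-negative smoother) so both ratio parts stay
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .data_model import CrossAdjacency, DiagnosisVector, ModalityMatrix, ValidationError
from .hypergraph import HypergraphLaplacian
from .initialization import InitBundle, random_init, svd_init

__all__ = [
    "FactorizationParams",
    "FactorizationResult",
    "NumericalError",
    "objective",
    "update_step",
    "fit",
    "jnmf_fit",
    "relative_error",
    "gradients",
]


class NumericalError(RuntimeError):
    """Raised when an update produces non-finite values."""


@dataclass
class FactorizationParams:
    """Regularization weights, rank and iteration control.

    alpha rewards adjacency-linked cross-modality coefficient pairs;
    lambda1/lambda2 weight the hypergraph smoothness of H1/H2; beta1/beta2
    the soft row-orthogonality of H1/H2; gamma1 the l1 penalty on W and
    gamma2 the shared l1 penalty on H1 and H2. K is the number of
    coexpression modules (factorization rank).
    """

    K: int
    alpha: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    max_iter: int = 500
    tol: float = 1e-6
    eps_div: float = 1e-12
    seed: int = 0
    init_strategy: Literal["svd", "random"] = "svd"
    sample_weighting: Literal["squared", "linear"] = "squared"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        for name in ("alpha", "lambda1", "lambda2", "beta1", "beta2", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative, got {v}")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.eps_div <= 0:
            raise ValidationError("eps_div must be positive")


@dataclass
class FactorizationResult:
    W: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    objective_trace: np.ndarray  # F at init and after each iteration
    component_traces: dict[str, np.ndarray]
    relative_error_trace: np.ndarray
    converged: bool
    n_iter: int
    params: FactorizationParams | None = None

    def reconstruction(self, modality: int) -> np.ndarray:
        h = self.H1 if modality == 1 else self.H2
        return self.W @ h


# ---------------------------------------------------------------------------
# helpers

def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ModalityMatrix) else np.asarray(x, dtype=float)


def _sample_weights(d, n: int, mode: str) -> np.ndarray:
    """Per-sample weights omega entering the quadratic form tr(R^T Omega R)."""
    if d is None:
        return np.ones(n)
    labels = d.labels if isinstance(d, DiagnosisVector) else np.asarray(d, dtype=float)
    if labels.size != n:
        raise ValidationError(f"{labels.size} labels for {n} samples")
    w = labels.astype(float)
    return w**2 if mode == "squared" else w


def _adjacency(a) -> np.ndarray | None:
    if a is None:
        return None
    return a.weights if isinstance(a, CrossAdjacency) else np.asarray(a, dtype=float)


def _laplacian_parts(b) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """(full, pos, neg) with full = pos - neg, both parts entrywise >= 0."""
    if b is None:
        return None
    if isinstance(b, HypergraphLaplacian):
        return b.matrix, b.positive_part, b.negative_part
    m = np.asarray(b, dtype=float)
    return m, np.maximum(m, 0.0), np.maximum(-m, 0.0)


def _check_shapes(x1, x2, w, h1, h2, K) -> None:
    n, p1 = x1.shape
    p2 = x2.shape[1]
    if x2.shape[0] != n:
        raise ValidationError("X1 and X2 disagree on sample count")
    if w.shape != (n, K) or h1.shape != (K, p1) or h2.shape != (K, p2):
        raise ValidationError(
            f"factor shapes {w.shape}/{h1.shape}/{h2.shape} inconsistent with "
            f"data {x1.shape}/{x2.shape} at K={K}"
        )


# ---------------------------------------------------------------------------
# objective

def objective(x1, x2, d, a, b1, b2, w, h1, h2, params: FactorizationParams):
    """Evaluate the full objective; returns (total, per-term components).

    Components are signed as they enter the total, so the adjacency reward
    appears as a non-positive ``cross`` entry.
    """
    X1, X2 = _values(x1), _values(x2)
    W = np.asarray(w, dtype=float)
    H1 = np.asarray(h1, dtype=float)
    H2 = np.asarray(h2, dtype=float)
    _check_shapes(X1, X2, W, H1, H2, params.K)
    omega = _sample_weights(d, X1.shape[0], params.sample_weighting)
    A = _adjacency(a)

    r1 = X1 - W @ H1
    r2 = X2 - W @ H2
    comp = {
        "recon1": float(np.sum(omega[:, None] * r1**2)),
        "recon2": float(np.sum(omega[:, None] * r2**2)),
        "cross": 0.0,
        "hyper1": 0.0,
        "hyper2": 0.0,
        "ortho1": 0.0,
        "ortho2": 0.0,
        "l1_w": 0.0,
        "l1_h": 0.0,
    }
    if params.alpha != 0.0 and A is not None:
        comp["cross"] = -params.alpha * float(np.sum((H1 @ A) * H2))
    for tag, H, b, lam, beta in (
        ("1", H1, b1, params.lambda1, params.beta1),
        ("2", H2, b2, params.lambda2, params.beta2),
    ):
        if lam != 0.0 and b is not None:
            full = _laplacian_parts(b)[0]
            comp[f"hyper{tag}"] = lam * float(np.sum((H @ full) * H))
        if beta != 0.0:
            gram = H @ H.T
            comp[f"ortho{tag}"] = beta * float(np.sum((gram - np.eye(params.K)) ** 2))
    if params.gamma1 != 0.0:
        comp["l1_w"] = params.gamma1 * float(W.sum())
    if params.gamma2 != 0.0:
        comp["l1_h"] = params.gamma2 * float(H1.sum() + H2.sum())

    total = float(sum(comp.values()))
    if not np.isfinite(total):
        raise NumericalError("non-finite objective value")
    return total, comp


def gradients(x1, x2, d, a, b1, b2, w, h1, h2, params: FactorizationParams):
    """Exact gradients of the objective w.r.t. W, H1, H2 (for diagnostics)."""
    X1, X2 = _values(x1), _values(x2)
    W, H1, H2 = (np.asarray(m, dtype=float) for m in (w, h1, h2))
    omega = _sample_weights(d, X1.shape[0], params.sample_weighting)
    A = _adjacency(a)
    oW = omega[:, None] * W
    gW = 2 * (oW @ (H1 @ H1.T + H2 @ H2.T) - omega[:, None] * (X1 @ H1.T + X2 @ H2.T))
    gW += params.gamma1
    wow = W.T @ oW

    def grad_h(H, X, b, lam, beta, cross):
        g = 2 * (wow @ H - oW.T @ X)
        if params.alpha != 0.0 and A is not None:
            g -= params.alpha * cross()
        parts = _laplacian_parts(b)
        if lam != 0.0 and parts is not None:
            g += 2 * lam * (H @ parts[0])
        if beta != 0.0:
            g += 4 * beta * ((H @ H.T) @ H - H)
        return g + params.gamma2

    gH1 = grad_h(H1, X1, b1, params.lambda1, params.beta1, lambda: H2 @ A.T)
    gH2 = grad_h(H2, X2, b2, params.lambda2, params.beta2, lambda: H1 @ A)
    return gW, gH1, gH2


# ---------------------------------------------------------------------------
# updates

def update_step(x1, x2, d, a, b1, b2, w, h1, h2, params: FactorizationParams):
    """One round of multiplicative KKT updates; returns (W, H1, H2).

    Each factor is multiplied elementwise by (negative gradient part) /
    (positive gradient part + eps_div). W is updated first and the fresh W
    feeds the H updates, Gauss-Seidel style.
    """
    X1, X2 = _values(x1), _values(x2)
    W = np.asarray(w, dtype=float)
    H1 = np.asarray(h1, dtype=float)
    H2 = np.asarray(h2, dtype=float)
    _check_shapes(X1, X2, W, H1, H2, params.K)
    omega = _sample_weights(d, X1.shape[0], params.sample_weighting)
    A = _adjacency(a)
    eps = params.eps_div

    oX1 = omega[:, None] * X1
    oX2 = omega[:, None] * X2

    num_w = 2 * (oX1 @ H1.T + oX2 @ H2.T)
    den_w = 2 * (omega[:, None] * W) @ (H1 @ H1.T + H2 @ H2.T) + params.gamma1 + eps
    W = W * (num_w / den_w)

    oW = omega[:, None] * W
    wow = W.T @ oW

    def new_h(H, oX, cross, lam, beta, b):
        num = 2 * (W.T @ oX)  # = 2 W^T Omega X
        den = 2 * (wow @ H)
        if params.alpha != 0.0 and A is not None:
            num = num + params.alpha * cross
        parts = _laplacian_parts(b)
        if lam != 0.0 and parts is not None:
            num = num + 2 * lam * (H @ parts[2])
            den = den + 2 * lam * (H @ parts[1])
        if beta != 0.0:
            num = num + 4 * beta * H
            den = den + 4 * beta * ((H @ H.T) @ H)
        den = den + params.gamma2 + eps
        return H * (num / den)

    H1n = new_h(H1, oX1, (H2 @ A.T) if A is not None else None, params.lambda1, params.beta1, b1)
    H2n = new_h(H2, oX2, (H1n @ A) if A is not None else None, params.lambda2, params.beta2, b2)

    if not (np.isfinite(W).all() and np.isfinite(H1n).all() and np.isfinite(H2n).all()):
        raise NumericalError("non-finite factor entries after update")
    return W, H1n, H2n


def relative_error(x1, x2, w, h1, h2) -> float:
    """sqrt( sum_i ||X_i - W H_i||_F^2 / sum_i ||X_i||_F^2 ).

    ``x2``/``h2`` may be None for the single-matrix case.
    """
    X1 = _values(x1)
    W, H1 = np.asarray(w, dtype=float), np.asarray(h1, dtype=float)
    num = np.sum((X1 - W @ H1) ** 2)
    den = np.sum(X1**2)
    if x2 is not None:
        X2, H2 = _values(x2), np.asarray(h2, dtype=float)
        num += np.sum((X2 - W @ H2) ** 2)
        den += np.sum(X2**2)
    if den == 0.0:
        raise ValidationError("inputs have zero norm; relative error undefined")
    return float(np.sqrt(num / den))


# ---------------------------------------------------------------------------
# drivers

def fit(
    x1,
    x2,
    d=None,
    a=None,
    b1=None,
    b2=None,
    params: FactorizationParams | None = None,
    init: InitBundle | None = None,
) -> FactorizationResult:
    """Run multiplicative updates to (approximate) convergence.

    Stops when the relative objective change drops below ``params.tol`` or
    after ``params.max_iter`` iterations (returned with converged=False, not
    an exception). Fully deterministic given the init bundle / seed.
    """
    if params is None:
        raise ValidationError("params is required")
    X1, X2 = _values(x1), _values(x2)
    if isinstance(d, DiagnosisVector) and isinstance(x1, ModalityMatrix):
        d.check_against(x1)
    if init is None:
        maker = svd_init if params.init_strategy == "svd" else random_init
        init = maker(X1, X2, params.K, params.seed)
    W, H1, H2 = init.W0.copy(), init.H10.copy(), init.H20.copy()
    _check_shapes(X1, X2, W, H1, H2, params.K)

    total, comp = objective(X1, X2, d, a, b1, b2, W, H1, H2, params)
    obj_trace = [total]
    comp_traces = {k: [v] for k, v in comp.items()}
    err_trace = [relative_error(X1, X2, W, H1, H2)]

    converged = False
    n_iter = 0
    for t in range(params.max_iter):
        try:
            W, H1, H2 = update_step(X1, X2, d, a, b1, b2, W, H1, H2, params)
            new_total, comp = objective(X1, X2, d, a, b1, b2, W, H1, H2, params)
        except NumericalError as exc:
            raise NumericalError(f"iteration {t + 1}: {exc}") from exc
        n_iter = t + 1
        obj_trace.append(new_total)
        for k, v in comp.items():
            comp_traces[k].append(v)
        err_trace.append(relative_error(X1, X2, W, H1, H2))
        if abs(new_total - total) / max(abs(total), params.eps_div) < params.tol:
            converged = True
            total = new_total
            break
        total = new_total

    return FactorizationResult(
        W=W,
        H1=H1,
        H2=H2,
        objective_trace=np.asarray(obj_trace),
        component_traces={k: np.asarray(v) for k, v in comp_traces.items()},
        relative_error_trace=np.asarray(err_trace),
        converged=converged,
        n_iter=n_iter,
        params=params,
    )


def jnmf_fit(x1, x2, params: FactorizationParams, init: InitBundle | None = None) -> FactorizationResult:
    """Plain joint NMF baseline: all constraint weights zero, uniform samples."""
    plain = replace(
        params,
        alpha=0.0,
        lambda1=0.0,
        lambda2=0.0,
        beta1=0.0,
        beta2=0.0,
        gamma1=0.0,
        gamma2=0.0,
    )
    return fit(x1, x2, None, None, None, None, plain, init=init)
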