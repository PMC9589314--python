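"""Regularization-grid search and rank (K) sweep.

The grid enumerates every combination of the five free constraint weights
over a small value set — with the lambda pair and beta pair tied this is
|set|^5 combinations (243 for a three-value set) — fits each from the same
SVD initialization at a fixed rank, and selects the converged combination
with minimal relative reconstruction error. The K sweep refits over a rank
range and reports the error-vs-K curve; raw error is minimized at the
largest K on real data, so an elbow (maximum second difference) is reported
alongside as an advisory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_model import ValidationError
from .factorization import FactorizationParams, NumericalError, fit, relative_error
from .initialization import svd_init

__all__ = [
    "ParamCombo",
    "GridResult",
    "KSweepResult",
    "enumerate_grid",
    "grid_search",
    "select_k",
]

DEFAULT_VALUE_SET = (0.001, 0.01, 0.1)


class ParamCombo(NamedTuple):
    alpha: float
    lambda1: float
    lambda2: float
    beta1: float
    beta2: float
    gamma1: float
    gamma2: float


@dataclass
class GridResult:
    table: pd.DataFrame  # one row per combination, grid order
    best_index: int
    fixed_K: int

    @property
    def best_combo(self) -> ParamCombo:
        row = self.table.loc[self.best_index]
        return ParamCombo(*(float(row[c]) for c in ParamCombo._fields))


@dataclass
class KSweepResult:
    K_values: np.ndarray
    errors: np.ndarray
    chosen_K: int
    elbow_K: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.K_values, "reconstruction_error": self.errors})


def enumerate_grid(
    value_set: Sequence[float] = DEFAULT_VALUE_SET,
    tie_lambda: bool = True,
    tie_beta: bool = True,
) -> list[ParamCombo]:
    """Cartesian product over the free constraint weights, odometer order.

    alpha varies slowest, then lambda (or lambda1, lambda2), beta, gamma1,
    and gamma2 fastest. Tying the lambda and beta pairs reduces the grid
    from |set|^7 to |set|^5 combinations.
    """
    vals = tuple(float(v) for v in value_set)
    if not vals:
        raise ValidationError("value_set must be non-empty")
    combos: list[ParamCombo] = []
    lam_axes = [vals] if tie_lambda else [vals, vals]
    beta_axes = [vals] if tie_beta else [vals, vals]

    def expand(axes):
        if not axes:
            yield ()
            return
        for v in axes[0]:
            for rest in expand(axes[1:]):
                yield (v, *rest)

    for alpha in vals:
        for lams in expand(lam_axes):
            l1, l2 = (lams[0], lams[0]) if tie_lambda else lams
            for betas in expand(beta_axes):
                b1, b2 = (betas[0], betas[0]) if tie_beta else betas
                for g1 in vals:
                    for g2 in vals:
                        combos.append(ParamCombo(alpha, l1, l2, b1, b2, g1, g2))
    return combos


def _fit_cell(x1, x2, d, a, b1, b2, combo: ParamCombo, base: FactorizationParams, init):
    params = replace(base, **combo._asdict())
    try:
        res = fit(x1, x2, d, a, b1, b2, params, init=init)
    except NumericalError:
        # diverged (e.g. adjacency reward unchecked by any penalty): the cell
        # is recorded but never wins the argmin
        return np.nan, False
    err = relative_error(x1, x2, res.W, res.H1, res.H2)
    # a cell "converges" when its objective came down in one piece — matching
    # the convention that only blown-up combinations are blanked, not runs
    # that merely exhausted the iteration budget
    ok = bool(np.isfinite(err) and res.objective_trace[-1] <= res.objective_trace[0])
    return err, ok


def grid_search(
    x1,
    x2,
    d,
    a,
    b1,
    b2,
    value_set: Sequence[float] = DEFAULT_VALUE_SET,
    fixed_K: int = 15,
    budget_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    tie_lambda: bool = True,
    tie_beta: bool = True,
    n_jobs: int = 1,
) -> GridResult:
    """Fit every weight combination at ``fixed_K`` from one shared SVD init.

    Non-converged cells keep their recorded error but are excluded from the
    argmin (plotting utilities display them as 0, mirroring the convention
    of treating non-convergent combinations as blanks). Cells are
    independent, so results do not depend on execution order.
    """
    combos = enumerate_grid(value_set, tie_lambda, tie_beta)
    base = FactorizationParams(K=fixed_K, max_iter=budget_iter, tol=tol, seed=seed)
    init = svd_init(x1, x2, fixed_K, seed)

    out = Parallel(n_jobs=n_jobs)(
        delayed(_fit_cell)(x1, x2, d, a, b1, b2, c, base, init) for c in combos
    )
    table = pd.DataFrame(combos, columns=ParamCombo._fields)
    table["reconstruction_error"] = [e for e, _ in out]
    table["converged"] = [c for _, c in out]

    conv = table[table["converged"]]
    if conv.empty:
        raise ValidationError(
            "no grid combination converged within the iteration budget; "
            "increase budget_iter or loosen tol"
        )
    best_index = int(conv["reconstruction_error"].idxmin())
    return GridResult(table, best_index, fixed_K)


def select_k(
    x1,
    x2,
    d,
    a,
    b1,
    b2,
    params: FactorizationParams,
    k_min: int = 2,
    k_max: int | None = None,
) -> KSweepResult:
    """Sweep the rank K with fresh SVD inits; chosen_K = argmin error.

    Raw reconstruction error decreases with K, so the argmin gravitates to
    k_max; the advisory ``elbow_K`` (largest second difference of the error
    curve) marks where returns diminish.
    """
    n = (x1.values if hasattr(x1, "values") else np.asarray(x1)).shape[0]
    if k_max is None:
        k_max = n
    if not 1 <= k_min <= k_max <= n:
        raise ValidationError(f"need 1 <= k_min <= k_max <= n={n}")

    ks = np.arange(k_min, k_max + 1)
    errors = np.empty(ks.size)
    for i, k in enumerate(ks):
        p = replace(params, K=int(k))
        res = fit(x1, x2, d, a, b1, b2, p, init=svd_init(x1, x2, int(k), params.seed))
        errors[i] = relative_error(x1, x2, res.W, res.H1, res.H2)

    chosen = int(ks[int(np.argmin(errors))])
    elbow = None
    if ks.size >= 3:
        second_diff = errors[:-2] - 2 * errors[1:-1] + errors[2:]
        elbow = int(ks[1 + int(np.argmax(second_diff))])
    return KSweepResult(ks, errors, chosen, elbow)
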