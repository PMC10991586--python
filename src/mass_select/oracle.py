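"""Exhaustive-enumeration reference for small instances.

Because the MASS MILP couples response columns only through the predictor
indicator z, the optimum for a fixed predictor set decomposes into
independent per-response linear programs.  Enumerating all predictor
subsets and summing per-response LP optima therefore certifies the MILP
optimum exactly on small instances.  This module is a certification
device, not a performant solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .config import MASSConfig
from .phenotype_io import EncodedMatrix

SUBSET_GUARD = 12


@dataclass
class FitResult:
    beta: np.ndarray
    beta0: float
    loss: float  # sum of per-sample losses (unscaled)
    penalty: float  # ||beta||_1

    @property
    def objective(self) -> float:
        # loss + n*lambda*penalty is what the LP minimizes; callers rescale
        return self.loss


def _l1_lp(y: np.ndarray, Xs: np.ndarray, M: float, lam: float, hinge: bool) -> FitResult:
    """Shared LP core: variables [b+ (q), b- (q), b0, u (n)]."""
    y = np.asarray(y, dtype=float)
    Xs = np.asarray(Xs, dtype=float)
    if Xs.ndim == 1:
        Xs = Xs.reshape(-1, 1)
    if Xs.size == 0:
        Xs = Xs.reshape(len(y), 0)
    n, q = Xs.shape
    if len(y) != n:
        raise ValueError("rows of Xs must align with y")
    nv = 2 * q + 1 + n
    c = np.zeros(nv)
    c[: 2 * q] = n * lam
    c[2 * q + 1 :] = 1.0
    bounds = [(0.0, M)] * (2 * q) + [(None, None)] + [(0.0, None)] * n
    A = []
    b = []
    for i in range(n):
        row = np.zeros(nv)
        if hinge:
            # u_i >= 1 - y_i (x_i b + b0):  -y x b+ + y x b- - y b0 - u <= -1
            row[:q] = -y[i] * Xs[i]
            row[q : 2 * q] = y[i] * Xs[i]
            row[2 * q] = -y[i]
            row[2 * q + 1 + i] = -1.0
            A.append(row)
            b.append(-1.0)
        else:
            # u_i >= y_i - x_i b - b0 and u_i >= -(...)
            row[:q] = -Xs[i]
            row[q : 2 * q] = Xs[i]
            row[2 * q] = -1.0
            row[2 * q + 1 + i] = -1.0
            A.append(row)
            b.append(-y[i])
            row2 = -row.copy()
            row2[2 * q + 1 + i] = -1.0
            A.append(row2)
            b.append(y[i])
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"reference LP failed: {res.message}")
    x = res.x
    beta = x[:q] - x[q : 2 * q]
    beta0 = float(x[2 * q])
    loss = float(x[2 * q + 1 :].sum())
    return FitResult(beta=beta, beta0=beta0, loss=loss, penalty=float(np.abs(beta).sum()))


def l1_regression_lp(y, Xs, M: float = 10.0, lam: float = 0.0) -> FitResult:
    """Least-absolute-deviation regression with box-bounded coefficients.

    Minimizes sum_i |y_i - x_i' beta - beta0| + n*lam*||beta||_1 subject to
    |beta_j| <= M, beta0 free.  An empty predictor set fits the
    intercept-only model (the L1 optimum is any median of y).
    """
    return _l1_lp(y, Xs, M, lam, hinge=False)


def hinge_regression_lp(y, Xs, M: float = 10.0, lam: float = 0.0) -> FitResult:
    """Hinge-loss fit for a +/-1 response: minimizes
    sum_i max(0, 1 - y_i (x_i' beta + beta0)) + n*lam*||beta||_1 with
    |beta_j| <= M."""
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("hinge regression requires a +/-1 response")
    return _l1_lp(y, Xs, M, lam, hinge=True)


@dataclass
class SubsetFit:
    """Best predictor subset found by enumeration, with per-response fits."""

    predictor_groups: tuple[str, ...]
    predictor_features: tuple[int, ...]
    fits: dict[str, FitResult]  # response feature id -> fit
    per_response_loss: dict[str, float]  # scaled by 1/n
    objective: float


def _subset_objective(
    X: EncodedMatrix, cfg: MASSConfig, groups: tuple[str, ...]
) -> tuple[float, dict, dict, tuple[int, ...]]:
    pred_feats = tuple(i for g in groups for i in X.groups[g])
    pred_set = set(pred_feats)
    n = X.n_samples
    fits: dict[str, FitResult] = {}
    per_loss: dict[str, float] = {}
    total = 0.0
    hinge = cfg.loss == "hinge"
    Xs = X.values[:, list(pred_feats)]
    for j, fid in enumerate(X.feature_ids):
        if j in pred_set:
            continue
        y = X.values[:, j]
        fit = (
            hinge_regression_lp(y, Xs, cfg.big_m, cfg.sparsity_weight)
            if hinge
            else l1_regression_lp(y, Xs, cfg.big_m, cfg.sparsity_weight)
        )
        fits[fid] = fit
        per_loss[fid] = fit.loss / n
        total += fit.loss / n + cfg.sparsity_weight * fit.penalty
    return total, fits, per_loss, pred_feats


def enumerate_subsets(
    X: EncodedMatrix, cfg: MASSConfig
) -> tuple[SubsetFit, pd.DataFrame]:
    """Evaluate every predictor subset within the budget and return the
    global optimum plus the full subset/objective table.

    The budget is an inequality, so subsets of every size 0..p are scanned
    (with a positive sparsity weight a smaller set can win).  Groups are
    atomic: a subset either takes all dummies of an attribute or none.
    """
    labels = X.group_labels
    units = len(labels) if cfg.group_budget == "per_group" else X.n_features
    if units > SUBSET_GUARD:
        raise ValueError(
            f"{units} budget units exceed the enumeration guard "
            f"({SUBSET_GUARD}); use the MILP path"
        )
    sizes = {g: len(X.groups[g]) for g in labels}
    best: SubsetFit | None = None
    records = []
    for r in range(0, len(labels) + 1):
        for combo in combinations(labels, r):
            cost = len(combo) if cfg.group_budget == "per_group" else sum(
                sizes[g] for g in combo
            )
            if cost > cfg.p:
                continue
            total, fits, per_loss, feats = _subset_objective(X, cfg, combo)
            records.append({"subset": combo, "cost": cost, "objective": total})
            if best is None or total < best.objective - 1e-12:
                best = SubsetFit(
                    predictor_groups=combo,
                    predictor_features=feats,
                    fits=fits,
                    per_response_loss=per_loss,
                    objective=total,
                )
    table = pd.DataFrame.from_records(records).sort_values("objective", kind="stable")
    return best, table.reset_index(drop=True)
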