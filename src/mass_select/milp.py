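"""The MASS mixed-integer linear programs.

Both formulations jointly choose a binary predictor indicator z (one per
attribute group) and a full coefficient matrix B with intercepts beta0 so
that every response column j (z_j = 0) is regressed on the predictor
columns.  Big-M constraints tie coefficients to the indicators
(-M z_k <= B_kj <= M z_k) and deactivate the loss rows of predictor
columns.  The objective is (1/n) sum_ij w_ij + lambda sum_j ||beta_j||_1,
with the l1 penalty linearized by sign-splitting B = B+ - B-.

The solver backend is HiGHS through :func:`scipy.optimize.milp`; with a
single thread and a fixed model it is deterministic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .config import MASSConfig
from .phenotype_io import EncodedMatrix


def num_budget_units(X: EncodedMatrix, cfg: MASSConfig) -> int:
    """Total budget capacity: groups under per_group, features under
    per_feature."""
    return len(X.groups) if cfg.group_budget == "per_group" else X.n_features


@dataclass
class MILPModel:
    """A fully materialized MILP in standard sparse form.

    Variables are laid out as [B+ (m*m), B- (m*m), beta0 (m), z (G),
    w (n*m), t (n*m, absolute loss only)], with B[k, j] the coefficient of
    regressor feature k in the regression for feature j.  One binary per
    attribute group realizes the within-group equality constraint
    z_j = z_k structurally.
    """

    loss: str
    n: int
    m: int
    group_labels: list[str]
    feature_group: np.ndarray  # feature index -> group index
    group_sizes: np.ndarray
    cfg: MASSConfig
    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    rows: list[int] = field(default_factory=list, repr=False)
    cols: list[int] = field(default_factory=list, repr=False)
    data: list[float] = field(default_factory=list, repr=False)
    b_lo: list[float] = field(default_factory=list, repr=False)
    b_up: list[float] = field(default_factory=list, repr=False)

    # --- variable indexing -------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_vars(self) -> int:
        return len(self.c)

    def i_bp(self, k: int, j: int) -> int:
        return k * self.m + j

    def i_bm(self, k: int, j: int) -> int:
        return self.m * self.m + k * self.m + j

    def i_b0(self, j: int) -> int:
        return 2 * self.m * self.m + j

    def i_z(self, g: int) -> int:
        return 2 * self.m * self.m + self.m + g

    def i_w(self, i: int, j: int) -> int:
        return 2 * self.m * self.m + self.m + self.n_groups + i * self.m + j

    def i_t(self, i: int, j: int) -> int:
        off = 2 * self.m * self.m + self.m + self.n_groups + self.n * self.m
        return off + i * self.m + j

    # --- construction ------------------------------------------------------
    def add_row(self, idx: list[int], coef: list[float], lo: float, up: float) -> None:
        r = len(self.b_lo)
        self.rows.extend([r] * len(idx))
        self.cols.extend(idx)
        self.data.extend(coef)
        self.b_lo.append(lo)
        self.b_up.append(up)

    def copy(self) -> "MILPModel":
        out = self._copy_fields()
        out._X = self._X
        return out

    def _copy_fields(self) -> "MILPModel":
        return MILPModel(
            loss=self.loss,
            n=self.n,
            m=self.m,
            group_labels=list(self.group_labels),
            feature_group=self.feature_group.copy(),
            group_sizes=self.group_sizes.copy(),
            cfg=self.cfg,
            c=self.c.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            integrality=self.integrality.copy(),
            rows=list(self.rows),
            cols=list(self.cols),
            data=list(self.data),
            b_lo=list(self.b_lo),
            b_up=list(self.b_up),
        )

    def constraint_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        A = sparse.coo_matrix(
            (self.data, (self.rows, self.cols)), shape=(len(self.b_lo), self.n_vars)
        ).tocsr()
        return A, np.array(self.b_lo), np.array(self.b_up)


@dataclass
class MASSSolution:
    """One solved MASS instance."""

    predictor_indicator: np.ndarray  # bool per feature
    group_indicator: np.ndarray  # bool per group
    group_labels: list[str]
    coefficients: np.ndarray  # m x m, B[k, j]
    intercepts: np.ndarray
    objective: float
    loss_term: float
    penalty_term: float
    residuals: np.ndarray
    status: str
    gap: float
    wall_time_s: float

    @property
    def predictor_groups(self) -> list[str]:
        return [g for g, on in zip(self.group_labels, self.group_indicator) if on]


def _base_model(X: EncodedMatrix, cfg: MASSConfig, loss: str) -> MILPModel:
    n, m = X.n_samples, X.n_features
    groups = X.group_labels
    G = len(groups)
    fg = X.feature_to_group()
    sizes = np.array([len(X.groups[g]) for g in groups])

    if cfg.p > num_budget_units(X, cfg):
        raise ValueError(
            f"budget p={cfg.p} exceeds the {num_budget_units(X, cfg)} available "
            f"budget units ({cfg.group_budget})"
        )

    with_t = loss == "absolute"
    n_vars = 2 * m * m + m + G + n * m + (n * m if with_t else 0)
    c = np.zeros(n_vars)
    lb = np.full(n_vars, -np.inf)
    ub = np.full(n_vars, np.inf)
    integrality = np.zeros(n_vars)

    model = MILPModel(
        loss=loss,
        n=n,
        m=m,
        group_labels=groups,
        feature_group=fg,
        group_sizes=sizes,
        cfg=cfg,
        c=c,
        lb=lb,
        ub=ub,
        integrality=integrality,
    )

    M = cfg.big_m
    lam = cfg.sparsity_weight
    # B+ / B- split: both in [0, M], objective weight lambda
    lb[: 2 * m * m] = 0.0
    ub[: 2 * m * m] = M
    c[: 2 * m * m] = lam
    # intercepts
    if cfg.bound_intercept:
        lb[2 * m * m : 2 * m * m + m] = -M
        ub[2 * m * m : 2 * m * m + m] = M
    # z binaries
    for g in range(G):
        iz = model.i_z(g)
        lb[iz], ub[iz] = 0.0, 1.0
        integrality[iz] = 1
    # w loss slacks
    for i in range(n):
        for j in range(m):
            iw = model.i_w(i, j)
            lb[iw] = 0.0
            c[iw] = 1.0 / n

    # budget: sum over groups (weighted by group size under per_feature) <= p
    weights = np.ones(G) if cfg.group_budget == "per_group" else sizes.astype(float)
    model.add_row(
        [model.i_z(g) for g in range(G)], list(weights), -np.inf, float(cfg.p)
    )

    # coefficient indicator bounds: -M z_g(k) <= B_kj <= M z_g(k)
    for k in range(m):
        zk = model.i_z(fg[k])
        for j in range(m):
            bp, bm = model.i_bp(k, j), model.i_bm(k, j)
            model.add_row([bp, bm, zk], [1.0, -1.0, -M], -np.inf, 0.0)
            model.add_row([bp, bm, zk], [-1.0, 1.0, -M], -np.inf, 0.0)
    model._X = X.values.astype(float)
    return model


def build_absolute_loss_model(X: EncodedMatrix, cfg: MASSConfig) -> MILPModel:
    """Absolute-loss MASS MILP for real-valued (or +/-1) data.

    For each cell: t_ij is forced to X_ij when column j is a response
    (z = 0), so w_ij >= |X_ij - x_i' beta_j - beta0_j|; when j is a
    predictor, t_ij floats within +/-M of X_ij and the loss row can be
    satisfied with w_ij = 0.
    """
    if cfg.loss != "absolute":
        raise ValueError("cfg.loss must be 'absolute' for this model")
    Xv = X.values
    model = _base_model(X, cfg, "absolute")
    n, m, fg, M = model.n, model.m, model.feature_group, cfg.big_m
    for i in range(n):
        for j in range(m):
            iw, it = model.i_w(i, j), model.i_t(i, j)
            b0 = model.i_b0(j)
            bps = [model.i_bp(k, j) for k in range(m)]
            bms = [model.i_bm(k, j) for k in range(m)]
            x = Xv[i]
            # t - x'beta - b0 - w <= 0  and  -t + x'beta + b0 - w <= 0
            model.add_row(
                [it, *bps, *bms, b0, iw],
                [1.0, *(-x), *x, -1.0, -1.0],
                -np.inf,
                0.0,
            )
            model.add_row(
                [it, *bps, *bms, b0, iw],
                [-1.0, *x, *(-x), 1.0, -1.0],
                -np.inf,
                0.0,
            )
            # -M z_j <= t - X_ij <= M z_j
            zj = model.i_z(fg[j])
            model.add_row([it, zj], [1.0, -M], -np.inf, float(Xv[i, j]))
            model.add_row([it, zj], [-1.0, -M], -np.inf, -float(Xv[i, j]))
    return model


def build_hinge_loss_model(X: EncodedMatrix, cfg: MASSConfig) -> MILPModel:
    """Hinge-loss MASS MILP for +/-1 data.

    For each cell: X_ij (x_i' beta_j + beta0_j) >= 1 - w_ij - M z_j, so a
    response column pays the margin violation while a predictor column's
    rows are switched off by the M z_j slack.  All one-hot dummies of one
    attribute share a single binary, which is the group equality
    constraint.
    """
    if cfg.loss != "hinge":
        raise ValueError("cfg.loss must be 'hinge' for this model")
    if X.domain != "pm_one":
        raise ValueError("hinge loss requires a pm_one encoded matrix")
    Xv = X.values
    model = _base_model(X, cfg, "hinge")
    n, m, fg, M = model.n, model.m, model.feature_group, cfg.big_m
    for i in range(n):
        for j in range(m):
            iw = model.i_w(i, j)
            zj = model.i_z(fg[j])
            b0 = model.i_b0(j)
            bps = [model.i_bp(k, j) for k in range(m)]
            bms = [model.i_bm(k, j) for k in range(m)]
            y = Xv[i, j]
            x = Xv[i]
            # -y * (x'beta + b0) - w - M z_j <= -1
            model.add_row(
                [*bps, *bms, b0, iw, zj],
                [*(-y * x), *(y * x), -y, -1.0, -M],
                -np.inf,
                -1.0,
            )
    return model


_STATUS = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _run_milp(model: MILPModel):
    A, lo, up = model.constraint_matrix()
    options = {"presolve": True, "mip_rel_gap": model.cfg.mip_gap}
    if model.cfg.time_limit_s is not None:
        options["time_limit"] = model.cfg.time_limit_s
    return milp(
        c=model.c,
        constraints=LinearConstraint(A, lo, up),
        integrality=model.integrality,
        bounds=Bounds(model.lb, model.ub),
        options=options,
    )


def _extract(model: MILPModel, res, wall: float) -> MASSSolution:
    m, n = model.m, model.n
    x = res.x
    B = (x[: m * m] - x[m * m : 2 * m * m]).reshape(m, m)
    b0 = x[2 * m * m : 2 * m * m + m].copy()
    zg = np.array(
        [x[model.i_z(g)] for g in range(model.n_groups)]
    )
    group_ind = zg > 0.5
    feat_ind = group_ind[model.feature_group]
    # enforce the indicator invariant exactly: non-predictor rows are zero
    B[~feat_ind, :] = 0.0
    status = _STATUS.get(res.status, "failed")
    if status == "time_limit" and res.x is not None:
        status = "feasible_gap"
    gap = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else np.nan
    loss_term, penalty_term, resid = _decompose_arrays(
        model.loss, model.cfg, _model_X(model), B, b0, feat_ind
    )
    objective = loss_term + model.cfg.sparsity_weight * penalty_term
    return MASSSolution(
        predictor_indicator=feat_ind,
        group_indicator=group_ind,
        group_labels=model.group_labels,
        coefficients=B,
        intercepts=b0,
        objective=float(objective),
        loss_term=float(loss_term),
        penalty_term=float(penalty_term),
        residuals=resid,
        status=status,
        gap=gap,
        wall_time_s=wall,
    )


def _model_X(model: MILPModel) -> np.ndarray:
    if not hasattr(model, "_X"):
        raise RuntimeError("model missing data cache")
    return model._X


def _decompose_arrays(loss, cfg, Xv, B, b0, feat_ind):
    pred = Xv @ B + b0
    resid = Xv - pred
    if loss == "absolute":
        cell = np.abs(resid)
    else:
        cell = np.maximum(0.0, 1.0 - Xv * pred)
    cell = cell[:, ~feat_ind]  # predictors contribute no loss
    loss_term = cell.sum() / Xv.shape[0]
    penalty_term = np.abs(B).sum()
    return loss_term, penalty_term, resid


def solve(model: MILPModel, warm_start=None) -> MASSSolution:
    """Solve a MASS MILP and return the best incumbent.

    ``warm_start`` may be a MASSSolution or a boolean group-indicator
    array.  The HiGHS backend used here does not consume MIP starts, so the
    start serves as a safety incumbent: it is re-evaluated by a fixed-z
    solve and returned instead whenever the main solve fails or (under a
    time limit) ends worse than the start.
    """
    t0 = time.perf_counter()
    res = _run_milp(model)
    wall = time.perf_counter() - t0
    if res.x is None:
        if res.status == 2:
            if warm_start is None:
                return MASSSolution(
                    predictor_indicator=np.zeros(model.m, dtype=bool),
                    group_indicator=np.zeros(model.n_groups, dtype=bool),
                    group_labels=model.group_labels,
                    coefficients=np.zeros((model.m, model.m)),
                    intercepts=np.zeros(model.m),
                    objective=np.nan,
                    loss_term=np.nan,
                    penalty_term=np.nan,
                    residuals=np.zeros((model.n, model.m)),
                    status="infeasible",
                    gap=np.nan,
                    wall_time_s=wall,
                )
        if warm_start is not None:
            return solve_fixed_z(model, _start_groups(model, warm_start))
        raise RuntimeError(f"solver failed: {res.message}")
    sol = _extract(model, res, wall)
    if warm_start is not None and sol.status != "optimal":
        ws = solve_fixed_z(model, _start_groups(model, warm_start))
        if ws.objective < sol.objective - 1e-12:
            return ws
    return sol


def _start_groups(model: MILPModel, warm_start) -> np.ndarray:
    if isinstance(warm_start, MASSSolution):
        return warm_start.group_indicator
    return np.asarray(warm_start, dtype=bool)


def solve_fixed_z(model: MILPModel, group_indicator: np.ndarray) -> MASSSolution:
    """Solve the continuous restriction with the predictor set fixed."""
    fixed = model.copy()
    for g, on in enumerate(np.asarray(group_indicator, dtype=bool)):
        iz = fixed.i_z(g)
        fixed.lb[iz] = fixed.ub[iz] = 1.0 if on else 0.0
    t0 = time.perf_counter()
    res = _run_milp(fixed)
    wall = time.perf_counter() - t0
    if res.x is None:
        raise RuntimeError(f"fixed-z solve failed: {res.message}")
    return _extract(fixed, res, wall)


def objective_decompose(
    solution: MASSSolution, X: EncodedMatrix, cfg: MASSConfig
) -> tuple[float, float, dict[str, float]]:
    """Recompute (loss_term, penalty_term, per-response losses) from B,
    beta0 and the data, independently of solver variables."""
    B, b0 = solution.coefficients, solution.intercepts
    if B.shape != (X.n_features, X.n_features):
        raise ValueError(
            f"coefficient shape {B.shape} does not match {X.n_features} features"
        )
    Xv = X.values
    pred = Xv @ B + b0
    if cfg.loss == "absolute":
        cell = np.abs(Xv - pred)
    else:
        cell = np.maximum(0.0, 1.0 - Xv * pred)
    per_response = {
        fid: float(cell[:, j].sum() / X.n_samples)
        for j, fid in enumerate(X.feature_ids)
        if not solution.predictor_indicator[j]
    }
    loss_term = float(sum(per_response.values()))
    penalty_term = float(np.abs(B).sum())
    return loss_term, penalty_term, per_response
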