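"""Descending warm-start sweep over the predictor budget p.

Large budgets solve quickly because most loss rows are switched off;
small budgets are the hard instances.  The sweep therefore starts at
p_max and descends, reusing the predictor set found at p+1:

* greedy1 (monotone): predictors at budget p must all come from the
  p+1 support, enforced by z_prev' z >= p;
* greedy2 (relaxed): one outside swap is admitted, z_prev' z >= p - 1,
  warm-started at greedy1.

greedy2 seeds the next descent step.  An exact mode (no added
constraints) is available for instances small enough to solve directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MASSConfig
from .milp import (
    MASSSolution,
    MILPModel,
    build_absolute_loss_model,
    build_hinge_loss_model,
    num_budget_units,
    solve,
)
from .phenotype_io import EncodedMatrix


@dataclass
class SweepRecord:
    p: int
    mode: str  # exact | greedy1 | greedy2
    solution: MASSSolution


@dataclass
class SelectionPath:
    """Per-p sequence of solutions produced by one sweep."""

    records: list[SweepRecord] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)
    p_max: int = 0
    p_min: int = 1
    mode: str = "greedy"

    def at(self, p: int, mode: str) -> MASSSolution | None:
        for r in self.records:
            if r.p == p and r.mode == mode:
                return r.solution
        return None

    def final(self, p: int) -> MASSSolution | None:
        """The solution the sweep retains for budget p (greedy2 below
        p_max, the unconstrained solve at p_max)."""
        for mode in ("exact", "greedy2", "greedy1"):
            sol = self.at(p, mode)
            if sol is not None:
                return sol
        return None

    def predictor_frequency(self) -> pd.DataFrame:
        """Attributes x p table of predictor status (True = predictor),
        with attributes ordered by how often they were selected."""
        ps = sorted({r.p for r in self.records})
        data = {}
        for p in ps:
            sol = self.final(p)
            if sol is not None:
                data[p] = pd.Series(sol.group_indicator, index=self.group_labels)
        df = pd.DataFrame(data)
        return df.loc[df.sum(axis=1).sort_values(ascending=False, kind="stable").index]

    def objective_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "p": r.p,
                    "mode": r.mode,
                    "objective": r.solution.objective,
                    "loss": r.solution.loss_term,
                    "penalty": r.solution.penalty_term,
                    "status": r.solution.status,
                    "predictors": ";".join(r.solution.predictor_groups),
                }
                for r in self.records
            ]
        )

    def to_dict(self) -> dict:
        return {
            "p_max": self.p_max,
            "p_min": self.p_min,
            "mode": self.mode,
            "group_labels": self.group_labels,
            "records": [
                {
                    "p": r.p,
                    "mode": r.mode,
                    "objective": r.solution.objective,
                    "loss": r.solution.loss_term,
                    "penalty": r.solution.penalty_term,
                    "status": r.solution.status,
                    "gap": r.solution.gap,
                    "predictors": r.solution.predictor_groups,
                }
                for r in self.records
            ],
        }


def _support_constraint(
    model: MILPModel, z_prev: np.ndarray, rhs: int, p: int
) -> MILPModel:
    z_prev = np.asarray(z_prev, dtype=bool)
    if z_prev.sum() < p:
        raise ValueError(
            f"previous support has {int(z_prev.sum())} predictors, fewer than p={p}"
        )
    out = model.copy()
    idx = [out.i_z(g) for g in range(out.n_groups) if z_prev[g]]
    out.add_row(idx, [1.0] * len(idx), float(rhs), np.inf)
    return out


def constrain_monotone(model: MILPModel, z_prev: np.ndarray, p: int) -> MILPModel:
    """Monotone descent constraint z_prev' z >= p: all p predictors must
    come from the support found at budget p+1."""
    return _support_constraint(model, z_prev, p, p)


def constrain_relaxed(model: MILPModel, z_prev: np.ndarray, p: int) -> MILPModel:
    """Relaxed descent constraint z_prev' z >= p - 1: one predictor may be
    swapped in from outside the previous support."""
    return _support_constraint(model, z_prev, p - 1, p)


def _build(X: EncodedMatrix, cfg: MASSConfig) -> MILPModel:
    if cfg.loss == "hinge":
        return build_hinge_loss_model(X, cfg)
    return build_absolute_loss_model(X, cfg)


def sweep_descending(
    X: EncodedMatrix,
    cfg: MASSConfig,
    p_max: int | None = None,
    p_min: int = 1,
    mode: str = "greedy",
) -> SelectionPath:
    """Solve across budgets p_max..p_min.

    mode="greedy": unconstrained solve at p_max, then the greedy1/greedy2
    pair at each smaller p, chaining greedy2 downward.  mode="exact":
    an unconstrained solve at every p (small instances only).
    Infeasible or failed steps are recorded and the sweep continues from
    the last feasible support.
    """
    units = num_budget_units(X, cfg)
    if p_max is None:
        p_max = units - 1  # keep at least one response column
    if not (1 <= p_min <= p_max <= units):
        raise ValueError(f"need 1 <= p_min <= p_max <= {units}")

    from dataclasses import replace

    path = SelectionPath(
        group_labels=X.group_labels, p_max=p_max, p_min=p_min, mode=mode
    )

    if mode == "exact":
        for p in range(p_max, p_min - 1, -1):
            sol = solve(_build(X, replace(cfg, p=p)))
            path.records.append(SweepRecord(p, "exact", sol))
        path.records.sort(key=lambda r: r.p)
        return path

    top = solve(_build(X, replace(cfg, p=p_max)))
    path.records.append(SweepRecord(p_max, "exact", top))
    z_chain = top.group_indicator
    for p in range(p_max - 1, p_min - 1, -1):
        base = _build(X, replace(cfg, p=p))
        g1 = solve(constrain_monotone(base, z_chain, p))
        path.records.append(SweepRecord(p, "greedy1", g1))
        warm = g1 if g1.status in ("optimal", "feasible_gap") else None
        g2 = solve(constrain_relaxed(base, z_chain, p), warm_start=warm)
        path.records.append(SweepRecord(p, "greedy2", g2))
        if g2.status in ("optimal", "feasible_gap"):
            z_chain = g2.group_indicator
        elif g1.status in ("optimal", "feasible_gap"):
            z_chain = g1.group_indicator
        # otherwise keep the last feasible support
    path.records.sort(key=lambda r: (r.p, r.mode))
    return path
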