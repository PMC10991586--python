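"""Solver-facing configuration for the subset-selection MILP."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class MASSConfig:
    """All knobs of one MASS solve.

    Parameters
    ----------
    p
        Predictor budget: the maximum number of budget units (attribute
        groups, or raw features under ``group_budget="per_feature"``) that
        may be selected as predictors.
    sparsity_weight
        lambda, the weight of the l1 penalty on the coefficient columns.
        0 disables it; the default 1e-3 breaks ties toward sparse
        coefficient matrices without visibly moving the loss.
    big_m
        M, the box bound on every regression coefficient and the constant
        that deactivates loss rows for predictor columns.  For +/-1 data a
        margin of 1 never needs coefficients beyond a few units, so the
        default 10 is safe; too small an M cuts off optima, too large an M
        weakens the LP relaxation.
    loss
        "absolute" (real-valued data) or "hinge" (+/-1 data).
    group_budget
        "per_group": each source attribute costs one budget unit regardless
        of how many one-hot dummies it produced (so p counts whole
        conditions).  "per_feature": each encoded column costs one unit
        (the literal sum over feature indicators).
    bound_intercept
        If True, also box the intercepts into [-M, M]; by default they are
        free.
    """

    p: int
    sparsity_weight: float = 1e-3
    big_m: float = 10.0
    loss: str = "hinge"
    group_budget: str = "per_group"
    bound_intercept: bool = False
    solver: str = "highs"
    time_limit_s: float | None = None
    mip_gap: float = 1e-6
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be non-negative")
        if self.big_m <= 0:
            raise ValueError("big_m must be positive")
        if self.loss not in ("absolute", "hinge"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.group_budget not in ("per_group", "per_feature"):
            raise ValueError(f"unknown group_budget {self.group_budget!r}")
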