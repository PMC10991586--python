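"""Synthetic phenotype matrices with planted predictor structure.

The generator emulates the shape of real growth-phenotype tables: a small
set of "true" predictor columns drawn independently with controllable
marginal frequencies, and response columns computed from the predictors by
a known rule, then corrupted at a noise rate epsilon.  Unbalanced
(rare/ubiquitous) columns are produced by skewing the marginals.  Because
the ground truth is known, recovery, ordering and validation claims become
literally testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotype_io import PhenotypeMatrix

LEVELS3 = ["negative", "weak", "positive"]


@dataclass
class PlantedSpec:
    """Recipe for one planted matrix.

    Binary matrices use {0, 1} codes.  Three-level matrices use the
    ordered levels negative < weak < positive.  ``noise`` is the
    probability of flipping a binary response entry, or of resampling a
    three-level response entry uniformly among the other two levels.
    """

    n: int = 200
    m: int = 8
    p_true: int = 2
    response_rule: str = "linear_threshold"  # | majority | copy_with_noise
    noise: float = 0.0
    level_count: int = 2
    marginals: np.ndarray | None = None  # per-predictor P(positive)
    predictor_idx: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.p_true < self.m):
            raise ValueError("need 1 <= p_true < m")
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5) for identifiability")
        if self.level_count not in (2, 3):
            raise ValueError("level_count must be 2 or 3")
        if self.response_rule not in ("linear_threshold", "majority", "copy_with_noise"):
            raise ValueError(f"unknown response rule {self.response_rule!r}")
        if self.marginals is not None:
            marg = np.asarray(self.marginals, dtype=float)
            if len(marg) != self.p_true or ((marg <= 0) | (marg >= 1)).any():
                raise ValueError("marginals must be p_true values in (0, 1)")


def _threshold_rule(rng: np.random.Generator, p: int) -> tuple[np.ndarray, int]:
    """Draw a +/-1-weighted linear threshold rule with margin >= 1.

    Signs s in {-1,+1}^p and an offset c with parity opposite to p
    guarantee |s'x + c| >= 1 for x in {-1,+1}^p, so the rule is exactly
    representable by the hinge model with unit coefficients.
    """
    s = rng.choice([-1, 1], size=p)
    offsets = [c for c in range(-p + 1, p) if (c + p) % 2 == 1]
    c = int(rng.choice(offsets))
    return s, c


def generate_planted(spec: PlantedSpec) -> tuple[PhenotypeMatrix, dict]:
    """Generate a phenotype matrix plus a ground-truth record.

    Predictor columns are independent draws with the stated marginals;
    each response column is a deterministic function of the true
    predictors (per ``response_rule``) with entries corrupted at rate
    ``noise``.  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, p = spec.n, spec.m, spec.p_true
    pred_idx = (
        tuple(spec.predictor_idx)
        if spec.predictor_idx is not None
        else tuple(range(p))
    )
    if len(set(pred_idx)) != p or max(pred_idx) >= m:
        raise ValueError("predictor_idx must be p_true distinct indices < m")
    marg = (
        np.asarray(spec.marginals, dtype=float)
        if spec.marginals is not None
        else np.full(p, 0.5)
    )
    attrs = [f"A{j + 1:02d}" for j in range(m)]

    if spec.level_count == 2:
        Xp = (rng.random((n, p)) < marg).astype(float)  # {0,1}
        S = 2.0 * Xp - 1.0  # +/-1 view for the rules
        cols = np.zeros((n, m))
        rules = {}
        resp_cols = [j for j in range(m) if j not in pred_idx]
        for j in resp_cols:
            if spec.response_rule == "copy_with_noise":
                src = int(rng.integers(p))
                y = Xp[:, src].copy()
                rules[attrs[j]] = {"rule": "copy", "source": attrs[pred_idx[src]]}
            elif spec.response_rule == "majority":
                score = S.sum(axis=1)
                y = (score >= 0).astype(float)  # ties break positive
                rules[attrs[j]] = {"rule": "majority"}
            else:
                s, c = _threshold_rule(rng, p)
                y = (S @ s + c > 0).astype(float)
                rules[attrs[j]] = {"rule": "threshold", "signs": s.tolist(), "offset": c}
            flip = rng.random(n) < spec.noise
            y[flip] = 1.0 - y[flip]
            cols[:, j] = y
        for k, j in enumerate(pred_idx):
            cols[:, j] = Xp[:, k]
        matrix = PhenotypeMatrix(
            [f"S{i + 1:03d}" for i in range(n)], attrs, cols
        )
    else:
        # predictors: categorical with P(positive)=marg, the rest split
        # evenly between negative and weak
        codes = np.zeros((n, m), dtype=int)
        for k in range(p):
            u = rng.random(n)
            codes[:, pred_idx[k]] = np.where(
                u < marg[k], 2, np.where(u < marg[k] + (1 - marg[k]) / 2, 1, 0)
            )
        Sp = codes[:, list(pred_idx)] - 1  # {-1,0,1}
        rules = {}
        for j in [j for j in range(m) if j not in pred_idx]:
            s = rng.choice([-1, 1], size=p)
            score = Sp @ s
            y = np.clip(score, -1, 1) + 1  # three-level cut at +/-1
            resample = rng.random(n) < spec.noise
            for i in np.where(resample)[0]:
                y[i] = rng.choice([lvl for lvl in (0, 1, 2) if lvl != y[i]])
            codes[:, j] = y
            rules[attrs[j]] = {"rule": "ordinal_threshold", "signs": s.tolist()}
        vals = np.empty((n, m), dtype=object)
        for (i, j), v in np.ndenumerate(codes):
            vals[i, j] = LEVELS3[int(v)]
        matrix = PhenotypeMatrix(
            [f"S{i + 1:03d}" for i in range(n)], attrs, vals, level_set=list(LEVELS3)
        )

    truth = {
        "predictor_ids": tuple(attrs[j] for j in pred_idx),
        "predictor_idx": pred_idx,
        "rules": rules,
        "spec": spec,
    }
    return matrix, truth


def generate_unbalanced_suite(seed: int = 0) -> list[tuple[str, PhenotypeMatrix, dict]]:
    """Fixed small suite mixing balanced and near-constant columns.

    Returns (name, matrix, truth) triples: a planted matrix carrying one
    near-constant (marginal 0.97) predictor column, a mixed matrix whose
    responses copy a balanced predictor while a rare-phenotype column
    rides along, and an all-balanced control.
    """
    suite = []

    spec_rare = PlantedSpec(
        n=150, m=8, p_true=3, response_rule="linear_threshold",
        noise=0.05, marginals=np.array([0.5, 0.5, 0.97]), seed=seed,
    )
    suite.append(("rare_predictor", *generate_planted(spec_rare)))

    spec_mix = PlantedSpec(
        n=150, m=6, p_true=2, response_rule="copy_with_noise",
        noise=0.1, marginals=np.array([0.5, 0.97]), seed=seed + 1,
    )
    suite.append(("rare_copy", *generate_planted(spec_mix)))

    # copies of balanced predictors keep every column near 50/50, so the
    # control has no low-entropy column by construction
    spec_ctrl = PlantedSpec(
        n=150, m=6, p_true=2, response_rule="copy_with_noise",
        noise=0.05, marginals=np.array([0.5, 0.5]), seed=seed + 2,
    )
    suite.append(("balanced_control", *generate_planted(spec_ctrl)))
    return suite
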