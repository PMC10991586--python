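"""Supervised-learning assessment of a predictor selection.

Any selection (MASS, entropy, random) is judged the same way: split the
samples 50/50, train one tunable classifier per response attribute on the
training half using only the selected predictor columns, predict the test
half, and pool the predictions of all responses into a single confusion
before computing metrics.  Random forests are the default classifier;
hyperparameters are tuned by k-fold cross-validation on the training half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn import metrics as skm

from .baselines import SelectionSet
from .phenotype_io import PhenotypeMatrix


def split_half(matrix: PhenotypeMatrix, seed: int = 0):
    """Random disjoint, exhaustive 50/50 split of the samples.

    For odd n the training half receives the extra sample
    (ceil(n/2) train, floor(n/2) test).  Unstratified; reproducible
    under seed.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = n - n // 2
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def take(idx):
        from dataclasses import replace

        return replace(
            matrix,
            sample_ids=[matrix.sample_ids[i] for i in idx],
            values=matrix.values[idx],
        )

    return take(tr), take(te)


@dataclass
class RandomForestSpec:
    """Default classifier contract: a random forest with a small CV grid
    over candidate-features-per-split and maximum tree depth."""

    n_estimators: int = 100
    grid: dict = field(
        default_factory=lambda: {
            "max_features": ["sqrt", 0.5],
            "max_depth": [3, 5, None],
        }
    )

    def make(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        )


class _ConstantClassifier:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=object)


# --- metrics ---------------------------------------------------------------


def mcc(y_true, y_pred) -> float:
    """Matthews correlation coefficient (multiclass generalization)."""
    _check(y_true, y_pred)
    return float(skm.matthews_corrcoef(y_true, y_pred))


def accuracy(y_true, y_pred) -> float:
    _check(y_true, y_pred)
    return float(skm.accuracy_score(y_true, y_pred))


def balanced_accuracy(y_true, y_pred) -> float:
    _check(y_true, y_pred)
    return float(skm.balanced_accuracy_score(y_true, y_pred))


def cohens_kappa(y_true, y_pred) -> float:
    _check(y_true, y_pred)
    return float(skm.cohen_kappa_score(y_true, y_pred))


def f1_weighted(y_true, y_pred) -> float:
    """Weighted macro-averaged F1 score."""
    _check(y_true, y_pred)
    return float(skm.f1_score(y_true, y_pred, average="weighted", zero_division=0))


def jaccard_macro(y_true, y_pred) -> float:
    """Macro-averaged Jaccard similarity score on label agreement."""
    _check(y_true, y_pred)
    return float(skm.jaccard_score(y_true, y_pred, average="macro", zero_division=0))


METRICS = {
    "mcc": mcc,
    "accuracy": accuracy,
    "balanced_accuracy": balanced_accuracy,
    "cohens_kappa": cohens_kappa,
    "f1_weighted": f1_weighted,
    "jaccard": jaccard_macro,
}


def _check(y_true, y_pred):
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")


# --- evaluation harness ----------------------------------------------------


@dataclass
class ValidationResult:
    method: str
    p: int
    per_response: dict  # attr -> {"y_true","y_pred","metrics","constant"}
    pooled: dict  # metric name -> value
    split_seed: int
    cv_folds: int
    tuning: dict  # attr -> best params

    @property
    def n_models(self) -> int:
        return len(self.per_response)


def _labels(matrix: PhenotypeMatrix, attr: str) -> np.ndarray:
    col = matrix.column(attr)
    return np.array([str(v) for v in col], dtype=object)


def evaluate_selection(
    matrix: PhenotypeMatrix,
    selection: SelectionSet,
    classifier_spec: RandomForestSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    split=None,
) -> ValidationResult:
    """Train one classifier per response attribute and pool test metrics.

    Predictors enter as raw phenotype codes.  A response with a single
    class in training is served by a constant predictor and flagged.
    ``split`` may carry a precomputed (train, test) pair so that several
    selection methods share the identical split.
    """
    spec = classifier_spec or RandomForestSpec()
    missing = [a for a in selection.attribute_ids if a not in matrix.attribute_ids]
    if missing:
        raise KeyError(f"selection names unknown attributes: {missing}")
    train, test = split if split is not None else split_half(matrix, seed)
    pred_cols = [matrix.attribute_ids.index(a) for a in selection.attribute_ids]
    Xtr = train.codes()[:, pred_cols]
    Xte = test.codes()[:, pred_cols]
    responses = [a for a in matrix.attribute_ids if a not in selection.attribute_ids]

    per_response: dict = {}
    tuning: dict = {}
    all_true: list = []
    all_pred: list = []
    for attr in responses:
        ytr = _labels(train, attr)
        yte = _labels(test, attr)
        classes = np.unique(ytr)
        if len(classes) < 2:
            model = _ConstantClassifier(classes[0])
            tuning[attr] = {"constant": str(classes[0])}
            constant = True
        else:
            n_grid = int(np.prod([len(v) for v in spec.grid.values()]))
            folds = min(cv_folds, int(np.min(np.unique(ytr, return_counts=True)[1])))
            if folds >= 2 and n_grid > 1:
                gs = GridSearchCV(
                    spec.make(seed), spec.grid, cv=folds, scoring="accuracy", n_jobs=1
                )
                gs.fit(Xtr, ytr)
                model = gs.best_estimator_
                tuning[attr] = dict(gs.best_params_)
            else:
                model = spec.make(seed)
                model.fit(Xtr, ytr)
                tuning[attr] = {}
            constant = False
        yp = model.predict(Xte)
        per_response[attr] = {
            "y_true": yte,
            "y_pred": yp,
            "metrics": {name: fn(yte, yp) for name, fn in METRICS.items()},
            "constant": constant,
        }
        all_true.append(yte)
        all_pred.append(yp)

    y_true = np.concatenate(all_true) if all_true else np.array([], dtype=object)
    y_pred = np.concatenate(all_pred) if all_pred else np.array([], dtype=object)
    pooled = {name: fn(y_true, y_pred) for name, fn in METRICS.items()} if len(y_true) else {}
    return ValidationResult(
        method=selection.method,
        p=selection.p,
        per_response=per_response,
        pooled=pooled,
        split_seed=seed,
        cv_folds=cv_folds,
        tuning=tuning,
    )


def evaluate_random_baseline(
    matrix: PhenotypeMatrix,
    p: int,
    n_draws: int = 300,
    seed: int = 0,
    classifier_spec: RandomForestSpec | None = None,
    cv_folds: int = 5,
    split=None,
    metric: str = "mcc",
) -> tuple[float, list[float]]:
    """Mean pooled metric over ``n_draws`` random predictor selections.

    With a fixed split and classifier seed the evaluation of a subset is
    deterministic, so repeated draws of the same subset are evaluated once
    and weighted by multiplicity — exactly equivalent to evaluating every
    draw.  Returns (mean, per-draw values in draw order).
    """
    from .baselines import random_select

    sets = random_select(matrix, p, n_draws=n_draws, seed=seed)
    cache: dict[tuple[str, ...], float] = {}
    values = []
    for sel in sets:
        key = sel.attribute_ids
        if key not in cache:
            res = evaluate_selection(
                matrix, sel, classifier_spec=classifier_spec,
                cv_folds=cv_folds, seed=seed, split=split,
            )
            cache[key] = res.pooled[metric]
        values.append(cache[key])
    return float(np.mean(values)), values
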