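"""Comparator predictor selections: Shannon-entropy ranking and random draws.

The information content of a phenotype column bounds how useful it can be
as a predictor on its own; ranking columns by entropy is the natural
single-column baseline, and uniform random subsets give the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phenotype_io import PhenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionSet:
    """One predictor selection: which attributes, chosen how."""

    method: str  # mass | entropy | random
    p: int
    attribute_ids: tuple[str, ...]
    draw_index: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.attribute_ids) != self.p:
            raise ValueError(
                f"selection size {len(self.attribute_ids)} does not match p={self.p}"
            )


def shannon_entropy(column, base: float = 2.0) -> float:
    """Shannon entropy -sum_c f_c log_b f_c of the category frequencies of
    one phenotype column (bits for the default base 2)."""
    col = np.asarray(column, dtype=object)
    if col.size == 0:
        raise ValueError("empty column")
    if any(v is None for v in col.ravel()):
        raise ValueError("column contains missing values")
    _, counts = np.unique(col.astype(str), return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log(f) / np.log(base)).sum())


def column_entropies(matrix: PhenotypeMatrix, base: float = 2.0) -> dict[str, float]:
    """Entropy of every attribute, computed on the raw (categorical or
    binary) column, not on one-hot dummies."""
    return {
        a: shannon_entropy(matrix.values[:, j], base=base)
        for j, a in enumerate(matrix.attribute_ids)
    }


def entropy_select(matrix: PhenotypeMatrix, p: int, base: float = 2.0) -> SelectionSet:
    """The p attributes of highest Shannon entropy; ties broken by column
    order (logged)."""
    if p > matrix.n_attributes:
        raise ValueError(f"p={p} exceeds {matrix.n_attributes} attributes")
    ent = column_entropies(matrix, base=base)
    order = sorted(
        range(matrix.n_attributes),
        key=lambda j: (-ent[matrix.attribute_ids[j]], j),
    )
    chosen = order[:p]
    if len(order) > p:
        last, first_out = order[p - 1], order[p]
        if ent[matrix.attribute_ids[last]] == ent[matrix.attribute_ids[first_out]]:
            logger.info(
                "entropy tie at the selection boundary between %s and %s; "
                "earlier column kept",
                matrix.attribute_ids[last],
                matrix.attribute_ids[first_out],
            )
    return SelectionSet(
        method="entropy", p=p, attribute_ids=tuple(matrix.attribute_ids[j] for j in chosen)
    )


def random_select(
    matrix: PhenotypeMatrix, p: int, n_draws: int = 300, seed: int = 0
) -> list[SelectionSet]:
    """n_draws uniform without-replacement draws of p attributes,
    reproducible under seed."""
    if p > matrix.n_attributes:
        raise ValueError(f"p={p} exceeds {matrix.n_attributes} attributes")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n_draws):
        idx = rng.choice(matrix.n_attributes, size=p, replace=False)
        out.append(
            SelectionSet(
                method="random",
                p=p,
                attribute_ids=tuple(matrix.attribute_ids[j] for j in sorted(idx)),
                draw_index=d,
                seed=seed,
            )
        )
    return out
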