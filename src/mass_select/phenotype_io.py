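"""Phenotype tables and the preprocessing steps that make them MILP-ready.

A :class:`PhenotypeMatrix` holds raw phenotype codes: continuous growth
measurements (e.g. optical density), binary growth calls, or ordered
categorical growth levels such as negative < variable/weak/delayed <
positive.  Before subset selection the table is discretized, optionally
filtered for redundant (rank-correlated) attributes and incomplete samples,
and encoded into a numeric +/-1 matrix (:class:`EncodedMatrix`) whose
one-hot dummy columns are tied together in groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = None  # internal missing marker for categorical tables


@dataclass
class PhenotypeMatrix:
    """Labeled samples x attributes table of raw phenotype codes.

    ``values`` is a float array for numeric tables (NaN marks missing) or an
    object array of levels drawn from ``level_set`` for categorical tables
    (None marks missing).
    """

    sample_ids: list[str]
    attribute_ids: list[str]
    values: np.ndarray
    level_set: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.attribute_ids) != m:
            raise ValueError(
                f"shape mismatch: {n}x{m} values for {len(self.sample_ids)} "
                f"samples and {len(self.attribute_ids)} attributes"
            )
        for name, ids in (("sample", self.sample_ids), ("attribute", self.attribute_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} ids: {dup}")
        if self.level_set is not None:
            allowed = set(self.level_set)
            for (i, j), v in np.ndenumerate(self.values):
                if v is not MISSING and v not in allowed:
                    raise ValueError(
                        f"undeclared level {v!r} at sample {self.sample_ids[i]!r}, "
                        f"attribute {self.attribute_ids[j]!r}"
                    )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def is_categorical(self) -> bool:
        return self.level_set is not None

    def missing_mask(self) -> np.ndarray:
        if self.is_categorical:
            return np.array([[v is MISSING for v in row] for row in self.values])
        return np.isnan(self.values.astype(float))

    def codes(self) -> np.ndarray:
        """Numeric view: ordinal level index for categorical data (NaN for
        missing), the values themselves for numeric data."""
        if not self.is_categorical:
            return self.values.astype(float)
        lut = {lvl: float(i) for i, lvl in enumerate(self.level_set)}
        out = np.full(self.values.shape, np.nan)
        for (i, j), v in np.ndenumerate(self.values):
            if v is not MISSING:
                out[i, j] = lut[v]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.attribute_ids)

    def column(self, attribute_id: str) -> np.ndarray:
        return self.values[:, self.attribute_ids.index(attribute_id)]


@dataclass
class EncodedMatrix:
    """Numeric matrix ready for the MILP.

    ``domain`` is ``"pm_one"`` (every entry in {-1, +1}, required by the
    hinge formulation) or ``"real"``.  ``groups`` maps a group label (the
    source attribute) to the encoded column indices it owns; the one-hot
    dummies of a categorical attribute share a group so the MILP can force
    them to be predictors or responses together.  ``provenance`` maps each
    feature id back to its (source attribute, encoded level).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    domain: str
    groups: dict[str, list[int]]
    provenance: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.domain not in ("pm_one", "real"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if np.isnan(self.values).any():
            raise ValueError("encoded matrix must not contain missing values")
        if self.domain == "pm_one" and not np.isin(self.values, (-1.0, 1.0)).all():
            raise ValueError("pm_one domain requires every entry in {-1, +1}")
        seen: list[int] = sorted(i for idxs in self.groups.values() for i in idxs)
        if seen != list(range(len(self.feature_ids))):
            raise ValueError("groups must partition the feature columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    def feature_to_group(self) -> np.ndarray:
        """Group index (in ``group_labels`` order) of each feature column."""
        out = np.empty(self.n_features, dtype=int)
        for g, (label, idxs) in enumerate(self.groups.items()):
            out[idxs] = g
        return out

    def decode(self) -> PhenotypeMatrix:
        """Reconstruct the source categorical/binary matrix from provenance."""
        attrs = list(self.groups)
        levels: set[str] = set()
        for fid in self.feature_ids:
            _, lvl = self.provenance[fid]
            if lvl is not None:
                levels.add(lvl)
        if not levels:  # binary encoding: -1/+1 back to 0/1
            vals = np.zeros((self.n_samples, len(attrs)))
            for j, a in enumerate(attrs):
                vals[:, j] = (self.values[:, self.groups[a][0]] > 0).astype(float)
            return PhenotypeMatrix(self.sample_ids, attrs, vals)
        drop = [lvl for a in attrs for lvl in [self._dropped_level(a)] if lvl is not None]
        level_set = sorted(levels | set(drop))
        vals = np.empty((self.n_samples, len(attrs)), dtype=object)
        for j, a in enumerate(attrs):
            dropped = self._dropped_level(a)
            for i in range(self.n_samples):
                hot = [
                    self.provenance[self.feature_ids[k]][1]
                    for k in self.groups[a]
                    if self.values[i, k] > 0
                ]
                vals[i, j] = hot[0] if hot else dropped
        return PhenotypeMatrix(self.sample_ids, attrs, vals, level_set=level_set)

    def _dropped_level(self, attr: str) -> str | None:
        meta = getattr(self, "_drop_level", None)
        return meta


def read_phenotype_table(
    path,
    *,
    delimiter: str | None = None,
    missing_symbols: tuple[str, ...] = (),
    level_set: list[str] | None = None,
    level_map: dict[str, str] | None = None,
) -> PhenotypeMatrix:
    """Read a CSV/TSV phenotype table (header row of attribute ids, first
    column of sample ids).

    Numeric tables need no declarations.  Categorical tables must declare
    ``level_set`` (and optionally ``level_map`` translating raw symbols such
    as "+"/"-"/"W" to levels); any symbol that is neither a level, a mapped
    symbol, nor a declared missing symbol raises an error naming the cell.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    attribute_ids = [str(a) for a in df.columns]
    raw = df.to_numpy(dtype=object)

    if level_set is None:
        vals = np.empty(raw.shape, dtype=float)
        for (i, j), cell in np.ndenumerate(raw):
            cell = cell.strip()
            if cell in missing_symbols:
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"cannot parse cell ({sample_ids[i]!r}, {attribute_ids[j]!r}): "
                    f"{cell!r} is not numeric and not a declared missing symbol"
                ) from None
        return PhenotypeMatrix(sample_ids, attribute_ids, vals)

    level_map = level_map or {}
    vals = np.empty(raw.shape, dtype=object)
    for (i, j), cell in np.ndenumerate(raw):
        cell = cell.strip()
        if cell in missing_symbols:
            vals[i, j] = MISSING
        elif cell in level_map:
            vals[i, j] = level_map[cell]
        elif cell in level_set:
            vals[i, j] = cell
        else:
            raise ValueError(
                f"undeclared symbol {cell!r} at cell "
                f"({sample_ids[i]!r}, {attribute_ids[j]!r})"
            )
    return PhenotypeMatrix(sample_ids, attribute_ids, vals, level_set=list(level_set))


def write_phenotype_table(matrix: PhenotypeMatrix, path, *, delimiter: str | None = None) -> None:
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".tab")) else ","
    matrix.to_dataframe().to_csv(path, sep=delimiter)


def discretize_growth(matrix: PhenotypeMatrix, threshold: float = 0.0) -> PhenotypeMatrix:
    """Binarize continuous growth measurements: 1 if value > threshold else 0.

    The default threshold 0 implements the strict "non-zero growth" call.
    """
    if matrix.is_categorical:
        raise TypeError("discretize_growth expects real-valued input, got categorical")
    vals = matrix.values.astype(float)
    if np.isnan(vals).any():
        raise ValueError("discretize_growth requires complete (non-missing) values")
    return replace(matrix, values=(vals > threshold).astype(float))


def encode_for_mass(
    matrix: PhenotypeMatrix, drop_level: str | None = None
) -> EncodedMatrix:
    """Encode a phenotype matrix into the +/-1 feature matrix MASS consumes.

    Binary {0,1} tables map to {-1,+1} with one singleton-group feature per
    attribute.  k-level categorical tables are one-hot encoded with
    ``drop_level`` eliminated, giving k-1 dummies per attribute (0 cast to
    -1); all dummies of one attribute share a group.
    """
    if matrix.missing_mask().any():
        raise ValueError(
            "matrix contains missing values; run drop_incomplete_samples first"
        )
    if not matrix.is_categorical:
        vals = matrix.values.astype(float)
        uniq = np.unique(vals)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError(
                "numeric input must be binary {0,1}; discretize continuous data first"
            )
        enc = np.where(vals > 0, 1.0, -1.0)
        groups = {a: [j] for j, a in enumerate(matrix.attribute_ids)}
        prov = {a: (a, None) for a in matrix.attribute_ids}
        return EncodedMatrix(
            matrix.sample_ids, list(matrix.attribute_ids), enc, "pm_one", groups, prov
        )

    if drop_level is None:
        raise ValueError("categorical input requires drop_level (the reference level)")
    if drop_level not in matrix.level_set:
        raise ValueError(f"drop_level {drop_level!r} not in level set {matrix.level_set}")
    kept = [lvl for lvl in matrix.level_set if lvl != drop_level]
    feature_ids: list[str] = []
    groups: dict[str, list[int]] = {}
    prov: dict[str, tuple[str, str | None]] = {}
    cols: list[np.ndarray] = []
    for j, a in enumerate(matrix.attribute_ids):
        groups[a] = []
        for lvl in kept:
            fid = f"{a}={lvl}"
            groups[a].append(len(feature_ids))
            feature_ids.append(fid)
            prov[fid] = (a, lvl)
            col = np.array([1.0 if v == lvl else -1.0 for v in matrix.values[:, j]])
            cols.append(col)
    enc = EncodedMatrix(
        matrix.sample_ids, feature_ids, np.column_stack(cols), "pm_one", groups, prov
    )
    enc._drop_level = drop_level  # retained so decode() can reconstruct
    return enc


def spearman_filter(
    matrix: PhenotypeMatrix, threshold: float = 0.74
) -> tuple[PhenotypeMatrix, list[tuple[str, str, float]]]:
    """Drop one of each pair of attributes with |Spearman rho| > threshold.

    Pairs are scanned in column order and the later column of an offending
    pair is dropped (deterministic, auditable).  A constant column has
    undefined rho; it is treated as rho = 0 with a logged warning so that
    unbalanced phenotype columns survive to be judged by the selection
    itself.  Returns the reduced matrix and an audit list of
    (dropped attribute, retained partner, rho).
    """
    codes = matrix.codes()
    if np.isnan(codes).any():
        # pairwise-complete correlation, matching how redundancy is judged
        # before incomplete samples are removed
        pass
    m = matrix.n_attributes
    keep = [True] * m
    audit: list[tuple[str, str, float]] = []
    for j in range(m):
        if not keep[j]:
            continue
        for k in range(j + 1, m):
            if not keep[k]:
                continue
            mask = ~np.isnan(codes[:, j]) & ~np.isnan(codes[:, k])
            xj, xk = codes[mask, j], codes[mask, k]
            if len(xj) < 2 or np.all(xj == xj[0]) or np.all(xk == xk[0]):
                logger.warning(
                    "constant column in pair (%s, %s); treating rho as 0",
                    matrix.attribute_ids[j],
                    matrix.attribute_ids[k],
                )
                continue
            rho = stats.spearmanr(xj, xk).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) > threshold:
                keep[k] = False
                audit.append((matrix.attribute_ids[k], matrix.attribute_ids[j], float(rho)))
    kept_ids = [a for a, k in zip(matrix.attribute_ids, keep) if k]
    reduced = replace(
        matrix,
        attribute_ids=kept_ids,
        values=matrix.values[:, np.array(keep, dtype=bool)],
    )
    return reduced, audit


def drop_incomplete_samples(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Remove every sample (row) with at least one missing value."""
    keep = ~matrix.missing_mask().any(axis=1)
    if not keep.any():
        raise ValueError("all samples contain missing values")
    return replace(
        matrix,
        sample_ids=[s for s, k in zip(matrix.sample_ids, keep) if k],
        values=matrix.values[keep],
    )


def drop_attributes(matrix: PhenotypeMatrix, ids: list[str]) -> PhenotypeMatrix:
    unknown = [i for i in ids if i not in matrix.attribute_ids]
    if unknown:
        raise KeyError(f"unknown attribute ids: {unknown}")
    keep = [a not in set(ids) for a in matrix.attribute_ids]
    return replace(
        matrix,
        attribute_ids=[a for a, k in zip(matrix.attribute_ids, keep) if k],
        values=matrix.values[:, np.array(keep, dtype=bool)],
    )


def drop_samples(matrix: PhenotypeMatrix, ids: list[str]) -> PhenotypeMatrix:
    unknown = [i for i in ids if i not in matrix.sample_ids]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    keep = np.array([s not in set(ids) for s in matrix.sample_ids], dtype=bool)
    return replace(
        matrix,
        sample_ids=[s for s, k in zip(matrix.sample_ids, keep) if k],
        values=matrix.values[keep],
    )


def write_audit(audit: list[tuple[str, str, float]], path) -> None:
    """Write a spearman_filter audit list as TSV."""
    pd.DataFrame(audit, columns=["dropped", "retained_partner", "rho"]).to_csv(
        path, sep="\t", index=False
    )
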