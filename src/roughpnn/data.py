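"""Decision-table container, file I/O, min-max scaling and stratified splitting.

A decision table is the universe ``U`` of samples described by real-valued
condition attributes ``C`` and a nominal decision attribute ``D`` — the
standard decision system ``DS = (U, C ∪ D)`` of rough-set analysis.

Two file dialects are supported:

* the UCI Wisconsin Diagnostic Breast Cancer (WDBC) dialect: headerless CSV
  rows of ``ID, diagnosis (M/B), 30 real features``;
* a generic dialect with header ``id,label,a1..aK`` for synthetic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BENIGN = "benign"
MALIGNANT = "malignant"

_WDBC_DIAGNOSIS = {"M": MALIGNANT, "B": BENIGN}
_WDBC_N_FEATURES = 30


class ParseError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class DecisionTable:
    """Universe of samples with condition attributes and decision labels.

    Parameters
    ----------
    sample_ids
        Opaque per-sample identifiers (length ``n_samples``).
    features
        ``n_samples x n_attributes`` float matrix, no missing values.
    attribute_index
        1-based attribute labels, one per column, no duplicates.  For WDBC
        files these are 1..30 in file order (1-10 means, 11-20 standard
        errors, 21-30 worst values).
    labels
        Per-sample decision class, each drawn from ``label_set``.
    label_set
        The declared finite label set, in a fixed order.
    """

    sample_ids: tuple
    features: np.ndarray
    attribute_index: tuple
    labels: tuple
    label_set: tuple

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", feats)
        if feats.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, k = feats.shape
        if n < 1 or k < 1:
            raise ValueError("decision table needs >= 1 sample and >= 1 attribute")
        if np.isnan(feats).any():
            raise ValueError("features contain missing values")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length mismatch with features")
        if len(self.attribute_index) != k:
            raise ValueError("attribute_index length mismatch with features")
        if len(set(self.attribute_index)) != k:
            raise ValueError("attribute_index has duplicates")
        bad = set(self.labels) - set(self.label_set)
        if bad:
            raise ValueError(f"labels outside declared label set: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        return {lab: sum(1 for y in self.labels if y == lab) for lab in self.label_set}

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def column_of(self, attribute) -> int:
        """Column position of a 1-based attribute label."""
        try:
            return self.attribute_index.index(attribute)
        except ValueError:
            raise KeyError(f"unknown attribute label: {attribute!r}") from None

    def restrict(self, subset_B: Sequence) -> np.ndarray:
        """Feature matrix restricted to attribute subset B (in given order)."""
        cols = [self.column_of(a) for a in subset_B]
        return self.features[:, cols]

    def select_attributes(self, subset_B: Sequence) -> "DecisionTable":
        """New table keeping only attributes in ``subset_B``."""
        return replace(
            self,
            features=self.restrict(subset_B),
            attribute_index=tuple(subset_B),
        )

    def take(self, indices: Sequence[int]) -> "DecisionTable":
        idx = list(indices)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            features=self.features[idx],
            labels=tuple(self.labels[i] for i in idx),
        )


def read_wdbc(path) -> DecisionTable:
    """Read a UCI WDBC-dialect file into a :class:`DecisionTable`.

    Each row must have 32 comma-separated fields: ID, diagnosis (M/B), 30
    real features.  Attributes are labelled 1..30 in file order; ``M`` maps
    to ``malignant`` and ``B`` to ``benign``.

    Raises
    ------
    ParseError
        On a wrong field count, unknown diagnosis code or non-numeric
        feature, naming the offending line number.
    """
    path = Path(path)
    ids, labels, rows = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 2 + _WDBC_N_FEATURES:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 32 fields, got {len(fields)}"
                )
            diag = fields[1]
            if diag not in _WDBC_DIAGNOSIS:
                raise ParseError(
                    f"{path.name}:{lineno}: unknown diagnosis code {diag!r}"
                )
            try:
                rows.append([float(v) for v in fields[2:]])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric feature ({exc})")
            ids.append(fields[0])
            labels.append(_WDBC_DIAGNOSIS[diag])
    if not rows:
        raise ParseError(f"{path.name}: empty file")
    return DecisionTable(
        sample_ids=tuple(ids),
        features=np.asarray(rows, dtype=float),
        attribute_index=tuple(range(1, _WDBC_N_FEATURES + 1)),
        labels=tuple(labels),
        label_set=(BENIGN, MALIGNANT),
    )


def read_csv(path) -> DecisionTable:
    """Read a generic-dialect table (header ``id,label,a1..aK``)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["id", "label"]:
        raise ParseError(f"{Path(path).name}: expected header id,label,a1..aK")
    attrs = []
    for c in df.columns[2:]:
        if not c.startswith("a"):
            raise ParseError(f"{Path(path).name}: bad attribute column {c!r}")
        attrs.append(int(c[1:]))
    labels = tuple(str(v) for v in df["label"])
    return DecisionTable(
        sample_ids=tuple(str(v) for v in df["id"]),
        features=df.iloc[:, 2:].to_numpy(dtype=float),
        attribute_index=tuple(attrs),
        labels=labels,
        label_set=tuple(sorted(set(labels))),
    )


def write_csv(table: DecisionTable, path) -> None:
    """Write a table in the generic dialect; round-trips through read_csv."""
    df = pd.DataFrame(table.features, columns=[f"a{a}" for a in table.attribute_index])
    df.insert(0, "label", list(table.labels))
    df.insert(0, "id", list(table.sample_ids))
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class ScalingStats:
    """Per-attribute min and max fitted on a table, for min-max scaling to [0,1]."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        mn = np.asarray(self.minimum, dtype=float)
        mx = np.asarray(self.maximum, dtype=float)
        object.__setattr__(self, "minimum", mn)
        object.__setattr__(self, "maximum", mx)
        if mn.shape != mx.shape or mn.ndim != 1:
            raise ValueError("min/max must be 1-D and congruent")
        if np.any(mx < mn):
            raise ValueError("max < min for some attribute")


def fit_scaling(table: DecisionTable) -> ScalingStats:
    """Fit min-max scaling statistics on ``table`` (typically the training split).

    The neighborhood radius and the Gaussian kernel bandwidth are both
    scale-sensitive, so granulation and classification operate on features
    mapped to a common [0,1] range.
    """
    return ScalingStats(
        minimum=table.features.min(axis=0), maximum=table.features.max(axis=0)
    )


def apply_scaling(stats: ScalingStats, table: DecisionTable) -> DecisionTable:
    """Map each attribute through ``(x - min) / (max - min)``.

    Constant attributes (max == min on the fitting table) map to 0.  Values
    outside the fitted range (possible on a held-out split) extrapolate
    linearly and may fall outside [0,1].
    """
    if stats.minimum.shape[0] != table.n_attributes:
        raise ValueError(
            f"scaling fitted on {stats.minimum.shape[0]} attributes, "
            f"table has {table.n_attributes}"
        )
    span = stats.maximum - stats.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.features - stats.minimum) / safe
    scaled[:, span == 0] = 0.0
    return replace(table, features=scaled)


def stratified_split(
    table: DecisionTable, class_counts_train: Mapping, seed: int
) -> tuple[DecisionTable, DecisionTable]:
    """Split into disjoint train/test with exact per-class training counts.

    Sampling is uniform without replacement within each class, driven by
    ``seed``; the same seed always yields the same split.  Classes absent
    from ``class_counts_train`` contribute 0 training samples.
    """
    rng = np.random.default_rng(seed)
    labels = table.label_array()
    train_idx: list[int] = []
    for lab in table.label_set:
        want = int(class_counts_train.get(lab, 0))
        pool = np.flatnonzero(labels == lab)
        if want > pool.size:
            raise ValueError(
                f"requested {want} training samples of class {lab!r}, "
                f"only {pool.size} available"
            )
        chosen = rng.choice(pool, size=want, replace=False)
        train_idx.extend(int(i) for i in chosen)
    train_idx = sorted(train_idx)
    test_idx = sorted(set(range(table.n_samples)) - set(train_idx))
    if not test_idx:
        raise ValueError("split leaves an empty test set")
    return table.take(train_idx), table.take(test_idx)
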