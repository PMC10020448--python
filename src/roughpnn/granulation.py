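"""Neighborhood granules and their class statistics.

The granule of a sample x under attribute subset B and radius delta is the
closed Euclidean ball

    [x]_B^delta = { y : || x|B - y|B || <= delta }

computed on min-max-scaled coordinates restricted to B.  Three statistics
of a granule drive the loss matrix downstream:

* ``p_x = |[x] ∩ X| / |[x]|`` — conditional probability of class X in the granule;
* ``s_x = |[x] ∩ X| / |X|`` — significance: the granule's share of class X's
  global mass;
* ``s_c = |[x] ∩ X^C| / |X^C|`` — the complement-class counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import DecisionTable


@dataclass(frozen=True)
class Granule:
    """Neighborhood class of one sample under attribute subset B."""

    center: int
    members: frozenset
    subset_B: frozenset
    radius_delta: float

    def __post_init__(self):
        if self.radius_delta < 0:
            raise ValueError("radius_delta must be >= 0")
        if self.center not in self.members:
            raise ValueError("granule must contain its own center")


@dataclass(frozen=True)
class GranuleStats:
    p_x: float
    s_x: float
    s_c: float

    def __post_init__(self):
        if not 0.0 <= self.p_x <= 1.0:
            raise ValueError("p_x outside [0,1]")
        if self.s_x < 0 or self.s_c < 0:
            raise ValueError("significance must be >= 0")


def _check_subset(table: DecisionTable, subset_B) -> list:
    B = list(subset_B)
    if not B:
        raise ValueError("attribute subset B must be non-empty")
    for a in B:
        table.column_of(a)  # raises KeyError on unknown label
    return B


def membership_matrix(
    table: DecisionTable, subset_B, radius_delta: float
) -> np.ndarray:
    """Boolean n x n matrix; row i marks the members of sample i's granule.

    Boundary ties (distance exactly delta) are included — a closed ball.
    This is the vectorised workhorse behind :func:`neighborhood` and
    :func:`granulate` and is what the risk computation consumes.
    """
    B = _check_subset(table, subset_B)
    if radius_delta < 0:
        raise ValueError("radius_delta must be >= 0")
    X = table.restrict(B)
    d = cdist(X, X, metric="euclidean")
    # guard against fp noise putting the self-distance above 0
    np.fill_diagonal(d, 0.0)
    return d <= radius_delta + 1e-12


def neighborhood(
    table: DecisionTable, subset_B, radius_delta: float, center: int
) -> Granule:
    """Granule [center]_B^delta of one sample."""
    M = membership_matrix(table, subset_B, radius_delta)
    return Granule(
        center=center,
        members=frozenset(int(i) for i in np.flatnonzero(M[center])),
        subset_B=frozenset(subset_B),
        radius_delta=float(radius_delta),
    )


def granulate(table: DecisionTable, subset_B, radius_delta: float) -> list[Granule]:
    """One granule per sample, in sample order."""
    M = membership_matrix(table, subset_B, radius_delta)
    fb = frozenset(subset_B)
    return [
        Granule(
            center=i,
            members=frozenset(int(j) for j in np.flatnonzero(M[i])),
            subset_B=fb,
            radius_delta=float(radius_delta),
        )
        for i in range(table.n_samples)
    ]


def granule_stats(granule: Granule, labels, target_class) -> GranuleStats:
    """Class statistics (p_x, s_x, s_c) of a granule for target class X.

    Requires both X and its complement to be globally non-empty, otherwise
    the significances are undefined.
    """
    y = np.asarray(labels, dtype=object)
    in_X = y == target_class
    n_X = int(in_X.sum())
    n_Xc = int(y.size - n_X)
    if n_X == 0 or n_Xc == 0:
        raise ValueError(f"class {target_class!r} or its complement is empty")
    mem = np.fromiter(granule.members, dtype=int)
    k = mem.size
    k_X = int(in_X[mem].sum())
    return GranuleStats(p_x=k_X / k, s_x=k_X / n_X, s_c=(k - k_X) / n_Xc)
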