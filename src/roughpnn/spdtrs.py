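"""Loss matrix, three-way regions, overall Bayes risk and attribute reduction.

The single-parameter decision-theoretic rough set (SPDTRS) replaces the six
hand-set losses of classical decision-theoretic rough sets with quantities
generated per granule from its class statistics and one compensation
coefficient xi (the decision-maker's tolerance of uncertainty, valid range
(0, 0.4]):

    lambda_PP = 0                    lambda_PN = s_c
    lambda_BP = s_x * (p_x - xi)     lambda_BN = s_c * (1 - p_x - xi)
    lambda_NP = s_x                  lambda_NN = 0

where p_x, s_x, s_c are the granule's conditional probability and the two
class significances.  The factors in lambda_BP / lambda_BN can go negative
(e.g. p_x < xi); they are clamped at 0 so that every loss stays
non-negative and the Bayes-risk ordering of actions is preserved.

Each sample is assigned to the positive / boundary / negative region by
comparing p_x with the granule-local Bayes-minimum-risk thresholds

    alpha = (l_PN - l_BN) / ((l_PN - l_BN) + (l_BP - l_PP))
    beta  = (l_BN - l_NN) / ((l_BN - l_NN) + (l_NP - l_BP))

and the overall risk of attribute subset B is the sum over regions of the
expected conditional losses.  A subset B is an attribute reduction when
(1) risk(B) does not exceed risk(C) and (2) every proper subset of B has
strictly greater risk than B.  Condition (1) is read as non-increase
rather than strict decrease: on a fully consistent table every pure
granulation has risk exactly 0, and strictness would make such tables
irreducible even when a single attribute reproduces the partition;
minimality (condition 2) supplies the strictness that matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import DecisionTable
from .granulation import GranuleStats, membership_matrix

XI_MAX = 0.4

# two risks within this (relative + absolute) band are treated as equal;
# risk sums differ in the last bits depending on summation order
_RISK_RTOL = 1e-9
_RISK_ATOL = 1e-12


def _risk_tol(reference: float) -> float:
    return _RISK_RTOL * abs(reference) + _RISK_ATOL


class DegenerateThresholds(ArithmeticError):
    """Raised when the threshold closed forms have a non-positive denominator.

    Callers fall back to a two-way split (empty boundary region) decided by
    direct expected-loss comparison of acceptance vs. rejection.
    """


@dataclass(frozen=True)
class LossMatrix:
    """The six losses of one granule's decision problem, plus xi."""

    lambda_pp: float
    lambda_bp: float
    lambda_np: float
    lambda_pn: float
    lambda_bn: float
    lambda_nn: float
    xi: float

    def __post_init__(self):
        for name in ("lambda_pp", "lambda_bp", "lambda_np", "lambda_pn",
                     "lambda_bn", "lambda_nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RegionAssignment:
    """Three-way partition of the universe for one target class."""

    pos: frozenset
    bnd: frozenset
    neg: frozenset
    target_class: object

    def __post_init__(self):
        if self.pos & self.bnd or self.pos & self.neg or self.bnd & self.neg:
            raise ValueError("regions must be pairwise disjoint")


@dataclass(frozen=True)
class ReductResult:
    """Outcome of attribute reduction.

    ``selected_B`` keeps selection order; ``trace`` records the accepted
    greedy steps as (attribute, risk-after-step) pairs, with removals
    recorded as negative attribute labels.  ``is_reduct`` is False when no
    subset satisfied risk(B) < risk(C) and the full set C was returned.
    """

    selected_B: tuple
    risk_B: float
    risk_C: float
    trace: tuple
    is_reduct: bool = True


def _validate_xi(xi: float) -> None:
    if xi <= 0:
        raise ValueError("xi must be > 0")
    if xi > XI_MAX:
        warnings.warn(
            f"xi={xi} outside the recommended range (0, {XI_MAX}]", stacklevel=3
        )


def loss_matrix(stats: GranuleStats, xi: float) -> LossMatrix:
    """Generate the granule-local loss matrix from (p_x, s_x, s_c) and xi."""
    _validate_xi(xi)
    return LossMatrix(
        lambda_pp=0.0,
        lambda_bp=max(stats.s_x * (stats.p_x - xi), 0.0),
        lambda_np=stats.s_x,
        lambda_pn=stats.s_c,
        lambda_bn=max(stats.s_c * (1.0 - stats.p_x - xi), 0.0),
        lambda_nn=0.0,
        xi=xi,
    )


def decision_thresholds(lm: LossMatrix) -> tuple[float, float]:
    """Bayes-minimum-risk thresholds (alpha, beta) for one loss matrix.

    Raises :class:`DegenerateThresholds` when a denominator is not positive
    or the thresholds cross (beta > alpha), i.e. when the three-way reading
    is ill-posed for this granule.
    """
    d_pn = lm.lambda_pn - lm.lambda_bn
    d_np = lm.lambda_np - lm.lambda_bp
    denom_a = d_pn + (lm.lambda_bp - lm.lambda_pp)
    denom_b = (lm.lambda_bn - lm.lambda_nn) + d_np
    if denom_a <= 0 or denom_b <= 0 or d_pn < 0 or d_np < 0:
        raise DegenerateThresholds("non-positive threshold denominator")
    alpha = d_pn / denom_a
    beta = (lm.lambda_bn - lm.lambda_nn) / denom_b
    if beta > alpha:
        raise DegenerateThresholds("thresholds cross (beta > alpha)")
    return alpha, beta


def _granule_arrays(M: np.ndarray, in_X: np.ndarray):
    """Vectorised (p, s_x, s_c) for every granule given membership matrix M."""
    n_X = int(in_X.sum())
    n_Xc = int(in_X.size - n_X)
    if n_X == 0 or n_Xc == 0:
        raise ValueError("target class or its complement is empty")
    size = M.sum(axis=1)
    k_X = M @ in_X.astype(float)
    p = k_X / size
    return p, k_X / n_X, (size - k_X) / n_Xc


def _regions_and_risk(M: np.ndarray, in_X: np.ndarray, xi: float):
    """Per-sample region codes (0=POS, 1=BND, 2=NEG) and risk terms."""
    p, s_x, s_c = _granule_arrays(M, in_X)
    l_bp = np.maximum(s_x * (p - xi), 0.0)
    l_bn = np.maximum(s_c * (1.0 - p - xi), 0.0)
    l_pn = s_c
    l_np = s_x

    d_pn = l_pn - l_bn
    d_np = l_np - l_bp
    denom_a = d_pn + l_bp
    denom_b = l_bn + d_np
    ok = (denom_a > 0) & (denom_b > 0) & (d_pn >= 0) & (d_np >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(ok, d_pn / np.where(denom_a > 0, denom_a, 1.0), np.nan)
        beta = np.where(ok, l_bn / np.where(denom_b > 0, denom_b, 1.0), np.nan)
    ok &= ~(beta > alpha)

    r_pos = (1.0 - p) * l_pn
    r_bnd = p * l_bp + (1.0 - p) * l_bn
    r_neg = p * l_np

    region = np.full(p.size, 1, dtype=int)
    # three-way where thresholds are well-posed; ties at alpha accept (POS)
    region[ok & (p >= alpha)] = 0
    region[ok & (p <= beta) & (p < alpha)] = 2
    # degenerate granules: two-way accept/reject by expected loss
    region[~ok & (r_pos <= r_neg)] = 0
    region[~ok & (r_pos > r_neg)] = 2

    risk_terms = np.choose(region, [r_pos, r_bnd, r_neg])
    return region, risk_terms


def assign_regions(
    table: DecisionTable,
    subset_B,
    radius_delta: float,
    xi: float,
    target_class=None,
) -> RegionAssignment:
    """Three-way regions of the universe for one target class.

    ``target_class`` defaults to the first class in the table's label set.
    Samples whose granule yields degenerate thresholds are split two-way
    (boundary region excluded) by direct expected-loss comparison.
    """
    _validate_xi(xi)
    if target_class is None:
        target_class = table.label_set[0]
    M = membership_matrix(table, subset_B, radius_delta)
    in_X = table.label_array() == target_class
    region, _ = _regions_and_risk(M, in_X, xi)
    return RegionAssignment(
        pos=frozenset(int(i) for i in np.flatnonzero(region == 0)),
        bnd=frozenset(int(i) for i in np.flatnonzero(region == 1)),
        neg=frozenset(int(i) for i in np.flatnonzero(region == 2)),
        target_class=target_class,
    )


def bayes_risk(
    table: DecisionTable,
    subset_B,
    radius_delta: float,
    xi: float,
    classes=None,
) -> float:
    """Overall Bayes risk of attribute subset B.

    Sums, over every sample, the expected conditional loss of the action
    its region prescribes.  With ``classes=None`` the risk is computed
    one-vs-rest for every nominal class and summed; pass a single-element
    sequence to target one class only.
    """
    _validate_xi(xi)
    M = membership_matrix(table, subset_B, radius_delta)
    y = table.label_array()
    if classes is None:
        classes = table.label_set
    total = 0.0
    for cls in classes:
        _, terms = _regions_and_risk(M, y == cls, xi)
        total += float(terms.sum())
    return total


def _risk_fn(table, radius_delta, xi, classes):
    cache: dict = {}

    def risk(subset) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = bayes_risk(table, sorted(key), radius_delta, xi, classes)
        return cache[key]

    return risk


def reduce_attributes(
    table: DecisionTable,
    xi: float,
    radius_delta: float,
    classes=None,
) -> ReductResult:
    """Greedy risk-minimising attribute reduction.

    Forward phase: start from the single attribute of minimal risk, then
    repeatedly add the attribute giving the largest strict risk decrease.
    If the forward phase stalls while still above the full set's risk, it
    keeps adding the least-risk attribute (plateau escape) until the full
    set's risk is matched — in the worst case B grows to C itself.
    Backward phase: repeatedly delete the attribute whose removal does not
    increase the risk (smallest resulting risk first).  Ties are broken by
    the lowest attribute label, so the procedure is deterministic.

    When the final subset is the full attribute set, no proper-subset
    reduction exists along the greedy path; the result carries
    ``is_reduct=False`` and a warning.
    """
    _validate_xi(xi)
    attrs = sorted(table.attribute_index)
    if len(attrs) < 2:
        raise ValueError("reduction needs at least 2 attributes")
    risk = _risk_fn(table, radius_delta, xi, classes)
    risk_C = risk(attrs)
    tol = _risk_tol(risk_C)

    # forward: best singleton, then largest strict decrease
    best_a = min(attrs, key=lambda a: (risk([a]), a))
    selected = [best_a]
    current = risk(selected)
    trace = [(best_a, current)]
    while True:
        candidates = [a for a in attrs if a not in selected]
        if not candidates:
            break
        scored = [(risk(selected + [a]), a) for a in candidates]
        new_risk, add = min(scored)
        if new_risk < current - tol or current > risk_C + tol:
            # strict improvement, or plateau escape while above risk(C)
            selected.append(add)
            current = new_risk
            trace.append((add, current))
        else:
            break

    # backward: drop attributes whose removal does not increase risk
    changed = True
    while changed and len(selected) > 1:
        changed = False
        scored = [
            (risk([b for b in selected if b != a]), a) for a in sorted(selected)
        ]
        new_risk, drop = min(scored)
        if new_risk <= current + tol:
            selected = [b for b in selected if b != drop]
            current = new_risk
            trace.append((-drop, current))
            changed = True

    if len(selected) < len(attrs) and current <= risk_C + tol:
        return ReductResult(
            selected_B=tuple(selected),
            risk_B=current,
            risk_C=risk_C,
            trace=tuple(trace),
            is_reduct=True,
        )
    warnings.warn(
        "no proper attribute subset with risk at most that of the full set "
        "was found; returning the full attribute set",
        stacklevel=2,
    )
    return ReductResult(
        selected_B=tuple(attrs),
        risk_B=risk_C,
        risk_C=risk_C,
        trace=tuple(trace),
        is_reduct=False,
    )


def exhaustive_reduct_oracle(
    table: DecisionTable,
    xi: float,
    radius_delta: float,
    max_attributes: int = 10,
    classes=None,
) -> ReductResult:
    """Exhaustive-search reduct for small tables (test oracle).

    Enumerates every non-empty proper attribute subset, keeps those
    satisfying both reduction conditions — risk(B) no greater than risk(C)
    and risk(A) strictly greater than risk(B) for every proper subset A of
    B — and returns the admissible subset of minimal risk (ties: smaller
    size, then lexicographically smallest labels).  Refuses tables with
    more than ``max_attributes`` attributes.
    """
    _validate_xi(xi)
    attrs = sorted(table.attribute_index)
    k = len(attrs)
    if k > max_attributes or max_attributes > 10:
        raise ValueError(
            f"exhaustive search limited to min(max_attributes, 10) attributes, got {k}"
        )
    risk = _risk_fn(table, radius_delta, xi, classes)
    risk_C = risk(attrs)
    tol = _risk_tol(risk_C)
    risks = {
        frozenset(B): risk(list(B))
        for r in range(1, k + 1)
        for B in combinations(attrs, r)
    }

    admissible = []
    for B, r_B in risks.items():
        if len(B) == k or r_B > risk_C + tol:
            continue
        if all(
            risks[frozenset(A)] > r_B + _risk_tol(r_B)
            for r in range(1, len(B))
            for A in combinations(sorted(B), r)
        ):
            admissible.append((r_B, len(B), tuple(sorted(B))))
    if not admissible:
        return ReductResult(
            selected_B=tuple(attrs),
            risk_B=risk_C,
            risk_C=risk_C,
            trace=(),
            is_reduct=False,
        )
    r_B, _, B = min(admissible)
    return ReductResult(
        selected_B=B, risk_B=r_B, risk_C=risk_C, trace=(), is_reduct=True
    )
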