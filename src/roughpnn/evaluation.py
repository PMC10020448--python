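"""Confusion metrics, proportion confidence intervals, and parameter sweeps.

The sweep helpers reproduce the two protocol experiments of the pipeline:
a grid over the compensation coefficient xi (reduction re-run per value,
classifier fixed) and a grid over the PNN smoothing factor SPREAD
(attribute subset fixed, classifier re-fit per value).  Wall-clock timings
are recorded in the records for reporting but are hardware-dependent and
never asserted on.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .data import DecisionTable, apply_scaling, fit_scaling, stratified_split
from .pnn import fit as fit_pnn
from .spdtrs import ReductResult, reduce_attributes

DEFAULT_XI_GRID = tuple(np.round(np.arange(0.05, 0.401, 0.05), 2))
DEFAULT_SPREAD_GRID = tuple(np.round(np.arange(0.50, 1.551, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: object

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConfusionReport:
    """Confusion counts plus derived proportions and an accuracy CI.

    ``precision``/``recall`` are ``None`` when their ratio is undefined
    (empty denominator), never silently 0.  ``elapsed_seconds`` is logged
    wall-clock time; it is reported but carries no contract.
    """

    counts: ConfusionCounts
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    elapsed_seconds: float = 0.0


def confusion(y_true: Sequence, y_pred: Sequence, positive_class) -> ConfusionCounts:
    """Exact confusion counts with a declared positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty outcome vectors")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, positive_class=positive_class)


def metrics(counts: ConfusionCounts):
    """(accuracy, precision, recall); undefined ratios come back as None."""
    n = counts.n
    if n < 1:
        raise ValueError("no evaluated samples")
    accuracy = (counts.tp + counts.tn) / n
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    return accuracy, precision, recall


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0,1]."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def report(
    y_true, y_pred, positive_class, level: float = 0.95, elapsed: float = 0.0
) -> ConfusionReport:
    """Full confusion report: counts, metrics and an accuracy Wilson CI."""
    counts = confusion(y_true, y_pred, positive_class)
    accuracy, precision, recall = metrics(counts)
    lo, hi = proportion_ci(counts.tp + counts.tn, counts.n, level)
    return ConfusionReport(
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        ci_low=lo,
        ci_high=hi,
        ci_level=level,
        elapsed_seconds=elapsed,
    )


def evaluate_split(
    train: DecisionTable,
    test: DecisionTable,
    selected_B,
    sigma: float,
    positive_class=None,
) -> dict:
    """Fit a PNN on the training split restricted to ``selected_B`` and
    report train/test confusion metrics.

    The classifier sees the features in their native units: the SPREAD
    grid of the protocol (and its 0.75 operating point) is calibrated to
    raw feature scales, not to a [0,1] remapping.  Only the granulation
    stage normalises.  The positive class defaults to the first declared
    label.
    """
    if positive_class is None:
        positive_class = train.label_set[0]
    tr = train.select_attributes(selected_B)
    te = test.select_attributes(selected_B)
    model = fit_pnn(tr, sigma)

    t0 = time.perf_counter()
    pred_tr = model.predict_table(tr)
    train_elapsed = time.perf_counter() - t0
    t0 = time.perf_counter()
    pred_te = model.predict_table(te)
    test_elapsed = time.perf_counter() - t0

    return {
        "train": report(tr.labels, pred_tr, positive_class, elapsed=train_elapsed),
        "test": report(te.labels, pred_te, positive_class, elapsed=test_elapsed),
        "model": model,
    }


def evaluate(
    table: DecisionTable,
    train_counts,
    seed: int,
    xi: float,
    radius_delta: float,
    sigma: float,
    positive_class=None,
) -> dict:
    """End-to-end pipeline: split, reduce on the training split, classify.

    Returns a dict with the split, the :class:`ReductResult` and the
    train/test :class:`ConfusionReport` objects.  Attribute reduction runs
    on the training split only (scaled with training statistics), so the
    held-out split never informs the selection.
    """
    train, test = stratified_split(table, train_counts, seed)
    stats = fit_scaling(train)
    reduct = reduce_attributes(apply_scaling(stats, train), xi, radius_delta)
    out = evaluate_split(train, test, reduct.selected_B, sigma, positive_class)
    out["reduct"] = reduct
    out["train_table"], out["test_table"] = train, test
    return out


def sweep_xi(
    table: DecisionTable,
    xi_grid=DEFAULT_XI_GRID,
    radius_delta: float = 0.15,
    sigma: float = 0.75,
    seed: int = 0,
    train_counts=None,
) -> list[dict]:
    """Reduction + classification for every xi on a fixed train/test split.

    One record per xi: selected attributes, reduct size, train/test
    accuracy and elapsed prediction time.
    """
    if len(xi_grid) == 0:
        raise ValueError("xi grid must be non-empty")
    if train_counts is None:
        counts = table.class_counts()
        train_counts = {lab: int(round(0.7 * c)) for lab, c in counts.items()}
    train, test = stratified_split(table, train_counts, seed)
    stats = fit_scaling(train)
    scaled_train = apply_scaling(stats, train)
    records = []
    for xi in xi_grid:
        t0 = time.perf_counter()
        reduct = reduce_attributes(scaled_train, float(xi), radius_delta)
        res = evaluate_split(train, test, reduct.selected_B, sigma)
        records.append(
            {
                "xi": float(xi),
                "dim": len(reduct.selected_B),
                "selected": reduct.selected_B,
                "train_acc": res["train"].accuracy,
                "test_acc": res["test"].accuracy,
                "elapsed_s": time.perf_counter() - t0,
            }
        )
    return records


def sweep_spread(
    train: DecisionTable,
    test: DecisionTable,
    selected_B,
    spread_grid=DEFAULT_SPREAD_GRID,
) -> list[dict]:
    """Classification at every SPREAD value with the attribute subset fixed."""
    if len(spread_grid) == 0:
        raise ValueError("spread grid must be non-empty")
    records = []
    for sigma in spread_grid:
        t0 = time.perf_counter()
        res = evaluate_split(train, test, selected_B, float(sigma))
        records.append(
            {
                "sigma": float(sigma),
                "train_acc": res["train"].accuracy,
                "test_acc": res["test"].accuracy,
                "elapsed_s": time.perf_counter() - t0,
            }
        )
    return records


def records_to_csv(records: list[dict], path) -> None:
    """Write sweep records as CSV with a stable header."""
    import pandas as pd

    df = pd.DataFrame(records)
    if "selected" in df.columns:
        df["selected"] = df["selected"].map(lambda s: " ".join(map(str, s)))
    df.to_csv(path, index=False)
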