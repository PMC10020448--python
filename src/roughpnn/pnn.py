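"""Probabilistic neural network: a Parzen-kernel Bayes classifier.

The network stores every training vector (lazy learner, no iterative
optimisation).  For a query x the pattern layer evaluates a Gaussian
kernel on each stored vector x_ij of class i,

    psi_ij(x) = (2 pi)^(-b/2) sigma^(-b) exp(-||x - x_ij||^2 / (2 sigma^2)),

the summation layer averages the kernels within each class,

    g_i(x) = (1 / c_i) sum_j psi_ij(x),

and the output layer predicts argmax_i p_i * g_i(x) with empirical priors
p_i = c_i / n.  The smoothing factor sigma (the SPREAD) controls the
bandwidth: as sigma -> 0 the rule approaches 1-nearest-neighbour, large
sigma approaches the prior.

Kernels are accumulated in the log domain so that predictions survive
large dimension b or tiny sigma, where the naive product of a vanishing
normalisation constant and a vanishing exponential underflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .data import DecisionTable


@dataclass(frozen=True)
class PNN:
    """Fitted probabilistic neural network.

    Attributes
    ----------
    vectors : ndarray
        All n training vectors, n x b, in scaled feature units.
    class_labels : tuple
        Class label order; class i refers to ``class_labels[i]``.
    class_index : ndarray
        Per-training-vector class position into ``class_labels``.
    sigma : float
        Gaussian smoothing factor (SPREAD), in the units of ``vectors``.
    """

    vectors: np.ndarray
    class_labels: tuple
    class_index: np.ndarray
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != self.class_index.size:
            raise ValueError("vectors/class_index shape mismatch")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def b(self) -> int:
        return self.vectors.shape[1]

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.class_index, minlength=len(self.class_labels))

    @property
    def priors(self) -> np.ndarray:
        return self.class_counts / self.n

    # ---- layers ----------------------------------------------------------

    def _check_queries(self, x) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != self.b:
            raise ValueError(f"query dimension {X.shape[1]} != model dimension {self.b}")
        return X

    def _log_pattern(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(X, self.vectors, metric="sqeuclidean")
        const = -0.5 * self.b * np.log(2.0 * np.pi) - self.b * np.log(self.sigma)
        return const - d2 / (2.0 * self.sigma**2)

    def pattern_outputs(self, x) -> np.ndarray:
        """Kernel values psi_ij(x) for one query, in training-vector order."""
        X = self._check_queries(x)
        if X.shape[0] != 1:
            raise ValueError("pattern_outputs takes a single query vector")
        return np.exp(self._log_pattern(X)[0])

    def class_scores(self, x) -> dict:
        """Per-class (g_i, p_i * g_i) for one query."""
        psi = self.pattern_outputs(x)
        out = {}
        counts = self.class_counts
        for i, lab in enumerate(self.class_labels):
            g = psi[self.class_index == i].mean() if counts[i] else 0.0
            out[lab] = (g, counts[i] / self.n * g)
        return out

    def _log_scores(self, X: np.ndarray) -> np.ndarray:
        """log(p_i * g_i) per query and class, computed stably."""
        lp = self._log_pattern(X)
        scores = np.full((X.shape[0], len(self.class_labels)), -np.inf)
        for i in range(len(self.class_labels)):
            cols = self.class_index == i
            if cols.any():
                # log(p_i g_i) = logsumexp(psi over class) - log n
                scores[:, i] = logsumexp(lp[:, cols], axis=1) - np.log(self.n)
        return scores

    def predict(self, x):
        """Predicted class label(s); ties go to the lowest class index."""
        X = self._check_queries(x)
        idx = np.argmax(self._log_scores(X), axis=1)
        labels = [self.class_labels[i] for i in idx]
        return labels[0] if np.asarray(x).ndim == 1 else labels

    def predict_table(self, table: DecisionTable) -> list:
        return self.predict_matrix(table.features)

    def predict_matrix(self, X: np.ndarray) -> list:
        X = self._check_queries(X)
        idx = np.argmax(self._log_scores(X), axis=1)
        return [self.class_labels[i] for i in idx]


def fit(train: DecisionTable, sigma: float) -> PNN:
    """Store the training table as a PNN with smoothing factor ``sigma``.

    Every declared class must be non-empty; sigma must be positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    counts = train.class_counts()
    empty = [lab for lab, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty training class(es): {empty}")
    labels = tuple(train.label_set)
    pos = {lab: i for i, lab in enumerate(labels)}
    return PNN(
        vectors=np.array(train.features, dtype=float),
        class_labels=labels,
        class_index=np.array([pos[y] for y in train.labels], dtype=int),
        sigma=float(sigma),
    )
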