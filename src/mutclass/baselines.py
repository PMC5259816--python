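"""Comparison classifiers: k-nearest neighbors and naïve Bayes, plus an
optional linear-kernel SVM adapter.

KNN supports the two similarity measures common in gene-data analysis —
Euclidean distance and Pearson correlation (default, with neighborhood
size 4).  Voting is plain majority; vote ties go to the smallest class
index and distance ties to the earliest training sample.

The naïve Bayes model treats each gene as a class-conditional Bernoulli
variable with add-one (Laplace) smoothing.  Its prior is unusual: the
average fraction of non-zero elements in each class's samples, i.e. a
per-class mutation density rather than a class frequency.  These
densities do not sum to one across classes, so they are renormalized
before use (the argmax is invariant to the common scale; normalization
just keeps the log-posteriors interpretable) and the raw values are kept
on the model for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class KnnConfig:
    """Similarity measure ('euclidean' or 'pearson') and neighbor count."""

    metric: str = "pearson"
    k: int = 4

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "pearson"):
            raise ValueError("metric must be 'euclidean' or 'pearson'")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _pearson_rows(train_x: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Correlation of ``x`` with each training row; zero-variance rows
    correlate 0 by convention (logged)."""
    xc = x - x.mean()
    tc = train_x - train_x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc ** 2).sum())
    t_norm = np.sqrt((tc ** 2).sum(axis=1))
    degenerate = (t_norm == 0) | (x_norm == 0)
    if degenerate.any():
        logger.info("zero-variance vector(s) in correlation; defined 0")
    denom = t_norm * x_norm
    denom[degenerate] = 1.0
    corr = (tc @ xc) / denom
    corr[degenerate] = 0.0
    return corr


def knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, x: np.ndarray, cfg: KnnConfig
) -> int:
    """Classify one sample by majority vote over its k nearest training
    samples (smallest Euclidean distances or largest correlations)."""
    train_x = np.asarray(train_x, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    if cfg.k > len(train_y):
        raise ValueError(f"k={cfg.k} exceeds {len(train_y)} training samples")
    if cfg.metric == "euclidean":
        score = ((train_x - x) ** 2).sum(axis=1)  # ascending = nearest
    else:
        score = -_pearson_rows(train_x, x)  # ascending = most correlated
    # stable sort: ties resolved by training-sample order
    neighbors = np.argsort(score, kind="stable")[: cfg.k]
    votes = np.bincount(train_y[neighbors])
    return int(np.argmax(votes))  # argmax takes the smallest class on ties


class KnnClassifier:
    """Fit/predict wrapper around :func:`knn_predict`."""

    def __init__(self, cfg: KnnConfig | None = None):
        self.cfg = cfg or KnnConfig()

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "KnnClassifier":
        self._x = np.asarray(features, dtype=np.float64)
        self._y = np.asarray(labels, dtype=np.int64)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.array(
            [knn_predict(self._x, self._y, row, self.cfg) for row in np.atleast_2d(features)]
        )


@dataclass
class NbModel:
    """Per-class Bernoulli rates (smoothed) and the density-based prior."""

    priors: np.ndarray          # normalized to sum 1
    raw_priors: np.ndarray      # per-class mean non-zero fraction, as fitted
    rates: np.ndarray           # (n_classes, n_genes), in (0, 1)
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


def nb_fit(train_x: np.ndarray, train_y: np.ndarray) -> NbModel:
    """Fit the Bernoulli naïve Bayes model.

    Rates use add-one smoothing, ``(count + 1)/(n_c + 2)``; the prior of
    class c is the mean non-zero fraction of its training samples,
    renormalized across classes.
    """
    train_x = np.asarray(train_x, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    classes = np.arange(1, train_y.max() + 1)
    absent = [int(c) for c in classes if (train_y == c).sum() == 0]
    if absent:
        raise ValueError(f"no training samples for class(es) {absent}")
    rates, raw_priors = [], []
    for c in classes:
        xc = train_x[train_y == c]
        rates.append((xc.sum(axis=0) + 1.0) / (len(xc) + 2.0))
        raw_priors.append(float((xc != 0).mean()))
    raw_priors = np.array(raw_priors)
    total = raw_priors.sum()
    priors = raw_priors / total if total > 0 else np.full(len(classes), 1.0 / len(classes))
    return NbModel(priors=priors, raw_priors=raw_priors,
                   rates=np.array(rates), classes=classes)


def nb_predict(model: NbModel, x: np.ndarray) -> int:
    """argmax over classes of log prior + Σ_g log Bernoulli likelihood."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.rates.shape[1],):
        raise ValueError(f"sample has shape {x.shape}, expected ({model.rates.shape[1]},)")
    log_like = (x * np.log(model.rates) + (1 - x) * np.log1p(-model.rates)).sum(axis=1)
    posterior = np.log(model.priors) + log_like
    return int(model.classes[np.argmax(posterior)])


class NbClassifier:
    """Fit/predict wrapper around :func:`nb_fit` / :func:`nb_predict`."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "NbClassifier":
        self.model = nb_fit(features, labels)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.array([nb_predict(self.model, row) for row in np.atleast_2d(features)])


class SvmClassifier:
    """Optional adapter over scikit-learn's SVC with a linear kernel (the
    kernel recommended for high-dimensional gene features); hyperparameter
    grids are the caller's concern."""

    def __init__(self, c: float = 4.0, gamma: float = 0.0313):
        from sklearn.svm import SVC  # deferred: only needed when used

        self._svc = SVC(kernel="linear", C=c, gamma=gamma)

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "SvmClassifier":
        self._svc.fit(np.asarray(features), np.asarray(labels, dtype=np.int64))
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.atleast_2d(features)).astype(np.int64)
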