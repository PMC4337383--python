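"""Per-time-bin linear-classifier decoding of stimulus identity.

An independent soft-margin linear support-vector classifier is assigned to
each 100 ms bin and fed raw 60-dimensional spike-count vectors (no
scaling; classification is an inner product with the learned boundary,
one-vs-one voting for more than two classes).  The train/test protocol is
repeated random subsampling: a stratified 70/30 split redrawn 50 times,
reporting per-bin mean accuracy with its SEM over repeats.  Statistical
significance comes from a label-shuffle null: labels permuted uniformly,
the decoder trained and tested once per permutation, and per-bin accuracy
percentiles recorded as the null band (chance is 1/K for K equiprobable
stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .errors import ConfigError, DataError


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 3:
        raise DataError("X must be (n_trials, n_bins, n_features)")
    if len(y) != X.shape[0]:
        raise DataError("one label per trial required")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("decoding requires at least 2 stimulus classes")
    if counts.min() < 2:
        raise DataError("decoding requires at least 2 trials per class")
    return X, y


def _split(y: np.ndarray, train_frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(y))
    # stratified so that every class appears in both partitions
    train, test = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)


def _fit_bin(Xb: np.ndarray, y: np.ndarray, C: float) -> SVC:
    # libsvm linear machine; one-vs-one voting for K > 2, with vote ties
    # resolved toward the lowest class label (sklearn's argmax order)
    return SVC(kernel="linear", C=C).fit(Xb, y)


@dataclass
class DecoderSeries:
    """Per-bin summary of the repeated-subsampling decoder array."""

    train_mean: np.ndarray
    train_sem: np.ndarray
    test_mean: np.ndarray
    test_sem: np.ndarray
    chance_rate: float
    n_repeats: int
    bin_edges: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.test_mean)

    def to_dict(self) -> dict:
        d = {
            "train_mean": self.train_mean.tolist(),
            "train_sem": self.train_sem.tolist(),
            "test_mean": self.test_mean.tolist(),
            "test_sem": self.test_sem.tolist(),
            "chance_rate": self.chance_rate,
            "n_repeats": self.n_repeats,
        }
        if self.bin_edges is not None:
            d["bin_edges_ms"] = np.asarray(self.bin_edges).tolist()
        return d


@dataclass
class NullBand:
    """Label-shuffle null distribution of per-bin test accuracy."""

    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    accuracies: np.ndarray  # (n_shuffles, n_bins)
    percentiles: tuple[float, float]

    @property
    def overall_mean(self) -> float:
        return float(self.accuracies.mean())

    def to_dict(self) -> dict:
        return {
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "mean": self.mean.tolist(),
            "percentiles": list(self.percentiles),
            "n_shuffles": int(self.accuracies.shape[0]),
        }


@dataclass
class TrialTrace:
    """Per-bin prediction and hit/miss flags for one trial."""

    predicted: np.ndarray
    true_label: object
    hits: np.ndarray  # boolean per bin


class DecoderArray:
    """Array of independent per-bin linear classifiers.

    Parameters
    ----------
    train_frac : fraction of trials used for training in each repeat.
    n_repeats : number of stratified random subsamplings.
    C : soft-margin penalty of the linear machine.
    random_state : seed controlling all partitions.
    """

    def __init__(self, train_frac: float = 0.7, n_repeats: int = 50, C: float = 1.0,
                 random_state: int | None = None):
        if not 0 < train_frac < 1:
            raise ConfigError("train_frac must lie in (0, 1)")
        if n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        self.train_frac = train_frac
        self.n_repeats = n_repeats
        self.C = C
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray, bin_edges: np.ndarray | None = None
            ) -> "DecoderArray":
        """Train the per-bin machines under repeated random subsampling."""
        X, y = _check_xy(X, y)
        rng = np.random.default_rng(self.random_state)
        n_trials, n_bins, _ = X.shape
        self.classes_ = np.unique(y)
        self.chance_rate_ = 1.0 / len(self.classes_)
        self.bin_edges_ = bin_edges
        self._X, self._y = X, y

        self.models_: list[list[SVC]] = []
        self.splits_: list[tuple[np.ndarray, np.ndarray]] = []
        self.test_predictions_: list[np.ndarray] = []  # (n_test, n_bins) per repeat
        train_acc = np.empty((self.n_repeats, n_bins))
        test_acc = np.empty((self.n_repeats, n_bins))

        for r in range(self.n_repeats):
            seed = int(rng.integers(2**31))
            tr, te = _split(y, self.train_frac, seed)
            models = []
            preds = np.empty((len(te), n_bins), dtype=y.dtype)
            for b in range(n_bins):
                m = _fit_bin(X[tr, b, :], y[tr], self.C)
                models.append(m)
                train_acc[r, b] = np.mean(m.predict(X[tr, b, :]) == y[tr])
                p = m.predict(X[te, b, :])
                preds[:, b] = p
                test_acc[r, b] = np.mean(p == y[te])
            self.models_.append(models)
            self.splits_.append((tr, te))
            self.test_predictions_.append(preds)

        self.train_acc_ = train_acc
        self.test_acc_ = test_acc
        sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(self.n_repeats) if self.n_repeats > 1 \
            else np.zeros(a.shape[1])
        self.series_ = DecoderSeries(
            train_mean=train_acc.mean(axis=0),
            train_sem=sem(train_acc),
            test_mean=test_acc.mean(axis=0),
            test_sem=sem(test_acc),
            chance_rate=self.chance_rate_,
            n_repeats=self.n_repeats,
            bin_edges=bin_edges,
        )
        return self

    @property
    def series(self) -> DecoderSeries:
        self._require_fit()
        return self.series_

    def _require_fit(self) -> None:
        if not hasattr(self, "models_"):
            raise DataError("decoder array is not fitted")

    def score_trials(self, X2: np.ndarray, y2: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Cross-condition accuracy: apply every repeat's trained machines
        to an independent trial set (no retraining).

        Returns per-bin ``(mean, sem)`` over repeats.
        """
        self._require_fit()
        X2 = np.asarray(X2, dtype=float)
        y2 = np.asarray(y2)
        if X2.ndim != 3 or X2.shape[1] != len(self.models_[0]):
            raise DataError("trial set does not match the fitted bin grid")
        acc = np.empty((self.n_repeats, X2.shape[1]))
        for r, models in enumerate(self.models_):
            for b, m in enumerate(models):
                acc[r, b] = np.mean(m.predict(X2[:, b, :]) == y2)
        sem = acc.std(axis=0, ddof=1) / np.sqrt(self.n_repeats) if self.n_repeats > 1 \
            else np.zeros(acc.shape[1])
        return acc.mean(axis=0), sem

    def trial_trace(self, x: np.ndarray, true_label, repeat: int = 0) -> TrialTrace:
        """Per-bin prediction of one repeat's machines on a single trial."""
        self._require_fit()
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[0] != len(self.models_[repeat]):
            raise DataError("trial does not match the fitted bin grid")
        preds = np.array([m.predict(x[b][None, :])[0]
                          for b, m in enumerate(self.models_[repeat])])
        return TrialTrace(predicted=preds, true_label=true_label, hits=preds == true_label)


def train_decoder_array(
    X: np.ndarray,
    y: np.ndarray,
    split: float = 0.7,
    repeats: int = 50,
    C: float = 1.0,
    seed: int | None = None,
    bin_edges: np.ndarray | None = None,
) -> DecoderArray:
    """Functional entry point: fit a :class:`DecoderArray` on count vectors."""
    return DecoderArray(train_frac=split, n_repeats=repeats, C=C, random_state=seed).fit(
        X, y, bin_edges=bin_edges
    )


def shuffle_null(
    X: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 200,
    percentiles: tuple[float, float] = (5.0, 95.0),
    train_frac: float = 0.7,
    C: float = 1.0,
    seed: int | None = None,
) -> NullBand:
    """Label-shuffle null: per permutation, one stratified 70/30 split, one
    train/test pass per bin; per-bin percentiles of test accuracy form the
    band.  The mean across shuffles approximates the 1/K chance rate."""
    X, y = _check_xy(X, y)
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = X.shape[1]
    acc = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        y_perm = rng.permutation(y)
        tr, te = _split(y_perm, train_frac, int(rng.integers(2**31)))
        for b in range(n_bins):
            m = _fit_bin(X[tr, b, :], y_perm[tr], C)
            acc[s, b] = np.mean(m.predict(X[te, b, :]) == y_perm[te])
    lo, hi = percentiles
    return NullBand(
        lower=np.percentile(acc, lo, axis=0),
        upper=np.percentile(acc, hi, axis=0),
        mean=acc.mean(axis=0),
        accuracies=acc,
        percentiles=(lo, hi),
    )
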