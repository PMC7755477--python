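"""Log-variance band-power features and the RBF-SVM classification regime.

A spatial filter bank turns a trial X (channels x samples) into Z = W X;
the feature of filter p is the log of its variance *share*,

    f_p = log( var_p / sum_q var_q ),

so exp(f) sums to 1 per trial and the features are invariant to any global
amplitude scaling of the EEG.  Variances are population variances about the
row mean.  Classification is a Gaussian-kernel SVM on z-scored features with
hyperparameters picked by stratified 5-fold cross-validation over a fixed
logarithmic grid (degrading to leave-one-out below 5 samples per class),
deterministic given a fold seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .csp import FilterBank
from .errors import ConfigurationError, DataError
from .synthetic import EpochSet

#: Hyperparameter grids: C in 10^-1..10^3, kernel gamma in (10^-2..10^2)/d.
C_GRID = np.logspace(-1, 3, 5)
GAMMA_GRID = np.logspace(-2, 2, 5)


@dataclass
class FeatureTable:
    """Per-trial normalized log-variance features (+ optional labels)."""

    features: np.ndarray  # (n_trials, n_filters)
    labels: np.ndarray | None = None
    filter_provenance: FilterBank | None = None


@dataclass
class ClassifierModel:
    """A trained RBF-SVM with its standardization constants."""

    scaler: StandardScaler
    svc: SVC
    c: float
    gamma: float
    classes: np.ndarray
    n_features: int


def project(bank: FilterBank, epochs) -> np.ndarray:
    """Apply the bank to every trial: Z[i] = W @ X[i].

    Accepts an :class:`EpochSet` or a raw (trials, channels, samples) array;
    returns (trials, n_filters, samples).
    """
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if data.ndim == 2:
        data = data[None]
    if data.shape[1] != bank.n_channels:
        raise ValueError(
            f"bank expects {bank.n_channels} channels, data has {data.shape[1]}"
        )
    return np.einsum("fc,ics->ifs", bank.filters, data)


def row_variances(z: np.ndarray) -> np.ndarray:
    """Population variance of each projected row; (..., n_filters)."""
    return np.asarray(z).var(axis=-1)


def logvar_from_variances(var: np.ndarray) -> np.ndarray:
    """Normalized log-variance features from precomputed row variances."""
    var = np.atleast_2d(np.asarray(var, dtype=float))
    total = var.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DataError("all-zero projection: cannot form log variance shares")
    return np.log(var / total)


def logvar_features(z_per_trial: np.ndarray) -> np.ndarray:
    """Features f_p = log(var_p / sum var) for one trial (2-D Z) or a batch."""
    z = np.asarray(z_per_trial)
    if z.shape[-1] < 2:
        raise DataError("each projected row needs >= 2 samples for a variance")
    single = z.ndim == 2
    out = logvar_from_variances(row_variances(z))
    return out[0] if single else out


def extract_features(bank: FilterBank, epochs, labels=None) -> FeatureTable:
    """Project epochs through the bank and build the feature table."""
    if isinstance(epochs, EpochSet) and labels is None:
        labels = epochs.labels
    feats = logvar_features(project(bank, epochs))
    return FeatureTable(np.atleast_2d(feats), labels, bank)


def _cv_splitter(labels: np.ndarray, seed: int):
    _, counts = np.unique(labels, return_counts=True)
    mc = int(counts.min())
    if mc < 2:
        raise DataError(
            "every class needs >= 2 training samples for cross-validation"
        )
    if mc < 5:
        warnings.warn(
            f"only {mc} samples in the smallest class: degrading "
            "hyperparameter search from 5-fold CV to leave-one-out",
            stacklevel=3,
        )
        return LeaveOneOut()
    return StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)


def train_classifier(train: FeatureTable, seed: int = 0) -> ClassifierModel:
    """Fit the SVM: z-score, grid-search (C, gamma) by CV, refit on all data."""
    x = np.asarray(train.features, dtype=float)
    y = np.asarray(train.labels)
    if x.ndim != 2 or len(y) != len(x):
        raise ConfigurationError("features must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError("training data must contain >= 2 classes")
    splitter = _cv_splitter(y, seed)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    d = x.shape[1]
    best = (-1.0, None, None)
    for c in C_GRID:
        for g in GAMMA_GRID * (1.0 / d):
            correct = 0
            for tr, te in splitter.split(xs, y):
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(xs[tr], y[tr])
                correct += int((clf.predict(xs[te]) == y[te]).sum())
            if correct > best[0]:  # strict: first grid point wins ties
                best = (correct, c, g)
    _, c, g = best
    svc = SVC(C=c, gamma=g, kernel="rbf").fit(xs, y)
    return ClassifierModel(scaler, svc, float(c), float(g), classes, d)


def predict(model: ClassifierModel, test: FeatureTable) -> np.ndarray:
    """Predict one label per feature row, applying stored standardization."""
    x = np.asarray(test.features, dtype=float)
    if x.size == 0:
        return np.asarray([], dtype=model.classes.dtype)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got shape {x.shape}"
        )
    return model.svc.predict(model.scaler.transform(x))
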