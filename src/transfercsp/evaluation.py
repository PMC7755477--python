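"""Pipeline orchestration, inverted cross-validation and baselines.

The full transfer scheme: build a CSP bank from *source*-task trials, select
transferable filters on a handful of *target*-task training trials by Fisher
ratio, extract log-variance features, train the RBF-SVM, predict.  Two
baselines frame it: plain CSP trained on the target trials alone (the m most
extreme filters of its own bank) and band-power PSD features at C3/Cz/C4.

Evaluation uses the *inverted* 12-fold protocol repeated 5 times: each fold
serves once as the training set (1/12 of the target session, i.e. 5 trials
per class at 60 per class) and the remaining 11/12 are test data --
modelling a BCI user who records only a few calibration trials of a new
combined command.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .csp import (ANALYSIS_WINDOW_S, FilterBank, analysis_window,
                  covariance_pair, csp_filters, spatial_patterns)
from .errors import ConfigurationError, DataError, PipelineStageError
from .features import (FeatureTable, extract_features, logvar_from_variances,
                       predict, project, row_variances, train_classifier)
from .synthetic import BAND_HZ, EpochSet
from .transfer import select_filters_from_features, select_transfer_filters

#: Source-task pairing rules for the combined-command classifications: the
#: source pair is the most similar single-limb pair (domain-adaptation
#: standard).  Arbitrary TaskSpec pairings remain allowed.
DEFAULT_PAIRINGS: dict[tuple[str, str], tuple[str, str]] = {
    ("LH&F", "RH&F"): ("LH", "RH"),
    ("LH&RH", "RH&F"): ("F", "RH"),
    ("LH&RH", "LH&F"): ("F", "LH"),
}

PSD_CHANNELS = ("C3", "Cz", "C4")


@dataclass(frozen=True)
class TaskSpec:
    """A source-pair / target-pair classification task."""

    source_classes: tuple[str, str]
    target_classes: tuple[str, str]
    pairing_rationale: str = ""

    def __post_init__(self):
        if self.source_classes[0] == self.source_classes[1]:
            raise ConfigurationError("source class pair must be distinct")
        if self.target_classes[0] == self.target_classes[1]:
            raise ConfigurationError("target class pair must be distinct")


def default_task(target_classes: tuple[str, str]) -> TaskSpec:
    """Look up the default source pairing for a target pair."""
    key = tuple(target_classes)
    pair = DEFAULT_PAIRINGS.get(key) or DEFAULT_PAIRINGS.get(key[::-1])
    if pair is None:
        raise ConfigurationError(
            f"no default source pairing for target {target_classes}; "
            "supply a TaskSpec explicitly"
        )
    return TaskSpec(pair, key, "most similar single-limb pair")


@dataclass
class PipelineResult:
    predictions: np.ndarray
    bank: FilterBank  # transferred (reduced) bank
    source_bank: FilterBank  # full source bank
    fisher_report: object
    patterns: object  # PatternMap of the transferred filters
    model: object
    train_features: FeatureTable
    test_features: FeatureTable | None


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError(name, e) from e


def run_transfer_pipeline(source: EpochSet, target_train: EpochSet,
                          target_test: EpochSet | None,
                          k_per_group: int = 2, selection: str = "per_group",
                          window_s=ANALYSIS_WINDOW_S, shrinkage="auto",
                          seed: int = 0) -> PipelineResult:
    """Execute the full transfer scheme and return predictions + artifacts."""
    src = analysis_window(source, window_s)
    classes = tuple(np.unique(src.labels))
    if len(classes) != 2:
        raise ConfigurationError(
            f"source data must contain exactly 2 classes, got {classes}"
        )
    pair = _stage("class_covariance", covariance_pair, src, *classes,
                  window_s=None)
    bank = _stage("csp_filters", csp_filters, pair, shrinkage)
    tbank, freport = _stage("select_transfer_filters", select_transfer_filters,
                            bank, target_train, k_per_group, selection,
                            window_s)
    patterns = _stage("spatial_patterns", _transfer_patterns, bank, tbank,
                      source.montage)
    train_ft = _stage("logvar_features", extract_features, tbank,
                      analysis_window(target_train, window_s))
    model = _stage("train_classifier", train_classifier, train_ft, seed)
    test_ft, preds = None, np.asarray([], dtype=object)
    if target_test is not None and target_test.n_trials:
        test_ft = _stage("logvar_features", extract_features, tbank,
                         analysis_window(target_test, window_s))
        preds = _stage("predict", predict, model, test_ft)
    return PipelineResult(preds, tbank, bank, freport, patterns, model,
                          train_ft, test_ft)


def _transfer_patterns(full_bank: FilterBank, tbank: FilterBank, montage):
    """Patterns of the transferred filters, from the full bank's forward model."""
    pm = spatial_patterns(full_bank, montage)
    idx = tbank.source_indices
    from .csp import PatternMap

    return PatternMap(pm.patterns[idx], montage)


def csp_baseline(target_train: EpochSet, target_test: EpochSet, m: int = 2,
                 window_s=ANALYSIS_WINDOW_S, shrinkage="auto",
                 seed: int = 0) -> np.ndarray:
    """Plain CSP trained on target data alone: m first + m last filters."""
    tr = analysis_window(target_train, window_s)
    classes = tuple(np.unique(tr.labels))
    if len(classes) != 2:
        raise ConfigurationError("CSP baseline requires exactly 2 classes")
    bank = csp_filters(covariance_pair(tr, *classes, window_s=None), shrinkage)
    reduced = _extreme_rows(bank, m)
    model = train_classifier(extract_features(reduced, tr), seed)
    if target_test is None or not target_test.n_trials:
        return np.asarray([], dtype=object)
    te = analysis_window(target_test, window_s)
    return predict(model, extract_features(reduced, te))


def _extreme_rows(bank: FilterBank, m: int) -> FilterBank:
    if 2 * m > bank.n_filters:
        raise ConfigurationError(f"m={m} too large for {bank.n_filters} filters")
    idx = np.r_[np.arange(m), np.arange(bank.n_filters - m, bank.n_filters)]
    return bank.take(idx)


# ---------------------------------------------------------------------------
# PSD baseline
# ---------------------------------------------------------------------------

def _welch(epochs: EpochSet, channel_idx):
    nperseg = min(int(round(epochs.fs)), epochs.n_samples)  # 1 s windows
    freqs, psd = sps.welch(epochs.data[:, channel_idx, :], fs=epochs.fs,
                           nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    return freqs, psd  # (trials, channels, freqs)


def psd_band_features(epochs: EpochSet,
                      channels=PSD_CHANNELS,
                      window_s=ANALYSIS_WINDOW_S) -> np.ndarray:
    """8-30 Hz log band power per listed channel + their average (d+1 features)."""
    ep = analysis_window(epochs, window_s)
    idx = [ep.montage.index(c) for c in channels]
    freqs, psd = _welch(ep, idx)
    band = (freqs >= BAND_HZ[0]) & (freqs <= BAND_HZ[1])
    power = np.trapezoid(psd[:, :, band], freqs[band], axis=-1)
    return np.column_stack([np.log(power), np.log(power.mean(axis=1))])


def psd_baseline(target_train: EpochSet, target_test: EpochSet,
                 channels=PSD_CHANNELS, window_s=ANALYSIS_WINDOW_S,
                 seed: int = 0) -> np.ndarray:
    """Band-power baseline: Welch PSD features at C3/Cz/C4 + the same SVM."""
    ft_train = FeatureTable(psd_band_features(target_train, channels, window_s),
                            target_train.labels)
    model = train_classifier(ft_train, seed)
    if target_test is None or not target_test.n_trials:
        return np.asarray([], dtype=object)
    ft_test = FeatureTable(psd_band_features(target_test, channels, window_s))
    return predict(model, ft_test)


def psd_curves(epochs: EpochSet, channels=PSD_CHANNELS,
               window_s=ANALYSIS_WINDOW_S):
    """Per-class trial-averaged Welch PSD at the listed channels (long form)."""
    import pandas as pd

    ep = analysis_window(epochs, window_s)
    idx = [ep.montage.index(c) for c in channels]
    freqs, psd = _welch(ep, idx)
    rows = []
    for cls in np.unique(ep.labels):
        mean_psd = psd[ep.labels == cls].mean(axis=0)  # (channels, freqs)
        for ci, ch in enumerate(channels):
            rows.append(pd.DataFrame({"class": cls, "channel": ch,
                                      "freq": freqs, "psd": mean_psd[ci]}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Inverted cross-validation
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Per-repetition, per-fold accuracies of each evaluated method."""

    accuracies: dict[str, np.ndarray]  # method -> (reps, folds)
    folds: int
    reps: int
    seed: int
    task: TaskSpec | None = None
    n_train_per_class: int = 0

    def mean(self, method: str) -> float:
        return float(self.accuracies[method].mean())

    def max(self, method: str) -> float:
        return float(self.accuracies[method].max())

    def min(self, method: str) -> float:
        return float(self.accuracies[method].min())

    @property
    def methods(self) -> list[str]:
        return list(self.accuracies)


def _stratified_folds(labels: np.ndarray, folds: int):
    """Per-class index arrays; adjust fold count to the nearest stratifiable
    value if the class counts do not divide evenly."""
    classes, counts = np.unique(labels, return_counts=True)
    ok = [f for f in range(2, int(counts.min()) + 1)
          if all(c % f == 0 for c in counts)]
    if not ok:
        raise DataError("class counts admit no stratified fold split")
    if folds in ok:
        chosen = folds
    else:
        chosen = min(ok, key=lambda f: (abs(f - folds), -f))
        warnings.warn(
            f"class counts {counts.tolist()} not divisible into {folds} "
            f"stratified folds; using {chosen} folds instead", stacklevel=3)
    return classes, chosen


def _fold_seed(seed: int, rep: int, fold: int) -> int:
    return int((seed * 1_000_003 + rep * 1009 + fold * 13 + 7) % (2**31))


def inverted_cv(target: EpochSet, source: EpochSet | None = None,
                methods=("transfer_csp", "csp", "psd"), folds: int = 12,
                reps: int = 5, seed: int = 0, k_per_group: int = 2,
                m: int = 2, selection: str = "per_group",
                window_s=ANALYSIS_WINDOW_S, shrinkage="auto",
                task: TaskSpec | None = None) -> AccuracyReport:
    """Train on one fold (1/12), test on the rest; repeat over fresh shuffles.

    ``methods`` may mix the built-in names ``"transfer_csp"``, ``"csp"``,
    ``"psd"`` with ``(name, callable)`` pairs where the callable has the
    signature ``fn(target_train, target_test, source, seed) -> labels``.
    Projections, PSD features and the source bank are computed once per call;
    per-fold work touches only variance tables and the SVM.
    """
    tgt = analysis_window(target, window_s)
    classes, folds = _stratified_folds(tgt.labels, folds)
    if len(classes) != 2:
        raise ConfigurationError("inverted_cv requires a 2-class target set")
    names, customs = [], {}
    need_transfer = need_csp = need_psd = False
    for meth in methods:
        if isinstance(meth, str):
            if meth not in ("transfer_csp", "csp", "psd"):
                raise ConfigurationError(f"unknown method {meth!r}")
            names.append(meth)
            need_transfer |= meth == "transfer_csp"
            need_csp |= meth == "csp"
            need_psd |= meth == "psd"
        else:
            name, fn = meth
            names.append(name)
            customs[name] = fn

    src_bank = None
    var_all = None
    if need_transfer:
        if source is None:
            raise ConfigurationError("transfer_csp needs source data")
        src = analysis_window(source, window_s)
        src_classes = tuple(np.unique(src.labels))
        if len(src_classes) != 2:
            raise ConfigurationError("source data must contain exactly 2 classes")
        src_bank = csp_filters(covariance_pair(src, *src_classes,
                                               window_s=None), shrinkage)
        var_all = row_variances(project(src_bank, tgt))  # (trials, n_filters)
    psd_all = psd_band_features(tgt, window_s=None) if need_psd else None

    per_class_idx = [np.flatnonzero(tgt.labels == c) for c in classes]
    n_train_pc = len(per_class_idx[0]) // folds
    acc = {name: np.zeros((reps, folds)) for name in names}

    for rep in range(reps):
        rng = np.random.default_rng([seed, 2654435769, rep])
        perms = [rng.permutation(ix).reshape(folds, -1) for ix in per_class_idx]
        for fold in range(folds):
            train_idx = np.concatenate([p[fold] for p in perms])
            test_idx = np.concatenate(
                [np.delete(p, fold, axis=0).ravel() for p in perms])
            y_train, y_test = tgt.labels[train_idx], tgt.labels[test_idx]
            fseed = _fold_seed(seed, rep, fold)
            for name in names:
                if name in customs:
                    preds = customs[name](tgt.select(train_idx),
                                          tgt.select(test_idx), source, fseed)
                elif name == "transfer_csp":
                    preds = _transfer_fold(src_bank, var_all, tgt.labels,
                                           train_idx, test_idx, k_per_group,
                                           selection, fseed)
                elif name == "csp":
                    preds = csp_baseline(tgt.select(train_idx),
                                         tgt.select(test_idx), m,
                                         window_s=None, shrinkage=shrinkage,
                                         seed=fseed)
                else:  # psd
                    model = train_classifier(
                        FeatureTable(psd_all[train_idx], y_train), fseed)
                    preds = predict(model, FeatureTable(psd_all[test_idx]))
                acc[name][rep, fold] = float(np.mean(preds == y_test))
    return AccuracyReport(acc, folds, reps, seed, task, n_train_pc)


def _transfer_fold(src_bank, var_all, labels, train_idx, test_idx,
                   k_per_group, selection, seed):
    """One transfer fold from the precomputed per-trial variance table."""
    scoring = logvar_from_variances(var_all[train_idx])
    tbank, _ = select_filters_from_features(src_bank, scoring,
                                            labels[train_idx], k_per_group,
                                            selection)
    chosen = tbank.source_indices
    ft_train = FeatureTable(logvar_from_variances(var_all[train_idx][:, chosen]),
                            labels[train_idx])
    model = train_classifier(ft_train, seed)
    return predict(model, FeatureTable(
        logvar_from_variances(var_all[test_idx][:, chosen])))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def format_pct(value: float) -> str:
    return f"{100 * value:.2f}%"


def format_cell(mean: float, mx: float, mn: float) -> str:
    return f"{format_pct(mean)} ({format_pct(mx)}-{format_pct(mn)})"


def report(accuracy_reports: dict[str, AccuracyReport]):
    """Comparison table: rows = sessions, cells = "mean% (max%-min%)".

    Adds a transfer-minus-CSP difference column (in percentage points) when
    both methods are present.
    """
    import pandas as pd

    rows = {}
    methods_seen: list[str] = []
    for session, rep in accuracy_reports.items():
        row = {}
        for meth in rep.methods:
            row[meth] = format_cell(rep.mean(meth), rep.max(meth),
                                    rep.min(meth))
            if meth not in methods_seen:
                methods_seen.append(meth)
        if "transfer_csp" in rep.methods and "csp" in rep.methods:
            diff = 100 * (rep.mean("transfer_csp") - rep.mean("csp"))
            row["transfer-csp [pp]"] = f"{diff:+.2f}"
        rows[session] = row
    cols = methods_seen + (["transfer-csp [pp]"]
                           if any("transfer-csp [pp]" in r for r in rows.values())
                           else [])
    df = pd.DataFrame.from_dict(rows, orient="index")
    if rows:
        df = df.reindex(columns=cols)
    else:
        df = pd.DataFrame(columns=["transfer_csp", "csp", "psd"])
    df.index.name = "session"
    return df
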