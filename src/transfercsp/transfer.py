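"""Fisher-ratio transfer: score source filters on scarce target data.

A CSP bank built from a *source* task pair (e.g. left hand vs right hand) is
transferred to a *target* pair of combined commands (e.g. LH&F vs RH&F) by
keeping only the filters that remain discriminative on a handful of target
training trials.  Each filter is scored by the Fisher ratio of its
normalized log-variance feature across the target classes,

    J = S_between / S_within,
    S_between = sum_i (n_i / n) (m_i - m)^2,
    S_within  = (1/n) sum_i sum_{x in class i} (x - m_i)^2,

and an equal number of top-scoring filters is kept from the high-eigenvalue
and low-eigenvalue halves of the bank, preserving CSP's symmetric structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csp import FilterBank, analysis_window
from .errors import ConfigurationError, DataError
from .features import logvar_features, project
from .synthetic import EpochSet


@dataclass
class FisherReport:
    """Per-filter Fisher diagnostics and the transfer selection mask."""

    scores: np.ndarray  # (n_filters,) J values
    class_means: np.ndarray  # (n_classes, n_filters)
    grand_mean: np.ndarray  # (n_filters,)
    s_between: np.ndarray
    s_within: np.ndarray
    selected: np.ndarray  # boolean mask over the source bank
    k_per_group: int
    classes: tuple
    source_indices: np.ndarray | None = None  # selected rows, output order

    def to_frame(self, bank: FilterBank | None = None):
        import pandas as pd

        cols = {"filter_index": np.arange(len(self.scores)),
                "J": self.scores, "selected": self.selected}
        if bank is not None:
            cols["group"] = bank.group
            cols["eigenvalue"] = bank.eigenvalues
        return pd.DataFrame(cols)


def fisher_scores(features: np.ndarray, labels,
                  return_report: bool = False):
    """Fisher ratio of every feature dimension.

    Perfectly separated constant features (zero within-class scatter,
    positive between-class scatter) score +inf; dimensions constant across
    all samples score 0.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if len(y) != len(x):
        raise ConfigurationError("one label per feature row required")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError("fisher_scores needs >= 2 classes")
    n = len(x)
    grand = x.mean(axis=0)
    s_between = np.zeros(x.shape[1])
    s_within = np.zeros(x.shape[1])
    class_means = np.empty((len(classes), x.shape[1]))
    for i, c in enumerate(classes):
        xi = x[y == c]
        if len(xi) < 2:
            raise ConfigurationError(
                f"class {c!r} has {len(xi)} sample(s); need >= 2"
            )
        mi = xi.mean(axis=0)
        class_means[i] = mi
        s_between += (len(xi) / n) * (mi - grand) ** 2
        s_within += ((xi - mi) ** 2).sum(axis=0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        j = s_between / s_within
    j[(s_within == 0) & (s_between > 0)] = np.inf
    j[(s_within == 0) & (s_between == 0)] = 0.0
    if not return_report:
        return j
    return j, FisherReport(j, class_means, grand, s_between, s_within,
                           selected=np.zeros(x.shape[1], bool),
                           k_per_group=0, classes=tuple(classes))


def _rank_within_group(indices: np.ndarray, j: np.ndarray,
                       eigenvalues: np.ndarray) -> np.ndarray:
    """Order candidate filters by J descending; ties go to the filter with
    the more extreme source eigenvalue, then to the lower index."""
    extremity = np.abs(eigenvalues - 0.5)
    key = sorted(indices, key=lambda i: (-j[i], -extremity[i], i))
    return np.asarray(key, dtype=int)


def select_filters_from_features(bank: FilterBank, features: np.ndarray,
                                 labels, k_per_group: int,
                                 selection: str = "per_group"
                                 ) -> tuple[FilterBank, FisherReport]:
    """Core selection given precomputed whole-bank features (one row/trial)."""
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ConfigurationError("transfer selection requires exactly 2 classes")
    for c, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < 2:
            raise DataError(f"class {c!r} has {cnt} target training trial(s); "
                            "need >= 2 (the operating point is 5 per class)")
    high = np.flatnonzero(bank.group == "high")
    low = np.flatnonzero(bank.group == "low")
    if k_per_group < 1 or k_per_group > min(len(high), len(low)):
        raise ConfigurationError(
            f"k_per_group={k_per_group} out of range for a bank with "
            f"{len(high)} high / {len(low)} low filters"
        )
    j, report = fisher_scores(features, y, return_report=True)
    if selection == "per_group":
        chosen = np.concatenate([
            _rank_within_group(high, j, bank.eigenvalues)[:k_per_group],
            _rank_within_group(low, j, bank.eigenvalues)[:k_per_group],
        ])
    elif selection == "overall":
        pool = np.concatenate([high, low])
        chosen = _rank_within_group(pool, j, bank.eigenvalues)[:2 * k_per_group]
    else:
        raise ConfigurationError(f"unknown selection mode {selection!r}")
    # restore the bank's eigenvalue ordering (descending, stable)
    chosen = chosen[np.argsort(-bank.eigenvalues[chosen], kind="stable")]
    selected_mask = np.zeros(bank.n_filters, bool)
    selected_mask[chosen] = True
    report.selected = selected_mask
    report.k_per_group = k_per_group
    report.source_indices = chosen
    return bank.take(chosen), report


def select_transfer_filters(source_bank: FilterBank, target_train: EpochSet,
                            k_per_group: int = 2,
                            selection: str = "per_group",
                            window_s=None) -> tuple[FilterBank, FisherReport]:
    """Score the source bank on target training trials and keep the best.

    The scoring feature of each filter is its normalized log-variance
    computed over the *whole* bank -- the same transform the classifier
    sees -- so selection and inference are consistent.  ``window_s``
    optionally crops trials to the post-cue analysis window first (the
    pipeline passes the CSP analysis window).
    """
    epochs = analysis_window(target_train, window_s) if window_s else target_train
    feats = logvar_features(project(source_bank, epochs))
    return select_filters_from_features(source_bank, feats, epochs.labels,
                                        k_per_group, selection)
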