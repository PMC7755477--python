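"""Common spatial patterns: the full ordered filter bank for two classes.

Given trial-averaged, trace-normalized class covariances R1 and R2, CSP
simultaneously diagonalizes them: whiten the composite R = R1 + R2 with
P = Lambda^(-1/2) U^T (from R = U Lambda U^T), eigendecompose the whitened
class-1 covariance S1 = B Lambda1 B^T, and take the filter bank
W = B^T P.  Because S1 + S2 = I after whitening, Lambda1 + Lambda2 = I: a
filter with a large class-1 variance share lambda automatically has a small
class-2 share 1 - lambda, so the two ends of the eigenvalue spectrum are the
discriminative filters.  The bank keeps all N rows, ordered by lambda
descending, tagged "high" (first half) or "low" (last half); reduction to a
subset is deferred to the transfer / baseline selection steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DataError, NumericalError
from .synthetic import EpochSet, Montage

#: Post-cue analysis window (seconds relative to cue) feeding covariance
#: estimation and feature extraction: imagery activity only, no pre-cue
#: baseline.
ANALYSIS_WINDOW_S = (0.0, 2.0)

_SHRINKAGE_LADDER = (0.0, 1e-6, 1e-4, 1e-2)
_COND_LIMIT = 1e10


def analysis_window(epochs: EpochSet,
                    window_s: tuple[float, float] | None = ANALYSIS_WINDOW_S
                    ) -> EpochSet:
    """Crop trials to the post-cue analysis window when they contain it.

    Trials that do not span the requested window (already cropped, or epoched
    without a pre-cue segment) are used as-is; cropping twice is a no-op.
    """
    if window_s is None:
        return epochs
    t0, t1 = window_s
    lo = epochs.t0_offset_s
    hi = lo + epochs.n_samples / epochs.fs
    a, b = max(t0, lo), min(t1, hi)
    if b - a > 1.0 / epochs.fs and (a > lo + 1e-9 or b < hi - 1e-9):
        return epochs.subwindow(a, b)
    return epochs


@dataclass(frozen=True)
class CovariancePair:
    """Trial-averaged normalized covariances of the two source classes."""

    r1: np.ndarray
    r2: np.ndarray
    n_trials_1: int
    n_trials_2: int
    classes: tuple[str, str] = ("1", "2")


@dataclass(frozen=True)
class FilterBank:
    """Ordered CSP spatial filters.

    ``filters`` rows are applied to channel data; ``eigenvalues`` are the
    whitened class-1 variance shares (descending); ``group`` tags each row
    "high" / "low" (middle row of an odd bank: "mid").  ``source_indices``
    records, for a reduced bank, which rows of the originating full bank
    each filter came from.
    """

    filters: np.ndarray  # (n_filters, n_channels)
    eigenvalues: np.ndarray  # (n_filters,)
    group: np.ndarray  # (n_filters,) of {"high", "low", "mid"}
    source_classes: tuple[str, str]
    source_indices: np.ndarray | None = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    def take(self, indices) -> "FilterBank":
        idx = np.asarray(indices)
        prov = (self.source_indices[idx] if self.source_indices is not None
                else idx)
        return FilterBank(self.filters[idx], self.eigenvalues[idx],
                          self.group[idx], self.source_classes, prov)


@dataclass(frozen=True)
class PatternMap:
    """Forward-model spatial patterns paired with a bank's filters."""

    patterns: np.ndarray  # (n_filters, n_channels)
    montage: Montage | None = None


def class_covariance(epochs: EpochSet, class_label: str,
                     window_s: tuple[float, float] | None = ANALYSIS_WINDOW_S
                     ) -> tuple[np.ndarray, int]:
    """Average normalized spatial covariance of one class.

    Each trial contributes its scatter X X^T divided by its own trace, so
    every trial enters with unit weight regardless of amplitude and the
    average has trace 1.
    """
    sub = analysis_window(epochs, window_s).select(np.asarray([class_label]))
    if sub.n_trials < 2:
        raise DataError(
            f"need >= 2 trials of class {class_label!r}, got {sub.n_trials}"
        )
    n = sub.n_channels
    acc = np.zeros((n, n))
    for i, x in enumerate(sub.data):
        scatter = x @ x.T
        tr = np.trace(scatter)
        if tr <= 0:
            raise DataError(f"trial {i} of class {class_label!r} has zero variance")
        acc += scatter / tr
    r = acc / sub.n_trials
    return 0.5 * (r + r.T), sub.n_trials


def covariance_pair(epochs: EpochSet, class_1: str, class_2: str,
                    window_s: tuple[float, float] | None = ANALYSIS_WINDOW_S
                    ) -> CovariancePair:
    r1, n1 = class_covariance(epochs, class_1, window_s)
    r2, n2 = class_covariance(epochs, class_2, window_s)
    return CovariancePair(r1, r2, n1, n2, (class_1, class_2))


def _shrink(r: np.ndarray, gamma: float) -> np.ndarray:
    n = r.shape[0]
    return (1 - gamma) * r + gamma * (np.trace(r) / n) * np.eye(n)


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Scale each filter row so its largest-magnitude coefficient is positive."""
    peak = np.take_along_axis(w, np.abs(w).argmax(axis=1)[:, None], axis=1)
    return w * np.where(peak < 0, -1.0, 1.0)


def csp_filters(cov_pair: CovariancePair,
                shrinkage: float | str = "auto") -> FilterBank:
    """Compute the full CSP bank from a covariance pair.

    ``shrinkage="auto"`` starts with no regularization and escalates
    (1e-6, 1e-4, 1e-2) only if the composite covariance is too
    ill-conditioned to whiten; a float applies that gamma directly.
    """
    ladder = _SHRINKAGE_LADDER if shrinkage == "auto" else (float(shrinkage),)
    last_cond = np.inf
    for gamma in ladder:
        r1 = _shrink(cov_pair.r1, gamma)
        r2 = _shrink(cov_pair.r2, gamma)
        r = r1 + r2
        evals, u = np.linalg.eigh(r)
        last_cond = float(evals[-1] / max(evals[0], np.finfo(float).tiny))
        if evals[0] <= 0 or last_cond > _COND_LIMIT:
            continue
        p = (u / np.sqrt(evals)).T  # Lambda^(-1/2) U^T
        s1 = p @ r1 @ p.T
        s1 = 0.5 * (s1 + s1.T)
        lam, b = np.linalg.eigh(s1)
        order = np.argsort(-lam, kind="stable")  # descending, stable ties
        lam = np.clip(lam[order], 0.0, 1.0)
        w = _fix_signs(b[:, order].T @ p)
        n = len(lam)
        group = np.array(["high"] * (n // 2)
                         + (["mid"] if n % 2 else [])
                         + ["low"] * (n // 2))
        return FilterBank(w, lam, group, cov_pair.classes,
                          source_indices=np.arange(n))
    raise NumericalError(
        f"composite covariance not positive definite after shrinkage "
        f"(condition number {last_cond:.3g})"
    )


def spatial_patterns(bank: FilterBank,
                     montage: Montage | None = None) -> PatternMap:
    """Forward-model patterns: row p satisfies patterns @ filters.T = I.

    For the full square bank this is the transposed inverse of the filter
    matrix; a reduced bank uses the pseudo-inverse (valid while the rows are
    linearly independent).  Patterns, not filters, are the physiologically
    interpretable scalp maps.
    """
    w = bank.filters
    if w.shape[0] == w.shape[1]:
        try:
            pat = np.linalg.inv(w).T
        except np.linalg.LinAlgError as e:
            raise NumericalError(f"singular filter matrix: {e}") from e
    else:
        pat = np.linalg.pinv(w).T
        if np.linalg.matrix_rank(w) < w.shape[0]:
            raise NumericalError("filter rows are linearly dependent")
    return PatternMap(pat, montage)
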