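"""Signal conditioning: re-reference, interpolate, band-pass, epoch, baseline.

The chain order is fixed and enforced by :func:`preprocess`:

    linked-mastoid re-reference -> bad-channel interpolation ->
    8-30 Hz zero-phase band-pass -> epoching -> baseline correction

Every operation preserves channel count and trial labels.  ICA-based ocular
artifact rejection and manual trial screening are deliberately outside this
module: they are user-supplied steps, and the synthetic generator produces
artifact-free sessions by default so the chain can be tested without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DataError, InterpolationError
from .synthetic import BAND_HZ, EpochSet, Montage


@dataclass
class ContinuousRecord:
    """A continuous multichannel recording with cue events.

    ``events`` is a list of ``(sample_index, class_label)`` pairs;
    ``reference`` names the current reference ("LM" as recorded, or
    "linked-mastoids" after re-referencing).
    """

    data: np.ndarray  # (channels, samples), microvolts
    fs: float
    montage: Montage
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: str = "LM"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be (channels, samples)")
        if self.montage.n_channels != self.data.shape[0]:
            raise ConfigurationError("montage size must match channel dimension")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        for s, _ in self.events:
            if not (0 <= s < self.data.shape[1]):
                raise ConfigurationError(f"event sample {s} outside record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def rereference_linked_mastoids(rec: ContinuousRecord) -> ContinuousRecord:
    """Switch the reference from the left mastoid to the mastoid average.

    With LM as recording reference, re-referencing to (LM+RM)/2 amounts to
    subtracting half the recorded RM channel from every channel.
    """
    if rec.reference != "LM":
        raise ConfigurationError(
            f"record is referenced to {rec.reference!r}, expected 'LM'; "
            "linked-mastoid re-referencing applies only once"
        )
    if "RM" not in rec.montage.channel_names:
        raise ConfigurationError("montage lacks the RM (right mastoid) channel")
    rm = rec.data[rec.montage.index("RM")]
    data = rec.data - 0.5 * rm[None, :]
    return ContinuousRecord(data, rec.fs, rec.montage, list(rec.events),
                            reference="linked-mastoids")


def default_neighbor_map(montage: Montage, k: int = 4) -> dict[str, list[str]]:
    """Nearest-neighbor adjacency from montage geometry (k closest channels)."""
    pos = montage.positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    out = {}
    for i, name in enumerate(montage.channel_names):
        idx = np.argsort(d2[i], kind="stable")[:k]
        out[name] = [montage.channel_names[j] for j in idx]
    return out


def interpolate_bad_channels(
    rec: ContinuousRecord,
    bad: list[str],
    neighbor_map: dict[str, list[str]] | None = None,
) -> ContinuousRecord:
    """Replace each bad channel samplewise by the mean of its good neighbors."""
    if neighbor_map is None:
        neighbor_map = default_neighbor_map(rec.montage)
    bad_set = set(bad)
    data = rec.data.copy()
    for name in bad:
        neighbors = [n for n in neighbor_map.get(name, []) if n not in bad_set]
        if len(neighbors) < 2:
            raise InterpolationError(
                f"channel {name!r} has {len(neighbors)} good neighbor(s); "
                "need at least 2 to interpolate"
            )
        idx = [rec.montage.index(n) for n in neighbors]
        data[rec.montage.index(name)] = rec.data[idx].mean(axis=0)
    return ContinuousRecord(data, rec.fs, rec.montage, list(rec.events),
                            rec.reference)


def bandpass_8_30(rec_or_epochs):
    """Zero-phase 8-30 Hz band-pass (4th-order Butterworth, forward-backward).

    Applies per channel; works on both continuous records and epoch sets and
    returns the same type.  Requires fs > 60 Hz for Nyquist headroom.
    """
    fs = rec_or_epochs.fs
    if fs <= 60:
        raise ConfigurationError(f"fs={fs} too low for an 8-30 Hz band-pass")
    sos = sps.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    if isinstance(rec_or_epochs, ContinuousRecord):
        rec = rec_or_epochs
        data = sps.sosfiltfilt(sos, rec.data, axis=-1)
        return ContinuousRecord(data, fs, rec.montage, list(rec.events),
                                rec.reference)
    ep = rec_or_epochs
    data = sps.sosfiltfilt(sos, ep.data, axis=-1)
    return EpochSet(data, ep.labels, fs, ep.montage, ep.t0_offset_s)


def extract_epochs(rec: ContinuousRecord, tmin_s: float = -0.5,
                   tmax_s: float = 2.0) -> EpochSet:
    """Cut one half-open window [cue+tmin, cue+tmax) per event.

    The half-open convention makes the sample count exactly
    ``(tmax_s - tmin_s) * fs``; at 500 Hz the default window is 1250 samples.
    """
    if tmax_s <= tmin_s:
        raise ConfigurationError("tmax_s must exceed tmin_s")
    n_win = int(round((tmax_s - tmin_s) * rec.fs))
    if n_win < 1:
        raise ConfigurationError("window shorter than one sample")
    truncated = []
    trials, labels = [], []
    for sample, label in rec.events:
        i0 = sample + int(round(tmin_s * rec.fs))
        i1 = i0 + n_win
        if i0 < 0 or i1 > rec.n_samples:
            truncated.append((sample, label))
            continue
        trials.append(rec.data[:, i0:i1])
        labels.append(label)
    if truncated:
        raise DataError(
            "events with truncated windows: "
            + ", ".join(f"(sample {s}, {l})" for s, l in truncated)
        )
    data = np.stack(trials) if trials else np.empty((0, rec.n_channels, n_win))
    return EpochSet(data, np.asarray(labels, dtype=str), rec.fs, rec.montage,
                    t0_offset_s=tmin_s)


def baseline_correct(epochs: EpochSet,
                     interval: tuple[float, float] = (-0.5, 0.0)) -> EpochSet:
    """Subtract the per-trial per-channel mean over [interval[0], interval[1])."""
    t0, t1 = interval
    i0 = int(round((t0 - epochs.t0_offset_s) * epochs.fs))
    i1 = int(round((t1 - epochs.t0_offset_s) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples or i1 <= i0:
        raise ConfigurationError(
            f"baseline interval [{t0}, {t1}) outside the trial window"
        )
    base = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.labels, epochs.fs,
                    epochs.montage, epochs.t0_offset_s)


def preprocess(
    rec: ContinuousRecord,
    bad_channels: list[str] = (),
    neighbor_map: dict[str, list[str]] | None = None,
    tmin_s: float = -0.5,
    tmax_s: float = 2.0,
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> EpochSet:
    """Run the full conditioning chain in its fixed order."""
    rec = rereference_linked_mastoids(rec)
    if bad_channels:
        rec = interpolate_bad_channels(rec, list(bad_channels), neighbor_map)
    rec = bandpass_8_30(rec)
    epochs = extract_epochs(rec, tmin_s, tmax_s)
    return baseline_correct(epochs, baseline)
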