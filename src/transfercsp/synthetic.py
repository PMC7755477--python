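"""Synthetic motor-imagery EEG sessions with planted ground truth.

The generator emulates a cue-based motor-imagery experiment: multichannel
scalp EEG in which imagining a limb movement modulates 8-30 Hz (alpha/beta)
band power over sensorimotor cortex.  The signal model is linear
instantaneous mixing -- the generative model under which common spatial
patterns (CSP) is optimal -- so spatial-filter recovery against the planted
mixing matrix is a meaningful test:

    X(t) = A s(t) * (modulation per class) + background + artifacts

Three band-limited Gaussian task sources are anchored at the classical hand
and foot motor areas: a source under C3 (controlled by right-hand imagery),
one under C4 (left hand) and one under Cz (feet).  A class scales the 8-30 Hz
variance of its sources by (1 - erd_depth) on the contralateral side
(event-related desynchronization) and (1 + erd_depth) ipsilaterally
(synchronization).  Combined commands (LH&F, RH&F, LH&RH) apply the
elementwise product of their components' modulations, which is exactly the
invariance that makes source-task spatial filters transferable to the
combined tasks.

Background activity is spatially correlated 1/f ("pink") noise plus ongoing
class-independent alpha/beta rhythms: broad-footprint band-limited sources
at fixed anatomical locations (occipital/parietal/premotor) whose amplitude
varies strongly from trial to trial, as ongoing EEG rhythms do.  Their
volume-conducted leakage is what makes single-channel band power an
unreliable feature, while a spatial filter with enough channels can null
them and keep the task sources.  An optional EOG-like artifact (slow, high amplitude, frontal) can
be mixed in to exercise preprocessing, and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError

# Canonical command set: three single-limb commands and their pairwise
# combinations.  Order is fixed so that per-trial random substreams are
# addressed by (class index, trial index) and never depend on which subset
# of classes a session requests.
SINGLE_CLASSES = ("LH", "RH", "F")
COMBINED_CLASSES = ("LH&RH", "LH&F", "RH&F")
ALL_CLASSES = SINGLE_CLASSES + COMBINED_CLASSES

#: Source order used throughout: anchored at C3 (right-hand control),
#: C4 (left-hand control), Cz (feet control).
SOURCE_ANCHORS = ("C3", "C4", "Cz")

# Channels every montage must contain, with unit-disc coordinates
# (x: left->right, y: posterior->anterior).
REQUIRED_CHANNELS = {
    "Cz": (0.0, 0.0),
    "C3": (-0.4, 0.0),
    "C4": (0.4, 0.0),
    "FC5": (-0.62, 0.25),
    "FC6": (0.62, 0.25),
    "LM": (-0.95, -0.45),
    "RM": (0.95, -0.45),
}

BAND_HZ = (8.0, 30.0)  # sensorimotor alpha+beta band used everywhere
_SOURCE_SPREAD = 0.20  # spatial std-dev of a source's scalp footprint
_NOISE_SPREAD = 0.35  # correlation length of the background noise
_BACKGROUND_RMS_UV = 10.0  # overall amplitude calibration of the output
#: Fixed scalp locations of ongoing (class-independent) alpha/beta rhythm
#: generators: occipital and parietal alpha, a central-parietal source and
#: bilateral premotor rhythms.  Fixed anatomy, shared by every session of
#: the simulated subject; only their trial-to-trial amplitudes are random.
RHYTHM_CENTERS = np.array([
    (0.0, -0.70), (-0.50, -0.40), (0.50, -0.40), (0.0, -0.35),
    (-0.30, 0.35), (0.30, 0.35), (0.0, 0.55),
])
_RHYTHM_SPREAD = 0.45  # broad far-field footprints (volume conduction)
_RHYTHM_POWER = 12.0  # typical in-band peak-channel power over background
_RHYTHM_LOGSTD = 0.4  # log-std of their trial-to-trial amplitude


@dataclass(frozen=True)
class Montage:
    """Electrode names and 2-D unit-disc positions for topographic export."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not in montage") from None

    def __post_init__(self):
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("montage channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_names), 2):
            raise ConfigurationError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(pos)):
            raise ConfigurationError("montage positions must be finite")
        object.__setattr__(self, "positions", pos)


def make_montage(n_channels: int) -> Montage:
    """Build a montage with the seven required channels plus ring-layout fillers.

    Required channels (C3, C4, Cz, FC5, FC6 and the mastoids LM, RM) sit at
    fixed approximate 10-20 coordinates; the remaining ``n_channels - 7``
    electrodes are auto-named ``E<k>`` and laid out on concentric rings.
    """
    if n_channels < 8:
        raise ConfigurationError(
            f"n_channels must be >= 8 to place the {len(REQUIRED_CHANNELS)} "
            f"required channels, got {n_channels}"
        )
    names = list(REQUIRED_CHANNELS)
    positions = [REQUIRED_CHANNELS[n] for n in names]
    n_fill = n_channels - len(names)
    if n_fill:
        # concentric rings, inner to outer, equal angular spacing per ring
        n_rings = max(1, math.ceil(n_fill / 16))
        radii = np.linspace(0.3, 0.9, n_rings)
        per_ring = [n_fill // n_rings + (1 if i < n_fill % n_rings else 0)
                    for i in range(n_rings)]
        k = 1
        for r, cnt in zip(radii, per_ring):
            for j in range(cnt):
                theta = 2 * np.pi * j / cnt + 0.1 * r  # offset avoids collisions
                names.append(f"E{k}")
                positions.append((r * np.cos(theta), r * np.sin(theta)))
                k += 1
    return Montage(tuple(names), np.asarray(positions, dtype=float))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated motor-imagery session.

    Defaults reproduce the emulated acquisition: 64 channels sampled at
    500 Hz, 2.5 s trials (0.5 s pre-cue baseline + 2 s of imagery), 60 trials
    per class.  ``snr_db`` is the in-band (8-30 Hz) power ratio of a task
    source to the background *at the source's peak channel* (C3/C4/Cz), at
    baseline modulation; ``erd_depth`` is the fractional band-variance
    change an active source undergoes.
    """

    n_channels: int = 64
    fs: float = 500.0
    trial_len_s: float = 2.5
    n_trials_per_class: int = 60
    classes: tuple[str, ...] = ("LH", "RH", "F", "LH&RH", "LH&F", "RH&F")
    snr_db: float = 0.0
    erd_depth: float = 0.5
    background_rhythms: float = 1.0
    eog_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.erd_depth < 1.0):
            raise ConfigurationError("erd_depth must be in [0, 1)")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_trials_per_class <= 0:
            raise ConfigurationError("n_trials_per_class must be positive")
        if self.trial_len_s <= 0.5:
            raise ConfigurationError("trial_len_s must exceed the 0.5 s baseline")
        for c in self.classes:
            if c not in ALL_CLASSES:
                raise ConfigurationError(
                    f"unknown class {c!r}; valid classes: {ALL_CLASSES}"
                )
        object.__setattr__(self, "classes", tuple(self.classes))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a simulated session.

    ``mixing`` holds one scalp column per task source (order
    ``SOURCE_ANCHORS``), ``class_source_variance`` maps each class to its
    post-cue per-source 8-30 Hz variance in source units (baseline 1.0).
    """

    mixing: np.ndarray  # (n_channels, 3)
    class_source_variance: dict[str, np.ndarray]
    seed: int

    def __post_init__(self):
        if np.linalg.matrix_rank(self.mixing) < self.mixing.shape[1]:
            raise ConfigurationError("mixing matrix must have full column rank")
        for c, v in self.class_source_variance.items():
            if np.any(np.asarray(v) <= 0):
                raise ConfigurationError(f"non-positive source variance for {c}")


@dataclass
class EpochSet:
    """Labeled fixed-length multichannel trials.

    ``data`` is a (trials, channels, samples) tensor in microvolts;
    ``t0_offset_s`` is the time of sample 0 relative to the imagery cue
    (negative = pre-cue baseline included).
    """

    data: np.ndarray
    labels: np.ndarray  # (trials,) of str
    fs: float
    montage: Montage
    t0_offset_s: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError("label count must equal trial count")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.montage.n_channels != self.data.shape[1]:
            raise ConfigurationError("montage size must match channel dimension")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.n_samples) / self.fs

    def class_counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def select(self, mask_or_labels) -> "EpochSet":
        """Subset trials by boolean mask/index array or by label set."""
        m = np.asarray(mask_or_labels)
        if m.dtype.kind in "US":
            m = np.isin(self.labels, m)
        return EpochSet(self.data[m], self.labels[m], self.fs, self.montage,
                        self.t0_offset_s)

    def subwindow(self, tmin_s: float, tmax_s: float) -> "EpochSet":
        """Half-open time crop [tmin_s, tmax_s) relative to the cue."""
        i0 = int(round((tmin_s - self.t0_offset_s) * self.fs))
        i1 = int(round((tmax_s - self.t0_offset_s) * self.fs))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ConfigurationError(
                f"window [{tmin_s}, {tmax_s}) outside trial "
                f"[{self.t0_offset_s}, {self.t0_offset_s + self.n_samples / self.fs})"
            )
        return EpochSet(self.data[:, :, i0:i1], self.labels, self.fs,
                        self.montage, tmin_s)


# ---------------------------------------------------------------------------
# class -> per-source variance modulation
# ---------------------------------------------------------------------------

def _single_class_modulation(label: str, erd_depth: float) -> np.ndarray:
    """Per-source variance factors (order C3, C4, Cz) for a single command.

    Right-hand imagery desynchronizes the contralateral (C3) source and
    synchronizes the ipsilateral (C4) one; mirrored for the left hand; feet
    imagery desynchronizes the midline (Cz) source.
    """
    d = erd_depth
    if label == "LH":
        return np.array([1 + d, 1 - d, 1.0])
    if label == "RH":
        return np.array([1 - d, 1 + d, 1.0])
    if label == "F":
        return np.array([1.0, 1.0, 1 - d])
    raise ConfigurationError(f"unknown single class {label!r}")


def class_modulation(label: str, erd_depth: float) -> np.ndarray:
    """Variance modulation of a (possibly combined) command.

    Combined commands apply the elementwise product of their components'
    modulations -- the superposition that makes single-task filters carry
    over to combined tasks.
    """
    if label in SINGLE_CLASSES:
        return _single_class_modulation(label, erd_depth)
    if label in COMBINED_CLASSES:
        parts = label.split("&")
        # "F" is spelled as-is; hands are LH/RH
        mod = np.ones(3)
        for p in parts:
            mod = mod * _single_class_modulation(p, erd_depth)
        return mod
    raise ConfigurationError(f"unknown class {label!r}")


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _band_sos(fs: float):
    return sps.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")


def _band_gain(fs: float) -> float:
    """Variance gain of the band filter on unit white noise (for exact scaling)."""
    w, h = sps.sosfreqz(_band_sos(fs), worN=4096, fs=fs)
    return float(np.trapezoid(np.abs(h) ** 2, w) / (fs / 2))


def _band_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                fs: float, gain: float) -> np.ndarray:
    """Unit-variance Gaussian processes band-limited to 8-30 Hz."""
    pad = int(fs)  # 1 s warm-up absorbs filter transients
    white = rng.standard_normal((n_rows, n_samples + 2 * pad))
    out = sps.sosfilt(_band_sos(fs), white, axis=-1)[:, pad:pad + n_samples]
    return out / math.sqrt(gain)


def _pink_weights(n_samples: int, fs: float) -> np.ndarray:
    """rFFT amplitude weights for 1/f power, normalized to unit variance."""
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = 1.0 / np.sqrt(np.maximum(f[1:], 1.0))
    # Var per output sample is (1/n) * sum_k c_k w_k^2 (c=2 off DC/Nyquist);
    # scale so the synthesized noise has unit variance.
    power = np.sum(w**2)
    power += np.sum(w[1:-1] ** 2) if n_samples % 2 == 0 else np.sum(w[1:] ** 2)
    return w * math.sqrt(n_samples / power)


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                weights: np.ndarray) -> np.ndarray:
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=-1) * weights
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _pink_band_fraction(weights: np.ndarray, n_samples: int, fs: float) -> float:
    """Fraction of pink-noise variance inside the 8-30 Hz band."""
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    p = weights**2
    if n_samples % 2 == 0:
        p = p.copy()
        p[1:-1] *= 2
    else:
        p = p.copy()
        p[1:] *= 2
    inband = (f >= BAND_HZ[0]) & (f <= BAND_HZ[1])
    return float(p[inband].sum() / p.sum())


def _gaussian_bump(positions: np.ndarray, center: np.ndarray,
                   spread: float) -> np.ndarray:
    d2 = np.sum((positions - center) ** 2, axis=1)
    return np.exp(-d2 / (2 * spread**2))


def mixing_matrix(montage: Montage) -> np.ndarray:
    """Scalp forward model: one smooth Gaussian footprint per task source."""
    cols = [_gaussian_bump(montage.positions,
                           montage.positions[montage.index(a)], _SOURCE_SPREAD)
            for a in SOURCE_ANCHORS]
    return np.stack(cols, axis=1)


def _noise_mixer(montage: Montage) -> np.ndarray:
    """Cholesky factor of a smooth spatial covariance, unit channel variance."""
    pos = montage.positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2 * _NOISE_SPREAD**2)) + 0.05 * np.eye(len(pos))
    dk = np.sqrt(np.diag(k))
    k = k / np.outer(dk, dk)
    return np.linalg.cholesky(k)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def simulate_session(config: SimConfig) -> tuple[EpochSet, SyntheticTruth]:
    """Simulate one labeled session with planted ground truth.

    Deterministic given ``config.seed``: each trial draws from its own
    substream keyed by (seed, class index, trial index), so the content of a
    trial never depends on which other classes or how many trials a session
    requests.  ERD/ERS modulation applies only after the cue (t >= 0); the
    0.5 s pre-cue segment carries baseline source variance.
    """
    montage = make_montage(config.n_channels)
    fs = config.fs
    n_samp = int(round(config.trial_len_s * fs))
    n_pre = int(round(0.5 * fs))  # pre-cue baseline samples
    t0 = -0.5

    A = mixing_matrix(montage)
    L = _noise_mixer(montage)
    gain = _band_gain(fs)
    pink_w = _pink_weights(n_samp, fs)
    rho = _pink_band_fraction(pink_w, n_samp, fs)

    # Signal amplitude from the SNR definition: at a source's peak channel
    # (mixing weight 1) its in-band power is g^2, the background's is rho.
    g = math.sqrt(10 ** (config.snr_db / 10) * rho)

    # Ongoing rhythm sources: fixed anatomical locations, trial-varying
    # lognormal amplitudes drawn from each trial's substream.
    rhythm_cols = np.zeros((montage.n_channels, 0))
    if config.background_rhythms > 0:
        rhythm_cols = np.stack(
            [_gaussian_bump(montage.positions, c, _RHYTHM_SPREAD)
             for c in RHYTHM_CENTERS], axis=1)
        rhythm_gain = config.background_rhythms * math.sqrt(_RHYTHM_POWER * rho)

    eog_col = None
    if config.eog_amplitude > 0:
        eog_col = _gaussian_bump(montage.positions, np.array([0.0, 0.95]), 0.3)
        eog_sos = sps.butter(4, 4.0, btype="lowpass", fs=fs, output="sos")
        w, h = sps.sosfreqz(eog_sos, worN=4096, fs=fs)
        eog_gain = float(np.trapezoid(np.abs(h) ** 2, w) / (fs / 2))

    n_total = config.n_trials_per_class * len(config.classes)
    data = np.empty((n_total, montage.n_channels, n_samp))
    labels = np.empty(n_total, dtype=object)

    trial = 0
    truth_var: dict[str, np.ndarray] = {}
    for label in config.classes:
        mod = class_modulation(label, config.erd_depth)
        truth_var[label] = mod.copy()
        scale = np.sqrt(mod)
        for i in range(config.n_trials_per_class):
            rng = np.random.default_rng(
                [config.seed, ALL_CLASSES.index(label), i]
            )
            src = _band_noise(rng, 3, n_samp, fs, gain)
            src[:, n_pre:] *= scale[:, None]  # post-cue ERD/ERS
            x = g * (A @ src)
            if rhythm_cols.shape[1]:
                amp = np.exp(rng.normal(-0.5 * _RHYTHM_LOGSTD**2,
                                        _RHYTHM_LOGSTD, rhythm_cols.shape[1]))
                rhythm = _band_noise(rng, rhythm_cols.shape[1], n_samp, fs,
                                     gain)
                x += rhythm_gain * (rhythm_cols * amp) @ rhythm
            x += L @ _pink_noise(rng, montage.n_channels, n_samp, pink_w)
            if eog_col is not None:
                blink = rng.standard_normal(n_samp + int(fs))
                blink = sps.sosfilt(eog_sos, blink)[int(fs):]
                blink /= math.sqrt(eog_gain)
                x += config.eog_amplitude * np.outer(eog_col, blink)
            data[trial] = _BACKGROUND_RMS_UV * x
            labels[trial] = label
            trial += 1

    epochs = EpochSet(data, np.asarray(labels, dtype=str), fs, montage, t0)
    truth = SyntheticTruth(A, truth_var, config.seed)
    return epochs, truth


def to_continuous(epochs: EpochSet, gap_s: float = 0.5):
    """Stitch trials into one continuous record with a cue-event table.

    Trials are concatenated with ``gap_s`` of silence between them; each
    trial contributes one event at its cue sample (sample 0 of the trial is
    at ``t0_offset_s`` before the cue).  The record's reference is the left
    mastoid, matching the simulated acquisition.
    """
    from .preprocessing import ContinuousRecord  # local import avoids a cycle

    gap = int(round(gap_s * epochs.fs))
    n, c, s = epochs.data.shape
    total = n * (s + gap)
    data = np.zeros((c, total))
    events = []
    pre = int(round(-epochs.t0_offset_s * epochs.fs))
    for i in range(n):
        start = i * (s + gap)
        data[:, start:start + s] = epochs.data[i]
        events.append((start + pre, str(epochs.labels[i])))
    return ContinuousRecord(data, epochs.fs, epochs.montage, events,
                            reference="LM")
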