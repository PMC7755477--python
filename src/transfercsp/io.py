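"""Serialization: HDF5 trial containers, EDF continuous export, TSV tables.

The canonical container for epoched data is a small HDF5 layout::

    /data            float64 (trials, channels, samples), microvolts
    /labels          UTF-8 strings, one per trial
    /fs              scalar sampling rate [Hz]
    /t0_offset_s     time of sample 0 relative to the cue [s]
    /montage/channel_names
    /montage/positions

Continuous records additionally round-trip through EDF (16-bit, so subject
to quantization at the chosen physical range) with a TSV event table
(columns ``sample``, ``label``) on the side.  EDF files are written by a
minimal writer for the fixed-layout EDF header and read back through MNE's
EDF reader.
"""

from __future__ import annotations

import numpy as np

from .csp import FilterBank, PatternMap
from .errors import FormatError
from .synthetic import EpochSet, Montage, make_montage
from .transfer import FisherReport


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels",
                         data=np.asarray(epochs.labels, dtype=object),
                         dtype=h5py.string_dtype())
        f["fs"] = float(epochs.fs)
        f["t0_offset_s"] = float(epochs.t0_offset_s)
        g = f.create_group("montage")
        g.create_dataset("channel_names",
                         data=np.asarray(epochs.montage.channel_names,
                                         dtype=object),
                         dtype=h5py.string_dtype())
        g.create_dataset("positions", data=epochs.montage.positions)


def _require(f, key: str):
    if key not in f:
        raise FormatError(f"epoch container is missing field '{key}'")
    return f[key]


def read_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        data = _require(f, "data")[()]
        labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                           for s in _require(f, "labels")[()]])
        fs = float(_require(f, "fs")[()])
        t0 = float(_require(f, "t0_offset_s")[()])
        g = _require(f, "montage")
        names = tuple(s.decode() if isinstance(s, bytes) else str(s)
                      for s in _require(g, "channel_names")[()])
        positions = _require(g, "positions")[()]
    return EpochSet(data, labels, fs, Montage(names, positions), t0)


# ---------------------------------------------------------------------------
# EDF continuous export / import
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec, path, events_path=None) -> None:
    """Write a continuous record as EDF (1-second data records, int16).

    The signal is zero-padded to a whole number of seconds; amplitudes are
    quantized to the per-channel physical range, so the round-trip is exact
    only to 16-bit resolution.  Events go to ``events_path`` as TSV
    (see :func:`write_events_tsv`), defaulting to ``<path>.events.tsv``.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    nchan = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((nchan, n_rec * spr))
    padded[:, :rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    dig_max = 32767
    digital = np.round(padded / phys_max[:, None] * dig_max).astype("<i2")

    header = b"".join([
        _edf_ascii(0, 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii("01.01.00", 8),
        _edf_ascii("00.00.00", 8),
        _edf_ascii(256 * (1 + nchan), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_rec, 8),
        _edf_ascii(1, 8),
        _edf_ascii(nchan, 4),
    ])
    fields = [
        (16, list(rec.montage.channel_names)),
        (80, [""] * nchan),
        (8, ["uV"] * nchan),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, [-dig_max] * nchan),
        (8, [dig_max] * nchan),
        (80, [""] * nchan),
        (8, [spr] * nchan),
        (32, [""] * nchan),
    ]
    for width, values in fields:
        header += b"".join(_edf_ascii(v, width) for v in values)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())

    if events_path is None:
        events_path = str(path) + ".events.tsv"
    write_events_tsv(rec.events, events_path)


def write_events_tsv(events, path) -> None:
    with open(path, "w") as f:
        f.write("sample\tlabel\n")
        for sample, label in events:
            f.write(f"{int(sample)}\t{label}\n")


def read_events_tsv(path) -> list[tuple[int, str]]:
    events = []
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        if header != ["sample", "label"]:
            raise FormatError(
                f"event table must have columns 'sample'/'label', got {header}"
            )
        for line in f:
            if not line.strip():
                continue
            sample, label = line.rstrip("\n").split("\t")
            events.append((int(sample), label))
    return events


def read_edf(path, events_path=None, montage: Montage | None = None):
    """Read an EDF continuous record (via MNE's EDF reader).

    EDF stores no electrode coordinates: pass ``montage`` to restore exact
    positions, otherwise a default ring layout is rebuilt from the channel
    count (names are taken from the file).
    """
    import mne

    from .preprocessing import ContinuousRecord

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    fs = float(raw.info["sfreq"])
    names = tuple(raw.ch_names)
    if montage is None:
        layout = make_montage(len(names))
        montage = Montage(names, layout.positions)
    elif tuple(montage.channel_names) != names:
        raise FormatError("supplied montage does not match EDF channel names")
    events = read_events_tsv(events_path) if events_path else []
    return ContinuousRecord(data, fs, montage, events, reference="LM")


# ---------------------------------------------------------------------------
# Filter banks, patterns, reports
# ---------------------------------------------------------------------------

def write_filter_bank(bank: FilterBank, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=bank.filters)
        f.create_dataset("eigenvalues", data=bank.eigenvalues)
        f.create_dataset("group", data=np.asarray(bank.group, dtype=object),
                         dtype=h5py.string_dtype())
        f.create_dataset("source_classes",
                         data=np.asarray(bank.source_classes, dtype=object),
                         dtype=h5py.string_dtype())
        if bank.source_indices is not None:
            f.create_dataset("source_indices", data=bank.source_indices)


def read_filter_bank(path) -> FilterBank:
    import h5py

    with h5py.File(path, "r") as f:
        dec = lambda a: np.array([s.decode() if isinstance(s, bytes) else str(s)
                                  for s in a])
        return FilterBank(
            _require(f, "filters")[()],
            _require(f, "eigenvalues")[()],
            dec(_require(f, "group")[()]),
            tuple(dec(_require(f, "source_classes")[()])),
            f["source_indices"][()] if "source_indices" in f else None,
        )


def write_patterns_tsv(patterns: PatternMap, path) -> None:
    """One row per channel, one ``pattern_<j>`` column per filter."""
    if patterns.montage is None:
        raise FormatError("pattern export needs a montage for channel names")
    import pandas as pd

    df = pd.DataFrame(patterns.patterns.T,
                      columns=[f"pattern_{j}"
                               for j in range(patterns.patterns.shape[0])])
    df.insert(0, "channel", list(patterns.montage.channel_names))
    df.insert(1, "x", patterns.montage.positions[:, 0])
    df.insert(2, "y", patterns.montage.positions[:, 1])
    df.to_csv(path, sep="\t", index=False)


def write_fisher_report_tsv(report: FisherReport, bank: FilterBank, path) -> None:
    report.to_frame(bank).to_csv(path, sep="\t", index=False)
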