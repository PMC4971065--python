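"""Readers and writers for every artifact the pipeline touches.

EEG arrives either as EDF (read through :mod:`mne`) or as a plain
delimited channels x samples matrix with a declared sampling rate.
Montages, subject tables and all result tables are tab-separated text
with a fixed header line so outputs diff cleanly between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: significant digits used for every float written to disk; 12 keeps
#: round-trip error comfortably under 1e-9 relative
_FLOAT_FMT = "%.12g"

# 64-channel subset of the extended 10-20 system matching a typical
# MR-compatible recording cap (Fpz is not populated on these caps).
STANDARD_64_NAMES = [
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]


@dataclass(frozen=True)
class Montage:
    """Electrode identities and 2-D scalp positions (head-top view, nose up)."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), unitless

    def __post_init__(self):
        names = tuple(self.channel_names)
        pos = np.asarray(self.positions, dtype=float)
        if len(names) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must be ({len(names)}, 2), got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("montage positions must be finite")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    subject_id: str = "s00"
    group: str = "control"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SubjectTable:
    """Per-subject metadata: group membership plus the model covariates."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("subject_id", "group", "age", "gender")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"subject table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in subject table")

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())


def builtin_montage(name: str = "standard-10-20-64") -> Montage:
    """Return a named built-in montage.

    ``standard-10-20-64`` is a 64-channel extended 10-20 layout whose 2-D
    positions come from stereographic projection of the mne standard
    electrode digitization (head-top view, nose up).
    """
    if name != "standard-10-20-64":
        raise ValueError(f"unknown built-in montage {name!r}")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = std.get_positions()["ch_pos"]
    pos2d = np.empty((len(STANDARD_64_NAMES), 2))
    for i, ch in enumerate(STANDARD_64_NAMES):
        x, y, z = ch_pos[ch]
        r = np.sqrt(x * x + y * y + z * z)
        # stereographic projection from below the head: nose-up 2-D layout
        denom = 1.0 + z / r
        pos2d[i] = (x / r / denom, y / r / denom)
    # normalize to roughly unit head radius
    pos2d /= np.abs(pos2d).max()
    return Montage(tuple(STANDARD_64_NAMES), pos2d)


def read_montage(path: str | Path) -> Montage:
    """Read a montage TSV with columns ``name<TAB>x<TAB>y``.

    Whitespace-delimited files are accepted; a header line is optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names, xs, ys = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'name x y', got {line!r}")
            if ln == 1 and parts[0].lower() == "name":
                continue
            try:
                x, y = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric position") from exc
            names.append(parts[0])
            xs.append(x)
            ys.append(y)
    return Montage(tuple(names), np.column_stack([xs, ys]))


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tx\ty\n")
        for name, (x, y) in zip(montage.channel_names, montage.positions):
            fh.write(f"{name}\t{_FLOAT_FMT % x}\t{_FLOAT_FMT % y}\n")


def read_subject_table(path: str | Path) -> SubjectTable:
    df = pd.read_csv(path, sep="\t")
    return SubjectTable(df)


def write_subject_table(subjects: SubjectTable, path: str | Path) -> None:
    subjects.table.to_csv(path, sep="\t", index=False)


def _match_channels(
    data: np.ndarray, names: list[str], montage: Montage
) -> np.ndarray:
    """Reorder rows of ``data`` to montage order, dropping unmatched channels."""
    index = {n: i for i, n in enumerate(names)}
    rows, missing = [], []
    for ch in montage.channel_names:
        if ch in index:
            rows.append(index[ch])
        else:
            missing.append(ch)
    if missing:
        raise ValueError(f"montage channels absent from file: {missing}")
    unmatched = [n for n in names if n not in set(montage.channel_names)]
    if unmatched:
        logger.warning("dropping %d unmatched channels: %s", len(unmatched), unmatched)
    if not rows:
        raise ValueError("no channels matched the montage")
    return data[rows]


def read_eeg(
    path: str | Path,
    montage: Montage,
    fs: float | None = None,
    subject_id: str = "s00",
    group: str = "control",
) -> EEGRecording:
    """Read EEG from EDF or from a delimited channels x samples matrix.

    EDF carries its own sampling rate and channel labels; channels are
    matched to the montage by name and unmatched ones dropped with a
    warning.  For a plain matrix, ``fs`` must be given and rows are taken
    to already follow montage order unless the first column is a label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads volts; we keep microvolts
        data = _match_channels(data, list(raw.ch_names), montage)
        return EEGRecording(data, float(raw.info["sfreq"]), montage, subject_id, group)

    if fs is None:
        raise ValueError("fs is required for plain-matrix EEG input")
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    first_col = df.iloc[:, 0]
    if first_col.dtype == object:  # labelled rows
        names = first_col.astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise ValueError(f"non-numeric EEG values in {path}")
        data = _match_channels(np.asarray(values, dtype=float), names, montage)
    else:
        data = df.to_numpy()
        if not np.issubdtype(data.dtype, np.number):
            raise ValueError(f"non-numeric EEG values in {path}")
        data = np.asarray(data, dtype=float)
    return EEGRecording(data, fs, montage, subject_id, group)


def write_eeg_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write EEG as a labelled TSV matrix (one row per channel)."""
    with open(path, "w") as fh:
        for name, row in zip(rec.montage.channel_names, rec.data):
            fh.write(name + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def write_eeg_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write an EDF file (16-bit, one data record per second).

    Minimal writer covering the fixed-header EDF layout; physical range
    is set per channel from the data so quantization error stays below
    ~2**-15 of the signal range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.montage.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.where(pmax - pmin < 1e-6, 1.0, pmax - pmin)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / span
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f(f"X X X {rec.subject_id}", 80),
        f("Startdate X X X X", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8),
        f("", 44),
        f(str(n_rec), 8),
        f("1", 8),
        f(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(f(n, 16) for n in rec.montage.channel_names),
        b"".join(f("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(f(f"{v:.6g}"[:8], 8) for v in pmin + span),
        b"".join(f(str(dmin), 8) for _ in range(n_ch)),
        b"".join(f(str(dmax), 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(fs), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a generic delimited numeric table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Write one TSV per named table plus a JSON manifest.

    Column order is preserved as given (deterministic); floats use 9
    significant digits.  The manifest lists every file with its SHA-1 and
    a hash of the configuration that produced it.
    """
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "config_hash": None}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        manifest["config_hash"] = hashlib.sha1(blob).hexdigest()
    for name, df in tables.items():
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        df.to_csv(fpath, sep="\t", index=False, float_format=_FLOAT_FMT)
        manifest["files"][fname] = hashlib.sha1(fpath.read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
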