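"""Reading, filtering and windowing of multichannel recordings.

A :class:`Recording` is one subject's multichannel signal with a binary
class label (patient = 1, control = 0).  Recordings are band-limited with
zero-phase Butterworth filters and cut into fixed-length
:class:`Segment` windows that carry subject and label provenance through
the rest of the pipeline.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Canonical 10-20 montage labels used to restore capitalisation of EDF
#: channel names ("FP1" -> "Fp1" etc.).
TEN_TWENTY_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4", "P3", "Pz", "P4",
    "T3", "T4", "T5", "T6", "O1", "O2",
)

_CANONICAL = {name.upper(): name for name in TEN_TWENTY_LABELS}


class ValidationError(ValueError):
    """An input violates a documented precondition."""


@dataclass
class Recording:
    """One subject's multichannel signal.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    label : int
        Binary class label; 1 = patient, 0 = control.
    channel_names : list of str
        One unique name per row of ``data``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Real-valued signal, channels in row order.
    """

    subject_id: str
    label: int
    channel_names: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite values")
        if self.label not in (0, 1):
            raise ValidationError("label must be 0 (control) or 1 (patient)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment:
    """A fixed-length window of one recording."""

    subject_id: str
    label: int
    segment_index: int
    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.segment_index < 0:
            raise ValidationError("segment_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def normalize_edf_label(raw: str) -> str:
    """Map an EDF channel label dialect onto a bare 10-20 name.

    Strips a leading ``"EEG "`` token and anything from the first ``"-"``
    onward (reference suffixes such as ``"-REF"`` or ``"-A2"``), then
    restores canonical 10-20 capitalisation when the result matches a
    montage label case-insensitively.
    """
    name = re.sub(r"^\s*EEG\s+", "", raw, flags=re.IGNORECASE)
    name = name.split("-", 1)[0].strip()
    canonical = _CANONICAL.get(name.upper(), name)
    if canonical != raw:
        logger.info("renamed EDF channel %r -> %r", raw, canonical)
    return canonical


def read_recording(
    path: str | Path,
    label: int,
    format: str = "csv",
    *,
    subject_id: str | None = None,
    fs: float | None = None,
    transposed: bool = False,
    delimiter: str | None = None,
) -> Recording:
    """Read one subject's recording from disk.

    Parameters
    ----------
    path : path
        File to read.
    label : int
        Binary class label attached to the recording.
    format : {"csv", "edf"}
        ``"csv"`` expects a delimited text matrix: by default a header row
        of channel names with one column per channel (samples as rows);
        with ``transposed=True``, one row per channel whose first field is
        the channel name.  ``"edf"`` reads European Data Format via mne.
    subject_id : str, optional
        Defaults to the file stem.
    fs : float, optional
        Sampling rate for CSV input (the file does not carry one).
        Ignored for EDF, which stores it in the header.
    transposed : bool
        CSV orientation flag, see above.
    delimiter : str, optional
        CSV delimiter; inferred from the extension (``.tsv`` -> tab)
        when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    subject_id = subject_id if subject_id is not None else path.stem

    if format == "edf":
        names, fs_edf, data = _read_edf(path)
        rec_fs = float(fs_edf)
        channel_names, matrix = names, data
    elif format == "csv":
        if fs is None:
            raise ValidationError("fs is required for CSV input")
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
        channel_names, matrix = _read_csv_matrix(path, delimiter, transposed)
        rec_fs = float(fs)
    else:
        raise ValidationError(f"unknown format {format!r}; expected 'csv' or 'edf'")

    if len(channel_names) < 2:
        raise ValidationError(
            f"{path}: connectivity needs >= 2 channels, found {len(channel_names)}"
        )
    return Recording(subject_id, int(label), channel_names, rec_fs, matrix)


def _read_edf(path: Path) -> tuple[list[str], float, np.ndarray]:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error classes vary
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    names = [normalize_edf_label(ch) for ch in raw.ch_names]
    # mne scales EEG channels to volts; keep native units by undoing nothing —
    # connectivity measures are scale-aware only through the noise covariance.
    return names, raw.info["sfreq"], raw.get_data()


def _read_csv_matrix(
    path: Path, delimiter: str, transposed: bool
) -> tuple[list[str], np.ndarray]:
    try:
        if transposed:
            names: list[str] = []
            rows: list[list[float]] = []
            with open(path, newline="") as fh:
                for row in csv.reader(fh, delimiter=delimiter):
                    if not row:
                        continue
                    names.append(row[0])
                    rows.append([float(v) for v in row[1:]])
            matrix = np.asarray(rows, dtype=float)
        else:
            frame = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
            names = [str(c) for c in frame.columns]
            matrix = frame.to_numpy(dtype=float).T
    except (ValueError, pd.errors.ParserError) as exc:
        raise IOError(f"could not parse {path} as delimited matrix: {exc}") from exc
    return names, matrix


def write_recording(
    rec: Recording,
    path: str | Path,
    *,
    transposed: bool = False,
    delimiter: str | None = None,
) -> None:
    """Write a recording as a delimited text matrix (inverse of CSV read).

    Values are written with :func:`repr` precision so a read-back is
    bit-identical.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if transposed:
            for name, row in zip(rec.channel_names, rec.data):
                writer.writerow([name, *(repr(float(v)) for v in row)])
        else:
            writer.writerow(rec.channel_names)
            for col in rec.data.T:
                writer.writerow([repr(float(v)) for v in col])


def bandlimit(
    rec: Recording, low_cut: float = 0.5, high_cut: float = 50.0, order: int = 4
) -> Recording:
    """Band-limit a recording with zero-phase Butterworth filters.

    A high-pass at ``low_cut`` and a low-pass at ``high_cut`` (each of the
    given order) are applied forward-backward (``sosfiltfilt``), so the
    effective attenuation is doubled and the phase response is exactly
    zero — phase distortion would bias directed-causality estimates.
    """
    if not (0 < low_cut < high_cut < rec.fs / 2):
        raise ValidationError(
            f"need 0 < low_cut < high_cut < fs/2, got "
            f"({low_cut}, {high_cut}) at fs={rec.fs}"
        )
    sos_hp = signal.butter(order, low_cut, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(order, high_cut, btype="lowpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, rec.data, axis=1), axis=1)
    return Recording(rec.subject_id, rec.label, list(rec.channel_names), rec.fs, out)


def segment_recording(
    rec: Recording, window_seconds: float = 60.0, overlap_fraction: float = 0.0
) -> list[Segment]:
    """Cut a recording into fixed-length windows.

    Windows are anchored at sample 0 and advance by
    ``window_seconds * (1 - overlap_fraction)``; a trailing partial window
    is discarded.  A recording shorter than one window yields an empty
    list with a logged warning.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValidationError("overlap_fraction must be in [0, 1)")
    n_win = int(round(window_seconds * rec.fs))
    if n_win <= 0:
        raise ValidationError("window_seconds * fs must be >= 1 sample")
    if n_win > rec.n_samples:
        logger.warning(
            "recording %s (%d samples) shorter than one %d-sample window; "
            "no segments produced",
            rec.subject_id, rec.n_samples, n_win,
        )
        return []
    step = int(round(n_win * (1 - overlap_fraction)))
    step = max(step, 1)
    starts = range(0, rec.n_samples - n_win + 1, step)
    return [
        Segment(
            subject_id=rec.subject_id,
            label=rec.label,
            segment_index=k,
            data=rec.data[:, s : s + n_win].copy(),
            fs=rec.fs,
            channel_names=list(rec.channel_names),
        )
        for k, s in enumerate(starts)
    ]


def load_manifest(
    manifest_path: str | Path,
    format: str = "csv",
    *,
    fs: float | None = None,
) -> list[Recording]:
    """Load a cohort from a manifest CSV with columns subject_id, path, label.

    Relative paths in the manifest are resolved against its directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, "
            f"found {list(table.columns)}"
        )
    recordings = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        recordings.append(
            read_recording(
                p, int(row.label), format=format,
                subject_id=str(row.subject_id), fs=fs,
            )
        )
    return recordings


def segment_cohort(
    recordings: Sequence[Recording],
    window_seconds: float = 60.0,
    overlap_fraction: float = 0.0,
    *,
    low_cut: float | None = 0.5,
    high_cut: float | None = 50.0,
    filter_order: int = 4,
) -> list[Segment]:
    """Filter and window every recording of a cohort.

    Pass ``low_cut=None`` (or ``high_cut=None``) to skip filtering.
    """
    segments: list[Segment] = []
    for rec in recordings:
        if low_cut is not None and high_cut is not None:
            rec = bandlimit(rec, low_cut, high_cut, order=filter_order)
        segments.extend(segment_recording(rec, window_seconds, overlap_fraction))
    return segments
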