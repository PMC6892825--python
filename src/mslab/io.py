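"""In-memory containers and file I/O for multichannel EEG recordings.

The package's working container is :class:`Recording`, a plain channels x
samples matrix in microvolts with sampling rate, channel names, spherical
montage coordinates and a reference-state flag. EDF files are read through
MNE; recordings are written to disk as FIF (MNE's native format), which the
installed stack can both write and read round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import CHANNELS_1020, standard_1020_positions, validate_montage

RAW = "raw"
AVERAGE = "average"


@dataclass
class Recording:
    """A continuous multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels (10-20 names for the default montage).
    montage : ndarray, shape (n_channels, 3)
        Unit-sphere electrode positions.
    reference : str
        ``"raw"`` or ``"average"``; the latter asserts every sample has
        zero channel mean.
    annotations : dict
        Event onsets in seconds, e.g. ``{"eyes_closed": 0.0}``.
    boundaries : list of int
        Interior sample indices where concatenated epochs abut.
    subject_id : str
        Identifier carried through the pipeline.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    montage: np.ndarray
    reference: str = RAW
    annotations: dict = field(default_factory=dict)
    boundaries: list[int] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must have at least one channel and sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match channel count")
        self.montage = validate_montage(self.montage)
        if self.montage.shape[0] != self.data.shape[0]:
            raise ValueError("montage length must match channel count")
        if self.reference not in (RAW, AVERAGE):
            raise ValueError(f"unknown reference state {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with `data` (and any other fields) replaced."""
        if "data" in kwargs:
            kwargs["data"] = np.asarray(kwargs["data"], dtype=float)
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        return out


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one subject's recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    ch_names: list[str]
    montage: np.ndarray
    reference: str = RAW
    subject_id: str = ""
    quality: list[str] = field(default_factory=list)  # per-epoch flags
    source_epochs: list[int] = field(default_factory=list)  # provenance

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, length)")
        if not self.quality:
            self.quality = ["clean"] * len(self)
        if not self.source_epochs:
            self.source_epochs = list(range(len(self)))

    def __len__(self) -> int:
        return self.epochs.shape[0]


def _to_mne_raw(rec: Recording):
    import mne

    info = mne.create_info(rec.ch_names, rec.fs, ch_types="eeg", verbose="error")
    # MNE raws are in volts
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    if rec.annotations:
        onsets = [float(v) for v in rec.annotations.values()]
        descs = list(rec.annotations.keys())
        raw.set_annotations(
            mne.Annotations(onset=onsets, duration=[0.0] * len(onsets),
                            description=descs)
        )
    return raw


def write_fif(rec: Recording, path: str | Path) -> Path:
    """Write a recording to FIF; a JSON sidecar keeps the pipeline metadata."""
    path = Path(path)
    raw = _to_mne_raw(rec)
    raw.save(path, overwrite=True, fmt="double", verbose="error")
    sidecar = {
        "subject_id": rec.subject_id,
        "reference": rec.reference,
        "boundaries": [int(b) for b in rec.boundaries],
        "annotations": {k: float(v) for k, v in rec.annotations.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EEG file (FIF or EDF) into a :class:`Recording`.

    Channels are reordered to the standard 19-channel 10-20 layout when all
    of those labels are present; otherwise the file's own order is kept and
    the montage is looked up per label.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG file type: {path.suffix}")

    names = [n.strip() for n in raw.ch_names]
    # normalise legacy temporal labels
    legacy = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}
    names = [legacy.get(n, n) for n in names]
    if set(CHANNELS_1020) <= set(names):
        order = [names.index(ch) for ch in CHANNELS_1020]
        data = raw.get_data()[order] * 1e6
        ch_names = list(CHANNELS_1020)
    else:
        data = raw.get_data() * 1e6
        ch_names = names
    montage = standard_1020_positions(tuple(ch_names))

    annotations: dict = {}
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        annotations.setdefault(str(desc), float(onset))

    reference, boundaries = RAW, []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        reference = meta.get("reference", RAW)
        boundaries = [int(b) for b in meta.get("boundaries", [])]
        annotations.update(meta.get("annotations", {}))
        subject_id = subject_id or meta.get("subject_id")

    return Recording(
        data=data, fs=float(raw.info["sfreq"]), ch_names=ch_names,
        montage=montage, reference=reference, annotations=annotations,
        boundaries=boundaries, subject_id=subject_id or path.stem,
    )
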