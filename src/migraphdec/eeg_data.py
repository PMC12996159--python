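"""Trial containers and the multi-view band-pass filter bank.

A motor-imagery experiment yields epoched multichannel EEG: an array of
``n_trials x C x T`` microvolt samples with a class label per trial.  Before
decoding, each trial is decomposed into nine parallel band-limited views
(4-8, 8-12, ..., 36-40 Hz), covering the theta-to-gamma range in which
event-related (de)synchronisation is expressed.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (lo, lo + 4.0) for lo in np.arange(4.0, 40.0, 4.0)
)

#: 10-20 montage of the 22-electrode cap used for the canonical 4-class setup.
BCI2A_CHANNELS = [
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4", "C5", "C3", "C1", "Cz", "C2",
    "C4", "C6", "CP3", "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2", "POz",
]


class FormatError(ValueError):
    """A trial container is malformed or of an unknown version."""


@dataclass
class TrialSet:
    """Labelled raw EEG trials plus recording metadata.

    signals are ``(n_trials, C, T)`` in microvolts; labels are integer class
    indices.  Optional ``session`` / ``subject`` arrays (one entry per trial)
    enable the split protocols in :mod:`migraphdec.training`.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str]
    session: np.ndarray | None = None
    subject: np.ndarray | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (n_trials, C, T)")
        if len(self.labels) != self.signals.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != n_trials {self.signals.shape[0]}"
            )
        if len(self.channel_names) != self.signals.shape[1]:
            raise ValueError("channel_names length must equal C")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            signals=self.signals[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
            session=None if self.session is None else self.session[idx],
            subject=None if self.subject is None else self.subject[idx],
        )


@dataclass(frozen=True)
class FilterBankSpec:
    """Band edges and filter design of the analysis filter bank.

    The default design is a Chebyshev type-II band-pass (30 dB stop-band,
    order 8 realised as second-order sections) applied forward-backward so
    each view is zero-phase; a Butterworth order-4 alternative is available.
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    design: str = "chebyshev2"
    order: int = 8
    zero_phase: bool = True
    stop_atten_db: float = 30.0

    def __post_init__(self):
        if not self.bands:
            raise ValueError("at least one band is required")
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have low < high")
        if self.design not in ("chebyshev2", "butterworth"):
            raise ValueError(f"unknown filter design {self.design!r}")
        if self.order < 1:
            raise ValueError("order must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def sos(self, band: tuple[float, float], fs: float) -> np.ndarray:
        lo, hi = band
        if hi >= fs / 2:
            raise ValueError(f"band edge {hi} Hz >= Nyquist {fs / 2} Hz")
        if self.design == "chebyshev2":
            # order N band-pass from an N/2 prototype; edges are stop-band
            # corners so the nominal band sits inside the pass-band
            return signal.cheby2(
                max(self.order // 2, 1), self.stop_atten_db, [lo, hi],
                btype="bandpass", fs=fs, output="sos",
            )
        return signal.butter(
            max(self.order // 2, 1), [lo, hi], btype="bandpass", fs=fs,
            output="sos",
        )


@dataclass
class MultiViewTrial:
    """One trial decomposed into band-limited views, shape (N_b, C, T)."""

    data: np.ndarray
    bands: tuple[tuple[float, float], ...] = field(default=DEFAULT_BANDS)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.bands):
            raise ValueError("data must be (N_b, C, T) matching the band list")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("multi-view data contains non-finite values")


def apply_filter_bank(
    trial: np.ndarray, fs: float, spec: FilterBankSpec | None = None
) -> MultiViewTrial:
    """Decompose a single (C, T) trial into its (N_b, C, T) band views."""
    spec = spec or FilterBankSpec()
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2:
        raise ValueError("trial must be a (C, T) array")
    if not np.all(np.isfinite(trial)):
        raise ValueError("trial contains non-finite values")
    if trial.shape[1] <= 3 * spec.order:
        raise ValueError("trial too short for stable forward-backward filtering")

    views = np.empty((spec.n_bands, *trial.shape), dtype=np.float64)
    for b, band in enumerate(spec.bands):
        sos = spec.sos(band, fs)
        if spec.zero_phase:
            views[b] = signal.sosfiltfilt(sos, trial, axis=-1)
        else:
            views[b] = signal.sosfilt(sos, trial, axis=-1)
    return MultiViewTrial(data=views, bands=spec.bands)


def filter_bank_batch(
    signals: np.ndarray, fs: float, spec: FilterBankSpec | None = None
) -> np.ndarray:
    """Vectorised filter bank over (n, C, T) -> (n, N_b, C, T) float32."""
    spec = spec or FilterBankSpec()
    signals = np.asarray(signals, dtype=np.float64)
    n, C, T = signals.shape
    out = np.empty((n, spec.n_bands, C, T), dtype=np.float32)
    for b, band in enumerate(spec.bands):
        sos = spec.sos(band, fs)
        flat = signals.reshape(n * C, T)
        if spec.zero_phase:
            out[:, b] = signal.sosfiltfilt(sos, flat, axis=-1).reshape(n, C, T)
        else:
            out[:, b] = signal.sosfilt(sos, flat, axis=-1).reshape(n, C, T)
    return out


# ---------------------------------------------------------------------------
# container I/O

_FORMAT_VERSION = 1
_REQUIRED = ("signals", "labels")
_REQUIRED_ATTRS = ("fs", "channel_names", "class_names")


def save_trialset(tset: TrialSet, path) -> None:
    """Write a TrialSet to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.create_dataset("signals", data=tset.signals.astype(np.float32))
        f.create_dataset("labels", data=tset.labels.astype(np.int64))
        f.attrs["fs"] = float(tset.fs)
        f.attrs["channel_names"] = [str(c) for c in tset.channel_names]
        f.attrs["class_names"] = [str(c) for c in tset.class_names]
        if tset.session is not None:
            f.create_dataset("session", data=np.asarray(tset.session, dtype=np.int64))
        if tset.subject is not None:
            f.create_dataset("subject", data=np.asarray(tset.subject, dtype=np.int64))


def _load_hdf5(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is not None and int(version) > _FORMAT_VERSION:
            raise FormatError(f"unknown container version {version}")
        for name in _REQUIRED:
            if name not in f:
                raise FormatError(f"container missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"container missing attribute {name!r}")
        return TrialSet(
            signals=f["signals"][()],
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            class_names=[str(c) for c in f.attrs["class_names"]],
            session=f["session"][()] if "session" in f else None,
            subject=f["subject"][()] if "subject" in f else None,
        )


def _load_zip(path) -> TrialSet:
    import json

    with zipfile.ZipFile(path) as z:
        names = set(z.namelist())
        if "meta.json" not in names:
            raise FormatError("container missing attribute 'fs' (no meta.json)")
        meta = json.loads(z.read("meta.json"))
        for key in _REQUIRED_ATTRS:
            if key not in meta:
                raise FormatError(f"container missing attribute {key!r}")
        arrays = {}
        for name in ("signals", "labels", "session", "subject"):
            if f"{name}.npy" in names:
                arrays[name] = np.load(io.BytesIO(z.read(f"{name}.npy")))
        for name in _REQUIRED:
            if name not in arrays:
                raise FormatError(f"container missing dataset {name!r}")
        return TrialSet(
            signals=arrays["signals"],
            labels=arrays["labels"],
            fs=float(meta["fs"]),
            channel_names=list(meta["channel_names"]),
            class_names=list(meta["class_names"]),
            session=arrays.get("session"),
            subject=arrays.get("subject"),
        )


def load_trialset(path) -> TrialSet:
    """Read a TrialSet from HDF5 (preferred) or a zip-of-arrays container."""
    if h5py.is_hdf5(path):
        return _load_hdf5(path)
    if zipfile.is_zipfile(path):
        return _load_zip(path)
    raise FormatError(f"{path}: not an HDF5 or zip trial container")


# ---------------------------------------------------------------------------
# real-data adapters (declared interface; implementations are optional and
# depend on recording-format libraries not required by the core package)

class TrialSetAdapter:
    """Interface for readers of external recording formats.

    Implementations epoch a continuous recording into a :class:`TrialSet`.
    """

    def read(self, path) -> TrialSet:  # pragma: no cover - interface only
        raise NotImplementedError


def read_gdf(path) -> TrialSet:  # pragma: no cover - optional adapter
    """Stub for GDF/EDF ingestion (e.g. 22-channel 4-class cued MI).

    Requires an EDF/GDF reader such as ``mne``; epoch on cue markers and
    return a TrialSet.  Not needed for any functionality in this package.
    """
    raise NotImplementedError("GDF/EDF ingestion is not implemented")


def read_openbmi_mat(path) -> TrialSet:  # pragma: no cover - optional adapter
    """Stub for MAT-file ingestion of 2-class left/right-hand MI sessions."""
    raise NotImplementedError("MAT ingestion is not implemented")
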