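"""Reading and writing recordings, respiration references, and reports.

Two on-disk formats are supported for optical-density recordings:

* **CSV** -- one header row, comma separated, UTF-8, ``.`` decimal: a
  ``time_s`` column followed by one column per wavelength per channel named
  ``<channel>_<wavelength>nm`` (e.g. ``ch1_760nm``). One file per recording.
* **SNIRF** -- an HDF5 container following the SNIRF v1.0 group layout
  (``/nirs1/data1/dataTimeSeries``, per-column ``measurementList`` entries,
  probe wavelengths and optode positions).

Sample indexing is 0-based with half-open intervals; timestamps are seconds.
The time axis of a recording is reconstructed from the sampling rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError
from .rr import DEFAULT_PAD_FACTOR, DEFAULT_SEARCH_BAND, estimate_rr

__all__ = [
    "Recording",
    "RespirationRef",
    "read_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_snirf",
    "read_recording_snirf",
    "write_respiration_csv",
    "read_respiration_csv",
    "reference_rr",
    "write_json",
]


@dataclass
class Recording:
    """Multichannel optical-density recording.

    ``od`` is (n_samples, n_channels * 2) with the two wavelength columns of
    each channel adjacent, in the order of ``channel_labels`` x
    ``wavelengths``. Values are unitless OD changes.
    """

    od: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float] = (760.0, 850.0)
    channel_labels: list[str] = field(default_factory=list)
    source_detector_distance_mm: float = 35.0

    def __post_init__(self) -> None:
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValidationError("exactly two wavelengths required")
        if self.od.shape[1] % 2 != 0:
            raise ValidationError("OD matrix must have two columns per channel")
        n_channels = self.od.shape[1] // 2
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(n_channels)]
        if len(self.channel_labels) != n_channels:
            raise ValidationError("channel_labels length mismatch")
        if self.od.shape[0] < 10 * self.sampling_rate:
            raise ValidationError(
                "recording must span at least one 10 s quality window"
            )

    @property
    def n_channels(self) -> int:
        return self.od.shape[1] // 2

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.od.shape[0]) / self.sampling_rate

    def channel_od(self, label: str) -> np.ndarray:
        i = self.channel_labels.index(label)
        return self.od[:, 2 * i : 2 * i + 2]


@dataclass
class RespirationRef:
    """Concurrent reference respiration trace (arbitrary units)."""

    signal: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")


def _column_names(recording: Recording) -> list[str]:
    names = []
    for label in recording.channel_labels:
        for wl in recording.wavelengths:
            names.append(f"{label}_{wl:g}nm")
    return names


def write_recording_csv(path: str | Path, recording: Recording) -> None:
    df = pd.DataFrame(recording.od, columns=_column_names(recording))
    df.insert(0, "time_s", recording.time)
    df.to_csv(path, index=False)


def read_recording_csv(
    path: str | Path, source_detector_distance_mm: float = 35.0
) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValidationError("malformed header: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError("recording too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("non-monotone time column")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("time column is not uniformly sampled")
    fs = 1.0 / float(dt[0])

    labels: list[str] = []
    wavelengths: list[float] = []
    for col in df.columns[1:]:
        try:
            label, wl = col.rsplit("_", 1)
            wl_nm = float(wl.removesuffix("nm"))
        except ValueError as exc:
            raise ValidationError(f"malformed column name: {col!r}") from exc
        if label not in labels:
            labels.append(label)
        if wl_nm not in wavelengths:
            wavelengths.append(wl_nm)
    if len(wavelengths) != 2:
        raise ValidationError("exactly two wavelengths required")
    expected = [f"{lb}_{wl:g}nm" for lb in labels for wl in wavelengths]
    if list(df.columns[1:]) != expected:
        raise ValidationError("columns are not channel-major wavelength pairs")
    return Recording(
        od=df[expected].to_numpy(dtype=float),
        sampling_rate=fs,
        wavelengths=(wavelengths[0], wavelengths[1]),
        channel_labels=labels,
        source_detector_distance_mm=source_detector_distance_mm,
    )


def write_recording_snirf(path: str | Path, recording: Recording) -> None:
    """Write the recording as a SNIRF v1.0 HDF5 container.

    Each channel is a source-detector pair at ``source_detector_distance_mm``
    along x; columns carry dataType 1 (continuous-wave amplitude-like OD)
    with a wavelength index into ``probe/wavelengths``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs1")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=recording.od)
        data.create_dataset("time", data=recording.time)
        col = 0
        for ch in range(recording.n_channels):
            for wl_idx in range(2):
                ml = data.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl_idx + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))
        d = recording.source_detector_distance_mm
        n = recording.n_channels
        probe.create_dataset(
            "sourcePos3D",
            data=np.column_stack([np.zeros(n), np.arange(n) * 30.0, np.zeros(n)]),
        )
        probe.create_dataset(
            "detectorPos3D",
            data=np.column_stack([np.full(n, d), np.arange(n) * 30.0, np.zeros(n)]),
        )
        labels = np.asarray(recording.channel_labels, dtype=h5py.string_dtype())
        probe.create_dataset("landmarkLabels", data=labels)


def read_recording_snirf(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["/nirs1/data1"]
        od = np.asarray(data["dataTimeSeries"], dtype=float)
        t = np.asarray(data["time"], dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("non-monotone time vector")
        fs = 1.0 / float(t[1] - t[0])
        wavelengths = np.asarray(f["/nirs1/probe/wavelengths"], dtype=float)
        if wavelengths.size != 2:
            raise ValidationError("exactly two wavelengths required")
        src = np.asarray(f["/nirs1/probe/sourcePos3D"], dtype=float)
        det = np.asarray(f["/nirs1/probe/detectorPos3D"], dtype=float)
        distance = float(np.linalg.norm(det[0] - src[0]))
        if "landmarkLabels" in f["/nirs1/probe"]:
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["/nirs1/probe/landmarkLabels"][()]
            ]
        else:
            labels = []
    return Recording(
        od=od,
        sampling_rate=fs,
        wavelengths=(float(wavelengths[0]), float(wavelengths[1])),
        channel_labels=labels,
        source_detector_distance_mm=distance,
    )


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording, inferring the format from the extension if needed."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if fmt is None:
        fmt = "snirf" if path.suffix.lower() in (".snirf", ".h5", ".hdf5") else "csv"
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "snirf":
        return read_recording_snirf(path)
    raise ValidationError(f"unknown format: {fmt!r} (expected csv or snirf)")


def write_respiration_csv(path: str | Path, resp: RespirationRef) -> None:
    t = np.arange(resp.signal.size) / resp.sampling_rate
    pd.DataFrame({"time_s": t, "respiration": resp.signal}).to_csv(path, index=False)


def read_respiration_csv(path: str | Path) -> RespirationRef:
    df = pd.read_csv(path)
    for col in ("time_s", "respiration"):
        if col not in df.columns:
            raise ValidationError(f"malformed header: missing {col} column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError("non-monotone time column")
    return RespirationRef(
        signal=df["respiration"].to_numpy(dtype=float),
        sampling_rate=1.0 / float(t[1] - t[0]),
    )


def reference_rr(
    resp: RespirationRef | np.ndarray,
    sampling_rate: float | None = None,
    band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    pad_factor: int = DEFAULT_PAD_FACTOR,
) -> float:
    """Reference respiratory rate (BPM) from a respiration trace window.

    Uses the same spectral estimator as the final stage of the O2Hb
    pipeline -- mean removal, zero-padded FFT, argmax within the search
    band, x 60 -- so that reference and estimate share one frequency grid.
    The window must span at least two breathing cycles at the slowest rate
    of the search band.
    """
    if isinstance(resp, RespirationRef):
        signal, fs = resp.signal, resp.sampling_rate
    else:
        if sampling_rate is None:
            raise ValidationError("sampling_rate required for a bare array")
        signal, fs = np.asarray(resp, dtype=float), float(sampling_rate)
    if signal.size / fs < 2.0 / band[0]:
        raise ValidationError(
            f"window must span at least two cycles at {band[0]:g} Hz "
            f"({2.0 / band[0]:g} s), got {signal.size / fs:g} s"
        )
    return estimate_rr(signal, fs, band=band, pad_factor=pad_factor).rr_bpm


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
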