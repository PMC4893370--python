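"""Containers and file I/O for M-Scans, pulse traces, labels, features and models.

An M-Scan is a depth x time raster of OCT intensities recorded at a fixed
lateral position: row = depth pixel, column = A-Scan (time step).  Rasters are
interchanged as single-image 32-bit float TIFF plus a JSON metadata sidecar
(id, A-Scan rate, axial pixel pitch); a raw little-endian float32 binary with
the same sidecar is supported as a fallback.  Labels, manifests and feature
matrices travel as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MScan",
    "PulseTrace",
    "LabeledDataset",
    "read_mscan",
    "write_mscan",
    "read_trace",
    "write_trace",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

_SIDECAR_KEYS = ("id", "ascan_rate", "axial_pitch", "shape")


@dataclass
class MScan:
    """A depth x time OCT intensity raster with acquisition metadata.

    Parameters
    ----------
    data
        L x T matrix of non-negative, finite intensities on a linear scale.
        Stored as float32 (the on-disk precision), row 0 = shallowest depth,
        column 0 = earliest time; indices 0-based, ranges half-open.
    ascan_rate
        A-Scan (line) rate in Hz; one column per 1/ascan_rate seconds.
    axial_pitch
        Axial sampling in micrometres per depth pixel.
    id
        Free-form scan identifier.
    """

    data: np.ndarray
    ascan_rate: float
    axial_pitch: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"M-Scan raster must be a non-empty 2-D array, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("M-Scan raster contains non-finite values")
        if (arr < 0).any():
            raise ValueError("M-Scan raster contains negative intensities")
        if not self.ascan_rate > 0:
            raise ValueError("ascan_rate must be positive")
        self.data = np.ascontiguousarray(arr, dtype=np.float32)

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Scan duration in seconds."""
        return self.n_time / self.ascan_rate

    def with_data(self, data: np.ndarray, id_suffix: str = "") -> "MScan":
        """A copy of this scan with a new raster and the same metadata."""
        return MScan(data=data, ascan_rate=self.ascan_rate,
                     axial_pitch=self.axial_pitch, id=self.id + id_suffix)


@dataclass
class PulseTrace:
    """Photodetector recording of the treatment-laser pulse train.

    The photodetector samples scattered treatment light (default 1 MHz) and is
    used only to localise pulse onsets within the M-Scan time axis.
    """

    samples: np.ndarray
    sample_rate: float = 1e6
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64).ravel()
        if arr.size == 0:
            raise ValueError("pulse trace is empty")
        if not np.isfinite(arr).all():
            raise ValueError("pulse trace contains non-finite values")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        self.samples = arr


@dataclass
class LabeledDataset:
    """Pairs of scan ids with binary outcome labels and an optional payload.

    ``entries`` maps scan id -> (payload, label) where the payload is either a
    raster path or a feature vector, and label 1 marks a successful treatment
    (RPE cell rupture visible in the M-Scan).
    """

    ids: list[str]
    labels: np.ndarray
    payloads: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("dataset ids must be unique")
        lab = np.asarray(self.labels)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.labels = lab.astype(np.int64)


# ---------------------------------------------------------------------------
# M-Scan raster I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mscan(mscan: MScan, path: str | Path) -> Path:
    """Write an M-Scan as TIFF (or raw ``.bin``) plus a JSON sidecar.

    The raster is stored as float32; write -> read round-trips are bit-exact.
    Returns the sidecar path.
    """
    path = Path(path)
    data = mscan.data
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".bin":
        data.astype("<f4").tofile(path)
    else:
        raise ValueError(f"unsupported raster container {path.suffix!r}; use .tif/.tiff or .bin")
    sidecar = _sidecar_path(path)
    meta = {
        "id": mscan.id,
        "ascan_rate": mscan.ascan_rate,
        "axial_pitch": mscan.axial_pitch,
        "shape": list(data.shape),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_mscan(path: str | Path) -> MScan:
    """Read an M-Scan written by :func:`write_mscan`.

    Raises if the file or sidecar is missing, if required sidecar keys are
    absent, or if the raster violates the M-Scan invariants (non-finite or
    negative values, shape mismatch with the sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"M-Scan raster not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar not found: {sidecar} (required keys: {', '.join(_SIDECAR_KEYS)})")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar} is missing required keys: {missing}")
    shape = tuple(meta["shape"])
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".bin":
        data = np.fromfile(path, dtype="<f4").reshape(shape)
    else:
        raise ValueError(f"unsupported raster container {path.suffix!r}")
    if tuple(data.shape) != shape:
        raise ValueError(
            f"raster shape {data.shape} does not match sidecar-declared shape {shape}")
    return MScan(data=data, ascan_rate=float(meta["ascan_rate"]),
                 axial_pitch=float(meta["axial_pitch"]), id=str(meta["id"]))


def write_trace(trace: PulseTrace, path: str | Path) -> None:
    """Write a pulse trace as single-column CSV (header: sample_rate)."""
    path = Path(path)
    pd.DataFrame({f"value@{trace.sample_rate:g}Hz": trace.samples}).to_csv(path, index=False)


def read_trace(path: str | Path) -> PulseTrace:
    path = Path(path)
    df = pd.read_csv(path)
    col = df.columns[0]
    if "@" not in col or not col.endswith("Hz"):
        raise ValueError(f"trace CSV header {col!r} does not declare a sample rate")
    rate = float(col.split("@")[1][:-2])
    return PulseTrace(samples=df[col].to_numpy(), sample_rate=rate, id=path.stem)


# ---------------------------------------------------------------------------
# Labels and feature matrices


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    pd.DataFrame({"id": list(labels), "label": list(labels.values())}).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read an id -> {0,1} label table from CSV (columns ``id``, ``label``)."""
    df = pd.read_csv(path)
    for col in ("id", "label"):
        if col not in df.columns:
            raise ValueError(f"label CSV {path} lacks required column {col!r}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in label CSV: {dupes}")
    if not df["label"].isin((0, 1)).all():
        bad = sorted(df.loc[~df["label"].isin((0, 1)), "label"].unique().tolist())
        raise ValueError(f"labels must be 0 or 1, found {bad}")
    return dict(zip(df["id"].astype(str), df["label"].astype(int)))


def write_features(matrix: np.ndarray, ids: list[str], path: str | Path,
                   feature_names: list[str] | None = None) -> None:
    """Write a samples x features matrix as CSV with an ``id`` column.

    Values are written with shortest round-trip float repr, so a
    write -> read cycle preserves them exactly.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != len(ids):
        raise ValueError("feature matrix must be 2-D with one row per id")
    if feature_names is None:
        feature_names = [f"f{i:03d}" for i in range(matrix.shape[1])]
    if len(feature_names) != matrix.shape[1]:
        raise ValueError("feature_names length must match matrix width")
    df = pd.DataFrame(matrix, columns=feature_names)
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature CSV -> (matrix, ids, feature_names)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError(f"feature CSV {path} lacks an 'id' column")
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in feature CSV {path}")
    names = [c for c in df.columns if c != "id"]
    return df[names].to_numpy(dtype=np.float64), ids, names


# ---------------------------------------------------------------------------
# Model artifacts


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model with a format-version tag."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an srtoct model artifact")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model artifact version {payload['format_version']} does not match "
            f"supported version {MODEL_FORMAT_VERSION}")
    return payload["model"]
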