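"""Plain-text I/O for multi-channel sEMG recordings and feature tables.

Recordings are stored as UTF-8 CSV with a "." decimal point, one sample per
row and one column per muscle channel.  Channel order is taken from the
caller-supplied schema, never inferred, because downstream feature-column
semantics depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Lower-limb muscles recorded in the knee-abnormality protocol:
#: rectus femoris, biceps femoris, vastus medialis, semitendinosus.
DEFAULT_CHANNELS: tuple[str, ...] = ("RF", "BF", "VM", "ST")

LABELS = ("healthy", "abnormal")


@dataclass
class Recording:
    """One multi-channel sEMG recording with its class label.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``; no missing values.
    sampling_rate
        Sampling frequency in Hz (the source hardware samples at 1000 Hz).
    channel_names
        Ordered muscle labels, one per column of ``samples``.
    label
        ``"healthy"`` or ``"abnormal"``.
    subject_id
        Opaque provenance string.
    """

    samples: np.ndarray
    sampling_rate: float = 1000.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    label: str = "healthy"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a non-empty 2-D array")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D signal of the named channel."""
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
        return self.samples[:, j]


def load_recording(
    path: str | Path,
    schema: Sequence[str] = DEFAULT_CHANNELS,
    sampling_rate: float = 1000.0,
    label: str = "healthy",
    subject_id: str | None = None,
) -> Recording:
    """Read a delimited-text recording with one column per channel.

    ``schema`` names the columns to keep, in the desired channel order.
    Ragged rows, missing cells and non-numeric cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged rows in {path}: {exc}") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(
            f"unknown channel name(s) {missing} for {path}; "
            f"file has columns {list(df.columns)}"
        )
    df = df[list(schema)]
    if df.isna().to_numpy().any():
        raise ValueError(f"ragged rows or missing cells in {path}")
    try:
        samples = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return Recording(
        samples=samples,
        sampling_rate=sampling_rate,
        channel_names=tuple(schema),
        label=label,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV with a channel-name header row."""
    df = pd.DataFrame(recording.samples, columns=list(recording.channel_names))
    df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round-trip


def save_feature_matrix(matrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: ``<channel>_<feature>`` columns
    followed by ``label`` and ``subject_id`` metadata columns.

    Values round-trip at full float64 precision.  Synthetic (oversampled)
    rows keep their ``synthetic_*`` subject ids, so provenance survives
    a save/load cycle without extra columns.
    """
    if matrix.n_rows == 0:
        raise ValueError("refusing to write an empty feature matrix")
    df = pd.DataFrame(matrix.values, columns=list(matrix.column_names))
    df["label"] = matrix.labels
    df["subject_id"] = matrix.subject_ids
    df.to_csv(path, index=False, float_format="%.17g")


def load_feature_matrix(path: str | Path):
    """Read a feature matrix written by :func:`save_feature_matrix`."""
    from .features import FeatureMatrix  # deferred: avoids import cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such feature file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("label", "subject_id"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")
    meta = ["label", "subject_id"]
    feat_cols = [c for c in df.columns if c not in meta]
    subject_ids = df["subject_id"].astype(str).to_numpy(dtype=str)
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        column_names=list(feat_cols),
        labels=df["label"].astype(str).to_numpy(),
        subject_ids=subject_ids,
        is_synthetic=np.char.startswith(subject_ids, "synthetic"),
    )


def save_dataset(recordings: Sequence[Recording], out_dir: str | Path) -> Path:
    """Write one CSV per recording plus a ``labels.csv`` manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        save_recording(rec, out_dir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "file": fname,
                "n_samples": rec.n_samples,
                "sampling_rate": rec.sampling_rate,
            }
        )
    manifest = out_dir / "labels.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(
    data_dir: str | Path, schema: Sequence[str] = DEFAULT_CHANNELS
) -> list[Recording]:
    """Read every recording listed in a ``labels.csv`` manifest."""
    data_dir = Path(data_dir)
    manifest = data_dir / "labels.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest at {manifest}")
    table = pd.read_csv(manifest)
    recs = []
    for row in table.itertuples(index=False):
        recs.append(
            load_recording(
                data_dir / row.file,
                schema=schema,
                sampling_rate=float(getattr(row, "sampling_rate", 1000.0)),
                label=str(row.label),
                subject_id=str(row.subject_id),
            )
        )
    return recs
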