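"""Epoched two-class motor-imagery EEG container and file I/O.

The central in-memory object is :class:`MIEEGDataset`, a stack of epoched
trials (trial x channel x sample) with per-trial class labels in {1, 2}
(left / right hand imagery).  Every downstream stage — band-pass filtering,
r2 band selection, CSP, LDA, cross-validated evaluation — consumes this one
container.

Two on-disk layouts are supported and round-trip with each other:

* a flat CSV bundle (``trials.csv`` with columns trial, channel,
  sample_index, value; a ``labels.csv`` sidecar; ``meta.yaml``), lossless;
* EDF (European Data Format), the field's standard 16-bit container, with
  one data record per trial and the same ``labels.csv`` sidecar.  EDF files
  are read back through :func:`mne.io.read_raw_edf`; writing uses a small
  built-in EDF encoder.  EDF is 16-bit quantized, so values round-trip only
  to within the quantization step recorded in the header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MIEEGDataset",
    "write_csv_bundle",
    "read_csv_bundle",
    "write_edf",
    "read_edf",
    "read_dataset",
    "write_dataset",
    "edf_quantization_step",
]


@dataclasses.dataclass
class MIEEGDataset:
    """Epoched multichannel EEG trials with binary class labels.

    Parameters
    ----------
    trials : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched signals in microvolt-scale arbitrary units.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial, values in {1, 2} (left / right).
    sampling_rate : float
        Sampling frequency in Hz.
    channel_names : list of str
        One name per channel.
    provenance : str
        Free text describing where the data came from (synthetic config,
        source file, ...).
    """

    trials: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError(
                f"trials must be 3-d (trial, channel, sample); got shape {self.trials.shape}"
            )
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError(
                f"label count {len(self.labels)} does not match trial count {self.trials.shape[0]}"
            )
        if not np.all(np.isin(self.labels, (1, 2))):
            raise ValueError("labels must take values in {1, 2}")
        if not np.all(np.isfinite(self.trials)):
            raise ValueError("trials contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.trials.shape[1]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def class_trials(self, label: int) -> np.ndarray:
        """Trials belonging to one class, shape (n, channels, samples)."""
        return self.trials[self.labels == label]

    def require_two_classes(self) -> None:
        """Raise if either class is absent (fitting precondition)."""
        present = set(np.unique(self.labels))
        if present != {1, 2}:
            raise ValueError(f"both classes required for fitting; present: {sorted(present)}")


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------

def write_csv_bundle(dataset: MIEEGDataset, out_dir: str | Path) -> Path:
    """Write a dataset as a flat CSV bundle (lossless round trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_t, n_c, n_s = dataset.trials.shape
    idx = np.indices((n_t, n_c, n_s))
    df = pd.DataFrame(
        {
            "trial": idx[0].ravel(),
            "channel": idx[1].ravel(),
            "sample_index": idx[2].ravel(),
            "value": dataset.trials.ravel(),
        }
    )
    df.to_csv(out / "trials.csv", index=False)
    pd.DataFrame({"trial": np.arange(n_t), "label": dataset.labels}).to_csv(
        out / "labels.csv", index=False
    )
    meta = {
        "sampling_rate": float(dataset.sampling_rate),
        "channel_names": list(dataset.channel_names),
        "provenance": dataset.provenance,
        "n_trials": int(n_t),
        "n_channels": int(n_c),
        "n_samples": int(n_s),
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))
    return out


def read_csv_bundle(in_dir: str | Path) -> MIEEGDataset:
    """Read a dataset written by :func:`write_csv_bundle`."""
    src = Path(in_dir)
    meta = yaml.safe_load((src / "meta.yaml").read_text())
    df = pd.read_csv(src / "trials.csv")
    labels_df = pd.read_csv(src / "labels.csv")
    n_t, n_c, n_s = meta["n_trials"], meta["n_channels"], meta["n_samples"]
    if len(labels_df) != n_t:
        raise ValueError(
            f"labels file has {len(labels_df)} rows but metadata declares {n_t} trials"
        )
    if len(df) != n_t * n_c * n_s:
        raise ValueError("trials.csv row count inconsistent with declared shape")
    df = df.sort_values(["trial", "channel", "sample_index"])
    trials = df["value"].to_numpy().reshape(n_t, n_c, n_s)
    labels = labels_df.sort_values("trial")["label"].to_numpy()
    return MIEEGDataset(
        trials=trials,
        labels=labels,
        sampling_rate=meta["sampling_rate"],
        channel_names=meta["channel_names"],
        provenance=meta.get("provenance", str(src)),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def edf_quantization_step(physical_min: float, physical_max: float) -> float:
    """Physical units per digital step for a 16-bit EDF signal."""
    return (physical_max - physical_min) / (_DIG_MAX - _DIG_MIN)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} (> {width})")
    return b.ljust(width)


def _fmt_float(x: float, width: int) -> str:
    """Shortest ascii rendering of x that fits an EDF numeric field."""
    for fmt in (f"{x:g}", f"{x:.6g}", f"{x:.4g}", f"{x:.3g}"):
        if len(fmt) <= width:
            return fmt
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(dataset: MIEEGDataset, path: str | Path) -> Path:
    """Write a dataset to EDF, one data record per trial.

    Physical ranges are symmetric per channel around the channel's absolute
    maximum, so the quantization step is ``2*max|x| / 65535``.  A
    ``<stem>_labels.csv`` sidecar carries the per-trial class labels.
    """
    path = Path(path)
    n_t, n_c, n_s = dataset.trials.shape
    duration = n_s / dataset.sampling_rate

    phys_max = np.abs(dataset.trials).max(axis=(0, 2))
    phys_max = np.where(phys_max > 0, phys_max, 1.0)  # avoid zero range
    phys_min = -phys_max

    header = b""
    header += _pad("0", 8)  # version
    header += _pad("X X X X", 80)  # patient id (anonymous)
    header += _pad("Startdate X midecode", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header_bytes = 256 + 256 * n_c
    header += _pad(str(header_bytes), 8)
    header += _pad("", 44)
    header += _pad(str(n_t), 8)  # one record per trial
    header += _pad(_fmt_float(duration, 8), 8)
    header += _pad(str(n_c), 4)
    # per-signal fields, each field grouped across signals
    header += b"".join(_pad(name, 16) for name in dataset.channel_names)
    header += b"".join(_pad("", 80) for _ in range(n_c))  # transducer
    header += b"".join(_pad("uV", 8) for _ in range(n_c))
    header += b"".join(_pad(_fmt_float(lo, 8), 8) for lo in phys_min)
    header += b"".join(_pad(_fmt_float(hi, 8), 8) for hi in phys_max)
    header += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(n_c))
    header += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_c))
    header += b"".join(_pad("", 80) for _ in range(n_c))  # prefiltering
    header += b"".join(_pad(str(n_s), 8) for _ in range(n_c))
    header += b"".join(_pad("", 32) for _ in range(n_c))
    assert len(header) == header_bytes

    # gain maps physical -> digital; phys_min written with _fmt_float may be
    # rounded, so recompute the gain from the values actually in the header
    hdr_min = np.array([float(_fmt_float(lo, 8)) for lo in phys_min])
    hdr_max = np.array([float(_fmt_float(hi, 8)) for hi in phys_max])
    gain = (_DIG_MAX - _DIG_MIN) / (hdr_max - hdr_min)
    offset = _DIG_MIN - hdr_min * gain

    with open(path, "wb") as fh:
        fh.write(header)
        for t in range(n_t):
            dig = np.rint(dataset.trials[t] * gain[:, None] + offset[:, None])
            dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())  # signal-major within record

    labels_path = path.with_name(path.stem + "_labels.csv")
    pd.DataFrame({"trial": np.arange(n_t), "label": dataset.labels}).to_csv(
        labels_path, index=False
    )
    return path


def read_edf(path: str | Path, labels_path: str | Path | None = None) -> MIEEGDataset:
    """Read an EDF file plus labels sidecar back into a dataset.

    Uses :func:`mne.io.read_raw_edf`; the continuous signal is re-epoched
    using the trial count from the labels sidecar.
    """
    import mne

    path = Path(path)
    if labels_path is None:
        labels_path = path.with_name(path.stem + "_labels.csv")
    labels_df = pd.read_csv(labels_path)
    n_t = len(labels_df)

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    n_c, total = data.shape
    if total % n_t:
        raise ValueError(
            f"total sample count {total} not divisible by trial count {n_t} from labels file"
        )
    n_s = total // n_t
    trials = data.reshape(n_c, n_t, n_s).transpose(1, 0, 2)
    return MIEEGDataset(
        trials=trials,
        labels=labels_df.sort_values("trial")["label"].to_numpy(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        provenance=str(path),
    )


# ---------------------------------------------------------------------------
# format dispatch
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path, format: str | None = None) -> MIEEGDataset:
    """Read a dataset from ``edf`` or ``csv-bundle`` layout.

    ``format=None`` infers: directories are CSV bundles, ``.edf`` files EDF.
    """
    path = Path(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "edf"
    if format == "csv-bundle":
        return read_csv_bundle(path)
    if format == "edf":
        return read_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'csv-bundle'")


def write_dataset(dataset: MIEEGDataset, path: str | Path, format: str = "csv-bundle") -> Path:
    if format == "csv-bundle":
        return write_csv_bundle(dataset, path)
    if format == "edf":
        return write_edf(dataset, path)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'csv-bundle'")
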