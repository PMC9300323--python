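"""Band-pass filtering and subject-specific band selection via r2.

The discriminability statistic is the squared point-biserial correlation
between class label and band power, written in the BCI literature as

    r2 = [ sqrt(N1*N2) / (N1 + N2) * (mean(P1) - mean(P2)) / std(P1 u P2) ]^2

with P1, P2 the per-trial band-power samples of the two classes and the
pooled standard deviation taken with the population (divide-by-n)
convention.  Under that convention the expression is algebraically identical
to the squared Pearson correlation of the (power, label) pairs, which is the
oracle the tests check against.  A large r2 at a frequency means that band's
power separates left- from right-hand imagery well; the subject-specific
band-pass filter is placed over the window of maximal mean r2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal

from .dataset import MIEEGDataset

__all__ = [
    "DiscriminabilitySpectrum",
    "BandSelection",
    "bandpass_filter",
    "discriminability_r2",
    "compute_r2_spectrum",
    "select_band",
]


@dataclasses.dataclass(frozen=True)
class DiscriminabilitySpectrum:
    """Per-frequency r2 values with the class sample sizes used."""

    freqs: np.ndarray
    r2: np.ndarray
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.r2):
            raise ValueError("freqs and r2 must have the same length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise ValueError("r2 values must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class BandSelection:
    """A selected filter band and its mean r2 score."""

    low: float
    high: float
    score: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high; got ({self.low}, {self.high})")


def bandpass_filter(dataset: MIEEGDataset, low: float, high: float) -> MIEEGDataset:
    """Zero-phase band-pass filter every trial; returns a filtered copy.

    Order-4 Butterworth applied forward-backward (``sosfiltfilt``), so the
    effective magnitude response is squared and there is no group delay
    between channels.
    """
    nyq = dataset.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for Nyquist {nyq} Hz; need 0 < low < high < Nyquist"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=dataset.sampling_rate, output="sos")
    # default filtfilt padding must fit inside a trial
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if dataset.n_samples <= padlen:
        raise ValueError(
            f"trial length {dataset.n_samples} too short for the filter warm-up ({padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, dataset.trials, axis=-1)
    return MIEEGDataset(
        trials=np.ascontiguousarray(filtered),
        labels=dataset.labels.copy(),
        sampling_rate=dataset.sampling_rate,
        channel_names=list(dataset.channel_names),
        provenance=dataset.provenance + f" | bandpass {low}-{high} Hz",
    )


def discriminability_r2(p1: np.ndarray, p2: np.ndarray) -> float:
    """r2 between two per-trial power samples (population-SD convention).

    Returns 0 (with a warning) when the pooled sample has zero variance.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1, n2 = len(p1), len(p2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each class needs >= 2 trials; got {n1} and {n2}")
    pooled = np.concatenate([p1, p2])
    sd = pooled.std()  # population (divide-by-n) convention
    if sd == 0:
        warnings.warn("zero pooled variance; r2 defined as 0", stacklevel=2)
        return 0.0
    r = np.sqrt(n1 * n2) / (n1 + n2) * (p1.mean() - p2.mean()) / sd
    return float(r**2)


def _band_powers(
    dataset: MIEEGDataset, fmin: float, fmax: float, channel_agg: str | int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Welch power at ~1 Hz resolution, restricted to [fmin, fmax].

    Returns (freqs, powers) with powers shaped (n_trials, n_bins).
    """
    nperseg = min(int(round(dataset.sampling_rate)), dataset.n_samples)
    freqs, psd = signal.welch(
        dataset.trials, fs=dataset.sampling_rate, nperseg=nperseg, axis=-1
    )
    keep = (freqs >= fmin) & (freqs <= fmax)
    psd = psd[..., keep]  # (trial, channel, bin)
    if channel_agg == "mean":
        powers = psd.mean(axis=1)
    elif isinstance(channel_agg, (int, np.integer)):
        powers = psd[:, int(channel_agg), :]
    else:
        raise ValueError(f"channel_agg must be 'mean' or a channel index; got {channel_agg!r}")
    return freqs[keep], powers


def compute_r2_spectrum(
    dataset: MIEEGDataset,
    channel_agg: str | int = "mean",
    fmin: float = 4.0,
    fmax: float = 40.0,
) -> DiscriminabilitySpectrum:
    """r2 discriminability at each frequency bin of a Welch periodogram.

    Power per bin is a Welch-type averaged periodogram per trial; channels
    are averaged by default (``channel_agg='mean'``) or a single channel
    index can be used.  Frequency resolution is ~1 Hz (one-second Welch
    segments, capped at the trial length).
    """
    dataset.require_two_classes()
    n1 = int((dataset.labels == 1).sum())
    n2 = int((dataset.labels == 2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each class needs >= 2 trials; got {n1} and {n2}")
    freqs, powers = _band_powers(dataset, fmin, fmax, channel_agg)
    mask1 = dataset.labels == 1
    r2 = np.array(
        [discriminability_r2(powers[mask1, b], powers[~mask1, b]) for b in range(len(freqs))]
    )
    return DiscriminabilitySpectrum(freqs=freqs, r2=r2, n1=n1, n2=n2)


def select_band(
    spec: DiscriminabilitySpectrum,
    min_width: float = 4.0,
    max_width: float = 12.0,
    search_range: tuple[float, float] | None = None,
) -> BandSelection:
    """Pick the contiguous window of maximal mean r2.

    All windows on the spectrum's bin grid with width between ``min_width``
    and ``max_width`` (inclusive) inside ``search_range`` are enumerated;
    ties break toward lower frequency, then narrower width.
    """
    if search_range is None:
        search_range = (float(spec.freqs[0]), float(spec.freqs[-1]))
    lo, hi = search_range
    in_range = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if in_range.size == 0:
        raise ValueError(f"search range {search_range} contains no spectrum bins")

    # scores equal up to rounding noise count as ties so the tie rule
    # (lower frequency, then narrower width) is deterministic
    tie_tol = 1e-12
    best_sel: BandSelection | None = None
    for a in in_range:
        for b in in_range[in_range >= a]:
            width = spec.freqs[b] - spec.freqs[a]
            if width < min_width or width > max_width:
                continue
            score = float(spec.r2[a : b + 1].mean())
            if best_sel is None:
                better = True
            else:
                gap = score - best_sel.score
                if gap > tie_tol * max(1.0, abs(best_sel.score)):
                    better = True
                elif gap < -tie_tol * max(1.0, abs(best_sel.score)):
                    better = False
                else:  # tied score
                    better = (float(spec.freqs[a]), width) < (
                        best_sel.low,
                        best_sel.high - best_sel.low,
                    )
            if better:
                best_sel = BandSelection(
                    low=float(spec.freqs[a]), high=float(spec.freqs[b]), score=score
                )
    if best_sel is None:
        raise ValueError(
            f"no window of width in [{min_width}, {max_width}] Hz fits in range {search_range}"
        )
    return best_sel
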