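"""Artifact-channel screening and the common-median-reference spatial filter.

Channels whose low-frequency (<6 Hz, ocular) or high-frequency (>20 Hz,
muscle) spectra differ between low-workload (SPN) and high-workload
(MER+MEC) blocks are proxies for workload-correlated artifacts and are
discarded rather than cleaned.  The screen compares per-block mean log band
power between the two workload groups with a Wilcoxon rank-sum test, per
channel and band, at a configurable alpha (no multiplicity correction).

Band power is estimated on an equal-length leading segment of every block
(the minimum block duration by default): SPN blocks are roughly half as
long as task blocks, and equalising segment length keeps the power
estimator's sampling variance condition-independent, so the rank-sum test
is exchangeable under the null.

An amplitude pre-check (channel variance > k x median channel variance)
stands in for the study's manual visual inspection of raw traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .data import BlockAnnotation, Recording

#: Default screening bands (Hz): ocular proxies below 6, muscle above 20.
LOW_BAND = (0.5, 6.0)
HIGH_BAND = (20.0, 40.0)


@dataclass(frozen=True)
class ChannelScreen:
    """Screening outcome for one channel in one band."""

    channel: str
    band: str  # "low" | "high"
    statistic: float
    p_value: float
    rejected: bool


@dataclass(frozen=True)
class ScreeningResult:
    """Per-channel, per-band screening statistics and the rejection set."""

    entries: tuple[ChannelScreen, ...]
    alpha: float
    variance_rejected: tuple[str, ...] = ()

    @property
    def rejected_channels(self) -> tuple[str, ...]:
        stat = {e.channel for e in self.entries if e.rejected}
        return tuple(sorted(stat | set(self.variance_rejected)))

    def retained_channels(self, labels: Sequence[str]) -> tuple[str, ...]:
        bad = set(self.rejected_channels)
        return tuple(l for l in labels if l not in bad)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "channel": e.channel,
                    "band": e.band,
                    "statistic": e.statistic,
                    "p": e.p_value,
                    "rejected": e.rejected,
                }
                for e in self.entries
            ]
        )


def block_band_power(
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
    band: tuple[float, float],
    segment_samples: int | None = None,
) -> np.ndarray:
    """Mean log10 band power per (block, channel).

    Welch's method with 1-s Hamming sub-windows, 50% overlap.  When
    ``segment_samples`` is given, only the leading segment of each block is
    used so that every block contributes an estimate of equal variance.
    """
    fs = recording.sampling_rate
    nperseg = int(round(fs))
    out = np.empty((len(annotations), recording.n_channels))
    for i, ann in enumerate(annotations):
        stop = ann.end_sample
        if segment_samples is not None:
            stop = min(stop, ann.start_sample + segment_samples)
        seg = recording.signal[:, ann.start_sample : stop]
        f, psd = sps.welch(
            seg, fs=fs, window="hamming", nperseg=min(nperseg, seg.shape[1])
        )
        mask = (f >= band[0]) & (f <= band[1])
        if not mask.any():
            raise ValueError(f"band {band} contains no frequency bins")
        out[i] = np.log10(psd[:, mask].mean(axis=1))
    return out


def screen_artifact_channels(
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
    alpha: float = 0.05,
    low_band: tuple[float, float] = LOW_BAND,
    high_band: tuple[float, float] = HIGH_BAND,
    variance_factor: float = 25.0,
    equalize_segments: bool = True,
) -> ScreeningResult:
    """Flag channels whose artifact-band power differs between workloads.

    For each channel and each band, per-block mean log band power in SPN
    blocks is compared against MER+MEC blocks with a Wilcoxon rank-sum
    test; a channel significant in either band is rejected.  Deterministic
    given its inputs.

    Raises ``ValueError`` when either workload group has fewer than two
    blocks (the rank test is undefined).
    """
    lw = [a for a in annotations if a.workload == "LW"]
    hw = [a for a in annotations if a.workload == "HW"]
    if len(lw) < 2 or len(hw) < 2:
        raise ValueError(
            f"screening needs >= 2 blocks per workload group, got "
            f"{len(lw)} LW and {len(hw)} HW"
        )

    variance_rejected: list[str] = []
    if variance_factor is not None:
        var = recording.signal.var(axis=1)
        bad = var > variance_factor * np.median(var)
        variance_rejected = [l for l, b in zip(recording.labels, bad) if b]

    segment = None
    if equalize_segments:
        segment = min(a.n_samples for a in annotations)

    entries: list[ChannelScreen] = []
    for band_name, band in (("low", low_band), ("high", high_band)):
        power = block_band_power(recording, annotations, band, segment)
        lw_idx = [i for i, a in enumerate(annotations) if a.workload == "LW"]
        hw_idx = [i for i, a in enumerate(annotations) if a.workload == "HW"]
        for ch, label in enumerate(recording.labels):
            stat, p = stats.ranksums(power[hw_idx, ch], power[lw_idx, ch])
            entries.append(
                ChannelScreen(label, band_name, float(stat), float(p), p < alpha)
            )
    return ScreeningResult(tuple(entries), alpha, tuple(variance_rejected))


def common_median_reference(window: np.ndarray) -> np.ndarray:
    """Subtract the across-channel median from every channel, per sample.

    The output's channel median is 0 at every sample; any signal common to
    all channels is removed exactly.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    return window - np.median(window, axis=0, keepdims=True)
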