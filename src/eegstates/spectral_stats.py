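"""Physiological band-power analysis: workload contrasts per channel.

Complements the decoders with the classical spectral picture: per-channel
theta (3-7 Hz) and alpha (8-12 Hz) band power is contrasted between
high-workload (MER+MEC) and low-workload (SPN) blocks with a Wilcoxon
signed-rank test.  The pairing unit respects the alternating block design:
each task block is paired with the SPN block immediately preceding it in
the same session, giving one HW - LW log-power difference per task block.

The output is a per-channel table (difference, statistic, p, significance
flag) from which a topographic dot map can be drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import BlockAnnotation, Recording
from .preprocessing import block_band_power

#: The two physiological bands analysed (Hz).
THETA_BAND = (3.0, 7.0)
ALPHA_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class ChannelContrast:
    channel: str
    band: tuple[float, float]
    mean_difference: float  # mean HW - LW log10 band power
    statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class BandContrastResult:
    """Signed-rank workload contrast for every retained channel in one band."""

    band: tuple[float, float]
    alpha: float
    entries: tuple[ChannelContrast, ...]

    @property
    def significant_channels(self) -> tuple[str, ...]:
        return tuple(e.channel for e in self.entries if e.significant)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "channel": e.channel,
                    "band": f"{e.band[0]:g}-{e.band[1]:g}Hz",
                    "diff": e.mean_difference,
                    "statistic": e.statistic,
                    "p": e.p_value,
                    "significant": e.significant,
                }
                for e in self.entries
            ]
        )


def band_power_by_condition(
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
    band: tuple[float, float],
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean log10 band power per channel and condition (blocks averaged)."""
    channels = list(channels) if channels is not None else list(recording.labels)
    power = block_band_power(recording, annotations, band)  # blocks x channels
    ch_idx = [recording.labels.index(c) for c in channels]
    rows = {}
    for cond in ("SPN", "MER", "MEC"):
        idx = [i for i, a in enumerate(annotations) if a.condition == cond]
        if idx:
            rows[cond] = power[np.ix_(idx, ch_idx)].mean(axis=0)
    return pd.DataFrame(rows, index=channels)


def _paired_differences(
    annotations: Sequence[BlockAnnotation], power: np.ndarray
) -> np.ndarray:
    """HW - LW log-power differences, each task block paired with the SPN
    block immediately preceding it within its session."""
    diffs = []
    by_session: dict[int, list[int]] = {1: [], 2: []}
    for i, a in enumerate(annotations):
        by_session[a.session].append(i)
    for session, idx in by_session.items():
        last_spn: int | None = None
        for i in idx:
            if annotations[i].condition == "SPN":
                last_spn = i
            elif last_spn is not None:
                diffs.append(power[i] - power[last_spn])
    if not diffs:
        raise ValueError("no (SPN, task) adjacent pairs found")
    return np.asarray(diffs)  # pairs x channels


def workload_contrast(
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
    band: tuple[float, float],
    alpha: float = 0.001,
    channels: Sequence[str] | None = None,
) -> BandContrastResult:
    """Wilcoxon signed-rank HW vs LW contrast per channel in one band.

    Refuses to run with fewer than 6 pairs (the signed-rank test has
    essentially no power below that).  The statistic is reported with the
    sign of the mean difference so direction is visible.
    """
    channels = list(channels) if channels is not None else list(recording.labels)
    power = block_band_power(recording, annotations, band)
    diffs = _paired_differences(annotations, power)
    ch_idx = [recording.labels.index(c) for c in channels]
    diffs = diffs[:, ch_idx]
    if diffs.shape[0] < 6:
        raise ValueError(
            f"only {diffs.shape[0]} HW/LW pairs; signed-rank needs >= 6"
        )
    entries = []
    for j, ch in enumerate(channels):
        d = diffs[:, j]
        _, p = stats.wilcoxon(d)
        # signed-rank sum T+ - T-: carries the effect direction (scipy's
        # two-sided statistic is min(T+, T-), which loses the sign)
        ranks = stats.rankdata(np.abs(d))
        signed_rank_sum = float(np.sum(np.sign(d) * ranks))
        entries.append(
            ChannelContrast(
                channel=ch,
                band=band,
                mean_difference=float(d.mean()),
                statistic=signed_rank_sum,
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    return BandContrastResult(band, alpha, tuple(entries))
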