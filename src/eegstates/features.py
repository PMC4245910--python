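"""Sliding-window spectral features for continuous decoding.

Each annotated block is tiled with fixed-length windows advanced every
200 ms; windows never cross block boundaries and inherit their block's
condition label.  Per window and channel, power spectral density is
estimated with Welch's method (1-s Hamming sub-windows, 50% overlap, hence
1 Hz bins), restricted to the parameter set's frequency band, and
log10-transformed.  Features are concatenated channel-major.

A :class:`FeatureCache` precomputes the full-montage PSD once per
(window length, spatial filter) pair, so evaluating the 64-point parameter
grid — which only varies the channel subset and the band on top of those
two — costs a slice, not a recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data import BlockAnnotation, Montage, Recording
from .preprocessing import common_median_reference

#: '#' channel groups: label-prefix matches over the canonical montage.
#: F# deliberately excludes Fp1/Fp2 (prefix "F" followed by a non-'p').
CHANNEL_GROUPS = {
    "F#": ("F7", "F3", "Fz", "F4", "F8"),
    "FC#": ("Fc5", "Fc1", "Fc2", "Fc6"),
    "C#": ("C3", "Cz", "C4"),
    "CP#": ("Cp5", "Cp1", "Cp2", "Cp6"),
    "P#": ("P7", "P3", "Pz", "P4", "P8"),
    "O#": ("O1", "Oz", "O2"),
}

#: The four candidate channel subsets of the per-subject parameter grid.
CHANNEL_SUBSETS = {
    "S1": ("FC#", "C#", "P#", "CP#"),
    "S2": ("F#", "FC#", "C#", "P#", "CP#", "O#"),
    "S3": ("F#", "FC#", "C#", "P#", "CP#", "O#", "T7", "T8"),
    "S4": ("FC#", "C#", "P#", "CP#", "T7", "T8"),
}

#: Candidate frequency bands (Hz) and window lengths (s) of the grid.
GRID_BANDS = ((3.0, 15.0), (7.0, 15.0), (10.0, 15.0), (3.0, 10.0))
GRID_WINDOWS = (2.0, 5.0)
SPATIAL_FILTERS = ("common_median", "none")

#: Sliding-window shift (s): one decision every 200 ms, i.e. 5 per second.
WINDOW_SHIFT = 0.2


@dataclass(frozen=True)
class ParameterSet:
    """One point of the per-subject selection grid."""

    subset: str = "S2"
    spatial_filter: str = "common_median"
    band: tuple[float, float] = (3.0, 15.0)
    window_length: float = 5.0
    shift: float = WINDOW_SHIFT
    aggregate: bool = False  # one mean band power per channel instead of per-bin

    def __post_init__(self) -> None:
        if self.subset not in CHANNEL_SUBSETS:
            raise ValueError(f"unknown channel subset {self.subset!r}")
        if self.spatial_filter not in SPATIAL_FILTERS:
            raise ValueError(f"unknown spatial filter {self.spatial_filter!r}")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band needs 0 < low < high")
        if self.window_length <= 0 or self.shift <= 0:
            raise ValueError("window_length and shift must be positive")


def default_grid() -> list[ParameterSet]:
    """The canonical 4 x 2 x 4 x 2 = 64-point grid, in canonical order
    (subset, spatial filter, band, window length); ties in selection are
    broken by this order."""
    return [
        ParameterSet(subset=s, spatial_filter=f, band=b, window_length=w)
        for s in ("S1", "S2", "S3", "S4")
        for f in SPATIAL_FILTERS
        for b in GRID_BANDS
        for w in GRID_WINDOWS
    ]


def expand_channel_group(
    subset_id: str,
    montage: Montage | None = None,
    rejected_channels: Sequence[str] = (),
) -> list[str]:
    """Expand a subset id (S1..S4) to channel labels, montage order,
    minus rejected channels."""
    montage = montage or Montage()
    if subset_id not in CHANNEL_SUBSETS:
        raise ValueError(f"unknown channel subset {subset_id!r}")
    chosen: set[str] = set()
    for item in CHANNEL_SUBSETS[subset_id]:
        if item in CHANNEL_GROUPS:
            chosen.update(CHANNEL_GROUPS[item])
        else:
            chosen.add(item)
    chosen -= set(rejected_channels)
    return [l for l in montage.labels if l in chosen]


@dataclass(frozen=True)
class Window:
    """One sliding window: start sample, length, and source-block metadata."""

    start_sample: int
    n_samples: int
    block_id: int
    condition: str
    session: int

    @property
    def centre_sample(self) -> int:
        return self.start_sample + self.n_samples // 2


def slide_windows(
    annotations: Sequence[BlockAnnotation],
    window_length: float,
    shift: float = WINDOW_SHIFT,
    sampling_rate: float = 250.0,
) -> list[Window]:
    """Tile each block with windows: floor((D - W) / shift) + 1 per block
    of duration D >= W; blocks shorter than the window contribute none."""
    w = int(round(window_length * sampling_rate))
    step = int(round(shift * sampling_rate))
    if w <= 0 or step <= 0:
        raise ValueError("window and shift must span at least one sample")
    windows: list[Window] = []
    for block_id, ann in enumerate(annotations):
        start = ann.start_sample
        while start + w <= ann.end_sample:
            windows.append(Window(start, w, block_id, ann.condition, ann.session))
            start += step
    return windows


@dataclass
class WindowFeatureSet:
    """Per-window feature vectors aligned with window metadata."""

    features: np.ndarray  # windows x features
    windows: tuple[Window, ...]
    feature_names: tuple[str, ...]
    params: ParameterSet

    def __post_init__(self) -> None:
        if self.features.shape != (len(self.windows), len(self.feature_names)):
            raise ValueError("features shape does not match metadata")

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.condition for w in self.windows])

    @property
    def block_ids(self) -> np.ndarray:
        return np.array([w.block_id for w in self.windows])

    def subset(self, mask: np.ndarray) -> "WindowFeatureSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return WindowFeatureSet(
            self.features[idx],
            tuple(self.windows[i] for i in idx),
            self.feature_names,
            self.params,
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "block_id": self.block_ids,
                "condition": self.labels,
                "session": [w.session for w in self.windows],
                "centre_sample": [w.centre_sample for w in self.windows],
            }
        )
        feats = pd.DataFrame(self.features, columns=list(self.feature_names))
        return pd.concat([meta, feats], axis=1)


def _window_psd(
    signal: np.ndarray,
    windows: Sequence[Window],
    sampling_rate: float,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per (window, channel): returns (freqs, psd array)."""
    if not windows:
        raise ValueError("no windows to featurise")
    w = windows[0].n_samples
    nperseg = min(int(round(sampling_rate)), w)
    starts = np.array([win.start_sample for win in windows])
    offsets = np.arange(w)
    freqs = None
    out = None
    for lo in range(0, len(windows), chunk):
        idx = starts[lo : lo + chunk, None] + offsets[None, :]
        seg = signal[:, idx]  # channels x chunk x w
        f, psd = sps.welch(
            seg,
            fs=sampling_rate,
            window="hamming",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            axis=-1,
        )
        if out is None:
            freqs = f
            out = np.empty((len(windows), signal.shape[0], f.size))
        out[lo : lo + seg.shape[1]] = np.transpose(psd, (1, 0, 2))
    return freqs, out


class FeatureCache:
    """Full-montage window PSDs per (window length, spatial filter).

    Grid points share these base computations: the channel subset and band
    only slice the cached array.
    """

    def __init__(
        self,
        recording: Recording,
        annotations: Sequence[BlockAnnotation],
        montage: Montage | None = None,
        shift: float = WINDOW_SHIFT,
    ) -> None:
        self.recording = recording
        self.annotations = tuple(annotations)
        self.montage = montage or Montage()
        self.shift = shift
        self._psd: dict[tuple[float, str], tuple[np.ndarray, np.ndarray, tuple[Window, ...]]] = {}
        self._filtered: dict[str, np.ndarray] = {}

    def _signal(self, spatial_filter: str) -> np.ndarray:
        if spatial_filter not in self._filtered:
            if spatial_filter == "common_median":
                self._filtered[spatial_filter] = common_median_reference(
                    self.recording.signal
                )
            elif spatial_filter == "none":
                self._filtered[spatial_filter] = self.recording.signal
            else:
                raise ValueError(f"unknown spatial filter {spatial_filter!r}")
        return self._filtered[spatial_filter]

    def base(
        self, window_length: float, spatial_filter: str
    ) -> tuple[np.ndarray, np.ndarray, tuple[Window, ...]]:
        key = (window_length, spatial_filter)
        if key not in self._psd:
            windows = tuple(
                slide_windows(
                    self.annotations,
                    window_length,
                    self.shift,
                    self.recording.sampling_rate,
                )
            )
            freqs, psd = _window_psd(
                self._signal(spatial_filter), windows, self.recording.sampling_rate
            )
            self._psd[key] = (freqs, psd, windows)
        return self._psd[key]

    def features_for(
        self, params: ParameterSet, rejected_channels: Sequence[str] = ()
    ) -> WindowFeatureSet:
        freqs, psd, windows = self.base(params.window_length, params.spatial_filter)
        channels = expand_channel_group(params.subset, self.montage, rejected_channels)
        ch_idx = [self.recording.labels.index(c) for c in channels]
        band_mask = (freqs >= params.band[0]) & (freqs <= params.band[1])
        if not band_mask.any():
            raise ValueError(f"band {params.band} contains no frequency bins")
        if params.band[1] > self.recording.sampling_rate / 2:
            raise ValueError("band exceeds the Nyquist frequency")
        sub = psd[:, ch_idx][:, :, band_mask]
        floor = np.finfo(float).tiny
        if params.aggregate:
            feats = np.log10(np.maximum(sub.mean(axis=2), floor))
            names = tuple(channels)
        else:
            feats = np.log10(np.maximum(sub, floor)).reshape(len(windows), -1)
            names = tuple(
                f"{c}:{f:g}Hz" for c in channels for f in freqs[band_mask]
            )
        return WindowFeatureSet(feats, windows, names, params)


def spectral_features(
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
    params: ParameterSet,
    montage: Montage | None = None,
    rejected_channels: Sequence[str] = (),
) -> WindowFeatureSet:
    """One-shot feature extraction for a single parameter set."""
    cache = FeatureCache(recording, annotations, montage, params.shift)
    return cache.features_for(params, rejected_channels)
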