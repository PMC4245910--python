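"""Core containers: montage, recordings and block annotations.

A *recording* is a continuous multichannel EEG signal (channels x samples,
microvolts) with a sampling rate and ordered channel labels.  A *block* is a
contiguous, annotated span of one experimental condition — spatial navigation
(SPN), reading (MER) or calculation (MEC) — expressed as a 0-based half-open
sample interval.  Blocks are the atomic unit for every data split downstream,
because heavily overlapping sliding windows make any within-block split leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The three experimental conditions.
CONDITIONS = ("SPN", "MER", "MEC")

#: Workload relabelling: SPN is low workload, the two mental tasks are high.
WORKLOAD = {"SPN": "LW", "MER": "HW", "MEC": "HW"}

#: The canonical 28-electrode montage (10-20 system subset), in order.
CANONICAL_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "Fc5", "Fc1", "Fc2", "Fc6",
    "T7", "C3", "Cz", "C4", "T8",
    "Cp5", "Cp1", "Cp2", "Cp6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Scalp region per canonical label.
CANONICAL_REGIONS = {
    "Fp1": "frontal", "Fp2": "frontal", "F7": "frontal", "F3": "frontal",
    "Fz": "frontal", "F4": "frontal", "F8": "frontal",
    "Fc5": "central", "Fc1": "central", "Fc2": "central", "Fc6": "central",
    "C3": "central", "Cz": "central", "C4": "central",
    "T7": "temporal", "T8": "temporal",
    "Cp5": "parietal", "Cp1": "parietal", "Cp2": "parietal", "Cp6": "parietal",
    "P7": "parietal", "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "P8": "parietal",
    "O1": "occipital", "Oz": "occipital", "O2": "occipital",
}

REGIONS = ("frontal", "central", "parietal", "occipital", "temporal")


@dataclass(frozen=True)
class Montage:
    """An ordered set of channel labels with a scalp-region assignment."""

    labels: tuple[str, ...] = CANONICAL_LABELS
    regions: dict[str, str] = field(default_factory=lambda: dict(CANONICAL_REGIONS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        missing = [l for l in self.labels if l not in self.regions]
        if missing:
            raise ValueError(f"labels without region assignment: {missing}")
        bad = {r for r in self.regions.values()} - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def channels_in_region(self, region: str) -> list[str]:
        return [l for l in self.labels if self.regions[l] == region]


@dataclass(frozen=True)
class BlockAnnotation:
    """A labelled, non-overlapping span: ``[start_sample, end_sample)``."""

    condition: str
    session: int
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("need 0 <= start_sample < end_sample")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    @property
    def workload(self) -> str:
        return WORKLOAD[self.condition]


@dataclass
class Recording:
    """A channels x samples signal matrix (microvolts) with metadata."""

    signal: np.ndarray
    sampling_rate: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.signal.shape[0]} channels"
            )
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.labels.index(label)]


def validate_annotations(
    annotations: Sequence[BlockAnnotation], n_samples: int | None = None
) -> None:
    """Check that blocks are ordered and non-overlapping within each session.

    Raises ``ValueError`` on overlap, disorder, or a block running past the
    end of the recording (when ``n_samples`` is given).
    """
    for session in (1, 2):
        blocks = [a for a in annotations if a.session == session]
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.start_sample < prev.end_sample:
                raise ValueError(
                    f"session {session}: blocks overlap or are out of order "
                    f"at sample {cur.start_sample}"
                )
    if n_samples is not None:
        for a in annotations:
            if a.end_sample > n_samples:
                raise ValueError(
                    f"block [{a.start_sample}, {a.end_sample}) exceeds "
                    f"recording length {n_samples}"
                )


def count_blocks(annotations: Iterable[BlockAnnotation]) -> dict[str, int]:
    """Number of blocks per condition."""
    counts = {c: 0 for c in CONDITIONS}
    for a in annotations:
        counts[a.condition] += 1
    return counts
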