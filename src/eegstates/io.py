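"""Plain-text I/O: CSV signal matrices with JSON annotation sidecars.

A recording is stored as a CSV matrix (rows = samples, columns = channels,
header = channel labels, 17 significant digits so float64 round-trips
bit-exactly) next to a ``.json`` sidecar holding the sampling rate, the
labels and the block annotations as 0-based half-open sample intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import BlockAnnotation, Recording, validate_annotations


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def save_recording(
    csv_path: str | Path,
    recording: Recording,
    annotations: Sequence[BlockAnnotation],
) -> None:
    """Write the signal matrix and its annotation sidecar."""
    csv_path = Path(csv_path)
    validate_annotations(annotations, recording.n_samples)
    header = ",".join(recording.labels)
    np.savetxt(
        csv_path,
        recording.signal.T,
        delimiter=",",
        header=header,
        comments="",
        fmt="%.17g",
    )
    sidecar = {
        "schema_version": 1,
        "sampling_rate": recording.sampling_rate,
        "labels": list(recording.labels),
        "blocks": [
            {
                "condition": a.condition,
                "session": a.session,
                "start_sample": a.start_sample,
                "end_sample": a.end_sample,
            }
            for a in annotations
        ],
    }
    sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))


def load_recording(csv_path: str | Path) -> tuple[Recording, list[BlockAnnotation]]:
    """Read a CSV recording plus sidecar; round-trips ``save_recording``.

    Distinct diagnostics for: missing sidecar, label mismatch between CSV
    header and sidecar, invalid sampling rate, and blocks running past the
    end of the recording.
    """
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"annotation sidecar not found: {side}")
    meta = json.loads(side.read_text())

    with open(csv_path) as fh:
        header = fh.readline().strip()
    labels = tuple(header.split(","))
    if list(labels) != list(meta.get("labels", labels)):
        raise ValueError(
            f"channel labels in {csv_path.name} do not match sidecar {side.name}"
        )
    fs = meta.get("sampling_rate")
    if not isinstance(fs, (int, float)) or fs <= 0:
        raise ValueError(f"sidecar {side.name} has invalid sampling_rate: {fs!r}")

    signal = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2).T
    recording = Recording(signal, float(fs), labels)
    annotations = [
        BlockAnnotation(
            b["condition"], b["session"], b["start_sample"], b["end_sample"]
        )
        for b in meta["blocks"]
    ]
    validate_annotations(annotations, recording.n_samples)
    return recording, annotations
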