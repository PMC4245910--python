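#!/usr/bin/env python
"""Simulate one synthetic subject: two sessions of the alternating design.

Session 1 alternates 9 navigation (SPN) blocks with 8 calculation (MEC)
blocks, session 2 with 8 reading (MER) blocks; the workload signature
raises frontal alpha and frontal+parietal theta power during the mental
tasks.  Writes the recording (CSV + JSON sidecar) to scratch/ (it is
~50 MB of text) and a per-block summary table to results/.
"""

from pathlib import Path

import pandas as pd

import eegstates as es

SEED = 1
OUT = Path("results")
SCRATCH = Path("scratch/data")


def main() -> None:
    design = es.ExperimentDesign()
    recording, annotations = es.generate_experiment(
        design, es.default_signature(), seed=SEED
    )
    SCRATCH.mkdir(parents=True, exist_ok=True)
    es.save_recording(SCRATCH / "subject01.csv", recording, annotations)

    table = pd.DataFrame(
        [
            {
                "block": i,
                "condition": a.condition,
                "session": a.session,
                "start_s": a.start_sample / recording.sampling_rate,
                "duration_s": a.n_samples / recording.sampling_rate,
            }
            for i, a in enumerate(annotations)
        ]
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "block_summary.tsv", sep="\t", index=False)

    counts = es.count_blocks(annotations)
    print(
        f"simulated subject (seed {SEED}): {recording.n_channels} channels, "
        f"{recording.n_samples / recording.sampling_rate:.0f} s at "
        f"{recording.sampling_rate:g} Hz"
    )
    print(f"blocks: {counts['SPN']} SPN, {counts['MEC']} MEC, {counts['MER']} MER")
    print(f"recording -> {SCRATCH / 'subject01.csv'}")
    print(f"block table -> {OUT / 'block_summary.tsv'}")


if __name__ == "__main__":
    main()
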