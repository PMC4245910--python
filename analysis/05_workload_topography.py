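#!/usr/bin/env python
"""Physiological analysis: per-channel workload band-power contrasts.

For the theta (3-7 Hz) and alpha (8-12 Hz) bands, pairs each task block
with the navigation block preceding it and runs a Wilcoxon signed-rank
test per channel (significance at p < 0.001).  The tables reproduce the
topographic dot-map classification: which channels carry a significant
high-minus-low workload power difference, and in which direction.
"""

from pathlib import Path

import eegstates as es

SEED = 1
OUT = Path("results")


def main() -> None:
    recording, annotations = es.generate_experiment(
        es.ExperimentDesign(), es.default_signature(), seed=SEED
    )
    OUT.mkdir(exist_ok=True)
    for name, band in (("theta", es.THETA_BAND), ("alpha", es.ALPHA_BAND)):
        res = es.workload_contrast(recording, annotations, band, alpha=0.001)
        res.to_frame().to_csv(OUT / f"contrast_{name}.tsv", sep="\t", index=False)
        sig = res.significant_channels
        pos = [e.channel for e in res.entries if e.significant and e.mean_difference > 0]
        print(
            f"{name} ({band[0]:g}-{band[1]:g} Hz): {len(sig)} significant channels "
            f"(p < 0.001), {len(pos)} with higher power under workload: {pos}"
        )
        print(f"  table -> {OUT / f'contrast_{name}.tsv'}")


if __name__ == "__main__":
    main()
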