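"""Generator: block design, determinism, and spectral ground truth."""

import numpy as np
import pytest
from scipy import signal as sps

import eegstates as es
from eegstates.data import count_blocks


class TestBlockDesign:
    def test_default_session1_counts_and_order(self):
        design = es.ExperimentDesign()
        seq = design.block_sequence(1)
        assert seq.count("SPN") == 9 and seq.count("MEC") == 8
        # strict alternation starting and ending with SPN
        assert seq[0] == "SPN" and seq[-1] == "SPN"
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_session2_uses_reading_task(self):
        assert "MER" in es.ExperimentDesign().block_sequence(2)

    def test_experiment_combined_counts(self, tiny_design):
        _, ann = es.generate_experiment(tiny_design, es.null_signature(), seed=0)
        assert count_blocks(ann) == {"SPN": 6, "MER": 3, "MEC": 3}

    def test_minimal_design_counts(self):
        design = es.ExperimentDesign(
            n_spn_per_session=1,
            n_task_per_session=1,
            task_block_duration=2.0,
            spn_block_duration=1.0,
        )
        _, ann = es.generate_experiment(design, es.null_signature(), seed=0)
        assert count_blocks(ann) == {"SPN": 2, "MEC": 1, "MER": 1}

    def test_blocks_cover_recording_without_gaps(self, tiny_design):
        rec, ann = es.generate_session(tiny_design, es.null_signature(), seed=0)
        cursor = 0
        for a in ann:
            assert a.start_sample == cursor
            cursor = a.end_sample
        assert cursor == rec.n_samples

    def test_inter_block_gap(self):
        design = es.ExperimentDesign(
            n_spn_per_session=2,
            n_task_per_session=1,
            task_block_duration=2.0,
            spn_block_duration=1.0,
            inter_block_gap=0.5,
        )
        _, ann = es.generate_session(design, es.null_signature(), seed=0)
        gaps = [b.start_sample - a.end_sample for a, b in zip(ann, ann[1:])]
        assert gaps == [125, 125]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_spn_per_session": 0},
            {"n_task_per_session": -1},
            {"task_block_duration": 0.0},
            {"spn_block_duration": -2.0},
            {"sampling_rate": 0.0},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            es.ExperimentDesign(**kwargs)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tiny_design):
        rec1, ann1 = es.generate_session(tiny_design, es.default_signature(), seed=42)
        rec2, ann2 = es.generate_session(tiny_design, es.default_signature(), seed=42)
        assert np.array_equal(rec1.signal, rec2.signal)
        assert ann1 == ann2

    def test_seed_changes_noise_not_boundaries(self, tiny_design):
        rec1, ann1 = es.generate_experiment(tiny_design, es.default_signature(), seed=1)
        rec2, ann2 = es.generate_experiment(tiny_design, es.default_signature(), seed=2)
        assert ann1 == ann2
        assert not np.array_equal(rec1.signal, rec2.signal)


class TestSpectralGroundTruth:
    def test_band_gain_visible_in_periodogram(self):
        # alpha gain 3x in parietal channels for MEC -> >= 2x band power vs SPN
        sig = es.SpectralSignature(
            gains={"MEC": {"parietal": (es.BandGain(8, 12, 3.0),)}}
        )
        rec, ann = es.generate_session(
            es.ExperimentDesign(), sig, session_index=1, seed=2
        )
        pz = rec.labels.index("Pz")

        def alpha_power(block):
            f, p = sps.welch(
                rec.signal[pz, block.start_sample : block.end_sample],
                fs=rec.sampling_rate,
                nperseg=250,
            )
            return p[(f >= 8) & (f <= 12)].mean()

        mec = next(a for a in ann if a.condition == "MEC")
        spn = next(a for a in ann if a.condition == "SPN")
        assert alpha_power(mec) >= 2 * alpha_power(spn)

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 1.5])
    def test_one_over_f_slope(self, exponent):
        sig = es.SpectralSignature(
            background_exponent=exponent, osc_amplitude=0.0, base_bands=()
        )
        rec, _ = es.generate_session(es.ExperimentDesign(), sig, seed=0)
        f, psd = sps.welch(rec.signal[0], fs=rec.sampling_rate, nperseg=2048)
        m = (f >= 2) & (f <= 40)
        slope = np.polyfit(np.log10(f[m]), np.log10(psd[m]), 1)[0]
        assert slope == pytest.approx(-exponent, abs=0.15)

    def test_background_rms_matches_target(self):
        sig = es.SpectralSignature(noise_amplitude=10.0, osc_amplitude=0.0, base_bands=())
        rec, _ = es.generate_session(es.ExperimentDesign(), sig, seed=0)
        assert rec.signal.std() == pytest.approx(10.0, rel=0.05)


class TestArtifacts:
    def test_unknown_artifact_channel_rejected(self, tiny_design):
        art = es.ArtifactSpec(channels=("Xx9",), kind="muscle")
        with pytest.raises(ValueError, match="not in montage"):
            es.generate_session(tiny_design, es.null_signature(), [art], seed=0)

    def test_muscle_artifact_adds_high_frequency_power(self, tiny_design):
        art = es.ArtifactSpec(channels=("T7",), kind="muscle", amplitude=15.0)
        clean, _ = es.generate_session(tiny_design, es.null_signature(), seed=0)
        dirty, _ = es.generate_session(tiny_design, es.null_signature(), [art], seed=0)

        def high_power(rec, label):
            f, p = sps.welch(rec.channel(label), fs=250, nperseg=250)
            return p[(f >= 20) & (f <= 40)].mean()

        assert high_power(dirty, "T7") > 3 * high_power(clean, "T7")
        assert high_power(dirty, "Cz") == pytest.approx(high_power(clean, "Cz"))

    def test_condition_correlated_amplitude(self):
        art = es.ArtifactSpec(
            channels=("Fp1",), kind="ocular", amplitude=5.0, condition_correlated=True
        )
        assert art.block_amplitude("SPN") == 5.0
        assert art.block_amplitude("MEC") == 10.0
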