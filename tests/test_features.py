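"""Channel-subset expansion, sliding windows, spectral features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegstates as es
from eegstates.features import (
    CHANNEL_GROUPS,
    ParameterSet,
    default_grid,
    expand_channel_group,
    slide_windows,
    spectral_features,
)


class TestChannelGroups:
    def test_prefix_groups_exclude_fp(self):
        assert "Fp1" not in CHANNEL_GROUPS["F#"]
        assert CHANNEL_GROUPS["F#"] == ("F7", "F3", "Fz", "F4", "F8")

    def test_subset_sizes(self):
        assert len(expand_channel_group("S1")) == 16
        assert len(expand_channel_group("S2")) == 24
        assert len(expand_channel_group("S3")) == 26
        assert len(expand_channel_group("S4")) == 18

    def test_s3_is_s2_plus_temporals(self):
        s2, s3 = expand_channel_group("S2"), expand_channel_group("S3")
        assert set(s3) - set(s2) == {"T7", "T8"}

    def test_rejected_channels_removed(self):
        s1 = expand_channel_group("S1", rejected_channels=["Cp5"])
        assert "Cp5" not in s1 and len(s1) == 15

    def test_unknown_subset(self):
        with pytest.raises(ValueError):
            expand_channel_group("S9")

    def test_expansion_preserves_montage_order(self):
        montage = es.Montage()
        s2 = expand_channel_group("S2", montage)
        assert s2 == [l for l in montage.labels if l in set(s2)]


class TestSlidingWindows:
    def _block(self, duration_s, fs=250.0):
        return [es.BlockAnnotation("MEC", 1, 0, int(duration_s * fs))]

    def test_30s_block_5s_window_gives_126(self):
        assert len(slide_windows(self._block(30), 5.0)) == 126

    def test_exact_fit_gives_one_window(self):
        assert len(slide_windows(self._block(5), 5.0)) == 1

    def test_short_block_gives_none(self):
        assert len(slide_windows(self._block(3), 5.0)) == 0

    def test_windows_never_cross_boundaries_and_carry_labels(self):
        ann = [
            es.BlockAnnotation("SPN", 1, 0, 1250),
            es.BlockAnnotation("MEC", 1, 1250, 3750),
        ]
        wins = slide_windows(ann, 2.0)
        for w in wins:
            block = ann[w.block_id]
            assert block.start_sample <= w.start_sample
            assert w.start_sample + w.n_samples <= block.end_sample
            assert w.condition == block.condition

    @given(
        duration=st.floats(2.0, 60.0),
        window=st.floats(1.0, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula_matches_enumeration(self, duration, window):
        fs = 250.0
        ann = [es.BlockAnnotation("SPN", 1, 0, int(round(duration * fs)))]
        wins = slide_windows(ann, window, 0.2, fs)
        # brute-force enumeration of valid start samples
        w = int(round(window * fs))
        step = int(round(0.2 * fs))
        expected = len(
            [s for s in range(0, ann[0].end_sample, step) if s + w <= ann[0].end_sample]
        )
        assert len(wins) == expected
        if ann[0].n_samples >= w:
            assert expected == (ann[0].n_samples - w) // step + 1


def _tone_recording(freq_hz, n_channels=3, amp=5.0, duration=12.0, fs=250.0):
    t = np.arange(int(duration * fs)) / fs
    rng = np.random.default_rng(0)
    signal = rng.normal(scale=0.01, size=(n_channels, t.size))
    signal[0] += amp * np.sin(2 * np.pi * freq_hz * t)
    rec = es.Recording(signal, fs, ("Fz", "Cz", "Pz"))
    montage = es.Montage(
        ("Fz", "Cz", "Pz"),
        {"Fz": "frontal", "Cz": "central", "Pz": "parietal"},
    )
    ann = [es.BlockAnnotation("MEC", 1, 0, t.size)]
    return rec, ann, montage


class TestSpectralFeatures:
    def test_tone_localised_at_nearest_bin(self):
        rec, ann, montage = _tone_recording(10.0)
        params = ParameterSet(subset="S2", spatial_filter="none", band=(3, 15), window_length=2.0)
        fset = spectral_features(rec, ann, params, montage)
        fz_feats = [n for n in fset.feature_names if n.startswith("Fz:")]
        row = fset.features[0, : len(fz_feats)]
        assert fz_feats[int(np.argmax(row))] == "Fz:10Hz"

    def test_out_of_band_energy_rejected(self):
        rec, ann, montage = _tone_recording(5.0)  # all energy below 8 Hz
        in_band = ParameterSet(subset="S2", spatial_filter="none", band=(3, 10), window_length=2.0)
        out_band = ParameterSet(subset="S2", spatial_filter="none", band=(10, 15), window_length=2.0)
        f_in = spectral_features(rec, ann, in_band, montage)
        f_out = spectral_features(rec, ann, out_band, montage)
        fz_in = f_in.features[:, [n.startswith("Fz") for n in f_in.feature_names]]
        fz_out = f_out.features[:, [n.startswith("Fz") for n in f_out.feature_names]]
        assert fz_out.max() < fz_in.max() - 3  # > 3 decades below the tone

    def test_amplitude_doubling_adds_log10_4(self):
        rec, ann, montage = _tone_recording(10.0, amp=2.0)
        doubled = es.Recording(rec.signal * 2.0, rec.sampling_rate, rec.labels)
        params = ParameterSet(subset="S2", spatial_filter="none", band=(3, 15), window_length=2.0)
        f1 = spectral_features(rec, ann, params, montage)
        f2 = spectral_features(doubled, ann, params, montage)
        np.testing.assert_allclose(
            f2.features - f1.features, np.log10(4.0), atol=1e-8
        )

    def test_channel_reorder_commutes(self, null_experiment):
        rec, ann = null_experiment
        params = ParameterSet(subset="S1", spatial_filter="none", band=(3, 10), window_length=2.0)
        short_ann = ann[:3]
        fset = spectral_features(rec, short_ann, params)
        perm = np.random.default_rng(1).permutation(rec.n_channels)
        rec_p = es.Recording(
            rec.signal[perm], rec.sampling_rate, tuple(rec.labels[i] for i in perm)
        )
        fset_p = spectral_features(rec_p, short_ann, params)
        # same montage-ordered subset -> identical features and names
        assert fset.feature_names == fset_p.feature_names
        np.testing.assert_allclose(fset.features, fset_p.features, atol=1e-12)

    def test_stationary_windows_share_expectation(self, null_experiment):
        rec, ann = null_experiment
        params = ParameterSet(subset="S1", spatial_filter="none", band=(3, 15), window_length=2.0)
        fset = spectral_features(rec, ann[:1], params)
        half = len(fset.windows) // 2
        first, second = fset.features[:half].mean(), fset.features[half:].mean()
        assert first == pytest.approx(second, abs=0.1)

    def test_band_beyond_nyquist_rejected(self, null_experiment):
        rec, ann = null_experiment
        params = ParameterSet(subset="S1", spatial_filter="none", band=(3, 200), window_length=2.0)
        with pytest.raises(ValueError):
            spectral_features(rec, ann[:2], params)

    def test_aggregate_gives_one_feature_per_channel(self, null_experiment):
        rec, ann = null_experiment
        params = ParameterSet(
            subset="S1", spatial_filter="none", band=(3, 15), window_length=2.0, aggregate=True
        )
        fset = spectral_features(rec, ann[:2], params)
        assert len(fset.feature_names) == 16


def test_default_grid_is_canonical_64():
    grid = default_grid()
    assert len(grid) == 64
    assert grid[0] == ParameterSet(
        subset="S1", spatial_filter="common_median", band=(3.0, 15.0), window_length=2.0
    )
    # canonical order: window length varies fastest, then band, filter, subset
    assert grid[1].window_length == 5.0
    assert grid[2].band == (7.0, 15.0)
    assert [p.subset for p in grid[:16]] == ["S1"] * 16
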