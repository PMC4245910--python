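"""Surrogate multichannel EEG with the alternating-block task design.

Generates per-subject experiments of two sessions.  Each session alternates
spatial-navigation (SPN) blocks with mental-task blocks — calculation (MEC)
in session 1, reading (MER) in session 2 — so the default design yields
9 SPN + 8 task blocks per session, i.e. 18 SPN / 8 MEC / 8 MER per subject.

The signal model is power-spectrum-level, not waveform-level: every channel
is 1/f^beta background noise plus band-limited oscillation components
(band-pass-shaped Gaussian noise) whose amplitudes are scaled per condition
and scalp region.  Optional artifact components (ocular <6 Hz, muscle
>20 Hz) can be injected on chosen channels, optionally with workload-
correlated amplitude, to exercise the artifact-channel screening stage.

All randomness derives from one integer seed through
``numpy.random.SeedSequence([seed, session, block, channel, component])``,
so any sub-stream is reproducible in isolation and block boundaries never
depend on the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import (
    CONDITIONS,
    BlockAnnotation,
    Montage,
    Recording,
)

#: Canonical frequency bands (Hz) carrying the workload effects.
THETA = (3.0, 7.0)
ALPHA = (8.0, 12.0)

_COMPONENT_BACKGROUND = 0
_COMPONENT_OSC = 1
_COMPONENT_ARTIFACT = 2


@dataclass(frozen=True)
class ExperimentDesign:
    """Block layout of one session of the alternating-task experiment."""

    n_spn_per_session: int = 9
    n_task_per_session: int = 8
    task_block_duration: float = 30.0
    spn_block_duration: float = 15.0  # "approximately half" the task blocks
    inter_block_gap: float = 0.0
    sampling_rate: float = 250.0
    session_tasks: tuple[str, str] = ("MEC", "MER")

    def __post_init__(self) -> None:
        if self.n_spn_per_session <= 0 or self.n_task_per_session <= 0:
            raise ValueError("block counts must be positive")
        if self.task_block_duration <= 0 or self.spn_block_duration <= 0:
            raise ValueError("block durations must be positive")
        if self.inter_block_gap < 0:
            raise ValueError("inter_block_gap must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for t in self.session_tasks:
            if t not in ("MEC", "MER"):
                raise ValueError(f"session task must be MEC or MER, got {t!r}")

    def block_sequence(self, session_index: int) -> list[str]:
        """Condition labels in temporal order for one session."""
        task = self.session_tasks[session_index - 1]
        seq: list[str] = []
        n_spn, n_task = self.n_spn_per_session, self.n_task_per_session
        while n_spn or n_task:
            if n_spn:
                seq.append("SPN")
                n_spn -= 1
            if n_task:
                seq.append(task)
                n_task -= 1
        return seq


@dataclass(frozen=True)
class BandGain:
    """Amplitude multiplier for one frequency band: (low, high, multiplier)."""

    low: float
    high: float
    multiplier: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass(frozen=True)
class SpectralSignature:
    """Per-condition, per-region spectral structure of the surrogate EEG.

    ``gains[condition][region]`` lists band gains applied on top of the
    baseline oscillation amplitude ``osc_amplitude`` (multiplier 1.0 means
    baseline; unlisted (condition, region, band) combinations stay at
    baseline).  ``base_bands`` are the bands synthesised in every channel.
    """

    background_exponent: float = 1.0
    noise_amplitude: float = 10.0  # rms microvolts of the 1/f background
    osc_amplitude: float = 4.0  # rms microvolts of a multiplier-1 oscillation
    base_bands: tuple[tuple[float, float], ...] = (THETA, ALPHA)
    gains: dict[str, dict[str, tuple[BandGain, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0 or self.osc_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        for low, high in self.base_bands:
            if not 0 < low < high:
                raise ValueError("base band needs 0 < low < high")
        for cond in self.gains:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")

    def band_amplitudes(self, condition: str, region: str) -> list[tuple[tuple[float, float], float]]:
        """Resolve ((low, high), rms amplitude) for every band of a channel."""
        amps = {band: self.osc_amplitude for band in self.base_bands}
        for g in self.gains.get(condition, {}).get(region, ()):
            amps[(g.low, g.high)] = self.osc_amplitude * g.multiplier
        return sorted(amps.items())


@dataclass(frozen=True)
class ArtifactSpec:
    """An injected artifact source on a subset of channels.

    ``ocular`` artifacts live below 6 Hz, ``muscle`` artifacts above 20 Hz.
    When ``condition_correlated`` the amplitude is multiplied by
    ``hw_factor`` during high-workload (MER/MEC) blocks, which is exactly
    the situation the preprocessing screen is designed to catch.
    """

    channels: tuple[str, ...]
    kind: str  # "ocular" | "muscle"
    amplitude: float = 10.0
    condition_correlated: bool = False
    hw_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("ocular", "muscle"):
            raise ValueError("artifact kind must be 'ocular' or 'muscle'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def band(self, sampling_rate: float) -> tuple[float, float]:
        if self.kind == "ocular":
            return (0.5, 6.0)
        return (20.0, 0.98 * sampling_rate / 2)

    def block_amplitude(self, condition: str) -> float:
        if self.condition_correlated and condition != "SPN":
            return self.amplitude * self.hw_factor
        return self.amplitude


def default_signature(effect_scale: float = 1.0) -> SpectralSignature:
    """The study-condition signature: workload raises frontal alpha and
    frontal+parietal theta relative to navigation, with a theta-dominant
    profile for calculation and an alpha-dominant one for reading.

    ``effect_scale`` scales the elevation above baseline (1.0 = default
    conditions; larger values give a high-SNR variant for oracle checks).
    """

    def g(low_high: tuple[float, float], mult: float) -> BandGain:
        return BandGain(low_high[0], low_high[1], 1.0 + (mult - 1.0) * effect_scale)

    gains = {
        "MEC": {
            "frontal": (g(THETA, 2.4), g(ALPHA, 1.7)),
            "parietal": (g(THETA, 2.0), g(ALPHA, 1.5)),
            "central": (g(THETA, 1.5),),
        },
        "MER": {
            "frontal": (g(THETA, 1.6), g(ALPHA, 2.4)),
            "parietal": (g(THETA, 1.4), g(ALPHA, 2.0)),
        },
    }
    return SpectralSignature(gains=gains)


def null_signature() -> SpectralSignature:
    """No condition-dependent structure: every condition is exchangeable."""
    return SpectralSignature(gains={})


def _synth_from_psd(
    rng: np.random.Generator, psd: np.ndarray, n: int, sampling_rate: float
) -> np.ndarray:
    """Gaussian noise with the given one-sided target PSD (uV^2/Hz per bin).

    Fourier coefficients are drawn with variance proportional to the PSD, so
    the expected spectrum — and hence every band's expected power — is
    independent of the block length.  (Exact-rms renormalisation would tie
    per-Hz levels to the synthesis grid and bias comparisons between blocks
    of different duration.)
    """
    sigma = np.sqrt(psd * sampling_rate * n / 4.0)
    spectrum = sigma * (
        rng.standard_normal(psd.size) + 1j * rng.standard_normal(psd.size)
    )
    return np.fft.irfft(spectrum, n=n)


def _colored_noise(
    rng: np.random.Generator,
    n: int,
    sampling_rate: float,
    exponent: float,
    rms: float,
    f_cut: float = 0.5,
) -> np.ndarray:
    """1/f^exponent (power) noise, high-passed at ``f_cut``, with expected
    rms equal to ``rms`` regardless of block length."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    nyq = sampling_rate / 2.0
    if exponent == 1.0:
        integral = np.log(nyq / f_cut)
    else:
        integral = (nyq ** (1 - exponent) - f_cut ** (1 - exponent)) / (1 - exponent)
    scale = rms**2 / integral  # continuous-PSD amplitude so that var = rms^2
    psd = np.zeros_like(freqs)
    mask = freqs >= f_cut
    psd[mask] = scale * freqs[mask] ** (-exponent)
    return _synth_from_psd(rng, psd, n, sampling_rate)


def _band_noise(
    rng: np.random.Generator,
    n: int,
    sampling_rate: float,
    band: tuple[float, float],
    rms: float,
) -> np.ndarray:
    """Band-limited Gaussian noise (flat in-band PSD) with expected rms
    ``rms``, independent of block length."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any() or rms == 0:
        return np.zeros(n)
    psd = np.zeros_like(freqs)
    psd[mask] = rms**2 / (band[1] - band[0])
    return _synth_from_psd(rng, psd, n, sampling_rate)


def _block_rng(seed: int, session: int, block: int, channel: int, component: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, session, block, channel, component])
    )


def generate_session(
    design: ExperimentDesign,
    signature: SpectralSignature,
    artifacts: Sequence[ArtifactSpec] = (),
    session_index: int = 1,
    seed: int = 0,
    montage: Montage | None = None,
) -> tuple[Recording, list[BlockAnnotation]]:
    """Generate one session: a Recording plus its block annotations.

    Block boundaries depend only on the design; the seed only changes the
    noise realisation.  Identical inputs give bit-identical output.
    """
    if session_index not in (1, 2):
        raise ValueError("session_index must be 1 or 2")
    montage = montage or Montage()
    for spec in artifacts:
        unknown = set(spec.channels) - set(montage.labels)
        if unknown:
            raise ValueError(f"artifact channels not in montage: {sorted(unknown)}")

    fs = design.sampling_rate
    gap = int(round(design.inter_block_gap * fs))
    seq = design.block_sequence(session_index)
    n_task_samples = int(round(design.task_block_duration * fs))
    n_spn_samples = int(round(design.spn_block_duration * fs))

    annotations: list[BlockAnnotation] = []
    cursor = 0
    for cond in seq:
        n = n_spn_samples if cond == "SPN" else n_task_samples
        annotations.append(
            BlockAnnotation(cond, session_index, cursor, cursor + n)
        )
        cursor += n + gap
    total = annotations[-1].end_sample

    signal = np.zeros((len(montage), total))
    for b, ann in enumerate(annotations):
        n = ann.n_samples
        sl = slice(ann.start_sample, ann.end_sample)
        for ch, label in enumerate(montage.labels):
            region = montage.regions[label]
            rng_bg = _block_rng(seed, session_index, b, ch, _COMPONENT_BACKGROUND)
            x = _colored_noise(
                rng_bg, n, fs, signature.background_exponent, signature.noise_amplitude
            )
            rng_osc = _block_rng(seed, session_index, b, ch, _COMPONENT_OSC)
            for band, amp in signature.band_amplitudes(ann.condition, region):
                x += _band_noise(rng_osc, n, fs, band, amp)
            signal[ch, sl] = x
        for a_idx, spec in enumerate(artifacts):
            rng_art = _block_rng(
                seed, session_index, b, len(montage) + a_idx, _COMPONENT_ARTIFACT
            )
            amp = spec.block_amplitude(ann.condition)
            if amp == 0:
                continue
            source = _band_noise(rng_art, n, fs, spec.band(fs), amp)
            for label in spec.channels:
                signal[montage.index(label), sl] += source

    recording = Recording(signal, fs, montage.labels)
    return recording, annotations


def generate_experiment(
    design: ExperimentDesign,
    signature: SpectralSignature,
    artifacts: Sequence[ArtifactSpec] = (),
    seed: int = 0,
    montage: Montage | None = None,
) -> tuple[Recording, list[BlockAnnotation]]:
    """Generate a full per-subject dataset: both sessions concatenated.

    Session 2 annotations are offset by the session-1 length; with the
    default design the combined counts are 18 SPN, 8 MEC, 8 MER.
    """
    rec1, ann1 = generate_session(design, signature, artifacts, 1, seed, montage)
    rec2, ann2 = generate_session(design, signature, artifacts, 2, seed, montage)
    offset = rec1.n_samples
    ann2 = [
        replace(a, start_sample=a.start_sample + offset, end_sample=a.end_sample + offset)
        for a in ann2
    ]
    signal = np.concatenate([rec1.signal, rec2.signal], axis=1)
    recording = Recording(signal, design.sampling_rate, rec1.labels)
    return recording, ann1 + ann2
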