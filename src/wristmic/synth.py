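"""Parametric audio synthesis for wrist-microphone-like recordings.

Live speech is modelled source-filter style: a glottal sawtooth at the
speaker's fundamental frequency (with slow vibrato and cycle jitter) plus a
small aspiration-noise component, shaped by a cascade of second-order formant
resonators, then amplitude-modulated at a syllabic rate with inter-syllable
dips.  This is deliberately not phonetically realistic speech; it reproduces
the spectro-temporal cues a voice-activity detector exploits (harmonic
structure, formant envelope, 3-6 Hz modulation) at negligible CPU cost.

Device-generated speech (TV/radio loudspeakers) reuses the same speech
synthesiser and then applies a fixed loudspeaker channel: dynamic-range
compression, a 300-3000 Hz band-limit, and a fixed synthetic room response.
That channel is what makes the class learnably distinct from live speech.

Levels are RMS in dB relative to ``REF_RMS`` (the nominal level of a
bystander speaker at conversational distance from the wrist).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import SAMPLE_RATE

REF_RMS = 0.02

_SPEECH_KINDS = ("broadband_noise", "device_speech", "ambient")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class VoiceSpec:
    """Acoustic parameters of one synthetic speaker.

    fundamental_freq : glottal pitch in Hz (60-400).
    formant_freqs    : resonance centres in Hz, strictly increasing, < 4 kHz
                       (Nyquist for the 8 kHz device).
    syllable_rate    : amplitude-modulation rate in Hz (syllables per second).
    level_db         : RMS level in dB relative to REF_RMS.
    reverb_amount    : wet/dry mix in [0, 1]; proximity cue — a wearer's mouth
                       is near the wrist microphone, so wearer voices are dry.
    """

    fundamental_freq: float = 120.0
    formant_freqs: tuple = (500.0, 1500.0, 2500.0)
    syllable_rate: float = 4.0
    level_db: float = 0.0
    reverb_amount: float = 0.3

    def __post_init__(self) -> None:
        if not (60.0 <= self.fundamental_freq <= 400.0):
            raise ValueError(f"fundamental_freq {self.fundamental_freq} outside [60, 400] Hz")
        ff = tuple(float(f) for f in self.formant_freqs)
        if len(ff) < 1 or any(f2 <= f1 for f1, f2 in zip(ff, ff[1:])):
            raise ValueError("formant_freqs must be non-empty and strictly increasing")
        if ff[-1] >= 4000.0:
            raise ValueError("formants must lie below the 4 kHz Nyquist frequency")
        if not (0.0 <= self.reverb_amount <= 1.0):
            raise ValueError("reverb_amount must be in [0, 1]")
        if self.syllable_rate <= 0:
            raise ValueError("syllable_rate must be positive")
        object.__setattr__(self, "formant_freqs", ff)


def random_voice(rng, level_db: float = 0.0, reverb_amount: float = 0.3) -> VoiceSpec:
    """Draw a plausible speaker: pitch, three formants, syllable rate."""
    rng = _as_rng(rng)
    f0 = float(rng.uniform(85.0, 280.0))
    f1 = float(rng.uniform(350.0, 850.0))
    f2 = float(rng.uniform(f1 + 400.0, 2200.0))
    f3 = float(rng.uniform(f2 + 400.0, 3400.0))
    return VoiceSpec(
        fundamental_freq=f0,
        formant_freqs=(f1, f2, f3),
        syllable_rate=float(rng.uniform(3.0, 6.0)),
        level_db=level_db,
        reverb_amount=reverb_amount,
    )


def _resonator(freq: float, bandwidth: float, fs: int = SAMPLE_RATE):
    """Second-order all-pole resonator coefficients at unit peak gain."""
    r = np.exp(-np.pi * bandwidth / fs)
    theta = 2.0 * np.pi * freq / fs
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    b = np.array([1.0 - r])
    return b, a


def room_impulse_response(rng, duration_s: float = 0.25, decay_s: float = 0.05) -> np.ndarray:
    """Exponentially decaying noise burst as a minimal room response."""
    rng = _as_rng(rng)
    n = int(duration_s * SAMPLE_RATE)
    t = np.arange(n) / SAMPLE_RATE
    ir = rng.standard_normal(n) * np.exp(-t / decay_s)
    ir[0] = 1.0
    return ir / np.sqrt(np.sum(ir**2))


def _apply_reverb(x: np.ndarray, amount: float, rng) -> np.ndarray:
    if amount <= 0.0 or x.size == 0:
        return x
    # More distant sources get both a wetter mix and a longer tail; the tail
    # smears spectra across frames and fills inter-syllable dips.
    decay = 0.03 + 0.4 * amount
    ir = room_impulse_response(rng, duration_s=min(4.0 * decay, 1.0), decay_s=decay)
    wet = signal.fftconvolve(x, ir)[: x.size]
    wr = np.sqrt(np.mean(wet**2))
    xr = np.sqrt(np.mean(x**2))
    if wr > 0:
        wet *= xr / wr
    return (1.0 - amount) * x + amount * wet


def _set_rms(x: np.ndarray, level_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return x
    return x * (REF_RMS * 10.0 ** (level_db / 20.0) / rms)


def synthesize_speech_segment(duration_s: float, voice: VoiceSpec, seed) -> np.ndarray:
    """Render one utterance of live speech from a :class:`VoiceSpec`.

    Deterministic given (duration, voice, seed).  Returns a mono float
    waveform at 8 kHz with RMS set by ``voice.level_db``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(seed)
    n = int(round(duration_s * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE

    # Glottal source: sawtooth with vibrato and a small random pitch drift.
    vibrato = 1.0 + 0.02 * np.sin(2 * np.pi * rng.uniform(4.0, 7.0) * t + rng.uniform(0, 2 * np.pi))
    drift = 1.0 + 0.05 * np.cumsum(rng.standard_normal(n)) / np.sqrt(n) / 3.0
    f_inst = voice.fundamental_freq * vibrato * np.clip(drift, 0.8, 1.2)
    phase = 2 * np.pi * np.cumsum(f_inst) / SAMPLE_RATE
    source = signal.sawtooth(phase)
    source += 0.12 * rng.standard_normal(n)  # aspiration noise
    # Pre-emphasis flattens the 1/n harmonic rolloff so the formant
    # resonances, not the fundamental, dominate the spectral envelope.
    source = np.append(source[0], source[1:] - 0.97 * source[:-1])

    # Formant envelope: parallel bank of resonators (broadening with index).
    x = np.zeros(n)
    for k, freq in enumerate(voice.formant_freqs):
        b, a = _resonator(freq, bandwidth=90.0 + 60.0 * k)
        x += signal.lfilter(b, a, source) / (k + 1.0)

    # Syllabic amplitude modulation with inter-syllable dips (not silence:
    # voiced energy persists through the dips, as in running speech).
    phi = rng.uniform(0, 2 * np.pi)
    env = (0.5 - 0.5 * np.cos(2 * np.pi * voice.syllable_rate * t + phi)) ** 1.5
    x *= 0.15 + 0.85 * env

    x = _apply_reverb(x, voice.reverb_amount, rng)
    return _set_rms(x, voice.level_db)


# Fixed loudspeaker room: one constant response shared by all device audio,
# so the coloration is a stable, learnable class signature.
_DEVICE_ROOM_SEED = 715225741


def loudspeaker_channel(x: np.ndarray) -> np.ndarray:
    """Apply the fixed TV/radio channel: compression, band-limit, fixed room."""
    if x.size == 0:
        return x
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = np.tanh(1.5 * x / rms) * rms  # dynamic-range compression
    sos = signal.butter(4, [300.0, 3000.0], btype="bandpass", fs=SAMPLE_RATE, output="sos")
    x = signal.sosfilt(sos, x)
    ir = room_impulse_response(np.random.default_rng(_DEVICE_ROOM_SEED), duration_s=0.3, decay_s=0.08)
    wet = signal.fftconvolve(x, ir)[: x.size]
    wr = np.sqrt(np.mean(wet**2))
    xr = np.sqrt(np.mean(x**2))
    if wr > 0:
        wet *= xr / wr
    return 0.6 * x + 0.4 * wet


def synthesize_background(duration_s: float, kind: str, seed, level_db: float = 0.0,
                          voice: VoiceSpec | None = None) -> np.ndarray:
    """Render non-(live-)speech material: noise, ambience, or device speech.

    ``device_speech`` reuses the speech synthesiser and then passes it through
    the fixed loudspeaker channel; its truth class is non-speech for the
    occupancy measure.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(seed)
    n = int(round(duration_s * SAMPLE_RATE))
    if kind == "broadband_noise":
        x = rng.standard_normal(n)
    elif kind == "ambient":
        # Low-frequency-weighted noise with a slow level wander.
        x = signal.lfilter([1.0], [1.0, -0.97], rng.standard_normal(n))
        wander = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.05, 0.3) * np.arange(n) / SAMPLE_RATE
                                    + rng.uniform(0, 2 * np.pi))
        x *= wander
    elif kind == "device_speech":
        if voice is None:
            voice = random_voice(rng, level_db=0.0, reverb_amount=0.0)
        x = synthesize_speech_segment(duration_s, voice, rng)
        x = loudspeaker_channel(x)
    else:
        raise ValueError(f"unknown background kind {kind!r}; expected one of {_SPEECH_KINDS}")
    return _set_rms(x, level_db)
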