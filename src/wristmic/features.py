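"""Frame feature extraction for the frame-level classifiers.

Default representation: log-magnitude spectrum of each standardized
256-sample frame (Hann window, rFFT, 129 bins) concatenated with the mean
log-spectrum over a small symmetric context window.  The context term carries
the syllabic-modulation and reverberation-tail cues that a single 32 ms
frame cannot, while keeping the feature dimension small enough for a compact
fully connected network.
"""

from __future__ import annotations

import numpy as np

from .core import FRAME_SAMPLES
from .preprocess import FrameSet

_HANN = np.hanning(FRAME_SAMPLES)
_LOG_EPS = 1e-8

N_SPECTRUM_BINS = FRAME_SAMPLES // 2 + 1  # 129


def log_spectrum(frames: np.ndarray) -> np.ndarray:
    """Log-magnitude rFFT of each (windowed) frame; shape (n, 129)."""
    frames = np.asarray(frames, dtype=np.float64).reshape(-1, FRAME_SAMPLES)
    spec = np.abs(np.fft.rfft(frames * _HANN, axis=1))
    return np.log(spec + _LOG_EPS)


def _context_mean(spectra: np.ndarray, context: int) -> np.ndarray:
    """Mean spectrum over [-context, +context] frames, edge-padded."""
    if context <= 0 or spectra.shape[0] == 0:
        return spectra.copy()
    n = spectra.shape[0]
    padded = np.concatenate(
        [np.repeat(spectra[:1], context, axis=0), spectra, np.repeat(spectra[-1:], context, axis=0)]
    )
    csum = np.cumsum(padded, axis=0)
    width = 2 * context + 1
    windowed = np.empty_like(spectra)
    windowed[:] = (csum[width - 1 :] - np.concatenate([np.zeros((1, spectra.shape[1])), csum[: n - 1]])) / width
    return windowed


def _energy_features(log_e: np.ndarray, context: int) -> np.ndarray:
    """Relative-level features from the pre-standardization frame energies.

    All four are invariant to the per-recording rescale gain:
      * level above the recording's quiet floor (10th percentile),
      * level relative to the local context mean,
      * local energy spread (modulation depth: dry close speech keeps deep
        inter-syllable dips, reverberant distant speech fills them in),
      * smoothed level above the floor.
    """
    e = log_e.reshape(-1, 1)
    ctx = max(context, 1)
    ctx_mean = _context_mean(e, ctx)
    ctx_sq = _context_mean(e**2, ctx)
    ctx_std = np.sqrt(np.maximum(ctx_sq - ctx_mean**2, 0.0))
    floor = np.quantile(log_e, 0.10)
    return np.concatenate([e - floor, e - ctx_mean, ctx_std, ctx_mean - floor], axis=1)


# Long energy-context horizon (~±0.5 s): wide enough to see several syllables,
# so the modulation-depth feature distinguishes dry close speech (deep
# inter-syllable dips) from dynamic-range-compressed loudspeaker audio and
# reverberant distant speech (dips filled in).
LONG_CONTEXT = 15

_FREQS = np.fft.rfftfreq(FRAME_SAMPLES, d=1.0 / 8000.0)
_LOW_BAND = _FREQS < 300.0
_MID_BAND = (_FREQS >= 300.0) & (_FREQS <= 3000.0)
_HIGH_BAND = _FREQS > 3000.0


def _band_contrast(spectra: np.ndarray) -> np.ndarray:
    """Low/high band energy relative to the 300-3000 Hz mid band.

    Live speech carries fundamental energy below 300 Hz and aspiration noise
    above 3 kHz; loudspeaker (TV/radio) audio is band-limited to the telephone
    band, so both contrasts collapse for device-generated speech.
    """
    mid = spectra[:, _MID_BAND].mean(axis=1, keepdims=True)
    low = spectra[:, _LOW_BAND].mean(axis=1, keepdims=True)
    high = spectra[:, _HIGH_BAND].mean(axis=1, keepdims=True)
    return np.concatenate([low - mid, high - mid], axis=1)


def frame_features(frameset: FrameSet, mode: str = "log_spectrogram", context: int = 3) -> np.ndarray:
    """Feature matrix for a FrameSet.

    ``band_energy`` (default for the speech/non-speech model): the compact
    speaker-independent set — band contrasts at three temporal scales plus
    relative-level features at two scales (14 dims).  These carry the class
    physics (live-speech band structure vs the loudspeaker channel; level and
    modulation depth vs the floor) without the per-speaker spectral detail
    that invites a speaker-identity shortcut under session-wise validation.
    ``level_contour``: the relative-level features only — the wrist-proximity
    cues used by the wearer/other model.  ``log_spectrogram``: per-frame log
    spectrum + context mean, plus band and level features (266 dims).
    ``raw_frame``: the standardized waveform itself (256 dims).
    """
    if mode == "raw_frame":
        return frameset.frames.copy()
    if mode == "band_energy":
        if frameset.log_energy is None:
            raise ValueError("band_energy features need pre-standardization energies")
        if len(frameset) == 0:
            return np.empty((0, 14))
        spectra = log_spectrum(frameset.frames)
        bands = _band_contrast(spectra)
        log_e = np.asarray(frameset.log_energy)
        return np.concatenate(
            [
                bands,
                _context_mean(bands, max(context, 1)),
                _context_mean(bands, LONG_CONTEXT),
                _energy_features(log_e, context),
                _energy_features(log_e, LONG_CONTEXT),
            ],
            axis=1,
        )
    if mode == "level_contour":
        if frameset.log_energy is None:
            raise ValueError("level_contour features need pre-standardization energies")
        if len(frameset) == 0:
            return np.empty((0, 8))
        log_e = np.asarray(frameset.log_energy)
        return np.concatenate(
            [_energy_features(log_e, context), _energy_features(log_e, LONG_CONTEXT)], axis=1
        )
    if mode != "log_spectrogram":
        raise ValueError(f"unknown feature mode {mode!r}")
    spectra = log_spectrum(frameset.frames)
    parts = [spectra]
    if context > 0:
        parts.append(_context_mean(spectra, context))
    if spectra.shape[0] > 0:
        bands = _band_contrast(spectra)
        parts.extend([bands, _context_mean(bands, max(context, 1))])
        if frameset.log_energy is not None:
            log_e = np.asarray(frameset.log_energy)
            parts.append(_energy_features(log_e, context))
            parts.append(_energy_features(log_e, LONG_CONTEXT))
    return np.concatenate(parts, axis=1)
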