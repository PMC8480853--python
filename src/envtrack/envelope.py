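"""Stimulus envelopes in dB and their power spectra.

The regression target throughout this package is the dB envelope of the
auditory stimulus: the waveform is passed through a bank of auditory
filters, the magnitude of the analytic (Hilbert) signal is taken per band,
band envelopes are averaged, the peak is normalized to 1, values are
floored to avoid log-of-zero discontinuities, and the result is expressed
in dB and resampled to the EEG rate.  Working in dB makes the target more
linearly related to perceived loudness and to EEG responses to sound level
than the raw linear envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "AudioWaveform",
    "Envelope",
    "PowerSpectrum",
    "extract_envelope",
    "envelope_psd",
    "envelope_eeg_power_ratio",
    "read_wav",
]


@dataclass(frozen=True)
class AudioWaveform:
    """A pressure waveform in arbitrary linear units."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1:
            raise ValueError("audio must be one-dimensional (average channels first)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Envelope:
    """A dB stimulus envelope, the reconstruction target s(t)."""

    samples: np.ndarray
    rate: float
    floor_db: float = -100.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("envelope contains non-finite samples")
        if samples.size and samples.min() < self.floor_db - 1e-9:
            raise ValueError("envelope samples fall below the dB floor")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D and of equal length")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(power < -1e-12):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", np.maximum(power, 0.0))


def _gammatone_bank(rate: float, n_bands: int, f_lo: float, f_hi: float):
    """Order-4 gammatone filters at geometrically spaced center frequencies.

    Returned as second-order sections: the low-frequency filters have poles
    close to the unit circle and direct-form filtering loses precision.
    """
    centers = np.geomspace(f_lo, f_hi, n_bands)
    return [
        signal.tf2sos(*signal.gammatone(fc, "iir", fs=rate)) for fc in centers
    ]


def extract_envelope(
    audio: AudioWaveform,
    n_bands: int = 32,
    f_lo: float = 100.0,
    f_hi: float = 8000.0,
    floor_db: float = -100.0,
    out_rate: float = 512.0,
) -> Envelope:
    """Compute the dB envelope of an audio waveform.

    The waveform is filtered with ``n_bands`` order-4 gammatone filters whose
    center frequencies are geometrically spaced between ``f_lo`` and ``f_hi``
    (endpoints inclusive).  Per band the Hilbert magnitude is taken; band
    envelopes are averaged, the peak normalized to 1, values below
    ``10**(floor_db/20)`` are clipped to that level, and the result is
    converted to dB and polyphase-resampled to ``out_rate``.

    Silence maps to a flat envelope at ``floor_db``; scaling the audio by any
    positive constant leaves the output unchanged (peak normalization comes
    before the log).
    """
    if not (0 < f_lo < f_hi < audio.rate / 2):
        raise ValueError("need 0 < f_lo < f_hi < rate/2")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if out_rate <= 0:
        raise ValueError("out_rate must be positive")
    # the slowest filter rings for a few cycles of f_lo; demand at least that
    min_len = int(4 * audio.rate / f_lo)
    if audio.samples.size < min_len:
        raise ValueError(
            f"audio too short for the {f_lo:g} Hz filter impulse response "
            f"(need >= {min_len} samples)"
        )

    acc = np.zeros(audio.samples.size)
    for sos in _gammatone_bank(audio.rate, n_bands, f_lo, f_hi):
        band = signal.sosfilt(sos, audio.samples)
        acc += np.abs(signal.hilbert(band))
    env = acc / n_bands

    peak = env.max()
    if peak > 0:
        env = env / peak
    floor_lin = 10.0 ** (floor_db / 20.0)
    env = np.maximum(env, floor_lin)
    env_db = 20.0 * np.log10(env)

    # dB first, then resample (polyphase with a rational rate ratio)
    frac = Fraction(out_rate / audio.rate).limit_denominator(10**6)
    if frac != 1:
        # pad with a line fit: dB traces sit far from 0, so zero-padding
        # would bend the edges toward 0 dB
        env_db = signal.resample_poly(
            env_db, frac.numerator, frac.denominator, padtype="line"
        )
    env_db = np.maximum(env_db, floor_db)  # resampling ringing below the floor
    return Envelope(env_db, out_rate, floor_db)


def _welch(x: np.ndarray, rate: float, window_s: float, overlap_frac: float):
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    nper = int(round(window_s * rate))
    if x.size < nper:
        raise ValueError("signal shorter than one Welch window")
    freqs, power = signal.welch(
        x,
        fs=rate,
        window="hamming",
        nperseg=nper,
        noverlap=int(round(overlap_frac * nper)),
        detrend=False,
    )
    return freqs, power


def envelope_psd(
    env: Envelope, window_s: float = 16.0, overlap_frac: float = 0.5
) -> PowerSpectrum:
    """Welch power spectral density of a dB envelope (Hamming taper)."""
    freqs, power = _welch(env.samples, env.rate, window_s, overlap_frac)
    return PowerSpectrum(freqs, power)


def envelope_eeg_power_ratio(
    env_psds: list[PowerSpectrum], eeg_psd: PowerSpectrum
) -> PowerSpectrum:
    """Average envelope PSD divided bin-wise by the average EEG PSD.

    The ratio approximates the signal-to-noise ratio available for envelope
    tracking under the null hypothesis that the neural response is a scaled
    copy of the dB envelope riding on noise with the average EEG spectrum.
    Inputs must share one frequency grid; callers are expected to have applied
    the normalization preset (zero-centering, moving-average removal, division
    by the root-mean variance across stimuli) before computing the PSDs — see
    :func:`normalize_for_ratio`.
    """
    if not env_psds:
        raise ValueError("need at least one envelope spectrum")
    for p in env_psds:
        if p.freqs.shape != eeg_psd.freqs.shape or not np.allclose(
            p.freqs, eeg_psd.freqs
        ):
            raise ValueError("all spectra must share one frequency grid")
    if np.any(eeg_psd.power <= 0):
        raise ValueError("EEG spectrum has zero power in at least one bin")
    mean_env = np.mean([p.power for p in env_psds], axis=0)
    return PowerSpectrum(eeg_psd.freqs, mean_env / eeg_psd.power)


def normalize_for_ratio(
    traces: list[np.ndarray], rate: float, ma_window_s: float = 16.0
) -> list[np.ndarray]:
    """Normalization preset for the envelope/EEG power-ratio figure.

    Each trace is zero-centered and has a centered ``ma_window_s`` moving
    average subtracted; all traces are then divided by the square root of the
    mean variance across traces, so the set has unit average variance.
    """
    from .models import remove_moving_average

    out = [remove_moving_average(np.asarray(t, float) - np.mean(t), ma_window_s, rate)
           for t in traces]
    scale = np.sqrt(np.mean([np.var(t) for t in out]))
    if scale == 0:
        raise ValueError("all traces are constant after detrending")
    return [t / scale for t in out]


def read_wav(path) -> AudioWaveform:
    """Read a WAV file (16/24-bit PCM or float) as a mono waveform.

    Multichannel audio is averaged across channels; integer PCM is rescaled
    to [-1, 1).
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    return AudioWaveform(data.astype(float), float(rate))
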