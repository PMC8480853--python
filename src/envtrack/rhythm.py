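"""Rhythm spectra of envelope reconstructions.

After averaging a stimulus's reconstructions across subjects, the Welch
spectrum of the average contains peaks wherever the reconstructions are
temporally coherent across subjects.  The incoherent noise floor is
estimated by phase-randomizing each subject's reconstruction before
averaging ("null spectra"); subtracting the mean null spectrum from the
true spectrum gives the adjusted spectral density, in which coherent
peaks stand clear of zero.  Peaks are then sought at integer multiples
(1-4x) of the music's tempo, each within a ±8% frequency window, taking
the maximum over all supplied model bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import phase_randomize
from .envelope import PowerSpectrum, _welch

__all__ = [
    "AdjustedSpectrum",
    "TempoPeakSet",
    "reconstruction_psd",
    "null_spectra",
    "adjust_psd",
    "tempo_from_beats",
    "find_tempo_peaks",
]


@dataclass(frozen=True)
class AdjustedSpectrum:
    """True Welch PSD minus the mean phase-randomized surrogate PSD."""

    freqs: np.ndarray
    true_psd: np.ndarray
    null_mean_psd: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        t = np.asarray(self.true_psd, float)
        m = np.asarray(self.null_mean_psd, float)
        if not (f.shape == t.shape == m.shape):
            raise ValueError("spectra must share one frequency grid")
        if np.any(t < 0) or np.any(m < 0):
            raise ValueError("power spectra must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "true_psd", t)
        object.__setattr__(self, "null_mean_psd", m)

    @property
    def adjusted(self) -> np.ndarray:
        """May be negative where the true spectrum sits below the floor."""
        return self.true_psd - self.null_mean_psd


@dataclass(frozen=True)
class TempoPeakSet:
    """Adjusted-power peaks at integer multiples of the tempo."""

    tempo: float
    multiples: tuple
    windows: tuple  # (lo, hi) Hz per multiple
    peak_freqs: tuple
    peak_values: tuple

    def __post_init__(self):
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        for (lo, hi), f in zip(self.windows, self.peak_freqs):
            if not lo <= f <= hi:
                raise ValueError("peak frequency outside its search window")


def reconstruction_psd(
    recon: np.ndarray,
    rate: float,
    window_s: float = 10.0,
    overlap_frac: float = 0.5,
) -> PowerSpectrum:
    """Welch PSD of a reconstruction (Hamming taper, half-overlap default)."""
    freqs, power = _welch(np.asarray(recon, float), rate, window_s, overlap_frac)
    return PowerSpectrum(freqs, power)


def null_spectra(
    per_subject_recons: list[np.ndarray],
    rate: float,
    n_iter: int = 100,
    seed: int | None = None,
    window_s: float = 10.0,
) -> list[PowerSpectrum]:
    """Surrogate noise-floor spectra of the cross-subject average.

    Per iteration every subject's reconstruction is phase-randomized
    independently, the surrogates are averaged across subjects, and the
    Welch PSD of the average is computed.  Coherent structure shared by
    subjects is destroyed while each signal's power spectrum is preserved,
    so a peak shared by ``n`` subjects drops by about a factor ``n`` in the
    null (incoherent averaging).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    recons = [np.asarray(r, float) for r in per_subject_recons]
    if not recons:
        raise ValueError("need at least one subject reconstruction")
    n = recons[0].size
    if any(r.size != n for r in recons):
        raise ValueError("subject reconstructions must have equal lengths")
    stack = np.vstack(recons)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        surrogate = phase_randomize(stack, rng).mean(axis=0)
        freqs, power = _welch(surrogate, rate, window_s, 0.5)
        out.append(PowerSpectrum(freqs, power))
    return out


def adjust_psd(
    true_psd: PowerSpectrum, null_psds: list[PowerSpectrum]
) -> AdjustedSpectrum:
    """Subtract the mean null spectrum from the true spectrum, bin-wise."""
    if not null_psds:
        raise ValueError("need at least one null spectrum")
    for p in null_psds:
        if p.freqs.shape != true_psd.freqs.shape or not np.allclose(
            p.freqs, true_psd.freqs
        ):
            raise ValueError("null spectra must share the true spectrum's grid")
    null_mean = np.mean([p.power for p in null_psds], axis=0)
    return AdjustedSpectrum(true_psd.freqs, true_psd.power, null_mean)


def tempo_from_beats(beat_times: np.ndarray) -> float:
    """Tempo in Hz as the inverse of the median inter-beat interval."""
    beats = np.asarray(beat_times, float)
    if beats.size < 3:
        raise ValueError("need at least 3 beat times")
    intervals = np.diff(beats)
    if np.any(intervals <= 0):
        raise ValueError("beat times must be strictly increasing")
    return float(1.0 / np.median(intervals))


def tempo_window(tempo: float, multiple: float, tol: float = 0.08):
    """Inclusive ±`tol` search window around ``multiple × tempo``, in Hz."""
    center = multiple * tempo
    return ((1 - tol) * center, (1 + tol) * center)


def find_tempo_peaks(
    adjusted_spectra: list[AdjustedSpectrum],
    tempo: float,
    multiples=(1, 2, 3, 4),
) -> TempoPeakSet:
    """Locate the maximum adjusted power near each tempo multiple.

    For every multiple the maximum adjusted value over *all* supplied
    spectra (e.g. the three best model bands) within the inclusive ±8%
    window is reported with its frequency.  Ties go to the lowest
    frequency; the order of the supplied spectra does not matter.
    """
    if tempo <= 0:
        raise ValueError("tempo must be positive")
    if not adjusted_spectra:
        raise ValueError("need at least one adjusted spectrum")
    windows, peak_freqs, peak_vals = [], [], []
    for m in multiples:
        lo, hi = tempo_window(tempo, m)
        best_val, best_freq = -np.inf, None
        for spec in adjusted_spectra:
            mask = (spec.freqs >= lo) & (spec.freqs <= hi)
            if not mask.any():
                continue
            adj = spec.adjusted[mask]
            freqs = spec.freqs[mask]
            i = int(np.argmax(adj))
            # lowest frequency wins a tie, within and across spectra
            if adj[i] > best_val or (adj[i] == best_val and freqs[i] < best_freq):
                best_val, best_freq = float(adj[i]), float(freqs[i])
        if best_freq is None:
            df = np.min(np.diff(adjusted_spectra[0].freqs))
            raise ValueError(
                f"no frequency bins inside [{lo:g}, {hi:g}] Hz; spectral "
                f"resolution {df:g} Hz is too coarse"
            )
        windows.append((lo, hi))
        peak_freqs.append(best_freq)
        peak_vals.append(best_val)
    return TempoPeakSet(
        tempo, tuple(multiples), tuple(windows), tuple(peak_freqs), tuple(peak_vals)
    )
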