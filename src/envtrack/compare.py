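"""Stimulus-general vs stimulus-specific model comparison.

A stimulus-general model is fit on trials pooled across all stimulus
classes; its forward model is then compared with each class-specific
forward model by finding the circular shift (shared across channels) and
per-channel non-negative scaling of the general model that best matches
the specific model, scored by R² summed over channels.  Significance of a
fit comes from a surrogate null: the specific model's per-channel delay
series have their Fourier phases randomized (amplitude spectra preserved)
and the shift/scale fit is repeated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BackwardModel, ForwardModel, ModelSpec, fit_backward_model
from .trials import Trial

__all__ = [
    "ShiftScaleFit",
    "fit_general_model",
    "shift_scale_fit",
    "phase_randomized_model_null",
    "phase_randomize",
]


@dataclass(frozen=True)
class ShiftScaleFit:
    """Best circular shift and per-channel scales of one model onto another."""

    shift: int
    scale: np.ndarray
    r_squared: float

    def __post_init__(self):
        if np.any(np.asarray(self.scale) < 0):
            raise ValueError("scales must be non-negative")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def fit_general_model(all_trials: list[Trial], spec: ModelSpec) -> BackwardModel:
    """Fit one backward model on trials pooled across stimulus classes."""
    return fit_backward_model(all_trials, spec)


def _center(weights: np.ndarray) -> np.ndarray:
    return weights - weights.mean(axis=1, keepdims=True)


def _as_weights(model) -> np.ndarray:
    return model.weights if isinstance(model, ForwardModel) else np.asarray(model, float)


def shift_scale_fit(general, specific) -> ShiftScaleFit:
    """Fit a shifted, positively scaled general model to a specific model.

    Both channel × delay weight matrices are centered per channel.  For
    every circular shift of the delay axis the closed-form per-channel
    regression slope is computed and clipped at zero (the scaling is
    positively constrained; anti-correlated channels get scale 0), and
    R² = 1 - ΣSSE/ΣSST is evaluated across all channels.  The shift with
    maximum R² wins; it is reported signed, in (-n/2, n/2].  R² may be
    negative — a fit worse than the per-channel mean is reported as-is.
    """
    G = _center(np.atleast_2d(_as_weights(general)))
    P = _center(np.atleast_2d(_as_weights(specific)))
    if G.shape != P.shape:
        raise ValueError("models must share channel and delay counts")
    n_ch, n_delays = P.shape
    sst = float(np.sum(P**2))
    if sst == 0:
        raise ValueError("specific model has zero variance")

    # cross/auto products for all shifts at once via FFT cross-correlation
    fg = np.fft.rfft(G, axis=1)
    fp = np.fft.rfft(P, axis=1)
    cross = np.fft.irfft(np.conj(fg) * fp, n=n_delays, axis=1)  # ch × shifts
    auto = np.sum(G**2, axis=1, keepdims=True)  # shift-invariant
    with np.errstate(invalid="ignore", divide="ignore"):
        scales = np.where(auto > 0, np.maximum(cross / auto, 0.0), 0.0)
    # SSE(shift) = SST - 2*scale*cross + scale^2*auto, summed over channels
    sse = sst - np.sum(2 * scales * cross - scales**2 * auto, axis=0)
    best = int(np.argmin(sse))
    r2 = 1.0 - float(sse[best]) / sst
    shift = best if best <= n_delays // 2 else best - n_delays
    return ShiftScaleFit(shift, scales[:, best].copy(), r2)


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases along the last axis, preserving magnitudes.

    Phases are drawn with conjugate symmetry so the surrogate is real; the
    DC bin (and Nyquist bin, for even lengths) keep their phases.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(spec * np.exp(1j * phases), n=n, axis=-1)


def phase_randomized_model_null(
    specific,
    general,
    n_iter: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Null R² distribution from phase-randomized specific models.

    Each iteration phase-randomizes every channel's delay series of the
    specific model independently (amplitude spectra preserved, so high R²
    driven purely by shared low-frequency power survives in the null) and
    reruns the shift/scale fit against the general model.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    P = np.atleast_2d(_as_weights(specific))
    out = np.empty(n_iter)
    for i in range(n_iter):
        surrogate = phase_randomize(P, rng)
        out[i] = shift_scale_fit(general, surrogate).r_squared
    return out
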