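"""Cubic B-spline lag basis and lag-matrix plumbing.

The backward model regresses the stimulus envelope on time-lagged EEG
components.  Rather than fitting one weight per lag, the lag axis is
projected onto a basis of cubic B-splines with evenly spaced knots; the
knot sampling rate sets the low-pass cutoff of the lag weights (about
knot_rate/2), and the subtraction of a moving average the high-pass
cutoff (about 1/window).  Together the two stages act as a band-pass
filter on the reconstruction, which is what lets a single model
architecture sweep across frequency bands.

The collocation matrix ``S`` holds the basis splines evaluated at every
EEG sample delay: delays along rows, splines along columns.  With knots
at ``knot_rate`` spanning a window of ``window_s`` seconds and end knots
repeated to cubic order, the basis has ``window_s * knot_rate + 3``
splines (e.g. 19 splines for a 500 ms window with 32 Hz knots).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SplineBasis",
    "LagMatrix",
    "build_spline_basis",
    "build_lag_matrix",
    "spline_project",
    "weights_to_delays",
    "characterize_filter",
]

_COND_LIMIT = 1e10


@dataclass(frozen=True)
class SplineBasis:
    """Collocation matrix of cubic basis splines over model delays."""

    window_s: float
    knot_rate: float
    eeg_rate: float
    S: np.ndarray = field(repr=False)
    knots: np.ndarray = field(repr=False)

    @property
    def n_splines(self) -> int:
        return self.S.shape[1]

    @property
    def n_delays(self) -> int:
        return self.S.shape[0]

    @property
    def delays_s(self) -> np.ndarray:
        """Delay of each row, in seconds from the start of the window."""
        return np.arange(self.n_delays) / self.eeg_rate


@dataclass(frozen=True)
class LagMatrix:
    """Time × feature design matrix, component-major / delay-minor layout."""

    X: np.ndarray
    n_components: int
    n_features_per_component: int

    def __post_init__(self):
        if self.X.shape[1] != self.n_components * self.n_features_per_component:
            raise ValueError("feature count does not match the declared layout")

    def blocks(self):
        """Iterate over per-component feature blocks (views)."""
        f = self.n_features_per_component
        for c in range(self.n_components):
            yield self.X[:, c * f : (c + 1) * f]


def build_spline_basis(
    window_s: float, knot_rate: float, eeg_rate: float
) -> SplineBasis:
    """Build the cubic B-spline collocation matrix for a delay window.

    Interior knots are evenly spaced at ``1/knot_rate`` spanning exactly
    ``[0, window_s]``; boundary knots are repeated to order 4 (cubic).  The
    basis is evaluated at every EEG sample delay in ``[0, window_s)``, i.e.
    ``round(window_s * eeg_rate)`` rows.  Rows sum to one (partition of
    unity) and all entries are non-negative.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 < knot_rate <= eeg_rate:
        raise ValueError("need 0 < knot_rate <= eeg_rate")
    n_intervals_f = window_s * knot_rate
    n_intervals = int(round(n_intervals_f))
    if n_intervals < 1 or abs(n_intervals_f - n_intervals) > 1e-9:
        nearest = max(1, n_intervals) / window_s
        raise ValueError(
            f"window_s * knot_rate = {n_intervals_f:g} is not a positive "
            f"integer; nearest valid knot_rate is {nearest:g} Hz"
        )
    breaks = np.linspace(0.0, window_s, n_intervals + 1)
    knots = np.concatenate([[breaks[0]] * 3, breaks, [breaks[-1]] * 3])
    n_delays = int(round(window_s * eeg_rate))
    delays = np.arange(n_delays) / eeg_rate
    S = BSpline.design_matrix(delays, knots, k=3).toarray()
    return SplineBasis(window_s, knot_rate, eeg_rate, S, knots)


def build_lag_matrix(signals: np.ndarray, delays: np.ndarray) -> LagMatrix:
    """Stack delayed copies of each component into a design matrix.

    ``signals`` is components × time; ``delays`` is an integer array of
    sample delays.  Column ``d`` of a component block holds the signal
    delayed by ``delays[d]`` samples, zero-padded at the edges (trial
    boundaries carry no wraparound information; boundary rows are trimmed
    before fitting anyway).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    delays = np.asarray(delays)
    if delays.size == 0:
        raise ValueError("delay list must not be empty")
    if not np.issubdtype(delays.dtype, np.integer):
        raise ValueError("delays must be integer sample counts")
    n_comp, n_time = signals.shape
    if np.any(np.abs(delays) >= n_time):
        raise ValueError("delays exceed the signal duration")
    X = np.zeros((n_time, n_comp * delays.size))
    for c in range(n_comp):
        for j, d in enumerate(delays):
            col = c * delays.size + j
            if d >= 0:
                X[d:, col] = signals[c, : n_time - d]
            else:
                X[:d, col] = signals[c, -d:]
    return LagMatrix(X, n_comp, delays.size)


def _spline_gram_solver(S: np.ndarray):
    """Return a function solving (SᵀS) x = b, with a conditioning check.

    The Gram matrix is SPD for any proper basis; a Cholesky solve with a
    conditioning gate is used.  When the basis is overcomplete (knot rate at
    the EEG rate gives more splines than delays) SᵀS is structurally
    rank-deficient and the minimum-norm pseudoinverse solution is used —
    least-squares predictions are unchanged by the choice of solution.
    """
    G = S.T @ S
    if np.linalg.matrix_rank(S) < S.shape[1]:
        Gp = np.linalg.pinv(G)
        return lambda b: Gp @ b
    cond = np.linalg.cond(G)
    if cond > _COND_LIMIT:
        raise ValueError(
            f"spline Gram matrix is ill-conditioned (cond={cond:.3g}); "
            "the basis is degenerate"
        )
    c, low = cho_factor(G)
    return lambda b: cho_solve((c, low), b)


def spline_project(Xd: LagMatrix, basis: SplineBasis) -> LagMatrix:
    """Project lag features onto the spline basis: Xs = Xd S (SᵀS)⁻¹.

    Per component block this is the least-squares fit of the lag profile of
    each time sample by a spline curve; ``Xs @ S.T`` is the smoothed lag
    matrix and the residual ``Xd - Xs Sᵀ`` is orthogonal to the basis.
    """
    if Xd.n_features_per_component != basis.n_delays:
        raise ValueError(
            "lag count per component does not match the basis delay count"
        )
    solve = _spline_gram_solver(basis.S)
    blocks = [solve((block @ basis.S).T).T for block in Xd.blocks()]
    return LagMatrix(np.hstack(blocks), Xd.n_components, basis.n_splines)


def weights_to_delays(w_s: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Convert spline-space weights to delay-space weights, w_d = S w_s."""
    w_s = np.atleast_2d(np.asarray(w_s, dtype=float))
    if w_s.shape[1] != basis.n_splines:
        raise ValueError("spline dimension does not match the basis")
    return w_s @ basis.S.T


def characterize_filter(
    spec,
    noise_len_s: float = 256.0,
    seed: int | None = 0,
    psd_window_s: float | None = None,
) -> "tuple[np.ndarray, np.ndarray]":
    """Measure the band-pass response of the moving-average + spline chain.

    White noise is pushed through the preprocessing used for model fitting:
    the centered moving average over the model window is removed, delays
    spanning ``[-window/2, +window/2]`` are stacked (a centered grid avoids
    edge-spline artifacts that would misrepresent the low-pass behavior),
    the lag matrix is projected onto the spline basis, and the processed
    noise is least-squares refit to the detrended input.  Returns
    ``(freqs, gain_db)`` where gain is the ratio of output to input
    amplitude spectra in dB.

    For a 500 ms window with 32 Hz knots the passband is roughly 2–16 Hz:
    the nominal edges are 1/window and knot_rate/2.
    """
    from .models import remove_moving_average

    if noise_len_s < 8 * spec.window_s:
        raise ValueError("noise_len_s must be much longer than the window")
    rng = np.random.default_rng(seed)
    n = int(round(noise_len_s * spec.eeg_rate))
    noise = rng.standard_normal(n)
    detrended = remove_moving_average(noise, spec.window_s, spec.eeg_rate)

    basis = build_spline_basis(spec.window_s, spec.knot_rate, spec.eeg_rate)
    half = basis.n_delays // 2
    delays = np.arange(basis.n_delays) - half
    Xd = build_lag_matrix(detrended[None, :], delays)
    Xs = spline_project(Xd, basis)

    margin = basis.n_delays  # drop zero-padded edges
    rows = slice(margin, n - margin)
    A, y = Xs.X[rows], detrended[rows]
    w, *_ = np.linalg.lstsq(A, y, rcond=None)
    recon = A @ w

    from scipy import signal as _sig

    if psd_window_s is None:
        psd_window_s = min(32.0, noise_len_s / 8)
    nper = int(round(psd_window_s * spec.eeg_rate))
    freqs, p_in = _sig.welch(noise[rows], fs=spec.eeg_rate, window="hamming",
                             nperseg=nper, noverlap=nper // 2, detrend=False)
    _, p_out = _sig.welch(recon, fs=spec.eeg_rate, window="hamming",
                          nperseg=nper, noverlap=nper // 2, detrend=False)
    with np.errstate(divide="ignore"):
        gain_db = 10.0 * np.log10(p_out / p_in)
    return freqs, gain_db
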