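"""Backward (reconstruction) models and their forward-model transform.

The backward model reconstructs the stimulus dB envelope s(t) from
time-lagged EEG.  Per training trial: the centered moving average over the
model window is subtracted from both envelope and EEG (the high-pass
stage), the EEG is projected onto spatial principal components which are
z-scored per trial, each component is lagged from 0 up to the maximum
delay, the lag matrix is projected onto the cubic-spline basis (the
low-pass stage), edge-artifact margins are trimmed, and the design matrix
and envelope are z-scored per trial and concatenated.  Ordinary least
squares then gives the spline-space weights

    w_s = (Xsᵀ Xs)⁻¹ Xsᵀ s(t).

Because the backward weights compensate for autocorrelations they are not
directly interpretable as a neural response; the forward transform

    a_s = (1/N) (Xsᵀ Xs) w_s

(with N training samples) recovers channel × delay weights that read as an
envelope-evoked response after mapping splines to delays and components
back to channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import (
    LagMatrix,
    SplineBasis,
    build_lag_matrix,
    build_spline_basis,
    spline_project,
)
from .trials import Trial

__all__ = [
    "ModelSpec",
    "SpatialPCA",
    "BackwardModel",
    "ForwardModel",
    "ReconResult",
    "remove_moving_average",
    "fit_spatial_pca",
    "fit_backward_model",
    "reconstruct",
    "leave_one_out",
    "ridge_baseline",
    "grid_search",
    "backward_to_forward",
    "pearson_r",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one frequency-constrained reconstruction model.

    The nominal passband is ``[1/window_s, knot_rate/2]``: the moving-average
    removal sets the lower edge, the spline knot rate the upper edge.  Trim
    margins default to the values used with ~3-minute recordings; synthetic
    fixtures use proportionally smaller margins.
    """

    window_s: float
    knot_rate: float
    n_components: int
    eeg_rate: float
    trim_lead_s: float = 15.5
    trim_trail_s: float = 16.0

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.knot_rate > self.eeg_rate:
            raise ValueError("knot_rate cannot exceed eeg_rate")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    @property
    def band(self) -> tuple[float, float]:
        """Nominal (low, high) passband edges in Hz."""
        return (1.0 / self.window_s, self.knot_rate / 2.0)

    @property
    def n_delays(self) -> int:
        return int(round(self.window_s * self.eeg_rate))

    def with_trim(self, lead_s: float, trail_s: float) -> "ModelSpec":
        return replace(self, trim_lead_s=lead_s, trim_trail_s=trail_s)


@dataclass(frozen=True)
class SpatialPCA:
    """Spatial principal components of pooled training EEG.

    ``loadings`` (channels × retained components) has orthonormal columns;
    ``component_variance`` holds the variances of *all* components in
    descending order — the full spectrum is needed to normalize forward
    models across frequency bands.
    """

    channel_mean: np.ndarray
    loadings: np.ndarray
    component_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, eeg: np.ndarray) -> np.ndarray:
        """Project channels × time EEG onto the retained components."""
        centered = eeg - self.channel_mean[:, None]
        return self.loadings.T @ centered


@dataclass(frozen=True)
class BackwardModel:
    """Spline-space reconstruction weights with training metadata."""

    w_s: np.ndarray  # components × splines
    spec: ModelSpec
    pca: SpatialPCA
    basis: SplineBasis = field(repr=False)
    n_train_samples: int = 0
    design_gram: np.ndarray = field(repr=False, default=None)  # XsᵀXs
    trial_norms: tuple = ()

    @property
    def n_features(self) -> int:
        return self.w_s.size


@dataclass(frozen=True)
class ForwardModel:
    """Channel × delay weights interpretable as an evoked response."""

    weights: np.ndarray
    spec: ModelSpec

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_delays(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class ReconResult:
    trial_id: int
    reconstruction: np.ndarray
    r: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of [-1, 1]")


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; zero-variance inputs are an error, not NaN."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("Pearson r undefined for a zero-variance input")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def remove_moving_average(
    signal: np.ndarray, window_s: float, rate: float
) -> np.ndarray:
    """Subtract a centered moving mean; edge windows are truncated.

    Acts along the last axis of a 1-D or channels × time array.  The window
    equals the model's maximum lag, which removes envelope/EEG content below
    the model's nominal low edge before fitting.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    w = int(round(window_s * rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if w > n:
        raise ValueError("moving-average window longer than the signal")
    h_lo, h_hi = (w - 1) // 2, w // 2
    csum = np.cumsum(x, axis=-1)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - h_lo, 0)
    hi = np.minimum(idx + h_hi + 1, n)
    sums = csum[..., hi] - csum[..., lo]
    return x - sums / (hi - lo)


def fit_spatial_pca(trials: list[np.ndarray], n_components: int) -> SpatialPCA:
    """PCA of channel-mean-centered EEG pooled across training trials."""
    arrays = [np.atleast_2d(np.asarray(t, float)) for t in trials]
    n_channels = arrays[0].shape[0]
    if any(a.shape[0] != n_channels for a in arrays):
        raise ValueError("trials have inconsistent channel counts")
    if n_components > n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    pooled = np.concatenate(arrays, axis=1)
    if pooled.shape[1] <= n_channels:
        raise ValueError("fewer pooled samples than channels")
    mean = pooled.mean(axis=1)
    centered = pooled - mean[:, None]
    # SVD of time × channels; right singular vectors are the loadings
    _, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    variance = s**2 / (pooled.shape[1] - 1)
    return SpatialPCA(mean, vt[:n_components].T.copy(), variance)


def _zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _trial_design(
    trial: Trial, spec: ModelSpec, pca: SpatialPCA, basis: SplineBasis
):
    """Preprocess one trial into (trimmed z-scored design, target, norms)."""
    env = remove_moving_average(trial.envelope, spec.window_s, trial.rate)
    eeg = remove_moving_average(trial.eeg, spec.window_s, trial.rate)
    comps = _zscore(pca.transform(eeg))
    # EEG lags the stimulus: the decoder for s(t) uses EEG(t+d), d in
    # [0, window), which is a negative shift in lag-matrix convention
    delays = -np.arange(spec.n_delays)
    Xd = build_lag_matrix(comps, delays)

    lead = int(round(spec.trim_lead_s * trial.rate))
    trail = int(round(spec.trim_trail_s * trial.rate))
    keep = trial.n_samples - lead - trail
    if keep < trial.n_samples * 0.5 or keep <= 1:
        raise ValueError(
            f"trim margins ({spec.trim_lead_s}+{spec.trim_trail_s} s) leave "
            f"under half of a {trial.duration:.1f} s trial"
        )
    rows = slice(lead, trial.n_samples - trail)
    y = env[rows]
    if y.std() == 0:
        raise ValueError("envelope is constant after preprocessing")
    # per-trial design normalization at the lag stage, before the spline
    # projection: a shared (trial-independent) right factor is what makes
    # the full-resolution spline model exactly equal raw lagged regression
    Xl = Xd.X[rows]
    x_mu, x_sd = Xl.mean(axis=0), Xl.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Xz = LagMatrix((Xl - x_mu) / x_sd, Xd.n_components, Xd.n_features_per_component)
    X = spline_project(Xz, basis).X
    y_mu, y_sd = y.mean(), y.std()
    return X, (y - y_mu) / y_sd, (x_mu, x_sd, y_mu, y_sd)


def fit_backward_model(train_trials: list[Trial], spec: ModelSpec) -> BackwardModel:
    """Fit spline-space reconstruction weights by ordinary least squares."""
    if not train_trials:
        raise ValueError("need at least one training trial")
    basis = build_spline_basis(spec.window_s, spec.knot_rate, spec.eeg_rate)
    pca = fit_spatial_pca([t.eeg for t in train_trials], spec.n_components)
    designs, targets, norms = [], [], []
    for trial in train_trials:
        X, y, c = _trial_design(trial, spec, pca, basis)
        designs.append(X)
        targets.append(y)
        norms.append(c)
    X = np.concatenate(designs)
    y = np.concatenate(targets)
    n, n_feat = X.shape
    if n <= n_feat:
        raise ValueError(
            f"{n} training samples for {n_feat} features; add trials or "
            "reduce components/splines"
        )
    w, *_ = linalg.lstsq(X, y, cond=1e-10, lapack_driver="gelsd")
    return BackwardModel(
        w_s=w.reshape(spec.n_components, basis.n_splines),
        spec=spec,
        pca=pca,
        basis=basis,
        n_train_samples=n,
        design_gram=X.T @ X,
        trial_norms=tuple(norms),
    )


def reconstruct(model: BackwardModel, trial: Trial, trial_id: int = 0) -> ReconResult:
    """Reconstruct a held-out trial's envelope and score it with Pearson r.

    The test EEG is projected with the *training* PCA; preprocessing,
    trimming and per-trial normalization mirror the training pipeline, and
    r is computed on the trimmed region only.
    """
    if trial.n_channels != model.pca.channel_mean.size:
        raise ValueError("test trial channel count does not match the model")
    X, y, _ = _trial_design(trial, model.spec, model.pca, model.basis)
    recon = X @ model.w_s.ravel()
    if recon.std() == 0:
        raise ValueError("reconstruction has zero variance (degenerate model)")
    return ReconResult(trial_id, recon, pearson_r(recon, y))


def leave_one_out(trials: list[Trial], spec: ModelSpec) -> list[ReconResult]:
    """Leave-one-trial-out evaluation; PCA and norms refit per fold."""
    if len(trials) < 3:
        raise ValueError("leave-one-out needs at least 3 trials")
    results = []
    for i, test in enumerate(trials):
        train = trials[:i] + trials[i + 1 :]
        try:
            model = fit_backward_model(train, spec)
            results.append(reconstruct(model, test, trial_id=i))
        except ValueError as e:
            raise ValueError(f"fold {i}: {e}") from e
    return results


DEFAULT_LAMBDAS = (0.0,) + tuple(10.0 ** np.arange(0, 9))


def _ridge_trial_design(trial: Trial, window_s: float):
    """Raw lag design for the ridge baseline: channels, no PCA, no splines."""
    n_delays = int(round(window_s * trial.rate))
    eeg = remove_moving_average(trial.eeg, window_s, trial.rate)
    env = remove_moving_average(trial.envelope, window_s, trial.rate)
    chans = _zscore(eeg)
    X = build_lag_matrix(chans, -np.arange(n_delays)).X
    rows = slice(n_delays, trial.n_samples - n_delays)
    y = env[rows]
    if y.std() == 0:
        raise ValueError("envelope is constant after preprocessing")
    return _zscore(X[rows], axis=0), _zscore(y)


def _ridge_solve(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    A = G + lam * np.eye(G.shape[0])
    if lam == 0:
        # collinear channels make the unregularized system singular
        rank = np.linalg.matrix_rank(G)
        if rank < G.shape[0]:
            warnings.warn(
                "singular lag covariance at lambda=0; using pseudo-inverse",
                stacklevel=3,
            )
            return np.linalg.pinv(G) @ b
    return linalg.solve(A, b, assume_a="pos")


def ridge_baseline(
    trials: list[Trial],
    window_s: float,
    lambdas=DEFAULT_LAMBDAS,
) -> list[ReconResult]:
    """Leave-one-out ridge regression on raw channel lags.

    This is the conventional regularized decoder the spline model is
    benchmarked against.  For each outer test trial the regularization
    parameter is chosen by mean held-out r over inner leave-one-out folds of
    the training trials, then the model is refit on all training trials at
    the chosen lambda.  At lambda = 0 the fit reduces to OLS; as lambda grows
    the weights shrink toward zero and reconstructions approach zero
    variance, at which point r is undefined and an error is raised.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("lambda grid must not be empty")
    if len(trials) < 3:
        raise ValueError("ridge baseline needs at least 3 trials")
    prepped = [_ridge_trial_design(t, window_s) for t in trials]
    grams = [(X.T @ X, X.T @ y) for X, y in prepped]

    results = []
    for i in range(len(trials)):
        train_idx = [j for j in range(len(trials)) if j != i]
        # inner CV over the training trials for lambda selection
        scores = np.zeros(len(lambdas))
        for j in train_idx:
            inner = [k for k in train_idx if k != j]
            G = sum(grams[k][0] for k in inner)
            b = sum(grams[k][1] for k in inner)
            Xj, yj = prepped[j]
            for li, lam in enumerate(lambdas):
                w = _ridge_solve(G, b, lam)
                pred = Xj @ w
                scores[li] += pearson_r(pred, yj) if pred.std() > 0 else 0.0
        best = lambdas[int(np.argmax(scores))]
        G = sum(grams[k][0] for k in train_idx)
        b = sum(grams[k][1] for k in train_idx)
        w = _ridge_solve(G, b, best)
        Xi, yi = prepped[i]
        pred = Xi @ w
        if pred.std() == 0:
            raise ValueError("ridge reconstruction has zero variance")
        results.append(ReconResult(i, pred, pearson_r(pred, yi)))
    return results


def grid_search(
    trials: list[Trial],
    windows: list[float],
    knot_rates: list[float],
    n_components_list: list[int],
    eeg_rate: float | None = None,
    trim: tuple[float, float] | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Mean leave-one-out r over a (window, knot_rate, components) grid.

    Returns the best spec and the full score table.  Ties are broken toward
    the simplest model: fewer components first, then fewer splines.
    """
    if not (windows and knot_rates and n_components_list):
        raise ValueError("grid must be non-empty in every dimension")
    if eeg_rate is None:
        eeg_rate = trials[0].rate
    rows = []
    for w in windows:
        for kr in knot_rates:
            for nc in n_components_list:
                spec = ModelSpec(w, kr, nc, eeg_rate)
                if trim is not None:
                    spec = spec.with_trim(*trim)
                res = leave_one_out(trials, spec)
                rows.append(
                    {
                        "window_s": w,
                        "knot_rate": kr,
                        "n_components": nc,
                        "n_splines": int(round(w * kr)) + 3,
                        "mean_r": float(np.mean([r.r for r in res])),
                    }
                )
    table = pd.DataFrame(rows)
    ordered = table.sort_values(
        ["mean_r", "n_components", "n_splines"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    top = ordered.iloc[0]
    best = ModelSpec(top.window_s, top.knot_rate, int(top.n_components), eeg_rate)
    if trim is not None:
        best = best.with_trim(*trim)
    return best, table


def backward_to_forward(model: BackwardModel) -> ForwardModel:
    """Transform backward weights into an interpretable forward model.

    a_s = (1/N)(XsᵀXs) w_s maps decoding weights to encoding weights under
    the convention that the (z-scored) envelope has unit variance; splines
    are expanded to delays by w_d = S a_s per component, each component row
    is scaled by its share of the total EEG variance (which normalizes the
    frequency-dependent growth of low-frequency EEG power), and components
    are mapped back to channels through the PCA loadings.
    """
    if model.design_gram is None:
        raise ValueError("model carries no training covariance")
    spec, basis, pca = model.spec, model.basis, model.pca
    a_flat = model.design_gram @ model.w_s.ravel() / model.n_train_samples
    a_s = a_flat.reshape(spec.n_components, basis.n_splines)
    a_d = a_s @ basis.S.T  # components × delays
    var = pca.component_variance
    scale = var[: spec.n_components] / var.sum()
    weights = pca.loadings @ (a_d * scale[:, None])
    return ForwardModel(weights, spec)
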