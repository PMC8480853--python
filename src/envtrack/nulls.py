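"""Chance-level calibration for reconstruction accuracies.

Raw Pearson correlations are not comparable across frequency bands: as a
model admits lower frequencies, both the envelope and the EEG carry more
slow autocorrelated structure and chance correlations grow.  The remedy is
a circular-shift null — rotate every trial's envelope in time by one
shared random offset, refit, and score a randomly chosen held-out trial —
which preserves both signals' autocorrelations while destroying their
alignment.  True accuracies are then expressed in standard deviations of
this null ("z-scored" accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .models import (
    ModelSpec,
    fit_backward_model,
    pearson_r,
    reconstruct,
)
from .trials import Trial

__all__ = [
    "NullDistribution",
    "ZScoredAccuracy",
    "circular_shift_null",
    "zscore_accuracy",
    "within_trial_dprime",
]


@dataclass(frozen=True)
class NullDistribution:
    """Reconstruction accuracies under circularly shifted envelopes."""

    values: np.ndarray
    seed: int | None
    shifts: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.size < 2:
            raise ValueError("a null distribution needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("null values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_iterations(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class ZScoredAccuracy:
    trial_id: int
    r_true: float
    z: float

    def __post_init__(self):
        if not np.isfinite(self.z):
            raise ValueError("z must be finite")


def _shifted(trial: Trial, shift: int) -> Trial:
    return Trial(
        eeg=trial.eeg,
        envelope=np.roll(trial.envelope, shift),
        rate=trial.rate,
        label=trial.label,
        channel_names=trial.channel_names,
        beat_times=trial.beat_times,
    )


def circular_shift_null(
    trials: list[Trial],
    spec: ModelSpec,
    n_iter: int = 50,
    seed: int | None = None,
) -> NullDistribution:
    """Null distribution of reconstruction accuracies.

    Per iteration: one circular shift is drawn uniformly from
    ``[window, L - window]`` samples (the exclusion margin keeps shifted
    envelopes from nearly realigning with the truth), the same shift is
    applied to every trial's envelope, one trial is chosen at random (with
    replacement across iterations) as the test trial, the model is fit on
    the rest and scored on it.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    L = min(t.n_samples for t in trials)
    margin = spec.n_delays
    if L - margin <= margin:
        raise ValueError("trials too short to draw a circular shift")
    values = np.empty(n_iter)
    shifts = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        shift = int(rng.integers(margin, L - margin + 1))
        test_idx = int(rng.integers(len(trials)))
        shifts[i] = shift
        shifted = [_shifted(t, shift) for t in trials]
        test = shifted.pop(test_idx)
        model = fit_backward_model(shifted, spec)
        values[i] = reconstruct(model, test, trial_id=test_idx).r
    return NullDistribution(values, seed, shifts)


def zscore_accuracy(
    r_true: float, null: NullDistribution, trial_id: int = 0
) -> ZScoredAccuracy:
    """Express a true accuracy in standard deviations of its null."""
    sd = null.sd
    if sd < 1e-12:  # identical values up to float rounding
        raise ValueError("null distribution has zero spread")
    return ZScoredAccuracy(trial_id, float(r_true), (r_true - null.mean) / sd)


def _fold_fit_score(X, y, train_rows, test_rows):
    w, *_ = linalg.lstsq(X[train_rows], y[train_rows], cond=1e-10, lapack_driver="gelsd")
    pred = X[test_rows] @ w
    if pred.std() == 0 or y[test_rows].std() == 0:
        return None
    return pearson_r(pred, y[test_rows])


def within_trial_dprime(
    trial: Trial,
    spec: ModelSpec,
    n_folds: int = 10,
    n_repeats: int = 5,
    n_null: int = 50,
    seed: int | None = None,
) -> float:
    """Within-trial reconstruction accuracy as a d-prime.

    The trial's design matrix is built once (lags formed before any
    sampling, so the lag structure stays intact), its rows are randomly
    partitioned into ``n_folds`` folds, and each fold in turn is held out
    from an OLS fit on the rest; the partition is redrawn ``n_repeats``
    times, giving ``n_folds * n_repeats`` true accuracies.  The null draws
    ``n_null`` accuracies after circularly shifting the envelope and holding
    out a random 1/n_folds sample.  Both distributions inflate as lower
    frequencies enter the model (test rows correlate with training rows), so
    the separation is reported as

        d' = (mu_true - mu_null) / sqrt((var_true + var_null) / 2),

    positive when true accuracies exceed the null.
    """
    from .models import _trial_design, fit_spatial_pca
    from .basis import build_spline_basis

    rng = np.random.default_rng(seed)
    basis = build_spline_basis(spec.window_s, spec.knot_rate, spec.eeg_rate)
    pca = fit_spatial_pca([trial.eeg], spec.n_components)
    X, y, _ = _trial_design(trial, spec, pca, basis)
    n = X.shape[0]
    fold_size = n // n_folds
    if fold_size * (n_folds - 1) <= X.shape[1]:
        raise ValueError("trial too short: training folds smaller than the feature count")

    true_vals = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        for f in range(n_folds):
            test_rows = perm[f * fold_size : (f + 1) * fold_size]
            train_rows = np.setdiff1d(perm, test_rows, assume_unique=True)
            r = _fold_fit_score(X, y, train_rows, test_rows)
            if r is None:
                warnings.warn(f"degenerate fold {f} skipped", stacklevel=2)
                continue
            true_vals.append(r)
    if not true_vals:
        raise ValueError("all folds degenerate")

    margin = spec.n_delays
    L = trial.n_samples
    null_vals = []
    for _ in range(n_null):
        shift = int(rng.integers(margin, L - margin + 1))
        Xn, yn, _ = _trial_design(_shifted(trial, shift), spec, pca, basis)
        perm = rng.permutation(n)
        test_rows = perm[:fold_size]
        train_rows = perm[fold_size:]
        r = _fold_fit_score(Xn, yn, train_rows, test_rows)
        if r is not None:
            null_vals.append(r)
    if len(null_vals) < 2:
        raise ValueError("null sampling degenerate")

    t, u = np.asarray(true_vals), np.asarray(null_vals)
    pooled = np.sqrt((t.var(ddof=1) + u.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((t.mean() - u.mean()) / pooled)
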