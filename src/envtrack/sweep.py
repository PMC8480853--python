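"""Band sweep: reconstruction accuracy across frequency ranges.

The model's passband is moved by changing the window size while holding
the spline count fixed (19 splines by default, i.e. the knot rate scales
as 16/window), which keeps a constant three-octave bandwidth.  Per
window, every trial is scored by leave-one-out reconstruction, a
circular-shift null is computed, and accuracies are z-scored against it;
forward models are extracted per fold for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelSpec, backward_to_forward, fit_backward_model, leave_one_out
from .nulls import circular_shift_null, zscore_accuracy
from .trials import Trial

__all__ = ["SweepConfig", "run_band_sweep"]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one cross-frequency sweep."""

    windows_s: tuple = (0.03125, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    n_splines: int = 19
    n_components: int = 64
    n_null: int = 50
    seed: int = 0
    trim: tuple | None = None

    def knot_rate(self, window_s: float) -> float:
        return (self.n_splines - 3) / window_s

    def spec(self, window_s: float, eeg_rate: float) -> ModelSpec:
        spec = ModelSpec(window_s, self.knot_rate(window_s), self.n_components, eeg_rate)
        if self.trim is not None:
            spec = spec.with_trim(*self.trim)
        return spec


def run_band_sweep(trials: list[Trial], config: SweepConfig):
    """Run the sweep; returns (results table, forward models per window).

    The table has one row per (window, trial) with the raw r, the null mean
    and spread, and the z-scored accuracy; each window's nominal band edges
    travel with the rows.  Forward models come from a fit on all trials.
    """
    eeg_rate = trials[0].rate
    rows = []
    forward = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.windows_s))
    for w, seed in zip(config.windows_s, seeds):
        spec = config.spec(w, eeg_rate)
        results = leave_one_out(trials, spec)
        null = circular_shift_null(
            trials, spec, n_iter=config.n_null,
            seed=int(seed.generate_state(1)[0] % 2**31),
        )
        lo, hi = spec.band
        for res in results:
            z = zscore_accuracy(res.r, null, trial_id=res.trial_id)
            rows.append(
                {
                    "window_s": w,
                    "band_lo_hz": lo,
                    "band_hi_hz": hi,
                    "trial": res.trial_id,
                    "r": res.r,
                    "null_mean": null.mean,
                    "null_sd": null.sd,
                    "z": z.z,
                }
            )
        forward[w] = backward_to_forward(fit_backward_model(trials, spec))
    return pd.DataFrame(rows), forward
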