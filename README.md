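# envtrack

Frequency-constrained reconstruction of auditory stimulus envelopes from
multichannel EEG.

When people listen to speech or music, scalp EEG tracks the slow amplitude
contour (envelope) of the sound. A standard way to quantify this tracking is
a *backward* (decoding) model: a linear map from time-lagged EEG to the
stimulus envelope, scored by the Pearson correlation *r* between the
reconstructed and true envelope. Comparing tracking across stimuli with very
different envelope spectra (speech vs music) is confounded unless the model
is confined to a controlled frequency band. `envtrack` implements a model
family whose band limits are part of the architecture itself, so one
identical model can be swept across frequency bands:

- **High-pass stage** — the centered moving average over the model window
  `w` is subtracted from both envelope and EEG, removing content below
  `1/w` Hz.
- **Spatial PCA** — EEG channels are projected onto principal components to
  remove spatial collinearity; components are z-scored per trial.
- **Cubic B-spline lag basis (low-pass stage)** — each component is lagged
  over `[0, w)` and the lag axis is projected onto cubic B-splines with
  evenly spaced knots at rate `f_k`:
  `X_s = X_d S (SᵀS)⁻¹`, where `S` is the collocation matrix (delays ×
  splines). The basis has `w · f_k + 3` splines and low-passes the lag
  weights at about `f_k / 2`.
- **OLS fit** — `w_s = (X_sᵀX_s)⁻¹ X_sᵀ s(t)` with the dB envelope `s(t)` as
  target, evaluated by leave-one-trial-out Pearson *r*.

The nominal passband is the three-octave range `[1/w, f_k/2]`. Around this
core the package provides: dB envelope extraction from audio through a
gammatone filterbank; chance-level calibration via circular-shift null
distributions and z-scored accuracies (plus a within-trial d′ variant);
inversion of backward weights into interpretable forward (evoked-response)
models via `a_s = (XᵀX/N) w_s`; comparison of pooled ("stimulus-general")
and class-specific models by circular shift and positively constrained
per-channel scaling with a phase-randomized R² null; rhythm analysis of
reconstructions against phase-randomized surrogate spectra, with peak
detection at 1–4× the musical tempo (±8% windows); a ridge-regression
baseline and hyperparameter grid search; a synthetic-data generator with
known ground-truth kernels; and a CLI for reproducible runs.

It is intended for auditory/cognitive neuroscientists working with
continuous-stimulus EEG (or MEG) and for methodologists studying decoding
models.

## Worked example

Synthetic EEG is generated as a known spatiotemporal kernel convolved with a
speech-like envelope plus 1/f noise, then decoded blind:

```python
import numpy as np
import envtrack as et

cfg = et.SynthConfig(n_channels=16, eeg_rate=64.0, duration_s=60.0,
                     snr=10.0, envelope_kind="sparse-speechlike", seed=1)
trials = et.synth_trialset(cfg, n_trials=5)

spec = et.ModelSpec(window_s=0.5, knot_rate=32.0, n_components=16,
                    eeg_rate=64.0).with_trim(2.0, 2.0)

results = et.leave_one_out(trials, spec)
null = et.circular_shift_null(trials, spec, n_iter=50, seed=2)
for r in results:
    z = et.zscore_accuracy(r.r, null, trial_id=r.trial_id)
    print(f"trial {r.trial_id}: r = {r.r:.3f}, z = {z.z:.1f}")

fwd = et.backward_to_forward(et.fit_backward_model(trials, spec))
kern = trials[0].extras["kernel"]
padded = np.zeros_like(fwd.weights)
padded[:, :kern.shape[1]] = kern
print(f"kernel recovery r = {et.pearson_r(fwd.weights.ravel(), padded.ravel()):.3f}")
```

Output:

```
trial 0: r = 0.825, z = 29.6
trial 1: r = 0.809, z = 29.0
trial 2: r = 0.808, z = 29.0
trial 3: r = 0.810, z = 29.1
trial 4: r = 0.826, z = 29.7
kernel recovery r = 0.953
```

Each `r` is the held-out correlation between the reconstructed and true
envelope inside the model's 2–16 Hz band; `z` expresses it in standard
deviations of the circular-shift null (here the null has mean 0.001 and
sd 0.028, so tracking is far above chance). The final line shows that the
forward model recovered from the decoder correlates 0.95 with the
ground-truth response kernel the EEG was generated from.

The same pipeline is available from the shell:

```
envtrack simulate --trials 5 --channels 16 --rate 64 --duration 60 \
    --snr 10 --seed 1 --out data.h5
envtrack null --data data.h5 --window 0.5 --knot-rate 32 --components 16 \
    --trim 2 2 --iters 50 --seed 2 --out null.json
```

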