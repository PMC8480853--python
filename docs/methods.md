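# Methods

## The model

`envtrack` reconstructs the dB envelope of an auditory stimulus from
time-lagged multichannel EEG with an ordinary-least-squares backward model
whose frequency content is constrained by the architecture rather than by a
separate filtering stage. The assumption throughout is the evoked-response
view of envelope tracking: the EEG contains the envelope convolved with a
spatiotemporal response kernel, plus autocorrelated background activity.

Per trial, fitting proceeds as:

1. Subtract the centered moving average (window equal to the model's
   maximum lag `w`) from both the envelope and every EEG channel. This
   removes content below roughly `1/w` Hz from both sides of the
   regression. Edge windows are truncated rather than padded; the affected
   samples fall inside the trim margins anyway.
2. Project the EEG onto spatial principal components fit on the pooled
   training trials (channel-mean-centered, SVD-based). Retaining `K`
   components removes spatial collinearity; each retained component is
   z-scored per trial.
3. Lag each component over `[0, w)` at the EEG rate. The decoder for
   `s(t)` uses EEG *after* t (the response follows the stimulus), so lag
   column `d` holds the component advanced by `d` samples, zero-padded at
   trial edges.
4. Z-score the lagged design per trial, then project each component's lag
   block onto the cubic B-spline collocation basis,
   `X_s = X_d S (SᵀS)⁻¹`. With knots evenly spaced at rate `f_k` over
   `[0, w]` and end knots repeated to cubic order the basis has
   `w·f_k + 3` splines and acts as a low-pass on the lag weights at about
   `f_k/2`.
5. Trim the first and last seconds of each trial (defaults 15.5 s lead /
   16 s trail, sized for ~3-minute recordings so that the largest-window
   model's moving-average edge artifacts and the pre-stimulus interval
   never enter any fit; short synthetic fixtures scale the margins down
   via `ModelSpec.with_trim`). Z-score the envelope over the retained
   samples, concatenate trials, and solve OLS.

The combined moving-average-removal + spline chain gives the model a
nominal three-octave passband `[1/w, f_k/2]`; `characterize_filter`
measures the realized transfer function by pushing white noise through the
pipeline (with a delay grid centered on zero, since an edge-anchored grid
over-weights the boundary spline and misstates the low-pass behavior).

**Normalization ordering.** The per-trial z-scoring of the design is
applied at the lag stage, immediately *before* the spline projection. A
per-trial diagonal scaling applied after the projection does not commute
with the (trial-shared) basis factor once trials are concatenated, and
would break the exact algebraic identity this package guarantees: with
`f_k` equal to the EEG rate and all components retained, the spline model's
held-out r equals plain lagged regression to machine precision (the basis
is then full row rank, so the projected design spans exactly the raw lag
space). Scaling before the projection preserves both the identity and the
intent of the normalization — putting trials on a common scale before
concatenation.

**Numerics.** `SᵀS` is solved by Cholesky with a conditioning gate at 1e10.
When the basis is overcomplete (knot rate at the EEG rate — more splines
than delays) the Gram matrix is structurally singular and the minimum-norm
pseudoinverse solution is used; least-squares predictions are invariant to
that choice. The OLS solve uses an SVD-based least-squares routine with a
relative singular-value cutoff of 1e-10: the overcomplete limit makes the
design rank-deficient, and looser cutoffs let numerically-zero directions
contaminate the fit. Pearson r on a zero-variance input raises an error
rather than returning NaN, so degenerate fits surface immediately.

## Chance calibration

Chance-level r grows as lower frequencies enter the model, because both
envelope and EEG carry more slow autocorrelated structure. The null
preserves exactly those autocorrelations: per iteration one circular shift
is drawn and applied to *every* trial's envelope, one trial (sampled with
replacement across iterations) is held out, the model is refit and scored.
Shifts are drawn uniformly from `[w, L − w]` samples — the exclusion margin
keeps a shifted envelope from nearly realigning with the truth. True
accuracies are reported as z-scores against this null (sample sd, n−1).
One RNG stream drives each procedure and the drawn shifts are stored with
the distribution, so runs are reproducible bit-for-bit from the seed.

Note that for strictly periodic stimuli a circular shift can realign the
envelope with itself at multiples of the period; z-scores for such stimuli
are conservative by construction.

The within-trial variant partitions the rows of the already-built design
matrix (lags are formed before sampling, keeping lag structure intact)
into 10 random folds, refit 5 times, and contrasts the 50 held-out-fold
accuracies against 50 circular-shift null accuracies with the pooled
d′ = (μ_true − μ_null)/√((σ²_true + σ²_null)/2) — positive when true
tracking exceeds chance. Because test rows correlate with training rows
within a trial, both distributions inflate together; d′ is the
scale-free separation.

## Forward models

Backward weights are not interpretable as neural responses (they whiten
away autocorrelations), so they are inverted:
`a_s = (1/N)(X_sᵀX_s) w_s` with `N` training samples, which scales the
encoding weights under the convention of a unit-variance envelope. Spline
weights expand to delays by `w_d = S a_s`; each component row is multiplied
by its share of the total EEG variance (this undoes the per-component
z-scoring and normalizes the frequency-dependent growth of low-frequency
EEG power, making forward models comparable across bands); components map
back to channels through the PCA loadings.

## Model comparison

A pooled ("stimulus-general") model is fit on trials of all classes with
the identical pipeline. Its forward model is compared with each
class-specific forward model by an exhaustive search over circular delay
shifts (shared across channels, wraparound within the model window); per
shift, each channel's non-negative scale is the closed-form regression
slope clipped at zero (channels anti-correlated with the general model get
scale 0), and R² = 1 − ΣSSE/ΣSST is summed over channels after per-channel
mean-centering. Per-channel regressions carry no intercept (the models are
pre-centered), R² may be negative and is reported as-is, and the whole fit
is invariant to a global positive rescaling of the general model. The R²
null phase-randomizes each channel of the specific model (conjugate-
symmetric phase draws; DC and Nyquist fixed, so surrogates are real and
amplitude spectra are preserved to rounding) and refits.

## Rhythm spectra

Reconstructions of one stimulus are averaged across subjects and their
Welch PSD (10 s Hamming window, half-overlap; 16 s for stimulus envelopes)
is compared against surrogate spectra obtained by phase-randomizing each
subject's reconstruction *before* averaging — coherent structure is
destroyed, per-subject power is preserved, so a peak coherent across n
subjects drops by about a factor n. The adjusted spectrum is the true PSD
minus the mean of (by default 100) surrogate PSDs. The tempo is the
inverse of the median inter-beat interval (beat times are an input; no
beat tracker is included). Peaks are the maximum adjusted value within an
inclusive ±8% window around 1–4× the tempo, taken across all supplied
model bands; frequency ties resolve to the lowest frequency for
determinism.

## Synthetic data

The generator emulates the generative assumption directly: each channel is
the centered dB envelope convolved with a known channel × delay kernel plus
1/f^α noise (spectrally shaped white noise, α = 1 by default) scaled so the
per-channel signal-to-noise variance ratio equals `snr` exactly. The
default kernel is a difference of gammas peaking near 100 ms with a trough
near 200 ms and a smooth front-to-back amplitude gradient across channels.
Three envelope families are provided: sparse speech-like shot noise
(Poisson bursts at ~4/s, amplitude-modulated at ~0.3 Hz to mimic
phrase-level fluctuations), periodic music-like pulse trains at a
configured tempo with off-beat accents (putting power at the tempo and its
harmonics), and flat Gaussian noise. All are smoothed, peak-normalized and
floored at −100 dB like real envelopes. Trial sets cycle through classes,
share one kernel across classes unless overridden, emit beat times for
periodic classes, and attach the ground-truth kernel for recovery tests.
Everything is deterministic in the seed; the kernel does not depend on it.

What the generator does *not* emulate: volume conduction with realistic
channel covariance, non-stationarity, eyeblink/movement artifacts,
stimulus-correlated noise, or nonlinear (e.g. adaptation) response
components. Passing recovery tests therefore demonstrates correctness of
the estimator under the linear-convolution model, not robustness to
everything real EEG contains.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| window `w` | 0.5 s | standard decoding window; sets low edge at 2 Hz |
| knot rate `f_k` | 32 Hz | 19 splines on 0.5 s; upper edge 16 Hz |
| components | 64 (128-ch EEG) | best grid-search cell against the ridge baseline |
| trim | 15.5 s / 16 s | skips pre-stimulus click interval + largest-window edge artifacts |
| ridge λ grid | 0, 10⁰…10⁸ | spans no-regularization to heavy shrinkage |
| null iterations | 50 | stable mean/sd for z-scoring |
| R² null iterations | 20 per trial | pooled across trials for testing |
| surrogate spectra | 100 | stable noise-floor estimate |
| band sweep | windows 31.25 ms–16 s, 19 splines | bands 32–256 Hz down to 0.0625–0.5 Hz |

Synthetic test conditions use 16 channels at 64 Hz (8 at 32 Hz for the
light fixtures), 24–60 s trials, SNR 1–10 and proportionally reduced trim
margins (2 s); these sizes keep ground truth recoverable while every
statistical property under test (calibration, recovery, equivalence)
remains at full strength.

## Design choices and limitations

- Gammatone filterbank: the auditory front-end uses order-4 gammatone IIR
  filters (geometric center-frequency spacing, endpoints inclusive,
  second-order sections for numerical stability) as a standard
  approximation to compressive gammachirp filters; chirp parameters are
  deliberately not exposed, and envelope tests only assume
  single-band-Hilbert-level accuracy.
- Resampling order: envelopes are converted to dB first and then
  polyphase-resampled, with line-fit padding (zero padding would bend dB
  traces toward 0 dB at the edges).
- Grid-search ties break toward fewer components, then fewer splines
  (parsimony).
- The null's left-out trial is sampled with replacement across iterations.
- Per-trial z-scoring makes reconstruction invariant to a *global* linear
  rescaling of the test EEG exactly; per-channel rescalings alter the PCA
  projection and are not an invariance of the method.
- Group-level inferential statistics (signed-rank/rank-sum tests,
  bootstrap CIs) are standard library calls left to the user; no EEG
  preprocessing (ICA, artifact rejection) is included beyond optional
  mastoid re-referencing at container load.
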