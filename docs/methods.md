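# Methods

This note records the models, defaults, and design choices behind
`neurotsne`, and what the synthetic benchmarks do and do not demonstrate.

## Preprocessing

Raw multichannel EEG is band-pass filtered 1–40 Hz with a zero-phase
Butterworth filter (order 4, applied forward–backward, so the effective
magnitude response is the squared order-4 response and the phase is
identically zero). The filter order is a package choice — standard EEG
practice and numerically stable at 250 Hz in second-order-sections form.
Amplitudes are then divided by the 99th percentile of the absolute
amplitude of the *training* data (linear interpolation between order
statistics), so values mostly lie in [-1, 1] and the test split is scaled
by frozen training statistics. EDF recordings are converted to average
reference over the 21 retained 10–20 channels (Fp1, F7, T3, T5, Fp2, F8,
T4, T6, F3, C3, P3, O1, F4, C4, P4, O2, Fz, Cz, Pz, A1, A2 — this is also
the channel order everywhere in the package) and resampled to 250 Hz by
polyphase filtering when the source rate differs. Windows are half-open
sample ranges `[start, start + duration*fs)`, 0-based; a trailing remainder
shorter than one window is dropped.

## Neighbor distributions

**Rank distribution (CNN path).** Per batch row, the n = 5 nearest latent
vectors (squared Euclidean distance, ties broken by ascending index for
determinism) share conditional mass 1 − ε with ε = 0.01 spread uniformly
over all non-neighbors. Strict positivity keeps the KL divergence finite;
the split of mass between "high" and "low" probabilities is a package
choice, as is the t-SNE-style symmetrization
p_ij = (p(j|i) + p(i|j)) / 2B (a row-conditional variant is available via
`RankSpec(symmetrize=False)`). P is treated as a constant within each
optimization step: ranking is piecewise constant in the latent coordinates,
so a gradient through it is zero almost everywhere and matching a per-batch
neighbor structure is well defined only with the target held fixed.

**Gaussian distribution (feature baselines).** Classic t-SNE conditionals
p(j|i) ∝ exp(−d²_ij/2σ_i²), with σ_i found by bisection on the precision so
that 2^entropy equals the target perplexity (default 5) within 1e-5 bits,
at most 100 iterations.

**Embedding distribution.** Student-t with one degree of freedom, jointly
normalized over ordered pairs. The KL loss floors q (and p inside the log)
at 1e-12; this is far below any meaningful probability at batch sizes up to
10^4 and only guards against degenerate coincident embeddings. The gradient
with respect to the embedding is the standard analytic t-SNE gradient
dC/dy_i = 4 Σ_j (p̄_ij − q_ij)(1 + ‖y_i − y_j‖²)^-1 (y_i − y_j), with p̄ the
symmetrized P so the expression stays exact for row-conditional targets; it
is verified against numerical differentiation of the loss.

## Encoder architectures

The networks, backpropagation, and the Adam optimizer are implemented
directly in numpy (convolutions lowered to BLAS matrix multiplies through
an im2col view); every layer's backward pass is validated against central
finite differences in the test suite, which makes the training loop
self-contained and exactly reproducible across runs.

**CNN encoder.** Part 1 processes channels separately with shared weights.
Reference configuration: a width-5 convolution (16 filters, ELU) produces
level 1 at full length 250; five pool–conv blocks (max-pool width 2 stride
2, then conv width 5, 16 filters, ELU) produce levels at 125, 62, 31, 15,
and 7 samples. Each level is reduced by conv(16, width 5) + ELU, a global
max-pool over time, and a linear dense layer to 10 features. With 21
channels × 6 levels × 10 features the latent z has 1260 dimensions. Part 2
is dense 1260 → 500 → 500 → 250 → 2 with ELU between layers. 'Same'
zero-padding keeps level lengths aligned with the pooling cascade. The
filter counts and part-2 widths are package choices within the stated
architectural constraints; translation stability of the level features
holds for transients of physiological width (tens of ms) but not for
single-sample impulses, whose survival through stride-2 pooling depends on
alignment.

**MLP baselines.** Four dense layers (default hidden widths 1000, 500, 250,
then 2), input 630 (STFT) or 2436 (CWT); the input features themselves are
the high-dimensional representation. L2 regularization applies to all
convolution and dense weights (not biases), default coefficient 1e-5.
Weights use uniform fan-in variance scaling from a seeded generator.

## Features

**STFT.** One frame per 1-s window — a 1-s frame has exactly 1 Hz bin
spacing, so "30 bands spanning ~1–30 Hz" is realized as the magnitude of
rfft bins 1…30 after a Hann taper (configurable to rectangular). Magnitudes
are kept linear (no log), making the representation amplitude-homogeneous.

**Ricker CWT.** 29 wavelet widths chosen so the Ricker peak-response
frequencies are log-spaced from 1 to 30 Hz (peak frequency
f = fs·√2 / 2πa for width a in samples). Convolution uses 'same' mode with
zero padding; wavelet support is 10a truncated near twice the window
length, and boundary coefficients are included in the statistics (mean,
standard deviation, minimum, maximum per scale), giving 21 × 29 × 4 = 2436
values in (channel, scale, statistic) order. Features are z-scored
column-wise with training-set statistics before baseline training — neural
optimization on raw magnitudes of mixed dynamic range is ill-conditioned,
and the scaler is frozen with the run so test data are transformed
identically.

## Training

Batch size 500, n = 5 neighbors per batch (CNN) or perplexity 5
(baselines), Adam with learning rate 1e-4 and framework-default β1 = 0.9,
β2 = 0.999 are the package defaults. The last batch of an epoch is dropped
when incomplete (the neighbor distributions are defined over full batches)
and the order is reshuffled per epoch with a seeded generator, so a config
and seed fully determine the loss sequence. Epochs default to 200 with
early stopping after a 20-epoch plateau (mean epoch loss improving by less
than 1e-4); the stopping rule is a package choice. Desk-scale runs in the
documentation and tests use a narrower encoder (8 trunk/head filters,
part-2 widths 64/32/16), batch 100, learning rate 1e-3, and about 10
epochs; at these sizes training takes a few minutes on one CPU and already
saturates the synthetic contrasts.

## Evaluation

SVMs (scikit-learn, C = 1, RBF bandwidth by the `gamma='scale'` heuristic,
no embedding standardization — the embedding is already O(1) scale) are
fitted on training embeddings and scored with Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) on train and test splits; κ is 0 when both
raters are constant. The SVM is a fixed measuring stick, not a tuned
classifier. Cluster counts scan k-means over k = 2…50 (k-means++, 10
restarts, seeded per run) and report the k with the best mean silhouette,
ties toward smaller k. Method comparisons build a methods ×
{correct, incorrect} contingency table, run an omnibus chi-square without
continuity correction, and — if significant at 0.05 — compare the
most-correct method pairwise against the others with Bonferroni-adjusted
p-values.

## Synthetic data

The generator produces 1-s, 21-channel windows at 250 Hz: 1/f-shaped
Gaussian background (power-spectral slope −1 by default) plus parametric
class signatures — posterior 8–12 Hz rhythm for wake vs. 1–3 Hz slow waves
with occasional central 12–14 Hz spindles for sleep; a single ~70 ms spike
followed by a ~300 ms slow wave on a random contiguous channel subset for
the discharge contrast; and 3–5 Hz rhythmic activity with linearly
drifting frequency and growing amplitude for the seizure contrast. The
default signature-to-background amplitude ratio is 2, with 3 subjects
carrying log-normal amplitude and Gaussian frequency jitter. These are
caricatures built for controllable class structure: they contain no
artifacts, no volume-conduction correlation structure between channels,
and no within-class morphology diversity approaching clinical data, so
passing benchmarks demonstrates that the pipeline recovers planted
structure at a given contrast — not clinical-grade performance. Per-window
generative parameters are returned alongside the windows for
parameter-recovery tests.

## Degenerate inputs and numerical conventions

Batches must exceed n_neighbors + 1 (the rank distribution is undefined
otherwise) and perplexity must be below the batch size. Distance ties break
by ascending index; silhouette ties break toward smaller k; constant
feature columns pass the scaler unchanged; an empty segmentation result
(recording shorter than one window) warns rather than raises. Non-finite
inputs, losses, or embeddings raise immediately with the offending step in
the message.

## Known limitations

The numpy implementation is CPU-bound and practical to a few thousand
windows per run; no momentum schedules, early exaggeration, or
Barnes-Hut-style accelerations are included. Multi-class (>2) kappa is
supported arithmetically but only binary contrasts are exercised. The EDF
writer is minimal (16-bit, 1-s records, integer sampling rates) and meant
for simulation export and round-trip testing, not archival use.
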