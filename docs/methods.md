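# Methods

`coughdnn` implements a hybrid DNN-HMM classifier for isolated cough /
noncough sound samples, together with the GMM-HMM baseline it is built on
and a synthetic corpus generator that makes the whole chain testable
without clinical recordings. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Model overview

A sample (a short mono waveform) is converted to a sequence of 39-D MFCC
frames. Four left-to-right HMMs — three cough models and one noncough
model — compete for the frame sequence in a free decoding loop; the sample
is called *cough* whenever any cough model appears in the best-path
transcription, and *noncough* otherwise (including the no-valid-path
case). Three cough models with different state counts absorb the length
and shape variability of cough epochs; the decision rule is deliberately
sensitive, mirroring a screening use case.

Two observation models drive the same decoder:

* **Baseline**: diagonal-covariance GMM emissions per state,
  p(x | s), trained by segmental (Viterbi) re-estimation.
* **Hybrid**: a feedforward DNN predicts state posteriors p(s | x) for
  each spliced frame; decoding uses the scaled log likelihood
  log p(s|x) − κ log p(s), κ = 1, with state priors p(s) taken from
  forced-alignment frame counts (floored at 1e-8 and renormalized).

The DNN's frame-level targets come from forced alignment under the
trained GMM-HMM baseline: each training clip is aligned against its
class's model(s) (cough clips against all three cough models, best score
wins) and every frame inherits a global HMM-state index.

## Feature front end

Per frame: pre-emphasis (α = 0.97), 25 ms Hamming window with 10 ms
shift (window and shift rounded half-up to samples at the native rate;
no resampling), power spectrum on the next power-of-two FFT, 40
triangular mel filters on the HTK scale mel(f) = 2595·log10(1 + f/700)
spanning 0–Nyquist, natural log with floor 1e-10, orthonormal DCT-II
keeping c0–c12, and sinusoidal liftering
c′(n) = (1 + (L/2)·sin(nπ/L))·c(n) with L = 22 (so the multiplier is 1
at n = 0 and peaks at 12 for n = 11). Regression deltas and
delta-deltas (window W = 2, edge replication) complete the 39-D vector.

Choices the configuration leaves open were fixed as: c0 rather than log
energy as the zeroth coefficient; no cepstral mean normalization inside
the front end (the network path standardizes explicitly); splice context
k = 5 frames per side (429-D network input). GMM emissions consume the
raw 39-D vectors; only the network sees spliced, standardized input.
Standardization statistics are fitted on training frames only, which also
justifies fixing the Gaussian-visible RBM σ = 1.

## GMM-HMM baseline

Topologies are strictly left-to-right (self-loop + advance), with
non-emitting entry/exit states; defaults are 4/6/8 emitting states for
the cough models and 3 for the noncough model (configurable). Training is
hard-assignment segmental k-means rather than Baum-Welch: align, then
re-estimate Gaussian statistics, mixture weights and transition counts.
The aligned total log likelihood is non-decreasing and iteration stops
early below a 1e-4 relative improvement. Mixtures are grown by splitting
the largest-weight component (mean ± 0.2 std, weight halved) followed by
retraining; component responsibilities are hard assignments as well.
Numerical guards: diagonal covariances floored at 1e-3 of the per-dimension
global variance; self-loop probabilities clamped to [1e-3, 1−1e-3];
states or components that capture no (or <2) frames keep their previous
parameters.

Initialization is the classic uniform-segmentation start: each clip's
frames are divided into n_states contiguous chunks and state *s* pools
chunk *s* across clips. Initializing all states of a model identically
(global mean/variance) is degenerate here: the first alignment is an
all-ties problem, the tie-break collapses the state boundary to the first
frame, and transition re-estimation then locks segmental training into
that optimum.

How the three cough models share the cough data was a genuinely open
design point. Assigning each cough clip to its best-scoring cough model
at every iteration (a clustering reading) is winner-take-all at desk
scale: one or two models starve down to a handful of aligned frames, and
a starved model is worse than useless downstream — its states get floored
priors, so in hybrid decoding the prior correction inflates whatever
residual posterior the network emits for them. The implementation
therefore follows the keyword-spotting lineage instead: all three cough
HMMs train on *all* cough samples, each from its own forced alignment,
and differ only in state count (4/6/8), i.e. in how finely they carve
the burst-decay time course. Best-model selection still applies where a
single answer is needed: DNN state targets and classification.

## RBMs, DBN pretraining and fine-tuning

Binary-binary and Gaussian-Bernoulli RBMs are trained with one-step
contrastive divergence: hidden means from the data, a sampled hidden
state, a mean-field visible reconstruction, hidden means again; update
lr·(positive − negative)/batch. Weights start at N(0, 0.01²), biases at
zero; no momentum or weight decay by default. σ is fixed at 1 (inputs are
standardized); learning σ is famously unstable and the energy
implementation retains general σ for completeness. For small binary
models (V + H ≤ 16) the exact partition function and log-likelihood
gradient are computed by enumeration; these oracles back the CD-1 tests.

The DBN stacks RBMs greedily: layer 1 Gaussian-visible on the feature
vectors, upper layers binary on the previous layer's hidden expectations.
When consecutive widths permit, a new layer is initialized by unrolling
(W_k = W_{k−1}ᵀ, and its visible biases from the hidden biases below)
before CD refinement; otherwise it starts random. Pretraining schedules
follow the original conditions — batch 256, lr 0.01, more epochs for the
Gaussian layer than the binary layers — scaled down in the desk
configuration (15/10 epochs instead of 200/100).

The DNN copies the DBN weights as sigmoid hidden layers, stacks a random
N(0, 0.01²) softmax layer with one unit per global HMM state, and is
fine-tuned by minibatch cross-entropy SGD at the fixed published rate
(lr 0.008, batch 256). One practical finding shaped the early-stopping
design: at this small fixed rate the held-out *frame accuracy* sits at
the majority-state fraction for tens of epochs while the cross-entropy
falls steadily, so stopping on accuracy patience quits before learning
starts. Early stopping therefore watches the held-out cross-entropy
(patience 20, 10% held-out frame split) with a 200-epoch default budget
(400 in the experiment pipeline), and returns the parameters of the
best-accuracy epoch.

## Decoding

The four models compose into a loop graph over global emitting states:
uniform model priors (1/4) on entry and on every re-entry after a model
exit; cross-model arcs fold exit probability, prior and entry together.
A complete path must end in a state with an exit arc. Decoding is exact
Viterbi — at ~21 states beam pruning would be pointless — with ties
broken toward the lower global state index; a 1-state model's re-entry
arc runs parallel to its own self-loop and only the better arc is kept.
The decoder is score-source-agnostic: the baseline feeds GMM log
densities, the hybrid feeds scaled DNN log likelihoods times an acoustic
scale (default 1.0); feeding GMM scores through the hybrid path
reproduces the baseline decode exactly, which is tested.

One guard applies to the hybrid path only: states with zero
forced-alignment occupancy are barred from decoding (−inf observation
score). The network has no targets for such states, so its posteriors
there are untrained residue, and dividing by a floored prior would turn
that residue into a large spurious score; a state never realized in the
training alignments cannot legitimately be hypothesized.

## Synthetic corpus

The generator emulates the statistical shape of isolated-sample cough
datasets, not any specific recording: 44.1 kHz mono, coughs the minority
class, noncoughs heterogeneous. A cough is a sharp-attack broadband
onset (10–40 ms) followed by 400–2000 Hz band-limited noise decaying
exponentially (time constant 50–150 ms), duration uniform in
[0.25, 0.65] s, with a weaker second burst with probability 0.3.
Each noncough draws one of three kinds uniformly from its own seeded
stream: voiced (harmonic series, f0 in [100, 250] Hz, 5–10 partials with
1/k amplitudes), transient (a single 20–60 ms decaying click, 1.5–6 kHz),
and stationary colored noise (0.5–3 s, spectral slope exponent in
[0, 1.5]). The kind is drawn rather than cycled deliberately: patient ids
are assigned round-robin, and any deterministic kind cycle whose period
divides the patient cycle aliases with it, skewing the kind mix of
individual patients and hence of patient-held-out test sets. Pink
background noise is mixed at a configurable SNR (default 20 dB). The
corpus is a pure function of its spec — WAV bytes and manifest are
identical on re-run.

What this does *not* model: room acoustics, babble, overlapping sounds,
speaker physiology, continuous 24-hour streams, or the acoustic
statistics of any real patient population. Passing tests demonstrate
that the algorithms are implemented correctly and that the training
machinery extracts the class structure the generator plants; they say
nothing quantitative about clinical performance.

## Experiment pipeline and problem sizes

`run_experiment` executes: corpus → MFCCs → patient-dependent
(per-patient 2/3–1/3, seeded) and patient-independent (held-out
patients) splits → 2:1 noncough subsampling of the training set → GMM
baseline (segmental training, mixture growth to M = 2 in the desk
configuration) → decode + evaluate baseline → forced alignment →
normalization statistics (training frames only) → per grid point DBN
pretraining, fine-tuning and hybrid decoding → five-criteria report.
No test clip contributes to normalization, GMM training, alignment,
pretraining, fine-tuning or prior estimation.

Desk-scale defaults: 100 cough / 200 noncough clips over 6 synthetic
patients, grid {1×256, 2×128} hidden layers×units, 400 fine-tune epochs.
The published-scale grid (1–4 layers × 512–2048 units) is expressible
through the same config. The smaller 64–128-unit nets originally
considered for the desk grid underfit the hardest synthetic contrast —
transient clicks vs cough onsets — at the 429-D spliced input (hybrid
specificity 0.5–0.88), while one 256-unit layer separates them cleanly;
hence the default grid. The pretraining-benefit study uses a deliberately
harder regime (40/80-clip corpus, 2×64 network, fixed 300-epoch budget,
no early stopping) where the generative initialization's advantage is
largest; both arms share data, architecture, schedule and seeds.

## Metric definitions

With cough as the positive class: sensitivity = TP/(TP+FN), specificity
= TN/(TN+FP), F1 = cough-class F1 (defined 0 when TP = 0), macro average
= (sensitivity + specificity)/2, micro average = overall accuracy
(TP+TN)/total. The macro/micro definitions are not spelled out in the
source tables; these are the ones consistent, at three printed decimals,
with both published baseline rows, which the worked example and the
acceptance script reproduce from class sizes and recalls alone. Reported
numbers are rounded half-up to 3 decimals.

## Known limitations

* Segmental k-means is coarser than Baum-Welch; it is sufficient for
  alignment targets but underestimates emission variances slightly.
* The three cough models are distinguished only by state count; nothing
  enforces that they specialize to distinct cough subtypes.
* Fixed-rate SGD without momentum follows the published conditions but
  converges slowly; the pipeline compensates with epochs, not with
  optimizer changes.
* The any-cough-segment decision rule maximizes sensitivity by design;
  precision on heavily imbalanced test sets is correspondingly modest.
* Exact decoding scales quadratically in global states per frame; fine
  for this inventory, not for large vocabularies.
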