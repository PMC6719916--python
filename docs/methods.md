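# Methods

`meowdag` classifies the emission context of single cat meows (waiting for
food / isolation in an unfamiliar environment / brushing) from short 8 kHz
mono clips. The pipeline is: statistical silence removal, frame-level
feature extraction (MFCC and temporal modulation), and a directed acyclic
graph of binary GMM-HMM classifiers whose execution order is learned from
validation performance. Four reference systems — class-specific HMMs, a
universal (background) HMM with class adaptation, an RBF-SVM on pooled clip
vectors, and an echo state network — run on identical cross-validation
folds. Because the original recordings are not publicly deposited, a
synthetic corpus generator reproduces their documented statistics so that
every stage is testable end to end.

## Signal front end

Audio is mono, in [-1, 1], at 8 kHz; the usable band is 0–4 kHz, matching
a Bluetooth HFP/HSP transport with 8-bit a-law companding. Framing is a
30 ms Hamming window advanced by 10 ms with a 512-point FFT. A framing stated
as a 30 ms window with 10 ms overlap is read as a 10 ms frame *shift*
(the openSMILE convention); the literal 20 ms-shift grid is available via
`FrameGrid.literal_overlap()`.

**Silence removal.** Per frame and frequency bin, a Gaussian
likelihood-ratio test compares a noise hypothesis against signal-plus-noise
with a fixed a-priori SNR (default 15 dB): the per-bin log ratio is
`gamma * xi/(1+xi) - log(1+xi)` with `gamma` the a-posteriori SNR. A frame
is active when the geometric mean of the per-bin ratios exceeds the
threshold (default 1.0), and activity is held for a 3-frame hangover. The
noise spectrum is the elementwise minimum of (a) the mean spectrum of the
first 0.2 s — the corpus clips carry 0.5 s leading noise — and (b) a
bias-corrected low quantile over the whole clip (periodogram bins are
approximately exponential, so the 20 % quantile estimates the mean after
division by −ln 0.8). A clip voiced edge-to-edge gives the estimator
nothing to work with; `detect_activity` accepts an external noise-PSD
reference for that case, and this identifiability limit is a known
limitation of any purely relative detector. Clips with an empty activity
mask are excluded from training with a log record, not treated as fatal.
By default all inactive frames are removed, internal pauses included
(`trim_mode: edges` restricts trimming to the clip boundaries).

**MFCC.** Power spectrum → 23 triangular mel filters spanning 0–4 kHz
(centers equally spaced on `mel(f) = 2595 log10(1 + f/700)`) → log (floored
at 1e-10) → orthonormal DCT-II. Coefficient 0 is dropped, coefficients
1–12 are kept and the log frame energy appended (13 dims); first, second
and third regression derivatives over a ±2-frame context (edge-replicated,
applied iteratively) bring the stream to 52 dims. Apart from the energy
column the stream is invariant to global gain.

**Temporal modulation.** The STFT magnitude is pooled into 8 equal-width
subbands whose envelopes are sampled at the 100 Hz frame rate. Per 0.25 s
window (0.1 s shift) the mean-removed envelope of each subband is Fourier
transformed (64 points) and the energies pooled into 6 log-spaced
modulation bands between 2 and 32 Hz, log-compressed: 48 dims per
modulation frame. A harmonic event drives all its partials with one
envelope, so its modulation patterns are redundant across subbands — the
motivating property, covered by a test. The reference toolbox's exact
settings are not recoverable; these defaults cover meow AM rates at
moderate dimensionality.

**Fusion and normalization.** The slower modulation stream is mapped onto
the MFCC grid by nearest-frame lookup and concatenated. Per-dimension
z-normalization statistics are always fit on the training side of a fold
and applied to both sides.

## GMM-HMM engine

Emissions are diagonal-covariance Gaussian mixtures; the variance floor is
1e-3 times the pooled per-dimension training variance. Topology is
left-to-right with self-loops and single-step forward transitions
(standard for short vocalizations); an ergodic mode exists. Zeros planted
in the initial distribution and transition matrix are invariant under EM,
so topology is enforced at initialization only.

Initialization is segmental: each sequence is split into S contiguous
segments and segment s's pooled frames seed state s's mixture by k-means
(≤ 50 iterations; at most 1000 frames per state are passed to k-means — an
initialization-only subsample). For the ergodic topology, where no
temporal ordering exists, states are initialized from a global k-means
partition of the pooled frames instead.

Baum–Welch runs at most 25 iterations and stops when the relative
improvement of the total log-likelihood falls below 0.001 (the stopping
convention of the Torch-era C++ trainers; an absolute mode is available).
The E-step is batched: sequences are padded to a common length and the
scaled forward recursion runs across the whole batch; the backward pass is
renormalized per step, which is scale-free for the (per-frame normalized)
state and transition posteriors and cannot overflow even for
near-deterministic left-right models. Scoring uses the Viterbi
log-likelihood (the forward score is kept for diagnostics and
cross-checks); both are verified against explicit enumeration of all state
paths on small instances.

**Model-space search.** For a binary task, each (S, g) in
{3,4,5,6} × {2,4,8,…,256} trains one HMM per class and is scored by
validation recognition rate. Configurations with fewer than 5·S·g training
frames in either class are skipped (the feasibility rule; if nothing is
feasible the smallest configuration is used with a warning). Rate ties —
routine when several configurations solve an easy task perfectly on a
modest validation set — break toward the larger mean per-frame
log-likelihood margin between the true and the competing model, then
toward smaller g and S. The margin tie-break replaces a pure
smaller-model-first rule, which systematically selected undertrained
models for easy tasks.

## DAG-HMM

The training fold is split 80/20 (stratified, seeded) into a training part
TS and validation part VS; every one of the Cm(Cm−1)/2 pair tasks runs the
model-space search on TS and is rated on VS; tasks are sorted by
descending rate (ties lexicographic). The graph is the rooted triangular
layout over an ordered class list: each node tests the two endpoint
classes of a contiguous sublist and eliminates the loser. This is the only
layout in which every pair appears exactly once — which is precisely what
yields the Cm(Cm−1)/2 node count — so the freedom is the class ordering:
the two ends are the highest-rate pair (the root), and successive inward
positions are chosen greedily to maximize the rates of the tasks entering
at each level, placing easy tasks near the root. Classification walks from
the root along the larger Viterbi log-likelihood; exact ties keep the
lexicographically smaller class, logged. After selection, node models are
refit on TS∪VS at their winning (S, g) (VS is consumed by selection only;
a config flag disables the refit). A class may therefore be modelled with
different architectures at different nodes.

## Baselines

All baselines consume exactly the fold features the DAG sees.

* **Class-specific HMMs** — one model per class, argmax Viterbi. A single
  (S, g) shared by all classes is chosen by multiclass validation rate
  with the stock smaller-architecture tie rule; the per-task margin-guided
  selection above is part of the graph method, not the off-the-shelf bank.
* **Universal HMM** — one background model trained on all classes pooled,
  its (S, g) chosen by held-out pooled likelihood, specialised per class
  by MAP adaptation of the emission means with relevance factor τ = 2
  (adapted mean = (n·ȳ + τ·μ)/(n + τ)); weights, variances and
  transitions stay shared. A "universal HMM" has no single canonical definition;
  background-model-plus-mean-adaptation is the standard realization.
* **SVM** — clips become fixed-length mean++sd pooled vectors (2×52
  dims), z-scored; pairwise-voting RBF-SVM with C and γ from log grids by
  3-fold inner cross-validation on training data only.
* **ESN** — sparse random reservoir rescaled to spectral radius SR, input
  weights uniform(−1,1)·sc, tanh units; the readout is ridge regression
  (α = 1) from time-averaged post-washout states (washout 20 frames,
  a conventional transient-flush length) to one-hot labels. The (SR, size,
  sc) configuration minimizes the validation reconstruction error of the
  target signal (MSE; a classification-error mode exists). Desk-scale
  default grids are SR ∈ {0.9, 0.99}, size ∈ {100, 500},
  sc ∈ {0.5, 0.95}; the full published grids (sizes to 20 000, five SR and
  sc values) are available as constants.

## Synthetic corpus

The generator reproduces the documented corpus statistics exactly: 448
clips (93 food / 220 isolation / 135 brushing; 196 Maine Coon / 252
European Shorthair, with the full per-cell sex-status composition), 0.5 s
leading/trailing background-noise pads, 8 kHz sampling, a 3.8 kHz low-pass
plus 8-bit a-law round-trip for the transport, and per-clip peak levels
varied over an 8 dB range (recording-level variation; cepstral features
are gain-invariant apart from the energy column).

Voiced segments are harmonic series (six partials, 1/h^p rolloff)
following an f0 contour, all partials sharing one amplitude-modulation
envelope. Durations are truncated normals (lower bound 0.3 s) whose
location parameter is solved so the *truncated* mean equals the target —
the corpus mean therefore converges to 1.82 s (0.82 s voiced + 1 s pads)
instead of drifting upward with the truncation mass. The per-class nominal
variance is 0.36 s²; truncation makes the realized corpus variance
smaller (≈ 0.14 s²). The documented duration spread of 0.37 s is
ambiguous between a variance and an SD; the default treats it as a
variance
(`duration_spread_is_variance` switches the reading).

The three default class recipes realize the documented difficulty
pattern — food essentially perfectly recognizable, isolation/brushing the
one confusable pair — with a deliberate cue structure:

* **food**: rising linear f0 ramp from 560 Hz, fast AM (8.5 Hz), moderate
  jitters. Distinct from both other classes in f0, AM rate and contour.
* **isolation**: late-peaked arch at 540 Hz, 4 Hz AM, long duration
  (0.92 s voiced mean).
* **brushing**: early-peaked arch at 500 Hz with a darker spectrum
  (rolloff 1.5 vs 1.0), 3.2 Hz AM, short duration.

The early/late arches are time reversals of one another with identical
value and |slope| distributions and zero net f0 displacement (the warped
arch `a + b sin(pi w(t))` has static moments independent of the peak
position), so that part of the pair separation is carried purely by
temporal *order* — visible to sequence models, invisible to first/second
moment pooling. The residual static cues (40 Hz f0 offset, rolloff tilt)
are partially masked by heavy per-clip jitter (f0 ±12 %, AM rate ±25 %,
contour span ±33 %, spectral tilt sd 0.25) and a 9 dB noise floor. Sex
and breed tags are metadata only (an optional per-breed f0 offset knob
exists for imbalance experiments).

What the generator does **not** emulate: vocal-tract physics
(myoelastic-aerodynamic production), inter-individual identity structure,
session/channel effects, reverberation, or overlapping sources. Passing
the synthetic benchmark therefore demonstrates the *pipeline's* ability to
exploit spectro-temporal class structure under the documented recording
conditions — not field performance on real meows.

## Desk-scale benchmark

`run_benchmark` cross-validates the five systems on one stratified
ten-fold plan over the 448-clip default corpus. Desk-scale problem sizes,
chosen once as the package's defaults: HMM grid S ∈ {3,4} × g ∈ {2,4,8},
the 52-dim MFCC stream (fusion with the modulation stream is an option),
and the reduced ESN grids above. Model training is deterministic given
(data, configuration, seed), so a shared memoization cache lets the class
bank reuse models the DAG search already fit on identical data; this
changes runtime, not results. Typical rates on one corpus seed: DAG and
class-specific HMMs in the low 90s, universal HMM and SVM in the mid 80s,
ESN slightly below them — the qualitative ordering of the reference
comparison, checked over five corpus seeds (majority per pairwise
relation) in the acceptance tests.

## Numerical choices and degenerate inputs

* Log arguments floored at 1e-10 (features) and 1e-300 (probabilities);
  `log 0` stand-in −1e30 in the dynamic programs.
* Dead mixture components (occupancy < 1e-3) keep their previous
  parameters and a 1e-8 weight floor; transition rows never left keep
  their previous distribution.
* All-silence clips raise a no-event error at trimming and are skipped by
  the corpus pipeline; sequences shorter than one frame (features) or one
  modulation window (0.25 s) are rejected with the required minimum named.
* Tie rules are deterministic everywhere: argmax takes the
  lexicographically smaller label; DAG traversal keeps the smaller class.
* Every stochastic step (clip synthesis, splits, k-means, fold plans,
  reservoirs) derives from an explicit integer seed.

## Known limitations

* The node-count law ties the graph to the triangular interval layout; a
  learned, non-greedy topology is out of scope.
* The VAD assumes a stationary noise floor per clip and at least a little
  silence (or an external noise reference).
* The universal HMM adapts means only; weight/variance adaptation might
  narrow its gap to the class-specific bank.
* Generator realism limits are listed above; absolute recognition rates on
  real recordings are expected to differ from the synthetic benchmark.
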