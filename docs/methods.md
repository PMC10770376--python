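# Methods

## Overview

`gspgcn` classifies two groups of subjects — Parkinson's disease (PD)
patients and healthy controls (HC) — from event-related EEG recorded during
a frequency-altered-feedback (FAF) vocalisation task, and interprets what
the classifier used. The pipeline has four parts:

1. **EEG network construction.** Per subject, epoched EEG (64 channels,
   1 kHz, −200…+500 ms around the pitch-perturbation onset) is band-filtered,
   artifact-screened, mastoid-referenced and baseline-corrected. Functional
   connectivity in the 4–12 Hz band is estimated per trial by either the
   Pearson correlation coefficient (PCC, amplitude coupling) or the
   phase-locking value (PLV, phase synchrony from the analytic signal), and
   sparsified by the k-nearest-neighbour rule into a single-hop graph
   (k = 1) and a multi-hop graph (k = 8).
2. **Graph-signal-processing (GSP) reorganisation.** An
   incomplete-network-alignment step couples each subject's single- and
   multi-hop graphs through a Kronecker-product random-walk similarity fixed
   point `s = α(A₁⊗A₂)s + (1−α)h`, with the prior `h` built from the two
   groups' mean adjacency rows (training split only). A maximum-weight
   assignment on the similarity matrix yields a channel permutation used to
   reorganise the subject's signals and connectivity. A sparse
   self-expressive model then reconstructs each electrode's signal from the
   remaining electrodes under an ℓ2,1 row penalty and between-subject
   smoothness, pruning uninformative electrodes/edges into a common sparse
   graph.
3. **Classification.** A Chebyshev spectral graph convolutional network
   (two convolution layers with parameter counts `4096·K₁+64` and
   `2048·K₂+32`, two ½ node coarsenings, a 1056-parameter fully connected
   layer, softmax output) is trained on per-trial connectivity signals and
   evaluated with subject-level 5-fold cross-validation (ACC, AUC,
   sensitivity, specificity).
4. **Interpretation and verification.** Guided backpropagation (gradients
   zeroed wherever the forward activation or the upstream gradient is
   non-positive) produces channel/edge saliency maps; ERP microstate
   analysis (GFP, polarity-sensitive k-means, Krzanowski–Lai selection)
   characterises the group topography dynamics; and a posterior trial-voting
   scheme (10-trial draws, majority with a consecutive-pair tie-break,
   100 repetitions) summarises trial-level robustness.

## Training regime: trials, not subjects

The cross-entropy loss is defined over batches of *trials*. We follow that
regime: the classifier is trained on per-trial connectivity matrices (the
trial's z-scored band-limited correlation pattern, one 64×64 graph signal
per trial), with the subject's trial-averaged k-NN graph (or, with GSP, the
common sparse graph) supplying the convolution structure. A held-out subject
is scored by the mean softmax probability over their trials; the per-trial
hard labels feed the posterior voting stage. Trial-level training matters at
cohort scale: a 40-subject cohort yields ~3 200 training samples instead of
32, which is what lets a ~19 000-parameter network generalise.

Two numerical details proved load-bearing and are defaults:

- **Feature standardisation.** Per-feature mean/sd are estimated over all
  *training* trials and applied to train and test alike. The shared
  connectivity pattern (all subjects' matrices are dominated by the same
  volume-conduction-like structure) otherwise dwarfs the group contrast and
  full-batch training stalls near chance.
- **Class-balanced optimisation steps.** Each Adam step accumulates one
  subject's trial block per class before updating. All trials of one subject
  share one label; stepping on label-homogeneous blocks lets the output bias
  oscillate with the batch order, which we observed as near-perfect ranking
  (AUC ≈ 1) with chance-level thresholded accuracy.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| analysis band | 4–12 Hz | theta–alpha band of the connectivity estimates |
| broad band | 1–20 Hz | ERP preprocessing band, zero-phase 4th-order Butterworth |
| k₁, k₂ | 1, 8 | single-hop / multi-hop k-NN sparsification |
| α | 0.5 | prior-vs-walk mixing weight of the similarity fixed point |
| fixed-point tol / max iter | 1e-8 / 10 000 | residual in the ∞-norm |
| λ₁…λ₄ | 0.1, 0.01, 0.1, 0.01 | ℓ2,1 and smoothness weights of the sparse graph |
| K₁, K₂ | 3 | Chebyshev polynomial orders of the two conv layers |
| dropout | 0.35 | on the pooled 32-dim representation, training only |
| learning rate | 1e-3 | Adam, class-balanced trial blocks |
| weight decay | 1e-3 | L2 on weight matrices (not biases) |
| epochs | 60 | fixed-length schedule, deterministic |
| voting draw / repeats | 10 / 100 | posterior verification protocol |

The learning rate 1e-5 reported for the clinical-scale configuration is
config-exposed but is not the package default: with at most a few hundred
optimisation steps at desk scale, Adam's step-size bound (≈ lr per step)
caps total parameter displacement at ~10⁻³, which cannot leave the
initialisation basin. 1e-3 with weight decay is the default that trains
within the same epoch budget.

## The synthetic cohort

Clinical FAF-EEG data are not redistributable, so the generator produces the
statistical structure the pipeline assumes, with all randomness derived from
one seed:

- **Evoked components.** P1 (80 ms, +1.0), N1 (150 ms, −1.5), P2 (260 ms,
  +1.2) as temporal Gaussians (15/20/40 ms widths) times spatially smooth
  scalp topographies (Gaussian bumps on the unit sensor sphere). The P2
  topography is centred on a left fronto-temporal direction (an F7/FT7-like
  patch); in the PD group its amplitude is multiplied by `p2_effect`
  (default 2.5; 1.0 is the null condition). Per-trial amplitudes jitter
  multiplicatively (sd 0.1); component latencies are fixed (time-locked
  responses), so the noiseless trial average peaks exactly at the P2
  latency.
- **Background.** 1/f (pink) noise, spatially smoothed across the montage
  with a Gaussian channel kernel, plus a 10 Hz oscillation with a random
  phase per trial and a posterior topography. Units are arbitrary z-like
  amplitudes (single-trial component-to-noise ratio near 1); no µV
  calibration is attempted.
- **Montage.** A deterministic 64-channel geodesic-style net: 62 scalp
  sites on a Fibonacci spiral of the upper sphere labelled E1…E62, plus
  left/right inferior mastoid channels M1/M2.
- **Artifacts.** Optional step-plus-drift contamination of random trials at
  a configurable rate and amplitude, with the ground-truth mask returned for
  evaluating the rejection rule.

What the generator does *not* emulate: realistic forward head modelling and
volume conduction, subject-level random effects beyond finite-trial noise,
non-stationary artifact families (ocular, muscular), or any vocal-acoustic
signal. Passing tests therefore demonstrate that the pipeline recovers the
planted group structure under controlled conditions — not clinical
performance.

## Numerical choices

- **Filters** are zero-phase 4th-order Butterworth (forward–backward SOS);
  band edges are validated against Nyquist. Idempotence holds in-band to
  <1e-3 away from filtfilt edge transients.
- **PCC** z-scores per trial and channel (population sd) so the stated
  cross-moment equals the textbook Pearson correlation; zero-variance
  channels zero their rows/columns with a warning. **PLV** uses the phase of
  the analytic (Hilbert) signal with unit exponent on the phase difference.
- **k-NN sparsification** keeps each node's k largest |W| entries with a
  deterministic tie-break (lower channel index), symmetrises by union, and
  carries |W| as the edge weight (Laplacians need nonnegative weights).
- **The similarity fixed point** row-normalises both adjacencies
  (random-walk form) so the Kronecker operator is substochastic and the
  iteration contracts for α < 1; Kronecker products are applied implicitly
  via `(A⊗B)vec(X) = vec(BXAᵀ)` with column-major vectorisation — the
  n²×n² operator is never materialised.
- **The sparse-graph solver** is backtracking proximal gradient (ISTA). The
  ℓ2,1 proximal step is exact for row-constant weighting matrices (the
  all-ones default); the line-search slack is relative to the current
  objective so convergence is not floored at an absolute tolerance; a
  three-strike guard raises on genuine divergence.
- **Laplacians**: combinatorial `D−A` and symmetric-normalised
  `I−D^{−1/2}AD^{−1/2}` with zero-degree nodes handled; `λ_max` by power
  iteration (tol 1e-6); Chebyshev filtering by the three-term recursion —
  the spectral form `U g(Λ) Uᵀ x` exists only as a test oracle.
- **Graph coarsening** is greedy heavy-edge matching with deterministic
  tie-breaks; leftover nodes pair by index so the node count exactly halves;
  pooled features are pair means. Pooling carries no trainable parameters.
- **Initialisation** is He-scaled with the conv fan-in counted over all K
  polynomial bases. All training paths are deterministic given the seed.
- **Microstates**: topographies are sampled at GFP local maxima and
  unit-normalised; clustering is polarity-sensitive (ERP components carry
  meaningful polarity, unlike resting-state maps); the Krzanowski–Lai
  criterion uses `DIFF(k) = (k−1)^{2/p}W_{k−1} − k^{2/p}W_k`,
  `KL(k) = |DIFF(k)|/|DIFF(k+1)|`, maximised over the scanned range.
  Segmentation merges runs shorter than 10 ms into the better-correlating
  neighbour.
- **Voting**: the consecutive-pair scan increments a label's counter on
  equal neighbours and cancels on unequal ones; a BM double tie (possible,
  e.g. a strictly alternating draw) resolves to healthy and is logged.
  Draws are without replacement within a repetition.

## Design choices where the design was open

- "k = 1 / k = 8" is read as the k of the k-NN rule, not as adjacency
  powers; an adjacency-power reading of the multi-hop graph is possible but
  not implemented.
- The alignment prior's "sine" construction is implemented as
  `H_ij = sin(π/2 · cos⁺(row_i(Ā₀), row_j(Ā₁)))` with cosine similarity
  clipped to [0, 1] and H normalised to unit sum; the construction is
  swappable.
- Similarity is computed subject-vs-group-template (one permutation per
  subject), with the prior's group means taken from the training split only
  to avoid label leakage.
- The sparse-graph group/trial column split is configurable; the default
  pairs are within-group subjects (group smoothness) and within-subject
  trials (trial smoothness) when trial columns are supplied.
- Node input features are the subject's (reorganised) 64-dim connectivity
  rows, consistent with the first conv layer's 64-feature input width.
- The 32→M output layer beyond the documented three layers is required by
  the softmax output and is added explicitly; pooling rows are treated as
  parameter-free.
- Cross-validation folds split by *subject* (never by trial), preventing
  identity leakage.
- Saliency is computed on each subject's trial-averaged standardised input
  and averaged over correctly classified subjects of the target class.
- Group-level microstates cluster the two group-grand-average ERPs jointly,
  then back-fit each group.

## Problem sizes used in the test suite

The statistical checks run at the cohort scale the generator defines:
20 subjects per group × 100 trials for the separable condition
(`p2_effect = 2.5`), 10 per group × 60 trials for the null calibration,
8 per group × 60 trials (two seeds, three effect sizes) for the
effect-monotonicity property, and a 4-per-group × 16-trial cohort for
full-pipeline determinism. The acceptance script's in-text target is exact
and runs in milliseconds.

## Known limitations

- Electrode-level analysis only; no source localisation or forward
  modelling.
- The sparse-graph ℓ2,1 proximal step requires row-constant weighting
  matrices; general element-wise weights are accepted only for objective
  evaluation.
- The posterior-voting accuracy of desk-scale models declines relative to
  subject-level scoring (single-trial connectivity is noisy); the voting
  machinery itself is exact and exhaustively verified.
- Microstate counts on simulated cohorts are data outcomes, not method
  constants; the five-state solution reported for clinical data is not
  expected to reproduce on synthetic cohorts.
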