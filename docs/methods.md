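# Methods

This note records the model, the protocol constants, the synthetic-data
design, and the numerical and design choices behind `metaecg`, at the level
of detail a maintainer needs to modify it safely.

## Problem and model

One subject = one binary classification task: does a 2-s single-lead ECG
window overlap a ventricular-arrhythmia (VA) episode? Tasks share structure
(VA is oscillatory, normal rhythm is beat-like) but differ in morphology,
rate and noise, so the pipeline learns an initialization that adapts to a
new subject from K = 10 labeled windows per class.

**Meta-training (MAML).** For a mini-batch of ℬ tasks, each task copies the
meta-weights θ₀, takes `updates` plain gradient-descent steps (rate α) on a
support set of K windows per class, and records the query-set loss after
each step. The meta-objective is the sum of the recorded query losses over
steps and tasks (a `last_step` variant is available); the outer update
descends it with rate γ, differentiating through the inner steps. Gradients
are exact second-order ones computed by the package's reverse-mode autodiff
core (`autodiff.py`), whose vector-Jacobian products are themselves traced
operations; a first-order switch exists for comparisons. Inner and outer
losses use mean cross-entropy over 2 logits — the standard choice for this
head, and configurable via the backbone's `loss_on`.

**Meta-validation.** Every `val_check_every` iterations each validation
subject gets an adapted copy of θ₀ (same inner procedure, a per-subject
*fixed* support draw so successive checks are comparable); its summed loss
on the remaining windows is totaled across subjects. The θ₀ with the lowest
total is kept; training stops after `patience` = 3 checks without
improvement or at the iteration cap.

**Curriculum selector.** Before meta-training, each training task gets a
difficulty: a freshly initialized model is fitted (30 full-batch steps, rate
1e-2) on K windows per class and evaluated on the task's remaining windows;
the per-window average held-out losses are softmaxed across tasks. Two
details are deliberate:

* the divisor is the *actual* held-out count (the alternative — pool size
  minus K — miscounts when 2K windows are removed, and the two readings of
  the procedure disagree; the actual count is the one that makes "average
  loss" literal);
* the init/draw random stream restarts identically for every task, so
  difficulty differences come from the data, not the seed lottery
  (identical pools ⇒ identical losses ⇒ uniform difficulties).

Selection at iteration *i*: task k is eligible iff V_k < thres, with
thres = max(e^{i−MaxIter}, lowest) and MaxIter = 50. The indicator is
strict, and with `lowest` equal to the ℬ-th smallest difficulty a strict
comparison would leave only ℬ−1 tasks eligible; `CurriculumState` therefore
stores `lowest` as the next floating-point value above the ℬ-th smallest
difficulty — the minimal exclusive bound that keeps exactly the ℬ easiest
tasks eligible from iteration 1, which the sampling step requires (ℬ
distinct tasks per batch). Scores max(0, 1[eligible] − t_k/i)/#eligible are
renormalized to a proper distribution before cumulative-probability roulette
(the raw scores do not sum to 1 once damping bites); draws within a batch
are without replacement, and if damping zeroes all remaining scores the
residual slots fall back to a uniform draw over eligible tasks. Difficulties
are frozen after initialization; periodic refresh is out of scope.
`iter` starts at 1 so t_k/iter is always defined. With ℬ = B, threshold
forced above 1 and damping off, the selector reduces exactly (same rng
stream) to uniform task sampling — this degenerate path doubles as the
plain-MAML ablation arm and is asserted in the tests.

**Personalization.** An unseen subject's windows are split support (2K) /
validation (2K) / test. Pre-fine-tuning repeats, for `pre_ft_iters`
iterations: θ′ ← θ₀; θ″ ← θ′ − β₁∇L(θ′); θ₀ ← θ″ − β₂∇L(θ″). The second
gradient is taken *at θ″* — a first-order two-step lookahead, exactly as the
update reads; a variant differentiating through the lookahead exists behind
`second_order_lookahead` but is not the default, since nothing specifies the
update should be second-order. Fine-tuning is full-batch gradient descent on
the 2K support windows (a mini-batch size is otherwise unspecified and the
set is tiny), stopping when the loss changes less than `ft_tol` = 1e-5 over
a 10-step window, capped at 300 steps (200 for the direct-fine-tuning
control arm). Hyperparameters are selected per subject by lowest validation
loss from configurable grids; the desk-scale defaults (pre_ft_iters {10,30},
β₁ {1e-2, 5e-3, 5e-4}, β₂ {5e-3}, ft_lr {1e-2, 1e-3, 1e-4}) are subsets of
the full published grids sized for runtime. The test part is never read
during adaptation or selection (asserted by a poisoning test).

## Windowing and split protocol

Recordings are linearly resampled to 200 Hz; annotation intervals rescale
with floor(start)/ceil(end) so a VA interval never shrinks. Windows are 400
samples; a window is labeled 1 iff it shares ≥ 1 sample with a VA interval
(intervals are half-open, 0-based). The walker's stride after a window is
chosen by *that window's own label*: 20 samples after VA windows, 400
otherwise. The alternative reading — stride switching on entry into an
annotation rather than per emitted window — is ambiguous in prose but the
per-window rule is the one that oversamples VA regions, which is the stated
motivation; a brute-force walker re-deriving the rule is the test oracle.

Per-subject splits draw support first (K per class, uniform), mask every
window overlapping support or within one window length (400 samples) of it,
draw validation from the remainder, and drop anything overlapping
validation; the rest is test. Records must supply ≥ 4K windows per class up
front. Because one VA support window masks ±400 samples ≈ 77 stride-20
neighbours, short records can exhaust a class; the generator's default
duration (480 s) is sized so every subject survives the split at K = 10.

WFDB reading supports signal formats 16 and 212 and MIT annotations; VA
intervals come from a configurable symbol set (default: rhythm labels
`(VT`, `(VF`, `(VFL`, `(VFIB` and the `[`/`]` VF bracket pair). A rhythm
label opens an interval until the next rhythm change; single-character beat
symbols in the set mark only their own sample. Beat-by-beat VA definitions
beyond this are intentionally not hard-coded.

## Synthetic cohort: what it emulates, and what it does not

Each subject: periodic Gaussian-bump QRS train (rate 55–95 bpm, width
0.06–0.12 s, amplitude 0.8–1.4) for non-VA; an amplitude-modulated
quasi-sinusoid at 3.5–7 Hz with peak amplitude 1.5× the subject's QRS for VA
episodes; optional slow drift (gain ±20 % over 60 s, baseline wander);
additive white noise with per-subject σ drawn from (0.1, 1.5) — the
difficulty knob, chosen so that separability genuinely degrades across the
cohort rather than saturating. Generation is at 250 Hz so the resampling
path is always exercised. Episodes sit on the 2-s window grid and total
prevalence × duration to within one slot.

Two generator guarantees make *zero-noise* subjects separable by
construction under the ≥ 1-sample-overlap labeling rule: grid alignment
means a non-VA-labeled window never clips an episode and every VA-labeled
window carries at least 0.1 s of VA waveform; and any 0.1-s stretch of a
≥ 3.5 Hz sinusoid attains ≥ 0.89 of its peak, which at 1.5× QRS amplitude
exceeds every excursion the clean beat train can produce. (Wide ventricular
complexes of this relative size are ordinary on single leads.)

What the generator does **not** model: real QRS/T morphology, arrhythmias
other than a generic oscillatory VA, electrode artifacts, non-Gaussian
noise, or genuine within-subject nonstationarity beyond sinusoidal drift.
Consequences observed at desk scale and worth keeping in mind when reading
green tests: the meta-learned initialization is often already near-optimal
for unseen subjects, so fine-tuning mostly costs test AUC and the
pre-fine-tuning stage's published advantage — which its authors attribute to
within-subject variability of real recordings — shows up only on harder
cohort instances (the arm ordering full ≥ plain-MAML ≥ joint holds
instance-dependently; plain-MAML ≥ joint is robust). Passing tests here
demonstrate protocol and mathematics, not clinical performance.

## Backbones

The default network (2-s, 200-Hz windows): Conv1d(1→128, k5, s2, p2) ∥
Conv1d(1→128, k9, s2, p4) fused by element-wise averaging → BatchNorm →
ReLU → MaxPool(2) → Dropout(0.5) → Conv1d(128→64, k8, p4) → BatchNorm →
ReLU → adaptive average-pool to 50 → one post-norm transformer encoder
layer (d_model 64, 8 heads, ReLU feed-forward) → mean over positions →
Linear(64→2). Stride 2 in the first convolutions is the variant consistent
with the layer output sizes as printed in the source architecture table
(its prose says stride 1; the printed shapes require 2). The feed-forward
width is not specified anywhere; the default is 2048 and configurable — at
that width the model has 349 314 parameters, and no width we tried
reproduces the separately printed 0.596 M figure, so `count_params` simply
reports the true count of the configured model. Batch-norm uses batch statistics
(updating running buffers) only in joint-training/fine-tuning mode; inner-
loop adaptation and inference use the frozen running statistics, keeping
K-shot updates well-posed and evaluation deterministic (dropout off).

The MLP backbone (400 → 32 → 2 with dropout 0.5 on the hidden layer) is the
desk-scale default in the harness: the meta-trainer only sees the
build/forward/loss surface, and the full suite passes with either backbone.
The hidden-layer dropout is not cosmetic — without it, 200–300 full-batch
steps on 20 support windows overfit monotonically and the adaptation-stage
comparisons degenerate into coin flips.

## Numerical choices and degenerate inputs

* float64 throughout; Xavier-uniform init for weight matrices/kernels,
  zeros for biases.
* Softmax/log-sum-exp are max-shifted; the shift is a detached constant
  (gradient-exact for shift-invariant ops).
* Max-pool ties route the gradient to the first maximum; ReLU and pooling
  masks are constants in the backward graph (their a.e.-zero second
  derivatives are what finite-difference checks expect).
* Roulette draws use a cumulative-sum search; a draw landing exactly on a
  zero-mass boundary walks to the next positive-mass index.
* gmean-threshold ties break toward the smaller threshold; prediction is
  `score > threshold`; zero-denominator F1 reports 0.
* Non-finite losses: inner loops abort the episode with a diagnostic, the
  outer loop skips the update and continues, pre-fine-tuning/fine-tuning
  stop and return the last finite weights with a warning.
* Bootstrap CIs are percentile (2.5/97.5), subject-level, 20 000 resamples;
  BCa was not implemented because nothing downstream consumes more than the
  interval.
* Every random draw derives from a single seed via named SeedSequence
  streams per (stage, subject, repetition); identical configs reproduce
  outputs bit for bit.

## Desk-scale problem sizes

The bundled experiments run on one CPU: 12-subject cohorts (480-s records),
task pools capped at 120 windows per class, an MLP backbone, ℬ = 3, one
inner update, 120 meta-iterations with validation checks every 20, and the
reduced adaptation grids above. These sizes are the package's defaults for
its own studies; the full-scale constants from the source setting (ℬ = 9,
0.35 M-parameter backbone, full grids) remain available through the same
configuration objects.

## Known limitations

* Second-order meta-gradients cost roughly double memory/time; the engine
  is a readable numpy implementation, not a performance framework.
* Zero-noise perfection after adaptation is an optimization property, not a
  guarantee: from an unlucky initialization the episode-boundary windows
  (0.1–1.9 s of VA content) can remain misranked even though a perfect
  ranking exists; the bundled sanity check fixes its seed and documents
  this.
* The curriculum's easy-first behaviour is provable from the threshold
  schedule, but whether curriculum ordering *helps* final metrics is
  cohort-dependent at this scale; on the synthetic cohorts it is
  performance-neutral.
* Paired significance tests between arms are reported descriptively
  (per-seed paired differences), not inferentially, because the appropriate
  pairing unit is ambiguous.
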