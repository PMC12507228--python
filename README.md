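# metaecg

Few-shot **personalization of ventricular-arrhythmia (VA) detectors** on
single-lead ECG.

Detecting ventricular tachycardia/fibrillation from a single ECG lead is
dominated by inter-patient variability: a classifier trained on a population
often fails on a new wearer, while only a handful of labeled windows can
realistically be collected per person. `metaecg` implements a personalization
pipeline for this setting, aimed at researchers studying few-shot adaptation
of physiological classifiers:

* **Meta-learned initialization (MAML).** Each training subject is one
  binary VA-vs-non-VA *meta-task*. The inner loop adapts a copy of the
  meta-weights θ₀ with a few gradient steps on a support set D_s (K = 10
  windows per class); the outer loop updates θ₀ by descending the summed
  query-set losses *through* the inner updates (second-order):

      θ_b ← θ_b − α ∇ L_Ds(θ_b),    θ₀ ← θ₀ − γ ∇_θ₀ Σ_b L_Dq(θ_b)

* **Curriculum task selector.** Per-task difficulties V = softmax of quick
  fit-and-evaluate losses; at iteration *i* a task is eligible when
  V_k < max(e^{i−MaxIter}, lowest) (MaxIter = 50, *lowest* bounding the
  batch-size easiest tasks), and a mini-batch of ℬ = 9 distinct tasks is
  drawn by roulette with selection counts damped by max(0, 1 − t_k/i).

* **Pre-fine-tuning.** Personalization to an unseen subject starts with a
  two-step lookahead on the support set —
  θ″ ← θ′ − β₁∇L(θ′), then θ₀ ← θ″ − β₂∇L(θ″) — followed by conventional
  fine-tuning until the training loss stabilizes (≤ 300 steps).

* **Protocol & evaluation.** Recordings are resampled to 200 Hz, cut into
  2-s windows with a dynamic stride (0.1 s after VA-labeled windows, 2 s
  otherwise), and split per subject into temporally disjoint support /
  validation / test parts with a one-window safety gap. Metrics: ROC-AUC,
  PR-AUC, F1/accuracy/balanced accuracy at the threshold maximizing
  √(sensitivity × specificity) fitted on the validation part, with
  subject-level bootstrap CIs (20 000 resamples).

The default backbone is a lightweight 1-D convolution + transformer network
(two parallel convolutions fused by averaging → batch-norm/ReLU/max-pool/
dropout → conv block → adaptive pooling to 50 × 64 → one encoder layer →
linear head); the trainers only touch backbones through a build/forward/loss
interface, and a small MLP backbone is provided for fast experiments. The
numerical core is an in-package reverse-mode autodiff engine over numpy
(float64) with exact higher-order gradients, which is what makes the
second-order meta-updates verifiable against finite differences.

Everything runs offline on a bundled **synthetic multi-subject ECG
generator**: subject-specific QRS morphology, slow within-record drift,
grid-aligned VA episodes of controllable prevalence, and a per-subject noise
level that acts as a known difficulty ordering. WFDB (`.hea/.dat/.atr`)
records and a plain-text dialect are read natively.

## Worked example

Compare the full method (`maml_cl_preft`: curriculum MAML + pre-fine-tune),
plain MAML with direct fine-tuning (`maml_ft`), and a conventional pooled
pre-training baseline (`joint_ft`) on a 12-subject synthetic cohort
(8 train / 2 validation / 2 held-out test subjects):

```python
from metaecg import CohortSpec, make_cohort, ExperimentConfig, run_ablation

spec = CohortSpec(n_subjects=12, seed=3)
records, profiles = make_cohort(spec)
config = ExperimentConfig(cohort=spec)
table = run_ablation(records, arms=["maml_cl_preft", "maml_ft", "joint_ft"],
                     seeds=[0, 1, 2], config=config)
print(table.groupby("arm")[["roc_auc", "pr_auc", "f1", "balanced_acc"]]
      .mean().round(3))
```

which prints

```
               roc_auc  pr_auc     f1  balanced_acc
arm
joint_ft         0.710   0.912  0.749         0.661
maml_cl_preft    0.783   0.939  0.810         0.692
maml_ft          0.780   0.936  0.775         0.698
```

Each row is the macro (across held-out subjects) test metric averaged over
three pipeline seeds. On this cohort instance — whose two test subjects carry
heavy noise — the meta-learned initializations beat pooled pre-training by
~0.07 ROC-AUC after identical per-subject adaptation budgets, and the
pre-fine-tuned arm adds a small F1 edge; on easier instances all arms
saturate and the differences shrink to ties. ROC-AUC is the probability that
a VA window outranks a non-VA window; PR-AUC is high throughout because the
stride-20 oversampling makes VA the majority class in the test parts.

The same pipeline is scriptable from a shell:

```bash
metaecg simulate --out cohort/ --n-subjects 12 --seed 7
metaecg pretrain --cohort cohort/ --out run/ --arm maml_cl_preft --seed 7
metaecg adapt    --checkpoint run/pretrained.npz --cohort cohort/ \
                 --subject s11 --out run/ --seed 7
metaecg evaluate --scores run/ --out run/report.json
metaecg ablation --cohort cohort/ --out ablation.csv --seeds 0 --seeds 1
```

Every stage writes a manifest (config hash, seed, versions); re-running a
stage with the same manifest reproduces its outputs bit for bit.

## Layout

```
src/metaecg/
  autodiff.py     reverse-mode autodiff core (higher-order capable)
  nn.py           functional layers (conv1d, batch/layer norm, attention, ...)
  backbone.py     conv+transformer and MLP backbones, weights handles
  cohort.py       synthetic multi-subject ECG generator
  windowing.py    resampling, dynamic-stride windowing, subject splits
  io_wfdb.py      native WFDB header/signal/annotation reader+writer
  curriculum.py   difficulty estimation + thresholded roulette selector
  meta.py         MAML inner/outer loops, meta-validation, joint baseline
  personalize.py  pre-fine-tuning + fine-tuning + per-subject adaptation
  evaluation.py   metrics, gmean threshold, subject-level bootstrap
  harness.py      end-to-end experiment/ablation harness
  config.py,cli.py  run configs, seed streams, CLI stages
docs/methods.md   model, protocol and design notes
```
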