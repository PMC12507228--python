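"""End-to-end experiment harness: cohort -> tasks -> pre-training ->
per-subject adaptation -> metrics, plus the ablation-arm comparison.

Arms combine a pre-training strategy with an adaptation strategy:

=============  =============================  =====================
arm            pre-training                   adaptation
=============  =============================  =====================
maml_cl_preft  MAML + curriculum selector     pre-fine-tune + FT
maml_cl_ft     MAML + curriculum selector     direct fine-tune
maml_preft     MAML, uniform task sampling    pre-fine-tune + FT
maml_ft        MAML, uniform task sampling    direct fine-tune
joint_ft       pooled joint pre-training      direct fine-tune
=============  =============================  =====================

``maml_cl_preft`` is the full method; ``joint_ft`` is the conventional
transfer-learning baseline on the same sample budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .backbone import MLPBackbone, WeightsHandle
from .cohort import CohortSpec
from .curriculum import CurriculumState, MetaTask, init_difficulties
from .evaluation import ScoredSet, evaluate_subject, macro_report
from .meta import MetaHyperParams, TrainLog, joint_train, meta_train
from .personalize import (HyperGrids, PersonalizationHyperParams,
                          adapt_subject, segments_to_arrays)
from .windowing import resample_record, segment_record

logger = logging.getLogger(__name__)

__all__ = ["ARMS", "ExperimentConfig", "build_tasks", "predict_scores",
           "pretrain_arm", "evaluate_arm", "run_ablation",
           "first_selection_iterations"]

ARMS = ("maml_cl_preft", "maml_cl_ft", "maml_preft", "maml_ft", "joint_ft")
_CURRICULUM = {"maml_cl_preft": True, "maml_cl_ft": True,
               "maml_preft": False, "maml_ft": False, "joint_ft": False}
_PREFT = {"maml_cl_preft": True, "maml_cl_ft": False, "maml_preft": True,
          "maml_ft": False, "joint_ft": False}


@dataclass
class ExperimentConfig:
    """Desk-scale defaults: 12 subjects (8 train / 2 val / 2 test), a small
    MLP backbone, reduced batch size and short meta-training."""
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec())
    n_train_subjects: int = 8
    n_val_subjects: int = 2
    K: int = 10
    pool_cap_per_class: int = 120
    meta: MetaHyperParams = field(default_factory=lambda: MetaHyperParams(
        batch_size=3, update_lr=1e-2, meta_lr=5e-3, updates=1,
        train_iters=120, val_check_every=20, patience=3))
    adapt: PersonalizationHyperParams = field(
        default_factory=PersonalizationHyperParams)
    grids: HyperGrids = field(default_factory=HyperGrids)
    backbone_hidden: tuple[int, ...] = (32,)
    difficulty_train_steps: int = 30


def build_model(config: ExperimentConfig):
    return MLPBackbone(in_len=400, hidden=config.backbone_hidden)


def build_tasks(records, K: int, pool_cap: int, seed: int,
                subsample: bool = True):
    """Window each record and assemble per-subject class-indexed pools.

    Pools larger than ``pool_cap`` per class are subsampled (seeded) to keep
    desk-scale training affordable; caps never undercut the 2K minimum.
    """
    tasks, segments_by_subject = [], {}
    for i, rec in enumerate(records):
        segs = segment_record(resample_record(rec))
        segments_by_subject[rec.subject_id] = segs
        pools = {}
        for c in (0, 1):
            X = np.stack([s.samples for s in segs if s.label == c])
            if subsample and len(X) > pool_cap:
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 101, i, c]))
                X = X[rng.choice(len(X), size=pool_cap, replace=False)]
            pools[c] = X
        task = MetaTask(task_id=rec.subject_id, X_by_class=pools)
        task.check_pool(K)
        tasks.append(task)
    return tasks, segments_by_subject


def predict_scores(model, weights: WeightsHandle, X) -> np.ndarray:
    """Probability of the VA class for each window."""
    logits = model.forward(weights, X).data
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def pretrain_arm(arm: str, model, theta_init: WeightsHandle,
                 train_tasks, val_tasks, config: ExperimentConfig,
                 seed: int):
    """Run the arm's pre-training recipe; returns (weights, log, state)."""
    hp = replace(config.meta, seed=seed)
    if arm == "joint_ft":
        weights, log = joint_train(model, theta_init, train_tasks,
                                   val_tasks, hp)
        return weights, log, None
    if _CURRICULUM[arm]:
        v = init_difficulties(train_tasks, model, config.K,
                              train_steps=config.difficulty_train_steps,
                              seed=seed)
        state = CurriculumState(
            tasks=train_tasks, difficulties=v, batch_size=hp.batch_size,
            max_iter=hp.max_iter,
            rng=np.random.default_rng(np.random.SeedSequence([seed, 31])))
    else:
        n = len(train_tasks)
        state = CurriculumState(
            tasks=train_tasks, difficulties=np.full(n, 1.0 / n),
            batch_size=hp.batch_size, max_iter=hp.max_iter,
            rng=np.random.default_rng(np.random.SeedSequence([seed, 31])),
            force_uniform=True)
    weights, log = meta_train(model, theta_init, state, val_tasks, hp)
    return weights, log, state


def evaluate_arm(arm: str, model, weights: WeightsHandle,
                 test_segments: dict, config: ExperimentConfig, seed: int
                 ) -> dict:
    """Adapt to each held-out subject and compute test metrics."""
    mode = "pre_ft" if _PREFT[arm] else "direct_ft"
    per_subject = []
    for subject_id, segs in test_segments.items():
        hp = replace(config.adapt, seed=seed)
        adapted, split, report = adapt_subject(
            model, weights, segs, config.K, hp, mode=mode,
            grids=config.grids)
        X_v, y_v = segments_to_arrays(split.validation)
        X_te, y_te = segments_to_arrays(split.test)
        val_scored = ScoredSet(subject_id, predict_scores(model, adapted, X_v),
                               y_v)
        test_scored = ScoredSet(subject_id,
                                predict_scores(model, adapted, X_te), y_te)
        metrics = evaluate_subject(test_scored, validation=val_scored)
        metrics["adaptation"] = report
        per_subject.append(metrics)
    return macro_report(per_subject, with_ci=False)


def run_arm(arm: str, records, config: ExperimentConfig, seed: int) -> dict:
    """Full pipeline for one arm and seed on a prebuilt cohort."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; valid: {ARMS}")
    n_tr, n_val = config.n_train_subjects, config.n_val_subjects
    if n_tr + n_val >= len(records):
        raise ValueError("no test subjects left after train/val assignment")
    tasks, segs = build_tasks(records, config.K, config.pool_cap_per_class,
                              seed=config.cohort.seed)
    train_tasks = tasks[:n_tr]
    val_tasks = tasks[n_tr:n_tr + n_val]
    test_ids = [r.subject_id for r in records[n_tr + n_val:]]
    test_segments = {sid: segs[sid] for sid in test_ids}

    model = build_model(config)
    theta_init = model.init_params(seed)
    weights, log, state = pretrain_arm(arm, model, theta_init, train_tasks,
                                       val_tasks, config, seed)
    result = evaluate_arm(arm, model, weights, test_segments, config, seed)
    result["arm"] = arm
    result["seed"] = seed
    result["train_log"] = log
    result["curriculum_state"] = state
    return result


def run_ablation(records, arms, seeds, config: ExperimentConfig | None = None
                 ) -> pd.DataFrame:
    """Arm x seed comparison table of macro test metrics.

    All arms share the cohort, the per-seed weight initialization and the
    split protocol, so per-seed differences between arms are paired.
    """
    config = config or ExperimentConfig()
    rows = []
    for seed in seeds:
        for arm in arms:
            res = run_arm(arm, records, config, seed)
            row = {"arm": arm, "seed": seed}
            for m, entry in res["macro"].items():
                row[m] = entry["mean"]
            rows.append(row)
            logger.info("arm=%s seed=%d roc_auc=%.4f", arm, seed,
                        row["roc_auc"])
    return pd.DataFrame(rows)


def first_selection_iterations(log: TrainLog, task_ids) -> dict[str, float]:
    """Iteration at which each task was first drawn (inf if never)."""
    first = {tid: np.inf for tid in task_ids}
    for row in log.iterations:
        for tid in row["batch"]:
            if row["iteration"] < first[tid]:
                first[tid] = row["iteration"]
    return first
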