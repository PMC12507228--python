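"""MAML outer/inner loops over curriculum-sampled task batches.

The inner loop copies the meta-weights, takes ``updates`` plain
gradient-descent steps on a task's support set, and records the query loss
after each step.  The meta-objective is the sum of these recorded query
losses over the mini-batch of tasks; the outer step differentiates it with
respect to the meta-weights *through* the inner updates (second order) and
applies one gradient-descent step with the meta learning rate.

Meta-validation adapts a copy of the meta-weights to each held-out
validation subject (K windows per class) and sums the adapted model's loss
over that subject's remaining windows; the total across subjects drives
early stopping: training keeps the meta-weights with the lowest validation
loss and stops after ``patience`` consecutive checks without improvement.

A joint-training baseline (conventional pooled pre-training on the same
per-iteration sample budget) is provided behind the same interface for
ablation comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .backbone import WeightsHandle
from .curriculum import CurriculumState, MetaTask, sample_batch
from .sgd import loss_and_grads, gd_step

logger = logging.getLogger(__name__)

__all__ = ["MetaHyperParams", "EpisodeSets", "draw_episode", "inner_adapt",
           "meta_step", "meta_validate", "meta_train", "joint_train"]


@dataclass
class MetaHyperParams:
    K: int = 10
    batch_size: int = 9
    update_lr: float = 1e-2        # alpha, the inner-loop rate
    meta_lr: float = 1e-3          # gamma, the outer rate
    updates: int = 1
    max_iter: int = 50             # curriculum threshold horizon (MaxIter)
    train_iters: int = 200         # hard cap on meta-iterations
    val_check_every: int = 10
    patience: int = 3
    second_order: bool = True
    query_loss: str = "per_step_sum"   # or "last_step"
    seed: int = 0

    def validate(self):
        if self.update_lr < 0 or self.meta_lr < 0:
            raise ValueError("learning rates must be >= 0")
        if self.updates < 1:
            raise ValueError("updates must be >= 1")
        if self.query_loss not in ("per_step_sum", "last_step"):
            raise ValueError("query_loss must be per_step_sum or last_step")


@dataclass
class EpisodeSets:
    """Disjoint support/query sets, K windows per class each."""
    X_s: np.ndarray
    y_s: np.ndarray
    X_q: np.ndarray
    y_q: np.ndarray


def draw_episode(task: MetaTask, K: int, rng: np.random.Generator
                 ) -> EpisodeSets:
    """Uniform draw without replacement of disjoint support and query sets."""
    task.check_pool(K)
    X_s, y_s, used = task.draw(rng, K)
    X_q, y_q, _ = task.draw(rng, K, exclude=used)
    return EpisodeSets(X_s, y_s, X_q, y_q)


def _adapt_traced(model, theta0_t, episode: EpisodeSets, alpha: float,
                  updates: int, second_order: bool):
    """Inner loop keeping the graph from theta0 to the adapted weights."""
    theta = dict(theta0_t)
    query_losses = []
    for _ in range(updates):
        loss_s = model.loss_on(theta, episode.X_s, episode.y_s)
        if not np.isfinite(loss_s.item()):
            raise FloatingPointError("non-finite support loss in inner loop")
        grads = ad.grad(loss_s, theta.values(), create_graph=second_order)
        theta = {k: t - alpha * g for (k, t), g in zip(theta.items(), grads)}
        if episode.X_q is not None:
            query_losses.append(model.loss_on(theta, episode.X_q,
                                              episode.y_q))
    return theta, query_losses


def inner_adapt(model, theta0: WeightsHandle, X_s, y_s, alpha: float,
                updates: int = 1) -> WeightsHandle:
    """Adapt a copy of the meta-weights on a support set (theta0 untouched)."""
    episode = EpisodeSets(X_s, y_s, None, None)
    theta, _ = _adapt_traced(model, theta0.as_tensors(requires_grad=True),
                             episode, alpha, updates, second_order=False)
    return WeightsHandle.from_tensors(theta)


def meta_step(model, theta0: WeightsHandle, episodes: list[EpisodeSets],
              hp: MetaHyperParams) -> tuple[WeightsHandle, float]:
    """One outer update over a batch of task episodes.

    Returns the new meta-weights and the meta-loss (sum over tasks of the
    recorded query losses).  A non-finite meta-gradient skips the update.
    """
    theta0_t = theta0.as_tensors(requires_grad=True)
    total = None
    for ep in episodes:
        _, q_losses = _adapt_traced(model, theta0_t, ep, hp.update_lr,
                                    hp.updates, hp.second_order)
        if hp.query_loss == "last_step":
            task_loss = q_losses[-1]
        else:
            task_loss = q_losses[0]
            for ql in q_losses[1:]:
                task_loss = task_loss + ql
        total = task_loss if total is None else total + task_loss
    meta_loss = total.item()
    grads = ad.grad(total, theta0_t.values())
    if not all(np.isfinite(g.data).all() for g in grads):
        logger.warning("non-finite meta-gradient; skipping update")
        return theta0.copy(), meta_loss
    new = WeightsHandle({k: theta0.arrays[k] - hp.meta_lr * g.data
                         for k, g in zip(theta0_t, grads)})
    return new, meta_loss


def meta_validate(model, theta0: WeightsHandle, val_tasks: list[MetaTask],
                  hp: MetaHyperParams) -> float:
    """Sum over validation subjects of the adapted model's held-out loss.

    Each subject contributes: adapt a copy of theta0 on K windows per class
    (drawn with a per-subject fixed stream so repeated checks are
    comparable), then sum the loss over that subject's remaining windows.
    """
    if not val_tasks:
        raise ValueError("empty validation task set")
    import zlib
    total = 0.0
    for task in val_tasks:
        tid = zlib.crc32(task.task_id.encode())
        rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 7, tid]))
        X_t, y_t, used = task.draw(rng, hp.K)
        adapted = inner_adapt(model, theta0, X_t, y_t, hp.update_lr,
                              hp.updates)
        Xh, yh = [], []
        for c, pool in sorted(task.X_by_class.items()):
            held = np.setdiff1d(np.arange(len(pool)), used[c])
            Xh.append(pool[held])
            yh.append(np.full(len(held), c))
        total += model.loss_on(adapted, np.concatenate(Xh),
                               np.concatenate(yh), reduction="sum").item()
    return total


@dataclass
class TrainLog:
    iterations: list[dict] = field(default_factory=list)
    val_checks: list[dict] = field(default_factory=list)

    def to_jsonl(self) -> str:
        import json
        rows = [dict(kind="iter", **r) for r in self.iterations]
        rows += [dict(kind="val", **r) for r in self.val_checks]
        return "\n".join(json.dumps(r) for r in rows)


def meta_train(model, theta0: WeightsHandle, state: CurriculumState,
               val_tasks: list[MetaTask], hp: MetaHyperParams
               ) -> tuple[WeightsHandle, TrainLog]:
    """Curriculum-sampled MAML with validation-driven early stopping."""
    hp.validate()
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 11]))
    log = TrainLog()
    best = theta0.copy()
    best_val = np.inf
    stale = 0
    for it in range(1, hp.train_iters + 1):
        batch_idx = sample_batch(state)
        episodes = [draw_episode(state.tasks[i], hp.K, rng)
                    for i in batch_idx]
        theta0, meta_loss = meta_step(model, theta0, episodes, hp)
        log.iterations.append({"iteration": it,
                               "batch": [state.tasks[i].task_id
                                         for i in batch_idx],
                               "meta_loss": meta_loss})
        if it % hp.val_check_every == 0:
            val_loss = meta_validate(model, theta0, val_tasks, hp)
            log.val_checks.append({"iteration": it, "val_loss": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best = theta0.copy()
                stale = 0
            else:
                stale += 1
                if stale >= hp.patience:
                    logger.info("early stop at iteration %d", it)
                    break
    if not log.val_checks:        # no check ever ran; keep the final weights
        best = theta0.copy()
    return best, log


def joint_train(model, theta0: WeightsHandle, tasks: list[MetaTask],
                val_tasks: list[MetaTask], hp: MetaHyperParams
                ) -> tuple[WeightsHandle, TrainLog]:
    """Conventional pooled pre-training on the same sample budget.

    Per iteration, ``batch_size`` tasks are drawn uniformly and K windows per
    class from each are pooled into one batch for a single gradient step with
    the meta learning rate.  Validation and early stopping mirror
    :func:`meta_train` so the two strategies are directly comparable.
    """
    hp.validate()
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 11]))
    log = TrainLog()
    weights = theta0.copy()
    best = weights.copy()
    best_val = np.inf
    stale = 0
    for it in range(1, hp.train_iters + 1):
        idx = rng.choice(len(tasks), size=min(hp.batch_size, len(tasks)),
                         replace=False)
        Xs, ys = [], []
        for i in idx:
            X, y, _ = tasks[i].draw(rng, hp.K)
            Xs.append(X)
            ys.append(y)
        X, y = np.concatenate(Xs), np.concatenate(ys)
        loss, grads = loss_and_grads(model, weights, X, y, training=True,
                                     rng=rng)
        weights = gd_step(weights, grads, hp.meta_lr)
        log.iterations.append({"iteration": it,
                               "batch": [tasks[i].task_id for i in idx],
                               "meta_loss": loss})
        if it % hp.val_check_every == 0:
            val_loss = meta_validate(model, weights, val_tasks, hp)
            log.val_checks.append({"iteration": it, "val_loss": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best = weights.copy()
                stale = 0
            else:
                stale += 1
                if stale >= hp.patience:
                    break
    if not log.val_checks:
        best = weights.copy()
    return best, log
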