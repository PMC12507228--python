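"""Curriculum task selector: difficulty estimation and easy-to-hard sampling.

Each training subject is one meta-task.  Difficulty is estimated once before
meta-training: a freshly initialized model is fitted on K windows per class
of the task and evaluated on the task's remaining windows; the per-task
average held-out losses are passed through a softmax, giving a difficulty
distribution V over tasks (higher = harder).

During meta-training, tasks are sampled by thresholded roulette-wheel
selection.  At iteration ``iter`` a task k is *eligible* when its difficulty
lies strictly below ``thres = max(e^(iter - MaxIter), lowest)``; the selection
score is

    score_k = max(0, 1[V_k < thres] - t_k / iter) / (number eligible)

where ``t_k`` counts how often the task has been chosen (damping).  ``lowest``
is the tightest bound that keeps the batch-size-many easiest tasks eligible
from the first iteration; once ``iter >= MaxIter`` the threshold reaches 1 and
every task is eligible (softmax values are < 1 whenever there are >= 2 tasks).
Scores are renormalized to a proper distribution before the roulette draw and
batches are drawn without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sgd import sgd_fit

logger = logging.getLogger(__name__)

__all__ = ["MetaTask", "CurriculumState", "init_difficulties",
           "selection_threshold", "selection_scores", "sample_batch",
           "difficulty_table"]


@dataclass
class MetaTask:
    """One subject's window pool, indexed by class, treated as a meta-task."""
    task_id: str
    X_by_class: dict[int, np.ndarray]    # class -> (n_c, window) arrays
    selection_count: int = 0
    difficulty: float | None = None

    def n_per_class(self) -> dict[int, int]:
        return {c: len(x) for c, x in self.X_by_class.items()}

    def check_pool(self, K: int):
        for c, x in self.X_by_class.items():
            if len(x) < 2 * K:
                raise ValueError(
                    f"task {self.task_id}: class {c} has {len(x)} windows, "
                    f"needs >= {2 * K}")

    def draw(self, rng: np.random.Generator, k_per_class: int,
             exclude: dict[int, np.ndarray] | None = None):
        """Uniform draw without replacement of k windows per class; returns
        (X, y, index map).  ``exclude`` masks indices already used."""
        xs, ys, idxs = [], [], {}
        for c in sorted(self.X_by_class):
            pool = self.X_by_class[c]
            avail = np.arange(len(pool))
            if exclude is not None and c in exclude:
                avail = np.setdiff1d(avail, exclude[c])
            if len(avail) < k_per_class:
                raise ValueError(f"task {self.task_id}: class {c} pool "
                                 "exhausted")
            pick = rng.choice(avail, size=k_per_class, replace=False)
            xs.append(pool[pick])
            ys.append(np.full(k_per_class, c))
            idxs[c] = pick
        return np.concatenate(xs), np.concatenate(ys), idxs


@dataclass
class CurriculumState:
    """Mutable selector state over the training tasks."""
    tasks: list[MetaTask]
    difficulties: np.ndarray
    batch_size: int
    max_iter: int = 50
    iter: int = 1                      # t_k / iter is defined from the start
    lowest: float = field(init=False)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    damping: bool = True
    force_uniform: bool = False        # reduces the selector to uniform draws

    def __post_init__(self):
        v = np.asarray(self.difficulties, dtype=float)
        if v.ndim != 1 or len(v) != len(self.tasks):
            raise ValueError("one difficulty per task required")
        if np.any(v <= 0) or not np.isclose(v.sum(), 1.0):
            raise ValueError("difficulties must be positive and sum to 1")
        if not 1 <= self.batch_size <= len(self.tasks):
            raise ValueError("batch size must lie in [1, n_tasks]")
        # the smallest exclusive bound keeping the batch_size easiest tasks
        # eligible under the strict comparison of the indicator
        kth = np.sort(v)[self.batch_size - 1]
        self.lowest = float(np.nextafter(kth, np.inf))
        for task, d in zip(self.tasks, v):
            task.difficulty = float(d)
        self.difficulties = v


def init_difficulties(tasks: list[MetaTask], model, K: int,
                      train_steps: int = 30, lr: float = 1e-2,
                      seed: int = 0) -> np.ndarray:
    """Estimate task difficulties by a quick fit-and-evaluate per task.

    For each task a freshly initialized model is trained on K windows per
    class and evaluated on the remaining windows; the average held-out loss
    per window (total loss divided by the actual held-out count) is softmaxed
    across tasks into the difficulty vector.

    The initialization and draw stream is restarted identically for every
    task, so difficulty differences reflect the data rather than the
    random-seed lottery (identical pools get identical losses).
    """
    losses = []
    for i, task in enumerate(tasks):
        task.check_pool(K)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        weights = model.init_params(int(rng.integers(2**31)))
        X, y, used = task.draw(rng, K)
        weights = sgd_fit(model, weights, X, y, lr=lr, steps=train_steps,
                          training=True, rng=rng)
        Xh, yh = [], []
        for c, pool in sorted(task.X_by_class.items()):
            held = np.setdiff1d(np.arange(len(pool)), used[c])
            Xh.append(pool[held])
            yh.append(np.full(len(held), c))
        Xh, yh = np.concatenate(Xh), np.concatenate(yh)
        total = model.loss_on(weights, Xh, yh, reduction="sum").item()
        losses.append(total / len(yh))
    losses = np.asarray(losses)
    e = np.exp(losses - losses.max())
    v = e / e.sum()
    for task, d in zip(tasks, v):
        task.difficulty = float(d)
    return v


def selection_threshold(iteration: int, max_iter: int, lowest: float) -> float:
    """thres = max(e^(iter - MaxIter), lowest)."""
    if iteration < 1:
        raise ValueError("iteration starts at 1")
    return max(float(np.exp(iteration - max_iter)), lowest)


def selection_scores(state: CurriculumState) -> np.ndarray:
    """Per-task selection scores (may sum to less than 1)."""
    if state.force_uniform:
        return np.full(len(state.tasks), 1.0 / len(state.tasks))
    thres = selection_threshold(state.iter, state.max_iter, state.lowest)
    eligible = state.difficulties < thres        # strict comparison
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise AssertionError(
            "no eligible task; cannot happen when `lowest` bounds the "
            "batch-size easiest difficulties")
    t = np.array([task.selection_count for task in state.tasks], dtype=float)
    damp = t / state.iter if state.damping else 0.0
    return np.maximum(0.0, eligible.astype(float) - damp) / n_eligible


def _roulette(rng: np.random.Generator, probs: np.ndarray) -> int:
    """Cumulative-probability roulette draw over normalized probs."""
    c = np.cumsum(probs)
    r = rng.uniform(0.0, 1.0)
    idx = int(np.searchsorted(c, r, side="left"))
    idx = min(idx, len(probs) - 1)
    while probs[idx] == 0.0 and idx + 1 < len(probs):  # zero-mass boundary hit
        idx += 1
    return idx


def sample_batch(state: CurriculumState) -> list[int]:
    """Draw ``batch_size`` distinct task indices by roulette; updates the
    selection counts and advances the iteration counter."""
    scores = selection_scores(state)
    if state.force_uniform:
        eligible = np.ones(len(state.tasks), dtype=bool)
    else:
        thres = selection_threshold(state.iter, state.max_iter, state.lowest)
        eligible = state.difficulties < thres
    chosen: list[int] = []
    for _ in range(state.batch_size):
        s = scores.copy()
        s[chosen] = 0.0
        total = s.sum()
        if total > 0:
            idx = _roulette(state.rng, s / total)
        else:
            # damping has zeroed all remaining eligible scores: fall back to
            # a uniform draw over the remaining eligible tasks
            pool = np.flatnonzero(eligible)
            pool = pool[~np.isin(pool, chosen)]
            if len(pool) == 0:
                raise ValueError("fewer eligible tasks than the batch size")
            logger.debug("iter %d: uniform fallback over %d eligible tasks",
                         state.iter, len(pool))
            idx = int(pool[_roulette(state.rng,
                                     np.full(len(pool), 1.0 / len(pool)))])
        chosen.append(idx)
    for idx in chosen:
        state.tasks[idx].selection_count += 1
    state.iter += 1
    return chosen


def difficulty_table(state: CurriculumState) -> list[tuple[str, float]]:
    """Two-column (task_id, difficulty) report for inspection."""
    return [(task.task_id, float(d))
            for task, d in zip(state.tasks, state.difficulties)]
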