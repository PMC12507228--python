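"""Per-subject adaptation: pre-fine-tuning followed by conventional
fine-tuning on the subject's few-shot support set.

Pre-fine-tuning transplants the meta-learning "future loss" idea into the
adaptation stage.  Each iteration performs a two-step lookahead on the
support set D_t:

    theta'  <- copy(theta0)
    theta'' <- theta'  - beta1 * grad L_Dt(theta')
    theta0  <- theta'' - beta2 * grad L_Dt(theta'')

i.e. the second gradient is evaluated at the looked-ahead weights theta''
(first-order, as the update is written); a variant that differentiates the
second step through the lookahead is available behind a flag.  Conventional
fine-tuning then runs full-batch gradient descent on D_t until the training
loss stabilizes (change over a 10-step window below a tolerance) or an
iteration cap is reached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from . import autodiff as ad
from .backbone import WeightsHandle
from .sgd import loss_and_grads, gd_step
from .windowing import Segment, SubjectSplit, make_subject_split

logger = logging.getLogger(__name__)

__all__ = ["PersonalizationHyperParams", "HyperGrids", "pre_fine_tune",
           "fine_tune", "adapt_subject", "segments_to_arrays"]


@dataclass
class PersonalizationHyperParams:
    pre_ft_iters: int = 10
    beta1: float = 5e-3
    beta2: float = 5e-3
    ft_lr: float = 1e-2
    ft_max_iters: int = 300
    ft_tol: float = 1e-5         # loss-change threshold over a 10-step window
    updates: int = 1
    second_order_lookahead: bool = False
    seed: int = 0

    def validate(self):
        if min(self.beta1, self.beta2, self.ft_lr) < 0:
            raise ValueError("learning rates must be >= 0")


@dataclass
class HyperGrids:
    """Search grids for validation-based selection in :func:`adapt_subject`.

    Defaults are intentionally small for desk-scale runs; the full published
    grids (pre_ft_iters {10,30,50}, betas {1e-2,5e-3,1e-3,5e-4}, ft_lr
    {1e-2,1e-3,1e-4}) can be supplied explicitly.
    """
    pre_ft_iters: tuple[int, ...] = (10, 30)
    beta1: tuple[float, ...] = (1e-2, 5e-3, 5e-4)
    beta2: tuple[float, ...] = (5e-3,)
    ft_lr: tuple[float, ...] = (1e-2, 1e-3, 1e-4)


def pre_fine_tune(model, theta0: WeightsHandle, X_t, y_t,
                  hp: PersonalizationHyperParams) -> WeightsHandle:
    """The two-step lookahead update, repeated ``pre_ft_iters`` times."""
    hp.validate()
    theta0 = theta0.copy()
    for it in range(hp.pre_ft_iters):
        if hp.second_order_lookahead:
            t_prime = theta0.as_tensors(requires_grad=True)
            loss1 = model.loss_on(t_prime, X_t, y_t)
            g1 = ad.grad(loss1, t_prime.values(), create_graph=True)
            t_dd = {k: t - hp.beta1 * g
                    for (k, t), g in zip(t_prime.items(), g1)}
            loss2 = model.loss_on(t_dd, X_t, y_t)
            if not np.isfinite(loss2.item()):
                warnings.warn("non-finite loss in pre-fine-tuning; stopping")
                return theta0
            g2 = ad.grad(loss2, t_prime.values())
            theta0 = WeightsHandle(
                {k: t_dd[k].data - hp.beta2 * g.data
                 for k, g in zip(t_prime, g2)})
        else:
            loss1, g1 = loss_and_grads(model, theta0, X_t, y_t)
            theta_dd = gd_step(theta0, g1, hp.beta1)
            loss2, g2 = loss_and_grads(model, theta_dd, X_t, y_t)
            if not (np.isfinite(loss1) and np.isfinite(loss2)):
                warnings.warn("non-finite loss in pre-fine-tuning; stopping")
                return theta0
            theta0 = gd_step(theta_dd, g2, hp.beta2)
    return theta0


def fine_tune(model, theta: WeightsHandle, X_t, y_t,
              hp: PersonalizationHyperParams,
              max_iters: int | None = None,
              loss_trace: list | None = None) -> WeightsHandle:
    """Full-batch gradient descent on the support set until the training
    loss stabilizes (or ``ft_max_iters`` steps)."""
    hp.validate()
    w = theta.copy()
    losses: list[float] = []
    cap = hp.ft_max_iters if max_iters is None else max_iters
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 23]))
    for _ in range(cap):
        loss, grads = loss_and_grads(model, w, X_t, y_t, training=True,
                                     rng=rng)
        if not np.isfinite(loss):
            warnings.warn("non-finite loss in fine-tuning; stopping")
            break
        losses.append(loss)
        if loss_trace is not None:
            loss_trace.append(loss)
        w = gd_step(w, grads, hp.ft_lr)
        if len(losses) > 10 and abs(losses[-11] - losses[-1]) < hp.ft_tol:
            break
    return w


def segments_to_arrays(segments: list[Segment]):
    X = np.stack([s.samples for s in segments])
    y = np.array([s.label for s in segments])
    return X, y


def adapt_subject(model, theta0: WeightsHandle, segments: list[Segment],
                  K: int, hp: PersonalizationHyperParams,
                  mode: str = "pre_ft", grids: HyperGrids | None = None,
                  split: SubjectSplit | None = None):
    """Adapt the meta-weights to one unseen subject.

    Builds the temporal-disjoint split (support 2K / validation 2K / test),
    then either runs pre-fine-tuning followed by fine-tuning (``mode=
    "pre_ft"``) or direct fine-tuning only (``mode="direct_ft"``, capped at
    200 iterations).  Hyperparameters are selected on the validation part by
    lowest validation loss; the test part is never touched.

    Returns (adapted weights, split, report dict).
    """
    if mode not in ("pre_ft", "direct_ft"):
        raise ValueError("mode must be 'pre_ft' or 'direct_ft'")
    grids = grids or HyperGrids()
    if split is None:
        split = make_subject_split(segments, K=K, seed=hp.seed)
    X_t, y_t = segments_to_arrays(split.support)
    X_v, y_v = segments_to_arrays(split.validation)

    if mode == "pre_ft":
        combos = list(product(grids.pre_ft_iters, grids.beta1, grids.beta2,
                              grids.ft_lr))
    else:
        combos = [(0, 0.0, 0.0, lr) for lr in grids.ft_lr]

    best = None
    for pre_iters, b1, b2, lr in combos:
        trial_hp = PersonalizationHyperParams(
            pre_ft_iters=pre_iters, beta1=b1, beta2=b2, ft_lr=lr,
            ft_max_iters=hp.ft_max_iters if mode == "pre_ft" else 200,
            ft_tol=hp.ft_tol, updates=hp.updates,
            second_order_lookahead=hp.second_order_lookahead, seed=hp.seed)
        w = theta0.copy()
        if mode == "pre_ft":
            w = pre_fine_tune(model, w, X_t, y_t, trial_hp)
        trace: list[float] = []
        w = fine_tune(model, w, X_t, y_t, trial_hp, loss_trace=trace)
        val_loss = model.loss_on(w, X_v, y_v).item()
        if best is None or val_loss < best["val_loss"]:
            best = {"weights": w, "val_loss": val_loss,
                    "hyperparams": {"pre_ft_iters": pre_iters, "beta1": b1,
                                    "beta2": b2, "ft_lr": lr},
                    "ft_steps": len(trace),
                    "final_train_loss": trace[-1] if trace else None}
    report = {"mode": mode, "subject_id": split.support[0].subject_id,
              "chosen": best["hyperparams"], "val_loss": best["val_loss"],
              "ft_steps": best["ft_steps"],
              "final_train_loss": best["final_train_loss"],
              "split_sizes": {"support": len(split.support),
                              "validation": len(split.validation),
                              "test": len(split.test)}}
    logger.info("adapted %s (%s): %s", report["subject_id"], mode,
                best["hyperparams"])
    return best["weights"], split, report
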