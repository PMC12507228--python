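"""Meta-learning math against closed forms and finite-difference oracles."""

import numpy as np
import pytest

from metaecg import autodiff as ad
from metaecg.backbone import MLPBackbone
from metaecg.curriculum import CurriculumState, MetaTask
from metaecg.meta import (EpisodeSets, MetaHyperParams, draw_episode,
                          inner_adapt, meta_step, meta_train, meta_validate)


def _episode(rng, n=6, dim=2):
    X = rng.normal(size=(2 * n, dim))
    y = np.tile([0, 1], n)
    return EpisodeSets(X[:n], y[:n], X[n:], y[n:])


def _quad_episode():
    z = np.zeros((1, 1))
    return EpisodeSets(z, np.array([0]), z, np.array([0]))


# ------------------------------------------------------------- inner updates

def test_zero_inner_lr_returns_exact_copy(quadratic):
    theta0 = quadratic.init_params(theta0=2.5)
    theta_b = inner_adapt(quadratic, theta0, np.zeros((1, 1)), [0],
                          alpha=0.0, updates=3)
    assert theta_b.allclose(theta0)
    assert theta_b is not theta0


def test_quadratic_two_updates_closed_form(quadratic):
    alpha, theta_init = 0.1, 2.0
    theta0 = quadratic.init_params(theta0=theta_init)
    theta_b = inner_adapt(quadratic, theta0, np.zeros((1, 1)), [0],
                          alpha=alpha, updates=2)
    assert theta_b["theta"] == pytest.approx(
        (1 - alpha) ** 2 * theta_init, abs=1e-12)
    assert theta0["theta"] == theta_init  # untouched


def test_single_update_matches_finite_difference_gradient(tiny_mlp):
    rng = np.random.default_rng(0)
    theta0 = tiny_mlp.init_params(1)
    X, y = rng.normal(size=(8, 2)), np.tile([0, 1], 4)
    alpha = 0.05
    theta_b = inner_adapt(tiny_mlp, theta0, X, y, alpha=alpha, updates=1)
    eps = 1e-6
    for name in theta0.keys():
        arr = theta0.arrays[name]
        for i in np.ndindex(arr.shape):
            arr[i] += eps
            fp = tiny_mlp.loss_on(theta0, X, y).item()
            arr[i] -= 2 * eps
            fm = tiny_mlp.loss_on(theta0, X, y).item()
            arr[i] += eps
            step = theta_b[name][i] - arr[i]
            assert step == pytest.approx(-alpha * (fp - fm) / (2 * eps),
                                         rel=1e-4, abs=1e-9)


# ----------------------------------------------------------------- meta step

def test_zero_meta_lr_keeps_weights(quadratic):
    hp = MetaHyperParams(update_lr=0.1, meta_lr=0.0, updates=1)
    theta0 = quadratic.init_params(theta0=1.5)
    new, _ = meta_step(quadratic, theta0, [_quad_episode()], hp)
    assert new.allclose(theta0)


@pytest.mark.parametrize("alpha,gamma,B", [(0.1, 0.05, 3), (0.2, 0.01, 9)])
def test_meta_step_closed_form_on_quadratic(quadratic, alpha, gamma, B):
    """B identical tasks, 1 update: theta0_new = theta0 (1 - gamma B (1-a)^2)."""
    theta_init = 2.0
    hp = MetaHyperParams(update_lr=alpha, meta_lr=gamma, updates=1)
    theta0 = quadratic.init_params(theta0=theta_init)
    new, meta_loss = meta_step(quadratic, theta0,
                               [_quad_episode() for _ in range(B)], hp)
    expected = theta_init * (1 - gamma * B * (1 - alpha) ** 2)
    assert new["theta"] == pytest.approx(expected, abs=1e-12)
    expected_loss = B * 0.5 * ((1 - alpha) * theta_init) ** 2
    assert meta_loss == pytest.approx(expected_loss, abs=1e-12)


@pytest.mark.parametrize("updates", [1, 2])
def test_second_order_meta_gradient_matches_finite_differences(tiny_mlp,
                                                               updates):
    rng = np.random.default_rng(3)
    theta0 = tiny_mlp.init_params(2)
    episodes = [_episode(rng) for _ in range(2)]
    hp = MetaHyperParams(update_lr=0.08, meta_lr=1.0, updates=updates)

    def meta_loss_at(weights):
        _, loss = meta_step(tiny_mlp, weights, episodes,
                            MetaHyperParams(update_lr=hp.update_lr,
                                            meta_lr=0.0, updates=updates))
        return loss

    new, _ = meta_step(tiny_mlp, theta0, episodes, hp)
    eps = 1e-5
    for name in theta0.keys():
        arr = theta0.arrays[name]
        grad_impl = theta0[name] - new[name]      # meta_lr = 1
        for i in np.ndindex(arr.shape):
            arr[i] += eps
            fp = meta_loss_at(theta0)
            arr[i] -= 2 * eps
            fm = meta_loss_at(theta0)
            arr[i] += eps
            fd = (fp - fm) / (2 * eps)
            assert grad_impl[i] == pytest.approx(fd, rel=1e-3, abs=1e-7)


def test_first_order_switch_drops_curvature_term(quadratic):
    alpha, gamma = 0.1, 0.05
    theta0 = quadratic.init_params(theta0=2.0)
    hp = MetaHyperParams(update_lr=alpha, meta_lr=gamma, updates=1,
                         second_order=False)
    new, _ = meta_step(quadratic, theta0, [_quad_episode()], hp)
    # first-order MAML: gradient evaluated at theta_b without the (1-alpha)
    # Jacobian factor -> theta0 - gamma * (1-alpha) * theta0
    assert new["theta"] == pytest.approx(2.0 * (1 - gamma * (1 - alpha)),
                                         abs=1e-12)


# -------------------------------------------------------------- episode draw

def test_episode_partition_when_pool_is_exactly_2k():
    rng = np.random.default_rng(0)
    pools = {0: rng.normal(size=(6, 3)), 1: rng.normal(size=(6, 3))}
    task = MetaTask(task_id="t", X_by_class=pools)
    ep = draw_episode(task, K=3, rng=np.random.default_rng(1))
    seen = np.concatenate([ep.X_s, ep.X_q])
    full = np.concatenate([pools[0], pools[1]])
    assert sorted(map(tuple, seen)) == sorted(map(tuple, full))
    assert len(ep.X_s) == len(ep.X_q) == 6


def test_episode_deterministic_and_uniform():
    rng = np.random.default_rng(0)
    pools = {0: rng.normal(size=(10, 2)), 1: rng.normal(size=(10, 2))}
    task = MetaTask(task_id="t", X_by_class=pools)
    a = draw_episode(task, 2, np.random.default_rng(5))
    b = draw_episode(task, 2, np.random.default_rng(5))
    assert np.array_equal(a.X_s, b.X_s) and np.array_equal(a.X_q, b.X_q)

    counts = np.zeros(10)
    n = 1000
    rng = np.random.default_rng(7)
    for _ in range(n):
        ep = draw_episode(task, 2, rng)
        for row in np.concatenate([ep.X_s, ep.X_q]):
            idx = np.where((pools[0] == row).all(axis=1))[0]
            if len(idx):
                counts[idx[0]] += 1
    p = 0.4  # 4 of 10 class-0 windows used per episode
    se = np.sqrt(p * (1 - p) / n)
    assert np.all(np.abs(counts / n - p) < 3 * se)


# ------------------------------------------------------------ meta-validation

def test_meta_validate_sums_over_subjects(window_mlp):
    rng = np.random.default_rng(0)
    pools = {0: rng.normal(size=(25, 400)), 1: rng.normal(size=(25, 400)) + 1}
    task = MetaTask(task_id="v0", X_by_class=pools)
    hp = MetaHyperParams(update_lr=0.01, updates=1, K=5, seed=0)
    theta0 = window_mlp.init_params(0)
    single = meta_validate(window_mlp, theta0, [task], hp)
    doubled = meta_validate(window_mlp, theta0, [task, task], hp)
    assert doubled == pytest.approx(2 * single, abs=1e-10)
    with pytest.raises(ValueError):
        meta_validate(window_mlp, theta0, [], hp)


def test_meta_validate_matches_independent_recomputation(window_mlp):
    rng = np.random.default_rng(1)
    tasks = [MetaTask(task_id=f"v{i}",
                      X_by_class={0: rng.normal(size=(20, 400)),
                                  1: rng.normal(size=(20, 400)) + 0.5})
             for i in range(2)]
    hp = MetaHyperParams(update_lr=0.02, updates=2, K=4, seed=3)
    theta0 = window_mlp.init_params(1)
    got = meta_validate(window_mlp, theta0, tasks, hp)

    import zlib
    total = 0.0
    for task in tasks:                 # independent adapt-then-evaluate
        tid = zlib.crc32(task.task_id.encode())
        rng_i = np.random.default_rng(
            np.random.SeedSequence([hp.seed, 7, tid]))
        X_t, y_t, used = task.draw(rng_i, hp.K)
        adapted = inner_adapt(window_mlp, theta0, X_t, y_t, hp.update_lr,
                              hp.updates)
        for c, pool in sorted(task.X_by_class.items()):
            held = np.setdiff1d(np.arange(len(pool)), used[c])
            total += window_mlp.loss_on(adapted, pool[held],
                                        np.full(len(held), c),
                                        reduction="sum").item()
    assert got == pytest.approx(total, abs=1e-10)


# ---------------------------------------------------------------- meta_train

def _train_setup(n_tasks=4, seed=0, force_uniform=False, damping=True,
                 max_iter=50):
    rng = np.random.default_rng(seed)
    tasks = []
    for i in range(n_tasks):
        w = rng.normal(size=400)
        tasks.append(MetaTask(
            task_id=f"t{i}",
            X_by_class={0: rng.normal(size=(12, 400)) - w,
                        1: rng.normal(size=(12, 400)) + w}))
    n = len(tasks)
    state = CurriculumState(tasks=tasks, difficulties=np.full(n, 1 / n),
                            batch_size=2, max_iter=max_iter,
                            rng=np.random.default_rng(seed + 100),
                            force_uniform=force_uniform, damping=damping)
    return tasks, state


def test_early_stop_returns_best_checkpoint(window_mlp, monkeypatch):
    tasks, state = _train_setup()
    hp = MetaHyperParams(update_lr=0.01, meta_lr=0.01, updates=1, K=3,
                         train_iters=50, val_check_every=5, patience=1,
                         seed=0)
    vals = iter([1.0, 2.0, 3.0, 4.0])      # strictly increasing checks

    import metaecg.meta as meta_mod
    monkeypatch.setattr(meta_mod, "meta_validate",
                        lambda *a, **k: next(vals))
    snapshots = []
    orig_step = meta_mod.meta_step

    def recording_step(model, theta0, episodes, hp_):
        new, loss = orig_step(model, theta0, episodes, hp_)
        snapshots.append(new.copy())
        return new, loss

    monkeypatch.setattr(meta_mod, "meta_step", recording_step)
    best, log = meta_train(window_mlp, window_mlp.init_params(0), state,
                           tasks[:1], hp)
    assert len(log.val_checks) == 2        # first check + one stale check
    assert best.allclose(snapshots[hp.val_check_every - 1])


def test_meta_train_log_is_reproducible(window_mlp):
    def run():
        tasks, state = _train_setup(seed=2)
        hp = MetaHyperParams(update_lr=0.01, meta_lr=0.005, updates=1, K=3,
                             train_iters=8, val_check_every=4, patience=2,
                             seed=5)
        _, log = meta_train(window_mlp, window_mlp.init_params(3), state,
                            tasks[:1], hp)
        return log

    a, b = run(), run()
    assert a.iterations == b.iterations and a.val_checks == b.val_checks


def test_degenerate_curriculum_equals_uniform_sampling(window_mlp):
    """Batch = all tasks, threshold forced above 1, damping off: the
    curriculum selector reduces to uniform sampling and the training logs
    coincide stream-for-stream."""
    def run(force_uniform):
        tasks, state = _train_setup(n_tasks=3, seed=4,
                                    force_uniform=force_uniform,
                                    damping=False, max_iter=0)
        state.batch_size = 3
        state.lowest = 1.1
        hp = MetaHyperParams(update_lr=0.01, meta_lr=0.005, updates=1, K=3,
                             batch_size=3, train_iters=6, val_check_every=3,
                             patience=5, seed=9)
        _, log = meta_train(window_mlp, window_mlp.init_params(1), state,
                            tasks[:1], hp)
        return log

    assert run(True).iterations == run(False).iterations


def test_meta_training_beats_xavier_init_after_adaptation(window_mlp,
                                                          small_cohort):
    """Post-adaptation query accuracy of trained meta-weights exceeds the
    raw initialization (paired over seeds)."""
    from metaecg.harness import build_tasks
    _, records, _ = small_cohort
    tasks, _ = build_tasks(records, K=5, pool_cap=60, seed=0)
    margins = []
    for seed in range(3):
        state = CurriculumState(
            tasks=tasks[:4], difficulties=np.full(4, 0.25), batch_size=2,
            rng=np.random.default_rng(seed), force_uniform=True)
        hp = MetaHyperParams(update_lr=0.01, meta_lr=0.005, updates=1, K=5,
                             train_iters=30, val_check_every=10, patience=3,
                             seed=seed)
        theta_init = window_mlp.init_params(seed)
        theta_star, _ = meta_train(window_mlp, theta_init, state, tasks[4:5],
                                   hp)

        def post_adapt_acc(theta):
            accs = []
            for i, task in enumerate(tasks[5:6]):
                rng = np.random.default_rng((seed, i).__hash__() % 2**31)
                ep = draw_episode(task, 5, np.random.default_rng(seed + i))
                adapted = inner_adapt(window_mlp, theta, ep.X_s, ep.y_s,
                                      hp.update_lr, hp.updates)
                logits = window_mlp.forward(adapted, ep.X_q).data
                accs.append((logits.argmax(1) == ep.y_q).mean())
            return np.mean(accs)

        margins.append(post_adapt_acc(theta_star) - post_adapt_acc(theta_init))
    assert np.mean(margins) > 0
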