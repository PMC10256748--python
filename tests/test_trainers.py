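"""Strategy-level units: rehearsal sampling, Fisher, penalties, distillation
losses, RW updates, head isolation, and LwF staging."""

import numpy as np
import pytest

import contiseg as cs
from contiseg.model import TrainConfig, softmax
from contiseg.trainers import (ImportanceStore, MethodState, compute_fisher,
                               empirical_fisher, ewc_penalty, harden,
                               lwf_distillation, mib_ce, mib_losses,
                               rehearsal_sample, rw_update, run_sequence,
                               train_stage)


class TestRehearsalSample:
    def test_quarter_of_eight_is_two(self, tiny_pair):
        # tiny tasks have 8 cases -> 6 train / 2 test
        prev = [tiny_pair[0]]
        buf = rehearsal_sample(prev, 0.25, seed=0)
        assert len(buf) == round(0.25 * len(prev[0].train_idx))

    def test_fraction_zero_empty(self, tiny_pair):
        assert len(rehearsal_sample([tiny_pair[0]], 0.0, seed=0)) == 0

    def test_seeded_determinism(self, tiny_pair):
        a = rehearsal_sample(tiny_pair[:1], 0.5, seed=3)
        b = rehearsal_sample(tiny_pair[:1], 0.5, seed=3)
        assert [e[1] for e in a.entries] == [e[1] for e in b.entries]

    def test_without_replacement_from_train_only(self, tiny_pair):
        buf = rehearsal_sample(tiny_pair[:1], 1.0, seed=0)
        train_ids = {cid for cid, _, _ in tiny_pair[0].train_cases()}
        ids = [e[1] for e in buf.entries]
        assert len(set(ids)) == len(ids)
        assert set(ids) == train_ids

    def test_invalid_fraction(self, tiny_pair):
        with pytest.raises(ValueError):
            rehearsal_sample(tiny_pair[:1], 1.5, seed=0)


class TestFisher:
    def test_zero_gradients_give_zero_fisher(self):
        grads = [(1.0, {"w": np.zeros(3)})] * 4
        out = empirical_fisher(grads)
        assert (out["w"] == 0).all()

    def test_nonnegative_on_real_model(self, trained_tiny, tiny_task):
        fisher = compute_fisher(trained_tiny, tiny_task, n_samples=3)
        assert fisher.keys() == trained_tiny.all_named().keys()
        for v in fisher.values():
            assert (v >= 0).all()

    def test_empty_sample_rejected(self, trained_tiny, tiny_task):
        with pytest.raises(ValueError):
            compute_fisher(trained_tiny, tiny_task, n_samples=0)

    def test_logistic_toy_matches_closed_form(self):
        """Exact Fisher of a 1-parameter logistic model p = sigmoid(w*x):
        enumerating y in {0,1} with weights p(y) must reproduce p(1-p)x^2."""
        w = 0.7
        xs = np.array([-1.5, -0.2, 0.4, 2.0])
        ps = 1.0 / (1.0 + np.exp(-w * xs))

        def enumerate_grads():
            for x, p in zip(xs, ps):
                # d/dw log p(y|x) = (y - p) x ; outcomes weighted by p(y)
                yield p, {"w": np.array([(1.0 - p) * x])}
                yield 1.0 - p, {"w": np.array([(0.0 - p) * x])}

        # each case carries unit total weight, so the accumulator returns the
        # mean over cases of E_y[(d log p)^2]
        fisher = empirical_fisher(enumerate_grads())["w"][0]
        expected = float(np.mean(ps * (1 - ps) * xs**2))
        assert abs(fisher - expected) < 1e-6


class TestEwcPenalty:
    def _store(self, theta, omega):
        store = ImportanceStore()
        store.append("t1", {"w": np.array(theta, dtype=float)},
                     {"w": np.array(omega, dtype=float)})
        return store

    def test_hand_arithmetic(self):
        store = self._store([0.0, 0.0], [1.0, 2.0])
        params = {"w": np.array([1.0, 1.0])}
        assert ewc_penalty(params, store, lam=0.4) == pytest.approx(0.6, abs=1e-12)

    def test_zero_at_anchor_and_zero_lambda(self):
        store = self._store([0.5, -0.5], [1.0, 3.0])
        assert ewc_penalty({"w": np.array([0.5, -0.5])}, store, 0.4) == 0.0
        assert ewc_penalty({"w": np.array([9.0, 9.0])}, store, 0.0) == 0.0

    def test_shape_mismatch_rejected(self):
        store = self._store([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            ewc_penalty({"w": np.zeros(3)}, store, 0.4)

    def test_negative_importance_rejected(self):
        store = ImportanceStore()
        with pytest.raises(ValueError):
            store.append("t", {"w": np.zeros(2)}, {"w": np.array([1.0, -1.0])})


class TestLwfDistillation:
    def test_zero_when_student_matches_recorded_teacher(self):
        logits = np.random.default_rng(0).standard_normal((1, 3, 4, 4))
        val, _ = lwf_distillation(logits, logits, temperature=8.0)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_t1_reduction_to_soft_cross_entropy(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal((1, 3, 2, 2))
        s = rng.standard_normal((1, 3, 2, 2))
        val, _ = lwf_distillation(t, s, temperature=1.0)
        pt, ps = softmax(t, 1), softmax(s, 1)
        ce = float(-(pt * np.log(ps)).sum() / 4)
        ent = float(-(pt * np.log(pt)).sum() / 4)
        # KL = CE - teacher entropy: equivalent to CE up to a constant
        assert val == pytest.approx(ce - ent, abs=1e-9)

    def test_single_voxel_hand_case(self):
        # teacher logits (2,0), student (0,2), T=2 — independent recomputation
        t = np.array([2.0, 0.0]).reshape(1, 2, 1)
        s = np.array([0.0, 2.0]).reshape(1, 2, 1)
        val, _ = lwf_distillation(t, s, temperature=2.0)
        pt = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        ps = np.exp([0.0, 1.0]) / np.exp([0.0, 1.0]).sum()
        expected = 4.0 * float((pt * (np.log(pt) - np.log(ps))).sum())
        assert val == pytest.approx(expected, abs=1e-6)

    def test_requires_multi_head_mode(self, tiny_pair):
        cfg = TrainConfig(epochs=1, steps_per_epoch=2, method="lwf",
                          head_mode="single", seed=0)
        model = cs.build_model(tiny_pair[0], seed=0)
        with pytest.raises(ValueError, match="multi"):
            train_stage(model, tiny_pair[0], cfg, MethodState(), 0)


class TestMib:
    def test_harden_identity_at_alpha_one(self):
        p = np.array([[0.7], [0.2], [0.1]])[None]
        assert np.allclose(harden(p, 1.0), p, atol=1e-12)

    def test_harden_hand_computed_vector(self):
        p = np.array([[0.9], [0.1]])[None]
        q = harden(p, 0.9)
        expected = np.array([0.9, 0.1]) ** (1 / 0.9)
        expected /= expected.sum()
        assert np.allclose(q[0, :, 0], expected, atol=1e-9)

    def test_kd_minimum_is_hardened_teacher_entropy(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal((1, 3, 4))
        q = harden(softmax(t, 1), 0.9)
        # a student whose softmax equals the hardened teacher
        s = np.log(q)
        y = np.zeros((1, 4), dtype=np.int64)
        _, kd, _ = mib_losses(s, y, t, 0.9)
        entropy = float(-(q * np.log(q)).sum() / 4)
        assert kd == pytest.approx(entropy, abs=1e-9)

    def test_unbiased_ce_reduces_to_standard_ce(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal((1, 3, 5))
        y = rng.integers(0, 3, (1, 5))
        p = softmax(s, 1)
        ce_ref = float(-np.log(np.take_along_axis(p, y[:, None], 1)).mean())
        assert mib_ce(s, y, 3) == pytest.approx(ce_ref, abs=1e-12)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            harden(np.array([[0.5], [0.5]])[None], 0.0)


class TestRwUpdate:
    def test_alpha_one_keeps_last_squared_gradient(self):
        g1 = {"w": np.array([2.0])}
        g2 = {"w": np.array([3.0])}
        p = {"w": np.array([0.0])}
        state = rw_update(None, g1, p, p, alpha=1.0)
        state = rw_update(state, g2, p, p, alpha=1.0)
        assert state["fisher"]["w"][0] == pytest.approx(9.0)

    def test_zero_motion_leaves_score_unchanged(self):
        g = {"w": np.array([2.0])}
        p = {"w": np.array([1.0])}
        state = rw_update(None, g, p, p, alpha=0.5)
        assert state["score"]["w"][0] == 0.0

    def test_two_step_scalar_trace(self):
        """Hand-rolled trace: F ema and clipped -g*dtheta accumulation."""
        state = None
        # step 1: g=2, theta 0 -> -0.2  => F = .9*4 = 3.6 ; s = max(0, -2*-0.2)=0.4
        state = rw_update(state, {"w": np.array([2.0])},
                          {"w": np.array([0.0])}, {"w": np.array([-0.2])}, 0.9)
        # step 2: g=-1, theta -0.2 -> -0.1 => F = .9*1 + .1*3.6 = 1.26
        #         s += max(0, 1*0.1) = 0.1 -> 0.5
        state = rw_update(state, {"w": np.array([-1.0])},
                          {"w": np.array([-0.2])}, {"w": np.array([-0.1])}, 0.9)
        assert state["fisher"]["w"][0] == pytest.approx(1.26, abs=1e-12)
        assert state["score"]["w"][0] == pytest.approx(0.5, abs=1e-12)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            rw_update(None, {"w": np.zeros(1)}, {"w": np.zeros(1)},
                      {"w": np.zeros(1)}, alpha=1.5)


class TestStageMechanics:
    def test_equal_seeds_equal_trajectories(self, tiny_pair):
        cfg = TrainConfig(epochs=2, steps_per_epoch=4, seed=5)
        _, t1, _ = run_sequence(tiny_pair, cfg)
        _, t2, _ = run_sequence(tiny_pair, cfg)
        assert t1 == t2

    def test_trajectory_covers_every_task_every_epoch(self, tiny_pair):
        cfg = TrainConfig(epochs=2, steps_per_epoch=2, seed=5)
        _, traj, _ = run_sequence(tiny_pair, cfg)
        per_stage = 2 * len(tiny_pair)  # epochs * n validation tasks
        assert len(traj) == per_stage * len(tiny_pair)
        for rec in traj:
            assert 0.0 <= rec["dice"] <= 1.0

    def test_head_isolation_in_multi_head(self, tiny_pair):
        cfg = TrainConfig(epochs=1, steps_per_epoch=4, seed=2, head_mode="multi")
        model = cs.build_model(tiny_pair[0], seed=2, head_mode="multi")
        state = MethodState()
        train_stage(model, tiny_pair[0], cfg, state, 0)
        first = tiny_pair[0].task_id
        frozen = {k: v.copy() for k, v in model.heads[first].items()}
        cs.add_head(model, tiny_pair[1].task_id)
        train_stage(model, tiny_pair[1], cfg, state, 1)
        for k in frozen:
            assert (model.heads[first][k] == frozen[k]).all()

    def test_anchor_immutability(self, tiny_pair):
        cfg = TrainConfig(epochs=1, steps_per_epoch=4, seed=2, method="ewc")
        _, _, _ = run_sequence(tiny_pair[:1], cfg)
        # anchors recorded by a 2-stage run never change after their stage
        from contiseg.trainers import MethodState, _post_stage
        model = cs.build_model(tiny_pair[0], seed=2)
        st = MethodState()
        train_stage(model, tiny_pair[0], cfg, st, 0)
        _post_stage(model, tiny_pair[0], cfg, st)
        _, theta0, omega0 = st.importance.anchors[0]
        snap_t = {k: v.copy() for k, v in theta0.items()}
        snap_o = {k: v.copy() for k, v in omega0.items()}
        cs.add_head(model, tiny_pair[1].task_id)
        train_stage(model, tiny_pair[1], cfg, st, 1)
        _post_stage(model, tiny_pair[1], cfg, st)
        _, theta0b, omega0b = st.importance.anchors[0]
        assert all((theta0b[k] == snap_t[k]).all() for k in snap_t)
        assert all((omega0b[k] == snap_o[k]).all() for k in snap_o)

    def test_lwf_three_phase_runs_and_preserves_recording(self, tiny_pair):
        cfg = TrainConfig(epochs=3, steps_per_epoch=3, seed=4, method="lwf",
                          head_mode="multi")
        model, traj, evals = run_sequence(tiny_pair, cfg)
        assert len(model.heads) == 2
        assert {e["stage_task"] for e in evals} == {t.task_id for t in tiny_pair}

    def test_mib_stage_runs_with_teacher(self, tiny_pair):
        cfg = TrainConfig(epochs=1, steps_per_epoch=3, seed=4, method="mib")
        model, _, evals = run_sequence(tiny_pair, cfg)
        assert len(evals) == 2
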