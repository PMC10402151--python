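"""A2C loss pieces, returns, the outer training loop, and solution labels."""

import numpy as np
import pytest

import metaplast as mp
from metaplast import _engine
from metaplast.meta_trainer import (
    TrainConfig,
    a2c_loss,
    classify_solution,
    modulator_reward_split,
    returns_and_advantages,
    train,
)
from metaplast.task_env import EpisodeSpec, TrialSpec, make_stimuli


class TestReturnsAndAdvantages:
    def test_single_rewarded_trial_hand_recursion(self, rng):
        """gamma=1, one trial with reward +1, zero critic -> advantage +1."""
        params = mp.init_params(10, rng, scale=0.0)
        ep = mp.make_episode(4, rng,
                             trials=mp.schedule_standard(4, rng)[:1])
        trace = mp.run_episode(params, ep, rng)
        returns, adv = returns_and_advantages(trace, gamma=1.0,
                                              last10_weight=4.0)
        reward = trace.rewards[0]
        # a single trial is within the "last 10", hence weighted by 4
        assert returns[0] == returns[1] == returns[2] == 4.0 * reward
        assert returns[3] == 0.0
        assert adv[0] == 4.0 * reward  # critic is identically zero

    def test_zero_rewards_zero_critic_gives_zero_advantage(self, rng):
        params = mp.init_params(10, rng, scale=0.0)
        ep = mp.make_episode(4, rng)
        trace = mp.run_episode(params, ep, rng)
        for rec in trace.trials:
            rec.reward = 0
        _, adv = returns_and_advantages(trace, 0.9, 4.0)
        assert np.allclose(adv, 0.0)

    def test_discount_recursion_against_direct_sum(self, rng):
        params = mp.init_params(10, rng)
        ep = mp.make_episode(5, rng)
        trace = mp.run_episode(params, ep, rng)
        gamma = 0.7
        returns, _ = returns_and_advantages(trace, gamma, 1.0)
        # direct evaluation at a handful of steps
        rewards = np.zeros(120)
        rewards[2::4] = trace.rewards
        for g in (0, 17, 63, 118):
            direct = sum(rewards[u] * gamma ** (u - g) for u in range(g, 120))
            assert np.isclose(returns[g], direct, atol=1e-10)

    def test_last10_reward_counts_four_fold(self, rng):
        params = mp.init_params(10, rng)
        ep = mp.make_episode(5, rng)
        trace = mp.run_episode(params, ep, rng)
        base, _ = returns_and_advantages(trace, 1.0, 1.0)
        wtd, _ = returns_and_advantages(trace, 1.0, 4.0)
        # contribution of trial 25's reward = (weighted - unweighted) at its step
        step = 24 * 4 + 2
        early_step = 4 * 4 + 2
        assert np.isclose(wtd[step], 4.0 * base[step])
        # an early-trial reward's own contribution is unweighted
        assert np.isclose(wtd[early_step] - base[early_step],
                          3.0 * base[step])


class TestA2CLoss:
    def test_hand_computed_single_trial(self, rng):
        params = mp.init_params(10, rng, scale=0.0)  # uniform policy, v = 0
        ep = mp.make_episode(4, rng, trials=mp.schedule_standard(4, rng)[:1])
        trace = mp.run_episode(params, ep, rng)
        cfg = TrainConfig(gamma=1.0, value_coef=0.5, entropy_coef=0.1,
                          n_episodes=0)
        loss, parts = a2c_loss([trace], params, cfg)
        g = 4.0 * trace.rewards[0]  # weighted return at the response step
        expected = -np.log(0.5) * g + 0.5 * g ** 2 - 0.1 * np.log(2.0)
        assert np.isclose(loss, expected, atol=1e-12)
        # entropy of a uniform 2-way policy is log 2 per response step
        assert np.isclose(parts["entropy"], np.log(2.0), atol=1e-12)

    def test_matches_engine_loss_terms(self, rng):
        params = mp.init_params(12, rng)
        eps = [mp.make_episode(4, rng) for _ in range(3)]
        uni = np.random.default_rng(3).random((30, 3))
        tape = _engine.rollout(params, eps, uniforms=uni)
        terms = _engine.loss_terms(tape, 0.9, 4.0, 0.1, 0.03)
        # replay the same episodes through the single-run simulator
        traces = []
        for b, ep in enumerate(eps):
            class _F:
                def __init__(self, u):
                    self.u = list(u)

                def random(self):
                    return self.u.pop(0)
            traces.append(mp.run_episode(params, ep, _F(uni[:, b].copy())))
        cfg = TrainConfig(gamma=0.9, value_coef=0.1, entropy_coef=0.03,
                          n_episodes=0)
        loss, _ = a2c_loss(traces, params, cfg)
        assert np.isclose(loss, terms["loss"], rtol=1e-10)


class TestTrain:
    def test_zero_episodes_returns_init_unchanged(self):
        cfg = TrainConfig(n_episodes=0, n=10, seed=1)
        rng = np.random.default_rng(cfg.seed)
        expected = mp.init_params(10, rng)
        result = train(cfg)
        assert np.array_equal(result.params.w_rec, expected.w_rec)
        assert result.performance_curve.size == 0

    def test_reproducible_curves(self):
        cfg = TrainConfig(n_episodes=40, batch_size=8, n=16, seed=7,
                          n_items_min=4, n_items_max=5)
        r1 = train(cfg)
        r2 = train(cfg)
        assert np.array_equal(r1.performance_curve, r2.performance_curve)
        assert np.array_equal(r1.loss_curve, r2.loss_curve)

    def test_curve_lengths(self):
        cfg = TrainConfig(n_episodes=40, batch_size=8, n=16, seed=0,
                          n_items_min=4, n_items_max=5)
        res = train(cfg)
        assert res.performance_curve.shape == (40,)
        assert res.loss_curve.shape == (5,)

    def test_batch_must_divide_episodes(self):
        with pytest.raises(ValueError):
            TrainConfig(n_episodes=41, batch_size=8)

    def test_bandit_stub_recovers_better_arm(self):
        """Single-trial episodes where slot 1 always holds the higher item:
        pure policy learning (no plasticity needed) must commit to arm 1."""
        rng = np.random.default_rng(0)
        params = mp.init_params(16, rng, plast_mean=0.0, plast_gain=0.0)
        from metaplast.meta_trainer import Adam, clip_grad_norm
        opt = Adam(params, lr=3e-2)
        for _ in range(300):
            eps = []
            for _ in range(8):
                stim = make_stimuli(4, 15, rng)
                lo, hi = sorted(rng.choice(4, 2, replace=False))
                eps.append(EpisodeSpec(4, stim,
                                       [TrialSpec(int(lo), int(hi))]))
            tape = _engine.rollout(params, eps, rng=rng)
            _, grads = _engine.backward(params, tape, 1.0, 4.0, 0.05, 0.01)
            clip_grad_norm(grads, 1.0)
            opt.step(params, grads)
        # evaluate deterministically: probability of choosing slot 1
        eps = []
        for _ in range(200):
            stim = make_stimuli(4, 15, rng)
            lo, hi = sorted(rng.choice(4, 2, replace=False))
            eps.append(EpisodeSpec(4, stim, [TrialSpec(int(lo), int(hi))]))
        tape = _engine.rollout(params, eps, rng=rng, keep_tape=False)
        assert tape.o2[0, :, 0].mean() > 0.99


class TestClassifier:
    def _tape_with_modulator(self, m3_split, m4_split, perf, rng, B=600):
        """Hand-constructed rollout tape with planted modulator statistics."""
        n_trials = 30
        T = n_trials * 4
        rewards = np.where(rng.random((n_trials, B)) < perf, 1, -1)
        m = np.zeros((T, B))
        m[2::4] = -0.1 + m3_split * (rewards > 0)   # m(3)
        m[3::4] = -0.2 + m4_split * (rewards > 0)   # m(4)
        return _engine.RolloutTape(
            episodes=[None] * B, inputs=None, x=np.zeros((T, B, 1)),
            r=None, m=m, value=None, o2=None,
            responses=np.ones((n_trials, B), dtype=int),
            rewards=rewards, p_trial_start=None, p_snapshots=None,
            p_snapshot_trial=None)

    def test_planted_cases_recovered(self, small_params, rng):
        passive = self._tape_with_modulator(0.8, 0.05, 0.75, rng)
        cognitive = self._tape_with_modulator(0.05, 0.8, 0.85, rng)
        failed = self._tape_with_modulator(0.8, 0.05, 0.50, rng)
        assert classify_solution(small_params, passive)["label"] == "passive"
        assert classify_solution(small_params, cognitive)["label"] == "cognitive"
        assert classify_solution(small_params, failed)["label"] == "failed"

    def test_too_few_traces_rejected(self, small_params, rng):
        tape = self._tape_with_modulator(0.5, 0.5, 0.8, rng, B=100)
        with pytest.raises(ValueError):
            classify_solution(small_params, tape)

    def test_constant_modulator_has_zero_split(self, rng):
        tape = self._tape_with_modulator(0.0, 0.0, 0.8, rng)
        m3 = tape.m[2::4]
        m4 = tape.m[3::4]
        stats = modulator_reward_split(m3, m4, tape.rewards)
        assert stats["m3_split"] < 1e-12
        assert stats["m4_split"] < 1e-12
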