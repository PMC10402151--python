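"""Recoded-basis optimization and reinstatement probing."""

import numpy as np
import pytest

import metaplast as mp
from metaplast import _engine, reinstatement as rs
from metaplast.probe_analysis import decision_axis, pearson


@pytest.fixture(scope="module")
def fitted_basis(planted):
    rng = np.random.default_rng(5)
    return rs.optimize_recoded_basis(planted.params, planted.p,
                                     planted.stimuli, n_restarts=5,
                                     rng=rng)


class TestOptimizeRecodedBasis:
    def test_unit_norms(self, fitted_basis):
        norms = np.linalg.norm(fitted_basis.psi_tilde, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-10
        assert abs(np.linalg.norm(fitted_basis.w_tilde) - 1.0) < 1e-10

    def test_shift_gains_positive(self, fitted_basis):
        assert (fitted_basis.shift_gains > 0).all()

    def test_objective_monotone(self, fitted_basis):
        tr = fitted_basis.objective_trace
        assert (np.diff(tr) >= -1e-9 * np.abs(tr[:-1])).all()

    def test_uniform_plasticity_linear_limit(self, rng):
        """With constant A and linearization at zero, the recoded vectors
        collapse onto the originals: psi_tilde ∝ psi_t1, w_tilde ∝ axis."""
        params = mp.init_params(40, rng)
        params.a = np.ones((40, 40))
        stim = mp.make_stimuli(6, 15, rng)
        basis = rs.optimize_recoded_basis(params, np.zeros((40, 40)), stim,
                                          n_restarts=3, linearize_at="zero",
                                          rng=rng)
        axis = decision_axis(params).vector
        assert abs(pearson(basis.w_tilde, axis)) > 0.999
        from metaplast.probe_analysis import probe_item
        for i, s in enumerate(stim):
            psi1, _ = probe_item(params, np.zeros((40, 40)), s)
            assert abs(pearson(basis.psi_tilde[i], psi1)) > 0.999

    def test_deterministic_given_rng_seed(self, planted):
        b1 = rs.optimize_recoded_basis(planted.params, planted.p,
                                       planted.stimuli, n_restarts=2,
                                       rng=np.random.default_rng(3))
        b2 = rs.optimize_recoded_basis(planted.params, planted.p,
                                       planted.stimuli, n_restarts=2,
                                       rng=np.random.default_rng(3))
        assert np.array_equal(b1.psi_tilde, b2.psi_tilde)


def _tape_with_r2(r2, n_items, rng, trial_index=19, n=None):
    """Minimal tape whose step-2 activity at ``trial_index`` is ``r2``."""
    B, n = r2.shape
    tape_r = np.zeros((120, B, n))
    tape_r[trial_index * 4 + 1] = r2
    eps = [mp.make_episode(n_items, rng) for _ in range(B)]
    return _engine.RolloutTape(
        episodes=eps, inputs=None, x=None, r=tape_r, m=None, value=None,
        o2=None, responses=np.ones((30, B), dtype=int),
        rewards=np.ones((30, B), dtype=int), p_trial_start=None,
        p_snapshots=None, p_snapshot_trial=None)


class TestReinstatementProfile:
    def test_planted_difference_pattern(self, planted, fitted_basis, rng):
        """r(2) = psi_tilde(D) - psi_tilde(E) correlates positively with D
        and negatively with E (up to basis overlap)."""
        d, e = 3, 4
        r2 = np.tile(fitted_basis.psi_tilde[d] - fitted_basis.psi_tilde[e],
                     (8, 1))
        tape = _tape_with_r2(r2, 8, rng)
        prof = rs.reinstatement_profile(tape, fitted_basis, 19)
        step2 = prof[prof.step == 2].groupby("item")["corr"].mean()
        # expected values follow from the basis overlap itself
        expect_d = pearson(r2[0], fitted_basis.psi_tilde[d])
        expect_e = pearson(r2[0], fitted_basis.psi_tilde[e])
        assert np.isclose(step2[d], expect_d, atol=1e-10)
        assert np.isclose(step2[e], expect_e, atol=1e-10)
        assert step2[d] > 0.4 and step2[e] < -0.4
        assert step2[d] > step2.drop([d, e]).abs().max()

    def test_sign_flip_invariance(self, planted, fitted_basis, rng):
        """Flipping a basis vector's sign flips its correlations and nothing
        else (reported quantities are sign-covariant)."""
        r2 = np.tile(fitted_basis.psi_tilde[2], (4, 1))
        tape = _tape_with_r2(r2, 8, rng)
        prof1 = rs.reinstatement_profile(tape, fitted_basis, 19)
        import dataclasses
        flipped = dataclasses.replace(
            fitted_basis, psi_tilde=fitted_basis.psi_tilde
            * np.where(np.arange(8) == 2, -1.0, 1.0)[:, None])
        prof2 = rs.reinstatement_profile(tape, flipped, 19)
        c1 = prof1[prof1.step == 2].groupby("item")["corr"].mean()
        c2 = prof2[prof2.step == 2].groupby("item")["corr"].mean()
        assert np.isclose(c2[2], -c1[2])
        others = [i for i in range(8) if i != 2]
        assert np.allclose(c2[others], c1[others])

    def test_checkpoint_hash_mismatch_rejected(self, fitted_basis, rng,
                                               planted):
        import dataclasses
        basis = dataclasses.replace(fitted_basis, checkpoint_hash="aaa")
        tape = _tape_with_r2(np.zeros((2, planted.params.n)), 8, rng)
        with pytest.raises(ValueError):
            rs.reinstatement_profile(tape, basis, 19, checkpoint_hash="bbb")


def test_axis_reinstatement_detects_signed_pattern(planted, fitted_basis, rng):
    """r(3) containing ±w_tilde is detected with the matching sign."""
    n = planted.params.n
    signs = np.array([1.0, -1.0, 1.0, -1.0])
    r3 = signs[:, None] * fitted_basis.w_tilde + 0.01 * rng.standard_normal((4, n))
    tape_r = np.zeros((120, 4, n))
    tape_r[19 * 4 + 2] = r3
    eps = [mp.make_episode(8, rng) for _ in range(4)]
    responses = np.ones((30, 4), dtype=int)
    responses[19] = np.where(signs > 0, 1, 2)
    tape = _engine.RolloutTape(
        episodes=eps, inputs=None, x=None, r=tape_r, m=None, value=None,
        o2=None, responses=responses, rewards=np.ones((30, 4), dtype=int),
        p_trial_start=None, p_snapshots=None, p_snapshot_trial=None)
    out = rs.axis_reinstatement(tape, fitted_basis, 19)
    assert (np.sign(out["corr"]) == signs).all()
    assert (out[out.response == 1]["corr"] > 0.9).all()
    assert (out[out.response == 2]["corr"] < -0.9).all()


class TestOriginalRepresentationControl:
    def test_self_correlation_at_step1(self, planted, rng):
        """Probing with psi_t1 detects the literally presented pattern."""
        from metaplast.probe_analysis import probe_item
        n = planted.params.n
        B = 4
        eps = [mp.make_episode(8, rng) for _ in range(B)]
        tape_r = np.zeros((120, B, n))
        for b, ep in enumerate(eps):
            psi1, _ = probe_item(planted.params, planted.p, ep.stimuli[0])
            tape_r[19 * 4 + 0, b] = psi1
        tape = _engine.RolloutTape(
            episodes=eps, inputs=None, x=None, r=tape_r, m=None, value=None,
            o2=None, responses=np.ones((30, B), dtype=int),
            rewards=np.ones((30, B), dtype=int), p_trial_start=None,
            p_snapshots=None, p_snapshot_trial=None)
        prof = rs.original_representation_control(tape, planted.params, 19,
                                                  p_frozen=planted.p)
        step1 = prof[(prof.step == 1) & (prof.item == 0)]["corr"]
        assert (step1 > 0.999).all()


class TestNoiseBand:
    def test_band_contains_random_correlations(self, rng):
        ref = rng.standard_normal(100)
        lo, hi = rs.noise_band(None, ref, n_draws=500, rng=rng)
        assert lo < 0 < hi
        assert hi < 0.5  # random unit vectors in N=100 correlate weakly


class TestReinstatementVsShift:
    def test_shuffled_labels_kill_association(self, planted, fitted_basis,
                                              rng):
        """Shuffling the shift labels destroys the rank correlation: the
        permutation null is centered on zero."""
        from scipy import stats
        # an untrained network with nonzero modulator: shifts exist but are
        # unrelated to the (planted-basis) reinstatement strengths
        params = mp.init_params(planted.params.n, rng)
        eps = [mp.make_episode(8, rng) for _ in range(30)]
        tape = _engine.rollout(params, eps, rng=rng, keep_tape=False,
                               p_snapshot_trial=19)
        res = rs.reinstatement_vs_shift(tape, fitted_basis, params,
                                        n_perm=300, rng=rng)
        assert len(res["table"]) == 30 * 8
        x = res["table"].reinstatement.values
        y = rng.permutation(res["table"]["shift"].values)
        null_rhos = [stats.spearmanr(x, rng.permutation(y)).statistic
                     for _ in range(50)]
        assert abs(np.mean(null_rhos)) < 0.05
        assert abs(stats.spearmanr(x, y).statistic) < 0.25
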