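"""Batched episode rollout with hand-written reverse-mode differentiation.

The outer (meta-training) loop needs gradients of the A2C loss with respect
to every structural parameter, propagated through all time steps of an
episode *including* the Hebbian plastic updates.  This module implements
that computation directly in numpy:

* ``rollout`` runs a batch of episodes forward, sampling responses at step 2
  of every trial, and records a tape of per-step activations plus the
  plastic weights at each trial start.
* ``backward`` replays each trial from its stored start (H and r are zero
  there, so the trial-start P fully determines within-trial state) and
  accumulates parameter gradients in reverse over the whole episode, with
  the gradient of P flowing across trial boundaries.

Memory therefore scales with (n_trials x batch x N^2) for the trial-start
checkpoints rather than (n_steps x batch x N^2).

The backward pass exploits the trial structure: the eligibility trace is
identically zero during steps 1-2 (activity is reset at trial start), so
the plastic weights change only at steps 3 and 4, and the only nonzero
trace states inside a trial are H(3) = eta x(2) r(1)^T and
H(4) = eta x(3) r(2)^T + (1 - eta) H(3).

``dtype=float32`` roughly halves the wall time (the computation is memory-
bound); the default float64 is what the finite-difference gradient check
runs against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plastic_net import NumericalError, StructuralParams
from .task_env import EpisodeSpec, INPUT_DIM, STEPS_PER_TRIAL, STIM_DIM

_S = STEPS_PER_TRIAL


@dataclass
class RolloutTape:
    """Forward record of a batch of episodes (steps indexed 0..T-1)."""

    episodes: list[EpisodeSpec]
    inputs: np.ndarray       # (T, B, INPUT_DIM)
    x: np.ndarray            # (T, B, N)
    r: np.ndarray            # (T, B, N)
    m: np.ndarray            # (T, B)
    value: np.ndarray        # (T, B)
    o2: np.ndarray           # (n_trials, B, 2) policy at response steps
    responses: np.ndarray    # (n_trials, B) in {1, 2}
    rewards: np.ndarray      # (n_trials, B) in {-1, +1}
    p_trial_start: np.ndarray | None  # (n_trials, B, N, N)
    p_snapshots: np.ndarray | None    # (5, B, N, N) around one chosen trial
    p_snapshot_trial: int | None

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def batch_size(self) -> int:
        return self.responses.shape[1]

    @property
    def performance(self) -> np.ndarray:
        """Per-episode fraction correct over the last 10 trials."""
        return (self.rewards[-10:] > 0).mean(axis=0)


def _softmax2(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _bmv(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Batched matrix-vector product: (B,N,N) x (B,N) -> (B,N)."""
    return np.matmul(w, v[:, :, None])[:, :, 0]


def _bmv_t(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Batched transposed product: w^T v per batch element."""
    return np.matmul(v[:, None, :], w)[:, 0, :]


def rollout(params: StructuralParams, episodes: list[EpisodeSpec],
            rng: np.random.Generator | None = None,
            uniforms: np.ndarray | None = None,
            keep_tape: bool = True,
            p_snapshot_trial: int | None = None,
            dtype: np.dtype = np.float64) -> RolloutTape:
    """Run a batch of episodes forward (vectorized over the batch).

    All episodes must share the same trial count.  Responses are sampled at
    step 2 of each trial from pre-drawn ``uniforms`` (shape (n_trials, B)) or
    from ``rng``; pre-drawn uniforms make the rollout a deterministic
    function of the parameters, which the finite-difference gradient check
    relies on.

    ``p_snapshot_trial`` records P at entry to that trial and after each of
    its four steps (for stepwise representation-change analyses).
    """
    n_trials = episodes[0].n_trials
    if any(e.n_trials != n_trials for e in episodes):
        raise ValueError("all episodes in a batch must share the trial count")
    B, N = len(episodes), params.n
    T = n_trials * _S
    if uniforms is None:
        if rng is None:
            raise ValueError("provide either rng or pre-drawn uniforms")
        uniforms = rng.random((n_trials, B))

    w_in = params.w_in.astype(dtype, copy=False)
    w_rec = params.w_rec.astype(dtype, copy=False)
    a = params.a.astype(dtype, copy=False)
    w_out = params.w_out.astype(dtype, copy=False)
    w_mod = params.w_mod.astype(dtype, copy=False)
    w_val = params.w_val.astype(dtype, copy=False)
    eta = dtype(params.eta) if dtype == np.float32 else params.eta

    # Stimulus part of the input is schedule-determined; feedback fields are
    # filled in at run time from the sampled responses.
    inputs = np.zeros((T, B, INPUT_DIM), dtype=dtype)
    correct_resp = np.empty((n_trials, B), dtype=np.int64)
    for b, ep in enumerate(episodes):
        for t, trial in enumerate(ep.trials):
            inputs[t * _S, b, :STIM_DIM] = ep.stimuli[trial.rank1]
            inputs[t * _S, b, STIM_DIM:2 * STIM_DIM] = ep.stimuli[trial.rank2]
            correct_resp[t, b] = trial.correct_response

    xs = np.empty((T, B, N), dtype=dtype)
    rs = np.empty((T, B, N), dtype=dtype)
    ms = np.empty((T, B), dtype=dtype)
    vs = np.empty((T, B), dtype=dtype)
    o2 = np.empty((n_trials, B, 2), dtype=dtype)
    responses = np.empty((n_trials, B), dtype=np.int64)
    rewards = np.empty((n_trials, B), dtype=np.int64)
    p_starts = np.empty((n_trials, B, N, N), dtype=dtype) if keep_tape else None
    snaps = (np.empty((_S + 1, B, N, N), dtype=dtype)
             if p_snapshot_trial is not None else None)

    p = np.zeros((B, N, N), dtype=dtype)
    w_eff = np.broadcast_to(w_rec, (B, N, N))
    arange_b = np.arange(B)

    for t in range(n_trials):
        base = t * _S
        if keep_tape:
            p_starts[t] = p
        if p_snapshot_trial == t:
            snaps[0] = p
        for k in range(_S):
            g = base + k
            x = inputs[g] @ w_in.T
            if k > 0:
                x += _bmv(w_eff, rs[g - 1])
            if not np.all(np.isfinite(x)):
                raise NumericalError("non-finite activations in rollout", step=g)
            r_new = np.tanh(x)
            ms[g] = r_new @ w_mod
            vs[g] = r_new @ w_val
            if k == 1:
                o = _softmax2(r_new @ w_out.T)
                o2[t] = o
                resp = np.where(uniforms[t] < o[:, 0], 1, 2)
                responses[t] = resp
                rew = np.where(resp == correct_resp[t], 1, -1)
                rewards[t] = rew
                # feedback input at step 3: reward scalar + response one-hot
                inputs[g + 1, :, 2 * STIM_DIM] = rew
                inputs[g + 1, arange_b, 2 * STIM_DIM + resp] = 1.0
            elif k == 2:
                # P <- P + m(3) H(3), with H(3) = eta x(2) r(1)^T
                coef = eta * ms[g]
                p += coef[:, None, None] * xs[g - 1][:, :, None] \
                    * rs[g - 2][:, None, :]
                w_eff = w_rec + a * p
            elif k == 3:
                # P <- P + m(4) [eta x(3) r(2)^T + (1 - eta) H(3)]
                c4 = eta * ms[g]
                c3 = (1.0 - eta) * eta * ms[g]
                p += c4[:, None, None] * xs[g - 1][:, :, None] \
                    * rs[g - 2][:, None, :]
                p += c3[:, None, None] * xs[g - 2][:, :, None] \
                    * rs[g - 3][:, None, :]
                w_eff = w_rec + a * p
            xs[g], rs[g] = x, r_new
            if p_snapshot_trial == t:
                snaps[k + 1] = p
    return RolloutTape(list(episodes), inputs, xs, rs, ms, vs, o2,
                       responses, rewards, p_starts, snaps, p_snapshot_trial)


def discounted_returns(rewards: np.ndarray, n_trials: int, gamma: float,
                       last10_weight: float) -> np.ndarray:
    """Per-step discounted returns over the flattened episode.

    ``rewards`` is (n_trials, B); the reward of trial t lands on global step
    4t + 2 (the feedback step).  Rewards of the last 10 trials are multiplied
    by ``last10_weight`` — this affects the meta-learning loss only, never
    the reward signal the network receives as input.
    """
    B = rewards.shape[1]
    T = n_trials * _S
    w = np.ones(n_trials)
    w[max(0, n_trials - 10):] = last10_weight
    step_rewards = np.zeros((T, B))
    step_rewards[2::_S] = rewards * w[:, None]
    returns = np.zeros((T, B))
    acc = np.zeros(B)
    for g in range(T - 1, -1, -1):
        acc = step_rewards[g] + gamma * acc
        returns[g] = acc
    return returns


def loss_terms(tape: RolloutTape, gamma: float, last10_weight: float,
               value_coef: float, entropy_coef: float,
               adv_norm: bool = False) -> dict:
    """A2C loss pieces computed from a rollout tape (no gradients).

    loss = -sum logpi(a) * advantage + value_coef * sum (G - v)^2
           - entropy_coef * sum entropy,   averaged over the batch,
    with the advantage G - v at each response step treated as a constant for
    the policy term.  ``adv_norm`` standardizes the advantages used by the
    policy term across the batch (a standard variance-reduction device; the
    value target is unaffected).
    """
    n_trials, B = tape.n_trials, tape.batch_size
    returns = discounted_returns(tape.rewards, n_trials, gamma, last10_weight)
    resp_steps = np.arange(n_trials) * _S + 1
    g_resp = returns[resp_steps]                      # (n_trials, B)
    v_resp = tape.value[resp_steps]
    adv = g_resp - v_resp
    if adv_norm:
        adv_pol = (adv - adv.mean()) / (adv.std() + 1e-8)
    else:
        adv_pol = adv
    a_idx = tape.responses - 1                        # 0/1
    logp = np.log(np.take_along_axis(tape.o2, a_idx[:, :, None], axis=2))[:, :, 0]
    entropy = -(tape.o2 * np.log(tape.o2)).sum(axis=2)
    policy_loss = -(logp * adv_pol).sum(axis=0).mean()
    value_loss = (adv ** 2).sum(axis=0).mean()
    entropy_term = entropy.sum(axis=0).mean()
    total = policy_loss + value_coef * value_loss - entropy_coef * entropy_term
    return {
        "loss": float(total),
        "policy_loss": float(policy_loss),
        "value_loss": float(value_loss),
        "entropy": float(entropy_term),
        "returns": returns,
        "advantages": adv,
        "advantages_policy": adv_pol,
        "mean_reward": float(tape.rewards.mean()),
    }


def backward(params: StructuralParams, tape: RolloutTape, gamma: float,
             last10_weight: float, value_coef: float, entropy_coef: float,
             adv_norm: bool = False) -> tuple[dict, dict]:
    """Gradients of the A2C loss w.r.t. every structural parameter.

    Rebuilds the two nonzero within-trial trace states from the stored
    trial-start P, then walks each trial backward.  The gradient with
    respect to P flows across trial boundaries; gradients with respect to r
    and H are cut there by the per-trial reset.
    """
    if tape.p_trial_start is None:
        raise ValueError("rollout was run without keep_tape=True")
    n_trials, B, N = tape.n_trials, tape.batch_size, params.n
    dtype = tape.x.dtype.type
    eta = params.eta
    w_rec = params.w_rec.astype(tape.x.dtype, copy=False)
    a = params.a.astype(tape.x.dtype, copy=False)
    w_out = params.w_out.astype(tape.x.dtype, copy=False)
    w_mod = params.w_mod.astype(tape.x.dtype, copy=False)
    w_val = params.w_val.astype(tape.x.dtype, copy=False)

    terms = loss_terms(tape, gamma, last10_weight, value_coef, entropy_coef,
                       adv_norm=adv_norm)
    adv = terms["advantages"].astype(tape.x.dtype)
    adv_pol = terms["advantages_policy"].astype(tape.x.dtype)

    grads = {
        "w_in": np.zeros((N, INPUT_DIM), dtype=tape.x.dtype),
        "w_rec": np.zeros((N, N), dtype=tape.x.dtype),
        "a": np.zeros((N, N), dtype=tape.x.dtype),
        "w_out": np.zeros((2, N), dtype=tape.x.dtype),
        "w_mod": np.zeros(N, dtype=tape.x.dtype),
        "w_val": np.zeros(N, dtype=tape.x.dtype),
    }
    g_eta = 0.0
    g_p = np.zeros((B, N, N), dtype=tape.x.dtype)

    for t in range(n_trials - 1, -1, -1):
        base = t * _S
        x0, x1, x2, x3 = (tape.x[base + k] for k in range(4))
        r0, r1, r2, r3 = (tape.r[base + k] for k in range(4))
        m2, m3 = tape.m[base + 2], tape.m[base + 3]
        p_start = tape.p_trial_start[t]
        # nonzero within-trial trace states
        h2 = eta * x1[:, :, None] * r0[:, None, :]         # H(3)
        h3 = eta * x2[:, :, None] * r1[:, None, :] + (1.0 - eta) * h2  # H(4)
        p3 = p_start + m2[:, None, None] * h2              # P during step 4

        # ---- step 4 (k=3): m(4) gates H(4) into P -----------------------
        g_m = np.einsum("bij,bij->b", g_p, h3)
        grads["w_mod"] += g_m @ r3
        g_r = g_m[:, None] * w_mod
        g_x = (1.0 - r3 ** 2) * g_r
        outer3 = g_x[:, :, None] * r2[:, None, :]
        grads["w_rec"] += outer3.sum(axis=0)
        grads["a"] += np.einsum("bij,bij->ij", p3, outer3)
        g_r_next = _bmv_t(w_rec + a * p3, g_x)
        g_h = m3[:, None, None] * g_p                      # dL/dH(4)
        g_p = g_p + a * outer3
        # eta gradient from H(4) = eta x2 r1^T + (1-eta) H(3)
        g_eta += float(np.einsum("bij,bi,bj->", g_h, x2, r1)
                       - np.einsum("bij,bij->", g_h, h2))

        # ---- step 3 (k=2): m(3) gates H(3); reward input arrives --------
        g_m = np.einsum("bij,bij->b", g_p, h2)
        grads["w_mod"] += g_m @ r2
        g_r = g_r_next + g_m[:, None] * w_mod
        g_x = (1.0 - r2 ** 2) * g_r + eta * _bmv(g_h, r1)
        grads["w_in"] += g_x.T @ tape.inputs[base + 2]
        outer2 = g_x[:, :, None] * r1[:, None, :]
        grads["w_rec"] += outer2.sum(axis=0)
        w_eff01 = w_rec + a * p_start
        g_r_next = _bmv_t(w_eff01, g_x) + eta * np.einsum(
            "bij,bi->bj", g_h, x2, optimize=True)
        g_h = m2[:, None, None] * g_p + (1.0 - eta) * g_h  # dL/dH(3)
        g_p = g_p + a * outer2
        # eta gradient from H(3) = eta x1 r0^T  (H(2) = 0)
        g_eta += float(np.einsum("bij,bi,bj->", g_h, x1, r0))

        # ---- step 2 (k=1): response step; policy/value/entropy terms ----
        o = tape.o2[t]
        onehot = np.zeros((B, 2), dtype=dtype)
        onehot[np.arange(B), tape.responses[t] - 1] = 1.0
        ent = -(o * np.log(o)).sum(axis=1)
        g_z = (o - onehot) * adv_pol[t][:, None] / B
        g_z += entropy_coef * o * (np.log(o) + ent[:, None]) / B
        g_v = (-2.0 * value_coef / B) * adv[t]
        grads["w_out"] += np.einsum("bk,bi->ki", g_z, r1)
        grads["w_val"] += g_v @ r1
        g_r = g_r_next + g_z @ w_out + g_v[:, None] * w_val
        g_x = (1.0 - r1 ** 2) * g_r + eta * _bmv(g_h, r0)
        outer1 = g_x[:, :, None] * r0[:, None, :]
        grads["w_rec"] += outer1.sum(axis=0)
        # steps 2 and 3 both run on the trial-start plastic weights
        grads["a"] += np.einsum("bij,bij->ij", p_start, outer1 + outer2)
        g_r_next = _bmv_t(w_eff01, g_x) + eta * np.einsum(
            "bij,bi->bj", g_h, x1, optimize=True)
        g_p = g_p + a * outer1
        # (H gradient dies here: the trial-start trace is identically zero)

        # ---- step 1 (k=0): stimulus input; r_prev = 0 --------------------
        g_x = (1.0 - r0 ** 2) * g_r_next
        grads["w_in"] += g_x.T @ tape.inputs[base]
        # P enters step 1 only through the (zero) recurrent term

    out = {k: np.asarray(v, dtype=np.float64) for k, v in grads.items()}
    # eta is trained through a sigmoid; chain rule to the logit
    out["eta_logit"] = float(g_eta * eta * (1.0 - eta))
    return terms, out
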