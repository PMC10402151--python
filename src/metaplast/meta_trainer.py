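"""Outer-loop meta-training of the plastic network with A2C.

Within an episode the network learns through its own plasticity; between
episodes the structural parameters are improved by gradient descent on an
actor-critic objective, with gradients backpropagated through every time
step of the episode including the plastic weight updates.  Rewards from the
last 10 (all-pairs) trials are up-weighted in the loss so that meta-training
optimizes end-of-episode knowledge rather than early-trial guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _engine
from .plastic_net import (
    EpisodeTrace,
    NumericalError,
    PARAM_NAMES,
    StructuralParams,
    init_params,
)
from .task_env import EpisodeSpec, STEPS_PER_TRIAL, make_episode


@dataclass
class TrainConfig:
    """Meta-training settings.

    Defaults mirror the reference task: 30 000 episodes, lists of 4-9 items,
    last-10 rewards up-weighted by 4.  Optimizer settings are conventional
    for small recurrent policies: Adam, gradient-norm clipping at 1.0.
    """

    n_episodes: int = 30_000
    batch_size: int = 16
    gamma: float = 0.9
    last10_weight: float = 4.0
    value_coef: float = 0.05
    entropy_coef: float = 0.03
    lr: float = 1e-3
    grad_clip: float = 1.0
    adv_norm: bool = True
    compute_dtype: str = "float32"  # float64 for bit-level reproducibility
    n: int = 200
    n_items_min: int = 4
    n_items_max: int = 9
    seed: int = 0
    eta_init: float = 0.5
    init_scale: float = 1.0
    rec_gain: float = 0.3
    rec_identity: float = 0.4
    plast_gain: float = 0.004
    plast_mean: float = 0.004
    mod_gain: float = 0.5
    out_gain: float = 1.0
    checkpoint_every: int = 0  # updates between checkpoints; 0 = final only
    # solution-classification thresholds (see classify_solution)
    perf_floor: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.last10_weight <= 0:
            raise ValueError("last10_weight must be positive")
        if self.n_episodes % max(self.batch_size, 1) != 0:
            raise ValueError("n_episodes must be a multiple of batch_size")


@dataclass
class TrainResult:
    params: StructuralParams
    performance_curve: np.ndarray  # per-episode mean last-10 accuracy
    loss_curve: np.ndarray         # per-update loss
    label: str                     # cognitive | passive | failed
    diagnostics: dict = field(default_factory=dict)


def returns_and_advantages(trace: EpisodeTrace, gamma: float,
                           last10_weight: float) -> tuple[np.ndarray, np.ndarray]:
    """Discounted per-step returns and response-step advantages for one episode.

    Rewards of the last 10 trials are multiplied by ``last10_weight`` before
    the backward return recursion (loss-side only); the advantage at each
    response step is return minus the critic's value estimate there.
    """
    n_trials = len(trace.trials)
    rewards = trace.rewards.astype(float)[:, None]
    returns = _engine.discounted_returns(rewards, n_trials, gamma,
                                         last10_weight)[:, 0]
    resp_steps = np.arange(n_trials) * STEPS_PER_TRIAL + 1
    values = np.array([t.value[1] for t in trace.trials])
    advantages = returns[resp_steps] - values
    return returns, advantages


def a2c_loss(traces: list[EpisodeTrace], params: StructuralParams,
             config: TrainConfig) -> tuple[float, dict]:
    """A2C loss of recorded traces (batch-averaged); no gradients.

    The same quantity the training step differentiates: policy-gradient term
    with constant advantages, squared value error, minus an entropy bonus.
    """
    del params  # the loss is a function of recorded rollout quantities only
    totals = {"loss": 0.0, "policy_loss": 0.0, "value_loss": 0.0, "entropy": 0.0}
    for trace in traces:
        n_trials = len(trace.trials)
        returns, adv = returns_and_advantages(trace, config.gamma,
                                              config.last10_weight)
        o = np.array([t.o[1] for t in trace.trials])
        a_idx = trace.responses - 1
        logp = np.log(o[np.arange(n_trials), a_idx])
        entropy = -(o * np.log(o)).sum(axis=1)
        pol = -(logp * adv).sum()
        val = (adv ** 2).sum()
        ent = entropy.sum()
        totals["policy_loss"] += pol
        totals["value_loss"] += val
        totals["entropy"] += ent
        totals["loss"] += pol + config.value_coef * val - config.entropy_coef * ent
    return totals["loss"] / len(traces), {
        k: v / len(traces) for k, v in totals.items()
    }


class Adam:
    """Adam optimizer over the structural-parameter dict."""

    def __init__(self, params: StructuralParams, lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float))
                  for k in PARAM_NAMES}
        self.v = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float))
                  for k in PARAM_NAMES}

    def step(self, params: StructuralParams, grads: dict) -> None:
        b1, b2 = self.betas
        self.t += 1
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k in PARAM_NAMES:
            g = np.asarray(grads[k], dtype=float)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            update = self.lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps)
            if k == "eta_logit":
                params.eta_logit = float(params.eta_logit - update)
            else:
                getattr(params, k).__isub__(update)


def clip_grad_norm(grads: dict, max_norm: float) -> float:
    total = np.sqrt(sum(float(np.sum(np.asarray(g) ** 2))
                        for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for k, g in grads.items():
            grads[k] = np.asarray(g) * scale if np.ndim(g) else float(g) * scale
    return total


def sample_training_batch(config: TrainConfig, rng: np.random.Generator
                          ) -> list[EpisodeSpec]:
    n_items = rng.integers(config.n_items_min, config.n_items_max + 1,
                           size=config.batch_size)
    return [make_episode(int(k), rng) for k in n_items]


def train(config: TrainConfig, rng: np.random.Generator | None = None,
          out_dir: str | Path | None = None,
          params: StructuralParams | None = None,
          progress: bool = False) -> TrainResult:
    """Meta-train structural parameters; returns the final network and curves.

    A single update consumes ``batch_size`` episodes: batched rollout with a
    gradient tape, reverse-mode backward through all steps and plastic
    updates, global-norm clipping, one Adam step.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if params is None:
        params = init_params(config.n, rng, scale=config.init_scale,
                             rec_gain=config.rec_gain,
                             rec_identity=config.rec_identity,
                             plast_gain=config.plast_gain,
                             plast_mean=config.plast_mean,
                             mod_gain=config.mod_gain,
                             out_gain=config.out_gain,
                             eta_init=config.eta_init)
    opt = Adam(params, config.lr)
    n_updates = config.n_episodes // config.batch_size
    perf_curve = np.empty(config.n_episodes)
    loss_curve = np.empty(n_updates)
    eta_curve = np.empty(n_updates)
    out_dir = Path(out_dir) if out_dir is not None else None
    last_good = params.copy()

    dtype = np.float32 if config.compute_dtype == "float32" else np.float64
    divergent_updates = 0
    for u in range(n_updates):
        episodes = sample_training_batch(config, rng)
        try:
            tape = _engine.rollout(params, episodes, rng=rng, dtype=dtype)
            terms, grads = _engine.backward(
                params, tape, config.gamma, config.last10_weight,
                config.value_coef, config.entropy_coef,
                adv_norm=config.adv_norm)
        except NumericalError:
            terms = None
        if terms is not None and (
                not np.isfinite(terms["loss"]) or not all(
                    np.all(np.isfinite(np.atleast_1d(g)))
                    for g in grads.values())):
            terms = None
        if terms is None:
            # an exploding episode: skip the batch; if it keeps happening,
            # stop and hand back the last good parameters
            divergent_updates += 1
            perf_curve[u * config.batch_size:(u + 1) * config.batch_size] = np.nan
            loss_curve[u] = np.nan
            eta_curve[u] = params.eta
            if divergent_updates > max(10, n_updates // 100):
                perf_curve = perf_curve[:u * config.batch_size]
                loss_curve = loss_curve[:u]
                eta_curve = eta_curve[:u]
                params = last_good
                break
            continue
        clip_grad_norm(grads, config.grad_clip)
        opt.step(params, grads)
        b = config.batch_size
        perf_curve[u * b:(u + 1) * b] = tape.performance
        loss_curve[u] = terms["loss"]
        eta_curve[u] = params.eta
        if u % 50 == 0:
            last_good = params.copy()
            if progress:
                recent = perf_curve[max(0, (u - 49) * b):(u + 1) * b]
                print(f"update {u}/{n_updates} loss {terms['loss']:+.3f} "
                      f"perf {np.nanmean(recent):.3f} eta {params.eta:.3f}",
                      flush=True)
        if out_dir and config.checkpoint_every and u and \
                u % config.checkpoint_every == 0:
            from .cli_io import save_checkpoint
            save_checkpoint(params, out_dir / f"ckpt_{u:06d}.h5",
                            config=asdict(config), seed=config.seed)

    label = "unlabeled"
    if config.n_episodes > 0:
        label = classify_solution(params, n_eval_episodes=500,
                                  rng=np.random.default_rng(rng.integers(2**31)),
                                  n_items=min(config.n_items_max, 8),
                                  perf_floor=config.perf_floor)["label"]
    result = TrainResult(params, perf_curve, loss_curve, label,
                         diagnostics={"eta_curve": eta_curve,
                                      "final_eta": params.eta})
    if out_dir:
        from .cli_io import save_checkpoint, save_curves
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(params, out_dir / "ckpt_final.h5",
                        config=asdict(config), seed=config.seed)
        save_curves(result, out_dir)
    return result


def modulator_reward_split(m3: np.ndarray, m4: np.ndarray,
                           rewards: np.ndarray) -> dict:
    """Mean m(3) and m(4) split by reward sign, plus the split magnitudes.

    Arrays are (n_trials, n_runs); the split for a step is
    |mean over correct trials - mean over incorrect trials|.
    """
    correct = rewards > 0
    out = {}
    for name, m in (("m3", m3), ("m4", m4)):
        mc = float(m[correct].mean()) if correct.any() else np.nan
        mi = float(m[~correct].mean()) if (~correct).any() else np.nan
        out[f"{name}_correct"] = mc
        out[f"{name}_incorrect"] = mi
        out[f"{name}_split"] = abs(mc - mi)
    return out


def classify_solution(params: StructuralParams,
                      traces: "_engine.RolloutTape | None" = None,
                      n_eval_episodes: int = 500,
                      rng: np.random.Generator | None = None,
                      n_items: int = 8,
                      perf_floor: float = 0.55) -> dict:
    """Classify a trained network as cognitive, passive, or failed.

    ``failed``: mean last-10 performance at or below ``perf_floor``.
    ``passive``: the modulator's reward sensitivity is concentrated at the
    feedback step — |m(3) split by reward| exceeds |m(4) split by reward|.
    ``cognitive``: otherwise — reward sensitivity lives at the delay step
    (m(4)), leaving m(3) free to carry the sign-consistent coupling burst.

    Returns a dict with the label and the modulator statistics behind it.
    """
    if traces is None:
        if rng is None:
            raise ValueError("provide traces or an rng for evaluation")
        episodes = [make_episode(n_items, rng) for _ in range(n_eval_episodes)]
        traces = _engine.rollout(params, episodes, rng=rng, keep_tape=False)
    if traces.batch_size < 500:
        raise ValueError("need evaluation traces from at least 500 episodes")
    perf = float(traces.performance.mean())
    # m at step 3 (index 2 within a trial) and step 4 (index 3); (n_trials, B)
    m3 = traces.m[2::STEPS_PER_TRIAL]
    m4 = traces.m[3::STEPS_PER_TRIAL]
    stats = modulator_reward_split(m3, m4, traces.rewards)
    stats["performance"] = perf
    if perf <= perf_floor:
        stats["label"] = "failed"
    elif stats["m3_split"] > stats["m4_split"]:
        stats["label"] = "passive"
    else:
        stats["label"] = "cognitive"
    return stats
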