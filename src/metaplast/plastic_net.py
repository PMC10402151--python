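"""Recurrent network with neuromodulated Hebbian plasticity.

Dynamics, per time step::

    x(t) = W_in i(t) + (W_rec + A o P(t)) r(t-1)       (o = Hadamard product)
    r(t) = tanh(x(t))
    o(t) = softmax(W_out r(t))        policy over the two responses
    m(t) = w_mod . r(t)               scalar neuromodulatory output
    v(t) = w_val . r(t)               critic value estimate

Plasticity, applied after the outputs of each step::

    P(t+1) = P(t) + m(t) H(t)                          (pre-update H)
    H(t+1) = eta x(t) r(t-1)^T + (1 - eta) H(t)

The eligibility trace H is a decaying running outer product of post-synaptic
activations and pre-synaptic rates; the network-generated scalar m gates it
into the plastic weights P, with sign.  P is zeroed at episode start only;
x, r and H are additionally zeroed at every trial start, so plastic weights
are the sole carrier of information across trials.

At the trained limit eta -> 1 the rule reduces to
P(t+1) = P(t) + m(t) x(t-1) r(t-2)^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .task_env import (
    EpisodeSpec,
    INPUT_DIM,
    STEPS_PER_TRIAL,
    TrialSpec,
    encode_input,
    evaluate_response,
)

PARAM_NAMES = ("w_in", "w_rec", "a", "w_out", "w_mod", "w_val", "eta_logit")


class NumericalError(RuntimeError):
    """Non-finite values encountered in the network state."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class StructuralParams:
    """Episode-constant parameters, trained by the outer gradient loop.

    ``eta`` is stored through a sigmoid reparameterization (``eta_logit``)
    so that the trained value stays in [0, 1].
    """

    w_in: np.ndarray   # (N, INPUT_DIM)
    w_rec: np.ndarray  # (N, N) base recurrent weights
    a: np.ndarray      # (N, N) per-connection plasticity coefficients
    w_out: np.ndarray  # (2, N) policy readout
    w_mod: np.ndarray  # (N,)   neuromodulator readout
    w_val: np.ndarray  # (N,)   critic readout (never used by the policy)
    eta_logit: float

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def eta(self) -> float:
        return float(expit(self.eta_logit))

    def validate(self) -> None:
        n = self.n
        shapes = {
            "w_in": (n, INPUT_DIM), "w_rec": (n, n), "a": (n, n),
            "w_out": (2, n), "w_mod": (n,), "w_val": (n,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"non-finite values in {name}")

    def copy(self) -> "StructuralParams":
        return StructuralParams(
            self.w_in.copy(), self.w_rec.copy(), self.a.copy(),
            self.w_out.copy(), self.w_mod.copy(), self.w_val.copy(),
            float(self.eta_logit),
        )


def init_params(n: int = 200, rng: np.random.Generator | None = None,
                scale: float = 1.0, rec_gain: float = 0.3,
                rec_identity: float = 0.4, plast_gain: float = 0.004,
                plast_mean: float = 0.004, mod_gain: float = 0.5,
                out_gain: float = 1.0, eta_init: float = 0.5) -> StructuralParams:
    """Initialize structural parameters, zero-mean with ~1/sqrt(fan-in) scale.

    Two deliberate departures from plain i.i.d. initialization bootstrap the
    plasticity pathway for gradient training.  ``rec_identity`` adds an
    identity component to the base recurrent weights, so that step-2
    activity starts as a coherent echo of the step-1 stimulus pattern —
    with a purely random W_rec the Hebbian pre-synaptic patterns stored at
    steps 3-4 are incoherent rotations of the stimulus representation and
    early plastic updates cannot transfer to later presentations.
    ``plast_mean`` gives the per-connection plasticity coefficients a small
    positive mean so that a Hebbian event initially shifts population
    activity along the stored pattern rather than along a random resigning
    of it.  Both components are ordinary trainable parameters afterwards.
    The plasticity scale is deliberately small: stored patterns have squared
    norms of order N/2, so coefficients of order 1/N keep single-trial
    plastic effects comparable to, not dominant over, the base dynamics.

    The modulator and policy readouts start small (``mod_gain``, ``out_gain``)
    so that early plastic updates and policy logits are gentle.  ``scale=0``
    gives all-zero weights (uniform policy everywhere).
    """
    if n < 2:
        raise ValueError("network size must be at least 2")
    rng = np.random.default_rng() if rng is None else rng
    if not 0.0 < eta_init < 1.0:
        raise ValueError("eta_init must lie strictly inside (0, 1)")
    p = StructuralParams(
        w_in=scale * rng.standard_normal((n, INPUT_DIM)) / np.sqrt(INPUT_DIM),
        w_rec=scale * (rec_gain * rng.standard_normal((n, n)) / np.sqrt(n)
                       + rec_identity * np.eye(n)),
        a=scale * (plast_gain * rng.standard_normal((n, n)) / np.sqrt(n)
                   + plast_mean),
        w_out=scale * out_gain * rng.standard_normal((2, n)) / np.sqrt(n),
        w_mod=scale * mod_gain * rng.standard_normal(n) / np.sqrt(n),
        w_val=scale * mod_gain * rng.standard_normal(n) / np.sqrt(n),
        eta_logit=float(np.log(eta_init / (1.0 - eta_init))),
    )
    p.validate()
    return p


@dataclass
class PlasticState:
    """Within-episode mutable state."""

    p: np.ndarray  # (N, N) plastic weight component
    h: np.ndarray  # (N, N) Hebbian eligibility trace
    x: np.ndarray  # (N,) activations
    r: np.ndarray  # (N,) firing rates


@dataclass
class StepOutputs:
    o: np.ndarray      # (2,) response probabilities
    m: float           # neuromodulatory output
    value: float       # critic estimate


def reset_episode(params: StructuralParams) -> PlasticState:
    """Fresh state at episode start: everything, including P, is zero."""
    n = params.n
    return PlasticState(p=np.zeros((n, n)), h=np.zeros((n, n)),
                        x=np.zeros(n), r=np.zeros(n))


def reset_trial(state: PlasticState) -> PlasticState:
    """Zero x, r and H at trial start; plastic weights P are preserved."""
    state.x = np.zeros_like(state.x)
    state.r = np.zeros_like(state.r)
    state.h = np.zeros_like(state.h)
    return state


def step(params: StructuralParams, state: PlasticState,
         inp: np.ndarray, step_index: int | None = None
         ) -> tuple[PlasticState, StepOutputs]:
    """Advance the network by one time step (in place) and return outputs.

    Order within the step: new activations and outputs first, then the
    plastic update P += m H using the *pre-update* trace, then the trace
    update from the new activations and the previous rates.
    """
    r_prev = state.r
    x = params.w_in @ inp + (params.w_rec + params.a * state.p) @ r_prev
    if not np.all(np.isfinite(x)):
        raise NumericalError("non-finite activations", step=step_index)
    r = np.tanh(x)
    logits = params.w_out @ r
    logits = logits - logits.max()
    e = np.exp(logits)
    o = e / e.sum()
    m = float(params.w_mod @ r)
    value = float(params.w_val @ r)
    eta = params.eta
    state.p = state.p + m * state.h
    state.h = eta * np.outer(x, r_prev) + (1.0 - eta) * state.h
    state.x, state.r = x, r
    return state, StepOutputs(o=o, m=m, value=value)


@dataclass
class TrialRecord:
    """Per-step record of one trial (4 steps)."""

    r: np.ndarray          # (4, N)
    x: np.ndarray          # (4, N)
    o: np.ndarray          # (4, 2)
    m: np.ndarray          # (4,)
    value: np.ndarray      # (4,)
    response: int
    reward: int
    p_snapshots: np.ndarray | None = None  # (5, N, N): trial start + after each step


@dataclass
class EpisodeTrace:
    """Aggregated per-trial records for one episode."""

    episode: EpisodeSpec
    trials: list[TrialRecord]
    performance: float  # fraction correct over the last 10 trials

    @property
    def n_steps(self) -> int:
        return STEPS_PER_TRIAL * len(self.trials)

    @property
    def responses(self) -> np.ndarray:
        return np.array([t.response for t in self.trials])

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.trials])

    def m_at(self, step: int) -> np.ndarray:
        """m(step) for every trial (step in 1..4)."""
        return np.array([t.m[step - 1] for t in self.trials])

    def r_at(self, trial_index: int, step: int) -> np.ndarray:
        return self.trials[trial_index].r[step - 1]


def run_trial(params: StructuralParams, state: PlasticState, trial: TrialSpec,
              stimuli: np.ndarray, rng: np.random.Generator,
              record_p: bool = False) -> tuple[PlasticState, TrialRecord]:
    """Run one 4-step trial: stimulus, response, feedback, delay.

    The response is sampled from the policy at step 2 only; policy outputs
    at other steps are discarded.  The reward is fed back at step 3 together
    with a one-hot of the step-2 response.
    """
    n = params.n
    rec_r = np.empty((STEPS_PER_TRIAL, n))
    rec_x = np.empty((STEPS_PER_TRIAL, n))
    rec_o = np.empty((STEPS_PER_TRIAL, 2))
    rec_m = np.empty(STEPS_PER_TRIAL)
    rec_v = np.empty(STEPS_PER_TRIAL)
    snaps = np.empty((STEPS_PER_TRIAL + 1, n, n)) if record_p else None
    if record_p:
        snaps[0] = state.p
    response, reward = 0, 0
    for k in range(1, STEPS_PER_TRIAL + 1):
        inp = encode_input(trial, stimuli, k, prev_response=response,
                           reward=float(reward))
        state, out = step(params, state, inp, step_index=k)
        if k == 2:
            response = 1 if rng.random() < out.o[0] else 2
            reward = evaluate_response(trial, response)
        rec_r[k - 1] = state.r
        rec_x[k - 1] = state.x
        rec_o[k - 1] = out.o
        rec_m[k - 1] = out.m
        rec_v[k - 1] = out.value
        if record_p:
            snaps[k] = state.p
    return state, TrialRecord(rec_r, rec_x, rec_o, rec_m, rec_v,
                              response, reward, snaps)


def run_episode(params: StructuralParams, episode: EpisodeSpec,
                rng: np.random.Generator, record_p: bool = False
                ) -> EpisodeTrace:
    """Run one full episode with per-trial resets; P carries across trials."""
    state = reset_episode(params)
    records = []
    for trial in episode.trials:
        state = reset_trial(state)
        state, rec = run_trial(params, state, trial, episode.stimuli, rng,
                               record_p=record_p)
        records.append(rec)
    last = records[-10:] if len(records) >= 10 else records
    performance = float(np.mean([t.reward > 0 for t in last]))
    return EpisodeTrace(episode, records, performance)
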