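"""Serial-order task environments: episode generation, input encoding, scoring.

An *episode* presents a fresh, randomly ordered list of abstract items
(random binary vectors).  Each *trial* shows one pair of items, collects a
binary response ("choose slot 1" or "choose slot 2"), and returns a signed
reward indicating whether the chosen item was the higher-ranked of the two.
Rank index 0 denotes the highest-ranked item ("A").

Protocols
---------
``standard``
    30 trials: 20 adjacent-pair trials followed by 10 trials drawn from all
    ordered non-identical pairs.
``listlink`` / ``sham``
    Two 4-item sub-lists learned separately, then either a linking phase on
    the junction pair (listlink) or a single non-linking trial (sham),
    followed by one test trial over the joint 8-item list.
``massed``
    A standard schedule with one chosen pair repeated for a block of
    consecutive trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

STIM_DIM = 15
#: input layout: slot-1 stimulus, slot-2 stimulus, reward scalar, response one-hot
INPUT_DIM = 2 * STIM_DIM + 1 + 2
N_TRIALS_STANDARD = 30
N_ADJACENT_TRIALS = 20
STEPS_PER_TRIAL = 4


@dataclass(frozen=True)
class TrialSpec:
    """One pairwise presentation.

    ``rank1``/``rank2`` are the (0-based) list ranks of the items shown in
    slots 1 and 2.  The correct response is the slot holding the
    higher-ranked item, i.e. the smaller rank index.
    """

    rank1: int
    rank2: int
    phase: str = "standard"

    def __post_init__(self) -> None:
        if self.rank1 == self.rank2:
            raise ValueError("a trial must show two distinct items")

    @property
    def correct_response(self) -> int:
        return 1 if self.rank1 < self.rank2 else 2

    @property
    def distance(self) -> int:
        """Symbolic (intra-pair) distance."""
        return abs(self.rank1 - self.rank2)


@dataclass
class EpisodeSpec:
    """Stimuli plus a trial schedule for one episode."""

    n_items: int
    stimuli: np.ndarray  # (n_items, STIM_DIM), values in {0, 1}
    trials: list[TrialSpec]
    protocol: str = "standard"

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        if self.stimuli.shape != (self.n_items, STIM_DIM):
            raise ValueError(
                f"stimuli must have shape ({self.n_items}, {STIM_DIM}), "
                f"got {self.stimuli.shape}"
            )
        for t in self.trials:
            if not (0 <= t.rank1 < self.n_items and 0 <= t.rank2 < self.n_items):
                raise ValueError(f"trial ranks {t.rank1},{t.rank2} out of range")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_items": self.n_items,
                "protocol": self.protocol,
                "stimuli": ["".join(str(int(v)) for v in s) for s in self.stimuli],
                "trials": [
                    {"rank1": t.rank1, "rank2": t.rank2, "phase": t.phase}
                    for t in self.trials
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EpisodeSpec":
        d = json.loads(text)
        stimuli = np.array([[int(c) for c in s] for s in d["stimuli"]], dtype=float)
        trials = [TrialSpec(t["rank1"], t["rank2"], t.get("phase", "standard"))
                  for t in d["trials"]]
        return cls(d["n_items"], stimuli, trials, d["protocol"])


def make_stimuli(n_items: int, dim: int = STIM_DIM,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n_items`` pairwise-distinct binary vectors of length ``dim``.

    Entries are i.i.d. uniform over {0, 1}; collisions are resampled.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    if dim < 64 and 2 ** dim < n_items:
        raise ValueError(f"cannot draw {n_items} distinct vectors of length {dim}")
    rng = np.random.default_rng() if rng is None else rng
    seen: set[bytes] = set()
    out = np.empty((n_items, dim), dtype=float)
    i = 0
    while i < n_items:
        v = rng.integers(0, 2, size=dim)
        key = v.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out[i] = v
        i += 1
    return out


def _adjacent_trial(ranks: Sequence[int], rng: np.random.Generator,
                    phase: str = "standard") -> TrialSpec:
    """Uniform adjacent pair among consecutive ranks of ``ranks``, random slot order."""
    lo = int(rng.integers(0, len(ranks) - 1))
    a, b = ranks[lo], ranks[lo + 1]
    if rng.integers(0, 2):
        a, b = b, a
    return TrialSpec(a, b, phase)


def _any_pair_trial(n_items: int, rng: np.random.Generator,
                    phase: str = "standard") -> TrialSpec:
    a = int(rng.integers(0, n_items))
    b = int(rng.integers(0, n_items - 1))
    if b >= a:
        b += 1
    return TrialSpec(a, b, phase)


def schedule_standard(n_items: int, rng: np.random.Generator) -> list[TrialSpec]:
    """Standard 30-trial schedule: 20 adjacent-pair trials, then 10 all-pair trials.

    Adjacent pairs are sampled uniformly with replacement (no balancing), and
    the slot order of every pair is randomized independently.
    """
    if not 4 <= n_items <= 9:
        raise ValueError(f"n_items must be in [4, 9], got {n_items}")
    ranks = list(range(n_items))
    trials = [_adjacent_trial(ranks, rng, "adjacent")
              for _ in range(N_ADJACENT_TRIALS)]
    trials += [_any_pair_trial(n_items, rng, "allpairs")
               for _ in range(N_TRIALS_STANDARD - N_ADJACENT_TRIALS)]
    return trials


def schedule_listlink(sham: bool, rng: np.random.Generator) -> list[TrialSpec]:
    """List-linking schedule over an 8-item list.

    Two 4-item sub-lists (ranks 0-3, then 4-7) are each trained with 10
    adjacent-pair trials.  Then either 4 trials on the junction pair (3, 4)
    (linking), or a single trial on the non-linking pair (4, 5) (sham).
    One final test trial is drawn from all ordered pairs of the full list.
    """
    trials = [_adjacent_trial(range(0, 4), rng, "list1") for _ in range(10)]
    trials += [_adjacent_trial(range(4, 8), rng, "list2") for _ in range(10)]
    if sham:
        a, b = (4, 5) if rng.integers(0, 2) else (5, 4)
        trials.append(TrialSpec(a, b, "sham"))
    else:
        for _ in range(4):
            a, b = (3, 4) if rng.integers(0, 2) else (4, 3)
            trials.append(TrialSpec(a, b, "link"))
    trials.append(_any_pair_trial(8, rng, "test"))
    return trials


def schedule_massed(n_items: int, pair: tuple[int, int], block: int,
                    insert_at: int, rng: np.random.Generator) -> list[TrialSpec]:
    """Standard schedule with ``block`` consecutive repeats of ``pair`` inserted
    at trial index ``insert_at`` (replacing that many adjacent-phase trials)."""
    if not 0 <= insert_at <= N_ADJACENT_TRIALS - block:
        raise ValueError("massed block must fit inside the adjacent phase")
    trials = schedule_standard(n_items, rng)
    for i in range(insert_at, insert_at + block):
        a, b = pair if rng.integers(0, 2) else pair[::-1]
        trials[i] = TrialSpec(a, b, "massed")
    return trials


def make_episode(n_items: int, rng: np.random.Generator,
                 protocol: str = "standard", dim: int = STIM_DIM,
                 trials: list[TrialSpec] | None = None, **kwargs) -> EpisodeSpec:
    """Generate a full episode (stimuli + schedule) for the given protocol."""
    if protocol == "listlink":
        n_items = 8
        trials = schedule_listlink(sham=False, rng=rng) if trials is None else trials
    elif protocol == "sham":
        n_items = 8
        trials = schedule_listlink(sham=True, rng=rng) if trials is None else trials
    elif protocol == "standard":
        trials = schedule_standard(n_items, rng) if trials is None else trials
    elif protocol == "massed":
        trials = schedule_massed(n_items, rng=rng, **kwargs) if trials is None else trials
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    stimuli = make_stimuli(n_items, dim, rng)
    return EpisodeSpec(n_items, stimuli, trials, protocol)


def sample_schedule_until(n_items: int, rng: np.random.Generator,
                          predicate: Callable[[list[TrialSpec]], bool],
                          max_tries: int = 100_000) -> list[TrialSpec]:
    """Rejection-sample standard schedules until ``predicate`` holds.

    Used by conditional analyses that select runs by schedule properties
    (e.g. a given pair first shown at a given trial) — the condition depends
    only on the schedule, so it can be enforced before any simulation.
    """
    for _ in range(max_tries):
        trials = schedule_standard(n_items, rng)
        if predicate(trials):
            return trials
    raise RuntimeError("predicate not satisfied within max_tries schedules")


def conditioned_standard_schedule(n_items: int, pair: tuple[int, int],
                                  trial_index: int,
                                  exclude_before: Sequence[tuple[int, int]] = (),
                                  rng: np.random.Generator | None = None
                                  ) -> list[TrialSpec]:
    """Standard schedule with ``pair`` first shown exactly at ``trial_index``
    and ``exclude_before`` pairs never shown earlier.

    Because the adjacent-phase trials are i.i.d. uniform draws, conditioning
    on "these pairs never occur before trial t" leaves the remaining trials
    i.i.d. uniform over the allowed pairs — so the conditional distribution
    can be sampled directly instead of by (astronomically slow) rejection.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 <= trial_index < N_ADJACENT_TRIALS:
        raise ValueError("the conditioned trial must fall in the adjacent phase")
    banned = {frozenset(pair)} | {frozenset(p) for p in exclude_before}
    adjacent = [(i, i + 1) for i in range(n_items - 1)]
    allowed = [p for p in adjacent if frozenset(p) not in banned]
    if not allowed:
        raise ValueError("exclusions leave no adjacent pairs to sample")
    trials: list[TrialSpec] = []
    for _ in range(trial_index):
        a, b = allowed[rng.integers(0, len(allowed))]
        if rng.integers(0, 2):
            a, b = b, a
        trials.append(TrialSpec(a, b, "adjacent"))
    a, b = pair
    if rng.integers(0, 2):
        a, b = b, a
    trials.append(TrialSpec(a, b, "adjacent"))
    ranks = list(range(n_items))
    for _ in range(trial_index + 1, N_ADJACENT_TRIALS):
        trials.append(_adjacent_trial(ranks, rng, "adjacent"))
    trials += [_any_pair_trial(n_items, rng, "allpairs")
               for _ in range(N_TRIALS_STANDARD - N_ADJACENT_TRIALS)]
    return trials


def first_occurrence(trials: Sequence[TrialSpec], pair: tuple[int, int]) -> int | None:
    """Index of the first trial showing ``pair`` in either slot order, or None."""
    key = frozenset(pair)
    for i, t in enumerate(trials):
        if frozenset((t.rank1, t.rank2)) == key:
            return i
    return None


def encode_input(trial: TrialSpec, stimuli: np.ndarray, step: int,
                 prev_response: int = 0, reward: float = 0.0) -> np.ndarray:
    """Encode the network input for one step of a trial.

    Step 1 carries the two stimuli; step 3 carries the reward scalar and the
    one-hot of the step-2 response; steps 2 and 4 are all-zero.
    """
    if step not in (1, 2, 3, 4):
        raise ValueError(f"step must be in 1..4, got {step}")
    vec = np.zeros(INPUT_DIM)
    if step == 1:
        vec[:STIM_DIM] = stimuli[trial.rank1]
        vec[STIM_DIM:2 * STIM_DIM] = stimuli[trial.rank2]
    elif step == 3:
        vec[2 * STIM_DIM] = reward
        if prev_response in (1, 2):
            vec[2 * STIM_DIM + prev_response] = 1.0
    return vec


def evaluate_response(trial: TrialSpec, response: int) -> int:
    """Signed reward: +1 if ``response`` picked the higher-ranked item, else -1."""
    if response not in (1, 2):
        raise ValueError(f"response must be 1 or 2, got {response}")
    return 1 if response == trial.correct_response else -1
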