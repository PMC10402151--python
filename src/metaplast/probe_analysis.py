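"""Behavioral and representational analyses of trained networks.

The central objects are the *decision axis* — the difference between the two
rows of the policy readout ``W_out`` — and the frozen-weight single-item
probes: presenting one item alone in slot 1 for two steps yields its
feedforward representation ``psi_t1(X) = r(1)`` and its learned, plastic-
weight-dependent representation ``psi_t2(X) = r(2)``.  A trained network
encodes an item's rank as the correlation ("alignment") of ``psi_t2(X)``
with the decision axis.

All probes are read-only: the frozen plastic weights passed in are never
mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._engine import RolloutTape
from .plastic_net import StructuralParams
from .task_env import (
    STEPS_PER_TRIAL,
    STIM_DIM,
    TrialSpec,
    first_occurrence,
    make_stimuli,
    sample_schedule_until,
)


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.linalg.norm(uc) * np.linalg.norm(vc)
    if denom == 0.0:
        return np.nan
    return float(uc @ vc / denom)


def pearson_rows(mat: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``mat`` (..., N) with vector ``v``."""
    mc = mat - mat.mean(axis=-1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(mc, axis=-1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mc @ vc) / denom


@dataclass
class DecisionAxis:
    """Difference between the two rows of the policy readout."""

    vector: np.ndarray
    row_correlation: float  # Pearson r between the two readout rows
    degenerate: bool

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.vector, dtype=dtype)


def decision_axis(params: StructuralParams) -> DecisionAxis:
    """w_out = row 1 - row 2 of ``W_out``.

    In trained high-performance networks the two rows are strongly
    anti-aligned (r < -0.9), so either row carries the same axis.
    """
    vec = params.w_out[0] - params.w_out[1]
    rho = pearson(params.w_out[0], params.w_out[1])
    return DecisionAxis(vec, rho, degenerate=bool(not np.any(vec)))


def probe_item(params: StructuralParams, p_frozen: np.ndarray,
               stimulus: np.ndarray, slot: int = 1
               ) -> tuple[np.ndarray, np.ndarray]:
    """Two-step single-item probe with frozen plastic weights.

    The item is presented alone in the given slot at step 1 (the other slot,
    reward and response inputs all zero); returns (r(1), r(2)).  ``p_frozen``
    is read but never written.
    """
    n = params.n
    if p_frozen.shape != (n, n):
        raise ValueError(f"p_frozen must have shape ({n}, {n})")
    if slot not in (1, 2):
        raise ValueError("slot must be 1 or 2")
    inp = np.zeros(params.w_in.shape[1])
    off = 0 if slot == 1 else STIM_DIM
    inp[off:off + STIM_DIM] = stimulus
    psi1 = np.tanh(params.w_in @ inp)
    x2 = (params.w_rec + params.a * p_frozen) @ psi1  # step-2 input is zero
    psi2 = np.tanh(x2)
    return psi1, psi2


def alignment(params: StructuralParams, p_frozen: np.ndarray,
              stimulus: np.ndarray, method: str = "pearson") -> float:
    """Correlation of the item's step-2 representation with the decision axis."""
    _, psi2 = probe_item(params, p_frozen, stimulus)
    axis = decision_axis(params).vector
    if method == "pearson":
        return pearson(psi2, axis)
    if method == "cosine":
        return float(psi2 @ axis / (np.linalg.norm(psi2) * np.linalg.norm(axis)))
    raise ValueError(f"unknown method {method!r}")


def rank_alignment_curve(params: StructuralParams, p_frozen: np.ndarray,
                         stimuli: np.ndarray, method: str = "pearson"
                         ) -> np.ndarray:
    """Alignment of every item's psi_t2 with the decision axis, by rank.

    For a trained network probed late in an episode this is a monotonically
    decreasing curve: positive for the top-ranked item, negative for the
    bottom-ranked one.
    """
    return np.array([alignment(params, p_frozen, s, method) for s in stimuli])


def alignment_curves_batch(params: StructuralParams, p_frozen: np.ndarray,
                           stimuli: np.ndarray) -> np.ndarray:
    """Vectorized alignment curves for stacked plastic weights.

    ``p_frozen``: (..., N, N); ``stimuli``: (n_items, STIM_DIM) shared, or
    (..., n_items, STIM_DIM) per entry.  Returns alignments (..., n_items).
    """
    axis = decision_axis(params).vector
    lead = p_frozen.shape[:-2]
    if stimuli.ndim == 2:
        stimuli = np.broadcast_to(stimuli, lead + stimuli.shape)
    inp = np.zeros(stimuli.shape[:-1] + (params.w_in.shape[1],))
    inp[..., :STIM_DIM] = stimuli
    psi1 = np.tanh(inp @ params.w_in.T)                      # (..., items, N)
    w_eff = params.w_rec + params.a * p_frozen               # (..., N, N)
    x2 = np.einsum("...ij,...xj->...xi", w_eff, psi1, optimize=True)
    return pearson_rows(np.tanh(x2), axis)


# ---------------------------------------------------------------------------
# behavioral tables
# ---------------------------------------------------------------------------

def pairwise_performance(traces: RolloutTape,
                         window: slice | tuple[int, int] | None = None
                         ) -> pd.DataFrame:
    """Accuracy per ordered pair, with symbolic distance and end-anchor tags.

    ``window`` selects trial indices (default: the last 10 trials).  Returns
    a tidy table with one row per ordered (rank1, rank2) pair: trial count,
    accuracy, distance, and whether the pair touches a list end.
    """
    n_trials = traces.n_trials
    if window is None:
        window = slice(max(0, n_trials - 10), n_trials)
    elif isinstance(window, tuple):
        window = slice(*window)
    idx = range(*window.indices(n_trials))
    if len(list(idx)) == 0:
        raise ValueError("empty trial window")
    n_items = traces.episodes[0].n_items
    if any(e.n_items != n_items for e in traces.episodes):
        raise ValueError("pairwise_performance requires traces sharing n_items")
    rows = []
    for b, ep in enumerate(traces.episodes):
        for t in range(*window.indices(n_trials)):
            trial = ep.trials[t]
            rows.append((trial.rank1, trial.rank2,
                         int(traces.rewards[t, b] > 0)))
    raw = pd.DataFrame(rows, columns=["rank1", "rank2", "correct"])
    table = (raw.groupby(["rank1", "rank2"])
             .agg(n=("correct", "size"), accuracy=("correct", "mean"))
             .reset_index())
    table["distance"] = (table.rank1 - table.rank2).abs()
    table["end_pair"] = (table[["rank1", "rank2"]].min(axis=1) == 0) | \
                        (table[["rank1", "rank2"]].max(axis=1) == n_items - 1)
    return table


def distance_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Trial-weighted mean accuracy by symbolic distance."""
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series({"n": g.n.sum(),
                          "accuracy": np.average(g.accuracy, weights=g.n)})
    return (table.groupby("distance")[["n", "accuracy"]]
            .apply(agg).reset_index())


def modulator_stats(traces: RolloutTape) -> pd.DataFrame:
    """Long-form table of m(3) and m(4) per trial, split by reward sign."""
    n_trials, B = traces.n_trials, traces.batch_size
    m3 = traces.m[2::STEPS_PER_TRIAL]
    m4 = traces.m[3::STEPS_PER_TRIAL]
    trial = np.repeat(np.arange(n_trials), B)
    frames = []
    for name, m in (("m3", m3), ("m4", m4)):
        frames.append(pd.DataFrame({
            "trial": trial, "step": name, "m": m.ravel(),
            "correct": (traces.rewards > 0).ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def step2_pca(traces: RolloutTape, trial_index: int,
              params: StructuralParams, n_components: int = 10) -> dict:
    """PCA of step-2 population activity at one trial across runs.

    Features (neurons) are centered, not scaled.  Returns variance ratios,
    the |Pearson correlation| between PC1 and the decision axis, and labeled
    2-D projections of every run.
    """
    if traces.batch_size < traces.r.shape[-1]:
        import warnings
        warnings.warn("fewer runs than neurons: PCA components beyond the "
                      "run count are meaningless")
    data = traces.r[trial_index * STEPS_PER_TRIAL + 1]          # (B, N)
    pca = PCA(n_components=min(n_components, *data.shape))
    proj = pca.fit_transform(data)
    axis = decision_axis(params).vector
    trials = [ep.trials[trial_index] for ep in traces.episodes]
    labels = pd.DataFrame({
        "pc1": proj[:, 0],
        "pc2": proj[:, 1],
        "response": traces.responses[trial_index],
        "correct": traces.rewards[trial_index] > 0,
        "in_order": [t.rank1 < t.rank2 for t in trials],
        "rank1": [t.rank1 for t in trials],
        "rank2": [t.rank2 for t in trials],
    })
    return {
        "components": pca.components_,
        "variance_ratios": pca.explained_variance_ratio_,
        "pc1_axis_corr": abs(pearson(pca.components_[0], axis)),
        "projections": labels,
    }


# ---------------------------------------------------------------------------
# conditional (schedule-selected) analyses
# ---------------------------------------------------------------------------

def pair_first_at(pair: tuple[int, int], trial_index: int,
                  exclude_before: list[tuple[int, int]] | None = None):
    """Schedule predicate: ``pair`` first occurs exactly at ``trial_index``,
    optionally with other pairs never shown before that trial."""
    def pred(trials: list[TrialSpec]) -> bool:
        if first_occurrence(trials, pair) != trial_index:
            return False
        for other in exclude_before or ():
            occ = first_occurrence(trials[:trial_index], other)
            if occ is not None:
                return False
        return True
    return pred


def conditioned_episodes(n_runs: int, n_items: int, predicate=None,
                         rng: np.random.Generator | None = None,
                         dim: int = STIM_DIM,
                         pair: tuple[int, int] | None = None,
                         trial_index: int | None = None,
                         exclude_before=()):
    """Standard episodes satisfying a schedule condition, without simulation.

    With ``pair``/``trial_index`` given, schedules are drawn directly from
    the exact conditional distribution ("pair first shown at trial_index",
    optionally with ``exclude_before`` pairs absent earlier) — see
    :func:`metaplast.task_env.conditioned_standard_schedule`.  A generic
    ``predicate`` falls back to rejection sampling on the schedule only.
    """
    from .task_env import EpisodeSpec, conditioned_standard_schedule
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(n_runs):
        if pair is not None:
            trials = conditioned_standard_schedule(
                n_items, pair, trial_index, exclude_before, rng)
        else:
            trials = sample_schedule_until(n_items, rng, predicate)
        out.append(EpisodeSpec(n_items, make_stimuli(n_items, dim, rng), trials))
    return out


def stepwise_alignment(params: StructuralParams, traces: RolloutTape,
                       chunk: int = 200) -> dict:
    """Per-step alignment curves and deltas across one trial, per run.

    ``traces`` must have been rolled out with ``p_snapshot_trial`` set; the
    snapshots hold P at entry to that trial and after each of its 4 steps.
    Returns alignments (n_runs, 5, n_items) and deltas (n_runs, 4, n_items),
    where deltas[:, k-1] is the change produced by step k's plastic update.
    Deltas for steps 1 and 2 are identically zero (x, r and H are reset at
    trial start, so no weight change can occur there).
    """
    if traces.p_snapshots is None:
        raise ValueError("rollout was run without p_snapshot_trial")
    B = traces.batch_size
    if B == 0:
        raise ValueError("no runs matched the selection condition")
    n_items = traces.episodes[0].n_items
    aligns = np.empty((B, 5, n_items))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        stim = np.stack([ep.stimuli for ep in traces.episodes[lo:hi]])
        snaps = traces.p_snapshots[:, lo:hi].transpose(1, 0, 2, 3)
        aligns[lo:hi] = alignment_curves_batch(
            params, snaps, stim[:, None, :, :])
    return {
        "alignments": aligns,
        "deltas": np.diff(aligns, axis=1),
        "trial_index": traces.p_snapshot_trial,
    }


def spearman_permutation(x: np.ndarray, y: np.ndarray, n_perm: int = 2000,
                         rng: np.random.Generator | None = None
                         ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p-value."""
    rng = np.random.default_rng(0) if rng is None else rng
    rho = stats.spearmanr(x, y).statistic
    y = np.asarray(y, dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1)
    return float(rho), float(p)
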