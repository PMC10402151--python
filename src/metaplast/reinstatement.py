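"""Recoded-representation analysis: fitting and probing reinstated items.

The trained network reinstates, during each trial, representations of items
that are *not* currently shown — but in a recoded form.  Because every
synapse has its own base weight and plasticity coefficient, the activity
pattern whose Hebbian pairing with a "teaching" pattern shifts an item's
learned representation along the decision axis is generally very different
from the item's sensory (feedforward) pattern.

This module computes those recoded vectors by optimization.  For candidate
unit vectors v (pre-synaptic, standing for item X at step 2) and a shared
unit vector w (post-synaptic, standing for the decision axis at step 3), a
Hebbian event adds an outer product to the plastic weights, changing the
effective recurrent weights by eps * A o (w v^T).  The induced first-order
change in the item's alignment with the decision axis is the bilinear form

    S_X(v, w) = c_X^T D_X [ w o (A (v o psi_t1(X))) ]

where psi_t1(X) is the item's feedforward probe pattern, D_X the tanh
Jacobian at the probe operating point, and c_X the gradient of the Pearson
alignment at psi_t2(X).  The fit alternates exact maximizations: given w,
the optimal v_X is closed-form (making every S_X positive); given all v_X,
the optimal shared w is the top eigenvector of a rank-n_items Gram matrix.
The objective sum_X S_X^2 is therefore non-decreasing across iterations;
seeded restarts guard against local optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import RolloutTape
from .plastic_net import StructuralParams
from .probe_analysis import (
    DecisionAxis,
    decision_axis,
    pearson,
    pearson_rows,
    probe_item,
    stepwise_alignment,
)
from .task_env import STEPS_PER_TRIAL


@dataclass
class RecodedBasis:
    """Recoded item vectors psi_tilde(X) and recoded decision axis w_tilde."""

    psi_tilde: np.ndarray        # (n_items, N), unit rows
    w_tilde: np.ndarray          # (N,), unit norm
    shift_gains: np.ndarray      # (n_items,) S_X at the optimum (all > 0)
    objective: float
    n_iterations: int
    converged: bool
    checkpoint_hash: str | None = None
    objective_trace: np.ndarray = field(default=None, repr=False)


def _probe_operating_point(params: StructuralParams, p_frozen: np.ndarray,
                           stimuli: np.ndarray, linearize_at: str):
    """Per-item (psi1, D, c): probe pattern, tanh Jacobian diag, alignment
    gradient at the operating point."""
    axis = decision_axis(params).vector
    n_items = stimuli.shape[0]
    n = params.n
    psi1 = np.empty((n_items, n))
    d = np.empty((n_items, n))
    c = np.empty((n_items, n))
    for i, s in enumerate(stimuli):
        p1, p2 = probe_item(params, p_frozen, s)
        psi1[i] = p1
        if linearize_at == "zero":
            # identity Jacobian; the Pearson gradient at the origin points
            # along the centered decision axis
            d[i] = 1.0
            c[i] = axis - axis.mean()
        elif linearize_at == "operating":
            d[i] = 1.0 - p2 ** 2
            rc = p2 - p2.mean()
            ac = axis - axis.mean()
            na, nr = np.linalg.norm(ac), np.linalg.norm(rc)
            rho = float(rc @ ac / (na * nr))
            grad = (ac / na - rho * rc / nr) / nr
            c[i] = grad
        else:
            raise ValueError("linearize_at must be 'operating' or 'zero'")
    return psi1, d, c


def optimize_recoded_basis(params: StructuralParams, p_frozen: np.ndarray,
                           stimuli: np.ndarray, n_restarts: int = 20,
                           max_iter: int = 500, tol: float = 1e-8,
                           linearize_at: str = "operating",
                           rng: np.random.Generator | None = None
                           ) -> RecodedBasis:
    """Fit psi_tilde(X) for every item and a shared w_tilde by alternating
    ascent of sum_X S_X(v_X, w)^2 over unit vectors.

    The modulator's sign at apply time is *not* folded in here: the basis is
    fit with a positive unit update, and the (negative) m(3) bookkeeping is
    carried by the dynamics.  Returns the best of ``n_restarts`` seeded
    restarts; ``converged`` is False if the iteration cap was hit.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    psi1, d, c = _probe_operating_point(params, p_frozen, stimuli, linearize_at)
    cd = c * d                                    # (n_items, N)
    n_items, n = psi1.shape

    def v_given_w(w: np.ndarray) -> np.ndarray:
        raw = psi1 * (params.a.T @ (cd * w).T).T  # (n_items, N)
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        return raw / np.where(norms == 0, 1.0, norms)

    def gains(v: np.ndarray, w: np.ndarray) -> np.ndarray:
        q = cd * ((v * psi1) @ params.a.T)        # (n_items, N)
        return q @ w

    best = None
    for _ in range(n_restarts):
        w = rng.standard_normal(n)
        w /= np.linalg.norm(w)
        obj_prev, trace = -np.inf, []
        converged = False
        for it in range(max_iter):
            v = v_given_w(w)
            q = cd * ((v * psi1) @ params.a.T)    # S_X = q_X . w
            gram = q.T @ q
            # top eigenvector of the rank-n_items Gram matrix
            evals, evecs = np.linalg.eigh(gram)
            w_new = evecs[:, -1]
            obj = float(evals[-1])
            trace.append(obj)
            # keep a consistent overall sign: majority of S_X positive
            if np.sum(q @ w_new) < 0:
                w_new = -w_new
            w = w_new
            if obj - obj_prev <= tol * max(1.0, abs(obj)):
                converged = True
                break
            obj_prev = obj
        v = v_given_w(w)
        g = gains(v, w)
        # per-item sign: flip v_X so that its induced shift is positive
        flip = np.sign(g)
        flip[flip == 0] = 1.0
        v = v * flip[:, None]
        g = g * flip
        cand = RecodedBasis(v, w, g, float(np.sum(g ** 2)), len(trace),
                            converged, objective_trace=np.array(trace))
        if best is None or cand.objective > best.objective:
            best = cand
    if not best.converged:
        import warnings
        warnings.warn("recoded-basis fit hit the iteration cap; returning "
                      "the best iterate")
    return best


# ---------------------------------------------------------------------------
# probing traces for reinstatement
# ---------------------------------------------------------------------------

def _check_hash(traces_hash: str | None, basis: RecodedBasis) -> None:
    if (basis.checkpoint_hash and traces_hash
            and basis.checkpoint_hash != traces_hash):
        raise ValueError("basis and traces come from different checkpoints")


def reinstatement_profile(traces: RolloutTape, basis: RecodedBasis,
                          trial_index: int,
                          checkpoint_hash: str | None = None) -> pd.DataFrame:
    """Correlation of r(t) with each recoded item vector at every step of a
    trial, per run.

    Long-form table with columns run, step (1..4), item, corr, plus the
    pair shown at that trial and the run's response — grouping by shown pair
    reproduces the reinstatement-by-pair profiles.
    """
    _check_hash(checkpoint_hash, basis)
    n_items = basis.psi_tilde.shape[0]
    B = traces.batch_size
    rows = []
    for k in range(STEPS_PER_TRIAL):
        r = traces.r[trial_index * STEPS_PER_TRIAL + k]        # (B, N)
        for item in range(n_items):
            corr = pearson_rows(r, basis.psi_tilde[item])
            rows.append(pd.DataFrame({
                "run": np.arange(B), "step": k + 1, "item": item,
                "corr": corr,
            }))
    out = pd.concat(rows, ignore_index=True)
    pair = [f"{traces.episodes[b].trials[trial_index].rank1}-"
            f"{traces.episodes[b].trials[trial_index].rank2}"
            for b in range(B)]
    out["pair"] = np.tile(np.repeat(pair, 1), STEPS_PER_TRIAL * n_items)
    out["response"] = np.tile(traces.responses[trial_index],
                              STEPS_PER_TRIAL * n_items)
    return out


def axis_reinstatement(traces: RolloutTape, basis: RecodedBasis,
                       trial_index: int) -> pd.DataFrame:
    """Correlation of r(3) with the recoded decision axis, signed by response."""
    r3 = traces.r[trial_index * STEPS_PER_TRIAL + 2]
    corr = pearson_rows(r3, basis.w_tilde)
    return pd.DataFrame({
        "run": np.arange(traces.batch_size),
        "corr": corr,
        "response": traces.responses[trial_index],
    })


def original_representation_control(traces: RolloutTape,
                                    params: StructuralParams,
                                    trial_index: int,
                                    p_frozen: np.ndarray | None = None
                                    ) -> pd.DataFrame:
    """Same profile as ``reinstatement_profile`` but probing with the raw
    feedforward patterns psi_t1(X) instead of the recoded ones.

    In trained networks the shown items are detected at step 1 only (where
    they are literally the input-driven pattern); no step-2 reinstatement of
    the unrecoded patterns occurs.
    """
    n = params.n
    p0 = np.zeros((n, n)) if p_frozen is None else p_frozen
    B = traces.batch_size
    rows = []
    for b in range(B):
        psi1 = np.stack([probe_item(params, p0, s)[0]
                         for s in traces.episodes[b].stimuli])
        for k in range(STEPS_PER_TRIAL):
            r = traces.r[trial_index * STEPS_PER_TRIAL + k, b]
            corr = pearson_rows(psi1, r)
            for item in range(psi1.shape[0]):
                rows.append((b, k + 1, item, corr[item]))
    return pd.DataFrame(rows, columns=["run", "step", "item", "corr"])


def noise_band(vectors: np.ndarray, reference: np.ndarray, n_draws: int = 1000,
               rng: np.random.Generator | None = None,
               level: float = 0.95) -> tuple[float, float]:
    """Null band for 'no reinstatement' calls: the central ``level`` interval
    of correlations between ``reference``-sized random unit vectors and a
    representative activity vector."""
    rng = np.random.default_rng(0) if rng is None else rng
    ref = np.asarray(reference, dtype=float)
    draws = rng.standard_normal((n_draws, ref.size))
    draws /= np.linalg.norm(draws, axis=1, keepdims=True)
    corrs = pearson_rows(draws, ref)
    lo, hi = np.quantile(corrs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def reinstatement_vs_shift(traces: RolloutTape, basis: RecodedBasis,
                           params: StructuralParams,
                           n_perm: int = 2000,
                           rng: np.random.Generator | None = None) -> dict:
    """Association between step-2 reinstatement strength and step-4 learning.

    For every run and item, pairs |corr(r(2), psi_tilde(X))| with the
    magnitude of that item's step-4 alignment change (from the per-step P
    snapshots).  Reports the Spearman rank correlation with a permutation
    p-value, plus the underlying per-(run, item) table.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    sw = stepwise_alignment(params, traces)
    trial_index = traces.p_snapshot_trial
    r2 = traces.r[trial_index * STEPS_PER_TRIAL + 1]            # (B, N)
    n_items = basis.psi_tilde.shape[0]
    strength = np.abs(np.stack(
        [pearson_rows(r2, basis.psi_tilde[i]) for i in range(n_items)],
        axis=1))                                                 # (B, items)
    shift = np.abs(sw["deltas"][:, 3, :])                        # step-4 delta
    x, y = strength.ravel(), shift.ravel()
    rho = stats.spearmanr(x, y).statistic
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    p = (1 + np.sum(null >= rho)) / (n_perm + 1)
    return {
        "spearman": float(rho),
        "p_value": float(p),
        "table": pd.DataFrame({
            "run": np.repeat(np.arange(strength.shape[0]), n_items),
            "item": np.tile(np.arange(n_items), strength.shape[0]),
            "reinstatement": x,
            "shift": y,
        }),
    }
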