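"""Terminal-fate calling for mutation trajectories with a three-state HMM.

Each trajectory is modelled as a hidden sequence over the states *extinct*,
*polymorphic* and *fixed*.  Emissions at an observed timepoint (A, D) are
binomial: an extinct mutation is seen only through sequencing error at rate
``epsilon``, a fixed one at rate ``1 - epsilon``, and a polymorphic one at an
unknown frequency marginalized uniformly over (0, 1), which gives every
alternate count the same probability 1/(D+1).  Transitions keep the current
state with probability ``kappa`` and split the remainder evenly.  The fate
of a mutation is the Viterbi state at its last observed timepoint.

This is a deliberately simplified re-implementation of HMM-based fate
calling for evolve-and-resequence trajectories; it makes terminal-state
calls only and does not attempt frequency-path smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATES = ("extinct", "polymorphic", "fixed")

__all__ = ["FateModel", "FateCall", "classify_fate", "fixation_counts", "STATES"]


@dataclass
class FateModel:
    """Parameters of the three-state fate HMM."""

    epsilon: float = 0.01
    kappa: float = 0.9
    initial: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must be in (0, 1)")
        if not np.isclose(sum(self.initial), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @property
    def log_transition(self) -> np.ndarray:
        off = (1 - self.kappa) / 2
        T = np.full((3, 3), off)
        np.fill_diagonal(T, self.kappa)
        return np.log(T)

    def log_emission(self, A: np.ndarray, D: np.ndarray) -> np.ndarray:
        """(T, 3) log emission probabilities for observed counts."""
        A = np.asarray(A, dtype=int)
        D = np.asarray(D, dtype=int)
        le = stats.binom.logpmf(A, D, self.epsilon)
        lf = stats.binom.logpmf(A, D, 1 - self.epsilon)
        lp = -np.log(D + 1.0)  # uniform marginal over the frequency
        return np.column_stack([le, lp, lf])


@dataclass
class FateCall:
    trajectory_id: str
    path: list = field(default_factory=list)  # state names at observed timepoints
    final_state: str = "polymorphic"
    log_likelihood: float = float("nan")


def _viterbi(log_emis: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray):
    T = log_emis.shape[0]
    delta = log_init + log_emis[0]
    back = np.zeros((T, 3), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(3)] + log_emis[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(np.max(delta))


def classify_fate(trajectory, model: FateModel | None = None) -> FateCall:
    """Viterbi fate call for one trajectory; fate = state at last observed timepoint.

    Timepoints with D = 0 are dropped.  With a single observed timepoint the
    call falls back to thresholding the naive frequency (with a warning).
    """
    model = model or FateModel()
    obs = trajectory.depths > 0
    A = trajectory.alt_counts[obs]
    D = trajectory.depths[obs]
    tid = f"{trajectory.population_id}:{trajectory.contig}:{trajectory.position}"
    if A.size == 0:
        raise ValueError("trajectory has no observed timepoints")
    if A.size == 1:
        warnings.warn("single observed timepoint: threshold fallback", stacklevel=2)
        f = A[0] / D[0]
        if f < model.epsilon:
            state = "extinct"
        elif f > 1 - model.epsilon:
            state = "fixed"
        else:
            state = "polymorphic"
        return FateCall(tid, [state], state, float("nan"))
    path_idx, ll = _viterbi(model.log_emission(A, D), model.log_transition,
                            np.log(np.asarray(model.initial)))
    path = [STATES[i] for i in path_idx]
    return FateCall(tid, path, path[-1], ll)


def fixation_counts(populations, model: FateModel | None = None) -> pd.DataFrame:
    """Fixed-mutation counts per population, with taxon/treatment columns for aggregation."""
    model = model or FateModel()
    rows = []
    for pop in populations:
        n_fixed = 0
        for traj in pop.trajectories:
            if (traj.depths > 0).sum() == 0:
                continue
            if classify_fate(traj, model).final_state == "fixed":
                n_fixed += 1
        rows.append(
            {
                "taxon": pop.taxon,
                "treatment_days": pop.treatment_days,
                "replicate": pop.replicate,
                "n_fixed": n_fixed,
            }
        )
    return pd.DataFrame(rows, columns=["taxon", "treatment_days", "replicate", "n_fixed"])
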