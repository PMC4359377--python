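"""Stepwise elimination of context positions and consensus derivation.

Starting from the full 12-position model, the position with the smallest
sum of squared regression coefficients (the least important one) is removed
and the model refitted, re-selecting the regularisation strength by
leave-one-out CV at every step, until only the stop codon remains.  The
step with the smallest loo-CV error identifies the best reduced model; on
the published training data this is the stop plus positions +4..+6, whose
argmax-weight consensus reads UGA CUA in the RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import BASES, CONTEXT_POSITIONS, STOP_CODONS
from .ridge import RidgeModel, TrainingSet, fit_ridge, loo_cv_sse, select_k


@dataclass
class EliminationStep:
    removed_position: int | None  # None for the initial full-model record
    remaining_positions: tuple[int, ...]
    k_used: float
    loo_sse: float


@dataclass
class EliminationTrace:
    """Initial full-model record followed by exactly 12 removal steps."""

    steps: list[EliminationStep]

    def sse_sequence(self) -> np.ndarray:
        return np.array([s.loo_sse for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "removed_position": [s.removed_position for s in self.steps],
                "n_context_positions": [len(s.remaining_positions) for s in self.steps],
                "k": [s.k_used for s in self.steps],
                "loo_sse": [s.loo_sse for s in self.steps],
            }
        )


def position_importance(model: RidgeModel) -> dict[int, float]:
    """Sum of squared coefficients per context position.

    The stop codon is never a removal candidate, so it is excluded here.
    """
    return {
        p: float(sum(model.context_weights[(p, b)] ** 2 for b in BASES))
        for p in model.positions
    }


def _distance_from_stop(p: int) -> int:
    # -6..-1 are 6..1 nt upstream of the stop; +4..+9 are 1..6 nt downstream
    return -p if p < 0 else p - 3


def _removal_candidate(importance: dict[int, float]) -> int:
    """Least-important position; ties drop the position farthest from the
    stop, upstream before downstream."""
    return min(
        importance,
        key=lambda p: (importance[p], -_distance_from_stop(p), p > 0, p),
    )


def run_elimination(train: TrainingSet) -> EliminationTrace:
    """Full backward elimination over the 12 context positions."""
    positions = tuple(CONTEXT_POSITIONS)
    steps: list[EliminationStep] = []
    k, sse = select_k(train, positions)
    model = fit_ridge(train, positions, k)
    steps.append(EliminationStep(None, positions, k, sse))
    while positions:
        victim = _removal_candidate(position_importance(model))
        positions = tuple(p for p in positions if p != victim)
        k, sse = select_k(train, positions)
        model = fit_ridge(train, positions, k)
        steps.append(EliminationStep(victim, positions, k, sse))
    return EliminationTrace(steps=steps)


def pick_minima(trace: EliminationTrace) -> tuple[tuple[int, ...], list[tuple[int, ...]]]:
    """Global-minimum model spec and interior local minima (global excluded).

    A local minimum is a step whose loo SSE is smaller than both
    neighbours'.  Specs are the remaining context-position tuples (the stop
    is always implied).
    """
    sse = trace.sse_sequence()
    global_idx = int(np.argmin(sse))
    locals_: list[tuple[int, ...]] = []
    for i in range(1, len(sse) - 1):
        if i != global_idx and sse[i] < sse[i - 1] and sse[i] < sse[i + 1]:
            locals_.append(trace.steps[i].remaining_positions)
    return trace.steps[global_idx].remaining_positions, locals_


def logo_matrix(model: RidgeModel) -> tuple[pd.DataFrame, pd.Series]:
    """Signed-coefficient matrix for logo rendering.

    Returns (positions x A,C,G,T DataFrame, 3-entry stop Series); entries
    are the raw weights, positive for readthrough-promoting bases.
    """
    mat = pd.DataFrame(
        {b: [model.context_weights[(p, b)] for p in model.positions] for b in BASES},
        index=list(model.positions),
    )
    mat.index.name = "position"
    stops = pd.Series({s: model.stop_weights[s] for s in STOP_CODONS}, name="stop")
    return mat, stops


def model_from_logo(
    mat: pd.DataFrame, stops: pd.Series, k: float
) -> RidgeModel:
    """Reassemble a model from its logo matrix (round-trip helper)."""
    cw = {(int(p), b): float(mat.loc[p, b]) for p in mat.index for b in BASES}
    return RidgeModel(
        positions=tuple(int(p) for p in mat.index),
        context_weights=cw,
        stop_weights={s: float(stops[s]) for s in STOP_CODONS},
        k=k,
    )


@dataclass
class ConsensusMotif:
    stop: str
    bases: dict[int, str]  # position -> argmax base
    ambiguous: tuple[int, ...] = ()  # positions (or -1000 for stop) with ties

    def as_rna(self) -> str:
        """Human-readable RNA consensus, e.g. 'UGA CUA' for the reduced model."""
        down = "".join(self.bases[p] for p in sorted(b for b in self.bases if b > 0))
        up = "".join(self.bases[p] for p in sorted(b for b in self.bases if b < 0))
        parts = [s for s in (up, self.stop, down) if s]
        return " ".join(parts).replace("T", "U")


def consensus_motif(model: RidgeModel) -> ConsensusMotif:
    """Per-position argmax-weight base plus the argmax stop codon.

    Ties take the lexicographically first base and flag the position
    ambiguous.
    """
    bases: dict[int, str] = {}
    ambiguous: list[int] = []
    for p in model.positions:
        weights = {b: model.context_weights[(p, b)] for b in BASES}
        top = max(weights.values())
        winners = [b for b in BASES if weights[b] == top]
        bases[p] = winners[0]
        if len(winners) > 1:
            ambiguous.append(p)
    top_stop = max(model.stop_weights.values())
    stop_winners = [s for s in STOP_CODONS if model.stop_weights[s] == top_stop]
    if len(stop_winners) > 1:
        ambiguous.append(-1000)
    return ConsensusMotif(stop=stop_winners[0], bases=bases, ambiguous=tuple(ambiguous))
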