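"""Ridge-regression readthrough-propensity (RTP) models.

Basal translational readthrough (BTR) of a stop codon is approximated as a
linear function of its indicator-encoded sequence context.  Given the n x d
matrix X of unit-normalised context feature vectors and the vector y of
experimental readthrough values, the weight vector solves the regularised
least-squares problem

    w = (X^T X + k I)^(-1) X^T y

with no intercept.  Prediction for a context x is w . x; the dimensionless
RTP score divides this by the Euclidean norm of the full weight stack, so
that RTP is invariant to uniform rescaling of the weights (and of y).

Two published weight sets are bundled: ``LINiter`` (all 12 context
positions plus the stop) and ``LINfs3`` (stop plus positions +4..+6, the
feature-selected global optimum whose consensus is UGA CUA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .context import (
    BASES,
    CONTEXT_POSITIONS,
    STOP_CODONS,
    StopCodonContext,
    encode,
)

#: Regularisation strength used for the published models.
DEFAULT_K: float = 10 ** 0.3  # approximately 1.995

PUBLISHED_POSITIONS = {
    "LINiter": CONTEXT_POSITIONS,
    "LINfs3": (4, 5, 6),
}


def default_k_grid() -> np.ndarray:
    """The regularisation grid 10^i for i = -3, -2.7, ..., 3 (21 values)."""
    exponents = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.3), 10)
    return 10.0 ** exponents


@dataclass
class TrainingSet:
    """Contexts paired with experimental basal readthrough values.

    ``units`` records whether y is in percent or as a fraction; the
    normalised RTP score is scale-free, so the choice affects predicted
    BTR units only.
    """

    contexts: list[StopCodonContext]
    y: np.ndarray
    units: str = "percent"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.contexts) != len(self.y):
            raise ValueError("contexts and y must have equal length")
        if len(self.y) < 2:
            raise ValueError("need at least 2 training examples")
        if np.any(self.y < 0):
            raise ValueError("readthrough values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class RidgeModel:
    """A fitted (or bundled) readthrough-propensity regression model.

    ``context_weights`` maps (position, base) to a raw regression
    coefficient; ``stop_weights`` maps each stop codon to its coefficient.
    Raw weights are the direct output of the ridge solve on unit-normalised
    feature vectors.
    """

    positions: tuple[int, ...]
    context_weights: dict[tuple[int, str], float]
    stop_weights: dict[str, float]
    k: float
    units: str = "percent"
    name: str | None = None

    def __post_init__(self) -> None:
        self.positions = tuple(self.positions)
        missing = [
            (p, b) for p in self.positions for b in BASES
            if (p, b) not in self.context_weights
        ]
        if missing or set(self.stop_weights) != set(STOP_CODONS):
            raise ValueError("incomplete weight table for the declared positions")

    @property
    def feature_divisor(self) -> float:
        """sqrt(active positions): the unit-normalisation divisor (context
        positions + 1 for the stop)."""
        return float(np.sqrt(len(self.positions) + 1))

    def weight_vector(self) -> np.ndarray:
        """Raw weights stacked in canonical block order (bases then stops)."""
        vals = [self.context_weights[(p, b)] for p in self.positions for b in BASES]
        vals.extend(self.stop_weights[s] for s in STOP_CODONS)
        return np.asarray(vals)

    @property
    def weight_norm(self) -> float:
        """Euclidean norm of the full raw-weight stack."""
        return float(np.linalg.norm(self.weight_vector()))

    @property
    def shortcut_divisor(self) -> float:
        """weight_norm x feature_divisor: divides a raw weight sum straight
        into the normalised RTP score (0.0317 for LINiter, 0.0126 for
        LINfs3, at the precision the weights are printed)."""
        return self.weight_norm * self.feature_divisor

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "positions": list(self.positions),
            "k": self.k,
            "units": self.units,
            "context_weights": {
                f"{p}:{b}": self.context_weights[(p, b)]
                for p in self.positions for b in BASES
            },
            "stop_weights": dict(self.stop_weights),
            "weight_norm": self.weight_norm,
            "feature_divisor": self.feature_divisor,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeModel":
        cw = {}
        for key, w in d["context_weights"].items():
            p, b = key.split(":")
            cw[(int(p), b)] = float(w)
        model = cls(
            positions=tuple(d["positions"]),
            context_weights=cw,
            stop_weights={s: float(w) for s, w in d["stop_weights"].items()},
            k=float(d["k"]),
            units=d.get("units", "percent"),
            name=d.get("name"),
        )
        stored = d.get("weight_norm")
        if stored is not None and not np.isclose(stored, model.weight_norm, rtol=1e-6):
            raise ValueError("stored weight_norm disagrees with recomputed value")
        return model

    @classmethod
    def load(cls, path) -> "RidgeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RTPScore:
    """Predicted BTR (training-y units) and the normalised RTP score."""

    predicted_btr: float
    rtp: float


@dataclass
class LooResult:
    """Leave-one-out cross-validation summary."""

    sse: float
    predictions: np.ndarray  # held-out prediction per example


def design_matrix(
    contexts: Sequence[StopCodonContext], positions: Sequence[int]
) -> np.ndarray:
    """Unit-normalised compact feature matrix (n x (4p + 3))."""
    pos = tuple(positions)
    divisor = np.sqrt(len(pos) + 1)
    return np.stack([encode(c, pos).subvector() for c in contexts]) / divisor


def _solve_ridge(X: np.ndarray, y: np.ndarray, k: float) -> np.ndarray:
    d = X.shape[1]
    A = X.T @ X + k * np.eye(d)
    return scipy.linalg.solve(A, X.T @ y, assume_a="pos")


def _weights_to_maps(
    w: np.ndarray, positions: Sequence[int]
) -> tuple[dict[tuple[int, str], float], dict[str, float]]:
    cw = {}
    for i, p in enumerate(positions):
        for j, b in enumerate(BASES):
            cw[(p, b)] = float(w[4 * i + j])
    sw = {s: float(w[4 * len(positions) + j]) for j, s in enumerate(STOP_CODONS)}
    return cw, sw


def fit_ridge(
    train: TrainingSet,
    positions: Sequence[int] = CONTEXT_POSITIONS,
    k: float = DEFAULT_K,
) -> RidgeModel:
    """Fit the ridge closed form on unit-normalised indicator vectors."""
    if k <= 0:
        raise ValueError("regularisation k must be > 0")
    pos = tuple(positions)
    X = design_matrix(train.contexts, pos)
    w = _solve_ridge(X, train.y, k)
    cw, sw = _weights_to_maps(w, pos)
    return RidgeModel(positions=pos, context_weights=cw, stop_weights=sw,
                      k=k, units=train.units)


def loo_cv_sse(
    train: TrainingSet,
    positions: Sequence[int] = CONTEXT_POSITIONS,
    k: float = DEFAULT_K,
) -> LooResult:
    """Leave-one-out CV error: sum of squared held-out prediction errors.

    Uses the exact hat-matrix identity for ridge LOO residuals,
    e_i / (1 - H_ii) with H = X (X^T X + kI)^(-1) X^T, which equals
    refitting n models each without example i.
    """
    if train.n < 3:
        raise ValueError("leave-one-out CV needs at least 3 examples")
    X = design_matrix(train.contexts, tuple(positions))
    y = train.y
    d = X.shape[1]
    A = X.T @ X + k * np.eye(d)
    # H = X A^{-1} X^T; solve once for all columns
    B = scipy.linalg.solve(A, X.T, assume_a="pos")
    H = X @ B
    resid = y - H @ y
    loo_resid = resid / (1.0 - np.diag(H))
    preds = y - loo_resid
    return LooResult(sse=float(np.sum(loo_resid ** 2)), predictions=preds)


def select_k(
    train: TrainingSet,
    positions: Sequence[int] = CONTEXT_POSITIONS,
    grid: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Grid-search k by loo-CV SSE; ties go to the smallest k."""
    ks = np.asarray(default_k_grid() if grid is None else grid, dtype=float)
    if ks.size == 0:
        raise ValueError("empty k grid")
    sses = np.array([loo_cv_sse(train, positions, k).sse for k in ks])
    order = np.lexsort((ks, sses))  # smallest sse, then smallest k
    best = order[0]
    return float(ks[best]), float(sses[best])


def raw_sum(model: RidgeModel, ctx: StopCodonContext) -> float:
    """Sum of raw weights matched by the context (the published add-up rule)."""
    total = model.stop_weights[ctx.stop]
    for p in model.positions:
        total += model.context_weights[(p, ctx.base_at(p))]
    return float(total)


def predict_btr(model: RidgeModel, ctx: StopCodonContext) -> float:
    """w . x on the unit-normalised feature vector (training-y units)."""
    return raw_sum(model, ctx) / model.feature_divisor


def rtp_score(model: RidgeModel, ctx: StopCodonContext) -> RTPScore:
    """Normalised, dimensionless readthrough propensity (may be negative)."""
    norm = model.weight_norm
    if norm == 0.0:
        raise ValueError("cannot score with a zero-norm model")
    btr = predict_btr(model, ctx)
    return RTPScore(predicted_btr=btr, rtp=btr / norm)


def published_model(name: str) -> RidgeModel:
    """Bundled weight sets transcribed from the published model table.

    Only ``LINiter`` and ``LINfs3`` weights were published; the first-pass
    LIN and the LINfs5 local-optimum weights were not and are unavailable.
    """
    if name not in PUBLISHED_POSITIONS:
        raise KeyError(
            f"unknown model {name!r}: published weights exist only for "
            f"{sorted(PUBLISHED_POSITIONS)}"
        )
    path = resources.files("readthrough.data") / "table2.tsv"
    with resources.as_file(path) as p:
        tab = pd.read_csv(p, sep="\t")
    tab = tab[tab["model"] == name]
    cw = {}
    sw = {}
    for _, row in tab.iterrows():
        if row["position"] == "stop":
            sw[row["base"]] = float(row["weight"])
        else:
            cw[(int(row["position"]), row["base"])] = float(row["weight"])
    return RidgeModel(
        positions=PUBLISHED_POSITIONS[name],
        context_weights=cw,
        stop_weights=sw,
        k=DEFAULT_K,
        units="percent",
        name=name,
    )


def score_table(
    models: dict[str, RidgeModel], table: pd.DataFrame
) -> pd.DataFrame:
    """Batch-score a parsed context table (from read_context_table)."""
    rows = []
    for _, rec in table.iterrows():
        for mname, model in models.items():
            s = rtp_score(model, rec["context"])
            rows.append({
                "context_id": rec["context_id"],
                "model": mname,
                "raw_sum": raw_sum(model, rec["context"]),
                "predicted_btr": s.predicted_btr,
                "rtp": s.rtp,
            })
    return pd.DataFrame(rows)
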