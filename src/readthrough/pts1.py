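"""Peroxisomal targeting signal (PTS1) classification of C-termini.

PTS1 is a C-terminal signal centred on a tripeptide (canonically -SKL) but
modulated by upstream residues.  Peptides are represented as binary
indicator vectors over their last 15 residues (20 amino acids per
position, 300 dimensions); 'X' — used for the recoded stop codon of a
readthrough extension — and residues absent in short peptides leave their
block zero, contributing nothing.

The classifier is a regularised least-squares classifier (RLSC): ridge
regression against +1/-1 class labels, sharing its closed-form solver with
the readthrough-propensity model.  Raw margin-like scores are mapped to
posterior probabilities with a two-parameter logistic (Platt-style)
calibration fitted to held-out cross-validation scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import expit
from sklearn import metrics as skmetrics

WINDOW = 15
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DIM = WINDOW * len(AMINO_ACIDS)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def encode_cterm(seq: str) -> np.ndarray:
    """Indicator-encode the last 15 residues of a peptide.

    Position blocks run -15..-1 from the C-terminus; the number of ones
    equals the number of defined (non-'X') residues in the window.
    """
    s = seq.upper()
    bad = set(s) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {seq!r}")
    v = np.zeros(DIM)
    tail = s[-WINDOW:]
    for offset, aa in enumerate(reversed(tail)):  # offset 0 == position -1
        if aa != "X":
            v[(WINDOW - 1 - offset) * 20 + _AA_INDEX[aa]] = 1.0
    return v


@dataclass
class LabeledPeptideSet:
    """C-terminal peptides with +1 (PTS1-positive) / -1 labels."""

    sequences: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) == 0:
            raise ValueError("empty peptide set")
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels must have equal length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")

    @property
    def n(self) -> int:
        return len(self.sequences)

    def design_matrix(self) -> np.ndarray:
        return np.stack([encode_cterm(s) for s in self.sequences])


@dataclass
class RLSCModel:
    """RLSC weights plus logistic posterior calibration.

    ``calibration`` is (alpha, beta) with alpha > 0; posterior =
    expit(alpha * raw + beta), strictly increasing in the raw score with
    midpoint (p = 0.5) at raw = -beta/alpha.
    """

    weights: np.ndarray
    k: float
    calibration: tuple[float, float] | None = None

    def raw_score(self, seq: str) -> float:
        return float(self.weights @ encode_cterm(seq))


def _solve_rlsc(X: np.ndarray, y: np.ndarray, k: float) -> np.ndarray:
    A = X.T @ X + k * np.eye(X.shape[1])
    return scipy.linalg.solve(A, X.T @ y, assume_a="pos")


def stratified_folds(labels: np.ndarray, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin within class)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def _heldout_scores(
    X: np.ndarray, y: np.ndarray, k: float, folds: int, seed: int = 0
) -> np.ndarray:
    scores = np.empty(len(y))
    for test_idx in stratified_folds(y, folds, seed):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError("a training fold lost one of the classes")
        w = _solve_rlsc(X[train_mask], y[train_mask], k)
        scores[test_idx] = X[test_idx] @ w
    return scores


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Fit expit(alpha*s + beta) to +-1 labels by logistic log-loss.

    alpha is constrained positive so the posterior is strictly increasing.
    """
    t = (labels > 0).astype(float)

    def nll(params):
        alpha, beta = params
        z = alpha * scores + beta
        # log(1+exp(-z)) stable in both tails
        return float(np.sum(np.logaddexp(0.0, z)) - np.sum(t * z))

    res = scipy.optimize.minimize(
        nll, x0=np.array([1.0, 0.0]), method="L-BFGS-B",
        bounds=[(1e-8, None), (None, None)],
    )
    alpha, beta = res.x
    return float(alpha), float(beta)


def fit_rlsc(
    data: LabeledPeptideSet, k: float = 1.0, folds: int = 5, seed: int = 0
) -> RLSCModel:
    """Train the classifier and calibrate its posterior.

    Calibration uses held-out scores from an internal stratified CV at the
    same k; the final weights are refitted on the full data.
    """
    if k <= 0:
        raise ValueError("regularisation k must be > 0")
    y = data.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    X = data.design_matrix()
    heldout = _heldout_scores(X, data.labels, k, folds, seed)
    calibration = fit_platt(heldout, data.labels)
    w = _solve_rlsc(X, y, k)
    return RLSCModel(weights=w, k=k, calibration=calibration)


def posterior(model: RLSCModel, seq: str) -> float:
    """PTS1 posterior probability for a C-terminal peptide."""
    if model.calibration is None:
        raise ValueError("model has no posterior calibration")
    alpha, beta = model.calibration
    return float(expit(alpha * model.raw_score(seq) + beta))


@dataclass
class CVResult:
    auroc: float
    auprc: float
    scores: np.ndarray  # pooled held-out raw scores
    labels: np.ndarray
    class_balance: tuple[int, int]  # (n_positive, n_negative)


def cross_validate(
    data: LabeledPeptideSet, folds: int = 5, k: float = 1.0, seed: int = 0
) -> CVResult:
    """Stratified k-fold CV; pooled held-out scores give auROC and auPRC."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = data.design_matrix()
    scores = _heldout_scores(X, data.labels, k, folds, seed)
    y01 = (data.labels > 0).astype(int)
    auroc = float(skmetrics.roc_auc_score(y01, scores))
    precision, recall, _ = skmetrics.precision_recall_curve(y01, scores)
    auprc = float(skmetrics.auc(recall, precision))
    return CVResult(
        auroc=auroc,
        auprc=auprc,
        scores=scores,
        labels=data.labels.copy(),
        class_balance=(int(np.sum(y01)), int(np.sum(1 - y01))),
    )


def select_k(
    data: LabeledPeptideSet,
    grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Choose k by CV squared error of held-out scores against +-1 labels."""
    from .ridge import default_k_grid

    ks = np.asarray(default_k_grid() if grid is None else grid, dtype=float)
    X = data.design_matrix()
    y = data.labels.astype(float)
    errs = np.array([
        float(np.sum((_heldout_scores(X, data.labels, k, folds, seed) - y) ** 2))
        for k in ks
    ])
    order = np.lexsort((ks, errs))
    return float(ks[order[0]]), float(errs[order[0]])
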