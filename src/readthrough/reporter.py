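"""Dual-reporter readthrough statistics.

In the dual-reporter assay an N-terminal fluorescent protein (Venus) and a
C-terminal luciferase (hRluc) flank the test stop-codon context; stop
suppression expresses the luciferase, and Venus controls for expression.
Readthrough of a construct is the luminescence/fluorescence ratio,
normalised to a no-stop fusion control set to 100%.

Uncertainties follow first-order (delta-method) propagation:
sigma_y = [sigma_x1^2 (dy/dx1)^2 + sigma_x2^2 (dy/dx2)^2]^0.5 for the
ratio y = x2/x1, and replicates are combined by inverse-variance
weighting, x_m = sum(x_i w_i)/sum(w_i) with w_i = 1/sigma_i^2 and
sigma_xm = (sum w_i)^-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReplicateMeasurement:
    """Blank-corrected replicate means and SDs (arbitrary units)."""

    venus: float  # x1, fluorescence
    venus_sd: float
    rluc: float  # x2, luminescence
    rluc_sd: float

    def __post_init__(self) -> None:
        if self.venus <= 0:
            raise ValueError("Venus fluorescence must be positive")
        if self.venus_sd < 0 or self.rluc_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class ReadthroughEstimate:
    """Readthrough in % of the no-stop control, with propagated SD."""

    value: float
    sd: float
    ratios: np.ndarray | None = None
    ratio_sds: np.ndarray | None = None
    n_replicates: int = 1


def ratio_with_sd(m: ReplicateMeasurement) -> tuple[float, float]:
    """Luciferase-per-Venus ratio with first-order error propagation."""
    y = m.rluc / m.venus
    var = (m.rluc_sd / m.venus) ** 2 + (m.venus_sd * m.rluc / m.venus ** 2) ** 2
    return y, float(np.sqrt(var))


def normalize_to_control(
    y: float, sigma_y: float, control: tuple[float, float]
) -> tuple[float, float]:
    """Express a ratio as percent of the no-stop control ratio."""
    y_c, sigma_c = control
    if y_c <= 0:
        raise ValueError("control ratio must be positive")
    value = 100.0 * y / y_c
    var = (100.0 * sigma_y / y_c) ** 2 + (100.0 * y * sigma_c / y_c ** 2) ** 2
    return value, float(np.sqrt(var))


def weighted_mean(
    values: np.ndarray, sds: np.ndarray
) -> tuple[float, float]:
    """Inverse-variance weighted mean of replicate values.

    Zero-SD replicates are rejected: their weight 1/sigma^2 is undefined.
    """
    x = np.asarray(values, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one replicate")
    if x.shape != s.shape:
        raise ValueError("values and sds must have equal length")
    if np.any(s <= 0):
        raise ValueError("replicate SDs must be strictly positive")
    w = 1.0 / s ** 2
    xm = float(np.sum(x * w) / np.sum(w))
    return xm, float(np.sum(w) ** -0.5)


def combine_replicates(
    measurements: list[ReplicateMeasurement],
    control: tuple[float, float],
) -> ReadthroughEstimate:
    """Per-replicate ratios -> percent of control -> weighted mean."""
    vals, sds = [], []
    for m in measurements:
        y, sy = ratio_with_sd(m)
        v, sv = normalize_to_control(y, sy, control)
        vals.append(v)
        sds.append(sv)
    vals = np.asarray(vals)
    sds = np.asarray(sds)
    xm, sxm = weighted_mean(vals, sds)
    return ReadthroughEstimate(
        value=xm, sd=sxm, ratios=vals, ratio_sds=sds, n_replicates=len(vals)
    )


def induction_factor(
    treated: ReadthroughEstimate, untreated: ReadthroughEstimate
) -> tuple[float, float]:
    """Fold induction (e.g. by an aminoglycoside) with propagated SD."""
    if untreated.value <= 0:
        raise ValueError("untreated readthrough must be positive")
    factor = treated.value / untreated.value
    var = (treated.sd / untreated.value) ** 2 + (
        treated.value * untreated.sd / untreated.value ** 2
    ) ** 2
    return factor, float(np.sqrt(var))


def analyze_plate(plate: pd.DataFrame, control_id: str) -> pd.DataFrame:
    """Summarise a plate table into per-sample readthrough estimates.

    Expected columns: sample_id, replicate, venus_mean, venus_sd,
    rluc_mean, rluc_sd, and optional venus_blank / rluc_blank columns that
    are subtracted from the means before any ratio is formed.  The control
    sample (no-stop fusion) defines 100% readthrough; its replicate ratios
    are combined by inverse-variance weighting first.
    """
    df = plate.copy()
    for col, blank in (("venus_mean", "venus_blank"), ("rluc_mean", "rluc_blank")):
        if blank in df.columns:
            df[col] = df[col] - df[blank]
    if control_id not in set(df["sample_id"]):
        raise ValueError(f"control sample {control_id!r} not on the plate")

    def _measurements(sub: pd.DataFrame) -> list[ReplicateMeasurement]:
        return [
            ReplicateMeasurement(
                venus=r["venus_mean"], venus_sd=r["venus_sd"],
                rluc=r["rluc_mean"], rluc_sd=r["rluc_sd"],
            )
            for _, r in sub.iterrows()
        ]

    ctrl = df[df["sample_id"] == control_id]
    ratios = [ratio_with_sd(m) for m in _measurements(ctrl)]
    ctrl_mean, ctrl_sd = weighted_mean(
        np.array([r[0] for r in ratios]), np.array([r[1] for r in ratios])
    )

    rows = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        est = combine_replicates(_measurements(sub), (ctrl_mean, ctrl_sd))
        rows.append({
            "sample_id": sample_id,
            "readthrough_pct": est.value,
            "sd": est.sd,
            "n_replicates": est.n_replicates,
        })
    return pd.DataFrame(rows)
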