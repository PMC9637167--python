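"""Calibration and validation statistics for quantitative NIR models.

RMSEC/RMSEP are root-mean-square errors over the calibration set and an
independent prediction set.  R² (calibration) and Q² (prediction) share the
formula 1 - SS_res/SS_tot; by default Q² centers SS_tot on the test-set
reference mean (a ``train_mean`` option exists).  SECV is the
bias-corrected standard deviation of leave-one-out residuals, and RPD is
the reference SD divided by an error term (SECV by default, RMSEP by
option).  Bias = mean(predicted - reference) is reported, never
thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["rmse", "r_squared", "secv", "rpd", "bias", "EvaluationReport", "evaluate"]


def _as_pair(ref, pred) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(ref, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if r.size != p.size:
        raise ValueError("reference and prediction lengths differ")
    return r, p


def rmse(ref, pred) -> float:
    """Root-mean-square residual (%w/w)."""
    r, p = _as_pair(ref, pred)
    if r.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((r - p) ** 2)))


def r_squared(ref, pred, *, center: float | None = None) -> float:
    """1 - SS_res/SS_tot; ``center`` overrides the mean used in SS_tot.

    Can be negative for worse-than-mean predictions.
    """
    r, p = _as_pair(ref, pred)
    c = float(np.mean(r)) if center is None else float(center)
    ss_tot = float(np.sum((r - c) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in reference values")
    return 1.0 - float(np.sum((r - p) ** 2)) / ss_tot


def secv(loo_residuals) -> float:
    """Bias-corrected SD of leave-one-out residuals: sqrt(Σ(e-ē)²/(n-1))."""
    e = np.asarray(loo_residuals, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("SECV needs at least 2 residuals")
    return float(np.std(e, ddof=1))


def rpd(ref_sd: float, error: float) -> float:
    """Reference SD over a prediction error (dimensionless)."""
    if error <= 0:
        raise ValueError("error term must be > 0")
    return float(ref_sd) / float(error)


def bias(ref, pred) -> float:
    r, p = _as_pair(ref, pred)
    return float(np.mean(p - r))


@dataclass
class EvaluationReport:
    """Summary + per-sample predictions for one analyte on one dataset."""

    analyte: str
    role: str  # calibration | internal_validation | external
    sample_ids: list[str]
    reference: np.ndarray
    predicted: np.ndarray
    rmse: float = field(init=False)
    r2: float = field(init=False)
    bias: float = field(init=False)
    secv: float | None = None
    rpd: float | None = None
    q2_center: str = "test_mean"  # or "train_mean"
    train_mean: float | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float).ravel()
        self.predicted = np.asarray(self.predicted, float).ravel()
        if not (len(self.sample_ids) == self.reference.size == self.predicted.size):
            raise ValueError("ids/reference/predicted lengths differ")
        self.rmse = rmse(self.reference, self.predicted)
        center = None
        if self.q2_center == "train_mean":
            if self.train_mean is None:
                raise ValueError("train_mean required for q2_center='train_mean'")
            center = self.train_mean
        self.r2 = r_squared(self.reference, self.predicted, center=center)
        self.bias = bias(self.reference, self.predicted)

    @property
    def n(self) -> int:
        return self.reference.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "reference": self.reference,
                "predicted": self.predicted,
            }
        )

    def summary(self) -> dict:
        out = {
            "analyte": self.analyte,
            "role": self.role,
            "n": self.n,
            "rmse": self.rmse,
            "r2_or_q2": self.r2,
            "bias": self.bias,
        }
        if self.secv is not None:
            out["secv"] = self.secv
        if self.rpd is not None:
            out["rpd"] = self.rpd
        return out

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for key, val in self.summary().items():
                fh.write(f"# {key}: {val}\n")
            self.to_frame().to_csv(fh, index=False)


def evaluate(
    analyte: str,
    role: str,
    sample_ids: list[str],
    reference,
    predicted,
    *,
    loo_residuals=None,
    rpd_error: str = "secv",
    q2_center: str = "test_mean",
    train_mean: float | None = None,
) -> EvaluationReport:
    """Assemble an EvaluationReport, with SECV/RPD when CV residuals exist."""
    rep = EvaluationReport(
        analyte=analyte,
        role=role,
        sample_ids=list(sample_ids),
        reference=reference,
        predicted=predicted,
        q2_center=q2_center,
        train_mean=train_mean,
    )
    if loo_residuals is not None:
        rep.secv = secv(loo_residuals)
    sd_ref = float(np.std(np.asarray(reference, float), ddof=1))
    err = None
    if rpd_error == "secv" and rep.secv is not None:
        err = rep.secv
    elif rpd_error == "rmsep":
        err = rep.rmse
    if err is not None and err > 0:
        rep.rpd = rpd(sd_ref, err)
    return rep
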