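"""NIPALS partial least squares regression (single response).

PLS1 links pretreated spectra X (samples x channels) to one analyte
concentration y (%w/w) through a small number of latent variables.  Each
NIPALS round extracts a weight vector w maximizing cov(Xw, y), computes
scores t = Xw, loadings p = X't/t't and y-loading q = t'y/t't, then
deflates X.  The latent model collapses to a single regression vector

    b = W (P'W)^-1 q,       yhat = (x - x_center) b + y_center

so prediction is affine in the input spectrum.  The latent-variable count
is chosen by leave-one-out cross-validation: global-minimum RMSECV, ties
broken toward fewer LVs, with centering refitted inside every fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import CenteringModel
from .spectra_io import ReferenceTable, SpectraSet, WavelengthGrid

__all__ = ["PLSModel", "CVResult", "fit_pls1", "predict", "select_n_lv_loo"]

# NIPALS inner-loop settings: PLS1 converges in one pass, the loop is kept
# for generality (and exercised by the PLS2 variant used for transfer).
_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def nipals_pls(
    X: np.ndarray, Y: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw NIPALS on already-centered (or deliberately uncentered) data.

    Y may have one column (PLS1) or several (PLS2).  Returns (W, P, Q, T)
    with W, P of shape (p, n_lv), Q of shape (m, n_lv), T of (n, n_lv).
    Components whose score norm underflows terminate extraction early.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    actual = 0
    for a in range(n_lv):
        u = Y[:, np.argmax(np.sum(Y**2, axis=0))].copy()
        if np.linalg.norm(u) < 1e-14 or np.linalg.norm(X) < 1e-14:
            break
        w = np.zeros(p)
        for _ in range(_NIPALS_MAX_ITER):
            w_new = X.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-14:
                break
            w_new /= nrm
            t = X @ w_new
            tt = t @ t
            if tt < 1e-28:
                break
            q = Y.T @ t / tt
            if m == 1:
                w = w_new
                break
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
            u = u_new
        t = X @ w
        tt = t @ t
        if tt < 1e-28 or np.linalg.norm(w) < 1e-14:
            break
        p_vec = X.T @ t / tt
        q_vec = Y.T @ t / tt
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q_vec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q_vec, t
        actual = a + 1
    return W[:, :actual], P[:, :actual], Q[:, :actual], T[:, :actual]


def regression_matrix(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Collapse NIPALS factors into B with X B ~= Y (shape p x m)."""
    if W.shape[1] == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    return W @ np.linalg.solve(P.T @ W, Q.T)


@dataclass
class PLSModel:
    """A fitted PLS1 calibration for one analyte."""

    n_lv: int
    weights: np.ndarray  # (p, n_lv)
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    regression_vector: np.ndarray  # (p,)
    x_center: CenteringModel
    y_center: float
    analyte: str
    training_ids: list[str] = field(default_factory=list)
    grid: WavelengthGrid | None = None
    pretreatment: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "nirtransfer.pls_model/1",
            "analyte": self.analyte,
            "n_lv": self.n_lv,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "x_center": self.x_center.column_means.tolist(),
            "x_center_n": self.x_center.source_n,
            "y_center": self.y_center,
            "training_ids": self.training_ids,
            "grid": None
            if self.grid is None
            else [self.grid.start_nm, self.grid.step_nm, self.grid.n_channels],
            "pretreatment": self.pretreatment,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if d.get("format") != "nirtransfer.pls_model/1":
            raise ValueError("unrecognized model file format")
        grid = d["grid"]
        return cls(
            n_lv=d["n_lv"],
            weights=np.array(d["weights"], float),
            x_loadings=np.array(d["x_loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
            regression_vector=np.array(d["regression_vector"], float),
            x_center=CenteringModel(
                column_means=np.array(d["x_center"], float),
                source_n=d["x_center_n"],
            ),
            y_center=d["y_center"],
            analyte=d["analyte"],
            training_ids=list(d["training_ids"]),
            grid=None if grid is None else WavelengthGrid(*grid),
            pretreatment=list(d["pretreatment"]),
        )


def fit_pls1(X: SpectraSet, y: ReferenceTable, n_lv: int) -> PLSModel:
    """Fit a PLS1 model on pretreated spectra.

    Centering of X and y happens here (means are stored in the model), so
    ``X`` should carry any SNV-type pretreatment but NOT be pre-centered.
    """
    yv = y.aligned_to(X)
    n, p = X.absorbance.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    if np.std(yv) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.absorbance.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = X.absorbance - x_mean
    yc = yv - y_mean
    W, P, Q, _T = nipals_pls(Xc, yc, n_lv)
    b = regression_matrix(W, P, Q)[:, 0]
    return PLSModel(
        n_lv=W.shape[1],
        weights=W,
        x_loadings=P,
        y_loadings=Q[0],
        regression_vector=b,
        x_center=CenteringModel(column_means=x_mean, source_n=n),
        y_center=y_mean,
        analyte=y.analyte,
        training_ids=list(X.sample_ids),
        grid=X.grid,
        pretreatment=list(X.pretreatment),
    )


def predict(model: PLSModel, X: SpectraSet, *, strict: bool = False) -> np.ndarray:
    """Predict %w/w for each row of X via the regression vector.

    With ``strict`` the pretreatment tag trail must equal the training one
    (ignoring the 'centered' tag, since centering is part of the model).
    """
    if model.grid is not None and X.grid != model.grid:
        raise ValueError("wavelength grid differs from the training grid")
    if strict:
        trained = [t for t in model.pretreatment if t != "centered"]
        got = [t for t in X.pretreatment if t != "centered"]
        if trained != got:
            raise ValueError(
                f"pretreatment mismatch: model fitted on {trained}, input has {got}"
            )
    Xc = X.absorbance - model.x_center.column_means
    return Xc @ model.regression_vector + model.y_center


def predict_scores(model: PLSModel, X: SpectraSet) -> np.ndarray:
    """Score-space prediction path (t·q); algebraically equal to `predict`."""
    Xc = X.absorbance - model.x_center.column_means
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    T = Xc @ R
    return T @ np.asarray(model.y_loadings) + model.y_center


@dataclass
class CVResult:
    """Leave-one-out cross-validation over candidate LV counts."""

    rmsecv: dict[int, float]
    chosen_n_lv: int
    loo_residuals: np.ndarray  # (n_samples,) at the chosen LV count

    @property
    def secv_residuals(self) -> np.ndarray:
        return self.loo_residuals


def select_n_lv_loo(X: SpectraSet, y: ReferenceTable, max_lv: int) -> CVResult:
    """LOO-CV latent-variable selection with per-fold centering."""
    yv = y.aligned_to(X)
    n, p = X.absorbance.shape
    if n < 3:
        raise ValueError("LOO selection needs at least 3 samples")
    cap = min(n - 2, p)
    if not 1 <= max_lv <= cap:
        raise ValueError(f"max_lv must be in [1, {cap}], got {max_lv}")
    preds = np.zeros((n, max_lv))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, ytr = X.absorbance[keep], yv[keep]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, Q, _ = nipals_pls(Xtr - x_mean, ytr - y_mean, max_lv)
        xc = X.absorbance[i] - x_mean
        for a in range(1, max_lv + 1):
            k = min(a, W.shape[1])
            b = regression_matrix(W[:, :k], P[:, :k], Q[:, :k])[:, 0]
            preds[i, a - 1] = xc @ b + y_mean
    rmsecv = {
        a: float(np.sqrt(np.mean((preds[:, a - 1] - yv) ** 2)))
        for a in range(1, max_lv + 1)
    }
    best = min(rmsecv.values())
    chosen = min(a for a, v in rmsecv.items() if v <= best + 1e-12)
    return CVResult(
        rmsecv=rmsecv,
        chosen_n_lv=chosen,
        loo_residuals=preds[:, chosen - 1] - yv,
    )
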