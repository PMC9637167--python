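"""Direct and piecewise direct standardization (DS / PDS).

Both methods learn a transformation matrix F mapping slave-state spectra
(tablets) into the master-state domain (powders) from samples measured in
both states:

    X_master = X_slave @ F

DS estimates F with one global multivariate PLS regression of the master
matrix on the slave matrix, giving a dense F.  PDS regresses each master
channel j only on the slave channels j-k .. j+k (windows truncated at the
spectrum edges) with a small local PLS, and assembles the coefficient
vectors into a banded F — which is what makes PDS robust to low-frequency
baseline drift that a dense DS map propagates across the whole axis.

No intercept is fitted by default (the transfer equation has none); the
classical additive offset term is available via ``with_offset``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plsr import nipals_pls, regression_matrix
from .spectra_io import SpectraSet, WavelengthGrid

__all__ = ["TransferModel", "fit_ds", "fit_pds", "apply_transfer"]


@dataclass
class TransferModel:
    """A fitted slave -> master standardization map."""

    method: str  # "DS" | "PDS"
    F: np.ndarray  # (p, p); banded with half-width k for PDS
    k: int | None  # PDS window half-width in channels
    per_window_lv: int
    fit_on: list[str]  # pretreatment tags of the fitting spectra
    master_ids: list[str] = field(default_factory=list)
    slave_ids: list[str] = field(default_factory=list)
    offset: np.ndarray | None = None
    training_residual_rms: float = float("nan")
    grid: WavelengthGrid | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "nirtransfer.transfer_model/1",
            "method": self.method,
            "k": self.k,
            "per_window_lv": self.per_window_lv,
            "fit_on": self.fit_on,
            "master_ids": self.master_ids,
            "slave_ids": self.slave_ids,
            "training_residual_rms": self.training_residual_rms,
            "grid": None
            if self.grid is None
            else [self.grid.start_nm, self.grid.step_nm, self.grid.n_channels],
            "offset": None if self.offset is None else self.offset.tolist(),
        }
        if self.method == "PDS" and self.k is not None:
            # store only the diagonal band to keep files small
            p = self.F.shape[0]
            band = {}
            for d in range(-self.k, self.k + 1):
                band[str(d)] = np.diagonal(self.F, offset=d).tolist()
            payload["band"] = band
            payload["n_channels"] = p
        else:
            payload["F"] = self.F.tolist()
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TransferModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if d.get("format") != "nirtransfer.transfer_model/1":
            raise ValueError("unrecognized transfer model format")
        if "band" in d:
            p = d["n_channels"]
            F = np.zeros((p, p))
            for off, diag in d["band"].items():
                off = int(off)
                idx = np.arange(len(diag))
                if off >= 0:
                    F[idx, idx + off] = diag
                else:
                    F[idx - off, idx] = diag
        else:
            F = np.array(d["F"], float)
        grid = d["grid"]
        return cls(
            method=d["method"],
            F=F,
            k=d["k"],
            per_window_lv=d["per_window_lv"],
            fit_on=list(d["fit_on"]),
            master_ids=list(d["master_ids"]),
            slave_ids=list(d["slave_ids"]),
            offset=None if d["offset"] is None else np.array(d["offset"], float),
            training_residual_rms=d["training_residual_rms"],
            grid=None if grid is None else WavelengthGrid(*grid),
        )


def _check_pairs(master: SpectraSet, slave: SpectraSet) -> tuple[np.ndarray, np.ndarray]:
    if master.grid != slave.grid:
        raise ValueError("master and slave grids differ")
    if set(master.sample_ids) != set(slave.sample_ids):
        raise ValueError("master and slave sample IDs are not paired")
    if master.n_samples < 2:
        raise ValueError("need at least 2 standardization pairs")
    slave = slave.select(master.sample_ids)  # align row order by ID
    return master.absorbance, slave.absorbance


def _finish(
    model: TransferModel, Xm: np.ndarray, Xs: np.ndarray
) -> TransferModel:
    fitted = Xs @ model.F
    if model.offset is not None:
        fitted = fitted + model.offset
    model.training_residual_rms = float(np.sqrt(np.mean((fitted - Xm) ** 2)))
    return model


def fit_ds(
    master: SpectraSet,
    slave: SpectraSet,
    lv: int,
    *,
    with_offset: bool = False,
) -> TransferModel:
    """Dense F from one global PLS2 regression of master on slave."""
    Xm, Xs = _check_pairs(master, slave)
    n = Xm.shape[0]
    if not 1 <= lv <= n:
        raise ValueError(f"lv must be in [1, {n}]")
    offset = None
    if with_offset:
        ms, mm = Xs.mean(axis=0), Xm.mean(axis=0)
        W, P, Q, _ = nipals_pls(Xs - ms, Xm - mm, lv)
        F = regression_matrix(W, P, Q)
        offset = mm - ms @ F
    else:
        W, P, Q, _ = nipals_pls(Xs, Xm, lv)
        F = regression_matrix(W, P, Q)
    model = TransferModel(
        method="DS",
        F=F,
        k=None,
        per_window_lv=lv,
        fit_on=list(slave.pretreatment),
        master_ids=list(master.sample_ids),
        slave_ids=list(master.sample_ids),
        offset=offset,
        grid=master.grid,
    )
    return _finish(model, Xm, Xs)


def fit_pds(
    master: SpectraSet,
    slave: SpectraSet,
    k: int,
    lv: int,
    *,
    with_offset: bool = False,
) -> TransferModel:
    """Banded F from per-channel windowed PLS regressions.

    For each master channel j the slave window j-k .. j+k (truncated at the
    edges) is regressed onto master column j; the coefficient vectors are
    assembled into the band of F.  ``lv`` is clamped to the window width at
    the edges.
    """
    Xm, Xs = _check_pairs(master, slave)
    n, p = Xm.shape
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= p:
        raise ValueError(f"k must be < n_channels ({p})")
    if lv < 1 or lv > 2 * k + 1:
        raise ValueError(f"lv must be in [1, window width {2 * k + 1}]")
    F = np.zeros((p, p))
    offset = np.zeros(p) if with_offset else None
    for j in range(p):
        lo, hi = max(0, j - k), min(p - 1, j + k)
        win = Xs[:, lo : hi + 1]
        yj = Xm[:, j]
        a = min(lv, win.shape[1])
        if with_offset:
            wm, ym = win.mean(axis=0), yj.mean()
            W, P, Q, _ = nipals_pls(win - wm, yj - ym, a)
            b = regression_matrix(W, P, Q)[:, 0]
            offset[j] = ym - wm @ b
        else:
            W, P, Q, _ = nipals_pls(win, yj, a)
            b = regression_matrix(W, P, Q)[:, 0]
        F[lo : hi + 1, j] = b
    model = TransferModel(
        method="PDS",
        F=F,
        k=k,
        per_window_lv=lv,
        fit_on=list(slave.pretreatment),
        master_ids=list(master.sample_ids),
        slave_ids=list(master.sample_ids),
        offset=offset,
        grid=master.grid,
    )
    return _finish(model, Xm, Xs)


def apply_transfer(
    model: TransferModel, unknown: SpectraSet, *, strict: bool = True
) -> SpectraSet:
    """Map unknown slave-state spectra into the master domain via F."""
    if model.grid is not None and unknown.grid != model.grid:
        raise ValueError("grid mismatch between transfer model and spectra")
    if strict and list(unknown.pretreatment) != list(model.fit_on):
        raise ValueError(
            f"pretreatment mismatch: F fitted on {model.fit_on}, "
            f"input has {list(unknown.pretreatment)}"
        )
    out = unknown.absorbance @ model.F
    if model.offset is not None:
        out = out + model.offset
    return unknown.with_matrix(out, state="transformed")
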