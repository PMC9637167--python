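"""End-to-end study orchestration.

Stages: build the spiking design -> simulate (or load) powder/tablet
spectra -> pretreat (SNV, then mean-centering with training statistics) ->
fit a PLS1 calibration per analyte with LOO-CV latent-variable selection ->
evaluate on the internal validation powders -> fit DS and PDS on the
external powder/tablet pairs -> predict the external tablets under three
conditions (no transfer, DS, PDS) -> emit per-analyte report tables.

The only quantity ever fitted on external samples is the transformation
matrix F itself, matching a strict external-validation protocol.  Under
the default ``fit_on_all`` pairing all available pairs feed F (and the run
log notes this prominently); ``leave_pair_out`` refits F without each pair
before predicting it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, plsr, preprocess, synthetic, transfer
from .metrics import EvaluationReport
from .spectra_io import SpectraSet, read_spectra_csv, read_reference_csv

__all__ = ["RunConfig", "StudyResult", "run_study", "report_table"]

CONDITIONS = ("none", "DS", "PDS")


@dataclass
class RunConfig:
    """Validated, serializable configuration of one study run."""

    seed: int = 1
    analytes: tuple[str, ...] = ("sucrose", "lactose")
    max_lv: int = 15
    transfer_on: str = "raw"  # or "snv"
    ds_lv: int = 5
    pds_k: int = 5
    pds_lv: int = 2
    protocol: str = "fit_on_all"  # or "leave_pair_out"
    drift_amplitude: float = 0.0  # extra low-frequency baseline on tablets
    q2_center: str = "test_mean"
    rpd_error: str = "secv"
    data_dir: str | None = None  # load spectra instead of simulating
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.transfer_on not in ("snv", "raw"):
            raise ValueError("transfer_on must be 'snv' or 'raw'")
        if self.protocol not in ("fit_on_all", "leave_pair_out"):
            raise ValueError("protocol must be 'fit_on_all' or 'leave_pair_out'")
        for a in self.analytes:
            if a not in ("sucrose", "lactose"):
                raise ValueError(f"unknown analyte {a!r}")
        if self.max_lv < 1 or self.ds_lv < 1 or self.pds_lv < 1 or self.pds_k < 0:
            raise ValueError("latent-variable counts must be >= 1 and k >= 0")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class StudyResult:
    config: RunConfig
    reports: dict[tuple[str, str, str], EvaluationReport]  # (analyte, role, cond)
    pls_models: dict[str, plsr.PLSModel]
    cv: dict[str, plsr.CVResult]
    transfer_models: dict[str, transfer.TransferModel]
    transformed: dict[str, SpectraSet]
    log: list[str] = field(default_factory=list)

    def report(self, analyte: str, role: str, condition: str = "-") -> EvaluationReport:
        return self.reports[(analyte, role, condition)]


def _pretreat(spectra: SpectraSet, on: str) -> SpectraSet:
    return preprocess.snv(spectra) if on == "snv" else spectra


def _load_bundle(data_dir: str) -> synthetic.StudyBundle:
    d = Path(data_dir)
    train = read_spectra_csv(d / "train.csv")
    internal = read_spectra_csv(d / "internal.csv")
    ext_p = read_spectra_csv(d / "external_powder.csv")
    ext_t = read_spectra_csv(d / "external_tablet.csv")
    return synthetic.StudyBundle(
        train=train,
        train_refs=read_reference_csv(d / "train_refs.csv"),
        internal=internal,
        internal_refs=read_reference_csv(d / "internal_refs.csv"),
        external_powder=ext_p,
        external_tablet=ext_t,
        external_refs=read_reference_csv(d / "external_refs.csv"),
        effect=synthetic.default_tablet_effect(),
    )


def _fit_transfers(
    master: SpectraSet, slave: SpectraSet, cfg: RunConfig
) -> dict[str, transfer.TransferModel]:
    return {
        "DS": transfer.fit_ds(master, slave, lv=min(cfg.ds_lv, master.n_samples)),
        "PDS": transfer.fit_pds(master, slave, k=cfg.pds_k, lv=cfg.pds_lv),
    }


def _transfer_predictions(
    method: str,
    master: SpectraSet,
    slave_fit: SpectraSet,
    slave_pred: SpectraSet,
    cfg: RunConfig,
    models_all: dict[str, transfer.TransferModel],
) -> SpectraSet:
    """Standardized slave spectra under the configured pairing protocol."""
    if cfg.protocol == "fit_on_all":
        return transfer.apply_transfer(models_all[method], slave_pred)
    # leave_pair_out: refit F without each pair, predict the held-out row
    rows = []
    ids = list(master.sample_ids)
    for sid in ids:
        rest = [s for s in ids if s != sid]
        m_fit, s_fit = master.select(rest), slave_fit.select(rest)
        models = _fit_transfers(m_fit, s_fit, cfg)
        out = transfer.apply_transfer(models[method], slave_pred.select([sid]))
        rows.append(out.absorbance[0])
    return slave_pred.with_matrix(np.asarray(rows), state="transformed")


def run_study(config: RunConfig) -> StudyResult:
    """Run the full calibration-transfer study; deterministic given seed."""
    log: list[str] = [f"config hash {config.config_hash()}"]
    log.append(f"settings: {json.dumps(asdict(config), sort_keys=True)}")

    if config.data_dir:
        bundle = _load_bundle(config.data_dir)
        log.append(f"stage load: spectra read from {config.data_dir}")
    else:
        bundle = synthetic.make_study(config.seed)
        log.append(f"stage simulate: synthetic study bundle, seed {config.seed}")

    # The standardization pairs are measured at fit time; drift models a
    # later instrumental shift, so it affects only the predicted spectra.
    tablet_fit = bundle.external_tablet
    tablet = tablet_fit
    if config.drift_amplitude > 0:
        tablet = synthetic.add_baseline_drift(
            tablet_fit,
            seed=(config.seed * 4 + 3 + 1000) % (2**31 - 1),
            amplitude=config.drift_amplitude,
        )
        log.append(
            f"stage drift: baseline drift (amplitude {config.drift_amplitude} AU) "
            "added to the prediction-time tablet spectra"
        )

    # --- pretreatment ------------------------------------------------------
    train_snv = preprocess.snv(bundle.train)
    internal_snv = preprocess.snv(bundle.internal)
    log.append("stage pretreat: SNV on train/internal; centering via PLS fit")

    # --- calibration per analyte ------------------------------------------
    reports: dict[tuple[str, str, str], EvaluationReport] = {}
    pls_models: dict[str, plsr.PLSModel] = {}
    cv_results: dict[str, plsr.CVResult] = {}
    for analyte in config.analytes:
        y = bundle.train_refs[analyte]
        max_lv = min(config.max_lv, bundle.train.n_samples - 2)
        cv = plsr.select_n_lv_loo(train_snv, y, max_lv)
        model = plsr.fit_pls1(train_snv, y, cv.chosen_n_lv)
        pls_models[analyte] = model
        cv_results[analyte] = cv
        log.append(
            f"stage train[{analyte}]: n_lv={cv.chosen_n_lv} "
            f"(RMSECV {cv.rmsecv[cv.chosen_n_lv]:.4f})"
        )
        yv = y.aligned_to(train_snv)
        reports[(analyte, "calibration", "-")] = metrics.evaluate(
            analyte,
            "calibration",
            train_snv.sample_ids,
            yv,
            plsr.predict(model, train_snv),
            loo_residuals=cv.loo_residuals,
            rpd_error=config.rpd_error,
        )
        y_int = bundle.internal_refs[analyte].aligned_to(internal_snv)
        reports[(analyte, "internal_validation", "-")] = metrics.evaluate(
            analyte,
            "internal_validation",
            internal_snv.sample_ids,
            y_int,
            plsr.predict(model, internal_snv),
            q2_center=config.q2_center,
            train_mean=float(yv.mean()),
        )

    # --- calibration transfer on the external pairs -----------------------
    master = _pretreat(bundle.external_powder, config.transfer_on)
    slave_fit = _pretreat(tablet_fit, config.transfer_on)
    slave = _pretreat(tablet, config.transfer_on)
    transfer_models = _fit_transfers(master, slave_fit, config)
    if config.protocol == "fit_on_all":
        log.append(
            "NOTE: transfer matrices fitted on ALL external pairs "
            "(fit-on-all protocol); the same pairs are then predicted."
        )
    transformed: dict[str, SpectraSet] = {}
    for method in ("DS", "PDS"):
        transformed[method] = _transfer_predictions(
            method, master, slave_fit, slave, config, transfer_models
        )
        log.append(
            f"stage transfer[{method}]: training residual RMS "
            f"{transfer_models[method].training_residual_rms:.5f}"
        )

    # --- external predictions: none / DS / PDS ----------------------------
    slave_for_model = preprocess.snv(tablet) if config.transfer_on == "raw" else slave
    for analyte in config.analytes:
        model = pls_models[analyte]
        y_ext = bundle.external_refs[analyte].aligned_to(tablet)
        y_train_mean = model.y_center
        cases = {"none": slave_for_model}
        for method in ("DS", "PDS"):
            std = transformed[method]
            cases[method] = (
                preprocess.snv(std) if config.transfer_on == "raw" else std
            )
        for cond, spectra in cases.items():
            pred = plsr.predict(model, spectra)
            reports[(analyte, "external", cond)] = metrics.evaluate(
                analyte,
                "external",
                spectra.sample_ids,
                y_ext,
                pred,
                q2_center=config.q2_center,
                train_mean=y_train_mean,
            )
            log.append(
                f"stage predict[{analyte},{cond}]: RMSEP "
                f"{reports[(analyte, 'external', cond)].rmse:.4f}"
            )

    result = StudyResult(
        config=config,
        reports=reports,
        pls_models=pls_models,
        cv=cv_results,
        transfer_models=transfer_models,
        transformed=transformed,
        log=log,
    )
    if config.output_dir:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _write_artifacts(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(asdict(result.config)), encoding="utf-8"
    )
    (outdir / "run.log").write_text("\n".join(result.log) + "\n", encoding="utf-8")
    for analyte, model in result.pls_models.items():
        model.to_json(outdir / f"pls_{analyte}.json")
    for method, model in result.transfer_models.items():
        model.to_json(outdir / f"transfer_{method.lower()}.json")
    for analyte in result.config.analytes:
        report_table(result, analyte).to_csv(outdir / f"table_{analyte}.csv", index=False)
    summary = {
        f"{a}/{r}/{c}": rep.summary() for (a, r, c), rep in result.reports.items()
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")


def report_table(result: StudyResult, analyte: str) -> pd.DataFrame:
    """External-prediction table: actual vs predicted per condition, plus
    summary Q2 and RMSEP rows (conditions ordered none, DS, PDS)."""
    base = result.report(analyte, "external", "none")
    df = pd.DataFrame({"sample_id": base.sample_ids, "actual": base.reference})
    for cond in CONDITIONS:
        rep = result.report(analyte, "external", cond)
        df[f"predicted_{cond}"] = rep.predicted
    summary_rows = []
    for stat in ("Q2", "RMSEP"):
        row = {"sample_id": stat, "actual": np.nan}
        for cond in CONDITIONS:
            rep = result.report(analyte, "external", cond)
            row[f"predicted_{cond}"] = rep.r2 if stat == "Q2" else rep.rmse
        summary_rows.append(row)
    return pd.concat([df, pd.DataFrame(summary_rows)], ignore_index=True)
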