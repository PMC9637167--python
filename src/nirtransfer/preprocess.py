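"""Spectral pretreatment: standard normal variate and mean-centering.

SNV removes per-spectrum offset and multiplicative scatter by centering and
scaling each row to unit standard deviation (n-1 denominator).  Centering
statistics are fitted on the training set only and re-applied to any later
set, so validation and transferred spectra are always centered with the
TRAINING column means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraSet

__all__ = ["CenteringModel", "snv", "fit_centering", "apply_centering"]


@dataclass
class CenteringModel:
    """Column means learned from a training SpectraSet."""

    column_means: np.ndarray
    source_n: int

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        if self.column_means.ndim != 1:
            raise ValueError("column_means must be 1-D")
        if not np.all(np.isfinite(self.column_means)):
            raise ValueError("non-finite centering means")


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each row to mean 0, sample SD 1.

    Raises if any row has zero variance (the offending sample is named).
    """
    X = spectra.absorbance
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        names = [spectra.sample_ids[i] for i in bad]
        raise ValueError(f"zero variance row(s), cannot apply SNV: {names}")
    return spectra.with_matrix((X - mu) / sd, extra_tags=["snv"])


def fit_centering(train: SpectraSet) -> CenteringModel:
    """Column means of the training matrix (>= 2 rows required)."""
    if train.n_samples < 2:
        raise ValueError("centering needs at least 2 training rows")
    return CenteringModel(
        column_means=train.absorbance.mean(axis=0), source_n=train.n_samples
    )


def apply_centering(model: CenteringModel, spectra: SpectraSet) -> SpectraSet:
    """Subtract the stored training means from every row."""
    if model.column_means.size != spectra.n_channels:
        raise ValueError(
            f"centering model has {model.column_means.size} channels, "
            f"spectra have {spectra.n_channels}"
        )
    return spectra.with_matrix(
        spectra.absorbance - model.column_means[None, :], extra_tags=["centered"]
    )
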