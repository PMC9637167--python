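"""Two-factor spiking design for building sugar calibration sets.

Base milk powders are spiked with sucrose and lactose at three coded
levels (-1, 0, +1 -> 0.00, 15.00, 30.00 g added per 100 g base), in a
face-centered central composite layout whose axial points coincide with the
3x3 factorial frame — nine runs per base sample, 27 rows for three bases.
Final concentrations follow a mass-balance convention: adding ``a`` grams
to 100 g of base dilutes everything into ``100 + a_s + a_l`` grams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_io import ReferenceTable

__all__ = [
    "BaseSample",
    "DesignTable",
    "ccd_points",
    "decode_amount",
    "final_composition",
    "build_training_design",
    "TRAINING_BASES",
    "INTERNAL_BASES",
    "EXTERNAL_SAMPLES",
]

#: code level -> grams of sugar added per 100 g base powder (%w/w basis)
_CODE_TO_AMOUNT = {-1: 0.00, 0: 15.00, 1: 30.00}

# Published reference concentrations (%w/w) of the thirteen commercial
# milk-tablet brands used in the study design.
TRAINING_BASES = [("T1", 21.31, 36.24), ("T2", 27.11, 28.66), ("T3", 14.20, 26.46)]
INTERNAL_BASES = [("I1", 27.76, 25.71), ("I2", 27.00, 33.40), ("I3", 22.31, 28.48)]
EXTERNAL_SAMPLES = [
    ("E1", 21.78, 38.99),
    ("E2", 39.04, 0.000),
    ("E3", 43.69, 0.000),
    ("E4", 28.04, 28.47),
    ("E5", 20.06, 30.68),
    ("E6", 16.72, 29.32),
    ("E7", 25.48, 28.94),
]


@dataclass(frozen=True)
class BaseSample:
    """A base (pre-spiking) milk powder with its native sugar contents."""

    id: str
    sucrose0: float
    lactose0: float

    def __post_init__(self) -> None:
        for v in (self.sucrose0, self.lactose0):
            if not 0 <= v <= 100:
                raise ValueError("base concentrations must lie in [0, 100] %w/w")
        if self.sucrose0 + self.lactose0 > 100:
            raise ValueError("base sugar contents exceed 100 %w/w")


@dataclass
class DesignTable:
    """Decoded spiking design: one row per (base sample, code pair)."""

    frame: pd.DataFrame  # columns: sample_id, base_id, code_sucrose,
    # code_lactose, added_sucrose, added_lactose, final_sucrose, final_lactose

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def reference(self, analyte: str) -> ReferenceTable:
        """Extract the reference-concentration vector for one analyte."""
        return ReferenceTable(
            sample_ids=self.sample_ids,
            analyte=analyte,
            values=self.frame[f"final_{analyte}"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def ccd_points() -> list[tuple[int, int]]:
    """The nine (sucrose, lactose) code pairs, in published run order."""
    return [(s, l) for s in (-1, 0, 1) for l in (-1, 0, 1)]


def decode_amount(code: int) -> float:
    """Coded level -> added amount in %w/w (0.00 / 15.00 / 30.00)."""
    try:
        return _CODE_TO_AMOUNT[code]
    except KeyError:
        raise ValueError(f"code must be -1, 0 or +1, got {code!r}") from None


def final_composition(
    base: BaseSample, added_sucrose: float, added_lactose: float
) -> tuple[float, float]:
    """Mass-balance final concentrations after spiking.

    ``a`` %w/w added is read as ``a`` grams per 100 g of base powder, so the
    total mass grows to ``100 + a_s + a_l`` grams.
    """
    if added_sucrose < 0 or added_lactose < 0:
        raise ValueError("added amounts must be >= 0")
    total = 100.0 + added_sucrose + added_lactose
    fs = 100.0 * (base.sucrose0 + added_sucrose) / total
    fl = 100.0 * (base.lactose0 + added_lactose) / total
    return fs, fl


def final_composition_no_renorm(
    base: BaseSample, added_sucrose: float, added_lactose: float
) -> tuple[float, float]:
    """Alternative convention: final = base + added, capped at 100 %w/w."""
    if added_sucrose < 0 or added_lactose < 0:
        raise ValueError("added amounts must be >= 0")
    return (
        min(base.sucrose0 + added_sucrose, 100.0),
        min(base.lactose0 + added_lactose, 100.0),
    )


def build_training_design(
    bases: list[BaseSample], *, mixing: str = "mass_balance"
) -> DesignTable:
    """Nine spiking runs per base sample (27 rows for the usual 3 bases)."""
    if len({b.id for b in bases}) != len(bases):
        raise ValueError("duplicate base sample IDs")
    mix = {
        "mass_balance": final_composition,
        "additive_no_renorm": final_composition_no_renorm,
    }[mixing]
    rows = []
    for base in bases:
        for run, (cs, cl) in enumerate(ccd_points(), start=1):
            a_s, a_l = decode_amount(cs), decode_amount(cl)
            fs, fl = mix(base, a_s, a_l)
            rows.append(
                {
                    "sample_id": f"{base.id}-{run}",
                    "base_id": base.id,
                    "code_sucrose": cs,
                    "code_lactose": cl,
                    "added_sucrose": a_s,
                    "added_lactose": a_l,
                    "final_sucrose": fs,
                    "final_lactose": fl,
                }
            )
    return DesignTable(frame=pd.DataFrame(rows))


def bases_from_tuples(spec: list[tuple[str, float, float]]) -> list[BaseSample]:
    return [BaseSample(id=i, sucrose0=s, lactose0=l) for i, s, l in spec]


def default_training_design(*, mixing: str = "mass_balance") -> DesignTable:
    """27-row design over the published T1-T3 base compositions."""
    return build_training_design(bases_from_tuples(TRAINING_BASES), mixing=mixing)


def default_internal_design(*, mixing: str = "mass_balance") -> DesignTable:
    """27-row design over the published I1-I3 base compositions."""
    return build_training_design(bases_from_tuples(INTERNAL_BASES), mixing=mixing)
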