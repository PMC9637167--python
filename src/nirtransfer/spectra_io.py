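"""Spectral data model and bit-exact CSV / JCAMP-DX I/O.

The in-memory container is :class:`SpectraSet`: a samples x channels
absorbance matrix on a :class:`WavelengthGrid` (constant nm spacing),
tagged with a measurement state (``powder`` | ``tablet`` | ``transformed``)
and an append-only list of pretreatment tags.  Files use one CSV dialect
only: comma separated, ``.`` decimal, UTF-8, ``#``-prefixed metadata lines,
header ``sample_id`` followed by wavelengths in nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "ReferenceTable",
    "DEFAULT_GRID",
    "read_spectra_csv",
    "write_spectra_csv",
    "import_jcamp",
    "read_reference_csv",
]

STATES = ("powder", "tablet", "transformed")

#: Relative tolerance used when checking grid spacing constancy.
_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered wavelength axis with fixed spacing.

    Channel ``i`` maps to ``start_nm + i * step_nm``.  The default
    instrument grid starts at 400 nm with 2 nm spacing and exactly 1050
    channels (ending at 2498 nm).
    """

    start_nm: float
    step_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be > 0")
        if self.n_channels < 2:
            raise ValueError("a grid needs at least 2 channels")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    @property
    def end_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_channels - 1)

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Channel indices with lo_nm <= wavelength <= hi_nm."""
        wl = self.wavelengths
        return np.nonzero((wl >= lo_nm) & (wl <= hi_nm))[0]

    @classmethod
    def from_wavelengths(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least 2 wavelengths")
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=_SPACING_RTOL, atol=1e-9):
            raise ValueError("non-constant spacing in wavelength axis")
        return cls(start_nm=float(wl[0]), step_nm=float(step), n_channels=int(wl.size))


#: 400-2498 nm at 2 nm: the acquisition grid (1050 channels).
DEFAULT_GRID = WavelengthGrid(start_nm=400.0, step_nm=2.0, n_channels=1050)


@dataclass
class SpectraSet:
    """Absorbance spectra for a set of samples on a common grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    state: str = "powder"
    pretreatment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x channels)")
        n, p = self.absorbance.shape
        if p != self.grid.n_channels:
            raise ValueError(
                f"matrix has {p} channels but grid has {self.grid.n_channels}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal row count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance values")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def with_matrix(
        self,
        absorbance: np.ndarray,
        *,
        state: str | None = None,
        extra_tags: Iterable[str] = (),
        grid: WavelengthGrid | None = None,
    ) -> "SpectraSet":
        """Copy metadata onto a new matrix, appending pretreatment tags."""
        return SpectraSet(
            grid=grid or self.grid,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            state=state or self.state,
            pretreatment=list(self.pretreatment) + list(extra_tags),
        )

    def select(self, ids: Sequence[str]) -> "SpectraSet":
        """Row subset in the order of ``ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        rows = [index[s] for s in ids]
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[rows],
            sample_ids=list(ids),
            state=self.state,
            pretreatment=list(self.pretreatment),
        )


@dataclass
class ReferenceTable:
    """Reference concentrations (%w/w) for one analyte."""

    sample_ids: list[str]
    analyte: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.analyte not in ("sucrose", "lactose"):
            raise ValueError("analyte must be 'sucrose' or 'lactose'")
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 1 or self.values.size != len(self.sample_ids):
            raise ValueError("values must be 1-D and match sample_ids")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("concentrations must lie in [0, 100] %w/w")

    def aligned_to(self, spectra: SpectraSet) -> np.ndarray:
        """y vector in the spectra's row order."""
        lut = dict(zip(self.sample_ids, self.values))
        missing = [s for s in spectra.sample_ids if s not in lut]
        if missing:
            raise KeyError(f"reference values missing for: {missing}")
        return np.array([lut[s] for s in spectra.sample_ids], dtype=float)


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectra_csv(
    path: str | Path, expected_grid: WavelengthGrid | None = None
) -> SpectraSet:
    """Read a spectral CSV written by :func:`write_spectra_csv`.

    Header row is ``sample_id`` then wavelengths in nm (strictly increasing,
    constant spacing).  ``#`` lines before the header carry ``state`` and
    ``pretreatment`` metadata.
    """
    path = Path(path)
    state = "powder"
    pretreatment: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        meta = line[1:].strip()
        if meta.startswith("state:"):
            state = meta.split(":", 1)[1].strip()
        elif meta.startswith("pretreatment:"):
            tags = meta.split(":", 1)[1].strip()
            pretreatment = [t for t in tags.split(",") if t]
    header = lines[body_start].split(",")
    if header[0] != "sample_id":
        raise ValueError("first header column must be 'sample_id'")
    try:
        wavelengths = [float(w) for w in header[1:]]
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength in header: {exc}") from None
    grid = WavelengthGrid.from_wavelengths(wavelengths)
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"grid mismatch: file has {grid}, expected {expected_grid}")

    ids: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise ValueError(f"ragged row at line {ln}: {len(cells)} cells")
        ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError:
            raise ValueError(f"non-numeric cell at line {ln}") from None
    return SpectraSet(
        grid=grid,
        absorbance=np.array(rows, dtype=float),
        sample_ids=ids,
        state=state,
        pretreatment=pretreatment,
    )


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet at full float precision (round-trips bit-exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# state: {spectra.state}\n")
        if spectra.pretreatment:
            fh.write(f"# pretreatment: {','.join(spectra.pretreatment)}\n")
        wl = spectra.grid.wavelengths
        fh.write("sample_id," + ",".join(repr(float(w)) for w in wl) + "\n")
        for sid, row in zip(spectra.sample_ids, spectra.absorbance):
            fh.write(sid + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_reference_csv(path: str | Path) -> dict[str, ReferenceTable]:
    """Read a reference CSV (columns sample_id,sucrose,lactose)."""
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    required = {"sample_id", "sucrose", "lactose"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference CSV needs columns {sorted(required)}")
    ids = df["sample_id"].tolist()
    return {
        analyte: ReferenceTable(
            sample_ids=ids, analyte=analyte, values=df[analyte].to_numpy(float)
        )
        for analyte in ("sucrose", "lactose")
    }


def write_reference_csv(
    tables: dict[str, ReferenceTable], path: str | Path
) -> None:
    suc, lac = tables["sucrose"], tables["lactose"]
    if suc.sample_ids != lac.sample_ids:
        raise ValueError("sucrose/lactose tables must share sample IDs")
    df = pd.DataFrame(
        {"sample_id": suc.sample_ids, "sucrose": suc.values, "lactose": lac.values}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, AFFN numerics)

_LDR = re.compile(r"^##(?P<label>[^=]+)=(?P<value>.*)$")
_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
# ASDF compression digits (SQZ/DIF/DUP) are not supported.
_ASDF_CHARS = re.compile(r"[@A-DF-Za-df-z%JKLMNOPQRjklmnopqrSTUVWXYZs-z]")


def import_jcamp(path: str | Path) -> SpectraSet:
    """Import a single-spectrum JCAMP-DX file onto a constant-spacing grid.

    Supports ``##XYPOINTS=(XY..XY)`` and AFFN ``##XYDATA=(X++(Y..Y))``.
    Decreasing abscissa files are reversed into increasing order; a
    non-constant abscissa or ASDF-compressed data is an error.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8", errors="replace").splitlines()

    title = "jcamp"
    xfactor = yfactor = 1.0
    mode: str | None = None
    data_lines: list[str] = []
    for raw in lines:
        line = raw.split("$$")[0].rstrip()
        m = _LDR.match(line)
        if m:
            label = m.group("label").strip().upper().replace(" ", "")
            value = m.group("value").strip()
            if label == "TITLE" and value:
                title = value
            elif label == "XFACTOR":
                xfactor = float(value)
            elif label == "YFACTOR":
                yfactor = float(value)
            elif label in ("XYDATA", "XYPOINTS"):
                mode = label
                data_lines = []
            elif label == "END":
                break
            elif mode is not None:
                mode = None  # data block ended at the next LDR
        elif mode is not None and line.strip():
            data_lines.append(line.strip())

    if not data_lines:
        raise ValueError("no XYDATA/XYPOINTS block found")

    xs: list[float] = []
    ys: list[float] = []
    if mode == "XYPOINTS" or any("," in ln or ";" in ln for ln in data_lines):
        for ln in data_lines:
            for pair in re.split(r"[;]", ln):
                nums = _NUM.findall(pair)
                if len(nums) == 0:
                    continue
                if len(nums) % 2:
                    raise ValueError(f"odd number of values in XYPOINTS line: {ln!r}")
                for i in range(0, len(nums), 2):
                    xs.append(float(nums[i]))
                    ys.append(float(nums[i + 1]))
    else:
        # (X++(Y..Y)): first number per line is X of the first Y.
        stripped = [_NUM.sub("", ln).replace(" ", "").replace("+", "").replace("-", "")
                    for ln in data_lines]
        if any(_ASDF_CHARS.search(s) for s in stripped):
            raise ValueError("ASDF-compressed XYDATA is not supported")
        rows = []
        for ln in data_lines:
            nums = [float(v) for v in _NUM.findall(ln)]
            if len(nums) < 2:
                raise ValueError(f"XYDATA line with fewer than 2 values: {ln!r}")
            rows.append(nums)
        # infer per-point X spacing from consecutive line starts
        for i, nums in enumerate(rows):
            x0, yvals = nums[0], nums[1:]
            if i + 1 < len(rows):
                dx = (rows[i + 1][0] - x0) / len(yvals)
            elif i > 0:
                dx = (x0 - rows[i - 1][0]) / len(rows[i - 1][1:])
            else:
                dx = 1.0 if len(yvals) < 2 else None
                if dx is None:
                    raise ValueError("cannot infer X spacing from a single line")
            for j, y in enumerate(yvals):
                xs.append(x0 + j * dx)
                ys.append(y)

    x = np.asarray(xs, dtype=float) * xfactor
    y = np.asarray(ys, dtype=float) * yfactor
    if x.size < 2:
        raise ValueError("need at least 2 data points")
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    grid = WavelengthGrid.from_wavelengths(x)
    sid = re.sub(r"[,\s]+", "_", title)[:64] or "jcamp"
    return SpectraSet(
        grid=grid, absorbance=y[None, :], sample_ids=[sid], state="powder"
    )
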