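"""Seeded Beer-Lambert generator for powder/tablet NIR mixture spectra.

The study's raw spectra are not deposited, so this module emulates their
statistical structure: additive Gaussian-band absorbance for three
components (sucrose, lactose, and a lumped milk matrix whose concentration
closes the mixture to 100 %w/w), spiking-design concentration variation,
per-sample multiplicative scatter plus baseline jitter and white noise, and
a parameterized powder -> tablet measurement effect (band broadening, a
gain > 1 because compacted tablets absorb more, low-order additive baseline,
extra scatter and noise — applied in that documented order).

Every output is a pure function of (scenario, seed): the same seed yields
bit-identical matrices.  The generator aims at statistical structure
(collinearity, scatter, state shift), not radiometric realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import (
    DesignTable,
    EXTERNAL_SAMPLES,
    default_internal_design,
    default_training_design,
)
from .spectra_io import DEFAULT_GRID, ReferenceTable, SpectraSet, WavelengthGrid

__all__ = [
    "ComponentLibrary",
    "TabletEffect",
    "SimScenario",
    "StudyBundle",
    "default_library",
    "default_tablet_effect",
    "simulate_powder",
    "apply_tablet_effect",
    "make_study",
]


@dataclass(frozen=True)
class ComponentLibrary:
    """Gaussian absorption bands per component.

    Each band is (center nm, width nm, amplitude per %w/w).  Band positions
    follow the sugar-associated O-H/C-H overtone and combination regions
    (first overtone near 1450 nm, water/O-H combination near 1940 nm,
    sugar C-H combination near 2100 nm); the two sugar profiles share
    regions but differ in detail so they are distinguishable without being
    orthogonal, like real saccharide spectra.
    """

    bands: dict[str, tuple[tuple[float, float, float], ...]]

    def profile(self, component: str, grid: WavelengthGrid) -> np.ndarray:
        """Unit-concentration absorbance profile (per 1 %w/w)."""
        wl = grid.wavelengths
        out = np.zeros_like(wl)
        for center, width, amp in self.bands[component]:
            out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out

    def mixture(
        self, grid: WavelengthGrid, concentrations: dict[str, float]
    ) -> np.ndarray:
        """Noiseless Beer-Lambert spectrum: sum of conc x profile."""
        out = np.zeros(grid.n_channels)
        for comp, conc in concentrations.items():
            out += conc * self.profile(comp, grid)
        return out


def default_library() -> ComponentLibrary:
    """Fixed band sets for sucrose, lactose and the milk matrix."""
    return ComponentLibrary(
        bands={
            # amplitudes in AU per %w/w; sugar C-H/O-H combination bands
            "sucrose": (
                (1436.0, 42.0, 0.0060),
                (1688.0, 30.0, 0.0035),
                (1930.0, 55.0, 0.0045),
                (2078.0, 38.0, 0.0075),
                (2270.0, 32.0, 0.0050),
            ),
            "lactose": (
                (1450.0, 48.0, 0.0055),
                (1540.0, 35.0, 0.0030),
                (1938.0, 50.0, 0.0060),
                (2100.0, 45.0, 0.0055),
                (2320.0, 36.0, 0.0045),
            ),
            # lumped fat/protein/water background of milk powder
            "matrix": (
                (1210.0, 60.0, 0.0030),
                (1460.0, 80.0, 0.0050),
                (1728.0, 40.0, 0.0040),
                (1940.0, 70.0, 0.0065),
                (2180.0, 60.0, 0.0035),
                (2310.0, 45.0, 0.0050),
            ),
        }
    )


@dataclass(frozen=True)
class TabletEffect:
    """Powder -> tablet measurement transform parameters.

    gain > 1 encodes that compacted tablets absorb more than loose powder;
    baseline coefficients are a polynomial (degree <= 2) in the normalized
    wavelength u in [0, 1]; broadening is a Gaussian smoothing width in nm.
    """

    gain: float = 1.30
    baseline: tuple[float, ...] = (0.10, 0.20, -0.12)  # AU: b0 + b1*u + b2*u^2
    broadening_nm: float = 20.0
    scatter_sd: float = 0.03
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if len(self.baseline) > 3:
            raise ValueError("baseline polynomial degree must be <= 2")
        if min(self.broadening_nm, self.scatter_sd, self.noise_sd) < 0:
            raise ValueError("effect parameters must be >= 0")


def default_tablet_effect() -> TabletEffect:
    return TabletEffect()


def identity_tablet_effect() -> TabletEffect:
    return TabletEffect(
        gain=1.0, baseline=(0.0,), broadening_nm=0.0, scatter_sd=0.0, noise_sd=0.0
    )


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to deterministically generate one powder set."""

    seed: int
    design: DesignTable
    grid: WavelengthGrid = DEFAULT_GRID
    library: ComponentLibrary = field(default_factory=default_library)
    scatter_sd: float = 0.01  # per-sample multiplicative jitter (powder)
    baseline_sd: float = 0.002  # per-sample linear baseline jitter, AU
    noise_sd: float = 0.001  # additive white noise, AU


def _concentration_rows(design: DesignTable) -> list[dict[str, float]]:
    rows = []
    for _, r in design.frame.iterrows():
        s, l = float(r["final_sucrose"]), float(r["final_lactose"])
        rows.append({"sucrose": s, "lactose": l, "matrix": 100.0 - s - l})
    return rows


def simulate_powder(
    scenario: SimScenario,
) -> tuple[SpectraSet, dict[str, ReferenceTable]]:
    """One powder spectrum per design row, plus its reference tables."""
    rng = np.random.default_rng(scenario.seed)
    grid = scenario.grid
    u = np.linspace(0.0, 1.0, grid.n_channels)
    rows = []
    for conc in _concentration_rows(scenario.design):
        clean = scenario.library.mixture(grid, conc)
        scatter = 1.0 + rng.normal(0.0, scenario.scatter_sd)
        baseline = rng.normal(0.0, scenario.baseline_sd) + rng.normal(
            0.0, scenario.baseline_sd
        ) * u
        noise = rng.normal(0.0, scenario.noise_sd, grid.n_channels)
        rows.append(clean * scatter + baseline + noise)
    spectra = SpectraSet(
        grid=grid,
        absorbance=np.asarray(rows),
        sample_ids=scenario.design.sample_ids,
        state="powder",
    )
    refs = {a: scenario.design.reference(a) for a in ("sucrose", "lactose")}
    return spectra, refs


def apply_tablet_effect(
    powder: SpectraSet, effect: TabletEffect, seed: int
) -> SpectraSet:
    """Transform powder spectra into the tablet measurement state.

    Order: broadening -> gain -> baseline -> scatter -> noise.
    """
    rng = np.random.default_rng(seed)
    X = powder.absorbance.copy()
    if effect.broadening_nm > 0:
        sigma = effect.broadening_nm / powder.grid.step_nm
        X = gaussian_filter1d(X, sigma=sigma, axis=1, mode="nearest")
    X = X * effect.gain
    u = np.linspace(0.0, 1.0, powder.grid.n_channels)
    X = X + np.polyval(list(reversed(effect.baseline)), u)[None, :]
    if effect.scatter_sd > 0:
        X = X * (1.0 + rng.normal(0.0, effect.scatter_sd, (X.shape[0], 1)))
    if effect.noise_sd > 0:
        X = X + rng.normal(0.0, effect.noise_sd, X.shape)
    return SpectraSet(
        grid=powder.grid,
        absorbance=X,
        sample_ids=list(powder.sample_ids),
        state="tablet",
        pretreatment=list(powder.pretreatment),
    )


def add_baseline_drift(
    spectra: SpectraSet, seed: int, *, amplitude: float = 0.1
) -> SpectraSet:
    """Add a random low-frequency (quadratic) baseline per sample.

    Models slow instrumental drift between standardization and prediction;
    the dense DS map is known to propagate such drift while the banded PDS
    map contains it locally.
    """
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, spectra.grid.n_channels)
    basis = np.stack([np.ones_like(u), u, u**2])
    coefs = rng.normal(0.0, amplitude, (spectra.n_samples, 3))
    return spectra.with_matrix(spectra.absorbance + coefs @ basis)


@dataclass
class StudyBundle:
    """Synthetic counterpart of the study's sample architecture."""

    train: SpectraSet
    train_refs: dict[str, ReferenceTable]
    internal: SpectraSet
    internal_refs: dict[str, ReferenceTable]
    external_powder: SpectraSet
    external_tablet: SpectraSet
    external_refs: dict[str, ReferenceTable]
    effect: TabletEffect


def make_study(
    seed: int,
    *,
    effect: TabletEffect | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> StudyBundle:
    """Training (27), internal validation (27) and 7 external powder/tablet
    pairs, mirroring the published sample architecture (two external
    samples carry zero lactose, emulating the non-milk tablets)."""
    effect = default_tablet_effect() if effect is None else effect
    # sub-seeds kept below 2**31 and disjoint per subset
    s_train, s_int, s_ext, s_tab = ((seed * 4 + i) % (2**31 - 1) for i in range(4))
    train_design = default_training_design()
    internal_design = default_internal_design()
    train, train_refs = simulate_powder(
        SimScenario(seed=s_train, design=train_design, grid=grid)
    )
    internal, internal_refs = simulate_powder(
        SimScenario(seed=s_int, design=internal_design, grid=grid)
    )

    # external samples: no spiking, published tablet compositions as-is
    ext_rows = [
        {
            "sample_id": sid,
            "base_id": sid,
            "code_sucrose": 0,
            "code_lactose": 0,
            "added_sucrose": 0.0,
            "added_lactose": 0.0,
            "final_sucrose": s,
            "final_lactose": l,
        }
        for sid, s, l in EXTERNAL_SAMPLES
    ]
    ext_design = DesignTable(frame=pd.DataFrame(ext_rows))
    external_powder, external_refs = simulate_powder(
        SimScenario(seed=s_ext, design=ext_design, grid=grid)
    )
    external_tablet = apply_tablet_effect(external_powder, effect, s_tab)
    return StudyBundle(
        train=train,
        train_refs=train_refs,
        internal=internal,
        internal_refs=internal_refs,
        external_powder=external_powder,
        external_tablet=external_tablet,
        external_refs=external_refs,
        effect=effect,
    )
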