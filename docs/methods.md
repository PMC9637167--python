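# Methods

## Problem setting

A PLS calibration built on NIR spectra of loose milk powders does not
predict well on intact milk tablets: compaction changes particle size and
effective path length, which raises absorbance, tilts the baseline and
broadens apparent bands. Calibration transfer fixes this without
recalibration by learning a linear map `F` from tablet-state ("slave")
spectra to powder-state ("master") spectra from a small set of samples
measured in both states, so that the powder-domain model can be applied to
standardized tablet spectra.

## Data model and design

Spectra live on a fixed wavelength grid: 400 nm start, 2 nm spacing, 1050
channels (so the last channel is 2498 nm; an inclusive 2500 nm endpoint
would give 1051 channels, and the channel count is what every matrix shape
depends on, so the endpoint is dropped). Absorbance matrices are
samples x channels; reference values are %w/w sucrose and lactose.

Calibration sets are built by spiking base milk powders with both sugars at
three coded levels each, `-1/0/+1 -> 0.00/15.00/30.00` g per 100 g of base,
in a face-centered central composite layout whose axial points coincide
with the 3x3 factorial frame: 9 runs per base, 27 rows for the three
training bases. Final concentrations follow a mass balance: adding `a_s`
and `a_l` grams to 100 g of base gives
`final_s = 100 (s0 + a_s) / (100 + a_s + a_l)`. The mixing arithmetic is a
declared convention (an `additive_no_renorm` alternative is available);
synthetic ground truth must be explicit about it.

## Pretreatment

Standard normal variate (SNV) centers and scales each spectrum to unit
standard deviation (n-1 denominator), removing per-sample offset and
multiplicative scatter. The modeling path is SNV then mean-centering;
centering statistics always come from the training set and are stored in
the model, so validation and transferred spectra are never centered with
their own means.

## PLS1 (NIPALS)

Each component extracts `w ∝ X'y` (unit norm), scores `t = Xw`, loadings
`p = X't/t't`, `q = t'y/t't`, then deflates `X`. The model collapses to a
regression vector `b = W(P'W)^{-1}q`; prediction is
`yhat = (x - x̄)b + ȳ`. Inner-loop tolerance is 1e-12 with a 500-iteration
cap (PLS1 converges in one pass; the loop matters for the multivariate
variant used in transfer). The latent-variable count is selected by
leave-one-out cross-validation over 1..min(15, n-2) candidates: global
minimum RMSECV, ties (within 1e-12) broken toward fewer components, with
centering refitted inside every fold to avoid leakage. y is centered, not
scaled — the %w/w scale is meaningful for a single response.

## Calibration transfer

Both methods fit `X_master ≈ X_slave F` on ID-paired samples, with no
intercept (an optional `with_offset` flag adds the classical additive
term).

* **DS** — one multivariate NIPALS PLS regression of the full master matrix
  on the full slave matrix (default 5 components), giving a dense `F`.
* **PDS** — for each channel `j`, a local PLS (default 2 components) of
  master column `j` on slave columns `j-k..j+k` (default half-width k = 5
  channels, i.e. an 11-channel / 22 nm window); windows are truncated at
  the spectrum edges and the local component count is clamped to the window
  width there. The coefficient vectors form a banded `F` (`F[i,j] = 0`
  whenever `|i-j| > k`).

Application is `standardized = slave @ F`, consistent with the fitting
equation. Transfer is fitted and applied on raw (untreated) spectra by
default, with a `transfer_on: snv` switch; the raw domain keeps the
comparison between DS and PDS meaningful under additive drift, which SNV
itself partially removes (see below), and matches the convention of
standardizing the measured signal before any model-side pretreatment.

The pipeline's default pairing protocol fits `F` on all available external
pairs and then predicts those same samples (the run log flags this); a
`leave_pair_out` protocol refits `F` without each pair before predicting
it and gives an honest but noisier transfer error from only 6 pairs.

## Validation statistics

RMSEC/RMSEP = root-mean-square residual on calibration / prediction data.
R² and Q² share `1 - SS_res/SS_tot`; Q² centers SS_tot on the test-set
reference mean by default (`q2_center: train_mean` option). SECV is the
bias-corrected SD of LOO residuals, `sqrt(Σ(e-ē)²/(n-1))`. RPD is
SD(reference)/SECV by default (`rpd_error: rmsep` option); published RPD
and SECV conventions vary between software packages, so both knobs are
exposed rather than asserted. Bias = mean(pred - ref) is reported and
never thresholded.

## Synthetic data generator

No public NIR spectra exist for this problem, so the generator emulates
their statistical structure rather than radiometric detail:

* **Forward model** — additive Beer-Lambert mixing of Gaussian absorption
  bands for sucrose, lactose and a lumped milk matrix whose concentration
  closes the mixture to 100 %w/w (embedding the closure correlation real
  powders have). Band centers sit in the sugar O-H/C-H overtone and
  combination regions (~1440, ~1940, ~2100, ~2300 nm) with profiles that
  are correlated but non-proportional (cosine similarity < 0.99), like real
  saccharides.
* **Powder measurement** — per-sample multiplicative scatter (SD 1%), a
  small random linear baseline (SD 0.002 AU) and white noise (SD 0.001 AU).
* **Tablet effect** — applied in a documented order (broadening -> gain ->
  baseline -> scatter -> noise): Gaussian band broadening of width 20 nm,
  a gain of 1.30 (tablets absorb more than powder), a fixed quadratic
  baseline (0.10, 0.20, -0.12) AU over normalized wavelength, 3% scatter
  and 0.002 AU noise. The magnitudes were chosen so that the components
  SNV cannot remove (broadening and baseline shape) leave a substantial
  prediction error without transfer — the condition calibration transfer
  exists to fix; a scalar gain plus offset alone would be erased by SNV and
  make the no-transfer condition trivially easy.
* **Study architecture** — `make_study(seed)` produces a 27-row training
  set (bases T1-T3), a 27-row internal-validation set (bases I1-I3) and 7
  external samples measured in both states (E1-E7, two of them with zero
  lactose, as in commercial non-milk tablets). Reference compositions of
  the 13 base samples are fixed study inputs. Every output is a pure
  function of (scenario, seed).

What passing tests on these data do **not** show: the generator has no
wavelength-dependent scatter physics, no reference-method (HPLC) error, no
instrument drift within a set, and its tablet effect is identical in form
across samples. Results transfer to real spectra only in direction, not in
magnitude.

## Drift benchmark

The DS-vs-PDS comparison adds an independent random quadratic baseline
(coefficient SD 0.1 AU) to each tablet spectrum **after** `F` has been
fitted, modeling instrumental drift between standardization and prediction.
The dense DS map propagates such drift across the whole axis, while the
banded PDS map contains it locally, so PDS degrades less. With only 7
external samples the ordering is subject to Monte Carlo noise: across 12
seeds it holds in 19 of 24 analyte-seed cases at this amplitude (22 of 24
at 0.2-0.3 AU). The shipped benchmark is therefore asserted at a fixed
seed, and the acceptance script reports whatever the supplied seed
produces.

## Numerical choices and degenerate inputs

SNV raises on zero-variance rows, naming the sample. PLS raises on
zero-variance responses and on component counts above min(n-1, p); NIPALS
stops extracting components early if the residual under-flows (scores norm
< 1e-14). PDS validates `k < n_channels` and `lv <= 2k+1`. CSV round-trips
are bit-exact (floats written with `repr`). JCAMP-DX import supports AFFN
XYPOINTS and XYDATA; ASDF-compressed files and non-constant abscissae are
rejected, and decreasing abscissae are reversed.

## Problem sizes

The default study (27 + 27 + 2x7 spectra at 1050 channels, LOO over 15
candidate components, DS and PDS on 7 pairs) runs in well under a minute;
the full test suite and the acceptance script each complete in a few
minutes on a single CPU.

## Known limitations

* With 7 standardization pairs and 1050 channels, both transfer fits are
  heavily rank-deficient; fit-on-all results are optimistic by
  construction, which is why the leave-pair-out protocol exists.
* PDS with finite per-window components does not reduce to the identity
  even when master equals slave; the "transfer is harmless when there is
  nothing to correct" property holds to ~0.02 %w/w, not machine precision.
* The visible region (400-780 nm) is retained by default; a wavelength
  window option exists (`WavelengthGrid.window_indices`) but no automatic
  trimming is applied.
* SECV/RPD conventions differ across chemometric software; values are
  comparable within this package, not across packages.
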