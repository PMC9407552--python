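# Methods

This note documents the models, algorithms and numerical choices behind
`pearscc`, and what the synthetic-data experiments do and do not show.

## Problem and data model

Stone cell content (SCC) is the mass percentage of lignified sclereid
tissue in pear pulp, measured gravimetrically as
`(m_total − m_filter) / m_pulp × 100` from the dried sediment of
homogenized pulp.  The pipeline calibrates a regression from Vis/NIR
diffuse-reflectance spectra to SCC.  Spectra are treated as unitless
reflectance; every preprocessing step used is invariant to an overall
affine scale, so raw counts, relative reflectance or absorbance-like
inputs behave equivalently.

A `SpectraSet` (wavelength grid, samples × channels matrix, unique ids)
and a `ReferenceSet` (ids, SCC in %) are aligned strictly by id, never by
row order, so mismatched files fail loudly.  The canonical grid is
498–1020 nm at 0.5 nm (1045 channels); channel spacing is configurable.
Wavelength trimming uses a closed interval.  Sample statistics use the
n − 1 denominator.

## Synthetic spectra generator

No pear spectra are publicly deposited, so the generator is the test bed
for every stage.  Its model:

* **base spectrum** — a smooth envelope plus Gaussian bands (SD 30 nm) at
  550 and 750 nm (peaks) and 680 and 980 nm (valleys), the feature set of
  pear flesh/skin reflectance;
* **SCC linkage** — the amplitudes of the carbohydrate/water-related 750
  and 980 nm bands are linear in SCC with negative slopes (−0.30 and
  −0.20 per % SCC): stone cell formation competes with carbohydrate
  accumulation, so more stone cells mean weaker carbohydrate features.
  The slope magnitudes are free parameters of the generator, not
  literature constants;
* **nuisance** — per-replicate multiplicative gain (SD 0.05), additive
  linear baseline drift (slope SD 1e−4 per nm) and white channel noise
  (SD 0.003), the exact corruption family SNV/MSC/S-G remove; plus a
  per-sample band-amplitude jitter (SD 0.01) representing biological
  variability uncorrelated with SCC.  The jitter is what keeps validation
  performance in a realistic range (R ≈ 0.95–0.99) instead of saturating:
  it is sample-level and does not average out over replicates or
  channels;
* **response** — SCC uniform on (0.240, 0.657) %, matching the range of
  the gravimetric study conditions (mean ≈ 0.45, SD ≈ 0.12); a truncated
  normal with mean 0.486 / SD 0.100 is available;
* **replicates** — three scans per sample by default (the acquisition
  rotates each fruit 120° between scans), averaged before modeling.

What the generator does **not** emulate: radiative-transfer/Kubelka–Munk
physics, wavelength-dependent noise, instrument drift over time,
skin-pigment kinetics, or a realistic covariance among many constituents.
Its SCC signal lives in a handful of latent degrees of freedom, so the
wavelength selectors typically keep far fewer channels (≈ 3–50) than a
real fruit study would (tens of channels spread over several absorption
regions).  Passing tests therefore demonstrate algorithmic correctness
and end-to-end sanity, not field performance on real pears.

Named fixtures: `paper-like-120` (study-sized, fixed seed), `tiny-10x8`
(noise-free, hand-enumerable; generated on a 12-channel grid because the
generator refuses fewer than 10 channels, then trimmed to 8) and
`noise-only` (no SCC-linked bands at all — the negative control).

## Preprocessing

* **SNV**: per-spectrum centering and scaling to unit sample SD
  (n − 1).  Constant spectra are an error naming the sample.
* **MSC**: per-spectrum OLS regression x ≈ a + b·ref against the mean
  spectrum (or a supplied reference), corrected to (x − a)/b; |b| < 1e−12
  is an error.
* **Savitzky–Golay**: window (frame) ∈ {3, 5, 7, 9}, order 1–7 with
  order < frame.  Edges use the truncated-window polynomial fit
  (`mode="interp"`), preserving length.  The acquisition-side two-point
  smoothing of the instrument is considered part of the data.
* **Comparison**: the candidate slate is none, MSC, SNV, S-G(f*, o*), and
  S-G(f*, o*) combined with MSC or SNV, where (f*, o*) maximizes
  validation R over the S-G grid.  Each candidate is scored by a PLSR
  model (factor count chosen by cross-validation, capped at 10).  Winner:
  highest validation R, ties broken by lower validation RMSE, then by the
  smaller calibration/validation R gap (robustness), then list order.
  Preprocessing is applied to the full matrix before splitting; since all
  three operators are per-spectrum, no information leaks across samples.

## SPXY partitioning

Joint distance d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y with
Euclidean d_x on the preprocessed spectra and |y_i − y_j| on SCC.
Selection is deterministic max–min: seed with the maximal-distance pair,
then repeatedly add the sample whose minimum distance to the selected set
is largest, until |Cs| = round(n·cal/(cal+val)).  Ties resolve to the
sample whose id sorts first, making the selected id sets invariant to row
order.  Because the pipeline's preprocessing comparison itself needs a
split, a provisional SPXY on the raw averaged spectra is used for that
stage only; the definitive split is recomputed on the winning
preprocessed spectra.

Coverage of the validation SCC range by the calibration range is the
typical outcome (and holds for the study-sized fixture) but is not
guaranteed: the joint distance can leave a y-extreme with an unremarkable
spectrum in the validation set.  `validate_split` reports coverage, per-set
statistics and a two-group ANOVA; a significant ANOVA does not gate the
pipeline.

## PLS regression

PLS1 via SIMPLS on mean-centered (not variance-scaled) X and y; SNV/MSC
already condition the spectra and unscaled coefficients stay
interpretable per channel.  SIMPLS produces the whole coefficient path
(1…A factors) in one pass, which the selectors' inner loops and the
venetian-blind cross-validation (folds by index stride, ties to fewer
factors) exploit.  For a univariate response SIMPLS coincides with NIPALS
PLS1; the test suite pins this against scikit-learn's NIPALS
implementation and against OLS at full rank.  The factor cap defaults
to 10.  Deflation stops early if the residual covariance is exhausted, so
exact low-rank fits report fewer effective factors.

## Wavelength selection

**SPA** — phase 1 builds, for every starting channel, a chain of channels
by successive orthogonal projection on the column-centered calibration
matrix (maximal residual norm; ties and exhausted channels to the lowest
index, so exact duplicates are appended last).  Chain length caps at
min(Ncal − 1, K, 100); the 100 cap reflects the design budget of keeping
models below one hundred wavelengths.  Phase 2 scores every chain prefix
(n_min = 5 … n_max) by the RMSE of a PLSR fit on the validation set
(RMSEV); ties prefer the shorter prefix, then the lower start.  Phase 3
ranks the surviving channels by |coefficient × channel SD|, computes
RMSEV(j) for the top-j channels, and keeps the smallest j with
RMSEV(j) ≤ min RMSEV · sqrt(F⁻¹(1 − α; Nval, Nval)), α = 0.25.  If no j
passes (a degenerate quantile), the argmin prefix is kept.  The
regression inside SPA is PLSR (cap min(10, prefix size)) rather than the
more traditional MLR, so the same model family scores every stage;
ratios and the threshold are recorded in the diagnostics.

**MCUVE** — n_runs = 500 Monte-Carlo draws of 80 % of the calibration
samples without replacement (both defaults are conventional for UVE-type
stability screening; the source literature leaves them open), a PLSR fit
per draw, stability C(k) = mean(β_k)/SD(β_k).  Channels whose coefficient
SD underflows get C = sign(mean) × 1e6 (0 for an identically-zero
coefficient) with a warning.  Channels are ordered by |C| — a strongly
negative but stable coefficient is informative, so magnitude rather than
signed value is ranked — and the forward RMSEV trajectory over the top-j
channels (j ≤ 100) is minimized; numerically tied minima resolve to the
smaller j.

Both selectors require an explicit validation set; their estimator
facades (`SPASelector`, `MCUVESelector`) take it as fit parameters.

## PSO-tuned SVR

ε-SVR with RBF kernel exp(−g‖u − v‖²) on column-standardized X (training
statistics; required for one shared g across channels) and standardized
y; ε = 0.01 on the standardized-y scale.  PSO searches (C, g) in log10
space over C ∈ [0.01, 100], g ∈ [0.001, 10]: swarm 20, 100 iterations,
inertia 0.9 → 0.4 linearly, cognitive = social = 1.7, positions clipped
to bounds.  The fitness is 5-fold cross-validated RMSE on the calibration
set (folds shuffled with a fixed seed, so fitness is deterministic and
comparable across particles).  The best-so-far trajectory is
non-increasing by construction and the whole search is reproducible from
its seed.  Degenerate (point) bounds short-circuit to a single
evaluation.

Final evaluation reports R and RMSE for both sets plus per-sample
relative errors and their maximum (undefined, hence an error, if any
reference value is 0).

## Pipeline, seeds, persistence

Stage order: generate/load → trim (498–1020 nm) → replicate averaging →
preprocessing (comparison or a fixed spec) → SPXY → selection → PSO-SVR →
evaluation.  One master seed derives the data, MCUVE and PSO seeds via
`numpy.random.SeedSequence` spawning (31-bit children).  Every stage
artifact can be persisted as CSV/JSON with a SHA-256 manifest; a rerun
with the same config and seed reproduces identical files.  Reports flag a
no-skill outcome when |validation R| < 0.35, the two-sided 5 % bound for
n ≈ 30 validation samples.

## Problem sizes used in the shipped experiments

The acceptance script runs the main study at full size (120 samples × 3
replicates, 1045 channels) for the preprocessing comparison and the MCUVE
branch; the SPA branch runs on a 2 nm grid (262 channels) because SPA
scores every chain prefix for every starting channel, and the negative
control uses 120 samples × 131 channels with 5 replicate draws.  The test
suite uses the same study-sized fixture for the end-to-end check and
smaller instances (n ≤ 60, K ≤ 50) for oracle equivalences.  These sizes
are the package's chosen experiment scales; all quantities are recomputed
at run time.

## Known limitations

* Synthetic validation only — no real pear spectra are bundled, so
  reported metrics characterize the pipeline on the generative model
  above, not instrument data.
* The forward-selection step (j* by validation RMSEV) reuses the
  validation set; under a pure-noise null this inflates validation R by
  roughly +0.1 on average.  The negative-control test quantifies exactly
  this leakage; for unbiased final error estimates on real data a third,
  untouched test set would be required.
* SPA cost grows as K × n_max PLSR fits; at 0.5 nm resolution (K ≈ 1000)
  it is minutes-scale, which is why the shipped SPA experiments use 2 nm.
* PLS1 only (univariate response); no derivative preprocessing, CARS/GA
  selectors, or nu-SVR variants.
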