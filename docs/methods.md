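# Methods

This note documents the models, parameter choices and numerical conventions
behind `serrscell`, and what the synthetic experiments do and do not show
about real chamber data.

## Synthetic reporter spectra

The three reporter signatures are rendered as sums of Lorentzian lines on a
400–1800 cm⁻¹ grid (1024 points) — the dye fingerprint region under
632.8 nm excitation. Line positions are loosely placed at strong bands of
the three dyes (Malachite Green, Texas Red, Nile Blue) but are surrogates:
no quantitative match to measured SERRS spectra is intended, and none is
needed, because every downstream stage consumes only the *correlation
structure* of the references. The lists are chosen so noise-free references
correlate pairwise below 0.1 in absolute value, which is what makes
single-spectrum multiplexing by Pearson scoring work. Reference spectra are
max-normalized to 1; Pearson correlation is scale- and offset-invariant, so
normalization is cosmetic.

## Per-cell spectra and noise

A cell's spectrum is `Σᵢ wᵢ·refᵢ + baseline + noise`, clipped at zero.

- **Mixing weights** `w = (w₁, w₂, w₃)` encode targeting biology: class
  mean loadings times independent per-channel lognormal jitter
  (`exp(σ·z)`, σ = 0.5). Defaults: LNCaP (0.10, 1.00, 0.12), U251
  (1.00, 0.04, 0.70), PBMC (0.72, 0.04, 1.00). Epithelial cells are marked
  by NS-2; mesenchymal cells and PBMCs both carry NS-1 and NS-3 but with a
  ~2.5-fold different NS-1:NS-3 ratio, so the two phenotypes overlap
  partially — deliberately, since that overlap is the hard part of the real
  classification.
- **Noise**: additive Gaussian (sd 0.20 counts against a unit-scale
  signal), a small linear baseline (0.05 + 0.05·x) and a broad Gaussian
  fluorescence bump (amplitude 0.05; plasmonic quenching makes background
  nearly negligible in the real assay). Optional Poisson shot noise at a
  1000-count photon budget is off by default.

**How the difficulty was set.** The published experiment reports three
observables that jointly characterize how hard the classification is at
instrument scale: a reference out-of-bag error near 11 %, a calibrated
attribution threshold of 60 %, and spiked-count recovery at that threshold.
The mixing-weight means, jitter and noise sd above were fixed once so that
the synthetic pipeline lands in the same regime (OOB ≈ 7–10 %, calibrated
threshold in the 60–70 % band, recovery errors of a few cells/ml with the
same mild mesenchymal overcount direction) and were then frozen; they are
exposed in `ClassModel`/`NoiseModel` for sensitivity studies.

## Cell populations and geometry

Retained cells are binomial thinnings of the nominal composition: tumor
cells survive capture-and-fixing with probability 0.84; PBMCs additionally
survive immunomagnetic depletion (retention 10⁻⁴). Thinning is stochastic
rather than deterministic because the efficiency itself was measured as a
proportion with spread. Binomial sampling is exact and instantaneous even
at n = 10⁷, so PBMC counts are not scaled down by default (`pbmc_scale`
remains available); only the ~10³ retained cells per ml are ever
instantiated.

Areas are lognormal in µm²: LNCaP median 80 (σ 0.35), U251 median 65
(σ 0.35), tumor areas resampled into (0, 300); PBMC median 16 (σ 0.42),
putting ~93 % of PBMCs below the 30 µm² gate — the qualitative pattern the
size gate exploits. The exact PBMC distribution is otherwise a free
parameter.

Chamber rasters are 3.5 × 3.5 mm at 1 µm/pixel (pixel size is a required
input in general; no magnification calibration is assumed). Each cell is a
filled elliptical disc built as a 3×3-dilation of a core pixel set, which
makes it invariant under the detector's radius-1 opening; core sizing by
bisection plus a greedy top-up hits the target pixel count exactly in
almost all cases and within ±1 pixel always (pixel counts of 10 or 11 are
not representable by any opening-stable shape). Cells are placed by
rejection sampling with a one-pixel separation so components never touch
under 8-connectivity; a chamber that cannot host its cells after bounded
retries raises an error rather than silently overlapping cells.

## Detection conventions

Pixels are 0-based, row 0/column 0 top-left, x = column·pixel size,
y = row·pixel size; bounding boxes are half-open. The morphological cleanup
is fixed as radius-1 opening followed by hole filling. The opening uses the
3×3 (Chebyshev-metric) footprint: the radius-1 cross would clip the corners
of a 5×5 square to 21 pixels, breaking the pixel-sum area convention.
Components smaller than `min_pixels` (default 4) are dropped; detected
cells are ordered by the (row, column) of their bounding-box corner so the
output is independent of labelling order. Touching-cell splitting
(watershed) and color processing are out of scope.

## Classifier

scikit-learn's `RandomForestClassifier` provides the ensemble (Gini
splitting, bootstrap aggregation, fully grown trees). Two departures from
its defaults are deliberate:

- **Vote fractions, not probability averages.** The attribution percentage
  is defined as the share of trees voting a class, so votes are recomputed
  from per-tree hard predictions rather than `predict_proba`.
- **Out-of-bag attribution for training cells.** Theoretical-mixing
  calibration draws cells from the training pools; in-bag votes for such
  cells are near-certain and would make every threshold look perfect. Pool
  cells are therefore attributed using only the trees in whose bootstrap
  they did not appear (reconstructed from the per-tree bootstrap indices),
  which reproduces the behaviour of classical random-forest implementations
  when predicting on the training set. The OOB error and per-class errors
  are computed from the same vote matrix, so they are exactly consistent
  with the calibration inputs.

`m_try` defaults to 3 on the 4-feature set (r₁, r₂, r₃, area) — the
conventional default for this feature count would be ⌊√4⌋ = 2, but 3 is the
documented setting of the reference analysis and is config-exposed.
Interaction/power features exist behind a flag, off by default. Ties in the
dominant class resolve by the fixed order (LNCaP, PBMC, U251). Class
weights are available but off by default.

## Calibration and enumeration

The threshold grid spans 35–95 % in 5 % steps (the open interval above the
33.3 % uninformative baseline). The selection rule: smallest τ whose
recovered LNCaP and U251 counts match the known mix composition within a
tolerance (default 2 cells) in every mix; if none matches, the τ with the
smallest summed absolute count error, ties to the smallest τ. Thresholds
compare inclusively (≥ τ), as does reporter positivity (≥ τ_pos,
default 0.5).

Identified counts divide by sample volume; uncertainty is the standard
deviation over 1000 bootstrap resamples of the cell list (a 68 % percentile
interval is also reported). The published ± values on identified counts
have no stated method; the bootstrap is this package's choice. Efficiency
correction (identified / 0.84) is reported alongside raw counts, never
silently substituted: the natural comparison for identified counts is the
expected *fixed* population, `round(spiked × efficiency)`.

## Statistics

Mann–Whitney U uses the exact null when n₁ + n₂ ≤ 12 without ties and the
normal approximation with tie-corrected variance and continuity correction
otherwise (SciPy backend; tests verify it against full rank enumeration).
P-values are two-sided throughout. Holm's step-down correction (statsmodels
backend) is applied across the three phenotype pairs. The quantity tested
is the cell *area* in µm²; source descriptions alternate between "diameter"
and "surface" with µm² units, and area is the reading consistent with the
units and with the pixel-sum measurement.

## Pipeline and reproducibility

`run_pipeline` derives all stage seeds from one root seed via
`SeedSequence`, so a fixed configuration reproduces its per-cell tables
byte for byte. Any stage failure removes partial outputs and raises an
error naming the stage. An empty chamber yields a zero-count result with a
warning, not an error.

Desk-scale defaults: reference pools of 300/300/3000 cells (pre-gate),
five theoretical mixes mirroring the expected gated sample composition
(the PBMC gate-pass rate is estimated from the pool itself), and — in the
acceptance script and end-to-end tests — 500-tree forests and ten to twenty
independent 1-ml chambers, sizes chosen to keep full runs in the minutes
range while leaving Monte-Carlo error well below the effects tested.

## What the synthetic experiments do not show

The generator emulates composition, geometry, targeting structure and
noise scale, not instrument physics: no cosmic rays, detector etaloning,
focus drift, cell debris or aggregates, no touching cells, no spatial
inhomogeneity of capture, and reporter line lists that are surrogates.
Passing tests therefore validate the *analysis logic* — detection
morphometry, scoring, gating, attribution, calibration and the counting
arithmetic — under realistic difficulty, not the assay chemistry itself.
Absolute error rates on real chambers may differ; the calibration machinery
exists precisely so the threshold can be re-derived per dataset.
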