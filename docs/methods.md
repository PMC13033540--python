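# Methods

This note documents the models, numerical choices and open design
decisions behind `shellbmd`, and what the synthetic generators do and
do not emulate.

## Two-energy calibration and decomposition

The pipeline assumes each voxel is a two-material mixture of soft
tissue and hydroxyapatite (HA) mineral, and that within the calibrated
range the HU response at each virtual-monoenergetic energy is affine
in mineral density.  Calibration fits `HU_E = a_E ρ + b_E`
independently at 50 and 200 keV by ordinary least squares over the
phantom-insert samples (unit weights; noise-variance weighting is out
of scope).  The per-pixel solve treats the two energies as two
equations in one unknown bone volume fraction `f` and minimizes the
summed squared HU misfit, which has the closed form given in the
README.  An alternative single joint fit `BMD = a·HU50 + b·HU200 + c`
(`mode="bilinear"`) is provided; on noise-free phantom data the two
modes coincide exactly, and the per-energy mode is the default because
it keeps the physical line parameters inspectable.

Parameters that matter:

* `rho_ref` (mgHA/cm³, default: densest insert = 800) — the
  pure-mineral basis endpoint.  Pure convention: it cancels in BMD and
  only fixes the scale of `f` so that `f ∈ [0, 1]` spans the
  calibrated range.
* `voi_shrink` (default 0.7) — insert VOI radius as a fraction of the
  physical insert radius, keeping the VOI clear of partial-volume rim
  voxels, as standard in quantitative-CT phantom practice.
* `clamp` (default `floor-zero`) — negative solved fractions are set
  to 0.  ROI population minima of 0 in the reference tables motivate a
  hard floor; there is no upper clamp because observed maxima exceed
  1200 mgHA/cm³.  The clamp is recorded in each map's provenance.

Pairs at energies other than (50, 200) keV are rejected rather than
extrapolated.  Degenerate calibrations (fewer than two distinct insert
densities) raise a singular-fit error.

## Phantom and volume synthesis

The synthetic phantom holds four cylindrical HA inserts spanning
100–800 mgHA/cm³.  Only the range endpoints are externally fixed; the
interior densities default to the geometric-type ladder
{100, 200, 400, 800} typical of quantitative-CT phantoms, and are
configurable.  Voxel HU is `background(E) + ρ · slope(E)` plus
optional i.i.d. Gaussian HU noise, independent across energies
(default 0 for analytic tests, 15 HU for realism tests).  The default
attenuation constants — slopes (1.40, 0.50) HU per mgHA/cm³ at
(50, 200) keV over a (40, 30) HU soft-tissue background — are
generator conventions chosen only to satisfy the physically required
monotone energy dependence of mineral attenuation (photoelectric
contribution fading above ~100 keV); they are not calibrated physics.

The generators deliberately omit scanner physics: no spectra, beam
hardening, scatter, detector model, partial-volume blur or motion
artifacts (missing sites are modelled as dropout only).  Passing tests
therefore demonstrate correctness of the calibration/decomposition/
quantification machinery, not robustness to acquisition artifacts of
real scans.

## ROI pixel-population model

Each (severity group, site) pixel law is a zero-inflated truncated
gamma: value 0 with probability π₀, else Gamma(k, θ) truncated above
at T.  The family was chosen because the reference summaries show hard
zeros that grow with severity, right skew (mean > median in every
row) and finite maxima.  Moments and quantiles of the truncated gamma
are computed analytically from regularized incomplete gamma
functions; sampling is inverse-CDF, so truncation is exact.

Fitting matches mean, SD and the zero/near-zero first percentile per
row, with T fixed at the reported maximum.  A reported 1st percentile
of 0 only bounds π₀ from below (π₀ ≥ 0.01), leaving it unidentified;
for those rows the reported median is used as the third matching
target instead (it is the only remaining statistic sensitive to π₀),
with π₀ constrained ≥ 0.0101.  Where the 1st percentile is positive,
π₀ < 0.01 is enforced, the percentile is matched and the median stays
a diagnostic (fitted medians land within ~7% of their targets).  The
fit is a bounded least-squares in (π₀, log k, log θ) from four starts;
all twelve rows converge with mean/SD residuals below 1%.  Fitted laws
are cached per process; `analysis/01_fit_reference_distributions.py`
tabulates them.

Shell-subject geometry (half-ellipsoid carapace, plastron slab,
bar-shaped scapula/ilium regions) exists solely to exercise
rasterization and mapping end to end; anatomical realism is a
non-goal.  The ROI-slice pixels are painted with the exact draws
recorded for that ROI, so generator and truth are self-consistent by
construction.

## ROI quantification

* Rasterization: a pixel belongs to an ROI iff its center is covered
  by the polygon (even-odd rule; centers exactly on an edge are
  included).  Coordinates are physical mm on the named plane
  (sagittal/dorsal/transverse = axis 0/1/2), voxel indexing is
  0-based half-open, centers at `(index + 0.5) · spacing`.  This makes
  pixel counts bit-reproducible; tests verify equality with a
  brute-force even-odd oracle and ~2% area convergence for polygons
  covering ≥ 400 pixels.
* Summary statistics: sample SD (n−1); percentiles by linear
  interpolation between order statistics (no method is externally
  prescribed; this is the numpy default and is stated in the docs so
  counts and percentiles reproduce exactly).
* Side gate: two-sided Wilcoxon rank-sum on the left vs right pixel
  populations; `alpha_side = 10⁻⁴`.  The threshold adopts the reported
  discordance level of the excluded pairs; the comparison runs on
  pixel values, since only pixel-level n makes such small p-values
  reachable.  A missing side passes through untested.
* Histograms: fixed-width bins from 0 (default width 25 mgHA/cm³,
  configurable and recorded in output), counts normalized to sum to 1.

## Cohort statistics

The comparison unit for the group tables is the animal-level site mean
with sides pooled (pixel-level pooling is available as a separate
mode).  The rank-sum test enumerates the exact null when the smaller
sample has at most 8 observations and the data are tie-free, falling
back to the tie-corrected normal approximation with continuity
correction otherwise.  Exact enumeration at these sizes is cheap and
markedly more accurate for the unbalanced group sizes of small
cohorts (asymptotic p for a fully separated 12-vs-4 split is ~4× the
exact value).

Bonferroni uses m = 6 (the pairwise comparisons within one site) by
default; m is configurable (e.g. 18 to correct across the three
sites) because the appropriate family is a reporting choice.
Significance *labels* follow the tier map `ns` (> 0.1), `*`
(0.05–0.1), `**` (0.001–0.05), `****` (≤ 0.001); note the `*` tier
annotates values above the conventional 0.05 cut-off — labels are
table cosmetics, while significance decisions in this package always
use adjusted p ≤ 0.05.  The `***` tier is unreachable under the
default map but kept for configurable alternatives.

Levene's test uses the classic mean-centered form (median-centered
Brown–Forsythe available via `center="median"`); all-constant groups
return statistic 0 and p = 1 by convention.

## Reference cohort

The shipped cohort plan encodes 23 animals in severity groups of
12/4/3/4, five sites per animal (gular; scapula and ilium left/right),
five motion-missing scapula sites and two paired sites with an
injected left/right inconsistency (left side scaled by 0.25) so the
side gate has true positives to find: accounting yields 115 planned,
110 obtained, 106 retained sites.  Default 1000 pixels per ROI — a
mid-range polygonal ROI at sub-millimetre in-plane resolution.  Each
planned slot draws from its own child seed in plan order, so removing
one slot never changes another slot's pixels.

## Problem sizes and determinism

Defaults keep everything desk-scale: 64×64×24 phantom, 64×64×48
subjects, 1000-pixel ROI populations, 100-seed Monte-Carlo checks, and
a 500-replicate null-cohort calibration of the site comparison's
familywise error.  All generators are deterministic given a seed
(NumPy `SeedSequence` spawning), and the full pipeline writes
byte-identical CSV outputs under identical config + seed.

## Known limitations

* The attenuation constants and geometry are conventions; absolute HU
  realism (beam hardening, kernels, scanner calibration drift) is not
  modelled, so numerical agreement with any particular scanner is not
  implied.
* The zero-inflated gamma matches first/second moments and tail
  bounds of each reference row, not full histograms; within-animal
  correlation of pixels is not modelled (animals are i.i.d. draws of
  their group law), which makes synthetic group separation cleaner
  than clinical data.
* Morphometric landmarks are user inputs; no anatomical landmark
  detection is attempted.
* Phantomless (internal-reference) calibration is out of scope; a
  phantom volume pair or a fitted model is always required.
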