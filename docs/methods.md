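# Methods

## Analyte and mass model

The analyte is the reduced TTR apo-monomer: serum is DTT-treated before
spotting, which dissociates the tetramer and strips Cys10 adducts
(cysteinylation, glutathionylation), so the default wild-type mass carries
a free Cys10 thiol. The mature secreted chain (127 residues, signal
peptide removed) is embedded as the reference sequence; mutation positions
use mature-chain numbering, the convention behind clinical labels such as
Val30Met. The precursor ("+20") numbering is deliberately not supported.

All masses are average masses. The residue-mass table
(`ttrscreen.masses.AMINO_ACID_AVERAGE_MASSES`, version tag `iupac-2021`)
holds the 20 standard average residue masses to 4 decimals from current
IUPAC standard atomic weights, plus 18.0153 Da for the terminal water.
With it the reduced WT monomer computes to 13,761.41 Da and the
theoretical shift of a substitution is exactly the residue-mass
difference; additivity (mutant chain mass = WT mass + residue delta) holds
to < 1e-9 Da by construction and is property-tested. Published shift
tables for this assay round to 2 decimals with ties away from zero;
`round_half_up` reproduces that display convention. Reference values
published for this cohort agree with the computed shifts to ≤ 0.008 Da
(the source's own mass table is unstated); the one printed outlier, a
Glu89Gln value of −9.90, is a typographical artefact for −0.99 and is
stored in the bundled fixture both as printed and corrected.

A shift is called resolvable when |Δm| ≥ 12 Da, inclusive at the boundary
(the smallest shift the platform demonstrably identified is +12.05 Da).

## Synthetic spectra

No public reference spectra exist for this assay, so the generator
produces the study conditions directly, with ground truth attached to
every spectrum:

* window 1,000–20,000 Da on a uniform 0.5-Da grid (≥ 18 samples per FWHM
  at the TTR mass);
* Gaussian peaks with σ = m/(R·2.3548), i.e. constant FWHM-based
  resolving power R; default R = 1500 (see below);
* heterozygotes split the fixed total TTR ion area 1:1 between alleles by
  default (`variant_fraction = 0.5`); the split conserves total area
  exactly, which is property-tested;
* the four calibrant proteins (insulin 5734.51, ubiquitin I 8565.76,
  cytochrome c 12360.97, myoglobin 16952.30 Da) and, by default,
  [M+2H]²⁺ companions at 30% relative area for every species;
* an exponential chemical baseline A·exp(−m/λ) with A = 60 units,
  λ = 3000 Da — a generic matrix-background shape;
* heteroscedastic Gaussian noise, sd = 0.3·√(signal + baseline + 1),
  emulating counting-like statistics; with the default areas the WT peak
  has SNR ≈ 100 and the calibrants ≥ 40;
* an optional affine axis warp m_obs = a·m_true + b (defaults 1.0 / 0.0)
  standing in for residual miscalibration;
* flag-gated, off by default: Cys10-cysteinylated satellites (+119.14 Da)
  and sodium adducts (+21.98 Da).

Determinism: each spectrum is fully determined by (config, genotype);
cohorts derive per-spectrum seeds from a master seed via numpy's
`SeedSequence`, and all derived seeds stay below 2³¹.

What the generator does **not** emulate: TOF peak tailing and detector
saturation, matrix cluster chemistry, isotope fine structure,
tetramer/dimer species, and the serum proteome background beyond the
smooth baseline. Passing tests therefore demonstrate correctness of the
analysis chain under idealised linear-MALDI physics, not robustness to
every real-serum artefact.

### Choice of resolving power

R is the one simulator parameter that decides which shifts resolve. The
detector reports two near-lying maxima as distinct peaks only when the
valley between them drops below 75% of the lower apex. For an equal-height
Gaussian doublet this criterion places the two-peak limit at ≈ 1.18·FWHM:
at R = 1500 (FWHM ≈ 9.2 Da at 13.76 kDa) a 12.05-Da doublet gives a
valley ratio of 0.60 (robustly split), a 9.9-Da doublet 0.85 (robustly
merged), and sub-1-Da doublets a single maximum outright. The emergent
resolution limit of the simulated platform is thus ≈ 10.8 Da — below
every resolvable catalogue shift (≥ 12.05 Da) and far above the
unresolvable ones (≤ 0.99 Da) — so cohort-level screening reproduces the
12-Da empirical minimum without encoding it anywhere downstream. A
nominally attractive alternative, FWHM ≈ 12 Da (R ≈ 1150), fails its own
purpose: under the 75% valley criterion a 12-Da doublet at 12-Da FWHM has
a valley ratio of 0.92 and merges.

## Signal processing

The processing chain is deliberately explicit (vendor software hides all
of it):

* **Baseline** — morphological opening (rolling minimum then maximum,
  200-Da window) followed by a 100-Da moving average. The window is wide
  relative to any peak (FWHM ≤ 13 Da in-window), so peaks are flattened
  while the exponential background is followed to < 5% relative error.
* **Noise** — 1.4826 × MAD of the baseline-subtracted signal in
  non-overlapping 100-Da windows, interpolated to the grid and floored at
  machine-epsilon scale so SNR stays defined on noiseless synthetic data.
  MAD keeps single spikes from inflating the estimate.
* **Peaks** — local maxima of the corrected signal with apex/noise ≥ 5
  (default `snr_min`). Adjacent maxima merge unless the valley drops below
  75% of the lower apex; this one rule both suppresses noise ripple on a
  broad peak (ripple valleys sit near 100%) and formalises when a variant
  doublet counts as resolved. Each peak is centroided
  (intensity-weighted mean m/z) over its half-max support, clipped at the
  valley toward a neighbour; FWHM comes from interpolated half-max
  crossings; support must span ≥ 3 grid points.
* **Calibration** — for each reference mass, the nearest centroid within
  0.3% of the reference is matched (ties to the more intense peak; peaks
  below 10% of the window's most intense peak are ineligible, so noise
  spicules cannot outcompete a calibrant), then reference is regressed on
  observed by OLS. Fits need ≥ 2 matches and a slope in (0.9, 1.1).
  Calibration is affine in m/z, not in flight time (unavailable after
  vendor export); over 5.7–17 kDa an affine map recovers warped TTR
  positions to < 0.1 Da across the tested warp grid (a ∈ [0.999, 1.001],
  b ∈ [−5, +5] Da).

Centroids, not apexes, are the reported positions: with a 0.5-Da grid and
9-Da-wide peaks, apex positions quantise to the grid while centroids are
good to ~0.1 Da.

### Centroid bias at barely resolved doublets

A just-resolved doublet (separation ≈ 12 Da at FWHM 9.2) has each
centroid pulled toward the other peak by the neighbour's tail inside the
shared support; the measured shift underestimates the true separation by
~1.4 Da deterministically, and up to ~1.6 Da with noise. This is a real
feature of unresolved-mixture centroiding, not an artefact: the reference
platform showed the same behaviour more strongly (12.05-Da variant
measured at 8.79 Da, a 3.26-Da deviation). The catalogue match tolerance
(3.5 Da) is sized to cover exactly this regime; well-separated doublets
(≥ 28 Da) measure true to ~0.1–0.3 Da.

## Variant screen

Defaults: WT window ± 6 Da (half the resolvability threshold, so WT
assignment can never swallow a resolvable variant), variant window
± 120 Da (covers the −76.10…+99.14 Da range single substitutions reach;
wider windows would admit adduct satellites), candidate intensity floor
20% of the WT apex, match tolerance 3.5 Da. All are `ScreenParams` fields.

Statuses: `detected` (a candidate peak matched the catalogue),
`not_detected`, `no_wt_peak`, and — only when an expected genotype from
genetic testing is supplied — `unresolvable_candidate` for carriers of
sub-threshold variants. Blind screening (no expected genotype) reports
sub-threshold carriers as `not_detected`, which is exactly the screening
behaviour being modelled. Isobaric catalogue entries within tolerance are
all reported, ranked by |measured − theoretical|.

## Cohort statistics

`ols_fit` is closed-form OLS of measured (y) on theoretical (x) shift with
r² the squared Pearson correlation; it is cross-checked in the tests
against an independent zooming grid-search minimiser of the squared error.
Sensitivity reports the exact fraction and a half-up integer percent —
note 38/42 = 90.48% rounds to 90 although such results are sometimes
published rounded up to 91. The minimum identified shift is the floor of
the smallest |theoretical shift| among detected samples.

The bundled 42-sample reference cohort (checksummed TSV fixture) supports
two regression conventions. `detected` uses the 38 detected pairs —
statistically the defensible choice, giving y = 1.0030x − 0.4567,
r² = 0.9993. `as_figure` enters all 42 samples with not-detected entries
at zero measured shift (and the theoretical column exactly as printed):
it gives y = 0.9927x + 0.1251, r² = 0.9969, matching the published fit's
r² exactly at printed precision and its slope to 0.001 — evidently the
convention behind the published figure. Its intercept (+0.13 vs the
published +0.08) is the one quantity not reproducible from the printed
2-decimal values under any convention we tried.

## Problem sizes and numerical choices

Default spectra carry 38,001 points; a full 42-spectrum cohort simulates
and screens in a couple of seconds, and the test suite's largest jobs
(100 centroid-accuracy replicates, 50 negative-control spectra, a 3×3
warp grid) each run in well under a minute. Ties in calibrant matching go
to the more intense peak; ties in WT location likewise. Degenerate inputs
fail loudly: empty sequences, silent substitutions, wild-type mismatches,
spectra not covering the variant window, < 2 matched calibrants, and
non-positive thresholds all raise typed exceptions rather than returning
partial results.

## Known limitations

Single heterozygous substitutions only: no indels, compound
heterozygotes, PTM-resolved species, or variant:WT quantification.
Overlapping-peak deconvolution is out of scope by design — the screen
formalises what a spectrum reader does, and its accuracy floor at
near-threshold shifts mirrors the platform it models. The mzML layer is
minimal (single MS1 spectrum, 32/64-bit float arrays, plain or zlib) and
is meant for interchange of simulated or exported traces, not for vendor
raw data.
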