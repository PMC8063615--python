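# Methods

## The measurement and its model

Intact-cell MALDI-TOF profiling deposits whole sperm cells with matrix on a
target plate and records linear positive-mode profile spectra over m/z
1,000–20,000. Each biological sample (one animal × one ejaculate) is spotted
12 times and each spot acquired 3 consecutive times, giving 36 technical
replicate spectra per sample. Peaks are intact peptidoforms and proteoforms
(linear mode does not resolve isotopes, and ions are predominantly singly
charged), so observed m/z is compared against theoretical *average* [M+H]⁺
masses.

The pipeline assumes profile spectra share no common m/z grid a priori, that
mass-axis error is dominantly gain-like (TOF calibration drift), that the
baseline is smooth and broad relative to peak widths, and that noise is
approximately symmetric around the baseline so a median absolute deviation
is a robust scale estimate.

## Processing chain

Order: square root → TopHat baseline → Savitzky–Golay → (external
calibration when a calibrant-mixture spectrum is supplied) → alignment on
prominent peaks → lock-mass recalibration → TIC normalization → peak
detection. Normalization is applied last so the replicate-correlation QC
operates on comparable vectors; the internal (lock-mass) correction follows
alignment so that a single gain factor suffices.

Key choices, all configuration-exposed:

* **Square root** stabilizes the variance of count-like detector noise.
  A consequence worth remembering when interpreting results: fold changes
  downstream are measured on this compressed scale, so a true r-fold
  abundance change appears as roughly √r in the feature matrix.
* **TopHat baseline**: grayscale opening (erosion then dilation) with a flat
  structuring element of 2·75+1 points by default, windows truncated at the
  edges; the opening never exceeds the signal, and the corrected spectrum is
  clipped at zero because negative intensities are unphysical and would
  break re-application of the square root. The implementation (scipy
  min/max filters) is tested for exact equality against an O(n·w)
  brute-force sliding min/max oracle.
* **Savitzky–Golay**: window 21, order 3 by default; window 1 is the
  identity; edge windows are handled by boundary polynomial fits.
* **External calibration** fits a least-squares affine map from observed
  apexes to the six reference masses (Glu1-fibrinopeptide B 1571.59,
  ACTH 18–39 2466.68, insulin 5734.52, ubiquitin 8565.76, cytochrome C
  12360.97, myoglobin 16952.31) and enforces a post-fit relative residual
  below 0.05%, the mass-accuracy bound the method targets. Fewer than two
  matched calibrants is a hard error.
* **Alignment** pools the 10 most intense local maxima per spectrum,
  clusters them within 2000 ppm, takes cluster medians (clusters present in
  ≥ half the spectra) as references, and warps each spectrum with its own
  least-squares affine fit; spectra with fewer than two matches pass
  through unwarped and flagged.
* **Lock mass** is a single-point *multiplicative* correction: the whole
  axis is scaled by reference/observed for the tallest local maximum in the
  5,000–12,000 window, restoring the dominant mid-range proteoform
  (phosphoglycerate kinase) to 7,983.457 m/z exactly. A gain rather than an
  offset is corrected because TOF mass error scales with m/z; the operation
  is idempotent. An additive variant was considered and rejected as it
  would leave proportional error at the spectrum extremes.
* **TIC normalization** scales each spectrum to unit summed intensity.
  Note the closure effect: a genuine abundance change in a few dominant
  peaks shifts *all* normalized intensities slightly in the opposite
  direction, which can manifest as weak but consistent group differences in
  otherwise null bins.

## Peaks, binning and replicate QC

Peaks are strict local maxima within ± 20 points whose intensity is at
least 2 × the MAD-based noise (1.4826 × median |x − median x|, computed
globally per spectrum). Plateau tops are not peaks. Detection is tested for
exact set equality against a windowed-argmax oracle.

Binning pools peaks from all spectra, sorts by m/z and starts a new bin
whenever the gap to the current bin's intensity-weighted mean exceeds
500 ppm (the annotation tolerance, reused deliberately). Absent peaks are
recorded as 0 rather than re-integrated local signal — the matrix has
detected-peak semantics; re-integration is a possible extension.

Replicate filtering interprets the 40–90% correlation iterations as Pearson
thresholds 0.40–0.90 in 0.05 steps: a replicate survives threshold τ when
its median (configurably mean) correlation with same-sample replicates is
≥ τ, and the selected τ is the largest at which at least half of all
replicates survive with every sample retaining at least one. Whether the
original procedure correlated raw vectors or binned intensities is
ambiguous; this implementation correlates binned vectors and documents the
choice. Retained replicates are merged by the arithmetic mean (technical →
sample, then sample → animal). CV% = 100 × SD/mean (SD with n − 1) per bin,
computed across technical replicates within an ejaculate (intra) or across
per-ejaculate means within an animal (inter); zero-mean bins are excluded
and counted.

## Annotation

Theoretical average [M+H]⁺ = Σ IUPAC average residue masses + 18.0153
(water) + 1.00728 (proton) + signed PTM shift. Average masses are the
default because linear-mode peaks are isotope-unresolved envelopes; a
monoisotopic table exists behind a flag. Matching returns *all* records
within ± 500 ppm ranked by |ppm error| (ties broken by record id):
with databases of hundreds of proteoforms over this mass range, ambiguity
must stay visible rather than being collapsed to a best hit. Unannotated
bins are a first-class outcome.

## Differential statistics

Per bin, a two-sided Mann–Whitney test on per-animal merged values: exact by
enumeration of the rank-sum distribution when both groups have ≤ 12
observations and the pooled values are tie-free, otherwise the mid-rank,
tie-corrected normal approximation. The fold change is the F/SF group-mean
ratio (0/positive → 0, positive/0 → ∞, 0/0 → 1). A bin is called
differential when p < 0.05 *and* FC ≤ 0.66 or ≥ 1.5; p-values are reported
without multiplicity correction, matching the per-feature usage this
pipeline mirrors (a Benjamini–Hochberg option exists, off by default). PCA
is an SVD of the column-centered (optionally standardized) per-animal
matrix with 1-based component labels and a fixed sign convention
(largest-magnitude loading positive).

A discreteness note: the exact two-sided test at 9 vs 9 animals can only
attain certain p-values, and the true size of the rule "p < 0.05" is
0.039984 — the largest attainable level below nominal. Calibration checks
therefore compare the observed rejection rate with this enumerated size,
not with 0.05 itself.

The GeLC branch consumes already-quantified cluster tables. Spectral counts
are column-normalized so every technical replicate's total equals the mean
total (NWS); per-animal values are means over the three technical
replicates; a two-sided t-test (Welch by default, pooled-variance switch)
is applied per protein. A protein is differentially abundant when p < 0.05,
FC ≤ 0.71 or ≥ 1.4, and — for spectral counting only — the larger
group-mean NWS is ≥ 5 (low-count proteins are left to the intensity-based
method, which has no such floor). One significant member represents each
cluster: members with a proper gene symbol and description are preferred
(LOC-style entries only when nothing else exists, and such clusters are
excluded from the unique-gene list); the draw is uniform from a seeded
generator, and when the representative is significant under both methods
the spectral-counting statistics are kept.

Phenotypes: fertility rate > 70% → fertile, < 40% → subfertile, otherwise
intermediate and excluded. Motility flags use strict VAP thresholds
(motile > 5 μm/s, rapid > 50 μm/s). The printed "progressive" rule
(VAP > 50) duplicates "rapid" and is almost certainly a reporting slip for
a straightness- or VSL-based criterion; it is implemented as printed and
flagged in the output so users can substitute their own rule. Group
comparisons are per-parameter Mann–Whitney tests at p ≤ 0.05, again without
multiplicity correction.

## Synthetic data

`simulate_dataset` emulates the acquisition design: Gaussian peaks with
σ(m/z) = m/z / (2.355 · R), R = 600 (linear-mode-like resolving power), an
a·exp(−(m/z − m₀)/τ) baseline (τ = 3,000 Da), additive Gaussian noise
truncated at zero with a per-spectrum lognormal scale factor
(heteroscedasticity), per-spot affine mass drift (150 ppm-scale gain SD plus
a small offset), a dominant lock-mass peak always planted at 7,983.457, and
per-animal lognormal amplitude variability (CV 15%). Differential peaks are
scaled by their fold change in the fertile group, so FC is F/SF by
construction. Quantification tables use a negative-binomial count model
(variance = μ + 0.3 μ²) and lognormal intensities (σ = 0.4), chosen to make
t-test behavior realistic; phenotype tables draw fertility rates inside the
disjoint classification bands and CASA parameters with overlapping group
distributions. `simulate_feature_matrix` generates per-animal peak matrices
directly (lognormal with a requested CV) for statistical calibration runs
where full spectrum simulation adds nothing.

What the simulator does *not* model: MS/MS fragmentation, ion statistics,
detector saturation, matrix/chemical-background structure, isotope
envelopes, or correlated (non-affine) mass-axis error. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated generative assumptions, not performance on real
instrument data — in particular, real baselines and noise are less benign
than the exponential-plus-truncated-Gaussian model.

Problem sizes used in the test and acceptance runs are deliberately small
(1–9 animals per group, 1–12 spots, 200-bin matrices, 50 calibration
seeds): large enough for the statistical bands being checked, small enough
that the whole suite completes in about a minute.

## Known limitations

* Fold-change gates act on the variance-stabilized, TIC-normalized scale;
  raw abundance ratios are compressed toward their square root and the TIC
  closure effect can create weak spurious group differences (see the
  README's worked example).
* Peaks closer than the linear-mode width merge into one bin; the
  simulator does not forbid planting differential peaks next to neighbors,
  so recovery tests see this realistic failure mode.
* The correlation-filter semantics ("iterations from 40 to 90%") and the
  TopHat/Savitzky–Golay window sizes are documented interpretations of an
  under-specified procedure, not recovered constants; all are exposed in
  the configuration.
* The mzXML support is a deliberate subset (scan list, float64 peak pairs,
  nameValue metadata) intended for interchange and testing, not full
  schema coverage; it round-trips exactly and is cross-read by pyteomics in
  the test suite.
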