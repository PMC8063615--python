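# icmprofile

Intact-cell MALDI-TOF (ICM-MS) profiling of sperm cells, reimplemented as a
tested, reusable Python pipeline. ICM-MS fingerprints whole cells without
protein extraction: linear positive-mode spectra over m/z 1,000–20,000 whose
peaks are peptidoforms and proteoforms below ~20 kDa. Comparing fertile (F)
and subfertile (SF) males on these fingerprints — together with label-free
GeLC-MS/MS quantification tables and fertility/semen phenotypes — identifies
candidate molecular markers of sperm-fertilizing ability.

The package covers:

* **Spectral preprocessing** — square-root variance stabilization, TopHat
  (morphological opening) baseline subtraction, Savitzky–Golay smoothing,
  external calibration on a six-component calibrant mixture, alignment of
  replicate spectra on prominent peaks, internal lock-mass recalibration on
  the dominant mid-range proteoform (phosphoglycerate kinase, 7,983.457 m/z),
  and TIC normalization.
* **Peak detection and QC** — strict local maxima at MAD-based
  signal-to-noise ≥ 2, greedy ppm binning into a samples × m/z-bins feature
  matrix, pairwise-correlation filtering of the 36 technical replicates per
  sample (12 spots × 3 acquisitions), replicate merging, and intra-/
  inter-assay CV%.
* **Annotation** — matching bins to a proteoform/peptidoform database by
  theoretical average [M+H]⁺ mass (computed from sequence + PTM shift) at a
  relative tolerance of 0.05% (± 500 ppm).
* **Differential statistics** — per-bin two-sided Mann–Whitney tests with
  fold-change gates (F/SF ≤ 0.66 or ≥ 1.5 at p < 0.05), volcano and PCA
  views; the GeLC branch's spectral-counting (normalized weighted spectra,
  NWS) and average-precursor-intensity (API) decision rules (t-test
  p < 0.05, FC ≤ 0.71 or ≥ 1.4, NWS floor of 5, cluster-representative
  selection); fertility-rate classification (> 70% fertile, < 40%
  subfertile) and CASA-based motility classes.
* **Synthetic data** — a generator reproducing the acquisition design
  (Gaussian peaks with linear-mode mass-dependent width, exponential
  baseline, truncated noise, per-spot affine mass drift, a planted lock-mass
  peak, injected differential proteoforms) with full ground truth, so every
  stage is testable without any deposited data.

## Worked example

```python
from icmprofile import (SimConfig, simulate_dataset, preprocess_chain,
                        PreprocessConfig, feature_matrix_from_spectra,
                        filter_replicates_by_correlation, merge_replicates,
                        differential_peaks)

cfg = SimConfig(n_fertile=4, n_subfertile=4, n_ejaculates=1, n_spots=3,
                n_acquisitions_per_spot=2, n_base_peaks=40,
                n_differential=3, differential_fc=(3.0, 0.3, 2.0), seed=42)
spectra, truth = simulate_dataset(cfg)
processed = preprocess_chain(spectra, PreprocessConfig())
matrix = feature_matrix_from_spectra(processed)
filtered, qc = filter_replicates_by_correlation(matrix)
per_animal = merge_replicates(merge_replicates(filtered, "sample"), "animal")
results = {r.bin_mz: r for r in differential_peaks(per_animal)}
```

prints (via the accompanying reporting code):

```
simulated 48 technical spectra, 3 spots x 2 acquisitions per sample
952 bins; replicate-correlation threshold 0.90; 48/48 replicates retained
injected truth vs recovered statistics (processed-intensity scale):
    8043.92 m/z (raw FC 0.3) -> bin   8049.37: p=0.0286  FC=0.87  [significant]
    9427.13 m/z (raw FC 2.0) -> bin   9427.16: p=0.0286  FC=1.49  [significant]
   15923.78 m/z (raw FC 3.0) -> bin  15923.59: p=0.0286  FC=1.82  [significant_fc]
```

All three injected effects are recovered as significant (p = 0.0286 is the
smallest two-sided exact Mann–Whitney p attainable at 4 vs 4 animals). Two
instructive attenuations are visible: fold changes are measured on the
variance-stabilized (square-root, TIC-normalized) scale, so a raw 2-fold
change compresses toward √2 ≈ 1.41 and narrowly misses the ≥ 1.5 gate; and
the 0.3-fold peak at 8043.9 sits only 6.4 Da from a neighboring peak —
unresolved at linear-mode resolution (σ ≈ 5.7 Da there), so its bin blends
both peaks and the apparent fold change shrinks to 0.87.

The same pipeline is scriptable from the shell:

```
icmprofile simulate --seed 7 --out-dir run/
icmprofile report --sim-dir run/ --out-dir run/report/
```

Every subcommand writes a `*.params.json` log (parameters + library
versions) sufficient to reproduce it, and two runs with the same seed and
configuration are byte-identical.

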