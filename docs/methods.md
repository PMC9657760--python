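# Methods

## Problem and scope

`planktofuse` implements an unsupervised-classification workflow for
zooplankton pellets measured by two laser spectroscopies: LIBS (atomic
emission, wavelength in nm) and Raman scattering (molecular vibrations,
Raman shift in cm⁻¹). The package covers the full chain — synthetic data
generation, spectral preprocessing, multi-block fusion, matrix
decompositions, and silhouette-based cluster-validity evaluation — and is
validated end to end on synthetic spectra with known ground truth. It does
not model plasma physics, instrument response, self-absorption line shapes,
or perform supervised classification; cluster labels always come from known
taxa.

## Synthetic spectra generator

The generator emulates the geometry of a pellet study: 29 samples
(14 Calanoida, 11 Euphausiacea, 2 Parasagitta, 1 Limacina, 1 mixed), three
visually distinct spot colours per pellet, `spots_per_colour ≥ 3` spots per
colour and modality (so ≥ 18 spot spectra per sample), a 12,275-point LIBS
grid over 186–1049 nm and a 2,801-point Raman grid over 450–3150 cm⁻¹.
Shot-level structure (≈10 laser shots per spot in practice) is collapsed to
spot-level replicates, since shots are averaged before any other processing
and the spot is the atomic unit of the workflow.

A spot spectrum is

    I(x) = Σ_f h_f · G(x; c_f, w_f) + B(x) + ε(x),  clipped at 0,

where `G` is a unit-height Gaussian with centre `c_f` and FWHM `w_f` (LIBS
line widths default to 3 detector pixels ≈ 0.21 nm; Raman bands to
10 cm⁻¹), `B` is a polynomial background (6th order for Raman, standing in
for residual uncorrected fluorescence), and `ε` is heteroscedastic Gaussian
noise with SD proportional to the local noise-free intensity plus a floor
tied to the spectrum maximum. Feature heights are

    h_f = relative_intensity_f × colour factor × sample-level multiplier
          (× per-spot resonance jitter for flagged features).

Sample-level multipliers are lognormal with σ = 0.2 per feature, shared by
all spots of a sample: they create the between-sample, within-taxon
variance the decompositions need. Resonance-flagged features (Na I D, K I
doublet, Ca II H&K, Mg II, Li I 670.8 nm; the Raman C–H stretch bands) get
an additional per-spot lognormal jitter with σ = 0.6: strongly self-absorbed
or saturating signals are poorly reproducible in practice, and this
irreproducible variance is precisely what downstream region masking removes.
Planted outliers multiply the feature component of a spot by
`outlier_scale` (default 5) at rate `outlier_rate` (default 0.05): rare,
unambiguous anomalies for the Grubbs filter to catch.

The taxon templates encode the qualitative inventory of the organisms: Li
lines (610.4/670.8 nm) and carotenoid bands (1004/1157/1518 cm⁻¹) for the
copepods; the 1609 cm⁻¹ phenyl band and stronger Sr/Cu emission for krill;
C₂/CN emission and amino-acid bands (755/945/486/503/3013 cm⁻¹) for the
weakly mineralised arrow worms; the line-richest LIBS spectrum (Ca I/II,
CaOH, CaCl) and feeble Raman features for the shelled sea snail; fatty-acid
bands (1268/1302/1446/1656 cm⁻¹) everywhere. Relative intensities are free
parameters of the generator, not measurements; they were fixed once so that
the synthetic study reproduces the qualitative structure the workflow is
meant to expose — taxa separable in feature space, LIBS more discriminative
than Raman (sharper, more variable features; Raman is flattened further by
total-intensity normalisation over a large shared background), and raw
spectra dominated by resonance-line variance. Passing tests on these data
show the *machinery* is correct and that the documented directional effects
(masking gain, fusion benefit) emerge under realistic structure; they say
nothing quantitative about real organisms.

## Preprocessing

- **Peak intensity** for outlier screening is the net area: trapezoidal
  integral over a window (± 0.5 nm LIBS, wider for band heads) minus the
  chord joining the window's endpoint intensities. Net areas are robust to
  one-pixel jitter and exactly zero on linear baselines. On grids coarser
  than the window the integral widens to the 3 points nearest the centre.
- **Grubbs test**: iterative, two-sided, α = 0.05 by default, critical
  value G(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper
  α/(2n) Student-t quantile on n−2 degrees of freedom. The extreme point is
  removed while G exceeds G_crit and ≥ 3 points remain, so a single pass
  can reduce a group to 2 spots but never fewer; zero-variance groups are
  kept whole. Screening runs sequentially over the five diagnostic windows
  (Li I 610.3, C I 247.8, Na I 568.3, Ca II 396.8, C₂ 473.6); a spot
  removed at any stage stays removed, and at least one spot survives.
  Whether peak *heights* or *areas*, one- or two-sided testing were meant
  is not decidable from the workflow description; areas and two-sided were
  chosen and are the package's contract.
- **Averaging and normalisation**: surviving LIBS spots are averaged
  pointwise; Raman spots are first normalised to unit total intensity
  (idempotent, scale-invariant), then averaged. LIBS spectra are *not*
  total-intensity normalised — their scaling happens only at block fusion.
- **Masking**: config-driven list of [lo, hi] regions with a modality tag;
  defaults mark the Na I 588.995/589.592, K I 766.49/769.90,
  Ca II 393.37/396.85 and Mg II 279.55/280.27 nm resonance doublets
  (± ≈ 0.5 nm) and the saturating Raman C–H stretch region
  (2780–3000 cm⁻¹). These defaults are stand-ins chosen by this package,
  not a reconstruction of any particular instrument's discard list.
  Masking records provenance on the block.
- **Chaining and fusion**: the three colour spectra of a sample are always
  concatenated — never averaged — in the fixed, audited order
  dark‖medium‖light, tripling the feature count; per-modality blocks are
  fused by dividing each by its Frobenius norm and concatenating columns.
  Masking and fusion commute up to the documented per-block rescaling (the
  fused sub-block is scaled by the pre-mask norm).

## Decompositions

- **PCA**: column mean-centring then SVD; eigenvalues λᵢ = sᵢ²/(n−1),
  per-component EV = λᵢ/Σλ. Centring is recorded in the output metadata.
  Scree selection returns the index before the largest relative eigenvalue
  drop among the first min(10, n−1), with the full table for manual
  override and a flat-scree warning.
- **NMF**: `sklearn.decomposition.NMF` (coordinate descent, random
  initialisation) under this package's restart-and-select policy: 20
  restarts by default, seeds derived from one root seed, and the run with
  the highest explained variance 1 − ‖X−WH‖²_F/‖X‖²_F wins (the
  factorisation is rotationally ambiguous, so single runs are unreliable).
  Tolerance 1e−6, max 500 iterations. Inputs must be non-negative; the
  pipeline clips negative cells (possible after background handling) to
  zero with a logged count before calling NMF, keeping the solution
  physically interpretable. Components are energy-ordered with unit-norm
  loading rows. EV is computed against the raw (uncentred) matrix; PCA's
  EV is against the centred one, so the two are not directly comparable
  and the convention is recorded.
- **JADE-ICA** (hand-written; no installed package provides JADE): whiten
  by PCA to p dimensions, build the parallel set of fourth-order cumulant
  matrices, jointly diagonalise by Jacobi rotations (rotation threshold
  1e−9, ≤ 100 sweeps). Components are ordered by |excess kurtosis| and
  sign-fixed like PCA loadings; the whitened scatter is the identity by
  construction. Near-Gaussian data (all |kurtosis| < 0.1) trigger an
  unidentifiability warning but still return components. sklearn's FastICA
  serves as an independent cross-check in the tests, never as the
  implementation.
- **ComDim/CCSWA** (hand-written): blocks scaled to unit Frobenius norm,
  cross-products W_k = X_k X_kᵀ; per dimension, initialise all saliences
  λ_k = 1 and iterate q ← dominant eigenvector of Σ_k λ_k W_k,
  λ_k ← qᵀ W_k q until ‖Δq‖ < 1e−10 or 100 iterations; record (q, λ),
  deflate X_k ← (I − qqᵀ)X_k, repeat p times. Q is orthonormal
  (deflation guarantees it; a re-orthogonalisation step guards round-off),
  saliences are non-negative because W_k is PSD, and exhaustive deflation
  conserves trace(W_k). Per-block EV is the salience sum over the
  unit-norm trace. With `inner_method="ica"` the dominant-eigenvector step
  is replaced by the leading (max-|kurtosis|) JADE component of the
  salience-weighted concatenation [√λ₁X₁ | √λ₂X₂ | …], falling back to the
  eigenvector when the deflated data are rank-deficient. How an ICA inner
  step should interleave with deflation is genuinely open; this is one
  defensible reading and is the package's contract.
- **Oblique coordinates**: for non-orthogonal factors, scores (s₁, s₂) are
  plotted at (s₁ + s₂cos α, s₂ sin α) with α the inter-axis angle of the
  two loading vectors; plot distances then equal the induced oblique-metric
  distances. Degenerate angles (0°, 180°) are rejected.
- **Loading signatures**: net baseline-subtracted integrals of each
  component's loading over named peak windows, per colour sub-spectrum,
  each window column normalised by its largest absolute value across
  components — the table behind spider (radar) diagrams.

## Silhouette evaluation

For labelled points with Euclidean distances, aᵢ is the mean distance to
co-cluster members (0 for singletons) and bᵢ the mean distance to **all**
points outside the cluster; sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ), with sᵢ = 0 when
both are 0. This all-outsiders bᵢ differs from the classical
nearest-other-cluster definition; a `classical` flag restores the textbook
version (cross-checked against scikit-learn) but is off by default. The
summary statistic averages per-cluster means over clusters ("macro",
default) or points ("micro") — a bare sum of per-cluster means would leave
the documented [−1, 1] range, so the macro mean is the only consistent
reading; both variants are always computed. Silhouettes are scanned over
all C(p, 2) component planes (ties broken toward the lexicographically
smallest pair) and over arbitrary subspaces; values are reported as
100·Sil in percent. Confidence ellipses scale the mean-centred covariance
by the χ²₂ quantile at the requested level, with a degenerate-covariance
flag and line-segment fallback.

## Pipeline

`run_pipeline` executes generate → filter/average/normalise → mask →
chain → assemble → fuse → decompose → evaluate over the full grid of
methods (PCA, NMF, ComDim-PCA, ComDim-ICA) × datasets (LIBS, Raman,
LIBS+Raman) × masking strata (raw, shortened), 24 report rows by default.
PCA of the fused block is SUM-PCA; ComDim on the fused dataset uses the two
blocks separately (that is its point). Cluster-label schemes are explicit
config because the discrimination task differs per dataset: Calanoida vs
Euphausiacea (25 samples) for LIBS and fused data, merged Crustacea vs
arrow worms vs snails for Raman; the mixed sample never enters a
silhouette. ComDim "total EV" is the trace-weighted mean of per-block EVs.
All randomness flows from one root seed through fixed-purpose
`SeedSequence` children (generation, NMF restarts, ICA), so stages are
independently reproducible and a rerun is byte-identical. The Li-masking
experiment reruns the pipeline with additional Li-line masks
(610.4/670.8 ± 0.5 nm) and reports signed silhouette deltas, probing
whether the copepod separation survives without the Li signal (it does;
Ca/Sr emission carries it).

## Problem sizes and numerical choices

Unit tests run the full study geometry on reduced grids (1,500-point LIBS,
600-point Raman); study-scale checks (fused 29 × 45,228 geometry, design
counts, the 50-seed modality-ordering study) use the full default design.
The 50-seed study uses PCA only, which carries the ordering claim. Key
tolerances: PCA orthonormality and reconstruction 1e−8; ComDim convergence
1e−10; silhouette oracle agreement 1e−12; NMF tolerance 1e−6. Tie-breaks
and sign conventions are stated per operation above; all are deterministic.

## Known limitations

- Template intensities, noise scales and jitter magnitudes are plausible
  but invented; absolute silhouette or EV values on synthetic data carry no
  information about real organisms — only the directional comparisons do.
- The generator renders independent Gaussian noise per pixel; real
  detectors have correlated baselines, wavelength-dependent response, and
  cosmic-ray artefacts, none of which are modelled.
- The ComDim-ICA inner step is one reading of an under-specified
  algorithm; its saliences agree with ComDim-PCA on symmetric inputs but
  can differ on strongly non-Gaussian structure.
- The all-outsiders silhouette grows optimistic as the number of clusters
  increases; with the 2–3 cluster schemes used here the effect is mild,
  but values are not comparable to classical silhouettes at larger k.
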