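# Methods

`traitconn` implements a seed-based resting-state functional connectivity
(RSFC) analysis relating five-factor (NEO domain) personality scores to
whole-brain connectivity of small spherical seed regions, together with a
synthetic BOLD cohort generator whose ground truth makes every stage of the
analysis testable. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## The analysis model

**Per-run preprocessing.** Each 4D run passes through a fixed stage order:
outlier despiking → temporal band-pass (0.009–0.1 Hz, ideal Fourier-bin mask,
inclusive edges) → polynomial detrending (linear + quadratic) → spatial
Gaussian smoothing (FWHM 6 mm) → grand-mean intensity normalization to
10,000 → voxelwise OLS regression on nine nuisance signals (global, white
matter, CSF means and six motion parameters) plus an intercept. The three
temporal stages operate on demeaned series and the voxelwise temporal mean is
restored before the spatial stages; without this the detrended grand mean is
zero and mean-based normalization is undefined. Runs whose maximum head
displacement — Euclidean norm of the translation parameters relative to the
first volume — reaches 3 mm are excluded before preprocessing (strict
inequality retains; rotations are not included in the displacement norm,
the most common reading of a translation-based criterion).

Despiking uses a quadratic running fit and robust SD (1.4826·MAD); residuals
beyond `c1` = 2.5 robust SDs are compressed by the smooth saturating map
`s → c1 + (c2−c1)·tanh((s−c1)/(c2−c1))`, bounded by `c2` = 4. The map is
continuous and monotone, so despiking never reorders in-range samples.

**Seed connectivity.** Seeds are 8 mm-diameter spheres voxelized by
voxel-centre distance with an inclusive boundary. The seed-mean time series
is correlated with every in-brain voxel; correlation maps are Fisher
r-to-z transformed (`z = atanh(r)`, |r| clamped at 1−1e-7) and averaged over
a subject's retained runs. Zero-variance voxels produce undefined
correlations that propagate as missing values.

**Group inference.** Per seed, subject z-maps are fit voxelwise by OLS on an
intercept, the five demeaned trait scores as simultaneous covariates, age,
sex, and the demeaned number of retained scans. When scan count is constant
(single-run designs) that covariate is structurally empty and is omitted.
Separate single-trait models are also fit for concordance checks. t statistics
are converted to Z by exact probability-integral mapping. The intercept
contrast (both signs) gives the group-mean positive/negative connectivity
maps; each trait contrast (both signs) gives the personality-association
maps. Voxels missing for some subjects are dropped complete-case and counted.

**Cluster-extent correction.** Maps are thresholded at Z > 2.3 per sign,
labelled with 26-connectivity, and assigned Gaussian-random-field corrected
p-values via the expected-cluster-count approximation
`p = 1 − exp(−E[m]·P(S ≥ k))`, with `E[m]` from the 3D Euler-characteristic
density (Worsley et al. 1992) and the extent tail
`P(S ≥ k) = exp(−β·k^(2/3))`, `β = (Γ(5/2)/E[n])^(2/3)` (Friston et al.
1994). Smoothness enters as per-axis FWHM estimated from the variance of
spatial first differences of the standardized residuals (for a Gaussian
autocorrelation, lag-one neighbour correlation ρ gives
`FWHM = d·√(−2 ln 2 / ln ρ)`), converted to resels. Clusters with corrected
p ≥ 0.05 are removed. Known limitation: the extent tail is heavier than the
empirical cluster-size distribution at Z = 2.3, so single-sign inference runs
conservative (measured ≈ 0.025 at nominal 0.05); because the pipeline tests
both signs on every map, the deployed two-sided family achieves ≈ 0.045.

**Valence sorting and conjunction.** Significant trait-association voxels
are labelled by the valence of group-mean connectivity at that voxel:
`invariant_pos` / `invariant_neg` if inside the corrected positive/negative
group-mean masks, `variable` otherwise. Conjunction maps binarize the
per-domain association maps (union over seeds) and sum them voxelwise; the
top level counts voxels common to all five domains. Local peaks are strict
26-neighbourhood maxima filtered greedily by descending Z with a 20 mm
minimum separation (the separation default is this package's choice).

**Confirmatory statistics.** For every significant connection (cluster), the
per-subject mean z inside the cluster is paired with the domain score.
Split-half verification randomly splits the sample into equal halves and
confirms the relationship iff both halves' Pearson correlations share the
full-sample sign. The permutation test shuffles scores against strengths
(5000 pairings) and reports the empirical tail fraction of null correlations
at least as extreme as the observed one, in the *pre-specified* direction of
the primary-analysis effect, floored at 1/(n_perm+1). An observed r at the
97.5th percentile of its null therefore has p = 0.025 exactly. The direction
must be a priori: with a data-dependent direction, null p-values concentrate
on (0, 0.5) and are no longer uniform. Raw per-connection p-values are
reported without multiplicity correction — these are confirmations of
already-corrected primary findings, not a discovery analysis. Kendall's W
(mid-rank ties, standard tie correction) measures concordance between the
simultaneous- and separate-model Z maps over in-mask voxels of the
unthresholded maps; thresholded maps would make W degenerate.

## The synthetic cohort

The generator emulates a 39-subject cohort with 1–5 runs each (197 volumes,
TR = 2 s) on a desk-scale grid (24×28×24 at 4 mm; all geometry configurable).
Trait scores are multivariate normal with means (78, 119, 128, 125, 122) and
SDs (28, 20, 21, 15, 22) on the raw NEO domain scale, identity correlation
by default (near-orthogonal domains); age is uniform on 19–45 years and sex
Bernoulli with 18/39 male fraction. Masks are geometric: an ellipsoidal
brain, a mid-radius "white matter" shell and a central "CSF" blob at 0.9
probability — stand-ins whose only role is to drive nuisance extraction.

Each seed owns a unit-variance latent network signal, band-limited to the
analysis pass-band. A planted effect couples a target sphere to its seed's
latent signal with per-subject coupling

    c = baseline + Σ_d slope_d · (score_d − mean_d),

realized as `y = c·u + √(1−c²)·ε` so the population seed–target correlation
equals `c` exactly. Effects are declared `invariant_pos`/`invariant_neg`
(strong signed baseline, mirroring consistently positive/negative
connections) or `variable` (baseline ≈ 0). Signal is planted on the target
dilated by a 4 mm halo so the evaluated core region is insulated from
smoothing-induced edge dilution. On top of the network structure every run
receives removable nuisance: low-frequency drift (below the pass-band),
a global fluctuation, WM/CSF signals weighted by tissue probability, and a
motion-locked artifact that is a linear combination of the motion parameters
(hence removable by the nine-regressor nuisance model). A configurable
fraction of runs after each subject's first receives a > 3 mm motion
excursion plus an intensity blip, exercising the QC-exclusion path without
ever emptying a subject's run list.

Observation noise is AR(1)-colored (φ = 0.4) but restricted to the analysis
pass-band at generation. This is deliberate: with broadband noise the
band-pass stage removes out-of-band noise power and inflates every recovered
correlation by a configuration-dependent factor, destroying the planted
coupling as a testable estimand. Out-of-band and shared structure still
enters through the nuisance processes, so the band-pass, detrend and
nuisance-regression stages retain real work. What the generator does *not*
emulate: hemodynamic response dynamics, spatially structured noise
(voxel noise is independent), susceptibility artifacts, registration error,
non-stationary smoothness and real anatomy. Passing tests therefore
demonstrate correctness of the estimation chain under the stated model, not
robustness to the full messiness of acquired fMRI data.

One emergent artifact is faithfully reproduced: because the global-signal
regressor contains a share of the planted network signals, global-signal
regression induces small, distributed negative couplings whose strength
co-varies with trait score — the well-known anticorrelation artifact of
global signal regression. The default study's confirmation report shows
these as diffuse negative connections alongside the planted positives.

## Benchmark problem sizes and expectations

- **Slope recovery** uses a single-run 39-subject variant on an 18×20×18
  grid with smoothing disabled. Smoothing intentionally trades amplitude
  bias for variance: with a regionally shared signal and voxel-independent
  noise it inflates correlations by a kernel-dependent factor (≈ 3× on the
  default grid), so recovery against planted truth is only well-posed
  unsmoothed. Default slopes give coupling SD ≈ 0.17 across subjects
  (per-voxel association Z ≈ 5 at n = 39); the residual atanh nonlinearity
  contributes ≈ +3% slope bias and the global-regression artifact a small
  negative bias, leaving replicate-mean recovery well within ±10%.
- **FWE calibration** simulates 500 null Gaussian fields on a 24³ grid at
  known FWHM 8 mm = 2 voxels (the canonical lower bound for lattice validity
  of random-field theory), exercising the correction exactly as deployed —
  both signs per map.
- **Map-level checks** (concordance, valence, conjunction) share one full
  default study (≈ 110 runs). Confirmation permutations are reduced to
  1000 pairings there; the permutation-rule checks themselves use the full
  5000.

## Numerical choices

- Fisher transform clamps |r| at 1−1e-7; correlations of zero-variance
  series are NaN and excluded voxelwise at the group level.
- Sphere membership is inclusive at the boundary; voxel indices are 0-based
  and internal, all external coordinates are MNI mm via the NIfTI affine.
- Permutation p-values are floored at 1/(n_perm+1), never exactly 0; the
  empirical-distribution-function rule (no interpolation between order
  statistics) keeps the 97.5th-percentile example exact.
- Smoothness estimation clamps the neighbour correlation to (1e-6, 1−1e-6);
  unsmoothed white noise therefore maps to a sub-voxel FWHM rather than an
  error.
- The full study is deterministic given the config RNG seed: each run's
  generator is keyed by (seed, CRC32 of subject id, run index), and each
  confirmatory test derives its own stream from the config seed and the
  connection index.
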