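# Methods

## The measurement model

A 3D-MINFLUX/DNA-PAINT experiment on blade-tip-tagged PIEZO1 exports a
table of localizations: `tid, x_nm, y_nm, z_nm, cfr, efo, t_s`. One `tid`
(trace ID) covers the localizations of one transient imager-binding event;
the same protomer is revisited by many traces. `cfr` (center frequency
ratio) and `efo` (effective frequency at offset, kHz) are per-localization
quality metrics whose high values indicate distorted or multi-emitter
events. The pipeline reduces this table to per-trimer interblade distances
in five stages (quality filter → trace filter/trim → z × 0.7 → trace
centers → DBSCAN merge → trimer rules); stage order matters and is fixed.

### Filter semantics and tie-breaks

* cfr and efo keep values **≤** the cutoff; the cfr cutoff is 0.8. The efo
  cutoff is unspecified by convention in the field, so the default is the
  dataset's 95th percentile (an upper cut against multi-emitter
  contamination); an absolute kHz value can be configured, and the cutoff
  actually used is logged in the run report.
* The per-axis trace SD rule excludes a trace when **any** single axis
  exceeds 10 nm (strict `>`, sample SD with n−1); ties at exactly 10 nm are
  kept. Traces with fewer than 3 localizations are excluded before
  trimming, so a 3-localization trace retains one localization after the
  2-point head trim and survives.
* z scaling (×0.7, refractive-index mismatch) is applied after trimming;
  scaling and center-of-mass commute, so the order is consequence-free (a
  test asserts this).
* Trimer rules: pairwise distances strictly `< 40 nm`; a non-member site
  strictly `< 60 nm` from **any** member disqualifies the triple; maximum
  internal angle strictly `< 120°`. Distances and angles are computed in 3D
  on z-corrected coordinates — the 40 nm bound derives from the 3D geometry
  of the flattened structure. The bivariate Gaussian fit of a protomer's
  raw localizations uses the 2D in-plane projection and serves for
  visualization and as an alternative position estimate (ML mean equals the
  arithmetic mean; singular covariances are ridge-regularized and flagged).
* DBSCAN `min_points` counts the point itself: `min_points=2` means "self
  plus ≥ 1 neighbor", which makes the clustering identical to the connected
  components of the 8 nm proximity graph (other implementations differ in
  this convention — documented because it changes singleton handling).
  Singleton centers are kept as single-trace protomer sites: a protomer
  detected once is still a protomer.
* Pose contacts use inclusive `≤ 3.5 Å`; hydrogens participate when present
  in the file (heavy-atom-only behind a flag).

### Statistics

Cohorts are summarized as mean ± SEM (unbiased SD). Two-group comparisons
are gated: both groups are tested with the D'Agostino–Pearson omnibus test
at α = 0.05 (configurable); if both pass, a two-sided unpaired Student's
t-test (classic equal-variance form; Welch behind a flag), otherwise a
two-sided Mann–Whitney U. Groups below n = 8 cannot run the gate and fall
back to Mann–Whitney with a warning. No multiple-testing adjustment is
applied. Simulation (2000 Normal-null pairs at n = 100/group) places the
gated procedure's type-I error within [0.03, 0.07].

## Functional-assay fits

* **Threshold** — first stimulus whose peak |deviation| from the pooled
  pre-stimulus baseline exceeds 6 baseline SDs; a zero baseline SD
  (noiseless synthetic input) falls back to an absolute floor (default
  1 pA, flagged).
* **Inactivation** — `C1 + C2·exp(−(t−t0)/τ)` by nonlinear least squares
  with `t0` fixed at the fit-window start; freeing t0 is degenerate with
  C2, which is why it is pinned. Cell-level τ is the equal-weight mean over
  converged sweeps whose |peak| lies in [100, 1500] pA. Flat traces (or
  fits collapsing to C2 ≈ 0) are flagged degenerate and excluded.
* **Pressure response** — per-sweep baseline-subtracted peak magnitude over
  the 500 ms stimulus, normalized by the cell's global maximum, fitted with
  `I_max_norm / (1 + exp((P−P50)/k))`. The saturating amplitude is free
  because normalization divides by the largest *sampled* response, which
  undershoots the true plateau whenever the curve is not saturated in
  range; with it free, the noiseless round-trip is exact. P50 is reported
  on the sampled (negative) pressure axis with an unsigned `p50_magnitude`
  convenience, since sign conventions vary between labs.
* **Peak/sustained** — peak over the mean of the final 10% of the stimulus
  window (both baseline-subtracted; window half-open so the offset sample
  is excluded). "Sustained" has no standard definition; the 10% tail is the
  package's choice and is configurable. Near-zero sustained currents give a
  capped, flagged ratio.
* **Single-channel** — each 1 s segment's sample histogram is modelled as a
  two-component Gaussian mixture initialized at the two modes of a
  Freedman–Diaconis histogram; amplitude = |Δ means|. Segments whose minor
  component weight is < 2% or whose mean separation is < 2 pooled SDs are
  flagged "no event" (unimodal histogram). The signed amplitude (open −
  closed, closed = heavier component) feeds the OLS I/V fit; the slope in
  pA/mV × 1000 is the conductance in pS.
* **Calcium** — F/F0 with F0 the mean over a 10 s control window; the
  per-cell maximum is taken within the drug-perfusion window only (washout
  excluded — the package's reading of an otherwise ambiguous convention).
  EC50 comes from a four-parameter logistic in log10 concentration fitted
  to per-concentration means; an EC50 outside the sampled range raises an
  extrapolation flag.

All fits are scale-consistent: scaling currents leaves τ, P50, threshold
and peak/sustained unchanged and scales amplitudes/conductance linearly.

## The synthetic-data generator

`synthgen` emulates the *valid-localization* level of a MINFLUX export — no
photophysics, photon budgets or iteration-level simulation. Per trimer: an
in-plane equilateral triangle whose side is drawn from
Normal(`interblade_mean`, `interblade_sd`) truncated to (0, 40] nm
(40 nm = physical bound of the fully flattened channel), randomly rotated,
given a Normal z-plane offset, with each vertex displaced by an isotropic
3D linkage error; ground truth records the post-linkage fluorophore
positions (the best any microscope could recover) and their mean pairwise
distance. Labelled protomers (Bernoulli `label_efficiency`) emit
Poisson-many traces (floor 1) of Poisson-many localizations (floor 3, so
the minimum-size filter path stays exercised) with per-axis Gaussian
precision noise. Emitted z is pre-divided by 0.7 so the pipeline's z
correction is exercised rather than bypassed. Contaminated traces
(`multi_emitter_fraction`) draw cfr strictly above 0.8 and efo from a high
regime, making filter efficacy measurable against ground truth; background
traces are uniform in the field. Timestamps are sequential (only ordering
is used downstream). Identical config + seed gives bit-identical tables.

Default study conditions (one 3 × 3 µm ROI): interblade 21.7 ± 5.5 nm,
localization σ 2 nm/axis, linkage σ 1.5 nm/axis (≈ 2.5 nm mean 3D linkage
error), z-plane σ 5 nm, labeling efficiency 0.9, 3 traces/label,
8 locs/trace, 10% multi-emitter traces, 1 background trace/µm². Labeling
efficiency and background density are free experimental parameters with no
published reference values; these defaults are the package's
one-time choice of a realistic regime. Trimer centroids sit on a jittered
150 nm grid so trimers cannot violate each other's isolation rule by
construction (background traces still can, as in a real sample).

The ephys/calcium generators put noise where the corresponding fit consumes
it (per-sweep peak amplitude for pressure sweeps, per-sample for decays and
single-channel traces, per-cell for dose-response), and the pose generator
places one ligand atom 2 Å from each planned contact residue on a 10 Å
residue grid, so planned contact fractions are reproduced exactly.

## What the synthetic benchmarks do and do not show

They establish that the implementation is faithful: zero-noise inputs
round-trip to < 1e-9 nm, the clustering and trimer search agree with
brute-force oracles, every fit recovers its generator's parameters, and
recovery stays within stated tolerances under 10% noise. They do **not**
establish performance on real samples, where drift residuals, anisotropic
z precision, nanobody-binding heterogeneity, partial fixation artifacts and
non-Gaussian backgrounds are all absent from the generator.

One emergent property of the method worth knowing: trimers whose true side
length approaches the 8 nm DBSCAN merge scale lose protomer resolution and
drop out of the accepted sample. This truncates the low tail of the
recovered distance distribution, biasing condition means upward by a few
tenths of a nanometre — more strongly for more-curved populations — and
slightly compressing recovered between-condition shifts (≈ 2.0 nm recovered
for a 2.2 nm true shift under default conditions). This is a property of
the measurement rules themselves, not of the simulation, and applies
equally to real data analyzed with the same rules.

## Problem sizes

The test suite and acceptance script use 150 generated trimers per
condition (≈ 100 accepted triple-labelled trimers, matching the scale at
which such experiments are typically powered), 100-seed repetitions for
noisy-recovery checks, 2000 simulations for the type-I calibration and 200
random site sets for the oracle-equivalence sweeps; these sizes make every
statistical check stable while keeping a full run in tens of seconds.

## Known limitations

* No drift correction, fiducial registration or multi-color handling; the
  input is assumed stabilized.
* Only triple-labelled trimers are quantified; no rescue of double-labelled
  channels or inference of missing protomers.
* The MATLAB-export reader is out of scope; the canonical input is the CSV
  dialect documented in `locfilter`.
* Docking itself (pocket detection, pose generation, scoring) is upstream;
  only the downstream contact quantification is implemented.
* The trimer search enumerates triangles of the pair graph; on pathological
  inputs that are globally dense at the 40 nm scale it degrades toward
  O(n³), which is irrelevant at realistic site densities.
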