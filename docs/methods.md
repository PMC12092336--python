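# Methods

This note documents the models, conventions, and design choices behind
`mapse3d`: what the measurement pipeline assumes, what the synthetic
generator does and does not emulate, and where numerical or boundary
conventions had to be fixed.

## Measurement model

A detection stream is the contract between an upstream landmark detector and
this package: for every 3D volume at time `t`, a set of candidate
mitral-annulus points `(azimuth, x, y, z)` with an optional confidence, plus
the R-wave times that define the cardiac cycles and the volume rate. The
pipeline makes no assumption about how the candidates were produced, only
that azimuths are measured about the LV long axis and coordinates are in mm.

**Long axis.** When no axis is supplied it is estimated as the line through
the time-averaged annulus centroid along the first principal direction of
the centroid's displacement over time. This surrogate works because annular
motion is dominated by its longitudinal component; it degrades when
transverse motion rivals longitudinal excursion (the principal direction
then tilts toward the mixed axis). The sign convention orients the axis
apex→base so that the end-diastolic (R-wave) position is maximal; MAPSE uses
max − min, so the sign never changes the value. A stationary stream (no
centroid motion) falls back to the annulus-plane normal.

**Views and walls.** The three standardized planes sit at `lax + {0, 60,
120}`° (mod 180). The wall labels follow the standard midesophageal layout —
LAX transects anteroseptal/inferolateral, 4C inferoseptal/anterolateral, 2C
anterior/inferior — with the LAX azimuth itself an acquisition convention
read from stream metadata (default 0°). Each wall collects the candidates in
a ±15° azimuth arc (inclusive edges, circular) and represents them by their
centre of mass.

**Artifact filtering.** Three rules, in order:

1. *Candidate neighbour rule* (default scope): a candidate farther than
   5 mm from the median position of the other candidates concurrently
   detected in its arc is rejected before aggregation. The median makes the
   reference robust when the arc itself contains an artifact; candidates
   with no concurrent arc companion are exempt. A wall-level variant
   (distance to the nearest concurrently detected *wall point*) is available
   via `FilterConfig(neighbour_scope="wall")`, but note that on an annulus of
   ~15 mm radius adjacent wall landmarks are ~15 mm apart, so the wall-level
   rule at 5 mm would reject everything; it is only meaningful with a
   correspondingly larger threshold.
2. *Jump rule*: an aggregated wall point that moved more than 5 mm
   (strictly) from its valid detection in the immediately preceding volume
   is rejected. If the preceding volume holds no valid sample the rule is
   inapplicable: genuine annular motion accumulated across a detection gap
   (which can exceed 5 mm within a few volumes) must not be mistaken for a
   jump.
3. *Cycle rule*: a cycle `[R_i, R_{i+1})` (half-open; partial cycles at the
   stream edges are not counted) is discarded when fewer than 60 % of its
   volumes carry a valid detection. The threshold is inclusive: exactly 60 %
   is retained, matching "discard below 60 %".

Boundary conventions throughout: exclusion thresholds are strict
(`> 5 mm` rejects, exactly 5.0 mm is retained); the retention threshold is
inclusive (`≥ 60 %`).

**Per-cycle MAPSE** is the global max − min of the rotation-corrected
longitudinal position over the cycle's valid samples (at least two
required), i.e. the excursion between the highest and lowest annular
positions — the same extremum definition used for manual measurement. An
ECG-phase-anchored alternative (end-diastole to end-systole) was considered
and not used, to keep the automatic and manual definitions identical.

**Recording MAPSE** is the unweighted mean of all feasible (wall, cycle)
sub-measurements. A recording is feasible when at least one wall in one
cycle survives; an artifact-saturated stream yields `feasible=False` rather
than an error.

## Synthetic annulus motion

The generator replaces both the detector front-end and the patient: it
emulates hands-free single-beat full-volume 3D acquisition (defaults:
19.4 volumes/s, heart rate 75/min, 10 cycles per recording) of a tilted
planar annulus ring.

- *Geometry*: ring radius 15 mm, plane tilted 5° to the long-axis normal.
  Only the landmark behaviour matters downstream, not anatomical fidelity.
- *Longitudinal motion*: raised cosine from end-diastole to end-systole,
  `w(φ) = (1 − cos 2πφ)/2`, single extremum exactly at mid-cycle, analytic
  amplitude — so every test knows the true excursion. The excursion field is
  piecewise-constant per 60° wall sector, so the arc centre of mass carries
  the wall's exact amplitude. Default per-wall amplitudes (4.6–8.7 mm,
  septal < lateral) reflect a postoperative cohort.
- *Non-longitudinal motion*: transverse translation (2 mm) and rigid
  in-plane rotation (3°) follow a sine waveform, L2-orthogonal to the
  raised cosine over a cycle; this keeps the PCA axis surrogate unbiased
  (axis recovered within 1° on noise-free streams) while still exercising
  rotation correction.
- *ECG*: R-times are exact cycle boundaries; cycles are `[R, next R)`.
- *Noise*: isotropic Gaussian per candidate (default SD 0.5 mm).
- *Dropout*: Bernoulli per (wall, volume) — the landmark detector failing
  for that wall in that volume, all five of the arc's candidates dropping
  together. Temporally independent; real dropout is often correlated with
  probe dislocation, a documented simplification.
- *Outliers*: Bernoulli per candidate; displacement of fixed magnitude
  (default 15 mm) in a uniformly random 3D direction, labelled in the
  ground-truth sidecar so filter tests have unambiguous targets.
- *Determinism*: one seed; all sub-generators draw from spawned child
  streams, so e.g. switching outliers off leaves the noise realization
  untouched (paired runs differ only in the artifacts).

**Outlier aliasing.** A displacement whose magnitude is close to an
inter-wall chord distance (≈15, 26, or 30 mm here) can land an artifact on a
*neighbouring* wall's position. Such a point is geometrically
indistinguishable from a genuine detection; at the 15 mm default about 5 %
of injected outliers survive the filters this way, while shifting the
recording MAPSE by ≲0.02 mm. The ≥99 % catch-rate property therefore holds
for magnitudes well clear of the aliasing band (tested at 40 mm); at
annulus-scale magnitudes the meaningful guarantee is the end-to-end one
(≤0.1 mm effect on the measurement), which holds at the defaults.

**What passing tests do not show.** The generator has no speckle, no
image-quality gradients, no respiratory or probe-dislocation drift, no
arrhythmia (cycles are identical in length), and detector errors are
unbiased — so the pipeline's accuracy here does not bound its accuracy on
real detections with systematic bias, and feasibility percentages on
synthetic data are not predictions of clinical feasibility.

## Test-retest and agreement statistics

The linked-replicates model treats replicate r of both methods as taken
under the same conditions (a shared replicate effect `a_ir`, e.g.
hemodynamic drift between triplicate recordings), with a method×subject
interaction `c_mi` and method-specific residuals. Estimation is by method of
moments on the balanced linked layout: between/within-subject mean squares
of the per-replicate differences give the bias, the interaction variance
(`(MSB−MSW)/n₀`, truncated at zero) and `SD(diff)`; the within-subject mean
squares of each method and of the per-replicate differences jointly separate
the shared replicate variance from the two residual variances. Closed-form
and auditable against hand-computed sums of squares — the reason it was
chosen over a likelihood fit. A REML alternative is deliberately not
offered: general mixed-model machinery pools the residual across methods,
which would silently change the per-method residual SDs that the LSC — the
headline precision statistic — is built from.

The bias standard error uses the between-subject mean square of the
differences (`SE² = MSB/N`), which is calibrated whether or not an
interaction is present; with 50 subjects the normal-multiplier 95 % interval
covers at ~95 %.

Limits of agreement use the fixed 1.96 normal multiplier (not t-adjusted),
so `loa = bias ± 1.96·SD(diff)` and the interval is symmetric about the bias
by construction — enforced as an invariant of `AgreementResult`.

The test-retest generator defaults are calibrated to a postoperative MAPSE
setting: population 5.2 ± 1.7 mm, triplicates, method offset −1.4 mm,
residual SDs 0.41/0.23 mm (backed out of single-measurement LSCs of 1.6 and
0.9 mm), linked replicate SD 0.5 mm, no interaction by default
(`interaction_sd=0`; the field exists for recovery tests of `c_mi`).

Other conventions: Spearman p-values use the t approximation for n > 10 and
exact permutation enumeration below (chunked, conditional on observed
midranks); correlation inputs use pairwise-complete deletion; the
correlation comparison is descriptive only (ordering by |rho|), with no
inferential test between coefficients. The single-beat Ees uses the
published normalized-elastance constants (7th-degree polynomial in the
pre-ejection/total-systole time ratio plus the EF/pressure-ratio
regression), transcription-tested against an independent evaluation.

## Numerical and problem-size choices

- Azimuth arithmetic is circular with inclusive arc edges; the smallest
  signed angular difference is used throughout.
- Temporal discretization bound used in tests: sampling a raised cosine of
  amplitude A at n volumes per cycle can miss each extremum by at most half
  a sample interval, so the measured excursion lies within
  `A·(1 − cos(π/n))` of A; a 0.2 mm margin covers the second-order coupling
  of ring tilt with rotation/translation.
- Variance components are truncated at zero; degenerate inputs (zero-noise
  tables) yield exact zeros, not NaNs.
- Simulation sizes in the test suite — single recordings of 160 volumes,
  replicate tables of 50–5000 subjects, 200-table recovery batches — were
  chosen so Monte-Carlo tolerances (3 standard errors) are decisive while
  the whole suite runs in seconds on one CPU.
- Reported precision is mm with one decimal where results mirror printed
  tables; internal computation is double precision throughout.

## Known limitations

- The long-axis surrogate assumes longitudinal dominance of annular motion;
  supply the axis explicitly when that fails.
- The wall-level neighbour filter is retained only as a configuration
  option and is degenerate at the default 5 mm threshold (see above).
- The linked-replicates fit supports exactly two methods and requires a
  linked, (near-)balanced design; unlinked or single-replicate tables are
  rejected with the violated assumption named.
- `Ees` validity is flagged, not guaranteed: extreme inputs can drive the
  normalized-elastance intermediate non-positive, marking the result
  invalid.
- No voxel/image I/O, no detector: the package starts at the landmark
  contract and ends at measurements and statistics.
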