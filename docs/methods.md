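# Methods

This note records the models implemented in `rtimagerisk`, the conventions
chosen where several were defensible, what the synthetic phantoms do and do
not emulate, and the package's known limitations.

## Dose accumulation

All dose arithmetic happens on dose grids in the DICOM patient coordinate
system (mm), indexed `(z, y, x)`, axis-aligned (identity direction
cosines). The course-total dose is

```
total = treatment + (MU / MU_ref) * imaging_per_fraction * n_fractions
```

where the per-fraction imaging RTDOSE was computed at a reference monitor
unit setting `MU_ref` (default 5 MU) and imaging dose is assumed **linear
in MU**. This linearity is the documented approximation that lets a single
per-fraction grid serve both the 5 MU and 10 MU protocols; if per-protocol
grids are available they can be supplied directly instead (run each
protocol with its own manifest). An *imaging-only* mode zeroes the
treatment term, isolating the imaging contribution — the analogue of
zeroing the therapeutic beams in a planning system. Grids on different
lattices are brought together by trilinear interpolation at target voxel
centres (exact for constant and trilinear fields; 0 Gy outside the source
extent). Default site fraction counts are 25 (breast), 28 (pelvic) and
35 (head & neck).

## Contours to masks

A closed planar contour is assigned to the dose-grid slice whose z-centre
is nearest, with tolerance half a slice spacing; contours farther than that
are dropped. A voxel belongs to an ROI iff its **centre** lies inside the
contour polygon, decided by an even-odd (crossing-parity) rule so that
nested contours on one slice carve holes; points within 1e-9 mm of an edge
count as inside. Centre sampling with binary masks matches common
TPS-engine practice, ignores partial-volume effects, and is exactly
testable against an independent point-in-polygon oracle (the test suite
checks equality with `shapely` on random convex polygons). ROI nomenclature
is standardized through a user-supplied `name_map`; ROIs mapping to one
canonical name are merged, unmapped ROIs keep their raw names.

## DVH and mean dose

The differential DVH bins masked voxel doses into left-closed, right-open
bins of width 0.01 Gy (configurable), **centred on integer multiples of
the bin width** so the midpoints are 0, 0.01, 0.02, … Gy. Centred bins make
an unirradiated organ contribute dose exactly 0 to the midpoint sums and
halve the worst-case quadrature bias relative to edges anchored at 0. With
the default width, the bin-midpoint error on OED and gEUD is below
0.005 Gy. Mean dose is reported **voxel-exactly** (arithmetic average over
masked voxels), not through the DVH; the DVH-based mean is only used where
a DVH is the sole input and its error is bounded by half a bin width.

## Risk models

* **Logistic NTCP** (on mean dose): `NTCP = 1/(1 + exp(gamma*(D50 - D)))`,
  evaluated through the numerically stable sigmoid so extreme slopes
  neither overflow nor lose monotonicity. `gamma` is the slope in 1/Gy as
  the formula is written; published tables usually give the normalized
  slope `gamma50`, converted as `gamma = 4*gamma50/D50`.
* **LKB NTCP** (on gEUD): `Phi((gEUD - D50)/(m*D50))` with
  `gEUD = (sum v_i D_i^(1/n))^n` over DVH bin midpoints. Which model an
  organ uses is set per organ in the registry.
* **OED**: `sum_i v_i D_i exp(-alpha' D_i)` over bin midpoints, the
  linear-exponential (cell-sterilization) mechanism with a single default
  `alpha' = 0.085 Gy^-1` for all organs. The plateau and bell-shaped
  variants of the mechanism are out of scope. OED is bounded above by the
  mean dose for `alpha' >= 0` and is non-increasing in `alpha'` — both are
  enforced as property tests.
* **EAR**: `EAR0 * OED * mu(e, a)` in excess cases per 10 000 person-years,
  with `mu(e,a) = exp(gamma_e*(e - e0)) * (a/a0)^gamma_a`, `e0 = 30`,
  `a0 = 70`. Attained age is fixed at 70 by default; for patients already
  older than that, EAR is evaluated at attained age = exposure age + 1 so
  the modifier stays in its valid domain (`e < a`). A photon gray is
  treated as one sievert (`gy_to_sv = 1.0`, configurable). Only the
  absolute-risk (EAR) pathway is implemented; no relative-risk model, no
  fractionation/LQ correction of the DVH, and no formal uncertainty
  propagation — a one-parameter sensitivity sweep is provided instead.

## Parameter registry

Organ parameters are loaded from a JSON registry in which **every record
carries a literature citation**; the shipped defaults cover breast, lung,
heart, rectum, bladder, bowel, parotid, spinal cord, brainstem and optic
nerve. They are explicitly labelled stand-ins assembled from the standard
NTCP literature (Emami/Burman, QUANTEC) and BEIR VII / Schneider-style EAR
coefficients, intended to be replaced by institutional values: a user file
passed to `load_parameter_registry` merges over the defaults organ by
organ. All default `gamma_e` are negative, so EAR decreases with age at
exposure for every organ — the qualitative age gradient the cohort
analysis stratifies on. The registry also carries the canonical
ROI-name → organ mapping used by the pipeline.

## Cohort statistics

Each metric (mean dose, NTCP in %, EAR) is compared between the two
imaging protocols with a two-tailed **paired** t-test per ROI, at
significance level 0.05, reported as mean ± SD per protocol. Raw p-values
are reported without multiple-testing correction (noted in the run
manifest). When the paired differences have (numerically) zero variance —
identical protocols, or shared dosimetry — the t statistic is undefined;
the comparison is flagged `degenerate_variance` with p = 1.0 for all-zero
differences and p = 0.0 for a constant nonzero shift, rather than failing
the run. Age strata are `< 40`, `40–60`, `> 60` with ages 40 and 60 falling
in the middle group (the inclusive reading of "40–60"); empty strata appear
with count 0 and null summaries.

## Synthetic phantoms

The generator exists so the entire pipeline is exercisable and testable
without clinical data. Each phantom is a 64³ lattice at 2.5 mm isotropic
spacing (160 mm extent) — small enough for seconds-scale patients while
keeping organs tens of voxels across; realism is deliberately sacrificed
for oracle-testability. Organs are spheres, ellipsoids and z-axis
cylinders, contoured as 48-vertex polygons per slice. The treatment field
is an isotropic sigmoid falloff from a target centre plus a low
exponential out-of-field tail (a head-leakage/scatter surrogate), which
gives per-ROI mean doses semi-analytic expectations; the three site
templates are calibrated so course-total means land at clinically typical
magnitudes (ipsilateral lung ≈ 19–21 Gy in breast courses, rectum
≈ 47–49 Gy in pelvic courses, parotids ≈ 25–27 Gy in head & neck courses),
verified by a ≥ 95 % in-range property test. The per-fraction imaging field
is spatially broad with a mild (±7.5 %) anterior–posterior gradient at
0.006 Gy/MU at isocentre — 3 cGy per 5 MU fraction, in the
several-cGy-per-fraction range of MV-CBCT; arc directionality of the
acquisition (gantry 260°→100°, stored as protocol metadata) is **not**
modelled, since the pipeline consumes dose grids, not beam geometry.
Per-patient variation is a ~8 % relative SD dose-scale jitter, a 2 mm SD
target offset, and mirrored anatomy for right-sided breast cases. Ages are
sampled uniformly within strata ([18,40), [40,60], (60,85]) from a
0.3/0.4/0.3 mixture; all randomness flows from per-patient substreams of
one seed, and DICOM UIDs/dates are deterministic functions of it, so
regeneration is byte-identical.

What passing tests on these phantoms shows: the plumbing (DICOM round
trips, rasterization, accumulation), the model algebra, the statistical
machinery, and directional/structural conclusions (MU linearity, dose →
risk monotonicity at imaging dose levels, inverse age gradient). What it
does not show: anatomical realism, heterogeneity corrections, registration
error, or the numerical values any real cohort would produce — those depend
on institution-specific plans and the registry parameters chosen.

## Problem sizes

The default test suite runs cohorts of 1–10 phantoms per site; the
reproduction script (`scripts/acceptance.py`) uses the study-scale cohort
sizes of 30 breast, 17 pelvic and 20 head & neck patients, which completes
in a few minutes on one CPU.

## Known limitations

* No dose computation from machine parameters, no image registration, no
  CBCT reconstruction: inputs are RTDOSE/RTSTRUCT already on a common
  planning frame.
* Only axis-aligned grids are supported.
* Mean-dose NTCP ignores volume effects for logistic-model organs;
  LKB/gEUD is available per organ where volume effects matter.
* OED is non-monotone in dose above `1/alpha' ≈ 11.8 Gy` by design (cell
  sterilization); pipeline-monotonicity guarantees therefore apply to the
  imaging-only dose range.
* Registry defaults are cited stand-ins, not a vetted clinical parameter
  set; conclusions at the level of absolute NTCP/EAR values require
  institutional parameters.
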