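# Methods

## Plate geometry and coordinates

The plate offers roots a 200 × 100 mm window imaged from the back; shoots
grow through three 5 mm holes spaced 29 mm apart on the top edge, the middle
hole at half the plate width. Image row 0 is the top of the root window,
depth increases downward, and the agar surface row is depth 0; all exported
traits are in cm and cm². The pixel calibration `px_per_mm` is a required
config input and is never auto-detected (plate images carry no fiducials the
package could rely on). The bulk default is 4 px/mm — enough for whole
experiments in seconds — while verification suites use 8 px/mm, closer to
the resolution of the platform's root camera.

## The simulator

`synth_plate` is a discrete-day polyline extension model, deliberately not a
mechanistic L-system: it exists to produce controllable root systems with
exact ground truth, not to explain growth.

- Each root is a 2-D polyline extended at its tip in 1 mm arc steps. Per
  step the heading receives Normal(0, `tortuosity_sd`) degrees of noise and
  a deterministic pull of `gravitropic_bend_per_mm` degrees toward vertical.
  Growth stops at the plate boundary, which is what makes ambient primaries
  plateau at the 20 cm window depth near day 20.
- First-order laterals initiate at hard-core-Poisson positions along the
  primary (minimum gap 2.5 mm plus an exponential with mean 10/density):
  lateral priming has a refractory zone, and a pure Poisson process would
  put a fifth of the gaps below the imaging resolution, making count
  recovery physically impossible for any analyzer. A lateral emerges a fixed
  whole-day delay after the parent tip passes its position plus a 5 mm
  elongation-zone exclusion, so every visible root has grown ≥ 1 full day
  (≥ 3 mm at the default rates). Second-order laterals follow the same rules
  along first-order laterals.
- Emergence angles are Normal(55°, 10°) truncated to (0°, 90°], drawn to a
  random side. The weak default gravitropic bend (0.4°/mm) keeps laterals on
  an oblique set-point course, as Arabidopsis laterals are; a strong bend
  turns every lateral vertical and physically fuses neighbours in the
  projection.
- Treatments act as multiplicative factors on the rates. Defaults encode
  bacterial growth stimulation (×1.25–1.5 on elongation, ×1.3 on initiation),
  heat inhibition (×0.35–0.6, strongest on laterals, plus a smaller
  branching angle), and partial rescue in the heat-plus-inoculation cell.
  The default design is n = 12/15/12/8 plants for ambient-control,
  ambient-inoculated, heat-control and heat-inoculated, imaged at days
  5, 7, 9, 12, 14, 16, 19 and 21 after inoculation.
- All randomness derives from per-root seed sequences keyed by
  (seed, plant, root lineage): trajectories are bit-reproducible and a
  plant's day-9 snapshot strictly extends its day-7 snapshot, which is what
  the time-series appending tests rely on.
- Rendering: root polylines are rasterized at a configurable stroke width on
  a 0.1 background with 1.0 foreground, plus Gaussian pixel noise, written
  as 16-bit gray (SNR = 0.9 / noise sd; the default 0.1 gives SNR 9, suites
  use 0.18 for SNR 5). Rosettes are green ellipses (hue 95–135°, saturation
  0.55–0.9, value 0.35–0.8) around a filled centre on a dark collar
  background, with small plant-coloured and bluish distractor specks below
  the cluster-filter limits; the returned true area is the exact rendered
  plant pixel count.

What the simulator does *not* emulate: root diameter variation and width
information (all strokes are one width), root hairs, 3-D depth cues,
illumination gradients, condensation artifacts, and agar autofluorescence.
Passing the recovery suites therefore demonstrates the geometry pipeline is
correct and well calibrated on resolvable systems — not that segmentation of
real, optically messy plates would reach the same accuracy.

## Shoot segmentation

Per-pixel HSV box thresholds (hue in degrees, saturation/value in [0, 1]),
defaults at the platform's published operating point: hue 21–222°,
sat ≥ 0.11, val ≥ 0.17, with val ≥ 0.08 on imaging days 19 and 21; upper
bounds at the channel maximum. Cleanup converts plant components (8-connected)
of size ≤ 95 px to background, then background components (4-connected) of
size ≤ 24 px to plant, with 502/473 on the late days, in that order. The
size rule is implemented as a small-cluster cleanup — components *at or
below* the limit are converted — because the literal "exceeding the limit
are converted" reading deletes the rosette itself; that literal reading
remains available behind `strict_exceeding`. Projected leaf area is the
plant pixel count over `px_per_mm²`. The optional chromatic-aberration
filter desaturates high-chroma pixels within 2 px of strong value-channel
edges; it is off by default since synthetic images have no optics.

## Root pipeline

1. **Binarize**: threshold at median + 2.5 × 1.4826 · MAD of the frame.
   Roots occupy well under 1% of a backlit frame, a regime where
   variance-based thresholds (Otsu) latch onto background noise; Otsu and
   fixed thresholds remain available. Speckles below 8 px are dropped,
   holes below 8 px filled.
2. **Skeleton graph**: `skimage` skeletonization, pixel chains traced
   between endpoints and junctions (redundant diagonal links removed),
   junction clusters within 3 px merged, spurs shorter than 1.5 mm pruned
   (SNR-5 boundary noise creates spurs up to ~1.3 mm), pass-through nodes
   contracted. Edge length is the Euclidean arc length of a moving-average
   smoothed chain (window ≈ 1 mm): raw 8-connected chain codes overestimate
   oblique lines by up to ~8%, the smoothed polyline is accurate to well
   under 1%. Tips are extended along their end tangent by the local mask
   radius − ½ px (the rounded cap the skeleton erodes); lateral branch ends
   get the same recovery capped at 1.5 px, and no recovery at single-pixel
   strokes where the skeleton is the stroke itself. Each connected component
   attaches to the nearest hole within 5 mm at the surface row; unattached
   components are debris, and when several components claim a hole the
   largest is kept.
3. **Order classification**: at every junction, edge ends are greedily
   paired by continuation turn (< 45°), so each root continues straight
   through a crossing; a shared stretch with shallow unpaired ends at both
   junctions (two roots tangentially merged) is duplicated as a pass-through
   strand so both roots keep their length, as in reality. The tree is then
   grown from the base hole respecting pairings. The primary root is the
   base-to-tip path reaching deepest (ties: longest, then straightest);
   subtrees off it are 1st-order laterals, each following its straightest
   continuation (longest only when every child turns sharply); branches off
   a lateral's path are 2nd-order, and anything deeper merges into the 2nd
   order. Branch-offs turning less than 25° continue their root rather than
   starting a new one (true emergence angles are 35–85°), and lateral roots
   shorter than 1.5 mm with no children fold back into their parent —
   both rules absorb crossing remnants that would otherwise create phantom
   laterals.
4. **Traits**: per-type lengths are edge-length sums (total = primary +
   lat1 + lat2 exactly); depth is the deepest root pixel, width the
   horizontal pixel extent, hull area the convex hull of all centreline
   points (0 for fewer than 3 non-collinear points). The branching angle is
   the mean over 1st-order junctions of the angle between the parent tangent
   continuing past the junction and the lateral tangent, both estimated over
   a 2 mm window after skipping 3 junction-distorted pixels; a
   vertical-reference variant is available. Plants without laterals report
   the angle as missing, never 0.
5. **Depth profile**: each edge's smoothed polyline is split exactly at the
   1-cm layer interfaces into 20 half-open bins [k, k+1) cm. Because
   profiles and totals read the same polylines, per-type layer sums equal
   per-type totals to rounding.

## Time series and growth rates

`append_timepoint` analyses the next day's mask de novo, then tests the
asymmetric containment roots imply: the fraction of the previous skeleton's
pixels within 3 px of the next skeleton must reach 0.8, otherwise a
tracking error (wrong plate, flipped image) is raised with the overlap
score. Each previous lateral is matched to the next-day lateral that best
contains it (≥ 0.5 of its pixels) and keeps its identity; unmatched new
laterals get fresh identities. Growth rates are per-interval finite
differences assigned to the interval's end day — so rate curves have points
at 7, 9, …, 21 under the default schedule — and sum exactly back to the
total length change. Negative rates beyond 0.05 cm/day are flagged as
suspect rather than clipped.

## Statistics

The per-day comparison is the classical equal-variance two-tailed Student
t-test of inoculated vs control within a temperature (Welch via a flag),
reported with group means ± standard errors. The factorial analysis is a
fixed-effects two-way ANOVA with interaction (type-II sums of squares);
the whole-period variant adds the imaging day as an additive fixed block — a
deliberate simplification, not a repeated-measures model, and documented as
such. Relative treatment effects are 100 × (treated − control)/control,
undefined for non-positive control means. Trendlines: y = a·e^(bx) by least
squares on log y with R² on the log scale, and quadratic OLS with R² on the
original scale; for data with no spread R² is 0 by convention. No
multiple-testing correction is applied by default (raw p < 0.05 is the
decision rule); Benjamini–Hochberg adjustment is provided as an option.

## Verification suites and their scope

The acceptance tests validate the pipeline against simulator truth at two
operating points, 30 plants each: a noise-free single-pixel suite at day 9
(pure arc-length fidelity: primary, 1st-order and total lengths within 1%,
no phantom 2nd-order roots) and an SNR-5, 3-px-stroke suite at the day-12
imaging point at 8 px/mm (per-type cohort lengths within 5%, both lateral
counts exact in ≥ 90% of plants). Length agreement is asserted on cohort
totals: single young roots are a dozen pixels long, where one ±0.2 mm
digitization error already exceeds the per-root percentage bounds.

Known limitations, all consequences of 2-D projection imaging rather than
implementation choices: a lateral that runs within a stroke width of another
root fuses with it — the strand-duplication rule recovers pass-through
merges but a root merged up to its tip is unrecoverable and its length is
credited to the host root (at 4 px/mm this occurs roughly once per 30
mid-experiment plants; at 8 px/mm it is rare). Order misattribution at dense
crossings can shift length between the 1st- and 2nd-order classes while
total and count stay correct. On full plates late in the experiment,
neighbouring plants' root mats can fuse into one component, which the
hole-attribution rule gives entirely to one plant; the full-experiment
checks therefore assert runtime and bit-reproducibility, not per-plant
accuracy, at those late time points.
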