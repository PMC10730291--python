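# Methods

This note documents the models, algorithms and numerical choices behind
`floracue`, and what its synthetic-data tests do and do not establish
about real spectra.

## Marker points

A *marker point* is the midpoint wavelength of a rapid change in a
reflectance spectrum: a change of at least `threshold` percentage points
of reflectance (relative to a white Lambertian standard) occurring within
a window narrower than `max_span` = 50 nm. Thresholds are absolute
percentage points, not relative change — spectra are expressed in percent
of the standard's reflectance, and the conventional salient-flower
threshold of 20 points is defined in those units. The working thresholds
are 5 points for natural background materials (rocks, minerals, dry plant
matter, green leaves) and 20 points for flower petals; 5 is the empirical
calibration that gives backgrounds roughly the same mean number of
markers per sample as the 20-point threshold gives flowers
(`threshold_calibration` reproduces this calibration on any pool).

Detection pipeline, on the canonical 1 nm grid over 300–700 nm:

1. **Smoothing.** Centred moving average, default window 21 points. Near
   the spectrum ends the window truncates symmetrically (no padding), so
   the boundary values are less smoothed — a property to keep in mind
   when interpreting markers within ~10 nm of 300 or 700 nm.
2. **Segmentation at confirmed extrema.** Classic delta/lookahead peak
   detection: a running extremum candidate is confirmed once the curve
   departs from it by `min_delta` (default `threshold/4`) in the opposing
   direction, provided no better candidate appears within the next
   `lookahead` = 5 points at confirmation time. The departure may occur
   at any distance, which is what makes broad smooth features (a leaf's
   ~550 nm green peak) segmentable at all; requiring the departure within
   the lookahead distance would censor every peak wider than a few nm.
   The first and last grid points are appended as virtual extrema so
   boundary transitions are scanned.
3. **One marker per monotone segment.** Within each segment between
   consecutive extrema, the shortest window with |ΔR| ≥ threshold and
   width < 50 nm qualifies the segment (ties broken toward the larger
   change, then the shorter wavelength). The qualifying window is then
   extended outward while reflectance keeps changing strictly in the same
   direction, so the emitted marker describes the full base-to-peak
   transition. Its wavelength is the half-height crossing
   (R(λ1)+R(λ2))/2 of the extended window, linearly interpolated between
   grid points; magnitude is the extended |ΔR| and span the extended
   width. One marker per segment prevents a single physical transition
   from being counted twice; conversely, two same-direction steps with no
   confirmed turning point between them merge into one marker.

Because the half-height level is set by the transition endpoints,
additive noise of sd *s* at the endpoints shifts the crossing by roughly
*s*/(√2·slope). For a 30-point step ~20 nm wide this means ~1.4 nm of
position noise at *s* = 3: marker positions are honest to a couple of
nm under realistic noise, not to fractions of a nm.

## Simulated natural backgrounds

A simulated background is one plausible visual scene behind a flower,
assembled from the pool of natural material samples in two stages:

1. draw 65 samples per background class (green leaf, dry material,
   rock/mineral) uniformly **without** replacement — 65 because the green
   leaf class, the smallest stratum in the field collection, caps the
   stratum size;
2. draw 195 (= 3 × 65) members **with** replacement from that subset, so
   one background can contain duplicates and unequal class mix.

The number of with-replacement draws is not uniquely determined by the
source description; 195 (the subset size) is the natural choice and
reproduces the reported scale of ~200 markers per background given ~1
marker per sample. It is exposed as `background_size`.

Markers of all drawn members are pooled per background and accumulated
into 5 nm bins (left-edge labels 300, 305, …, 695; a marker at 426.11 nm
belongs to the 425 bin; 700.0 exactly joins the last bin). The bin width
follows hue-discrimination limits of bee and bird vision: pollinators
cannot reliably distinguish stimuli within ~5 nm. The default
100 000 iterations are cheap (seconds); tests and the acceptance script
use 1 000–20 000, which leaves Monte-Carlo error in the reported median
below one marker. Each iteration consumes an RNG sub-stream spawned from
the root seed by index, so results are reproducible and independent of
evaluation order. The aggregate density weights every marker equally
(not every iteration equally); with a fixed background size the two
weightings only differ through per-iteration count variation.

## Multimodality statistics

**Dip test.** The dip statistic D of a sample is the smallest sup-norm
distance between its empirical CDF and any unimodal CDF; 1/(2n) ≤ D ≤
0.25, with the supremum approached by two equal distant point masses.
It is computed exactly with the greatest-convex-minorant /
least-concave-majorant sweep; the test suite verifies the implementation
to 1e-9 against an independent linear-programming minimax oracle.
P-values use the uniform(0, 1) bootstrap null (default B = 2000): the
proportion of uniform samples of the same size whose dip reaches the
observed one. The uniform is the asymptotically least favourable
unimodal null, making this the standard, table-free calibration.

**Critical bandwidth.** For Gaussian kernels the number of KDE modes is
non-increasing in the bandwidth, so the smallest h whose KDE has at most
k modes is found by bisection. The bracket is refined to
min(0.01 nm, 0.5 % of h); the relative term guarantees that 0.99·h sits
strictly below the true critical point, i.e. the returned bandwidth is a
certified bracket endpoint. Mode counting evaluates the KDE on a grid of
spacing min(h/5, 1 nm) extended 4h beyond the data, with plateau-merging
when consecutive grid densities tie exactly. Weighted samples (bin
centres + counts) are supported throughout so the pooled simulation
output need not be expanded.

**Mode location.** Density maxima at the critical bandwidth for the
chosen k, refined by a parabolic fit through the three neighbouring grid
points. At the critical bandwidth the density is maximally smoothed, so
located modes carry a few nm of sampling noise and a slight inward pull
when components are close — positions are meaningful at the 5 nm scale
of the analysis bins, not sub-nm. No boundary correction is applied at
300/700 nm; modes within ~one bandwidth of the interval ends (the red
edge near 700) are therefore slightly biased inward.

**Mode count selection.** A Silverman-type bootstrap sequence: for
k = 1, 2, … compute h_k, draw smooth-bootstrap samples from the KDE at
h_k (resample, add N(0, h_k²) noise, rescale to preserve the sample
variance), and report the fraction whose KDE at h_k shows more than k
modes; the first k not rejected at α = 0.05 is selected. Per-dataset
mode counts can also be fixed by the user, which the pipeline and
acceptance script use when reporting mode positions under stable keys.

**Cumulative comparisons.** `cumulative_left_fraction` is the strictly-
less-than fraction of marker mass below a reference wavelength; default
references are 500 nm (an illustrative centre line) and 531 nm (the main
simulated-background mode in the motivating analysis). For binned input
the reference should sit on a bin edge so bins count wholly.

**Pooled-background dip.** The pooled marker multiset of a large
simulation holds millions of values; the bootstrap dip test is instead
run on a fixed-size subsample (default 5 000) drawn from the binned
distribution. At that n the test's power is saturated; the subsample
size only matters through the p-value's bootstrap resolution.

## Synthetic spectra generator

The generator exists so every stage is testable without the field data.
Each class template is a smooth baseline plus planted logistic steps
(half-height at the centre, 10–90 % rise within `width`) plus correlated
Gaussian noise, clipped at zero. Noise is smooth (Gaussian-filtered
white noise, ~20 nm correlation length, generated on a padded grid so
its variance is stationary across 300–700 nm): a real spectrophotometer's
optical averaging does not produce point-to-point white noise, and white
noise would fragment every monotone segment. Steps carry presence
probabilities and centre/amplitude jitter; every realised step is
returned as ground truth.

Default templates (centres in nm, presence in parentheses): green leaf —
low UV/blue base with a gentle 550 nm bump, rise at 524 (.55), fall at
580 (.5), red-edge rise at 690 (.45); dry material — slight monotone
tilt, rises at 431 (.65) and 617 (.65); rock/mineral — flat-to-tilted
bases of widely varying brightness, sparse rises at 329/421/558 (.25
each); insect-pollinated flowers — large steps at 404 (.65), 513 (.45),
654 (.15); bird-pollinated flowers — steps at 439 (.30) and 606 (.42).
Small sub-threshold troughs sit between candidate step positions,
mimicking the local dips of real spectra and keeping co-occurring
same-direction steps in separate monotone segments. Presence rates were
chosen so per-class markers-per-sample means and the flower cumulative
fractions around 500 nm sit near the field collection's reported
summaries; default class sizes are the field collection's (65 green
leaves, 96 dry, 346 rocks, 153 insect- and 68 bird-pollinated flowers).

What the generator does *not* emulate: the long tail of jagged mineral
spectra with many markers per sample (so simulated per-background marker
counts are less dispersed than in the field data, and the 95 % interval
of the marker-count distribution is correspondingly narrower); pigment
physics (no radiative transfer); instrument artefacts beyond smooth
noise. Passing tests therefore certify the algorithms and the pipeline's
statistical behaviour under controlled truth, not ecological conclusions
about real backgrounds.

## Problem sizes and determinism

Tests run the simulation at 500–2 000 iterations and bootstraps at
50–500 replicates; the acceptance script uses 20 000 iterations and
B = 2000 dip bootstraps — sizes at which every reported quantity's
Monte-Carlo error is far below its scientific resolution. All
randomness descends from a single seed through `numpy` `SeedSequence`
spawning; identical configuration and seed give bit-identical reports
across process restarts.

## Known limitations

- The cited marker-point software's exact midpoint and direction
  conventions are not published; this package's conventions (documented
  above) coincide for symmetric steps but may differ by a few nm on
  asymmetric transitions.
- One marker per monotone segment merges double steps that lack a
  confirmed turning point between them (a double-stepped quartz rise is
  reported once unless a dip separates the steps).
- KDE mode positions at the critical bandwidth are biased inward near
  the 300/700 nm boundaries and between close components.
- The dip statistic floors at 1/(2n) for distinct values; an all-equal
  sample returns 0 by convention.
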