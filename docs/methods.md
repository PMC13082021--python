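# Methods

This note documents the models behind `ciliabase`, the parameters that
matter, and the numerical choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

All geometry is in nanometres; the only Å surface is structure mapping
(`StructureMap`, Cα coordinates, cross-link distances), matching the
convention of coordinate files and cross-linker chemistry. Residue
numbering is 1-based author numbering throughout. Particle orientations are
proper rotation matrices whose third column is the local filament tangent
(the subtomogram-averaging convention of Z along the filament); the STAR
dialect stores them as ZYZ Euler angles in degrees and guarantees
matrix-level round-tripping — at zero tilt the rot/psi split is degenerate
and only their sum is preserved, which is all the convention promises.
Profiles and diameter bins use half-open intervals `[start, start + bin)`.

## Synthetic ciliary barrel

`CiliumModel` places `n_filaments` (default 9) straight generatrices at
equally spaced azimuths on a barrel whose radius follows an ordered zone
model. The default zones are (name, length nm, diameter nm):

| zone | length | diameter |
|------|--------|----------|
| P (proximal centriole) | 205 | 215 |
| C (core centriole)     | 230 | 197 |
| B (boundary / distal-ring region) | 30 | 190 |
| TZ (transition zone)   | 253 | 169 |
| AX (early axoneme)     | 300 | 178 |

P/C/TZ lengths and all diameters are the measured means for this system;
the boundary region's length is not reported anywhere, so its default is
30 nm (roughly four 8 nm tubulin repeats), and the simulated early-axoneme
stretch defaults to 300 nm — both free, configurable parameters, not
estimates. The stepwise radius profile is smoothed with a 20 nm boxcar
(quadrature on a fixed 33-point stencil, so it is deterministic) because
real barrels taper continuously; a consequence is that the 30 nm B zone is
shorter than twice the smoothing window and never reaches its plateau
diameter, so B is excluded from the 2 nm diameter-recovery tolerance that
the four printed zones meet.

Particles sit every `step` (default 4 nm) of axial arc from 0 to the total
zone length inclusive, giving `floor(total/step) + 1` per filament.
Labels: each particle carries its true zone and an observed label flipped
with probability `label_noise` to a uniformly chosen *different* zone —
the simplest worst case for voting, with no structured confusion. Positions
get isotropic Gaussian jitter. All randomness flows from one
`SeedSequence(seed)` with per-filament substreams, so outputs are
bit-reproducible regardless of iteration order; the same scheme is used
per-row in the necklace generator and per-engine in the cross-link
generator.

The default *study conditions* used by the recovery tests are 20% label
noise and 1 nm jitter. The raw class-assignment noise level of real 3D
classification is not reported; 20% is a deliberately harsh free parameter,
not an estimate.

## Filament geometry

**Spline resampling.** A natural cubic spline through the control points,
parameterized by chord length and reparameterized by arc length via
trapezoid integration on a progressively refined grid (total length stable
to 1e-3 nm). Particles at `s = 0, step, 2·step, …`; tangents from the
spline derivative; the in-plane angle is drawn from a seeded uniform
distribution per particle. Natural end conditions were chosen over
not-a-knot for reproducibility on short traces (they degrade gracefully to
quadratic/linear behavior at 3/2 control points).

**Distance cleaning** is a greedy first-come-kept pass in stored order: a
particle survives iff it is ≥ `min_dist` (default 8 nm) from every
already-kept particle. This is deterministic, order-stable, idempotent, and
matches the semantics of list "cleaning" (the original order is the
priority). The exact algorithm used by the upstream tooling is unpublished;
greedy-in-order is the declared choice here.

**Half-sets** are split at the midpoint of each filament: particles below
the median arc rank go to half A (an odd count gives the extra particle to
A), producing contiguous halves with |#A − #B| ≤ 1 per filament, so
overlapping neighbor particles never straddle the two halves.

**Barrel axis and diameters.** The axis is a running centroid: the
principal direction of all positions defines the axial coordinate, and
overlapping 40 nm windows (centers every 20 nm) are averaged into a
polyline; particle radial distance is measured perpendicular to the locally
interpolated axis. Axial coordinates are snapped to 1e-6 nm before
windowing so that numerically identical layers of exactly symmetric
synthetic data cannot be split by a window boundary. Diameter is defined as
**2 × mean axis-to-particle-center distance** — whether the printed
diameters of the real system are center-based or wall-based is not stated,
and this choice is the one consistent with particle picks. Zone means
average bin diameters by the bin's majority class label. Zone length is
`s_last − s_first + step`, so a single-particle zone has length one step.

## Zone classification

Voting is an iterated **synchronous** majority vote (all particles update
from the same previous state, for determinism): each particle takes the
modal label among neighbors within ±24 nm of arc on its own filament
(≈13 particles at 4 nm oversampling), or its k = 15 nearest 3D neighbors in
the optional cross-filament mode; itself included. Ties keep the current
label, which guarantees fixed points exist; iteration stops at a fixed
point or 50 sweeps. The published description names both "nearest
neighbors" and a "sliding window", so both modes exist with the 1D window
as default; neither the window, k, nor the iteration count is published —
these defaults are declared choices.

Boundary-adjacent particles are genuinely ambiguous under uniform label
flips (the window sees both zones), so voting recovers ~98–99% of labels
overall but ≥ 99.5% away from boundaries; the residual disagreement is
boundary jitter of a particle or two, which is why boundary positions are
the quantity with a stated tolerance (8 nm, two steps) rather than raw
label accuracy.

The spatial-order constraint is a separate dynamic program (so each pass is
testable in isolation): per filament, segment the sequence into at most
|ordering| contiguous segments in the prescribed proximal→distal order,
mandatory zones non-empty, optional zones skippable (the short boundary
zone is optional by default — whether it may vanish on some filaments is
unstated), minimizing the number of relabeled particles. On ties the DP
prefers staying in the current zone, pushing boundaries distally — a fixed,
documented tie-break. Its cost equals exhaustive enumeration on small
instances (property-tested).

## Membrane lattice

**Cylinder fit**: least squares on radial residuals `rᵢ − mean(r)`, with
the axis initialized from the principal directions (largest-variance for
elongated tubes, smallest for flat patches; the better refinement wins) and
refined over direction and center; radius in closed form as the mean radial
distance. For **quasi-planar clouds** — axial span < 0.2 × mean in-plane
radius, e.g. a single necklace ring — radial residuals constrain axis tilt
only to second order and free refinement tilts the axis to fit noise, so
the direction is fixed to the best-fit plane normal and only the center is
refined. Degenerate (collinear/coincident, or < 6 points) input raises.

**Unrolling** maps each point to `u` (axial) and `v = R·θ` wrapped to
`[0, 2πR)`; this is an isometry for on-surface points and exactly
invertible (`FlatMap.to_3d`). Rows are maxima of a Gaussian KDE over `u`
(default bandwidth 4 nm ≈ a quarter of the 17.5 nm pitch, evaluated on a
0.5 nm grid); maxima closer than 2 × bandwidth are merged
(density-weighted), since a KDE cannot resolve modes below that separation
— the same limit means rows at < 8 nm pitch merge, a documented failure
mode. The real measurement was line-profile analysis on membranogram
images; this module operates on picked coordinates instead, the
quantitative content of those images.

**Spacing** pools, per row, the sorted-`v` neighbor gaps plus the
wrap-around gap (rows are closed rings, so k particles give exactly k
gaps); whether the published pooling included wrap-around gaps is unstated
and this choice is documented here. The pooled mean ± SD is the primary
statistic; under particle dropout a missing pick merges two gaps into one
double-width gap and biases the mean upward, so a robust `lattice_spacing`
(median of pooled gaps) is reported alongside and used for recovery under
dropout. Stoichiometry is mean per-row particle count ÷ 9 doublets.

## XL/MS interactome

Per-engine tables are filtered at their CSM-FDR cutoffs (defaults 1% and
5%, the conventional settings of the two search engines for this
cross-linker), canonicalized (case-fold, strip `-N` isoform suffixes,
order the two sides lexicographically), and de-duplicated per residue pair
keeping the best score. **Consensus** is exact residue-pair identity
(unique cross-links are counted at amino-acid level; a protein-pair-level
option exists). No additional link-level FDR is computed beyond the
per-engine thresholds.

Network statistics: unique links = distinct residue pairs; proteins =
distinct ids on either side; PPIs = distinct unordered pairs of *distinct*
proteins (homotypic pairs excluded by default, with an inclusive option,
since the published convention is unstated). Restraint mapping: a link is
*mapped* iff both residues resolve in the coordinate model — which is why
the mapped denominator is much smaller than the interactome; distance is
Cα–Cα (the standard practice for this linker), minimized over chain-copy
combinations for ambiguous homo-oligomer residues; with zero mapped links
the satisfied fraction is `None`, never 0.

The paired-search simulator plants true links uniformly among residue pairs
within the 35 Å cutoff and decoys beyond it (pairs with intra-chain
sequence separation < 3 are excluded from both pools as uninformative);
each engine reports true links and decoys with independent Bernoulli
probabilities. Two independent engines at detection 0.9/0.8 give an
expected consensus recall of 0.72 and near-unit precision — both verified
by seeded simulation in the tests.

## U-ExM metrics

EF is the mean of per-measurement `width / reference` ratios (identical to
mean-width/reference for a fixed reference; per-measurement EFs are kept
for spread reporting), with the 250 nm axoneme width as the reference.
The transition-zone length is the distance between the end of the
basal-body fluorescence support and the start of the axonemal support in
the GT335 channel, at half-maximum per channel (the published threshold
convention is unstated; half-maximum is the declared default,
configurable), with sub-sample edge placement by linear interpolation of
the threshold crossing, divided by EF. The profile generator plants
rectangular pulses on the expanded scale with the gap specified on the
corrected scale; recovery is exact to within one sampling step.

## What the generators do and do not emulate

The generators reproduce the *statistical* structure the estimators
consume: zone-dependent barrel radii, uniform label flips, lattice
periodicity with Gaussian jitter and Bernoulli dropout, paired detection
with planted distances, rectangular fluorescence pulses. They do **not**
simulate tilt-series artifacts (missing wedge, CTF), curved or tapering
membranes beyond the smoothed barrel, structured label confusion between
adjacent classes, engine score correlation, or image-level U-ExM effects.
Passing recovery tests therefore demonstrates correctness of the estimators
under these idealized conditions, not robustness to every failure mode of
real data.

## Problem sizes

The test suite and acceptance script run at the scales the analyses target
in practice: 9 × 255 particles per barrel, 7 × 54 necklace particles,
hundreds of planted cross-links on toy structures of ≤ 500 residues. Each
acceptance computation completes in seconds on one CPU.
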