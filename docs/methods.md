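# Methods

`chapsta` is a desk-scale re-implementation of the computational workflow
used to census bacterial chaperonin complexes in cellular cryo-electron
tomograms: template matching of barrel-shaped particles under a missing
wedge, subtomogram alignment and averaging with point-group symmetry,
consensus multireference classification of conformation and substrate
occupancy, and a per-tomogram state census with condition comparisons.
Everything runs on synthetic tomograms with planted ground truth, so each
stage can be scored against what was actually simulated.

## Conventions

Volumes are `(z, y, x)` arrays with an isotropic voxel size in Angstrom;
the beam axis is z and the single tilt axis is y. Orientations are
intrinsic ZYZ Euler triples in degrees describing the reference-to-
particle transform; a subtomogram is modelled as
`apply_transform(reference, euler, shift)` plus noise, with the missing
wedge fixed in the subtomogram frame. Rotations resample trilinearly
about the voxel at `floor(N/2)`, filling out-of-domain samples with the
volume mean (phantom rasterization fills with zero instead to avoid
box-edge artefacts). Particle tables use 0-based voxel coordinates with
the origin at array index (0, 0, 0).

## Missing wedge and constrained correlation

A `+-theta_max` single-axis tilt series samples the Fourier voxels whose
angle from the (kx, ky) plane, measured in the plane perpendicular to
the tilt axis, is within `theta_max` (default 60 degrees, 3 degrees of
cosine apodization). The constrained cross-correlation of two volumes
restricts both to the product of their wedge masks, zero-means and
unit-norms them under a real-space mask (mask-weighted moments), and
maximizes the plain circular correlation over integer shifts; by
Cauchy-Schwarz the score lies in [-1, 1]. The same quantity is computed
by a brute-force direct-space oracle in the test suite to 1e-6.

The original study delegated matching to an external package whose exact
"noise correlation" normalization is not published; the definition above
is this package's own and all internal consumers (alignment,
classification, template matching) use it consistently.

## Phantoms

The generator rasterizes smooth-edged analytic densities (6 A cosine
edges):

* a double ring of outer radius 70 A, 73 A per ring, cavity radius
  22.5 A, with a sevenfold azimuthal modulation (`sin(7*phi)`, amplitude
  0.15 — the sine phase keeps the y axis a genuine two-fold axis of the
  double ring, which a cosine phase would break for an odd rotational
  order);
* open ring ends carry a constant-bore apical opening over the outer
  24 A of the ring: diameter 45 A for the narrow conformation (equal to
  the cavity, i.e. a straight wall) and 65 A for the wide one, so the
  half-max rule recovers the nominal diameter irrespective of the exact
  measurement slab;
* GroES lids are half-ellipsoid shells (lateral semi-axis 40.5 A, height
  30 A) seated on capped ring ends;
* ordered substrate is a 3D Gaussian of sigma 10 A and amplitude ~1.1x
  the wall, centred 20 A below the chamber midplane ("bottom of the
  chamber" = toward the equator); disordered substrate carries the same
  integrated mass at 4x the width with a +-10 A uniform per-instance
  jitter, so it blurs to invisibility under averaging;
* narrow trans rings always carry an apical substrate blob on the axis
  (10 A below the rim), wide rings never do — the state space couples
  conformation and trans-side binding;
* ribosome-like distractors are 120 A-radius spheres with a fixed
  deterministic surface and radial texture;
* free GroEL gets one wide and one narrow end (intrinsic inter-ring
  asymmetry).

Mixtures are applied by exact largest-remainder quota so planted
proportions are constants. SNR is defined as the variance of the
wedge-filtered signal inside its own support over the white-noise
variance; noise is added after wedge filtering so the wedge region is
noise-filled, as in real reconstructions. Signal and noise use separate
RNG streams derived from one seed, so a noise-free rerun reproduces the
identical signal content. Condition presets encode the species splits
observed in cells (bullet:football 60:40 at 37 C, 70:30 under heat
stress, 55:45 under substrate overexpression, 90:10 free-GroEL:bullet
under GroEL excess), a wide-conformation fraction of 0.6 (0.75 under
heat stress) and a per-chamber ordered-substrate probability of 1/3;
these sub-state defaults are package choices where only the
species-level splits are constrained.

What the phantoms do not emulate: CTF, tilt-dependent dose, molecular
crowding, membranes, gold fiducials, conformational continua, or
atomic-detail density. Passing recoveries therefore demonstrate that the
algorithms are self-consistent at realistic SNR and wedge geometry, not
that they would meet the same tolerances on real cellular data.

## Template matching

Orientation grids combine a Fibonacci-spiral direction set (count
4*(180/step)^2/pi, halved for Dn) with a uniform in-plane angle spanning
360/n for Cn/Dn; the identity is always included. Tomogram matching
computes FFT-based locally normalized correlation of the rotated,
40 A-low-passed, wedge-filtered template under a soft spherical mask at
2x binning, keeping the per-voxel maximum and argmax orientation. The
local variance is floored at 5% of the global variance so structureless
regions cannot normalize into spurious peaks. Peaks are extracted by
greedy non-maximum suppression; the automatic threshold (mean + 5 sigma,
relaxed by the overpick factor) replaces the per-tomogram visual cutoff
of the original workflow, which is not reproducible in software. Hits
from different templates are merged with the higher score winning inside
half a particle diameter.

Subtomogram stacks are matched against a rotated template bank with
wedge-constrained normalized dot products (all particles share the
tomogram-frame wedge, so the bank is filtered once); this is the stack
analogue of tomogram matching, with translation search unnecessary for
centred particles.

## Alignment and averaging

Wedge-compensated averaging rotates each subtomogram (and its wedge
mask) to the reference frame and divides the Fourier sum by the summed
wedges, floored at 1% of the maximum. Alignment does a local cone search
(candidate rotations from concentric tilts plus in-plane twists) against
the evolving, optionally symmetrized and low-passed reference, with
translation search inside the constrained correlation; the reference is
re-averaged every iteration and a pass aborts if the mean score drops
twice. The desk default searches at 2x binning only; box 48 at 7.04 A
per voxel keeps one cohort of 200-1,000 particles within minutes on one
CPU. Half-set ("gold standard") refinement splits particles by a seeded
permutation, refines both halves from a common 40 A-filtered start and
reports the resolution at FSC = 0.143 with linear interpolation across
the crossing shell (Nyquist flagged as a bound when there is none).

Quasi-symmetric barrels leave a specific failure mode: a one-lidded
bullet can settle in the 180-degree-flipped pose, and whole-particle
correlation barely penalizes it at SNR 0.3. `resolve_flips` rescores the
two pose hypotheses under a two-cap mask covering the polar lid regions,
where all of the discriminating density lives; on the development
fixtures this decides every bullet correctly at 2x binning. It is
applied after template-bank matching and before alignment.

Chamber pooling implements the C2 symmetry expansion: every football
contributes its pose and the pose composed with the in-plane flip, every
bullet its lid-bound ring, and each record is recentred along its own z
axis by half the inter-ring offset (default 73 A, the ring height, from
the phantom geometry) so the chamber of interest sits at the box centre
with GroES toward +z. Signal subtraction poses the reference times
`1 - keep_mask` into each particle frame, wedge-filters it and
subtracts.

## Classification

Raw per-particle classification of low-SNR interiors separates by
missing wedge, so class structure is discovered on wedge-compensated
averages of random particle subsets: `n_bootstrap` averages of
`bootstrap_size` particles (desk defaults 500 x 50, scaled from the
source procedure's 5,000 x 250) are clustered by k-means (k = 2,
per-voxel standardized interior features, 10 restarts) and the
per-cluster means seed the class references. Because bootstrap averages
are mixtures, the seeds separate weakly along the discriminating
direction; the subsequent MRA sharpens them.

The annealed MRA scores every particle against every class each
iteration — the wedge-constrained correlation under the classification
mask, with both sides zero-meaned and unit-normed under that mask,
evaluated as Fourier-domain matrix products so no per-pair transforms
are needed — and assigns by hill climbing, except that a random other
class is accepted with probability `exp(-dScore/T_i)`. The schedule
`T_i = temperature_factor * s_bar * (1 - i/(n_iter-1))` (temperature
factor 10, 40 iterations, `s_bar` the initial mean inter-class score
spread) decays linearly to zero, so the final iteration is pure hill
climbing; the source describes the procedure without formulas, and this
schedule is the package's own definition, equivalent to plain argmax at
temperature zero. Emptied classes are reseeded from random particles.
The whole procedure is repeated (default five times) with independent
bootstrap seeds; labels are matched across runs by exhaustive
permutation of reference-to-reference correlations *within the
classification mask* (outside it all references share the consensus
structure and correlate to ~1), and only particles classified
identically in every run are retained.

Two engine geometries serve different contrasts: interior/occupancy
classification crops the central 24^3 box at full resolution (the
chamber is only ~6 voxels across, so binning would destroy the
substrate blob), while species classification re-poses each particle so
the trans pole sits at the box centre and classifies the same cropped
view — lid presence then becomes a compact central contrast, the same
geometry that makes the occupancy split balanced. The ordered class is
identified by probing the mean density in a 10 A sphere at the expected
substrate position; the bullet class by the weaker central density in
the pole view. A 30 A Gaussian-edged low-pass acts as the denoising
stage in place of the original learned 3D denoiser.

## Census and measurements

States map deterministically onto the taxonomy (wide bullets i/ii,
narrow bullets iii/iv by cis occupancy, footballs v/vi/vii by the
unordered pair of chamber labels — which ring is which is not
distinguished). Census tables count states per (condition, tomogram)
and report both pooled particle fractions and mean per-tomogram
proportions, since relative abundances can be read either way. Condition
comparisons use the two-sided Wilcoxon rank-sum test (exact enumeration
for n <= 10 without ties, tie-corrected normal approximation otherwise),
with p values reported uncorrected and the number of comparisons logged.

The aperture diameter is measured on an average oriented with the open
apical surface toward +z: the z extent is found from background-
subtracted slice means grown contiguously around the densest slice, the
apical slab is the top 15% of that extent, and the azimuthally averaged
radial profile (quarter-voxel sampling) is scanned outward from its
innermost minimum to the first rise through half the wall maximum;
starting at the minimum makes the rule robust to the on-axis substrate
density of narrow rings. The substrate centre of mass is the intensity-
weighted centroid of voxels above half the in-mask maximum, in Angstrom
relative to the chamber centre.

## Problem sizes and numerical choices

The recovery experiments use 1,000-particle cohorts for the mixture and
occupancy targets, 200 for the aperture cohorts, and five 288 x 288 x
160-voxel tomograms (46 ribosomes + 2 chaperonins each) for the
abundance ratio — sizes at which every experiment completes in minutes
on one CPU while the recovered quantities are statistically stable.
Alignment FFTs run in single precision; wedge sums are floored at 1% of
their maximum; k-means ties and label-matching ties resolve to the
lowest index and are logged. Determinism: every workflow seeds a numpy
`SeedSequence` hierarchy from one master seed, signal and noise draw
from separate streams, and the pipeline driver derives per-stage seeds
so stages can rerun independently; reruns are bitwise identical.

## Known limitations

* Discrete trilinear rotation is not an exact group action: the
  symmetrization operator is idempotent only to ~1-3% relative RMS on
  smooth maps, and round-trip rotations lose high-frequency content.
* The desk-scale demo pipeline (`chapsta all`) keeps matched species
  labels rather than re-classifying them (its cohort of tens of
  particles is below the classification regime); the recipe workflows
  are the quantitative reference experiments.
* Aperture recovery degrades if pose errors exceed a few degrees; the
  recipes refine alignment before averaging and the measurement is only
  guaranteed to one voxel width.
* The annealing acceptance rule reproduces the cited procedure's
  behaviour only at temperature zero, where it is exact argmax; the
  intermediate schedule is this package's definition.
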