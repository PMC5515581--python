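# Methods

`spherulescope` reimplements, on synthetic data, the quantitative analysis of
viral RNA replication "spherules" imaged by cryo-electron tomography: the
~50 nm invaginations of the outer mitochondrial membrane induced by Flock
house virus (FHV), each packed with a coiled dsRNA filament and crowned at its
necked aperture by a 12-fold-symmetric protein assembly. The package covers
four analyses — subtomogram averaging of the crown, Fourier shell correlation
(FSC) resolution estimation, cyclic-symmetry detection from angular power
spectra, and spherule morphometry with a parallel-cylinder dsRNA packing
model — and a phantom generator that supplies ground-truth data so no
microscope data is required.

## Conventions

All grids are indexed `[z, y, x]` with 0-based voxels and isotropic voxel
size in nanometres. Orientations are intrinsic Z-Y-Z Euler triples in
degrees, normalized to `[0,360) x [0,180] x [0,360)`; the rotation maps
reference-frame vectors into the tomogram frame. The Z-Y-Z choice is a
declared convention (subtomogram-averaging packages differ and none is
canonical); it is recorded in every particle-table header. Volumes are
MRC2014 maps (written through gemmi); particle tables are TSV with named
columns so fixtures stay diffable.

## Phantom generator

The generator defines the study conditions; its defaults are the published
geometry, not free dials.

**Crown.** A cup-shaped turret (19 nm outer diameter, 14 nm tall, 11 nm open
axial channel) rendered as a Gaussian-profile cylindrical wall, ringed by 12
prolate Gaussian "teeth" on a 35 nm diameter ring, 3 nm proud of the
membrane and tilted 15 degrees toward the axis (the tilt is described
qualitatively in the source imaging; 15 degrees is a declared choice). An
optional cone of density sits low inside the cup. Because every component is
an analytic function of position evaluated on the grid, the map deviates
from exact C12 symmetry only by voxelization (relative RMS under a 30-degree
rotation is ~4% at 1 nm voxels).

**Spherule.** A spherical vesicle shell (membrane rendered as a 5 nm FWHM
Gaussian profile) hangs from a planar membrane through an open 11 nm neck.
The interior is filled by a discretized worm-like chain: step 1.6 nm,
bending angles drawn so direction decorrelates over the 62 nm persistence
length of dsRNA (midpoint of the published 60–64 nm range), confined to the
vesicle interior with wall bouncing, self-avoiding with a hard core of
0.8x the target spacing. Growth stops when the mean nearest-neighbor
distance between chain points — excluding same-strand pairs closer than one
persistence length of arc, the same rule the spacing estimator uses —
reaches the 6.4 nm target; a chain that jams before the target backtracks
and regrows, and a chain that can never reach the target (radius too small)
is an explicit error. Dead-end jamming is resolved by retracting a
progressively longer stretch of chain, the standard remedy for
self-avoiding growth. Across radii 18–30 nm and many seeds the realized
spacing estimate falls in 6.2–7.0 nm, inside the contracted +/-10% band.

**Corruption model.** Tomographic acquisition over a +/-60 degree tilt range
leaves a wedge of Fourier space unsampled. The forward model applies a
binary missing-wedge mask (tilt axis y; a frequency is sampled when its
(f_x, f_z) direction lies within the tilt range; a half-range >= 90 degrees
means nothing is missing) followed by additive white Gaussian noise scaled
so that signal variance inside the structural support over noise variance
equals the requested SNR. The default SNR of 0.5 is a declared fixture
choice — the source imaging reports no contrast statistics. No contrast
transfer function is modelled: the analysis under test never models one
either, and published defocus values are metadata only. One physical
consequence worth noting: a membrane parallel to the x-y plane has its
spectral energy along f_z, inside the cone that remains unsampled at every
particle azimuth, so averages legitimately lack the flat membrane; tests
compare against a missing-cone-filtered reference rather than the raw
phantom.

**Size-class sampler.** Spherule volumes are drawn from a Gaussian mixture
truncated at zero. The default components (means 12,000 and 108,000 nm^3,
sds 20% of mean, equal weights, n = 541) emulate the two size classes
observed when only genomic RNA1 replicates; weights for a full-infection
distribution are never published, so full-infection emulation is left to
the caller.

What the phantoms do not emulate: electron-optical effects (CTF, dose
damage, detector MTF), membrane deformation away from sphere/plane
idealizations, crown structural heterogeneity or partial tooth occupancy,
and segmentation error in particle picking. Passing tests therefore show
the *pipeline* is correct under the stated corruption model, not that it
would reach any particular resolution on real micrographs.

## Subtomogram alignment

Particles receive initial orientations from the outward membrane normal
(zero azimuth), as in the original procedure; with a planar membrane this
makes the starting axis error equal to the picking jitter (default ~2
degrees). The initial template is the coverage-weighted average of the raw
particles at those orientations — no external reference, so reference bias
is excluded by construction.

Each iteration scans, per particle, a grid of candidate poses: axis
directions sampled approximately uniformly on a spherical cap by a
Fibonacci spiral (the exact previous axis is always the first candidate, and
score ties break to the first-found candidate, making the search
deterministic), crossed with an azimuth scan. The published schedule is
honored: a 60-degree initial cone with full 360-degree azimuth scan,
narrowing to 5 degrees, at most 12 iterations. Later iterations bound the
azimuth by the current cone half-angle, matching the published "5 degrees
around the axis located at the previous iteration"; a full azimuth scan at
fine steps would also be ~40x more expensive for no benefit once azimuth is
locked. Matching is normalized cross-correlation over mean-free Fourier
components, restricted to the particle's sampled (outside-wedge) region,
low-passed at 6.6 nm (twice the target resolution, to prevent alignment to
noise); the translational search uses one FFT cross-correlation per pose,
masked to shifts within 5 voxels of the original position ("particles stay
in a neighborhood of their original location"; the radius is unpublished
and declared here). Averages divide the Fourier-space sum of rotated
particles by the summed rotated wedge coverage, flooring coverage so
never-sampled regions stay zero rather than amplifying noise.

Half sets A/B are fixed at the start, immutable thereafter, and refined
against their own averages (gold standard) so the FSC between half maps is
not self-correlated. Convergence: the schedule advances every iteration;
after the final stage the loop stops when the median orientation change
drops below the current angular step, or at `max_iterations`. No symmetry
is imposed at any stage; the C11 control in the acceptance suite verifies
that 11-fold phantoms yield 11, not 12.

## FSC

Shells are one voxel wide at integer Fourier radii — the simplest auditable
binning. A soft spherical mask (cosine edge, 3 voxels) is applied by
default and its use is recorded on the curve, since masking is the classic
way to inflate FSC. Zero-power shells report correlation 0 and are flagged.
Resolution is the reciprocal of the linearly interpolated first downward
crossing of the threshold (0.5 and 0.143 both reported); a curve that never
crosses returns the Nyquist-limited value with a flag. The published 3.3 nm
applies to real micrograph data and is deliberately not an expectation for
phantoms; phantom FSC is checked by properties (self-FSC identity, the
3/sqrt(n) noise null, threshold monotonicity) and a bounded-resolution
assertion only.

## Symmetry detection

Density is sampled on circles about the crown axis in an annular band
(default 15–20 nm radius — the teeth ring — and a 4 nm height band at tooth
level; the source band is unpublished, so the default derives from the
crown geometry), 128 azimuths, trilinear interpolation. Each profile is
mean-subtracted and Fourier transformed; power is averaged across
particles. Because power is invariant to the azimuthal phase, per-particle
spectra do not require azimuthal registration — only the axis must be
right — which makes the detection robust even before refinement converges.
Component 0 is excluded; component 1 is reported as an axis-miscentring
quality metric. The detector reports the argmax over components 2–24 with
prominence = peak power / median power in the range (the median is floored
at 1e-3 of the peak so a nearly empty spectrum cannot make noise-level
components look prominent); below prominence 2 it reports "none detected".
If the argmax is the second harmonic of a component that is itself
prominent and carries at least a third of the harmonic's power, the
fundamental is reported — the physical subunit count — while trace power at
half the peak never demotes a clean peak.

## Morphometry and packing model

Spherule volume follows the published measurement convention exactly: the
radius at the widest circumference, volume by the sphere formula
(4/3)pi r^3; ellipsoidal fits are deliberately rejected. From a density
map, boundary points are the radial density peaks along ~500 sampled
directions (a 45-degree cone around the neck is excluded so the planar
membrane does not contaminate the caliper); from ground truth, any boundary
point cloud is accepted. The caliper diameter along an axis sums the mean
point radii in two antipodal 16-degree caps, which keeps the estimate from
riding on the outermost noise excursions; on 2%-noisy boundaries the radius
error stays ~1%.

Inter-filament spacing is the mean nearest-neighbor center-to-center
distance over cross-sections resampled every 2 nm of arc, excluding
same-strand pairs within one persistence length (62 nm) of arc — the
exclusion window is a declared choice, since the published measurement does
not state how self-pairs were handled. On parallel-cylinder lattices the
estimator is exact to <2% across pitches 2–10 nm.

Size classes are formalized as Gaussian mixtures fit by EM with 5 restarts
per component count, k selected by BIC over 1–5 (the source describes
"three to four peaks" without naming a method); means are reported sorted
with the full BIC trace for auditability.

The packing model treats locally straight dsRNA as parallel cylinders whose
base pairs per volume scale as the inverse square of center-to-center
spacing. Calibration: 24.7 kbp in a ~74,000 nm^3 reference core at 2.7 nm
spacing gives 334 bp/1000 nm^3. The published chain applies a stated
~5.8-fold reduction to reach ~58 bp/1000 nm^3 at 6.4 nm spacing, although
(6.4/2.7)^2 = 5.62; both folds are always computed and carried so the
discrepancy stays visible, with the stated fold authoritative for the
headline chain. Occupied volumes are computed from the display-rounded
density (58), exactly as the published chain does, so every downstream
number reproduces; display rounding is to whole bp for densities and to
the nearest 1000 nm^3 for volumes, matching the source's "~" precision.
Auxiliary arithmetic: the maximum immunogold label displacement is the sum
of two 8 nm antibody arms and the 14 nm crown height (30 nm); the
export count multiplies retained genome copies by the positive-to-negative
strand ratio (2 x 100 = 200 at the upper bound).

## Problem sizes and numerical choices

The demonstration pipeline and acceptance computations use 1 nm voxels in
48-voxel boxes (the target resolution scale of ~3.3 nm is oversampled
threefold), 100 crown particles at SNR 0.5, and 541 mixture draws — the
published sample size for the RNA1 size-class experiment. Angular steps per
iteration are (30, 15, 8, 4, 2.5) degrees against cones of (60, 30, 15, 8,
5) degrees. Alignment FFTs run in single precision (the correlation values
agree with the double-precision scorer to ~1e-4, far below the decision
margin between poses); averaging accumulates in double precision.
Degenerate inputs fail loudly: zero-variance volumes in scoring, empty
particle sets, mismatched boxes, non-positive physical quantities.

## Known limitations

Alignment cost scales linearly in particles x poses; the spiral-cap grid
keeps pose counts in the hundreds, but the implementation is a single-CPU
NumPy/SciPy pipeline, not a GPU code. The missing-cone region is
unrecoverable by azimuthal averaging, so planar-membrane features are
absent from averages by physics, not by bug. The worm-like-chain generator
produces a single filament per spherule; multi-strand topologies and
strand-strand entanglement statistics are not modelled. Symmetry detection
assumes an approximately known axis (from membrane normals or refinement);
it does not search axis space globally.
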