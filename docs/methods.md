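# Methods

## Grids and resampling

Two grid types carry all data. A `DensityMap` is a block of values on a
(possibly non-orthogonal) crystallographic grid with a Cartesian origin;
the stored block is treated as the map's extent, and for the synthetic P1
maps generated here it is the whole cell. An `OrthoGrid` is a regular
orthogonal grid with one isotropic spacing, 0.7 Å by default — the working
representation the network sees. All resampling is trilinear in both
directions.

Sampling beyond a grid's stored extent clamps to the edge value rather
than returning zero. This choice makes resampling round trips exact up to
the boundary (zero-fill bleeds into the interpolation cells at the edge
and corrupts even a constant map); explicit zeros are used only where
they mean something — the chunker's margin padding, and template points
that fall entirely outside the working grid when a prediction is
re-interpolated back (these are warned about and set to 0, since there is
no data there at all).

CCP4 I/O goes through gemmi. Maps are written in mode 2 (float32) with
x,y,z axis order; arbitrary axis permutations are resolved on read from
the MAPC/MAPR/MAPS header words, and the Cartesian origin is carried in
the MRC2014 ORIGIN header words plus any NXSTART offsets. Because header
cell parameters are float32, a voxel sitting exactly on the 1.5 Å
labelling boundary can flip across a write/read cycle; the tests treat
such single-voxel flips as boundary artifacts, not mismatches.
Crystallographic symmetry expansion is not performed: the map's stored
extent stands in for the asymmetric-unit section, which is exact for the
P1 synthetic maps and isolates symmetry handling behind the I/O module
for later addition.

## Chunked inference

The working grid is zero-padded by a 16-point margin and tiled into 32³
cubes with stride 16 (a 16-point overlap). The final chunk along each axis
is clamped to end at the padded boundary rather than dropped, so coverage
is guaranteed; edge strides may therefore be shorter, and reassembly
divides by per-point contribution counts instead of a fixed divisor.
Reassembled values are additionally clipped to the per-point [min, max] of
their contributions: this guarantees both the range invariant and exact
identity round trips (a floating-point mean of three identical values is
otherwise not exact). Interior points are covered by 8 chunks (2 per
axis), so averaging binary argmax votes yields 9 possible levels between 0
and 1; the same votes' population variance is the `-variance` uncertainty
map, and variance is computed over the argmax-classified values (the same
quantities standard inference averages), with raw-probability variance
available by passing raw mode through the same plumbing.

## Network

Canonical 3-D U-Net choices are used where only the data shapes are
pinned: 3×3×3 convolutions with same padding, 2×2×2 max pooling with
stride 2, 2×2×2 transposed convolutions with stride 2, instance
normalization (ε = 1e-5, affine) after every convolution except in the
bottleneck, ReLU activations, He-uniform initialisation from a seedable
generator. The filter schedule is fixed by the shape constraints: the
first block maps 1 → 16 channels, each later encoder block doubles them
(ending at 256 when the spatial edge reaches 1), the two bottleneck
convolutions map 256 → 512 → 512, and each decoder block halves the count
after its skip concatenation, ending at 16 before the two-channel softmax
head. Normalization is omitted in the bottleneck to avoid whitening the
(1,1,1,512) deep representation per sample. The head bias is initialised
so the positive channel starts at a class prior of 0.05 rather than 0.5 —
the standard companion to the focal loss for rare-class segmentation.
Without it, early training is dominated by the easy negatives and the
positive channel can stay under-confident (probabilities that never cross
the 0.5 argmax line) for many hundreds of steps, with strongly
seed-dependent convergence; with it, desk-scale training converges
reliably.

The layers are implemented directly in NumPy with hand-derived backward
passes; convolutions run as k³ shifted-slice matrix products (BLAS) rather
than one large im2col patch matrix, which dominates runtime on a CPU.
Gradient correctness is asserted against central finite differences in
float64 in the test suite.

## Training

Target maps label every working-grid point within 1.5 Å of an atom of the
chosen moiety. The moiety partition of a nucleotide is by atom name:
phosphate = {P, OP1, OP2, O5', O3'} (the two ester oxygens are bonded to
phosphorus and carry phosphate-like density), sugar = {C1'…C5', O4', O2'},
base = all remaining non-hydrogen atoms of nucleic residues.

Training samples are 32³ cubes interpolated at a uniformly random rotation
(unit-quaternion sampling) and a uniformly random translation within the
map extent, keeping the 0.7 Å lattice spacing. Interpolated target values
are re-binarised at 0.5 so labels stay exact under rotation. Three map
sources are cycled round-robin, one step each: nucleic-acid-only maps,
protein–nucleic complex maps, and degraded complex maps standing in for
post-molecular-replacement quality. During the restricted early phase —
the first 20% of epochs, mirroring a 200-of-1000 curriculum — a draw is
rejected until the target cube contains at least one positive point, with
a cap of 100 attempts before an error names the cap.

The loss is the focal cross-entropy on the two-channel softmax output with
the standard α = 0.25, γ = 2.0; the optimiser is Adam at learning rate
1e-4 by default (the desk-scale benchmark uses 1e-3 to converge within its
small step budget). All training is seeded and bit-reproducible.

## Synthetic data

The duplex generator stacks an idealized nucleotide template given in
cylindrical coordinates by the helical rise and twist of the chosen form
(B: 3.4 Å / 36°; A: 2.6 Å / 32.7°). The template's backbone and sugar
coordinates were fitted so that standard bond lengths (P–O5' 1.60 Å,
O3'(i)–P(i+1) 1.60 Å, ring bonds 1.41–1.53 Å) hold under the helical
symmetry with the phosphorus at radius 9.4 Å; the consecutive
intra-strand P–P distance comes out at 6.72 Å (B) and 5.90 Å (A). Bases
are planar idealized rings attached at C1' pointing toward the helix
axis; the complementary strand is the dyad image advanced by half a turn,
which puts paired C1' atoms 10.5 Å apart. These are idealized fiber-like
coordinates, embedded as literals — adequate for density synthesis and
geometry tests, not for chemical analysis.

Density is a sum of isotropic Gaussians weighted by atomic number
(P 15, O 8, N 7, C 6; hydrogens omitted), width parameterized as an
effective B-factor with σ² = B/(8π²) and B = 30 Å² by default, evaluated
within a 4σ box per atom. Post-molecular-replacement-like degradation is
an extra 1.5 Å Gaussian blur plus white noise at 10% of the peak — an
emulation of B-factor-flattened, protein-only-refined maps, not a
structure-factor-level phase-error simulation. Consequences for test
interpretation: passing desk-scale benchmarks demonstrates that the
architecture, sampling curriculum, loss and inference plumbing function
and that learning transfers across synthetic structures; they say nothing
about performance on real crystallographic maps with solvent, anisotropy,
series-termination ripple or genuine phase error.

## Model building

Phosphate positions: working-grid points of the predicted map above 0.1
climb the trilinear interpolant by hill-climbing with central-difference
gradients (step 0.2 Å, convergence when the step improves the value by
less than 1e-4, cap 200 iterations); maxima are merged by single-linkage
clustering at 1.5 Å and averaged; each merged point is then refined to the
local density maximum under the constraint that it stays inside the
positive predicted region.

Triplets: both legs from the middle point ≤ 8 Å and interior angle at the
middle point within 150° ± 50°, measured by arccos in [0°, 180°] (the
nominal upper bound of 200° therefore truncates to 180°). Each unordered
triple is reported once, by its lexicographically smallest qualifying
ordering.

Fragments: idealized A-form and B-form trinucleotides generated by the
duplex generator serve as the template library (keeping the package
download-free); a loader accepts any PDB file whose chains are
three-nucleotide fragments. Superposition is a least-squares rigid fit of
the three P atoms onto the triplet, evaluated in both direction
assignments, with no subsequent refinement. Placements are scored by the
summed density at phosphate and sugar atom positions; when sugar/base
predicted maps are supplied the score adds the mean predicted value at
the corresponding atoms — a simple moiety-consistency augmentation.
Placements sharing two consecutive phosphate anchors are joined into
chains; each chain region's two direction variants are compared by mean
density over atom positions and the better kept, ties preferring 5'→3'.

Clash resolution between a protein and a nucleic model: a clash region is
a run of contiguous nucleic residues all within 1 Å of a run of
contiguous protein residues. Each side is scored as the negated mean
absolute difference density over grid points within 5 Å of the region, on
a 1 Å resampling of the difference map; the score is always ≤ 0, and the
side with the **higher** score — i.e. the weaker difference density — is
removed. Afterwards, residues whose bonding atoms (P/O5'/O3' for nucleic,
N/C for protein) have no neighbouring atoms from another residue within
2.5 Å are pruned as isolated.

## Evaluation

A predicted grid point is positive when its value is strictly greater
than 0 (exposed as a threshold knob). Confusion counts compare these
labels against target labelling computed on the prediction's own grid —
the re-interpolated input-map grid, not the working grid. Atom inclusion
is the percentage of a moiety's atoms whose position interpolates to
positive predicted density (a nearest-grid-point variant is selectable).
Truth-as-prediction scores 100% inclusion identically, which the tests
use as a structural check. The quality sweep tabulates inclusion per
moiety across a series of synthetic degradation settings, emulating a
resolution series.

## Desk-scale benchmark sizes

The training benchmark uses a depth-3, 8-filter network (the full-size
depth-5, 16-filter configuration is the default everywhere else), batch
4, 10 epochs of 28 steps with the first 2 epochs restricted, on an 8 bp
duplex, a 9 bp duplex–helix complex and its degraded copy; evaluation is
on a held-out 10 bp duplex at extra blurs of 0, 1.5 and 3 Å. The builder
benchmark runs on a 10 bp duplex with a ground-truth phosphate map.
These sizes were chosen so the full suite remains a coffee-break run on
one CPU while leaving the learning signal unambiguous.

## Known limitations

* No crystallographic symmetry, solvent model, anisotropic displacement
  or structure-factor-level noise in the synthetic data.
* The published tool's trained weights and PDB-scale training are out of
  scope; all learning demonstrations are desk-scale and synthetic.
* Chain growth stops at fragment joining and direction selection; no
  sequence assignment, base typing or downstream refinement.
* The sugar/base-aware scoring augmentation is a documented stand-in for
  a full moiety-likelihood score.
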