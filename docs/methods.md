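# Methods

`arbordepth` computes laminar arbor-density depth profiles of sparsely
labeled neurons from two-channel confocal stacks, and the statistics used
to probe whether such profiles are stereotyped enough to identify cell
types. This note records the models, numerical choices and limitations;
the README shows the user-facing workflow.

## Coordinate conventions

Arrays are indexed `(x, y, z)` with `z` the laminar axis, increasing from
the ganglion-cell side toward the inner nuclear layer. Physical units are
micrometers; the default voxel pitch is 0.4 × 0.4 × 0.5 μm. After
registration the On starburst surface sits at depth 0 μm and the Off
surface at 12 μm, so the ganglion-cell side is negative depth. The
12 μm inter-surface figure is a fixed convention of the registration, not
a measured quantity.

## Topology-preserving inflation (topology3d)

A trace (SWC skeleton) is rasterized to 26-connected digital lines and
inflated into the set of bright voxels (≥ 60% of the stack's maximum by
default) one voxel layer per round, flipping a candidate voxel only when
it is a *simple point*: flipping it leaves the number of objects, tunnels
and cavities unchanged under the (26-foreground, 6-background) adjacency
pair. Simplicity is decided locally by the two topological numbers of the
3×3×3 neighborhood (both must equal 1); decisions are memoized by the
packed 26-bit neighborhood code. The test suite checks the local decision
against a global embed-and-count oracle (components/cavities/Euler before
vs after the flip) on 10⁵ random neighborhoods, exactly.

Candidates are visited in deterministic raster order (x fastest) and each
simplicity test reads the *live* volume; sequential simple flips provably
preserve topology, which a per-sweep snapshot does not guarantee. The
snapshot variant is available (`live=False`) for comparison. Sweeps repeat
until the count of remaining candidates stabilizes, with a hard cap of
10·max(shape) sweeps.

Because the growth kernel is the 6-neighborhood, one round adds one
city-block (L1) layer. After r rounds a seed voxel's growth spans
(2r + 1) voxels along each coordinate axis, hence the absorbable-diameter
helper returns (2r + 1)·pitch — 50 μm for 62 rounds at 0.4 μm pitch.
Diagonal directions are reached more slowly (an L1 ball inscribes a
Euclidean ball of radius r/√3), so this guarantee quantifies the axial
span; the simulated cross-check measures exactly that span.

## Enhancement (enhance)

The enhancement network is a feed-forward stack of 3-D convolutions with
all-to-all feature connectivity and sigmoid nonlinearities: seven hidden
layers of 8 features (filters 5×5×1, 5×5×1, 3×3×3, 5×5×1, 3×3×3, 3×3×3,
1×1×1), a fully connected hidden layer of 100 units realized as a 1×1×1
convolution, and a single-feature 1×1×1 output layer. The decision patch
(receptive field) is 1 + Σ(filter − 1) per axis = 19 × 19 × 7 voxels
(7.6 × 7.6 × 3.5 μm at the default pitch), verified by impulse probing.
Mirror padding keeps output shape equal to input shape; the border policy
is this package's choice. Training is out of scope — no training data are
distributable — so weights are loaded from an `.npz` container and the
pipeline defaults to the 60%-of-max threshold baseline, which exercises
the downstream stages identically.

## Cleanup (postprocess)

The enhanced (or thresholded) stack is min-max normalized, binarized at
0.7, dilated (ball, radius 2 voxels) to bridge small breaks, and reduced
to the largest 26-connected component; the surviving intensities are
re-binarized at 0.5, objects smaller than 500 voxels are dropped, and
soma-like lumps are removed: `lumps = dilate(open(mask, ball(r)), ball(r))`
deletes every region thick enough to enclose a ball of radius r plus a
one-radius guard margin. Ball erosions/dilations use Euclidean distance
transforms, which is exact for digital-ball structuring elements; a cubic
kernel is available by configuration. The default search radius is 10
voxels: digital balls live in (anisotropic) voxel units, and a radius-10
ball (4 μm in-plane, 5 μm axially) fits inside a 12 μm soma while
exceeding every plausible dendrite radius; a 15-voxel ball would span
7.5 μm axially and never fit. Defaults are overridable per run.

## Laminar registration (laminar)

The fiducial (ChAT) channel is smoothed (Gaussian, σ = 1 voxel); per
(x, y) column the two strongest intensity peaks along z (≥ 6 μm apart,
parabolically refined to sub-voxel precision) give the On/Off height
samples. Samples deviating from a 5×5 median-filtered height map by more
than 3 median absolute deviations are invalidated — with a floor of a
tenth of the axial pitch on the threshold, since sub-voxel scatter is
measurement noise, not a mis-picked peak — and holes are filled by
harmonic interpolation (sparse Laplace solve with valid nodes as
Dirichlet data). Detection fails if fewer than half the columns show two
usable peaks.

Each height map is triangulated (downsampled to ≤ 10⁴ vertices) and
flattened by a least-squares conformal map: minimize Σ_T A_T |∂f/∂z̄|²
over planar vertex positions with two opposite-corner vertices pinned at
distance equal to their 3-D separation, fixing the similarity gauge so a
developable surface maps isometrically. The sparse normal equations are
solved directly; the stored `energy` equals the functional's value, and
orientation is flipped if the majority of planar triangles come out
negative. On test phantoms (4 μm amplitude, 100 μm wavelength) the
maximum per-triangle angle distortion is < 0.1° and no triangle folds.

The two flattened surfaces are registered in-plane at the anchor window
(32 × 32 μm, stride half a window) minimizing the summed height variance
of both laminae — the flattest patch — with ties toward the smallest
(x, y); the offset makes both flattened images of the anchor center
coincide. The mapping is extended to all voxels by local weighted
least-squares models in the monomials (1, x, y, x², xy, y², x z, y z, z)
fitted componentwise to the surface correspondence points within a 25 μm
in-plane radius (Gaussian weights, σ = half the radius; the radius is
doubled once if the fit is rank-deficient), evaluated on a coarse lattice
(≈ 6 μm in-plane spacing, 5 z levels) and interpolated trilinearly.
Depth is the per-column affine map sending the On height to 0 and the Off
height to 12 μm, extrapolated linearly beyond the surfaces. Each voxel
carries a volume-compensation weight |det J| of the (x, y, z) → (u, v,
depth) map, estimated by central finite differences on the lattice; for
an identity geometry the weights are 1 to 10⁻⁶.

## Depth profiles and statistics (profiles_stats)

Warped voxels are gridded onto 0.5 μm depth bins spanning [−20, 25] μm
with a Kaiser-Bessel kernel (width 3 bins, shape β = 6 — values in the
accuracy regime of the gridding literature; both configurable), each
sample's kernel normalized to unit discrete sum so total mass is
conserved exactly. Samples outside the support are dropped. Profiles are
normalized to unit Euclidean norm for comparisons; peak positions and the
crest factor are normalization-invariant, so only the SNR depends on this
convention.

The peak is the bin center of the profile maximum (ties toward smaller
depth); for bistratified cells a second peak is the maximum at least 6 μm
(half the starburst separation) from the first. On the threshold path,
bins below −6 μm are dropped before peak detection, since thresholding
raw stacks builds up spurious mass near the ganglion-cell layer. Note the
default grid anchors bins at integer multiples of 0.5 μm from −20, so a
true depth of e.g. 0.3 μm is recovered as its nearest bin center.

Statistics: the crest factor is peak/RMS of the profile (a peak-to-mean
variant is available behind a flag — the two definitions appear
interchangeably in the literature; RMS is the formal one). The SNR of a
type is mean_i ‖signal‖/‖profile_i − signal‖ with signal the mean
unit-normalized profile. The 95% CI for the peak-position SD σ given
sample SD s of n cells is [√((n−1)s²/χ²_{n−1}(0.975)),
√((n−1)s²/χ²_{n−1}(0.025))]. Variance equality across reconstruction
methods uses the Brown-Forsythe test (ANOVA on median-centered absolute
deviations). The right-sided signed-rank test enumerates all 2ⁿ sign
assignments exactly for n ≤ 15 and refuses zero differences.

## Synthetic phantoms (synthdata)

Phantoms emulate the study conditions: a 256 × 256 × 120 stack at
0.4 × 0.4 × 0.5 μm; two starburst laminae rendered as Gaussian-profile
sheets (σ = 0.8 μm) 12 μm apart, both following a sinusoidal warp
(amplitude 4 μm, wavelength 100 μm, random phases) around a 20 μm base
height; a branching arbor grown as an in-plane persistent random walk
(step 1 μm, persistence 0.8, branch probability 0.05/step, ~1200 μm per
stratum) confined to its type's depth — 15.6 μm (JAM-B), 5.5 μm (W3),
0.3 and 12.3 μm (BDa, bistratified) — plus a per-stratum laminar jitter
drawn N(0, 0.25 μm); dendrite radii taper 1.5 → 0.3 μm; a 12 μm soma sits
8 μm below the On surface, joined by a primary dendrite. Channels are
blurred (Gaussian PSF σ = 0.3/0.3/0.6 μm), scaled to 400 photons at peak,
and corrupted by Poisson shot noise plus 2%-of-peak Gaussian read noise.
All randomness derives from the spec seed; identical specs render
bitwise-identical stacks. The recorded per-voxel truth depth is the
stratification depth of the centerline that stamped the voxel, so it
isolates laminar placement from tube thickness.

Distractors (disconnected blobs and neurite fragments) keep ≥ 20 μm from
the true structure and ≥ 8 μm from each other over their whole geometry,
and are individually scaled so the stack's global maximum — hence the
60% threshold — does not move.

What the phantoms do *not* emulate: real confocal PSF side-lobes and
depth-dependent attenuation, non-uniform labeling along dendrites,
overlapping arbors of multiple cells, starburst somata in the fiducial
channel, and tissue deformations beyond a smooth low-frequency warp.
Passing the end-to-end tests therefore demonstrates the correctness and
calibration of the pipeline's geometry and statistics under controlled
conditions, not performance on degraded real data.

## Problem sizes and determinism

The default phantom (≈ 7.9 M voxels) runs the full automated path in
roughly 10 s on one CPU core; the end-to-end recovery study uses 10
phantoms per type (seeds 0–9). The conformal solve is capped at 10⁴ mesh
vertices; the warp lattice uses ≈ 6 μm spacing. Every stochastic step
takes an explicit seed, and the CLI writes a manifest (config, versions,
seed) sufficient to reproduce outputs bit-identically.

## Known limitations

* Inflation's per-round growth is city-block; strongly diagonal thin
  structures inflate slightly slower than axis-aligned ones.
* Surface detection assumes exactly two dominant laminae per column;
  heavily stained starburst somata would need masking first.
* The local polynomial warp extension assumes the deformation is smooth
  at the 25 μm scale; high-frequency tissue distortion is not recovered.
* Depth quantization at 0.5 μm bins adds up to ±0.25 μm to recovered
  peak positions; sub-bin peak interpolation is deliberately not used so
  peak reports match the gridded profile.
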