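# Methods

## Model and assumptions

The package treats a fibre orientation as an *undirected* unit axis.  A
microscopy section is a plane with orthonormal frame (u, v) and normal
n = u × v; an axis decomposes into an in-plane angle θ ∈ [0, π), measured
from u towards v, and a signed inclination α ∈ (−π/2, π/2].  Axes are
canonicalised (sign-flipped) so the in-plane projection falls in the upper
half-plane, which makes (θ, α) a bijection over undirected axes away from
the plane normal.  Axes whose in-plane projection norm is below 10⁻³ are
flagged degenerate: they carry no usable in-plane evidence, so during
matching they are scored at Δθ = π/2 (their weight comes only from the
signal fraction), and if one is nevertheless selected the BAS axis is
emitted unchanged and counted.

The fusion assumes (i) microscopy in-plane angles are much more precise
than the diffusion model's orientation estimates, (ii) the BAS posterior
samples of a voxel span the orientations genuinely present in that voxel,
and (iii) microscopy and MRI are accurately co-registered.  Registration
is consumed, not estimated: pixel positions and orientation vectors are
mapped to world space by a 4×4 affine and, optionally, a dense
displacement field whose local rotation is the polar-decomposition factor
of the transform Jacobian (central differences on the field grid,
trilinear interpolation between grid points).

One subtlety in the reconstruction: the sign of a sample's inclination is
only meaningful together with its in-plane angle.  When a selected
sample's canonical θ lies on the opposite half-turn from θ_mic (true
difference > 90°), its α is mirrored before composing; otherwise axes
near the θ = 0/π seam would be reflected across the section plane.

## Microscopy estimators

*PLI.*  The transmitted intensity of birefringent myelin follows
I(ρ) = (I_T/2)[1 + sin δ · sin(2(ρ − φ))] as the analyser rotates through
180°.  On an equally spaced rotation series (the instrument protocol is
nine 20° steps) the second-harmonic discrete Fourier component recovers
φ, the retardance |sin δ| = 2|z|/mean and the transmittance 2·mean
exactly for noiseless model data — the fit is a projection, not an
iterative optimisation.  Pixels with non-positive transmittance or
retardance below 10⁻⁶ are masked.  The extinction convention (whether
minima occur at fibre-parallel or fibre-perpendicular analyser angles)
differs between instruments and is not assumed: a `phase_offset_deg`
option (typically 0 or 90) selects it.  An optional flat-field image is
divided out before fitting; by default no background correction is
applied.

*Histology.*  The 2D structure tensor uses Gaussian-derivative gradients
at σ_gradient = 1 px (the gradient scale is not dictated by the protocol;
1 px preserves the finest texture) smoothed at σ_smooth = 10 px (the
protocol's kernel).  The fibre angle is the minor-eigenvector orientation;
coherence (λ₁−λ₂)/(λ₁+λ₂) below 0.01 marks a pixel invalid.

## Matching and sampling

Candidates are all retained samples of all populations with mean signal
fraction ≥ 0.05 (the exclusion is per population, applied to its mean
fraction; per-sample fractions are not modelled).  Weights are
f·cos(Δθ) with cos clamped to exactly zero at right angles so the
documented all-orthogonal fallback (weights = fractions alone) can
trigger.  Sampling uses the cumulative distribution: smallest index with
C[i] ≥ r.  The per-pixel uniforms come from a counter-based Philox stream
keyed by (seed, section index) and indexed by flat pixel position, so
results are independent of pixel iteration order and of which pixels are
valid.  An `argmax` mode (highest weight, ties to the lowest index)
implements the simpler nearest-angle scheme for comparison.

## FOD construction

256 "evenly spaced" directions are built as a Fibonacci hemisphere lattice
(z offset 0.75, which keeps the pole gap at 3.6° and the minimal pairwise
angle at 8.6°) mirrored to antipodes.  Each axis increments its nearest
hemisphere point and that point's antipode — hard binning, no kernel: the
spherical-harmonic fit is the smoothing.  The histogram is normalised to
unit mass before the least-squares fit of the orthonormal real even basis
(l = 0..8, m = −l..l, 45 coefficients; design-matrix condition number
≈ 1.6 on the default point set), because absolute amplitude is delegated
to the scaling step: per voxel, hybrid coefficients are multiplied by
maxpeak(reference)/maxpeak(hybrid) so tracking thresholds calibrated on
CSD-style FODs transfer.  Matching the l = 0 coefficients instead is
available as `scale="l0"`.  Voxels with no hybrid axes copy the reference
coefficients (nearest-voxel lookup, no interpolation of SH fields) and
are flagged "gap-filled"; with no reference they stay zero ("empty").
Without any reference the amplitude is arbitrary, and
`normalise_unit_peak` applies the zero-reference fallback (unit maximum
peak) image-wide — this is what the phantom pipelines use before
tracking.

Peak extraction evaluates a 724-direction dense grid, takes local maxima
within a 12° neighbourhood above 0.2 of the global maximum, applies
greedy non-maximum suppression at 25° separation, then sharpens each peak
with a three-level local cap search (4° → 1° → 0.25°), giving ~0.2°
angular resolution.  The 0.2 relative threshold is deliberate: an order-8
least-squares fit of a near-delta histogram rings with sidelobe maxima at
~0.11–0.14 of the peak, so a 0.1 threshold would report ringing as
crossing fibres.

## Tracking (stand-in)

The tracker is intentionally simple and clearly labelled a stand-in: it
exists to exercise the FODs end to end, and FOD images can be exported to
NIfTI for external tractography when publication-grade streamlines are
needed.  From each seed a direction is drawn by rejection sampling of the
FOD (restricted to amplitudes ≥ 0.2 of the local maximum, again because
of ringing) and the walk proceeds bidirectionally: per step, candidate
directions are drawn uniformly in a 20° cone about the incoming direction
and accepted by rejection sampling against the FOD amplitude *at the
step's arrival point* (trilinearly interpolated over voxel centres), as
in arc-sampling trackers — evaluating at the current position instead
leaves the walk spatially unconfined.  The rejection envelope is 1.1×
the largest per-voxel maximum amplitude among the 8 trilinear neighbours
(a trilinear mix cannot exceed its largest contributor; the current voxel
alone is not a valid bound).  The draw budget is 250 candidates per step;
starving the sampler (e.g. 50 draws) measurably kills streamlines at the
walls of single-voxel-thick tracts.  Termination: amplitude below the
cut-off everywhere in the cone, leaving the grid, or the length budget.
Defaults follow the whole-brain protocol: 0.2 mm steps, cut-off 0.05,
lengths 5–120 mm, 30 seeds per voxel.  The walk is reproducible: each
seed index gets its own Philox substream.

## Refinement and evaluation

Streamlines are scored by the mean atlas probability over the unique
voxels they intersect and kept when the score is ≥ 0.2 (strictly-below
discarded); streamlines entirely outside the map are discarded and
counted separately.  Outlier removal runs length-first: length >
mean + 4 SD, then deviation from the tract core > mean + 5 SD, where the
core is the point-wise mean of all streamlines resampled to 50
equidistant points after orienting each against a running mean (the
"core" is not otherwise defined; this is the package's construction).  A
single streamline is never removed (SD undefined).

Fixels are FOD peaks; each streamline-voxel visit is assigned to the peak
maximising |tangent · direction|, per-tract fixel density is
assignments / streamline count, and the fixel mask thresholds density at
5% of the tract's maximum (relative, not absolute — a flag could flip
this).  Fixels masked by ≥ 2 tracts are "multi-bundle": the bottleneck.
The crossing-fibre ratio is the fraction of fibre-containing masked
voxels with ≥ 2 peaks.

Connectivity rows are streamline fractions: a streamline's target is the
region label at its final endpoint (the first endpoint is consulted when
the final one is unlabelled or in the seed region); traversal-based
assignment is not used.  ROC analysis binarises the reference at 10⁻⁴
and sweeps 101 prediction thresholds over [0, 0.25]; AUC is the
trapezoidal integral over points sorted by (FPR, TPR) with (0,0) and
(1,1) anchors.  Log-correlation keeps cells above 10⁻⁴ (prediction) and
10⁻⁶ (reference) and reports the Pearson coefficient of the log₁₀
values.

## Phantoms: what they emulate and what they do not

Phantoms are tubular bundles (straight, arc, oblique) in a voxel grid.
Per voxel, population axes are the principal eigenvectors of each
bundle's own tangent scatter over a 3³ sub-sample, fractions are
proportional to occupancy (capped at 0.95 total), and BAS samples are
drawn from a bipolar Watson distribution about the population axis
(exact inverse-CDF sampling of |cos ψ| via erfi; κ = ∞ copies the axis).
κ = 50 (≈ 8° rms dispersion) is the default sample scatter.  Microscopy
sections are planes at 0.35 mm spacing; pixel angles are the decomposed
true tangents plus von Mises noise on the doubled angle (σ = 3° on θ by
default), respecting π-periodicity.  Bundles thinner than a voxel get
probability maps from sub-sampled occupancy and endpoint label spheres of
radius at least one voxel.

The default phantom (24³ voxels at 0.6 mm) sections along y and routes
its curved bundle within the section plane, mirroring coronal PLI where
in-plane curvature is microscopy-resolved; an oblique straight bundle at
45° to the sections exercises the through-plane fusion.  This geometry
matters: for a bundle curving *through* the sections, all tangents share
one in-plane angle while their inclinations differ, so the matching
weight cannot identify the pixel-correct inclination and exact recovery
is impossible in principle — a genuine limitation of the method, not of
the implementation.  Likewise, pixels whose own population fell below
the 0.05 fraction exclusion (a handful at bundle-overlap edges) are
unrecoverable by construction and are reported separately by the tests.

Default sizes are chosen for orientation statistics, not realism of
scale: phantom pixels are 0.05–0.15 mm rather than the instrument's
4 μm (a full-resolution section would carry ~13 million pixels and add
nothing on a smooth phantom), and the bottleneck fixture uses 0.12 mm
radius bundles 0.5 mm apart so that a 0.2 mm grid separates them with an
empty voxel column.  The phantoms emulate orientation geometry and
sampling noise only — no diffusion signal formation, point-spread,
registration error, staining variability or gelatine-background artefact
(the latter can only be handled by masking affected regions and
gap-filling from a reference FOD).  Passing tests therefore demonstrate
the correctness of the fusion, reconstruction and evaluation machinery
under known geometry, not performance on real tissue.

One measured caveat: under the standard noise conditions (κ = 50, 3°)
the median 3D hybrid error on the default phantom is ≈ 5.0° — the
in-plane component contributes ~2° and the through-plane component,
inherited from a single Watson sample, ~3.9° (median), so the statistic
sits essentially at 5° and individual noise realisations scatter a few
hundredths of a degree around it.  The raw BAS samples' median error
under the same conditions is 6.7°, and the fused axes are never worse
than the samples they draw from.

## Numerical choices

Degeneracy tolerance 10⁻³ on the in-plane projection; canonicalisation
is purely sign-based so decompose(a) and decompose(−a) agree exactly.
Ties in `argmax` matching go to the lowest candidate index.  Histogram
fitting uses a cached pseudoinverse of the 256×45 design matrix.  All
generators and samplers take explicit seeds; per-pixel and per-seed
Philox substreams make every pipeline stage order-independent and
bit-reproducible.
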