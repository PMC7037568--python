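# Methods

`saxshape` reconstructs low-resolution 3D envelopes of biomolecules from
1D small-angle X-ray scattering (SAXS) profiles.  The model space is the
latent space of a 3D shape auto-encoder; a genetic algorithm searches that
space for a shape (and optionally a size) whose computed profile matches
the data.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Shape representation

Envelopes live on a fixed 31×31×31 binary voxel grid.  Every structure is
size-normalized before voxelization: translated so the center of its
minimal bounding sphere (computed with Welzl's algorithm on the convex
hull vertices) sits at voxel (15,15,15), and scaled so the bounding-sphere
radius spans 15 voxel units.  The physical size survives as a single
scalar, the model radius *R* (bounding-sphere radius in Å; reference
50 Å, voxel edge `R/15` Å).  Occupancy is binary — the uniform-density
approximation appropriate to the low information content of SAXS below
q = 0.2 Å⁻¹ — and restricted to the 15.5-voxel ball the cubic grid can
represent isotropically.

A voxel is occupied iff its center lies within 1.0 voxel edge of any model
point; this yields solid envelopes from CA-only and bead models without an
atom-radius table.  One pass of morphological closing (3³ element, with
padding so the grid border is not eroded) removes single-voxel holes.
Interior cavities are *not* filled; cavity-bearing shapes are genuinely
hard for this representation and we do not paper over that.

## SAXS computation

Two backends compute the orientation-averaged intensity of an envelope:

- **Debye sum** (oracle): I(q) = Σⱼₖ sinc(q·djk) over occupied voxel
  centers with unit form factors.  Exact — it depends only on pairwise
  distances.  Above 4000 points the pair distances are accumulated into a
  histogram (bin width = voxel edge/32) carrying per-bin mean and
  variance; a second-order Taylor correction makes the residual
  O((q·width)⁴), i.e. ~1e-8 of I(0) — in particular it stays exact at
  deep interference minima, where naive binning fails by tens of percent.

- **Zernike expansion** (production backend): the envelope is expanded in
  the orthonormal 3D Zernike basis Z_nlm = R_nl(r)·Y_lm(θ,φ) on the unit
  ball up to order n_max = 20, and

      I(q) = (4π)² Σ_lm │Σ_n c_nlm T_nl(q·λ)│²,

  with T_nl(s) = ∫₀¹ R_nl(r) j_l(sr) r² dr and λ the unit-ball-to-Å map.
  The radial polynomials come from the closed Jacobi form
  R_nl(r) = √(2n+3)·r^l·P_k^(0,l+1/2)(2r²−1), k = (n−l)/2, orthonormal
  under r²dr (verified to 1e-13 in tests).  T_nl is precomputed by
  200-node Gauss–Legendre quadrature on a dense s-grid (s ≤ 90, step
  1/30) and linearly interpolated, so changing the radius costs only a
  q-axis rescale — this is the size/shape decoupling that lets the radius
  be optimized as one extra parameter.  At n_max = 20 the backend agrees
  with the exact Debye sum to ~0.1% pointwise over q ≤ 0.2 Å⁻¹ on the
  synthetic families, far inside the 5% tolerance asserted in the
  acceptance suite.  n_max > 40 is refused (the radial recursion loses
  accuracy); the default 20 balances fidelity at q ≤ 0.2 against cost.

**Chi score.**  Model-data agreement is
χ = √[ 1/(N−1) Σ ((c·Im − Ie)/σ)² ] over data points with q ≤ 0.2 Å⁻¹,
with the scale c fitted in closed form.  The model is interpolated onto
the data's q points (linearly in log I when positive); data are never
resampled.  When σ is absent, σᵢ = 0.03·max(Ie, ε) with ε = 1e-6·max(Ie)
(typical counting noise; the floor avoids division blow-ups).  The 1/(N−1)
normalization and σ handling are declared conventions.

## Synthetic shape corpus

The training corpus is generated, not downloaded: six parametric families
(ellipsoids, cylinders, dumbbells, tori, rectangular prisms, and chained
blob unions emulating multi-domain complexes), each normalized to unit
bounding radius, rasterized at a random orientation drawn from the shape
seed.  Parameter bounds are chosen so occupancy stays in 2–55% of the
grid and every shape is 6-connected.  What this corpus does *not* contain:
cavities, flexible chains, surface roughness at sub-voxel scale, and the
long-tailed complexity of real assemblies — so round-trip and
reconstruction numbers on it are analogs, upper bounds on what identical
settings would achieve on database structures.

**Simulated data.**  `simulate_profile` emulates photon-counting noise:
σ(q) = noise·I(q)·√(I(q_min)/I(q)), so `noise` is the relative error at
the lowest angle and weak high-q signal is proportionally noisier.  A
constant *relative* error model was tried first and rejected: it weights
the fully decorrelated high-q region as strongly as the Guinier region,
which makes χ(radius) a needle (±2 Å at R = 30) with a spurious drift
toward large radii — size optimization is then impossible for any
optimizer, contradicting the error structure of real detector data.

## Auto-encoder

A VGG-style stack: three [3³ conv + ReLU + 2× max-pool] blocks
(31→16→8→4, channels 8/16/32) into a dense latent layer (200 dimensions
at full configuration); the decoder mirrors with nearest upsampling and a
final per-voxel sigmoid.  Per-voxel binary cross-entropy against the
binary targets is minimized with Adam (lr 1e-3, batch 8, seeded shuffles);
the output bias is initialized to −1.5 so early epochs are not spent
learning background sparsity; early stopping on held-out loss (patience
5) restores the best weights.  Output binarization (threshold 0.5)
happens only at inference.  One conv per block (rather than two) keeps
single-CPU training practical; the contract is the encode/decode
interface plus round-trip fidelity, not a particular weight count.

The official scaled-down configuration — 500 shapes, 64 latent
dimensions, 10 epochs — trains in minutes on one CPU and reaches mean
held-out encode–decode overlap cc ≈ 0.84–0.87 depending on the corpus
seed (the fixed-seed acceptance configuration measures 0.87 against a
bar of 0.85).
Alongside the weights, the per-dimension min/max/mean/std of the encoded
training set form the *latent prior*: valid codes occupy limited ranges,
and the prior bounds initialization and mutation of the search.

## Genetic-algorithm reconstruction

Genome = latent vector (+ optional radius gene).  Fitness = χ of the
decoded envelope's Zernike profile against the data.  Defaults:
population 100, 100 generations (convergence typically by 60–80), 5
elites, tournament size 3, uniform crossover p = 0.8, per-gene Gaussian
mutation p = 0.2 with std = 0.3× the prior std, genes clipped to the
prior box.  The mutation rate/scale were set by measurement: at
p = 0.05/scale 0.1 the search could not leave the random-shape χ plateau
(best χ ~43 where ~1 is attainable); 0.2/0.3 reliably reaches χ ≈ 1 on
synthetic targets.  Elitism guarantees the best-so-far χ never worsens.

Degenerate decodes are handled without exceptions: an empty or tiny
(<20 voxel) shape scores a 1e6 sentinel.  Two physical constraints close
loopholes that synthetic experiments exposed:

- **Connectivity** — fitness scores the largest 6-connected component.  A
  scattering particle is one body; without this, sparse disconnected
  "dust" decodes plus a free radius can mimic almost any smooth profile.
- **Size normalization** — the robust shape extent (98th-percentile
  distance from the occupied centroid, insensitive to thin whiskers) must
  stay near the training convention of ~15 voxels; outside the band
  [12.5, 15.5] a soft χ penalty (2 per voxel of violation) applies.  The
  radius gene is interpreted as the *model's* bounding-sphere radius:
  profiles are evaluated at `radius·15/bound`, so underfilled decodes
  cannot masquerade as larger or smaller particles.

**Free-radius mode.**  The radius joins the genome as an extra gene.
Blind co-evolution of shape and size is deceptive: wrong-size fits with
χ ~4–11 attract the whole population while the true basin (χ ≈ 1) is only
a few percent of radius wide.  Three measures, each validated on sphere
and dumbbell benchmarks, make size recovery reliable:

1. The gene's admissible range is derived from the data: an iterative
   Guinier fit gives Rg, and the bounding radius of any particle lies in
   roughly [Rg, 2.6·Rg] (shell-like through rod-like), so the gene is
   initialized uniformly in [0.9, 3.0]·Rg (capped at 300 Å) rather than
   (0, 300).
2. Lamarckian refinement: each evaluation also tries the radius at which
   the decoded shape's radius of gyration matches the data's Rg (±6%),
   and the gene adopts the best value.  Because the Zernike moments are
   radius-independent, this costs one interpolation per candidate; the
   elite additionally gets a full geometric line search over (5, 300) Å.
   Radius mutations are multiplicative (10% log-normal steps) so the
   search can fine-tune at any scale.
3. Template seeding: half the initial population is the encoded form of
   freshly generated synthetic shapes covering all six families
   (target-agnostic — the recipe uses only the generative prior).
   Uniform draws from the prior box decode exclusively to amorphous
   blobs; templates give the search a foothold in every major shape
   basin.

With these, radius-free reconstructions of sphere targets at 30/50/80 Å
recover the radius within ~2% across seeds (acceptance bar: 15%), and a
free-radius dumbbell reconstruction matches the fixed-radius result.

## Model comparison

Overlap correlation cc = |A∩B|/√(|A|·|B|) over occupied voxels; grids are
size-normalized by construction, so comparing occupancies compares shapes
at equal size.  `align_cc` maximizes cc over 576 quasi-uniform rotations
(super-Fibonacci sampling, always containing the 24 exact cube
rotations), the mirror image (solution scattering cannot distinguish
enantiomers), and ±5-voxel translations about centroid superposition via
FFT cross-correlation; the best few orientation basins are refined by
local descent at 10/5/2/1° steps.  Rotated grids are resampled by
trilinear pull interpolation re-thresholded at 0.5 — push-rasterizing
points loses ~15% of voxels to rounding collisions and caps achievable cc
well below the discretization tolerance.  Repeated reconstructions are
clustered by average linkage on the distance 1−cc, cut at 0.3 (members
of one cluster overlap with cc ≳ 0.7).

## Scaled-down benchmark sizes

All empirical checks run on one CPU: training 500 shapes × 10 epochs at
64 latent dimensions; backend equivalence on 20 shapes; fixed-radius
reconstruction with population 50 × 60 generations; radius-free sphere
recovery with population 40 × 32 generations.  These sizes
are the package's test-scale defaults; the library accepts the full-scale
configuration (200-d latent, thousands of shapes, population 100 × 100)
through the same interfaces.

## Known limitations

- Uniform-density envelopes only; no hydration layer or excluded-volume
  contrast, hence the hard q ≤ 0.2 Å⁻¹ policy.
- Shapes with large cavities or flexible ensembles compress poorly into
  the latent space and reconstruct at low cc.
- The 31³ grid sets the resolution floor: cubic-lattice anisotropy leaves
  l = 4,6,8 Zernike components at the few-percent level even for perfect
  spheres, and discretization caps alignment cc for rough shapes near
  0.95.
- Enantiomers are indistinguishable by construction; reported models are
  one hand of a mirror pair.
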