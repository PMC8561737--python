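# Methods

`saptfit` docks atomic search models into cryo-EM density maps. This note
records the models, conventions and numerical choices the package is built
on, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Problem setting

Given a density map with a nominal resolution, a target sequence and a
library of candidate structures (homologues of the target), the pipeline:

1. ranks the candidates by global sequence alignment to the target and
   removes redundant entries above an identity level (default 95%);
2. edits each candidate into a *mixed* search model: residues that align
   to nothing in the target are deleted, aligned residues of a different
   amino-acid type are truncated to main chain + Cβ (Cα only when either
   residue is glycine), identical residues keep all atoms, and the model
   is renumbered to target numbering;
3. docks each search model with a spherically averaged phased translation
   function (SAPTF), a local rotation search and rigid-body real-space
   refinement — either many copies into the full map, or one copy into
   each segment of a watershed segmentation;
4. scores placements with map–model correlations (global and local), the
   translation-function Z-score (TFZ), a clash-based packing score, and —
   when a reference structure is available — the lowest chain-to-chain
   r.m.s.d., with 5 Å as the success criterion.

## Density model

Simulated density is a sum of isotropic atomic Gaussians with weight equal
to the atomic number and width

    sigma_atom = resolution / (pi * sqrt(2))    [Å]

so a map at nominal resolution d attenuates the Fourier amplitude of each
atom to 1/e at spatial frequency 1/d. No per-element form factors are
used: at the ≥3 Å resolutions this pipeline targets, element-specific
shape differences are invisible and only the total scattering mass
matters. Maps are stored on axis-aligned grids, voxel index `i` at
position `origin + i * voxel_size`; MRC files with permuted axis-order
fields are transposed to this convention on read.

`d99` — the resolution beyond which Fourier coefficients are negligible —
is computed as the spatial frequency below which 99% of the non-DC power
lies, restricted to the Nyquist sphere of the coarsest axis; it is
scale-invariant by construction. The companion `lowpass_filter` uses a
raised-cosine edge whose amplitude passes through 1/2 exactly at the
cutoff frequency.

## The SAPTF translation search

The search model's rotation-invariant fingerprint is its radial density
profile: mean simulated density over concentric shells about its centre
of mass, out to its bounding-sphere radius (maximum atom distance from
the centre of mass; the radius of gyration is available as an
alternative convention but is not the default). The map's profile about
every grid point is obtained by convolving the map with one spherical-
shell kernel per shell — the trilinear splat of Fibonacci-sphere points —
via FFTs, which makes the every-grid-point search cost a handful of
64³-scale FFTs rather than millions of interpolations.

The score at a point is the **shell-volume-weighted** Pearson correlation
between the two profiles (weights ∝ r²). The weighting matters: an
unweighted profile correlation scores near 1 anywhere inside a smooth
blob (any monotonically decaying profile resembles any other), and its
maxima drift several Å off the true centre of mass. Weighting by shell
volume turns the score into a normalized overlap of spherically averaged
densities, which restores centre-of-mass localization while mean
subtraction keeps the score invariant to adding a constant to the map.
Points where the model sphere extends outside the grid are excluded
(shell means there average in zero padding); peaks are 26-neighbour local
maxima separated by at least half the model radius, and each carries
TFZ = (score − mean)/sd over the searched points.

Even so, the spherically averaged landscape is intrinsically broad: on
synthetic single-copy maps the top peak can sit a few voxels from the
true centre, and occasionally a secondary blob outranks it. Downstream
stages are therefore built to tolerate centre error, and multi-copy
placement picks among the leading peaks by refined local correlation
rather than trusting the raw peak order.

## Rotation search and refinement

A SAPTF peak carries no orientation, so the rotation search scans a
quasi-uniform SO(3) grid (Fibonacci directions × in-plane rolls, default
10° step). Orientations are scored by the *overlap* of the map with the
model's Gaussian density:

    score(R) = sum_i  Z_i * (g_sigma ⊛ map)(R x_i + t)

i.e. the map is smoothed once with the atom Gaussian and summed at the
rotated atom positions. For a rigid model the density norm is rotation-
invariant, so this ranks orientations identically to the real-space
correlation at a fraction of the cost. The coarse stage uses the Cα trace
and nearest-voxel lookups, and scans jointly over a small grid of centre
shifts (±3 Å per axis) to absorb SAPTF centre error; the best candidates
are polished over all six placement parameters, a 2° rotation-vector scan
finishes the winner, and the reported score is the true local correlation
(`cc_local`: Pearson over voxels within 3 Å of the placed atoms, against
the model's simulated density).

Rigid-body refinement (default 20 cycles) optimizes the same overlap
surrogate with Powell's method over translation and rotation-vector
offsets, then recomputes `cc_local`; if refinement failed to improve it,
the input placement is returned, so the local correlation never
decreases. Because the surrogate interpolates the smoothed map
trilinearly, a *single-atom* model snaps to the nearest voxel centre — a
degenerate case without practical consequence for multi-atom models,
whose many incommensurate lattice offsets smooth the objective.

Multi-copy placement is sequential: search, try the ranked peaks through
rotation search and refinement, require a packing score (fraction of
atoms ≥ 2 Å from previously accepted copies) of at least 0.7, prefer the
passing peak with the best refined `cc_local` (a peak reaching 0.9 is
accepted immediately), then zero the claimed density within
0.5 × resolution of the accepted atoms and repeat.

## Segmentation

Maps are segmented by scale-space watershed: threshold at mean + 1 sd of
the nonzero voxels (quantile and absolute policies available), watershed
the inverted density over the above-threshold voxels with 26-connectivity
seeded at local maxima, then repeatedly smooth the map with a Gaussian
whose σ grows by one voxel per round, re-find the maxima, and merge each
region into the new basin that claims its density maximum. Rounds stop
when the segment count reaches the target or σ exceeds 10 voxels (the
best achieved grouping is then returned with a warning flag). Segment
submaps are cropped to the segment bounding box plus a pad (default 8 Å
in the pipeline) with outside density zeroed and the origin adjusted so
model-space coordinates are unchanged. Zeroing outside the watershed
boundary clips some of the molecule's own density, which caps the
attainable local correlation in segmented mode; the pipeline accordingly
uses a lower early-accept level there.

## Evaluation

A reference model is built by least-squares (Kabsch) superposition of the
search model onto every chain of a fitted structure over Cα pairs matched
by target residue numbering (chains with fewer than 3 pairs are skipped).
Placements are scored by *direct* Cα r.m.s.d. against reference copies —
no re-superposition, so misorientation counts — with greedy one-to-one
assignment in ascending r.m.s.d. (optimal assignment available for small
n); `n_within_5A` counts placements at or below the 5 Å success
threshold. On well-separated instances greedy and optimal assignment
coincide; the greedy rule exists to prevent two placements claiming one
reference chain.

## Sequence stage

Candidate ranking replaces a profile-HMM database search with pairwise
global alignment (BLOSUM62, gap open 11, extend 1, Biopython's
`PairwiseAligner`); identity is reported over aligned non-gap columns.
Redundancy removal is greedy in input order: a candidate is dropped when
its identity to an already-kept sequence exceeds the level; at level 100
only exact duplicates are dropped. Domain-based fitting accepts
user-specified residue ranges (`split_domains`); no automatic domain
decomposition is attempted.

## Synthetic fixtures

The generators emulate a GroEL-like study system: a compact pseudo-protein
subunit (self-avoiding Cα walk, 3.8 Å steps, ≥3 Å non-bonded separation,
ideal-geometry N/C/O/Cβ atoms, random sequence), assembled into one or two
stacked rings of `n_fold` copies (14 subunits for the 7-fold double ring,
second ring flipped back-to-back), simulated at 3–18 Å with optional
Gaussian voxel noise, plus homologues at controlled sequence identity
(exact mutation counts) and coordinate perturbation. All generators are
pure functions of their arguments and a mandatory seed.

Default study conditions: 50-residue subunits, ring radius 28 Å, axial
ring separation 30 Å, 8 Å maps on ~2 Å voxels, homologue coordinate noise
0.5 Å. Noise-bearing experiments use `noise_sd_fraction = 0.3` — a
modest noise level representative of experimental reconstructions. The
noiseless case is a degenerate extreme for peak-significance statistics:
with no noise the score field's standard deviation collapses as the map
smooths, so TFZ *rises* with worsening resolution, whereas under noise
TFZ falls monotonically from 4 to 18 Å, the behaviour expected of
experimental maps.

What the fixtures do **not** emulate: side chains beyond Cβ, B-factor
variation, solvent, the contrast-transfer function and anisotropic or
correlated noise, map sharpening artefacts, and conformational change
between homologue and target beyond isotropic coordinate noise. Passing
tests therefore demonstrate correctness of the geometry, scoring and
search machinery at realistic sizes — not performance on experimental
data with model error, which the underlying method addresses through the
mixed-model editing tested here only in its geometric aspect.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen to exercise the
full pipeline: 48³–64³ grids, 50-residue subunits, 7- and 14-copy
assemblies, 10 seeded trials per resolution for recovery statistics. All
randomness flows through explicit seeds; reruns are bit-identical.

## Known limitations

- The SAPTF is a centre-of-mass detector; for models comparable in size
  to the whole map a phased translation function would be preferable (not
  implemented).
- Rotation search cost is independent of map size (it is dominated by the
  SO(3) grid), so segmenting pays off mainly through the cheaper
  translation search and earlier acceptance, not in the rotation stage.
- Greedy peak handling can mis-place copies when density of adjacent
  subunits overlaps strongly at low resolution — the packing score flags,
  but does not repair, such solutions.
- Refinement optimizes a trilinearly interpolated surrogate; sub-voxel
  accuracy relies on the multi-atom averaging effect and the final
  correlation guard, not on a smooth interpolant.
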