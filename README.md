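# saptfit

Search-model identification and map fitting for cryo-EM. Given a density
map, a target sequence and a library of candidate atomic models, `saptfit`
ranks the candidates against the target, edits them into truncated
*mixed* search models, docks one or many copies into the map, and scores
every placement — automating the molecular-replacement-style route to an
initial model for maps in the 3–18 Å range, where a homologue placed well
is most of the battle.

Intended users are structural biologists with a map and a sequence but no
fitted model, and methods developers who need a transparent, scriptable
docking baseline with ground-truth fixtures.

## Method

**Translation search (SAPTF).** The search model's rotation-invariant
fingerprint is its spherically averaged density: the radial profile
ρ̄(r) of its simulated density about its centre of mass, out to its
bounding-sphere radius. The map's profile about every grid point **p** is
computed by FFT convolution with spherical-shell kernels, and each point
is scored by the shell-volume-weighted correlation

    S(p) = Σₖ wₖ (ρ̄ₘₐₚ(rₖ; p) − μₘₐₚ)(ρ̄ₘₒdₑₗ(rₖ) − μₘₒdₑₗ) / (σₘₐₚ σₘₒdₑₗ),
    wₖ ∝ rₖ²

— a normalized overlap of spherically averaged densities that peaks at
the centre of mass of a matching molecule regardless of its orientation.
Peak significance is the translation-function Z-score,
TFZ = (S − ⟨S⟩)/sd(S).

**Orientation and refinement.** Because the profile is orientation-blind,
a rotation search scans a quasi-uniform SO(3) grid (10° coarse, 2° fine),
scoring each orientation by the overlap of the atom-smoothed map with the
rotated atoms; rigid-body refinement then polishes all six placement
parameters. Placements are scored by global and local real-space
correlation (`cc_global`, `cc_local`), and multi-copy docking accepts
copies sequentially under a clash-based packing score, masking claimed
density between rounds.

**Model editing.** Candidates are aligned to the target (BLOSUM62 global
alignment); unaligned loops are deleted, mismatched residues truncated to
main chain + Cβ (Cα for glycine), and the edited model renamed by the
convention `{source}_{pdbid}_{chain}_{prep}_{identity}_{first}-{last}`.

**Evaluation.** When a reference structure exists, the search model is
Kabsch-superposed onto each of its chains and every placement reports its
lowest direct chain-to-chain Cα r.m.s.d.; a placement within 5 Å counts
as correct.

The map can also be segmented first (scale-space watershed grouped down
to a target segment count, e.g. the 14 subunits of a double-ring
assembly) and a single copy docked per segment.

## Worked example

Generate a synthetic test case — a 7-fold ring of a 40-residue pseudo-
protein, its 8 Å map, and a homologue library — then dock two copies of
each ranked candidate:

```sh
saptfit fixture --out fx --n-rings 1 --n-res 40 --ring-radius 24 \
                --resolution 8 --seed 3
saptfit run --map fx/map.mrc --resolution 8 --seqin fx/target.fasta \
            --library fx/library --ncopies 2 --top-k 2 --out results
```

Output (abridged):

```
                         name  copy   tfz  saptf_score  cc_global  cc_local  packing_score
ALN_hom100_A_mixed_100.0_1-40     0  1.16       0.9996      0.362     0.995            1.0
ALN_hom100_A_mixed_100.0_1-40     1  1.24       0.9995      0.362     0.997            1.0
  ALN_hom70_A_mixed_70.0_1-40     0  1.14       0.9996      0.363     0.977            1.0
  ALN_hom70_A_mixed_70.0_1-40     1  1.22       0.9997      0.360     0.981            1.0
```

Each row is one placed copy of one search model. `saptf_score` is the
profile correlation at the accepted translation peak and `tfz` its
Z-score over the searched grid (modest here because a 7-fold ring map
contains seven equally good peaks, which inflates the score field's
spread; on a single-copy map the true peak's TFZ is ≈ 4). `cc_local` is
the real-space correlation between the map and the placed model's density
within 3 Å of its atoms, the most discriminating column: the true subunit
(100% identity) fits at ≈ 1.0 while the 70%-identity homologue, whose
coordinates carry 0.5 Å of noise and whose mismatched side chains were
truncated, trails it. `packing_score` = 1.0 means no atom clashes with
previously placed copies. Ranking by `cc_local` puts the true subunit
first.

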