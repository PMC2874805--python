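# Methods

## Geometry

Each residue's local frame sits at its Cβ atom: u_z is the unit vector from
Cα to Cβ (the side-chain direction), u_x the component of (N − Cα)
orthogonal to u_z, and u_y = u_z × u_x, giving a right-handed orthonormal
triad. The choice of u_x from the N–Cα bond is a convention: any fixed,
backbone-only rule spans the same score class as long as training and
evaluation share it, which the round-trip and rigid-motion-invariance tests
enforce rather than assume.

Glycine receives a virtual Cβ placed 1.53 Å from Cα with both central
angles (N–Cα–Cβ and C–Cα–Cβ) equal to the ideal tetrahedral angle
arccos(−1/3) ≈ 109.471°, on the branch consistent with L-amino-acid
chirality. The construction is closed-form (tilt off the N–Cα–C bisector in
the plane spanned by the bisector and the plane normal) and is
cross-checked in the tests against an independent internal-coordinate
(NeRF-style) placement.

The six relative coordinates of frame 2 with respect to frame 1 are
r = |v₁₂| (the Cβ separation), the polar/azimuthal angles (θ, φ) of v₁₂ in
frame 1, and z-y-z Euler angles (α, β, γ) of the rotation M with
M[i, j] = u2_i · u1_j. Conventions at singular points: φ = 0 when θ ∈
{0, π}; at the Euler gimbal locks (β ∈ {0, π}) γ = 0 and the in-plane
rotation is absorbed into α. These are removable, measure-zero choices;
correctness is enforced by the reconstruction property (frame 1 plus the six
coordinates reproduces frame 2 to < 1e-8) over random frame pairs.

## Pair scores

Qualifying pairs satisfy sequence separation ≥ 6 (within a chain) and
Cβ–Cβ distance ≤ 10 Å: closer pairs are dictated by local secondary
structure, farther ones barely interact. Scores are log-odds of a native
density over a type-independent background:

- the native density for an unordered type pair is fit to the relative
  coordinates of that pair in native structures;
- the background pools all pairs regardless of type — both frame
  orientations of every pair, since with types stripped neither residue is
  a preferred anchor — and is fit jointly in the same dimensionality as the
  native fits.

Because the 3D/6D coordinates depend on which residue anchors frame 1,
unordered type pairs are canonicalised: the alphabetically earlier type
anchors frame 1 (the lower residue index for equal types), in training and
evaluation alike, which makes the score exactly symmetric. Evaluating a
score with the types in non-canonical order inverts the relative
coordinates first (reconstruct frame 2 from the identity, measure the
reverse relation).

Densities are floored at 1e-12 before logs so scores stay finite; a native
density is fit only for type pairs with at least max(50, 10·dim)
observations — sparser pairs score exactly 0. For threading and design the
per-pair 20×20 score tables are precomputed once per template, so each
candidate sequence costs a table-lookup sum.

## Density estimation

**1D (KDE).** Gaussian kernels of uniform bandwidth, by default Silverman's
rule of thumb (any value, e.g. a Sheather–Jones estimate, can be passed);
the density is tabulated on a regular grid of ≥ 512 points spanning
[0, max + 4λ] and evaluated by linear interpolation, with the floor value
outside the grid.

**3D/6D (GMM).** Full-covariance Gaussian mixtures fit by EM (scikit-learn)
from a seeded k-means++ initialisation, covariance floor 1e-6. The
component count is selected by minimising BIC = −2 log L + p ln n with
p = K(D + D(D+1)/2) + (K−1), over the candidate schedule
{1, 2, 3, 4, 5, 7, 10, 14, 20, 28, 40, 56, 80, 100} (capped at 100 and at
n/(10·D)), refined by ±1 around the minimum; BIC curves are smooth enough
that the geometric schedule finds the minimum without fitting every K.
EM runs a single restart with tolerance 1e-4 and at most 300 iterations:
component recovery on well-separated mixtures is unchanged versus stricter
settings (100/100 in the acceptance check) at an order of magnitude less
cost. Backgrounds larger than 20 000 points are fit to a seeded subsample —
a smooth pooled density gains nothing from more points.

**Periodic angles.** φ, α, γ live on (−π, π]. Training points within π/2 of
a boundary are replicated shifted by ±2π (combinations included for corner
points) before fitting, and densities are evaluated at canonical
representatives. This removes boundary leakage at the cost of a bounded
normalisation factor identical for native and background fits, which
cancels in every log-odds score. θ and β ([0, π]) need no treatment, and
the non-uniform volume element on the angle coordinates likewise cancels
between numerator and denominator evaluated at the same point.

## Single-residue and depth scores

The single-residue score is a per-type log-odds table over burial class
(buried iff relative SASA < 0.01) × secondary structure class (H/E/C):
log P(Acc, SS | T, native) − log P(Acc, SS | non-native). The non-native
distribution is the pooled type-independent property distribution — exactly
what shuffling sequences on the same backbones converges to — with Laplace
smoothing (pseudocount 1) for sparse cells.

Relative SASA is computed by a Shrake–Rupley rolling-probe method (probe
1.4 Å, 256 sphere points) over the stored backbone + Cβ atoms only, divided
by a per-type theoretical maximum table and clipped to [0, 1.5]. Because
side chains are absent, absolute values are systematically low; only the
0.01 burial split matters, and it is robust to the precise maxima table
(which is configurable as a key-value text file).

Secondary structure comes from backbone torsions: H for runs of ≥ 4
residues with (φ, ψ) within ±40° of (−57°, −47°), E for runs of ≥ 3 within
±45° of (−135°, 135°), else C; externally supplied classes (e.g. parsed
DSSP output) can be passed to override.

The membrane depth score is log P(|z| | aa) − log P(|z|) with both
densities KDE-fit to |z| only, hence exactly symmetric in z.

## Threading benchmark machinery

Shuffled decoys are uniform permutations (Fisher–Yates via numpy) with only
the exact native string rejected; mutual collisions are permitted and
logged. Ranks use strict-greater counting (optimistic rank); fractional
rank divides by the number of candidates. Gapless cross-threading considers
every window of a donor at least as long as the template. Homolog averaging
replaces the threaded segment by aligned equal-length homolog windows and
averages the total scores. Grouped k-fold keeps all data for a protein in
one fold, balanced to within one protein. AUC uses the Mann–Whitney
identity with half-credit for ties (scikit-learn), checked in the tests by
hand enumeration.

## Design by max-product belief propagation

The total score decomposes into node terms (single-residue scores) and edge
terms (pair-score tables over qualifying pairs), i.e. the log-potential of
a pairwise MRF whose partition function is sequence-independent — so the
MAP sequence is the maximum-score sequence. Decoding:

1. synchronous max-product in log space, messages normalised to max 0,
   damping 0.2, tolerance 1e-8, 200 iterations;
2. the max-marginal argmax decode (ties to the lowest alphabet index) is
   refined by iterated conditional modes (greedy coordinate ascent), which
   never decreases the objective;
3. if the primary schedule did not converge, the schedule re-runs at
   dampings {0.5, 0.4, 0.7} with doubled iterations, and for small models
   (nodes × alphabet ≤ 1000) BP-guided decimation (clamping the most
   decided ~10% of nodes per round, at dampings {0.0, 0.2, 0.5}) is also
   tried; the best-scoring decode wins deterministically.

Plain synchronous max-product alone oscillates on a few percent of dense
loopy instances; the fallbacks are standard practice and keep the decoder
deterministic. On trees the decode is exact (verified against brute-force
enumeration on 200 random instances); on 3×3 loopy toys it reaches the
enumerated optimum or within 1% of it. Edge matrices that are identically
zero (no fitted type-pair densities touch them) are pruned as inert.

## Synthetic data

The generator emulates the statistical structure the scores assume, not
protein chemistry:

- **ideal helices/hairpins** are built by internal-coordinate chaining with
  ideal bond lengths and angles (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å;
  trans ω), so torsions are exact;
- **globules** place Cα atoms by a persistent self-avoiding walk (step
  3.8 Å, minimum non-adjacent separation 3.6 Å) confined to a sphere at
  roughly native packing density (~135 Å³/residue), then synthesise N and C
  positions from the neighbouring Cα directions with an out-of-plane tilt
  that keeps every frame non-degenerate;
- **helix bundles** and **transmembrane helix pairs** place ideal helices
  rigidly (grid spacing 8.6 Å for bundles; 7.2 Å antiparallel for
  contact-rich TM pairs, which exceed 15 inter-helix atomic contacts
  < 4 Å). Backbones are therefore not covalently continuous across
  segment junctions — irrelevant to the scores, which see only frames and
  distances, but a caveat for any chemistry-aware consumer.

Planted preferences are Gaussian affinity bumps over subsets of the six
coordinates, per unordered type pair, over a 6-letter alphabet. The default
spec gives every type exactly two bumps with comparably rare target regions
(a few percent occupancy), so no subset of the alphabet is globally
favoured: Cys–Cys at r = 3.8 Å and Ala–Cys at 5.0 Å (distance-visible,
hence 1D-visible), two θ/φ bumps (3D-visible only), and three Euler-angle
bumps (6D-visible only). Native sequences are Gibbs-sampled from the
induced pairwise field on the actual geometry (6 sweeps), with per-pair
affinity tables centred over the candidate-type axis so bumps express
relative preferences rather than a net drift. Homolog windows come in two
kinds: structure-aware (partial Gibbs resampling from the planted field —
substitutions that preserve structural fit, as real homologs do) and plain
random substitutions (what homologs of an unrelated donor look like). The
asymmetry is what makes homolog averaging informative; symmetric noise
provably does not help, and the tests exercise the asymmetric construction.

What passing these fixtures does **not** show: performance on real PDB
structures, where geometry, composition and correlation structure are far
richer, data per type pair is far more variable, and secondary-structure
and burial assignments face real noise. The fixture scale (20 structures ×
60 residues, ~290 qualifying pairs each; 5000 threading candidates per
template; 6-letter alphabet) is this package's desk-scale stand-in for a
bulk non-redundant benchmark; all problem sizes are parameters.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `r_max` | 10 Å | pair inclusion distance cutoff |
| `min_seq_sep` | 6 | pair inclusion sequence separation |
| KDE bandwidth | Silverman | 1D kernel width (Å) |
| `max_components` | 100 | GMM component cap (BIC-selected below it) |
| `min_count` | max(50, 10·dim) | observations needed to fit a type pair |
| density floor | 1e-12 | pdf floor before logs |
| burial threshold | 0.01 | relative SASA split |
| probe radius | 1.4 Å | SASA rolling probe |
| `R_prior` | 1 | prior odds in MAP classification (threshold −log R) |
| BP damping / iters / tol | 0.2 / 200 / 1e-8 | message passing schedule |

## Known limitations

- The frame x-axis and Euler branch conventions are this package's own
  (self-consistent, round-trip-verified); scores trained here are not
  numerically interchangeable with other orientation-dependent potentials.
- Loopy BP remains approximate on large design graphs; the decimation
  fallback is applied only to small models for cost, so non-convergent
  large decodes rely on the damping ladder plus coordinate ascent.
- SASA over backbone+Cβ understates exposure of long side chains; only the
  burial split is consumed downstream.
- Inter-chain pairs are excluded by default (flag to include, with the
  separation filter treated as passed).
- The benchmark curation statistic ("fewer than 50 contacts") reuses the
  pair-inclusion rule as the contact definition.
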