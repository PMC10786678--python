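# Methods

## Coarse-graining

Each amino acid is represented by a single point mass at its
alpha-carbon. Only `ATOM` records of amino-acid polymers contribute;
HETATM records, nucleic acids, ligands and waters are excluded, as are
residues without a CA atom (skipped with a warning). Alternate locations
are resolved to the highest-occupancy copy, ties broken by altloc
identifier order, so the model is a deterministic single-site chain.
Multi-model files contribute only their first model. Residue order is
canonical — chains in file order, then author residue number, then
insertion code — and internal indexing is positional and 0-based.

The input file must already contain the full shell: biological-assembly
expansion by symmetry operators is not performed.

## Elastic network models

Springs of stiffness γ_ij connect residue pairs closer than the cutoff
r_c (neighbor search via a k-d tree, contractually identical to the
all-pairs definition). Defaults follow the established calibrations for
B-factor reproduction: r_c = 15 Å for ANM, 7.5 Å for the other models.
A disconnected network is a hard error listing component sizes — silent
truncation of a shell would corrupt everything downstream.

With d̂_ij the equilibrium unit vector of pair (i, j):

- **ANM** — the exact Hessian of
  V = ½ Σ γ_ij (|r_i−r_j| − |d_ij|)²: off-diagonal 3×3 blocks
  −γ_ij d̂_ij d̂_ijᵀ, diagonal blocks closing each block row to zero.
  Six zero modes (rigid translations and rotations).
- **GNM** — the N×N Kirchhoff matrix Γ (graph Laplacian of the contact
  network). One zero mode.
- **U-ENM** — f·H_ANM + (1−f)·(Γ ⊗ I₃), equivalently per-edge blocks
  −γ_ij[f·d̂d̂ᵀ + (1−f)·I₃]. The isotropic term penalizes rotations, so
  only the three translations are zero modes for f < 1. Default f = 0.5
  (the midpoint; configurable). This convex-mixture form is the
  package's concrete choice of unified model.
- **bb-ENM** — ANM with γ multiplied by β ≥ 1 on sequence-adjacent
  same-chain pairs, which are included in the network even beyond the
  cutoff. Default β = 10 (a moderate backbone stiffening; configurable).

γ is uniform (= 1) internally. The physical scale is recovered by
B-factor calibration and cancels in correlations and clustering, so
nothing downstream depends on it. Distance-weighted springs and residue
masses are out of scope.

`potential_energy` exposes the harmonic energy itself so the anisotropic
builders can be validated against central-difference numerical Hessians;
the test suite and the acceptance script do exactly that (step 10⁻⁵ Å,
agreement to 10⁻⁶ relative).

## Normal modes and B-factor quality control

The stiffness matrix is singular, so eigenpairs are computed by
shift-invert Lanczos at a small negative shift (−10⁻⁶·λ̂_max, with
λ̂_max the largest diagonal entry — a cheap Gershgorin-style bound that
avoids a second eigensolve). The Lanczos start vector is drawn from a
fixed seed so repeated runs are bit-identical, and eigenvector signs are
normalized (first nonzero component positive). Very small systems fall
back to a dense solve.

Rigid modes are identified by the relative threshold λ < 10⁻⁸·λ̂_max
*and* verified against the analytic count for the model kind; a mismatch
(collinear geometry, marginally connected network, under-coordinated
sites in ANM) is a hard error rather than a silent off-by-one.

Mean-square fluctuations are MSF_i = Σ_k λ_k⁻¹‖u_k^(i)‖² (×3 with
scalar modes for GNM). The default of 200 modes is the established
operating point for large shells; `mode_convergence_profile` computes
the correlation as a function of retained modes (by truncating one
large solve, which is exactly equivalent to fresh smaller solves) to
justify the choice per structure. A rule of thumb for validation runs
is one mode per hundred residues.

The B-factor scale c minimizes Σ(B_exp − c·MSF)², giving
c = ΣMSF·B_exp/ΣMSF². The Pearson correlation is the quality metric;
the implied spring constant γ = (8π²/3)k_BT/c is reported at T = 293 K
in kcal/(mol·Å²). The temperature only affects this reported scale,
never the correlation or the clustering.

## Distance fluctuations

For anisotropic models the variance of the scalar distance is evaluated
to first order in the mode amplitudes:
σ_ij² = Σ_k λ_k⁻¹[(u_k^(i) − u_k^(j))·d̂_ij]². For GNM,
σ_ij² = 3Σ_k λ_k⁻¹(u_{k,i} − u_{k,j})², which with all modes equals the
pseudoinverse expression 3(Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij). The linearization
is validated against Monte-Carlo Boltzmann sampling (mode amplitudes
Gaussian with variance 1/λ_k, small-amplitude scaling) to 5%.

σ² is computed on a sparse neighborhood pair set (default radius twice
the model cutoff, always a superset of the network edge set) rather than
all N² pairs; the spectral clustering below operates on exactly that
sparse graph, and a dense option exists for small structures. Negative
values from floating-point cancellation are clipped to zero.

## Quasi-rigid clustering

Edge similarities use a Gaussian kernel S_ij = exp(−σ_ij²/(2bσ̄²)) with
σ̄² the mean σ² over stored pairs and b a configurable bandwidth factor
(default 1). Normalizing by the mean makes the construction invariant to
the global fluctuation scale (hence to γ and temperature).

Residues are embedded in the rows of the k lowest eigenvectors of the
symmetric-normalized Laplacian L = I − D^(−1/2)SD^(−1/2) (rows scaled to
unit length, signs fixed). One eigendecomposition at k_max is reused for
the whole scan. Partitions come from either iterative rotation of the
embedding to the nearest cluster-indicator matrix ("discretize", the
default: alternating orthogonal-Procrustes and row-argmax steps to a
fixed point, cap 500 iterations, reseeded retries on an empty cluster)
or seeded k-means with greedy initialization.

**Selection score.** Each candidate partition is scored by the
*fluctuation contrast*: the mean σ² over residue pairs crossing cluster
boundaries divided by the largest σ² inside any cluster, recovered from
the kernel weights as −log S (exact up to the bandwidth, which cancels).
This directly operationalizes the defining property of a quasi-rigid
decomposition — internal distance fluctuations uniformly small, boundary
fluctuations large: swallowing a floppy interface collapses the score
through the max in the denominator, while oversplitting a rigid unit
dilutes the numerator. A purely embedding-geometric centroid
distance-ratio score (mean over residues of the distance to the nearest
other centroid over the distance to the own centroid) is also provided
as `quality_score`; it was evaluated as the selection criterion first,
but on strongly block-structured fluctuation graphs several rigid blocks
collapse onto nearly coincident embedding points and the ratio becomes
arbitrarily large and noisy below the true cluster count, making its
argmax unreliable there. The fluctuation contrast selects the planted
count in every planted-partition benchmark in the test suite; the
embedding score remains available as a diagnostic.

The scan covers k from 4 (configurable down to 2) to a user-set maximum
(default 100, clamped to N−1). The maximum of the score is selected,
ties breaking to the smaller k; all local maxima are reported, and
`force_k` overrides the selection so alternative maxima can be
extracted. All stochastic steps derive from one configured seed.

## Synthetic fixtures

`make_hinged_toy` builds n compact residue blobs (points on a cubic
lattice at 3.8 Å — the CA–CA scale — with 0.25 Å jitter) arranged on a
ring with irregular angles and radii, adjacent blobs separated by a
3 Å surface gap. The geometry gives each domain a dense internal
network at the 7.5 Å cutoff while interfaces carry only a few springs;
an optional stiffness ratio additionally softens interface springs
(`planted_gammas`). The irregular placement avoids the degenerate,
symmetric spectra of a perfect ring, which would make low-dimensional
embeddings ill-conditioned in a way real shells (whose interfaces are
never exactly equivalent after thermal and structural noise) are not.
Generation is validated (per-domain connectivity, overall connectivity,
no interpenetration) with deterministic retries.

`make_spherical_shell` places quasi-uniform points on a sphere
(Fibonacci lattice, 0.2 Å jitter) as a closed-shell topology stand-in.
Both generators are bitwise deterministic per seed.

What the fixtures do *not* emulate: real protein geometry and sequence,
secondary structure, icosahedral symmetry orbits, and experimental noise
in B-factors. Passing tests therefore demonstrate the correctness of the
numerics and the recoverability of planted mechanical structure, not
predictive accuracy on real capsids, which depends on resolution and
model choice.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: networks of
20–300 residues, eigensolves up to dimension 900, 10⁵ Monte-Carlo draws,
planted-partition benchmarks of 60–300 residues over five seeds and both
clustering methods. Matrices are assembled exactly symmetric; PSD is
verified to −10⁻⁹·λ_max. Degenerate inputs (coincident connected sites,
all-zero fluctuations, zero-variance B-factors) are hard errors with
actionable messages rather than silent fallbacks.

## Known limitations

- The unified-model mixture form and its default f = 0.5, and the bb-ENM
  β = 10, are this package's documented choices; other implementations
  of these model families may differ in detail.
- The first-order distance-fluctuation formula omits second-order
  corrections; these matter only for pairs whose equilibrium separation
  is comparable to the fluctuation amplitude.
- Selection among near-tied local maxima of the quality profile is by
  construction parsimony (smaller k); domain structure at multiple
  scales should be inspected through the reported local maxima and
  `force_k`.
- No GPU solvers; no interactive 3D visualization (the emitted viewer
  script colors the annotated PDB in any standard molecular viewer).
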