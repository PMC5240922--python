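# Methods

This note documents the models implemented in `allonet`, the tunable
parameters and their defaults, the synthetic benchmark that the tests
and the acceptance script run on, and the design decisions taken where
the underlying methodology is genuinely open.

## 1. Coevolution statistics

**Alignment handling.** Alignments (FASTA/Stockholm) are encoded over
the 20 canonical amino acids plus a gap state; non-standard letters
(X, B, Z, U, O, J) carry no usable identity and are treated as gaps.
Columns are kept when their non-gap fraction is at least `min_coverage`
(default **0.8**, the usual column-inclusion threshold for family
alignments). Redundancy is removed by single-linkage clustering at
`identity_threshold` (default **0.62**) over mutually ungapped
positions, implemented as connected components of the ≥-threshold
identity graph — order-independent and deterministic; each sequence is
weighted 1/|its cluster|. Fewer than 400 clusters triggers a warning
(not an error): coevolution estimates from thinner alignments are
statistically fragile.

**Mutual information.** MI is the plug-in estimate from cluster-weighted
joint frequencies, in nats (`base=2` gives bits). Gap handling is
pairwise-complete: sequences gapped in either column of a pair are
dropped from that pair, avoiding gap-as-21st-letter artifacts. A
pseudocount (default **0.05**, spread uniformly over the 20×20 joint
table, i.e. 0.05/400 per cell) stabilizes sparsely observed pairs
without washing out signal; marginals are the joint's row/column sums so
MI ≥ 0 by construction. Pairs with < 2 effective sequences are zeroed
and flagged.

**APC.** The average product correction subtracts
(row mean_i × row mean_j)/overall mean, with means taken off-diagonal.
The correction is computed as `(row_i/overall) × row_j` so that a
2-column alignment yields exactly zero in floating point, not merely
approximately.

**Z-normalization.** The null distribution comes from `n_shuffles`
(default **100**) independent within-column permutations — column
compositions (and hence conservation) are preserved while inter-column
dependence is destroyed — each replicate APC-corrected, and the observed
APC value standardized per pair. Pairs with zero null spread get z = 0
and a flag. Fully seeded and bit-reproducible.

**Per-residue profiles.** KL conservation is Σ P ln(P/Q) per column; the
bundled background Q is the proteome-wide Swiss-Prot composition
(renormalized to sum to 1), replaceable by any 20-row TSV. The
cumulative MI threshold t = **6.5** is applied to the **Z-scored**
matrix: a fixed threshold is only portable across alignments on a
standardized scale, and 6.5 is far outside the shuffle null (|z| ≤ 4 for
≥ 99% of independent pairs). The matrix choice is configurable
(`cmi_matrix = z|apc|raw`).

**Structure mapping.** The k-th ungapped reference-row position pairs
with the k-th structure residue; a mismatch fraction above
`mismatch_tolerance` (default 0.05) is an error listing the offending
columns. Columns where the reference is gapped stay unmapped.

## 2. Ensemble dynamics

Multi-model PDB files are read with hydrogens ignored and disordered
atoms resolved to their highest-occupancy location; all models must
share atom bookkeeping. Before any coordinate statistic, frames are
superposed onto the ensemble mean by iterated least-squares (Kabsch,
2 passes) so rigid-body motion cannot masquerade as internal dynamics.
RMSF is the per-residue Cα root-mean-square fluctuation about the mean
(Å).

The GNM places unit springs between Cα pairs within `gnm_cutoff`
(default **7.3 Å**, the common single-parameter choice; the profile
shape is insensitive to ±0.5 Å). The Kirchhoff matrix has integer
off-diagonals and diagonal = −(row sum), so row sums are exactly zero;
more than one (near-)zero eigenvalue means a disconnected contact
network and is an error rather than a silent artifact. Slow-mode
fluctuations are Σ u²ᵢₖ/λₖ over the `gnm_modes` (default **3**) lowest
internal modes; strict local minima are flagged as hinge candidates.

Minimum heavy-atom distances use a KD-tree for neighbor queries and a
dense reduction for full matrices; both are contractually identical to
the brute-force all-pairs minimum (tested).

## 3. Coevolution–dynamics fusion

**pMI.** Per frame, pMIᵢ aggregates the cMI of residues within `t_pmi`
(default **5 Å** minimum heavy-atom distance); the ensemble mean is
reported. The aggregate is the neighborhood **mean** by default with a
`sum` option (`pmi_aggregate`): the two differ by a neighbor-count
factor and the choice matters when comparing against published sum-style
profiles, so it is a config switch rather than a silent decision.

**Generalized correlation.** Composite per-residue series are the three
superposed Cα coordinates plus the per-frame pMI, each channel
standardized; constant channels (e.g. pMI of residues with no coevolving
neighborhood) are dropped and flagged. The default MI estimator is the
Gaussian log-determinant form — deterministic, fast, exact in the
Gaussian regime — with a k-nearest-neighbor (KSG) estimator behind
`estimator="knn"` for strongly non-Gaussian signals. The map
r = sqrt(1 − exp(−2I/d)) uses d = mean active channel count of the pair;
r is clipped to [0, 1 − 1e-12] so w = −ln r stays positive and finite,
and r = 0 edges are excluded from path searches rather than capped.
At least 50 frames are required for a stable estimate.

## 4. Residue interaction network

Contact edges require n_ij ≥ 1 heavy-atom pairs within
`contact_distance` (default **4.5 Å**, the standard protein-structure-
network convention) and interaction strength
I_ij = 100·n_ij/√(Nᵢ·Nⱼ) ≥ `I_min`. The normalization table Nᵢ (maximum
heavy-atom contact count per residue type) is bundled as a versioned
TSV computed from the packaged synthetic structure set by
`compute_contact_normalization`; users analyzing real structures should
substitute published values via `load_contact_normalization(path)`.
`I_min` defaults to **1.0%**, calibrated once on the bundled benchmark
so that the contact graph's giant component spans the full structure
(single-bead contacts score 1.3–2.6% under the bundled table); it is the
most calibration-sensitive parameter of the pipeline and all
I_min-dependent outputs should be read with that in mind.

Shortest paths use Floyd–Warshall distances plus a per-source dynamic
program that counts **all** co-optimal paths (predecessor test with
relative tolerance 1e-9; edge lengths must be strictly positive).
Betweenness follows the fractional-credit convention — co-optimal paths
share one unit of credit — and the normalized form divides by
(N−1)(N−2)/2 within each connected component, so leaves score 0 and a
pure cut vertex scores 1.

Girvan–Newman removes edges in decreasing weighted edge betweenness
(w lengths as distances; igraph's C implementation) and returns the
dendrogram cut maximizing **unweighted** Newman modularity on the
contact topology, preferring fewer communities on ties. Output
communities are labelled by residue number and ordered by smallest
member, so partitions are deterministic. A maximal-clique post-processor
(`community_cliques`) can re-express communities as small cliques, off
by default.

**Persistence.** Frame-level partitions are matched by greedy maximum
Jaccard matching (threshold **0.8**, one match per community per frame);
a community is persistent when present in strictly more than
`persistence` (default **0.75**) of the frames. The pipeline samples
`community_frames` (default **10**) evenly strided frames: partition
quality, not statistics, limits this — Girvan–Neumann on instantaneous
contact topologies is noisy because contacts near the cutoff flicker
frame to frame, and on the bundled benchmark frame partitions often
subdivide the planted blocks, so the persistent set can legitimately be
empty at the default noise level. The persistence rule itself is
exercised with constructed partition series in the tests.

## 5. Communication propensity and pathways

CPᵢ = 3⟨w₁(dᵢ−⟨dᵢ⟩)² + w₂(ΔpMᵢ−⟨ΔpMᵢ⟩)²⟩ in units of k_B T (T default
**300 K**; k_B T is factored out of the reported numbers). The two
variance channels mix Å² with score², so by default each deviation
channel is divided by its pooled across-residue RMS, making w₁/w₂
unitless mixing weights; `normalize=False` keeps raw units, in which
the w₂ = 0 limit equals 3·w₁·Var(dᵢ) identically. Spreads
indistinguishable from rounding noise are treated as zero so a rigid
ensemble scores exactly 0. `tune_weights` scans w₁ + w₂ = 1 in steps of
0.1, scores each candidate by the unweighted modularity of the weighted
Girvan–Newman partition of the mean-frame contact graph with pairwise
composite-fluctuation edge lengths (w₁·Var d_ij + w₂·Var ΔpM_ij,
channel-rescaled), and resolves ties toward larger w₁ — deterministic,
since the underlying construction the published tuning used is not
specified.

**Path ensembles.** In the default `frames` mode each frame contributes
the shortest source→sink route on its own contact topology with the
ensemble-level w lengths; ties are broken by fewer nodes, then the
lexicographically smallest sequence, so results are deterministic.
Occupancy is the fraction of connected frames in which a distinct
residue sequence is optimal (occupancies sum to 1); disconnection in
more than half the frames is an error with diagnostics. The `mean` mode
is a comparison estimator: Yen's k shortest paths on the mean-frame
graph with Boltzmann-like weights exp(−(L−L_min)) — a heuristic for
sensitivity checks, not a sampling claim. Because the graph is
undirected, forward and reverse runs on the same ensemble give the same
routes: direction specificity must come from the inputs (different
ensembles or endpoint pairs), never from the algorithm.

**Hops.** Consecutive path residues in different communities form a
hop; each hop reports the two communities, the residue pair, and both
residues' CP values. In the community-hopping picture these pairs are
the stepping stones of allosteric communication.

## 6. Synthetic benchmark

The generators are pure functions of their spec (seed included).

*Alignments*: background columns i.i.d. from the bundled background
frequencies (pairwise identity ≈ 6%, so clusters are singletons);
planted pairs copy a latent letter (uniform over 8 letters) with
probability `coupling` (default **0.9**); gaps injected at **0.05**.
A `reference` row (column consensus, or the structure sequence in the
paired fixture) makes the structure mapping exercise the real code path.

*Ensembles*: one pseudo-heavy-atom per residue (min heavy-atom distance
degenerates to Cα distance, keeping oracles closed-form; a multi-atom
generator exists for the distance oracles). Blocks are compact cubic-
lattice clusters (constant 3.1 Å, inside √2-shell contact range, so
interior beads touch up to 18 neighbors), joined by stalk beads so that
exactly the planted bridge pair is in cross-block contact (3.8 Å).
Within-block correlation is a scalar **breathing mode** — every member
moves along its fixed radial direction with a shared per-frame latent
(weight √rho, default **0.6**) — because a breathing mode carries no net
translation or rotation and therefore survives superposition, whereas
shared block translations would be aliased into spurious anti-
correlations between blocks by the global fit. Bridge pairs share a 3-D
latent (√bridge_rho, default **0.6**) on top of their block's breathing
share. Bead noise sd is **0.5 Å**/axis (Cα RMSF ≈ 0.7 Å, a typical
folded-protein magnitude). The optional corridor (default on in the
paired fixture) threads a contact chain from the first block's far
side through every bridge to the last block's far side, all sharing one
strong latent (√corridor_rho, default **0.85**), planting a unique
low-weight communication route with a known node sequence.

*Default scale*: 60 residues, 400 sequences, 500 frames — every
benchmark run completes in seconds to minutes on one CPU.

**What the fixture does not emulate.** Real side-chain packing and
contact-count normalization statistics, phylogenetic correlation between
sequences (the shuffle null is exact here but only approximate under
real phylogeny), anharmonic and multi-basin dynamics, and gap structure
correlated with structure. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted signal, not
performance on real MD ensembles of real families.

## 7. Numerical conventions and degenerate inputs

- MI in nats throughout; symmetric matrices stored dense with zero
  diagonals; flagged masks accompany every degenerate statistic.
- Distance-tie tolerance in path counting: 1e-9 relative; test graphs
  quantize weights to multiples of 0.25 so co-optimality is exact.
- Singular covariances in the Gaussian estimator receive a 1e-8 ridge
  and a flag.
- Fully gapped columns score KL 0 (flagged); isolated residues score
  pMI 0; empty neighborhoods are zeros, not NaNs.
- Errors are typed: input problems raise `InputError` subclasses (CLI
  exit code 1); anything else is an internal error (exit code 2).

## 8. Known limitations

- Betweenness and path counting are O(N³)-ish dense operations: fine to
  ~1,000 residues, not tuned for complexes beyond that.
- The Gaussian r_MI estimator underestimates strongly non-Gaussian
  coupling; the KSG option is slower and noisier at small frame counts.
- Frame-level community partitions are sensitive to contact flicker
  near the cutoff (see §4); persistent-community output should be read
  together with `community_frames` and the noise level of the input
  ensemble.
- The bundled contact-normalization table is computed from synthetic
  structures and is a placeholder for published per-residue-type values
  when analyzing real proteins.
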