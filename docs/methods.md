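# Methods

## Scope and model

psnkit analyzes a conformational ensemble (frames × atoms × 3, tied to a
reference structure) with the ensemble-network toolbox commonly applied to
kinase MD trajectories. All stages operate on plain in-memory arrays; the
pipeline composes them without hidden state, so every pipeline output
equals the corresponding stage function called directly.

### Force-constant rigidity profile

For residue *i*, the per-frame statistic d_i is the mean representative-atom
(default CA) distance to all residues *j* with |i−j| > `exclude_neighbors`
(default 1) within the same chain; inter-chain pairs always count. The
effective force constant is k_i = 3 k_B T / Var(d_i) with
k_B = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ and T = 300 K by default. Variances
below 10⁻⁶ Å² are capped and flagged rather than reported as divergent
constants. Two structural facts about this statistic matter for
interpretation: it is invariant under global rigid motion (distances
only), and it structurally rewards geometrically central residues —
displacing a residue whose neighbors surround it changes its mean distance
little, because gains and losses cancel. Interface and hinge residues
therefore peak in k profiles even at moderate planted amplitude; the
synthetic study accounts for this by planting the interface clamp as part
of the rigid core.

### Mobility and essential dynamics

RMSF and computed B-factors, B = (8π²/3)⟨Δr²⟩, are taken about the
ensemble mean structure and averaged over each residue's selected atoms
(default: extended backbone heavy set N, CA, CB, C, O; no CB for Gly).
PCA diagonalizes the covariance of mean-centered selected coordinates;
"lowest-frequency" modes are the largest-variance components (the standard
essential-dynamics identification), and mode mobility reconstructs
per-atom ⟨Δr²⟩ from the top `n_modes` (default 3) as Σ λ_m |v_m|².
Cross-correlations use CA displacement vectors by default
(`centroid` optional): C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩).

Superposition is a Kabsch least-squares fit over the same mask used for
PCA, applied per frame. The pipeline's `superpose: auto` skips the fit for
ensembles whose frames are already expressed in the reference frame (the
synthetic generator's output); fitting such an ensemble would absorb part
of the flexible module's coherent motion into the rigid-body parameters
and bias the measured correlations downward. `superpose: always` forces
the fit, and parsed multi-model PDB ensembles are always fitted.

### Network construction

I_ij = 100 n_ij / √(N_i N_j); n_ij counts side-chain heavy-atom pairs
within 4.5 Å between residues with |i−j| ≥ 2 (Gly/Ala use their backbone
atoms; ligand groups, e.g. a bound nucleotide, enter as single nodes over
all their heavy atoms). The normalization constants N_i ship as an
editable JSON table; types missing from the table fall back to the residue
heavy-atom count. Ensemble mode averages per-frame I matrices. Edges
exist where I_ij > I_min (strict; default 3.0 %) and carry
w_ij = −log(max(|C_ij|, 10⁻⁶)) with |C| clamped to 1; ligand nodes
without correlation data get a neutral |C| = 0.5.

### Centrality

All-pairs distances come from Floyd–Warshall on the dense weight matrix;
shortest-path counts are accumulated per source over the shortest-path
DAG, with ties recognized at relative tolerance 10⁻⁹ and zero-weight
edges floored at 10⁻¹² to keep path counting well defined. Closeness is
C(i) = (N_c−1)/Σ d(i,j) within each connected component (isolated nodes
get 0 and a flag); betweenness is normalized by (N−1)(N−2)/2. Note the
weighted closeness is not bounded by 1 when mean edge weights fall below
1; the [0, 1] bound holds for betweenness. Default ensemble centrality is
the mean of per-frame-block graph centralities (10 equal blocks with
block-averaged contacts); a consensus-graph mode is available.

### Communities, persistence, paths

Communities are k-clique percolation clusters (default k = 3, the
smallest clique size; configurable) of the unweighted edge set, via
maximal-clique enumeration. Persistence is scored community-level by
default: communities detected in each block graph are clustered by
Jaccard overlap ≥ 0.75 against the first-seen representative, persistence
is the fraction of blocks contributing a match, and "stable" means
persistence strictly above 0.75. An edge-level persistence table is
reported alongside. Allosteric paths run Dijkstra (and Yen's algorithm
for the bounded suboptimal ensemble) on the subgraph of edges with
|C_ij| ∈ [0.5, 1.0].

## The synthetic generator

The generator emulates the statistical structure the analysis assumes in
an MD ensemble: Gaussian fluctuations about a reference fold with a
planted covariance containing a low-variance rigid core, high-variance
flexible regions, and correlated residue modules forming persistent
contact communities.

* **Toy structures.** Ideal-geometry backbones (N, CA, CB, C, O; no CB
  for Gly) with consecutive CA–CA spacing 3.7–3.9 Å: `alpha_helix`,
  `extended`, and `two_domain`. The two-domain fold grows two compact
  self-avoiding globular domains (seeded, deterministic) on either side
  of a fixed interface clamp: a central bridge residue with two gateway
  contacts into each domain, designed so that the bridge is a cut vertex
  of the contact graph with numerically verified clearance (> 4.5 Å
  cross-side atom distances). Each build validates the planted network
  properties — gateway counts, cut-vertex separation, one dominant
  clique-percolation community per domain, strict betweenness maximum at
  the bridge — and regrows under a derived sub-seed if a random globule
  violates them.
* **Planted covariance.** Isotropic per-residue variance (scalar × I₃ per
  residue; anisotropy out of scope), within-module displacement
  correlation ρ, optional weak background correlation, and explicit
  cross-links (the bridge is correlated at 0.6 with both domains — the
  communication mediator should be dynamically coupled to what it
  mediates, and this also keeps its edges inside the 0.5–1.0 correlation
  filter). Positive semidefiniteness is checked to an eigenvalue floor of
  −10⁻¹⁰.
* **Sampling.** Exact multivariate-normal sampling via Cholesky; non-CA
  atoms displace rigidly with their CA, keeping contact topology nearly
  frame-invariant. One seeded generator per call; the seed is recorded in
  the ensemble metadata.
* **Contact flicker.** To exercise the persistence rule, a chosen module
  is expanded threefold about its centroid in a seeded fraction of frame
  blocks (default 40 % of 10 blocks), deleting its contacts there.

**Study conditions** (pipeline defaults): 50 residues, 5000 frames,
rigid core 0.05 Å² per coordinate, flexible bulk 0.5 Å², ρ = 0.8,
bridge correlation 0.6, T = 300 K, I_min = 3.0 %, hub degree ≥ 4,
k = 3, persistence threshold 0.75, correlation filter 0.5–1.0, RSA
thresholds 20 %/50 %. Analysis drivers and recovery checks use 1000–20000
frames depending on the Monte-Carlo precision each quantity needs (e.g.
20000 frames put the sampled top-3 PCA fraction within a fraction of a
percentage point of the planted spectrum; 10000 frames put sampled
correlations within ~0.01 of ρ).

**What the generator does not emulate:** anharmonicity, conformational
substates and transitions, solvent effects, side-chain repacking, and
time correlation — passing tests demonstrate correctness of the
estimators and graph algorithms on Gaussian ensembles with planted
structure, not fidelity of any MD protocol.

## Solvent accessibility and stabilization centers

SASA uses the Shrake–Rupley method (probe 1.4 Å, 960 sphere points per
atom). RSA = 100 · SASA / max-ASA with the theoretical maximum per
residue type shipped as an editable table; toy conformers can exceed
100 % and are capped at 200 % with a flag. Classes: buried < 20 %,
exposed > 50 %, intermediate otherwise. Stabilization-center detection is
deliberately simplified: a residue is flagged when it has at least 2
long-range contacts (heavy-atom pairs within 4.5 Å at sequence separation
≥ 10 or across chains) and hydropathy above 0 on the shipped
Kyte–Doolittle scale; the stabilization-center index and
sequence-conservation components of the full published procedure are not
reproduced, and outputs are marked `simplified`.

## Numerical choices and degenerate inputs

* Altlocs: blank/'A' (first) records kept; hydrogens and waters dropped.
* PDB round trips are coordinate-stable to the 0.001 Å format precision.
* Superposition rejects collinear reference masks (second singular value
  ≈ 0); cross-correlation rejects zero-fluctuation residues by name.
* Shortest-path tie tolerance 10⁻⁹ relative; all co-optimal paths count
  in betweenness.
* Pearson/Spearman profile correlations reject zero-variance profiles;
  the pipeline records the error instead of failing when a degenerate
  profile (e.g. an edgeless network's closeness) makes a scatter
  statistic undefined.
* Empty community lists, disconnected path queries and isolated nodes
  are results, not errors.

## Known limitations

* The mean-distance force constant conflates rigidity with geometric
  centrality (see above); comparisons between residues are meaningful
  within similar coordination environments.
* Clique percolation on dense graphs can be exponential; intended for
  residue-contact graphs, which are sparse.
* Betweenness via dense Floyd–Warshall is O(N³) memory-light but not
  intended for networks beyond a few thousand nodes.
* The choice of representative atom for distances and correlations (CA
  vs heavy-atom centroid) is exposed in the API because the convention
  differs between published force-constant analyses.
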