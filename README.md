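# psnkit

Ensemble-based structural-stability and protein-structure-network (PSN)
analysis of conformational ensembles, built for the kind of question that
arises in kinase allostery: which residues anchor the structurally stable
core of a fold, which ones act as communication bottlenecks between
domains, and how do interaction communities persist (or dissolve) across
an ensemble of conformations?

The package implements the full analysis chain that practitioners apply to
molecular-dynamics ensembles of protein kinases — force-constant rigidity
profiling, essential dynamics, weighted residue-interaction networks,
centrality and clique-percolation community analysis, and
correlation-filtered allosteric pathway reconstruction — together with a
synthetic-ensemble generator that plants known rigidity, correlation and
contact structure so every stage can be tested quantitatively without any
trajectory data.

## The quantities computed

**Force-constant profile.** For residue *i*, let *d_i* be the mean CA–CA
distance from *i* to all residues *j* with |i−j| > 1 in sequence
(immediate neighbors are excluded because those distances are nearly
constant). Over the ensemble,

    k_i = 3 k_B T / ⟨(d_i − ⟨d_i⟩)²⟩        [kcal mol⁻¹ Å⁻²]

so residues whose position relative to the rest of the protein barely
fluctuates get large effective spring constants. At T = 300 K,
k_B T = 0.5962 kcal/mol.

**Mobility and essential dynamics.** Per-residue RMSF and computed
B-factors, B = (8π²/3)⟨Δr²⟩, averaged over the extended backbone heavy
atoms (N, CA, CB, C, O); PCA of the mean-centered backbone coordinates
with "lowest-frequency" modes identified as the largest-variance principal
components; per-residue mobility reconstructed from the top three modes.

**Weighted residue network.** Residues *i*, *j* are connected when their
percentage interaction strength

    I_ij = 100 · n_ij / √(N_i N_j)

exceeds I_min = 3.0 %, where n_ij counts side-chain heavy-atom contacts
within 4.5 Å (Gly/Ala fall back to backbone atoms) and N_i is a
per-residue-type normalization constant shipped as an editable table.
Edges are weighted by the dynamic cross-correlation of the two residues,
w_ij = −log|C_ij|, so strongly correlated contacts are short.

**Centrality, hubs, communities, paths.** Normalized closeness
C(i) = (N−1)/Σ_j d(i,j) and normalized betweenness (fraction of all-pairs
weighted shortest paths through a node, Floyd–Warshall with explicit path
counting); local hubs at degree ≥ 4; k-clique percolation communities
(default k = 3) scored for persistence across frame-block networks, stable
when present in more than 75 % of blocks; optimal and suboptimal
communication paths restricted to edges with |C_ij| ∈ [0.5, 1.0].

## Worked example

The synthetic study system is a 50-residue, two-domain fold: two compact
globular domains joined by a single bridge residue clamped between two
gateway contacts per side. The planted covariance makes domain A plus the
interface clamp rigid (0.05 Å² per coordinate) and the far-domain bulk
flexible (0.5 Å²), with intra-domain correlation ρ = 0.8 and a bridge
correlated at 0.6 with both domains.

```
$ python analysis/01_build_system.py
built two_domain system: 50 residues, 250 atoms, 2000 frames
bridge residue index: 24, rigid core size: 29

$ python analysis/03_stability_profiles.py
mean k: rigid core 18.80, flexible bulk 9.81 kcal/mol/A^2
top decile of k: residues [24, 25, 26, 27, 28] (all in rigid core: True)

$ python analysis/04_network_communities.py
[steady] edges: 152, communities with persistence:
  n=21 persistence=1.00 stable=True
  n=19 persistence=1.00 stable=True
bridge residue A:ALA25 betweenness rank: 1 of 50
[flicker] ...
  n=19 persistence=0.60 stable=False

$ python analysis/05_allosteric_paths.py
optimal path A:ALA1 -> A:ALA50: L = 2.334
  A:ALA1 -> A:ALA14 -> A:ALA18 -> A:ALA23 -> A:ALA25 -> A:ALA27 -> ...
bridge A:ALA25 on path: True
```

Reading these numbers: the planted rigid core carries systematically
larger force constants than the flexible bulk and fills the top decile of
the k profile; each domain percolates into one large interaction community
that is fully persistent unless its contacts are deliberately flickered
(persistence drops to 0.60, below the 0.75 stability threshold); the
bridge residue attains the maximum normalized betweenness and every
optimal/suboptimal communication path between the domains funnels through
it — the planted analogue of a spine residue mediating inter-lobe
allosteric communication in a kinase.

The same pipeline runs from a config file via the CLI
(`psnkit all --config config.yaml --seed 1 --out results/run`), or on a
user-supplied multi-model PDB ensemble through `input_pdb`. Annotation
tables for the canonical functional regions of the ErbB-family kinase
domains (P-loop, catalytic Lys/Glu, gatekeeper, HRD/DFG motifs, P+1 loop,
R-spine) are packaged and served by `psnkit.functional_annotation`.

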