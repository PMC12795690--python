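# Methods

## Overview

`ppisurf` predicts whether two protein chains interact. Each chain is
represented as an oriented point cloud sampled from its molecular surface,
turned into a sparse connected geometric graph by a spherical convex hull
construction, processed by point-transformer attention layers, pooled per
chain, fused with a projected protein-language-model sequence embedding, and
classified by a small perceptron head with a sigmoid output.

## Surface model

A chain is a cloud of atoms `{a_k}` with elements drawn from a 22-symbol
vocabulary (H, Li, C, N, O, Na, Mg, P, S, K, Ca, Mn, Fe, Co, Ni, Cu, Zn, Se,
Sr, Cd, Cs, Hg). Atoms outside the vocabulary are dropped at parse time and
counted; heteroatoms and waters are excluded. The surface is the level set

    f(x) = -s · log Σ_k exp(-(‖x - a_k‖ - r_k)/s) = c

of a soft-min distance field over the atomic spheres, with per-element van
der Waals radii `r_k` (Bondi-style values), smoothing width `s`
(`smoothing_sigma`, default 1 Å) and offset `c` (`level_set_offset`, default
1.05 Å). Sampling scatters `seeds_per_atom` seed points around every atom
and moves them onto the level set by damped Newton steps along the field
gradient (`descent_steps` iterations, per-step displacement capped at
`descent_step_size`; points whose gradient nearly vanishes — near the medial
axis — take bounded steps and are discarded by the convergence test, and the
run aborts with diagnostics if more than half of all seeds fail). Converged
points are thinned so no two survivors are closer than `subsample_spacing`
(greedy grid-hash pass in deterministic seed order). Normals are the
normalized field gradient, hence unit length and outward.

For a single atom this reduces to a sphere of radius `r + c`, which the test
suite checks directly, and the normals are validated against a
central-finite-difference gradient of the field.

## Per-point features (32 = 22 + 10)

*Chemical (22).* Each surface point aggregates the one-hot element vectors
of its `k_chem = 16` nearest atoms with inverse-distance weights normalized
to sum to one. The learnable 22→22 linear map described for the network
input lives in the network module (it is part of the trainable encoder), so
the stored features are the pre-network mixture.

*Curvature (10).* At every scale σ ∈ {1, 2, 3, 5, 10} Å a weighted quadric
`w = a u² + b uv + c v² + d u + e v + f` is fit to neighbour offsets
expressed in the point's tangent frame, with Gaussian weights
`exp(-d²/(2σ²))` over up to 128 nearest neighbours. The local shape operator
is the negated Hessian of the fit, so convex regions (diverging normals)
have positive trace; its determinant and trace are stored per scale under
convention-neutral names (`curv_det_σ`, `curv_trace_σ`). On a sphere of
radius R this recovers det ≈ 1/R² and trace ≈ 2/R (checked within 15 % at
R = 5 Å, σ = 1 Å); on a plane both vanish. Points with fewer than six
usefully weighted neighbours at a scale get zero curvature there, with a
logged count. Both quantities are rigid-motion invariant to ≤ 1e-3, which
the suite verifies under random rotations and translations.

The fused per-point feature vector is the 22-wide chemical block followed by
the 10 curvature columns, width exactly 32.

## Graph construction

*Spherical convex hull (default).* Points are projected onto the unit sphere
centred at the cloud centroid; near-coincident projections (angular distance
< 1e-8 rad) are deduplicated keeping the point farthest from the centroid;
the 3-D convex hull of the projections is computed and each hull edge is
mapped back to the original point indices. Because the hull of points on a
sphere is a triangulated polyhedron, the graph is connected and has at most
3N − 6 undirected edges — no radius or neighbour count is needed. Edge
attributes are the Euclidean distance between the original points and the
interior dihedral angle between the two hull faces sharing the projected
edge (π − arccos(n̂₁·n̂₂) with outward face normals, in [0, π]). The edge set
is invariant to rigid motions and to uniform scaling about the centroid.
Fewer than four points fall back to the complete graph with a warning; a
degenerate coplanar configuration raises an error unless a seeded 1e-6 Å
jitter retry is requested.

*Baselines.* A radial-cutoff builder (edge iff 0 < d ≤ r) and a k-nearest-
neighbour builder (directed k-NN with ties broken by lower index, then
symmetrized by union). The comparison harness defaults to r ∈ {3, 10} Å and
k ∈ {8, 16}; r = 16 Å is available through explicit arguments.

All builders store both directions of every undirected edge because the
attention layer aggregates over in-neighbourhoods.

## Network

All tensors run on a compact reverse-mode automatic-differentiation core
written on numpy (float32 by default; float64 selectable per model and used
by the gradient-check and attention-oracle tests). Architecture, per chain:

1. *Node encoding*: `h⁰ = dropout(ReLU(LayerNorm(W_in x)))` with
   `W_in ∈ R^{32×H}` (no bias, so a zero feature row maps to zero at
   initialisation).
2. *Positional term*: a two-layer perceptron `h_Θ` of the displacement
   `p_i − p_j`; the pairwise values are reduced to a node-wise additive term
   by averaging over each node's in-neighbourhood (the order-invariant,
   scale-stable reduction; nodes without in-edges receive `h_Θ(0)`).
3. *Point-transformer layers* (default two, configurable 1–5): channel-wise
   vector attention over in-neighbourhoods with self-loops,
   `out_i = Σ_j α_ij ⊙ (W₃ h_j + δ_ij)`,
   `α_ij = softmax_j(γ_Θ(W₁ h_i − W₂ h_j + δ_ij))`, where `δ_ij` is a
   per-layer two-layer perceptron of `p_i − p_j` and `γ_Θ` a two-layer
   perceptron; each layer ends with ReLU and dropout. The vectorised
   implementation is tested to 1e-5 against a dense per-node loop on small
   graphs.
4. *Pooling*: arithmetic mean of final node embeddings per chain.
5. *Sequence branch*: the pooled 1024-wide sequence embedding of each chain
   is projected to H by a two-layer perceptron.
6. *Fusion and head*: `[g_L, g_R, s_L, s_R]` (2H wide without the sequence
   branch) through a perceptron `→ H → 1` and a sigmoid.

Ablation switches: drop the sequence branch, drop the positional term,
replace the attention stack by a per-node two-layer perceptron, vary depth.

Numerical choices: Glorot-uniform initialisation (seeded); the *output*
layers of both positional perceptrons start at 0.05× Glorot scale because
their inputs are displacements in Angstrom (up to ~20 Å on hull edges) and
would otherwise dominate the normalized feature embeddings at
initialisation, which at small sample sizes buries the chemical/curvature
signal. Dropout rate 0.2 everywhere, inert in evaluation mode. Softmax over
neighbourhoods is max-shifted per segment.

## Sequence embeddings

Providers sit behind one interface returning an (L, 1024) per-residue matrix
and its column mean. The `mock` provider — used by the entire test suite —
assigns each residue a deterministic seeded-hash vector: a letter-specific
base direction plus a half-scale letter-and-position perturbation, so
identical sequences always embed identically, pooled vectors carry
composition information, and nothing is downloaded. The `prostt5` adapter
targets the frozen ProstT5 encoder (half precision, batched) and raises a
provider-unavailable error naming the mock fallback when the external
weights or the `transformers` library are absent. Non-standard residues map
to X before embedding.

## Data pipeline

*Filters.* A dimer is admitted iff both sequence lengths are within
[35, 300] residues (bounds inclusive; the source text's "varies between" is
ambiguous and inclusive is the permissive reading) and the minimum
inter-chain residue distance is strictly below 8 Å, where the
residue-residue distance is the minimum over the atoms of the two residues
(equivalently the global inter-chain atom minimum). Negative pairs are drawn
uniformly from the chain pool excluding a user-supplied known-interaction
set (two-column TSV); no live database access.

*Synthetic complexes.* The generator emulates the dimer regime end to end so
the framework is testable without downloads. Each chain is a compact blob of
residues (centres dart-thrown in a ball at protein-like density, four atoms
per residue over N/C/O with occasional S). Positives receive geometric
complementarity scaled by `complementarity_strength`: a tapered convex spike
("boss", ~28·strength atoms reaching 2 + 5·strength Å) on the ligand
interface face and a concave pocket (radius 1.5 + 3.2·strength Å) carved
into the receptor face, plus — at `sequence_signal_strength` > 0 — a shared
sequence motif written into both chains. Negatives are independent blobs
placed in contact range without complementarity. At zero strengths the two
classes are exchangeable, which the null-signal tests exploit. Chains are
placed along a canonical +x interface axis with a random translation; no
random rotation is applied, because the network's positional pathways are
orientation-variant and desk-scale sample counts cannot marginalise over
orientations (the surface features themselves are orientation-invariant, so
this only removes nuisance, not signal). Labels follow a deterministic
interleaved allocation, so class balance is exact to rounding over any
prefix. Everything is deterministic in (spec seed, pair index).

Synthetic fixtures can be written out as PDB plus FASTA files (synthetic
poly-alanine-style ATOM records) so the real structure and sequence readers
are exercised end to end.

*What the generator does not emulate:* real secondary structure, chemistry
beyond element frequencies, evolutionary sequence signal, conformational
change between bound and unbound states, or the redundancy structure of
curated datasets. Passing tests therefore demonstrate that the pipeline is
wired correctly and can learn planted geometric/sequence signal — not that
the model reaches any particular accuracy on real complexes.

## Training and evaluation

Adam (lr 1e-4, batch size 32 pairs), binary cross-entropy on the sigmoid
output, up to 80 epochs with early stopping on validation loss (patience
15), best-validation weights restored; fully seeded and reproducible.
Thresholded metrics use decision threshold 0.5. AUROC is the Mann-Whitney
pair-counting statistic with half credit for ties (computed via average
ranks); AUPRC is the precision-recall step integral over distinct score
thresholds with no interpolation; both are reported as undefined on
single-class samples while thresholded metrics are still computed.
Cross-validation partitions the samples into k near-equal folds
(|size difference| ≤ 1), trains on k−1 (reserving a small tail for early
stopping) and evaluates the held-out fold, reporting per-fold records and
mean ± sd. The ablation harness evaluates one configuration per grid cell;
the graph-builder harness swaps only edge sets, never node features (the
suite checks feature hashes).

## Desk-scale problem sizes

Test and acceptance runs use sizes chosen for a single CPU: synthetic chains
of 35–50 residues, a coarse sampler (2 Å spacing, 6 seeds per atom, 30
descent steps → ~150–250 surface points per chain), hidden width 32,
12-epoch training for the learnability checks (400 pairs, full
geometric+sequence signal, median held-out AUROC over three seeds) and a
400-pair null run whose 200-pair test split keeps chance-level AUROC well
inside its band. The signal-monotonicity check trains the perceptron-block
configuration (hidden width 16, lr 1e-3, 30 epochs) on 300 pairs per
complementarity strength with the sequence signal off. The default
`SamplerConfig`/`ModelConfig`/`TrainConfig` values remain the full-scale
settings described above.

## Known limitations

- The level-set sampler exposes constants the cited construction does not
  pin down; all are configuration, and densities differ from mesh-based
  pipelines.
- Deduplicated coincident projections receive no hull edges; on real
  surfaces coincident projection directions are measure-zero.
- The attention implementation is single-head vector attention with flat
  layers; no down/up-sampling stages.
- The mock embedding is a determinism device, not a biological model; the
  external language-model adapter requires its own weights.
- Training at realistic corpus sizes (10⁴–10⁵ pairs) is out of desk-scale
  reach of the numpy backend; the architecture is faithful but the backend
  favours clarity and testability over throughput.
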