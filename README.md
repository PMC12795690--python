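# ppisurf

Protein–protein interaction (PPI) prediction from protein **surface point
clouds**, **spherical-convex-hull geometric graphs**, and **point-transformer
attention**, fused with protein-language-model sequence embeddings.

## Who this is for

Structural bioinformaticians who want a binary interacts / does-not-interact
classifier for pairs of protein chains that learns from surface geometry and
chemistry rather than residue-contact graphs alone — and anyone studying how
graph construction (radius cutoff, k-NN, or hull-based) affects geometric
deep learning on molecular surfaces.

## The model

Each chain is converted to an oriented point cloud `{x_i, n̂_i}` sampled from
the level set `f(x) = −s·log Σ_k exp(−(‖x−a_k‖−r_k)/s) = c` of a soft-min
distance field over its atoms. Every point carries a 32-wide feature vector:
a 22-channel chemical mixture (inverse-distance-weighted one-hot element
types over a 22-symbol vocabulary) concatenated with det(S) and trace(S) of
the local shape operator S at five scales σ ∈ {1, 2, 3, 5, 10} Å.

The cloud becomes a graph by the **spherical convex hull** construction:
project points onto the unit sphere about the centroid, take the 3-D convex
hull of the projections, and map hull edges back. The result is always
connected with |E| ≤ 3N − 6 undirected edges — no cutoff radius or neighbour
count to choose — with edge distance and hull dihedral attributes.

The network encodes node features (`h⁰ = dropout(ReLU(LayerNorm(W_in x)))`),
adds a learned positional term from inter-point displacements, applies
point-transformer layers

    out_i = Σ_{j∈N(i)} α_ij ⊙ (W₃ h_j + δ_ij),
    α_ij  = softmax_j( γ_Θ(W₁ h_i − W₂ h_j + δ_ij) ),   δ_ij = h_Θ(p_i − p_j),

mean-pools per chain, concatenates the two pooled vectors with two projected
1024-wide sequence embeddings, and emits an interaction probability through
a perceptron head with a sigmoid. Training is Adam (lr 1e-4, batch 32,
binary cross-entropy, ≤ 80 epochs, early stopping with patience 15). Radius
and k-NN graph builders, per-component ablation switches (sequence branch,
positional encoder, attention block, depth 1–5), 3-fold cross-validation,
and a builder-comparison harness are included. See `docs/methods.md` for the
full model description and design choices.

The whole network and trainer run on a compact numpy reverse-mode autodiff
core (`ppisurf.autodiff`) — no deep-learning framework required.

## Worked example

```python
from ppisurf import (SyntheticSpec, generate_dataset, ModelConfig,
                     TrainConfig, train, evaluate)

spec = SyntheticSpec(n_pairs=120, residues_per_chain=(35, 50),
                     complementarity_strength=1.0,
                     sequence_signal_strength=1.0, rng_seed=7)
data = generate_dataset(spec)          # 120 labelled synthetic dimers
s = data[0]
print(f"pair {s.id}: label={s.label}, "
      f"ligand surface {len(s.ligand_surface)} points, "
      f"graph {s.ligand_graph.num_undirected_edges} edges")

test, val, tr = data[:24], data[24:36], data[36:]
model, hist = train(ModelConfig(hidden_dim=32, rng_seed=0), tr, val,
                    TrainConfig(max_epochs=12, patience=12, rng_seed=0))
rec = evaluate(model, test)
print(f"held-out: accuracy={rec.accuracy:.3f} f1={rec.f1:.3f} "
      f"auroc={rec.auroc:.3f} auprc={rec.auprc:.3f}")
```

prints

```
pair synthetic-00000: label=0, ligand surface 189 points, graph 561 edges
held-out: accuracy=1.000 f1=1.000 auroc=1.000 auprc=1.000
```

The first line shows one generated complex: a negative pair whose ligand
surface has 189 oriented points and a hull graph with 561 undirected edges
(within the 3N = 567 sparsity bound). After twelve epochs on 84 training
pairs the model separates held-out positives from negatives perfectly —
expected here, because the generator plants both a geometric
(boss-into-pocket) and a sequence-motif signal at full strength.

For real structures, `read_structure` + `featurize` + `build_schull` produce
the same objects from PDB/mmCIF files, and the `ppisurf` command line
(`featurize`, `build-graphs`, `train`, `evaluate`, `cross-validate`,
`ablate`, `benchmark-graphs`) wraps the same functions.

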