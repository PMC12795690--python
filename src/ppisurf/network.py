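"""Pair-classification network over geometric surface graphs.

Architecture, per chain: a linear 32 -> H node encoding with LayerNorm, ReLU
and dropout; an additive positional term computed by a two-layer perceptron of
inter-point displacements averaged over each node's in-neighbourhood; a stack
of point-transformer layers (channel-wise vector attention whose logits
combine projected feature differences with a learned encoding of the
displacement p_i - p_j); and mean pooling per chain.  The two pooled chain
vectors are concatenated with two projected sequence embeddings and passed to
a small perceptron head with a sigmoid output.

Ablation switches: drop the sequence branch, drop the positional term, or
replace the attention stack with a plain two-layer perceptron on node
features; depth is configurable between one and five layers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import (Parameter, Tensor, concat, dropout, mlp2,
                       segment_sum, segment_softmax)
from .errors import ConfigurationError, ShapeError, ValidationError
from .graphs import GeometricGraph


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and ablation switches of the pair classifier."""

    hidden_dim: int = 64
    num_pt_layers: int = 2
    dropout: float = 0.2
    use_sequence: bool = True
    use_positional_encoder: bool = True
    use_pt_block: bool = True
    seq_embed_dim: int = 1024
    in_feature_dim: int = 32
    rng_seed: int = 0
    dtype: str = "float32"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def __post_init__(self):
        if np.dtype(self.dtype).kind != "f":
            raise ValidationError("dtype must be a floating type")
        if self.hidden_dim <= 0:
            raise ValidationError("hidden_dim must be positive")
        if not 1 <= self.num_pt_layers <= 5:
            raise ValidationError("num_pt_layers must be in [1, 5]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")


@dataclass
class BatchedGraphs:
    """Disjoint union of per-chain graphs with a chain id per node."""

    pos: np.ndarray           # (N, 3)
    x: np.ndarray             # (N, F)
    edge_index: np.ndarray    # (2, E)
    node_chain: np.ndarray    # (N,) int chain/graph membership
    n_chains: int

    @classmethod
    def from_graphs(cls, graphs: list[GeometricGraph]) -> "BatchedGraphs":
        pos, xs, edges, chain = [], [], [], []
        offset = 0
        for g_id, g in enumerate(graphs):
            n = g.num_nodes
            pos.append(g.pos)
            if g.x is None:
                raise ConfigurationError("graph has no node features")
            xs.append(g.x)
            edges.append(g.edge_index + offset)
            chain.append(np.full(n, g_id))
            offset += n
        return cls(np.concatenate(pos), np.concatenate(xs),
                   np.concatenate(edges, axis=1) if edges else np.zeros((2, 0), int),
                   np.concatenate(chain), len(graphs))


@dataclass
class PairBatch:
    """A minibatch of ligand/receptor chain graphs with sequence embeddings."""

    ligand: BatchedGraphs
    receptor: BatchedGraphs
    seq_ligand: np.ndarray    # (B, seq_embed_dim) pooled embeddings
    seq_receptor: np.ndarray
    labels: np.ndarray        # (B,) in {0, 1}
    ids: list = field(default_factory=list)

    def __post_init__(self):
        b = len(self.labels)
        if self.ligand.n_chains != b or self.receptor.n_chains != b:
            raise ConfigurationError("one graph per pair per side required")

    def __len__(self) -> int:
        return len(self.labels)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            dtype=np.float64) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dtype)


class PairClassifier:
    """Point-transformer pair classifier; parameters live in ``self.params``."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.dtype = cfg.np_dtype
        rng = np.random.default_rng(cfg.rng_seed)
        H, F, S = cfg.hidden_dim, cfg.in_feature_dim, cfg.seq_embed_dim
        p: dict[str, Parameter] = {}

        dt = self.dtype
        # positional branches emit displacements in Angstrom units; their
        # output layers start small so delta terms do not drown the
        # normalized feature embeddings at initialisation
        pos_out_scale = 0.05
        p["W_in"] = Parameter(_glorot(rng, F, H, dt))
        p["ln_gamma"] = Parameter(np.ones(H, dt))
        p["ln_beta"] = Parameter(np.zeros(H, dt))
        # global positional encoder h_theta: two linear layers 3 -> H -> H
        p["pe_W1"], p["pe_b1"] = Parameter(_glorot(rng, 3, H, dt)), Parameter(np.zeros(H, dt))
        p["pe_W2"] = Parameter(pos_out_scale * _glorot(rng, H, H, dt))
        p["pe_b2"] = Parameter(np.zeros(H, dt))
        if cfg.use_pt_block:
            for l in range(cfg.num_pt_layers):
                for name, shape in (("W1", (H, H)), ("W2", (H, H)), ("W3", (H, H))):
                    p[f"L{l}_{name}"] = Parameter(_glorot(rng, *shape, dt))
                p[f"L{l}_pos_W1"] = Parameter(_glorot(rng, 3, H, dt))
                p[f"L{l}_pos_b1"] = Parameter(np.zeros(H, dt))
                p[f"L{l}_pos_W2"] = Parameter(pos_out_scale * _glorot(rng, H, H, dt))
                p[f"L{l}_pos_b2"] = Parameter(np.zeros(H, dt))
                p[f"L{l}_att_W1"] = Parameter(_glorot(rng, H, H, dt))
                p[f"L{l}_att_b1"] = Parameter(np.zeros(H, dt))
                p[f"L{l}_att_W2"] = Parameter(_glorot(rng, H, H, dt))
                p[f"L{l}_att_b2"] = Parameter(np.zeros(H, dt))
        else:
            p["mlp_W1"], p["mlp_b1"] = Parameter(_glorot(rng, H, H, dt)), Parameter(np.zeros(H, dt))
            p["mlp_W2"], p["mlp_b2"] = Parameter(_glorot(rng, H, H, dt)), Parameter(np.zeros(H, dt))
        if cfg.use_sequence:
            p["seq_W1"], p["seq_b1"] = Parameter(_glorot(rng, S, H, dt)), Parameter(np.zeros(H, dt))
            p["seq_W2"], p["seq_b2"] = Parameter(_glorot(rng, H, H, dt)), Parameter(np.zeros(H, dt))
        head_in = 4 * H if cfg.use_sequence else 2 * H
        p["head_W1"], p["head_b1"] = Parameter(_glorot(rng, head_in, H, dt)), Parameter(np.zeros(H, dt))
        p["head_W2"], p["head_b2"] = Parameter(_glorot(rng, H, 1, dt)), Parameter(np.zeros(1, dt))

        self.params = p
        self.training = False
        self._rng = np.random.default_rng(cfg.rng_seed + 1)

    # -- bookkeeping ---------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=self.dtype)

    def save(self, weights_path, config_path=None) -> None:
        np.savez(weights_path, **self.state_dict())
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(asdict(self.cfg), fh, indent=2)

    @classmethod
    def load(cls, weights_path, config_path) -> "PairClassifier":
        with open(config_path) as fh:
            cfg = ModelConfig(**json.load(fh))
        model = cls(cfg)
        model.load_state_dict(dict(np.load(weights_path)))
        return model

    # -- building blocks -----------------------------------------------------
    def _layernorm(self, t: Tensor) -> Tensor:
        mu = t.mean(axis=-1, keepdims=True)
        cen = t - mu
        var = (cen * cen).mean(axis=-1, keepdims=True)
        return cen / (var + 1e-5).sqrt() * self.params["ln_gamma"] + self.params["ln_beta"]

    def encode_nodes(self, x) -> Tensor:
        """Initial node embedding: dropout(ReLU(LayerNorm(W_in x)))."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, self.dtype))
        if x.shape[-1] != self.cfg.in_feature_dim:
            raise ShapeError(
                f"node features have width {x.shape[-1]}, expected {self.cfg.in_feature_dim}")
        h = self._layernorm(x @ self.params["W_in"]).relu()
        return dropout(h, self.cfg.dropout, self._rng, self.training)

    def _pos_mlp(self, diff: Tensor, prefix: str) -> Tensor:
        p = self.params
        return mlp2(diff, p[f"{prefix}_W1"], p[f"{prefix}_b1"],
                    p[f"{prefix}_W2"], p[f"{prefix}_b2"])

    def positional_encoding(self, pos: np.ndarray, edge_index: np.ndarray) -> Tensor:
        """Node-wise positional term: mean over in-neighbours of h_theta(p_i - p_j).

        Nodes with no in-edges receive h_theta(0).
        """
        pos = np.asarray(pos, float)
        n = len(pos)
        src, dst = np.asarray(edge_index, int).reshape(2, -1)
        if len(src) == 0:
            zero = Tensor(np.zeros((1, 3), self.dtype))
            return self._pos_mlp(zero, "pe").gather_rows(np.zeros(n, int))
        diff = Tensor((pos[dst] - pos[src]).astype(self.dtype))  # p_i - p_j per edge (j -> i)
        delta = self._pos_mlp(diff, "pe")
        sums = segment_sum(delta, dst, n)
        counts = np.bincount(dst, minlength=n).astype(self.dtype)
        mean = sums / Tensor(np.maximum(counts, 1.0)[:, None])
        empty = counts == 0
        if empty.any():
            h0 = self._pos_mlp(Tensor(np.zeros((1, 3), self.dtype)), "pe")
            mean = mean + h0 * Tensor(empty[:, None].astype(self.dtype))
        return mean

    def pt_layer(self, h: Tensor, pos: np.ndarray, edge_index: np.ndarray,
                 layer: int = 0) -> Tensor:
        """One vector-attention layer.

        Over each node's in-neighbourhood (self-loop included), attention
        logits gamma(W1 h_i - W2 h_j + delta_ij) are softmax-normalized per
        channel and weight the messages W3 h_j + delta_ij, with
        delta_ij = h_theta(p_i - p_j); the aggregate passes through ReLU and
        dropout.
        """
        p = self.params
        pos = np.asarray(pos, float)
        n = h.shape[0]
        src, dst = np.asarray(edge_index, int).reshape(2, -1)
        loops = np.arange(n)
        src = np.concatenate([src, loops])
        dst = np.concatenate([dst, loops])

        delta = self._pos_mlp(Tensor((pos[dst] - pos[src]).astype(self.dtype)),
                              f"L{layer}_pos")
        q = (h @ p[f"L{layer}_W1"]).gather_rows(dst)
        k = (h @ p[f"L{layer}_W2"]).gather_rows(src)
        logits_in = q - k + delta
        logits = mlp2(logits_in, p[f"L{layer}_att_W1"], p[f"L{layer}_att_b1"],
                      p[f"L{layer}_att_W2"], p[f"L{layer}_att_b2"])
        alpha = segment_softmax(logits, dst, n)
        msg = alpha * ((h @ p[f"L{layer}_W3"]).gather_rows(src) + delta)
        out = segment_sum(msg, dst, n).relu()
        return dropout(out, self.cfg.dropout, self._rng, self.training)

    @staticmethod
    def pool_chain(h: Tensor, chain_ids: np.ndarray, n_chains: int | None = None) -> Tensor:
        """Arithmetic mean of node embeddings per chain."""
        chain_ids = np.asarray(chain_ids, int)
        n_chains = n_chains if n_chains is not None else int(chain_ids.max()) + 1
        counts = np.bincount(chain_ids, minlength=n_chains).astype(h.data.dtype)
        if np.any(counts == 0):
            raise ConfigurationError("cannot pool an empty chain")
        sums = segment_sum(h, chain_ids, n_chains)
        return sums / Tensor(counts[:, None])

    def project_sequence(self, s) -> Tensor:
        """Two-layer perceptron mapping a pooled sequence embedding to H."""
        if not self.cfg.use_sequence:
            raise ConfigurationError("sequence branch disabled in this configuration")
        s = s if isinstance(s, Tensor) else Tensor(np.atleast_2d(np.asarray(s, self.dtype)))
        if s.shape[-1] != self.cfg.seq_embed_dim:
            raise ShapeError(
                f"sequence embedding width {s.shape[-1]} != {self.cfg.seq_embed_dim}")
        p = self.params
        return mlp2(s, p["seq_W1"], p["seq_b1"], p["seq_W2"], p["seq_b2"])

    # -- full forward ----------------------------------------------------------
    def _encode_side(self, side: BatchedGraphs) -> Tensor:
        h = self.encode_nodes(side.x)
        if self.cfg.use_positional_encoder:
            h = h + self.positional_encoding(side.pos, side.edge_index)
        if self.cfg.use_pt_block:
            for l in range(self.cfg.num_pt_layers):
                h = self.pt_layer(h, side.pos, side.edge_index, layer=l)
        else:
            p = self.params
            h = mlp2(h, p["mlp_W1"], p["mlp_b1"], p["mlp_W2"], p["mlp_b2"])
            h = dropout(h.relu(), self.cfg.dropout, self._rng, self.training)
        return self.pool_chain(h, side.node_chain, side.n_chains)

    def forward_pair(self, batch: PairBatch) -> Tensor:
        """Interaction probability in (0, 1) for every pair in the batch."""
        gL = self._encode_side(batch.ligand)
        gR = self._encode_side(batch.receptor)
        parts = [gL, gR]
        if self.cfg.use_sequence:
            parts += [self.project_sequence(batch.seq_ligand),
                      self.project_sequence(batch.seq_receptor)]
        fused = concat(parts, axis=1)
        p = self.params
        logit = mlp2(fused, p["head_W1"], p["head_b1"], p["head_W2"], p["head_b2"])
        return logit.sigmoid().reshape(-1)

    __call__ = forward_pair
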