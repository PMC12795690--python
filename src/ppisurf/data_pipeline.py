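"""Pair assembly, filtering, negative sampling, splits, and synthetic complexes.

The synthetic-complex generator builds paired atom clouds that emulate the
dimer regime the model is trained on: two compact chains of 35-300 residues
placed so their interface atoms lie within the 8 Å contact threshold.
Positives carry geometric complementarity (a convex boss on the ligand facing
a concave pocket carved into the receptor) and, optionally, a shared sequence
motif; negatives are independent chains in contact range with no
complementarity.  At zero complementarity and zero sequence signal the two
classes are statistically identical, which the null-signal tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .embeddings import SequenceRecord
from .errors import (ParameterError, SamplingExhaustedError, ValidationError)
from .graphs import GeometricGraph, build_graph
from .surface import AtomCloud, SamplerConfig, SurfacePointCloud, featurize

#: Sequence-length bounds (inclusive) and residue contact threshold (strict).
MIN_SEQ_LEN = 35
MAX_SEQ_LEN = 300
CONTACT_DISTANCE = 8.0

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: Motif written into both chains of a positive pair when sequence signal > 0.
POSITIVE_MOTIF = "WCWHWCWH"

#: Coarse sampler used for desk-scale synthetic complexes.
SYNTHETIC_SAMPLER = SamplerConfig(seeds_per_atom=6, descent_steps=30,
                                  subsample_spacing=2.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of the synthetic dimer generator."""

    n_pairs: int
    positive_fraction: float = 0.5
    residues_per_chain: tuple[int, int] = (MIN_SEQ_LEN, MAX_SEQ_LEN)
    interface_contact_distance: float = CONTACT_DISTANCE
    complementarity_strength: float = 1.0
    sequence_signal_strength: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.residues_per_chain
        if not (MIN_SEQ_LEN <= lo <= hi <= MAX_SEQ_LEN):
            raise ValidationError(
                f"residues_per_chain must lie within [{MIN_SEQ_LEN}, {MAX_SEQ_LEN}]")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValidationError("positive_fraction must be in [0, 1]")
        if self.complementarity_strength < 0 or self.sequence_signal_strength < 0:
            raise ValidationError("signal strengths must be >= 0")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")


@dataclass
class PairSample:
    """One labelled ligand/receptor pair with all derived representations."""

    id: str
    label: int
    ligand_cloud: AtomCloud
    receptor_cloud: AtomCloud
    ligand_surface: SurfacePointCloud
    receptor_surface: SurfacePointCloud
    ligand_graph: GeometricGraph
    receptor_graph: GeometricGraph
    ligand_seq: SequenceRecord
    receptor_seq: SequenceRecord


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# Filters and negative sampling
# ---------------------------------------------------------------------------

def min_interchain_distance(a: AtomCloud, b: AtomCloud) -> float:
    """Minimum atom-atom distance between two chains (Å).

    Because the residue-residue distance is defined as the minimum over the
    atoms of the two residues, its minimum over residue pairs equals the
    global atom-level minimum.
    """
    tree = cKDTree(b.coords)
    d, _ = tree.query(a.coords, k=1)
    return float(np.min(d))


def filter_pair(ligand_cloud: AtomCloud, ligand_seq: SequenceRecord | None,
                receptor_cloud: AtomCloud, receptor_seq: SequenceRecord | None,
                contact_distance: float = CONTACT_DISTANCE) -> FilterDecision:
    """Dimer admission filter.

    Accept iff both sequence lengths are within [35, 300] (inclusive) and the
    minimum inter-chain residue distance is strictly below the contact
    threshold (8 Å by default).
    """
    if ligand_seq is None or receptor_seq is None:
        raise ValidationError("both chains need a sequence to be filtered")
    for seq in (ligand_seq, receptor_seq):
        if not MIN_SEQ_LEN <= len(seq) <= MAX_SEQ_LEN:
            return FilterDecision(False, "length-out-of-range")
    if min_interchain_distance(ligand_cloud, receptor_cloud) >= contact_distance:
        return FilterDecision(False, "no-contact")
    return FilterDecision(True, None)


def sample_negatives(pool: list, known_pairs, n: int, seed: int = 0) -> list[tuple]:
    """Draw n distinct unordered non-excluded, non-self pairs from `pool`."""
    if n < 0:
        raise ParameterError("n must be non-negative")
    excluded = {frozenset(p) for p in known_pairs}
    rng = np.random.default_rng(seed)
    m = len(pool)
    n_all = m * (m - 1) // 2
    if n_all <= 200_000:
        allowed = [(a, b) for a, b in combinations(pool, 2)
                   if frozenset((a, b)) not in excluded]
        if len(allowed) < n:
            raise SamplingExhaustedError(
                f"only {len(allowed)} admissible pairs exist, {n} requested")
        picks = rng.choice(len(allowed), size=n, replace=False)
        return [allowed[i] for i in picks]
    chosen: list[tuple] = []
    seen: set[frozenset] = set()
    for _ in range(50 * n + 1000):
        i, j = rng.choice(m, size=2, replace=False)
        key = frozenset((pool[i], pool[j]))
        if key in excluded or key in seen:
            continue
        seen.add(key)
        chosen.append((pool[i], pool[j]))
        if len(chosen) == n:
            return chosen
    raise SamplingExhaustedError(f"could not find {n} admissible pairs")


# ---------------------------------------------------------------------------
# Synthetic complexes
# ---------------------------------------------------------------------------

def _blob_atoms(rng: np.random.Generator, n_res: int) -> tuple[np.ndarray, list, np.ndarray]:
    """A compact globule: residue centres in a ball, 4 atoms per residue."""
    radius = 3.0 * n_res ** (1 / 3)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_res and tries < 300 * n_res:
        tries += 1
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * radius * rng.random() ** (1 / 3)
        if centers and np.min(np.linalg.norm(np.array(centers) - v, axis=1)) < 3.2:
            continue
        centers.append(v)
    while len(centers) < n_res:  # dense fallback; overlap acceptable
        v = rng.normal(size=3)
        centers.append(v / np.linalg.norm(v) * radius * rng.random() ** (1 / 3))
    coords, elements, resid = [], [], []
    base_elems = ("N", "C", "C", "O")
    for ri, c in enumerate(centers, start=1):
        offs = rng.normal(scale=0.8, size=(4, 3))
        for k in range(4):
            coords.append(c + offs[k])
            e = base_elems[k]
            if e == "C" and rng.random() < 0.05:
                e = "S"
            elements.append(e)
            resid.append(ri)
    return np.array(coords), elements, np.array(resid)


def _add_boss(rng, coords, elements, resid, strength: float):
    """Append a convex finger-like protrusion along +x (the interface axis).

    The boss is a tapered spike of residues whose size and reach scale with
    the complementarity strength, so it visibly reshapes the sampled surface
    (a ridge of high positive curvature) rather than vanishing into the blob.
    """
    n_boss = int(round(28 * strength))
    if n_boss == 0:
        return coords, elements, resid
    tip = coords[np.argmax(coords[:, 0])]
    length = 2.0 + 5.0 * strength
    ts = np.linspace(0.5, 0.5 + length, n_boss)
    taper = np.linspace(1.6, 0.5, n_boss)      # wide base, sharp tip
    extra = np.stack([
        tip + np.array([t, 0, 0]) + rng.normal(scale=1.0, size=3) * [0.25, w, w]
        for t, w in zip(ts, taper)])
    next_res = resid.max() + 1
    extra_res = next_res + np.arange(n_boss) // 4
    return (np.concatenate([coords, extra]),
            list(elements) + ["C"] * n_boss,
            np.concatenate([resid, extra_res]))


def _carve_pocket(rng, coords, elements, resid, strength: float):
    """Remove atoms around a point just inside the -x face, leaving a crater."""
    rc = 1.5 + 3.2 * strength
    if strength <= 0:
        return coords, elements, resid
    entry = coords[np.argmin(coords[:, 0])]
    center = entry + np.array([0.5 * rc, 0, 0])
    keep = np.linalg.norm(coords - center, axis=1) > rc
    if keep.sum() < 0.5 * len(coords):   # never hollow out most of the chain
        return coords, elements, resid
    coords, resid = coords[keep], resid[keep]
    elements = [e for e, k in zip(elements, keep) if k]
    # reindex residues consecutively from 1
    uniq = {r: i + 1 for i, r in enumerate(dict.fromkeys(resid))}
    resid = np.array([uniq[r] for r in resid])
    return coords, elements, resid


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _insert_motif(rng, seq: str, strength: float) -> str:
    copies = max(1, int(round(2 * strength)))
    s = list(seq)
    for _ in range(copies):
        if len(s) <= len(POSITIVE_MOTIF):
            break
        start = int(rng.integers(0, len(s) - len(POSITIVE_MOTIF)))
        s[start:start + len(POSITIVE_MOTIF)] = POSITIVE_MOTIF
    return "".join(s)


def _is_positive(index: int, spec: SyntheticSpec) -> bool:
    f = spec.positive_fraction
    return int(np.floor((index + 1) * f)) - int(np.floor(index * f)) == 1


def generate_synthetic_complex(spec: SyntheticSpec, index: int,
                               sampler_cfg: SamplerConfig | None = None,
                               graph_method: str = "schull",
                               **graph_kwargs) -> PairSample:
    """Build one deterministic labelled dimer (see module docstring).

    Deterministic in ``(spec.rng_seed, index)``; the positive/negative label
    follows a deterministic interleaved allocation so class balance over any
    prefix is exact to rounding.
    """
    rng = np.random.default_rng((spec.rng_seed * 1_000_003 + index * 7_919) % 2**31)
    label = 1 if _is_positive(index, spec) else 0
    lo, hi = spec.residues_per_chain
    c = spec.complementarity_strength if label == 1 else 0.0

    for _attempt in range(8):
        # margin so boss residues / pocket carving keep lengths in range
        n_lig = int(rng.integers(lo, max(lo, hi - 6) + 1))
        n_rec = int(rng.integers(min(lo + 8, hi), hi + 1))
        lc, le, lr = _blob_atoms(rng, n_lig)
        rc_, re_, rr = _blob_atoms(rng, n_rec)
        lc, le, lr = _add_boss(rng, lc, le, lr, c)
        rc_, re_, rr = _carve_pocket(rng, rc_, re_, rr, c)
        if MIN_SEQ_LEN <= lr.max() <= MAX_SEQ_LEN and MIN_SEQ_LEN <= rr.max() <= MAX_SEQ_LEN:
            break
    else:
        raise ValidationError("could not realise chain lengths within bounds")

    # place receptor beyond ligand along +x with a sub-threshold gap
    gap = float(rng.uniform(2.5, 6.0))
    if c > 0:
        boss_yz = lc[np.argmax(lc[:, 0])][1:]
        entry_yz = rc_[np.argmin(rc_[:, 0])][1:]
        rc_[:, 1:] += boss_yz - entry_yz
    shift = lc[:, 0].max() - rc_[:, 0].min() + gap
    rc_ = rc_ + np.array([shift, 0.0, 0.0])
    for _ in range(4):
        d = float(cKDTree(rc_).query(lc, k=1)[0].min())
        if abs(d - gap) < 0.3:
            break
        rc_ = rc_ + np.array([gap - d, 0.0, 0.0])

    # random translation of the assembled complex; the interface axis stays
    # canonical (+x), so the position-dependent network pathways do not have
    # to marginalise over arbitrary orientations at desk scale (the surface
    # features themselves are orientation invariant regardless)
    trans = rng.normal(scale=10.0, size=3)
    lc = lc + trans
    rc_ = rc_ + trans

    ligand = AtomCloud(lc, np.array(le, object), np.full(len(lc), "L", object), lr)
    receptor = AtomCloud(rc_, np.array(re_, object), np.full(len(rc_), "R", object), rr)

    seq_l = _random_sequence(rng, int(lr.max()))
    seq_r = _random_sequence(rng, int(rr.max()))
    if label == 1 and spec.sequence_signal_strength > 0:
        seq_l = _insert_motif(rng, seq_l, spec.sequence_signal_strength)
        seq_r = _insert_motif(rng, seq_r, spec.sequence_signal_strength)
    lig_seq = SequenceRecord(f"synthetic-{index:05d}-L", seq_l)
    rec_seq = SequenceRecord(f"synthetic-{index:05d}-R", seq_r)

    cfg = sampler_cfg or SYNTHETIC_SAMPLER
    samples = []
    for cloud in (ligand, receptor):
        scfg = replace(cfg, rng_seed=int(rng.integers(2**31)))
        surf = featurize(cloud, scfg)
        graph = build_graph(surf.points, graph_method,
                            node_features=surf.features, **graph_kwargs)
        samples.append((surf, graph))

    return PairSample(
        id=f"synthetic-{index:05d}", label=label,
        ligand_cloud=ligand, receptor_cloud=receptor,
        ligand_surface=samples[0][0], receptor_surface=samples[1][0],
        ligand_graph=samples[0][1], receptor_graph=samples[1][1],
        ligand_seq=lig_seq, receptor_seq=rec_seq,
    )


def generate_dataset(spec: SyntheticSpec, sampler_cfg: SamplerConfig | None = None,
                     graph_method: str = "schull", **graph_kwargs) -> list[PairSample]:
    """All ``spec.n_pairs`` synthetic pairs, deterministic in the spec seed."""
    return [generate_synthetic_complex(spec, i, sampler_cfg, graph_method, **graph_kwargs)
            for i in range(spec.n_pairs)]


# ---------------------------------------------------------------------------
# Splits and file interfaces
# ---------------------------------------------------------------------------

def make_splits(samples, k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, exhaustive, near-equal folds (size difference <= 1)."""
    n = len(samples)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def write_pair_files(sample: PairSample, out_dir) -> tuple[str, str]:
    """Emit a synthetic complex as a PDB file plus a FASTA file.

    These files are synthetic fixtures; atoms are written as ATOM records of
    poly-alanine-style residues so the structure readers parse them end to end.
    """
    import gemmi
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = gemmi.Structure()
    st.name = sample.id
    model = gemmi.Model("1")
    for cloud in (sample.ligand_cloud, sample.receptor_cloud):
        chain = gemmi.Chain(str(cloud.chain_id[0]))
        for ri in np.unique(cloud.residue_index):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(ri), " ")
            res.het_flag = "A"
            mask = cloud.residue_index == ri
            for j, (xyz, el) in enumerate(zip(cloud.coords[mask], cloud.elements[mask])):
                atom = gemmi.Atom()
                atom.name = f"{el}{j + 1}"
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    pdb_path = out_dir / f"{sample.id}.pdb"
    st.setup_entities()
    st.write_pdb(str(pdb_path))

    fasta_path = out_dir / f"{sample.id}.fasta"
    with open(fasta_path, "w") as fh:
        for rec in (sample.ligand_seq, sample.receptor_seq):
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    return str(pdb_path), str(fasta_path)


def load_pair_list(path):
    """Read a pair list CSV with columns id_ligand, id_receptor, label."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id_ligand", "id_receptor", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pair list must have columns {sorted(required)}")
    return df


def load_exclusion_set(path) -> set[frozenset]:
    """Read a two-column TSV of known interacting pairs (the exclusion set)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return {frozenset((a, b)) for a, b in zip(df["a"], df["b"])}
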