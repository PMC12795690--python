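"""Oriented molecular-surface point clouds with chemical and curvature features.

A protein chain is represented first as a cloud of atoms (coordinates plus a
22-symbol element vocabulary), then as an oriented point cloud sampled from a
smooth level set of a soft-min distance field over the atoms.  Each surface
point carries a unit outward normal, a 22-channel chemical vector (inverse
distance weighted one-hot element types of its nearest atoms) and mean/Gaussian
type curvature summaries at five spatial scales, fused into a 32-wide feature
vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    DegenerateChainError,
    FormatError,
    SamplingFailureError,
    ShapeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Element vocabulary of the chemical one-hot encoding (22 symbols).
ELEMENT_VOCAB: tuple[str, ...] = (
    "H", "Li", "C", "N", "O", "Na", "Mg", "P", "S", "K", "Ca",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Sr", "Cd", "Cs", "Hg",
)
ELEMENT_INDEX = {sym: i for i, sym in enumerate(ELEMENT_VOCAB)}

#: Van der Waals radii in Angstrom for the vocabulary (Bondi-style values).
DEFAULT_ATOM_RADII: dict[str, float] = {
    "H": 1.10, "Li": 1.81, "C": 1.70, "N": 1.55, "O": 1.52, "Na": 2.27,
    "Mg": 1.73, "P": 1.80, "S": 1.80, "K": 2.75, "Ca": 2.31, "Mn": 2.05,
    "Fe": 2.05, "Co": 2.00, "Ni": 1.97, "Cu": 1.96, "Zn": 2.01, "Se": 1.90,
    "Sr": 2.49, "Cd": 2.18, "Cs": 3.43, "Hg": 2.05,
}

#: Curvature estimation scales in Angstrom (Gaussian window widths).
DEFAULT_CURVATURE_SCALES: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 10.0)

#: Convergence tolerance (Å) for the level-set descent.
LEVEL_SET_TOL = 1e-2

#: Default number of nearest atoms aggregated into the chemical vector.
DEFAULT_K_CHEM = 16


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the on-the-fly surface sampler.

    All lengths are in Angstrom.  ``level_set_offset`` is the distance of the
    sampled iso-surface outside the soft union of atomic spheres;
    ``smoothing_sigma`` controls how softly neighbouring atoms blend.
    """

    atom_radius_map: dict = field(default_factory=lambda: dict(DEFAULT_ATOM_RADII))
    level_set_offset: float = 1.05
    seeds_per_atom: int = 20
    descent_steps: int = 50
    descent_step_size: float = 0.5
    subsample_spacing: float = 1.0
    smoothing_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("level_set_offset", "descent_steps", "descent_step_size",
                     "subsample_spacing", "smoothing_sigma"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"SamplerConfig.{name} must be positive")
        if self.seeds_per_atom < 1:
            raise ValidationError("SamplerConfig.seeds_per_atom must be >= 1")


@dataclass
class AtomCloud:
    """Atom coordinates with element, chain and residue annotations."""

    coords: np.ndarray          # (A, 3) float, Å
    elements: np.ndarray        # (A,) str, members of ELEMENT_VOCAB
    chain_id: np.ndarray        # (A,) str
    residue_index: np.ndarray   # (A,) int
    dropped_atoms: int = 0      # out-of-vocabulary atoms removed at parse time

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("AtomCloud coordinates must be finite")
        bad = [e for e in self.elements if e not in ELEMENT_INDEX]
        if bad:
            raise ValidationError(f"elements outside the vocabulary: {sorted(set(bad))}")
        n = len(self.coords)
        if not (len(self.elements) == len(self.chain_id) == len(self.residue_index) == n):
            raise ShapeError("AtomCloud fields must have equal length")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def for_chain(self, chain: str) -> "AtomCloud":
        mask = self.chain_id == chain
        return AtomCloud(self.coords[mask], self.elements[mask],
                         self.chain_id[mask], self.residue_index[mask])

    def element_onehot(self) -> np.ndarray:
        """(A, 22) one-hot element encoding."""
        out = np.zeros((len(self), len(ELEMENT_VOCAB)))
        idx = np.array([ELEMENT_INDEX[e] for e in self.elements])
        out[np.arange(len(self)), idx] = 1.0
        return out

    # -- tabular round-trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2],
            "element": self.elements, "chain_id": self.chain_id,
            "residue_index": self.residue_index,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtomCloud":
        return cls(df[["x", "y", "z"]].to_numpy(float),
                   df["element"].to_numpy(object),
                   df["chain_id"].to_numpy(object),
                   df["residue_index"].to_numpy(int))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AtomCloud":
        return cls.from_frame(pd.read_csv(path, sep="\t",
                                          dtype={"element": str, "chain_id": str}))


@dataclass
class SurfacePointCloud:
    """Oriented surface points with fused 32-dim chemical+curvature features."""

    points: np.ndarray    # (N, 3) Å
    normals: np.ndarray   # (N, 3) unit vectors
    chem: np.ndarray      # (N, 22)
    curv: np.ndarray      # (N, 10): det then trace for each scale

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValidationError("SurfacePointCloud must contain at least one point")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValidationError("normals must be unit length to 1e-6")
        if self.chem.shape[1] != len(ELEMENT_VOCAB):
            raise ShapeError("chem must have 22 columns")

    @property
    def features(self) -> np.ndarray:
        """Fused per-point features: chem (22) followed by curvature columns."""
        return np.concatenate([self.chem, self.curv], axis=1)

    def __len__(self) -> int:
        return len(self.points)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
                "nx": self.normals[:, 0], "ny": self.normals[:, 1], "nz": self.normals[:, 2]}
        feats = self.features
        for j in range(feats.shape[1]):
            cols[f"f{j}"] = feats[:, j]
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurfacePointCloud":
        df = pd.read_csv(path, sep="\t")
        fcols = [c for c in df.columns if c.startswith("f")]
        feats = df[fcols].to_numpy(float)
        return cls(df[["x", "y", "z"]].to_numpy(float),
                   df[["nx", "ny", "nz"]].to_numpy(float),
                   feats[:, :22], feats[:, 22:])

    def to_npz(self, path) -> None:
        np.savez(path, points=self.points, normals=self.normals,
                 chem=self.chem, curv=self.curv)

    @classmethod
    def from_npz(cls, path) -> "SurfacePointCloud":
        d = np.load(path)
        return cls(d["points"], d["normals"], d["chem"], d["curv"])


# ---------------------------------------------------------------------------
# Structure parsing
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str = "pdb", min_chain_atoms: int = 4) -> AtomCloud:
    """Parse a PDB or mmCIF file into an :class:`AtomCloud`.

    Waters and heteroatoms are excluded; atoms whose element symbol is outside
    the 22-symbol vocabulary are dropped and counted in
    ``AtomCloud.dropped_atoms``.  A chain that retains fewer than
    ``min_chain_atoms`` atoms raises :class:`DegenerateChainError`.
    """
    import gemmi

    fmt = fmt.lower()
    if fmt not in ("pdb", "mmcif"):
        from .errors import ParameterError
        raise ParameterError(f"unknown structure format {fmt!r} (use 'pdb' or 'mmcif')")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()

    coords, elements, chains, resids = [], [], [], []
    dropped = 0
    for model in st:
        for chain in model:
            for res in chain:
                if res.is_water() or res.het_flag == "H":
                    continue
                for atom in res:
                    sym = atom.element.name
                    if sym not in ELEMENT_INDEX:
                        dropped += 1
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(sym)
                    chains.append(chain.name)
                    resids.append(res.seqid.num)
        break  # first model only
    if not coords:
        raise FormatError(f"no atoms retained from {path}")
    if dropped:
        logger.info("read_structure: dropped %d out-of-vocabulary atoms", dropped)
    cloud = AtomCloud(np.array(coords), np.array(elements, object),
                      np.array(chains, object), np.array(resids),
                      dropped_atoms=dropped)
    for ch in cloud.chains:
        n = int(np.sum(cloud.chain_id == ch))
        if n < min_chain_atoms:
            raise DegenerateChainError(ch, n, min_chain_atoms)
    return cloud


# ---------------------------------------------------------------------------
# Level-set surface sampling
# ---------------------------------------------------------------------------

def _soft_distance(x: np.ndarray, atoms: np.ndarray, radii: np.ndarray,
                   sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Soft-min signed distance to the union of atomic spheres and its gradient.

    f(x) = -sigma * log sum_k exp(-(|x - a_k| - r_k) / sigma); the gradient is
    the softmax-weighted average of the unit vectors away from each atom.
    Evaluates in chunks so the (points x atoms) matrix stays bounded.
    """
    x = np.atleast_2d(x)
    n = len(x)
    f = np.empty(n)
    g = np.empty((n, 3))
    chunk = max(1, int(5e6 / max(len(atoms), 1)))
    for lo in range(0, n, chunk):
        xs = x[lo:lo + chunk]
        diff = xs[:, None, :] - atoms[None, :, :]           # (c, A, 3)
        dist = np.sqrt(np.einsum("cad,cad->ca", diff, diff))  # (c, A)
        u = -(dist - radii[None, :]) / sigma
        m = u.max(axis=1, keepdims=True)
        e = np.exp(u - m)
        z = e.sum(axis=1, keepdims=True)
        f[lo:lo + chunk] = (-sigma * (np.log(z) + m)).ravel()
        w = e / z                                           # softmax weights
        unit = diff / np.maximum(dist, 1e-12)[:, :, None]
        g[lo:lo + chunk] = np.einsum("ca,cad->cd", w, unit)
    return f, g


def sample_surface(cloud: AtomCloud, cfg: SamplerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample an oriented point cloud on the level set f(x) = level_set_offset.

    Seeds are scattered around every atom and moved onto the iso-surface by
    damped Newton steps along the field gradient.  Converged points are
    subsampled so no two survivors are closer than ``subsample_spacing``;
    normals are the normalized field gradient.  Deterministic in
    ``cfg.rng_seed``.
    """
    if len(cloud) < 1:
        raise DegenerateChainError(str(cloud.chains), len(cloud), 1)
    atoms = cloud.coords
    radii = np.array([cfg.atom_radius_map[e] for e in cloud.elements])
    rng = np.random.default_rng(cfg.rng_seed)

    n_seeds = len(atoms) * cfg.seeds_per_atom
    dirs = rng.normal(size=(n_seeds, 3))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    base = np.repeat(atoms, cfg.seeds_per_atom, axis=0)
    r0 = np.repeat(radii, cfg.seeds_per_atom) + cfg.level_set_offset
    x = base + dirs * (r0 * (1.0 + 0.2 * rng.random(n_seeds)))[:, None]

    target = cfg.level_set_offset
    active = np.arange(n_seeds)
    for _ in range(cfg.descent_steps):
        if active.size == 0:
            break
        f, g = _soft_distance(x[active], atoms, radii, cfg.smoothing_sigma)
        resid = f - target
        keep = np.abs(resid) >= 0.1 * LEVEL_SET_TOL
        # damped Newton; |grad| <= 1 for this field, and points near the
        # medial axis (tiny gradient) take bounded steps and simply fail the
        # convergence check instead of diverging
        gn = np.maximum(np.einsum("nd,nd->n", g, g), 0.04)
        step = np.clip(resid, -cfg.descent_step_size, cfg.descent_step_size)
        x[active[keep]] -= ((step / gn)[:, None] * g)[keep]
        active = active[keep]

    f, g = _soft_distance(x, atoms, radii, cfg.smoothing_sigma)
    ok = np.abs(f - target) <= LEVEL_SET_TOL
    if ok.sum() < 0.5 * n_seeds:
        raise SamplingFailureError(
            f"level-set descent converged for only {int(ok.sum())}/{n_seeds} seeds",
            diagnostics={"converged": int(ok.sum()), "seeds": n_seeds,
                         "residual_median": float(np.median(np.abs(f - target)))},
        )
    x, g = x[ok], g[ok]

    keep = _poisson_subsample(x, cfg.subsample_spacing)
    x, g = x[keep], g[keep]
    normals = g / np.linalg.norm(g, axis=1, keepdims=True)
    return x, normals


def _poisson_subsample(points: np.ndarray, spacing: float) -> np.ndarray:
    """Greedy deterministic subsampling: keep a point iff no kept point is
    within ``spacing``.  Points are visited in input order via a grid hash."""
    cell = spacing
    grid: dict[tuple[int, int, int], list[int]] = {}
    kept: list[int] = []
    keys = np.floor(points / cell).astype(int)
    sp2 = spacing * spacing
    for i, (p, key) in enumerate(zip(points, map(tuple, keys))):
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = points[j] - p
                        if d @ d < sp2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(key, []).append(i)
            kept.append(i)
    return np.array(kept, dtype=int)


# ---------------------------------------------------------------------------
# Per-point features
# ---------------------------------------------------------------------------

def compute_chemical_features(points: np.ndarray, cloud: AtomCloud,
                              k_chem: int = DEFAULT_K_CHEM) -> np.ndarray:
    """Inverse-distance-weighted one-hot element mix of each point's nearest atoms.

    Rows sum to one.  The learnable 22->22 map of the network is applied
    downstream; this is the pre-network chemical vector.
    """
    k = min(k_chem, len(cloud))
    tree = cKDTree(cloud.coords)
    dist, idx = tree.query(points, k=k)
    dist = dist.reshape(len(points), k)
    idx = idx.reshape(len(points), k)
    w = 1.0 / np.maximum(dist, 1e-6)
    w /= w.sum(axis=1, keepdims=True)
    elem_idx = np.array([ELEMENT_INDEX[e] for e in cloud.elements])
    out = np.zeros((len(points), len(ELEMENT_VOCAB)))
    rows = np.repeat(np.arange(len(points)), k)
    np.add.at(out, (rows, elem_idx[idx].ravel()), w.ravel())
    return out


def _tangent_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pair (e1, e2) for each unit normal."""
    n = normals
    ref = np.zeros_like(n)
    smallest = np.argmin(np.abs(n), axis=1)
    ref[np.arange(len(n)), smallest] = 1.0
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    return e1, e2


def compute_curvatures(points: np.ndarray, normals: np.ndarray,
                       scales=DEFAULT_CURVATURE_SCALES,
                       max_neighbors: int = 128) -> np.ndarray:
    """det and trace of the local shape operator at each scale.

    At each point a weighted quadric w = a u^2 + b uv + c v^2 + d u + e v + f
    is fit to neighbour offsets in the tangent frame, with Gaussian weights
    exp(-|x_j - x_i|^2 / (2 sigma^2)).  The 2x2 shape operator is the negated
    Hessian of the fit, so convex regions (normals diverging) have positive
    trace.  Output columns: det at every scale, then trace at every scale.
    Points with fewer than 6 usefully weighted neighbours at a scale get zero
    curvature there (counted in the log).
    """
    scales = list(scales)
    if len(scales) < 1:
        raise ValidationError("at least one curvature scale required")
    N = len(points)
    k = min(max_neighbors, N)
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k)
    dist = dist.reshape(N, k)
    idx = idx.reshape(N, k)

    e1, e2 = _tangent_basis(normals)
    rel = points[idx] - points[:, None, :]                 # (N, k, 3)
    u = np.einsum("nkd,nd->nk", rel, e1)
    v = np.einsum("nkd,nd->nk", rel, e2)
    w_h = np.einsum("nkd,nd->nk", rel, normals)            # heights

    dets = np.empty((N, len(scales)))
    traces = np.empty((N, len(scales)))
    starved = 0
    # design matrix rows: [u^2, uv, v^2, u, v, 1]
    A = np.stack([u * u, u * v, v * v, u, v, np.ones_like(u)], axis=2)  # (N,k,6)
    for s, sigma in enumerate(scales):
        wgt = np.exp(-dist**2 / (2.0 * sigma * sigma))     # (N, k)
        usable = (wgt >= 1e-3).sum(axis=1)
        Aw = A * wgt[:, :, None]
        G = np.einsum("nki,nkj->nij", Aw, A)               # (N,6,6)
        b = np.einsum("nki,nk->ni", Aw, w_h)
        G += 1e-10 * np.eye(6)[None]
        try:
            coef = np.linalg.solve(G, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coef = np.stack([np.linalg.lstsq(Gi, bi, rcond=None)[0]
                             for Gi, bi in zip(G, b)])
        a_, b_, c_ = coef[:, 0], coef[:, 1], coef[:, 2]
        # S = -Hess(w): [[ -2a, -b ], [ -b, -2c ]]
        tr = -2.0 * (a_ + c_)
        de = 4.0 * a_ * c_ - b_ * b_
        bad = usable < 6
        starved += int(bad.sum())
        tr[bad] = 0.0
        de[bad] = 0.0
        dets[:, s] = de
        traces[:, s] = tr
    if starved:
        logger.info("compute_curvatures: %d point-scale fits starved of neighbors", starved)
    return np.concatenate([dets, traces], axis=1)


def featurize(cloud: AtomCloud, cfg: SamplerConfig | None = None,
              scales=DEFAULT_CURVATURE_SCALES,
              k_chem: int = DEFAULT_K_CHEM) -> SurfacePointCloud:
    """Full pipeline: sample the surface and attach chemical + curvature features."""
    cfg = cfg or SamplerConfig()
    points, normals = sample_surface(cloud, cfg)
    chem = compute_chemical_features(points, cloud, k_chem=k_chem)
    curv = compute_curvatures(points, normals, scales=scales)
    return SurfacePointCloud(points, normals, chem, curv)
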