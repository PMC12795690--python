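"""Shared fixtures: hand-written structure files and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ppisurf.data_pipeline import SyntheticSpec, generate_dataset
from ppisurf.surface import AtomCloud


def pdb_atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
                  xyz, element: str) -> str:
    """One fixed-width ATOM record."""
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def write_pdb(path, lines: list[str]) -> str:
    path.write_text("\n".join(lines) + "\nEND\n")
    return str(path)


@pytest.fixture
def three_atom_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "C1", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
        pdb_atom_line(2, "N1", "ALA", "A", 1, (1.5, 0.0, 0.0), "N"),
        pdb_atom_line(3, "O1", "ALA", "A", 1, (0.0, 1.5, 0.0), "O"),
    ]
    return write_pdb(tmp_path / "three.pdb", lines)


@pytest.fixture
def oov_pdb(tmp_path):
    """Three atoms, one of an element outside the 22-symbol vocabulary."""
    lines = [
        pdb_atom_line(1, "C1", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
        pdb_atom_line(2, "N1", "ALA", "A", 1, (1.5, 0.0, 0.0), "N"),
        pdb_atom_line(3, "X1", "ALA", "A", 1, (0.0, 1.5, 0.0), "X"),
    ]
    return write_pdb(tmp_path / "oov.pdb", lines)


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for chain, offset in (("A", 0.0), ("B", 6.0)):
        for r in range(1, 3):
            for k, el in enumerate(("N", "C", "C", "O")):
                xyz = (offset + 1.2 * k, 1.5 * r, 0.3 * k)
                lines.append(pdb_atom_line(serial, f"{el}{k}", "GLY", chain, r, xyz, el))
                serial += 1
    return write_pdb(tmp_path / "two_chain.pdb", lines)


def make_cloud(coords, elements=None, chain="A", start_res=1) -> AtomCloud:
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    elements = elements or ["C"] * n
    return AtomCloud(coords, np.array(elements, object),
                     np.array([chain] * n, object),
                     np.arange(start_res, start_res + n))


@pytest.fixture(scope="session")
def small_dataset():
    """Thirty-two small synthetic pairs shared across pipeline/training tests."""
    spec = SyntheticSpec(n_pairs=32, residues_per_chain=(35, 45), rng_seed=1234)
    return generate_dataset(spec)
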