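"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from crossbeta import (
    Structure,
    build_hexamer_topology,
    build_ideal_zipper,
)
from crossbeta.pdbio import Atom
from crossbeta.synthetic import ZipperGeometry


@pytest.fixture
def hexamer_topology():
    return build_hexamer_topology()


@pytest.fixture
def ideal_hexamer():
    return build_ideal_zipper(ZipperGeometry(), None)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def quaternion_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """Kearsley quaternion oracle for the optimal-superposition RMSD.

    Builds the 4x4 symmetric key matrix from coordinate sums and
    differences; its smallest eigenvalue lambda gives
    RMSD = sqrt(lambda / N).  Entirely independent of the SVD route.
    """
    q = np.asarray(reference, float)
    p = np.asarray(mobile, float)
    q = q - q.mean(axis=0)
    p = p - p.mean(axis=0)
    d = p - q
    s = p + q
    dx, dy, dz = d.T
    sx, sy, sz = s.T
    m = np.empty((4, 4))
    m[0, 0] = np.sum(dx**2 + dy**2 + dz**2)
    m[0, 1] = m[1, 0] = np.sum(sy * dz - sz * dy)
    m[0, 2] = m[2, 0] = np.sum(sz * dx - sx * dz)
    m[0, 3] = m[3, 0] = np.sum(sx * dy - sy * dx)
    m[1, 1] = np.sum(sy**2 + sz**2 + dx**2)
    m[1, 2] = m[2, 1] = np.sum(dx * dy - sx * sy)
    m[1, 3] = m[3, 1] = np.sum(dx * dz - sx * sz)
    m[2, 2] = np.sum(sx**2 + sz**2 + dy**2)
    m[2, 3] = m[3, 2] = np.sum(dy * dz - sy * sz)
    m[3, 3] = np.sum(sx**2 + sy**2 + dz**2)
    lam = np.linalg.eigvalsh(m)[0]
    return float(np.sqrt(max(lam, 0.0) / len(q)))


def brute_force_hbonds(structure: Structure, cutoff: float = 3.5) -> set:
    """All-pairs N/O pairs from different chains closer than cutoff."""
    found = set()
    atoms = structure.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if a.element.upper() not in ("N", "O") or b.element.upper() not in ("N", "O"):
                continue
            if a.chain_id == b.chain_id:
                continue
            if np.linalg.norm(a.coords - b.coords) < cutoff:
                key = tuple(
                    sorted(
                        [
                            (a.chain_id, a.residue_position, a.name),
                            (b.chain_id, b.residue_position, b.name),
                        ]
                    )
                )
                found.add(key)
    return found


def brute_force_sidechain_com(structure: Structure, chain: str, pos: int) -> np.ndarray:
    """Plain-loop mass-weighted mean over heavy non-backbone atoms."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    total = np.zeros(3)
    mass = 0.0
    ca = None
    for a in structure.atoms:
        if a.chain_id != chain or a.residue_position != pos:
            continue
        if a.name == "CA":
            ca = a.coords
        if a.name in backbone or a.element.upper() == "H":
            continue
        total += a.mass * a.coords
        mass += a.mass
    if mass == 0.0:
        return np.array(ca)
    return total / mass


def brute_force_contacts(structure: Structure, cutoff: float = 6.5) -> set:
    """All nonadjacent residue pairs with side-chain COMs closer than cutoff."""
    residues = []
    seen = set()
    for a in structure.atoms:
        key = (a.chain_id, a.residue_position)
        if key not in seen:
            seen.add(key)
            residues.append(key)
    found = set()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            (ca_, pa), (cb_, pb) = residues[i], residues[j]
            if ca_ == cb_ and abs(pa - pb) <= 1:
                continue
            da = brute_force_sidechain_com(structure, ca_, pa)
            db = brute_force_sidechain_com(structure, cb_, pb)
            if np.linalg.norm(da - db) < cutoff:
                found.add((residues[i], residues[j]))
    return found


def random_zipper_like_structure(rng: np.random.Generator, max_chains: int = 6) -> Structure:
    """A randomized multi-chain peptide-like structure for oracle tests.

    Chains of 6 residues; each residue has backbone N/CA/C/O plus 0-3
    side-chain heavy atoms (C or O), all at uniform random positions in a
    15 A box so that the 3.5/6.5 A cutoffs bite.
    """
    masses = {"N": 14.007, "C": 12.011, "O": 15.999}
    n_chains = int(rng.integers(2, max_chains + 1))
    atoms = []
    for c in range(n_chains):
        chain = "ABCDEF"[c]
        for pos in range(1, 7):
            for name in ("N", "CA", "C", "O"):
                el = name[0]
                atoms.append(
                    Atom(name, el, masses[el], pos, "ALA", chain,
                         rng.uniform(0, 15, 3))
                )
            for k in range(int(rng.integers(0, 4))):
                el = "O" if rng.random() < 0.3 else "C"
                atoms.append(
                    Atom(f"S{k+1}", el, masses[el], pos, "ALA", chain,
                         rng.uniform(0, 15, 3))
                )
    return Structure(atoms=atoms)
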