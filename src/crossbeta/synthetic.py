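"""Idealized cross-beta zipper coordinates and stochastic fluctuation ensembles.

This module stands in for molecular-dynamics trajectories: it builds an
idealized steric-zipper geometry (extended strands stacked at 4.8 Angstrom
within each sheet, two sheets 10 Angstrom apart) and decorates it with the
statistical features the analysis operators are designed to measure —
per-residue Gaussian fluctuations that grow toward the termini, per-strand
twist, strand-expulsion (disaggregation) drift, and sheet
compression/expansion ramps.  The noise is i.i.d. per atom per frame, with
no autocorrelation and no force field: sufficient for exercising and
validating estimators, with no claim of thermodynamic realism.

Canonical frame: x runs along each strand, y is the stacking (fibril) axis,
z is the sheet-separation axis.  Sheet 1 sits at z = 0, sheet 2 at
z = sheet_spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pdbio import ATOMIC_MASSES, Atom, Structure, Trajectory
from .topology import WILD_TYPE_SEQUENCE, ZipperTopology, build_hexamer_topology

__all__ = [
    "ZipperGeometry",
    "FluctuationSpec",
    "build_ideal_zipper",
    "generate_trajectory",
    "SIDECHAIN_MASSES",
]

ONE_TO_THREE = {
    "V": "VAL", "E": "GLU", "A": "ALA", "L": "LEU", "Y": "TYR", "G": "GLY",
}

#: Mass (Da) of the full side chain of each VEALYL residue type, carried by
#: the single side-chain pseudo-atom of the idealized builder.
SIDECHAIN_MASSES = {
    "VAL": 43.09,
    "GLU": 73.07,
    "ALA": 15.03,
    "LEU": 57.12,
    "TYR": 107.13,
}

# Backbone offsets (Angstrom) relative to CA, in the strand-local frame;
# x-offsets flip sign for reversed (direction -1) strands.  The carbonyl O
# points along +y so that stacked strands form N...O pairs within 3.5 A.
_N_OFFSET = np.array([-1.3, -0.9, 0.0])
_C_OFFSET = np.array([1.3, 0.6, 0.0])
_O_OFFSET = np.array([1.3, 1.8, 0.0])


@dataclass(frozen=True)
class ZipperGeometry:
    """Idealized zipper dimensions (Angstrom).

    ``strand_spacing`` is the stacking distance between neighbouring strands
    within a sheet (cross-beta repeat, 4.8 A), ``sheet_spacing`` the
    distance between the two sheets of the dry interface, ``ca_step`` the
    CA-CA step along an extended strand and ``sidechain_offset`` how far the
    side-chain pseudo-atom protrudes perpendicular to the sheet plane.
    ``antiparallel`` selects alternating strand orientations within each
    sheet when the builder constructs its own topology.
    """

    strand_spacing: float = 4.8
    sheet_spacing: float = 10.0
    ca_step: float = 3.5
    residues_per_strand: int = 6
    sidechain_offset: float = 2.0
    antiparallel: bool = False

    def __post_init__(self) -> None:
        for name in ("strand_spacing", "sheet_spacing", "ca_step", "sidechain_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FluctuationSpec:
    """Stochastic perturbations applied on top of the ideal coordinates.

    per_residue_sigma
        Isotropic Gaussian displacement std per residue position (A).  The
        default rises toward both termini, the fluctuation pattern of a
        stable zipper core (per-residue RMSF = sigma*sqrt(3), i.e. about
        0.35 A in the core and 0.7 A at the termini).
    twist_deg_per_strand
        Rotation about the stacking axis applied per stacking level,
        ramped linearly over the run.
    expelled_strands
        Strand index -> drift vector (A) reached at the final frame;
        intermediate frames interpolate linearly (a disaggregation event).
    sheet_compression
        Signed change of the sheet spacing reached at the final frame (A);
        negative values compress, positive expand (mutant-like behaviour).
    """

    per_residue_sigma: tuple[float, ...] = (0.4, 0.25, 0.2, 0.2, 0.25, 0.4)
    twist_deg_per_strand: float = 0.0
    expelled_strands: Mapping[int, Sequence[float]] = field(default_factory=dict)
    sheet_compression: float = 0.0
    n_frames: int = 200
    dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.per_residue_sigma):
            raise ValueError("sigmas must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _stacking_level(topology: ZipperTopology, strand: int) -> int:
    members = topology.sheet_members(topology.sheet_of_strand[strand])
    return members.index(strand)


def build_ideal_zipper(
    geometry: ZipperGeometry | None = None,
    topology: ZipperTopology | None = None,
    sequence: str = WILD_TYPE_SEQUENCE,
) -> Structure:
    """Build an idealized zipper: CA trace in extended conformation plus
    backbone N, C, O and one side-chain pseudo-atom per non-Gly residue.

    Strands are pure y-translates of each other at ``strand_spacing`` within
    each sheet (so every register-paired CA-CA distance equals the spacing
    exactly) and the two sheets are separated by ``sheet_spacing`` along z.
    Side-chain pseudo-atoms alternate up/down along the strand (beta pleat)
    and the sheets face each other, interdigitating across the dry
    interface.  Reversed strands (direction -1) run antiparallel along x.
    """
    geometry = geometry or ZipperGeometry()
    if topology is None:
        topology = build_hexamer_topology(antiparallel=geometry.antiparallel)
    if topology.n_strands > 6:
        raise ValueError("at most 6 strands supported")
    n_res = geometry.residues_per_strand
    if len(sequence) != n_res:
        raise ValueError(f"sequence length {len(sequence)} != {n_res}")
    chain_letters = "ABCDEF"
    atoms: list[Atom] = []
    for k, strand in enumerate(topology.strand_ids):
        sheet = topology.sheet_of_strand[strand]
        level = _stacking_level(topology, strand)
        direction = topology.strand_direction[strand]
        y0 = level * geometry.strand_spacing
        z0 = 0.0 if sheet == 1 else geometry.sheet_spacing
        facing = 1.0 if sheet == 1 else -1.0  # side chains point at the other sheet
        chain_id = chain_letters[k]
        for i in range(1, n_res + 1):
            res_name = ONE_TO_THREE[sequence[i - 1]]
            xi = (i - 1 if direction > 0 else n_res - i) * geometry.ca_step
            ca = np.array([xi, y0, z0])
            flip = np.array([direction, 1.0, 1.0])
            for name, offset in (
                ("N", _N_OFFSET),
                ("CA", np.zeros(3)),
                ("C", _C_OFFSET),
                ("O", _O_OFFSET),
            ):
                element = name[0]
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        mass=ATOMIC_MASSES[element],
                        residue_position=i,
                        residue_name=res_name,
                        chain_id=chain_id,
                        coords=ca + offset * flip,
                    )
                )
            if res_name != "GLY":
                pleat = 1.0 if i % 2 == 1 else -1.0
                sc = ca + np.array(
                    [0.0, 0.0, facing * pleat * geometry.sidechain_offset]
                )
                atoms.append(
                    Atom(
                        name="CB",
                        element="C",
                        mass=SIDECHAIN_MASSES[res_name],
                        residue_position=i,
                        residue_name=res_name,
                        chain_id=chain_id,
                        coords=sc,
                    )
                )
    return Structure(atoms=atoms)


def generate_trajectory(
    structure: Structure,
    spec: FluctuationSpec,
    topology: ZipperTopology | None = None,
) -> Trajectory:
    """Generate a stochastic ensemble around an ideal structure.

    Frame t (progress f = t/(n_frames-1), f = 0 for a single frame) is::

        ideal + per-atom Gaussian noise (residue-dependent sigma)
              + f * drift for each expelled strand
              + f * sheet_compression shift of sheet 2 along z
              + rotation by f * twist * level about the stacking axis
                through each strand's CA centroid

    Deterministic given ``spec.seed``; each frame draws from its own child
    stream of the seed, so frame i is reproducible in isolation.  The sheet
    shift acts on whole strands, so the final-frame intersheet (CA-centroid)
    distance is exactly ``sheet_spacing + sheet_compression`` when noise,
    twist and drift are zero.
    """
    if topology is None:
        if structure.n_chains != 6:
            raise ValueError(
                "a topology is required for structures that are not hexamers"
            )
        topology = build_hexamer_topology()
    base = structure.coords
    n_atoms = base.shape[0]
    chain_of_atom = np.array(
        [structure.chain_ids.index(a.chain_id) for a in structure.atoms]
    )
    strand_of_atom = np.array(
        [topology.strand_ids[c] for c in chain_of_atom]
    )
    sigma_of_atom = np.array(
        [spec.per_residue_sigma[a.residue_position - 1] for a in structure.atoms]
    )
    sheet2_mask = np.array(
        [topology.sheet_of_strand[s] == 2 for s in strand_of_atom]
    )
    ca_mask = np.array([a.name == "CA" for a in structure.atoms])

    # per-strand twist pivots (CA centroid) and angles per unit progress
    twist_info = []
    if spec.twist_deg_per_strand != 0.0:
        for strand in topology.strand_ids:
            sel = strand_of_atom == strand
            pivot = base[sel & ca_mask].mean(axis=0)
            level = _stacking_level(topology, strand)
            twist_info.append((sel, pivot, np.deg2rad(spec.twist_deg_per_strand) * level))

    drift_items = [
        (np.asarray(vec, dtype=float), strand_of_atom == int(strand))
        for strand, vec in spec.expelled_strands.items()
    ]

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_frames)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        f = t / (spec.n_frames - 1) if spec.n_frames > 1 else 0.0
        coords = base.copy()
        for sel, pivot, angle_per in twist_info:
            c, s = np.cos(angle_per * f), np.sin(angle_per * f)
            rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
            coords[sel] = (coords[sel] - pivot) @ rot.T + pivot
        for vec, sel in drift_items:
            coords[sel] += f * vec
        if spec.sheet_compression != 0.0:
            coords[sheet2_mask, 2] += f * spec.sheet_compression
        rng = np.random.default_rng(children[t])
        coords += rng.standard_normal((n_atoms, 3)) * sigma_of_atom[:, None]
        frames[t] = coords
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ns
    return Trajectory(structure=structure, coords=frames, times=times, topology=topology)
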