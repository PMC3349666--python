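"""Analysis operators for zipper ensembles.

Implements the full metric set used to judge steric-zipper stability:

* least-squares (Kabsch) superposition and per-frame CA RMSD against a
  native/initial reference;
* per-residue-per-chain CA RMSF;
* hydrogen-bond detection (polar heavy atoms N/O from different strands
  closer than 3.5 A; distance-only criterion, no angle term);
* native side-chain contacts (side-chain centers of mass of nonadjacent
  residues closer than 6.5 A in the native state), classified interstrand
  or intersheet through the topology's strand-pair lists;
* the fraction of native contacts Qf, the reaction coordinate for deviation
  from the native state;
* interstrand and intersheet distance metrics;
* interaction populations over pooled trajectories (an interaction is
  called stable when present in more than 40% of frames);
* per-residue interaction averages (per-frame counts binned by residue
  position, normalized by the number of peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pdbio import Structure, Trajectory, is_sidechain
from .topology import ZipperTopology

__all__ = [
    "InteractionRecord",
    "MetricSeries",
    "kabsch_superpose",
    "ca_rmsd",
    "ca_rmsf",
    "detect_hbonds",
    "detect_native_contacts",
    "qf",
    "qf_series",
    "interstrand_distance",
    "intersheet_distance",
    "interaction_population",
    "per_residue_average",
    "compute_metric_series",
    "presence_matrix",
    "HBOND_CUTOFF",
    "CONTACT_CUTOFF",
    "STABLE_POPULATION",
]

HBOND_CUTOFF = 3.5  # A, polar heavy-atom donor-acceptor distance
CONTACT_CUTOFF = 6.5  # A, side-chain COM distance in the native state
STABLE_POPULATION = 0.40  # an interaction is stable if population > 40%


@dataclass
class InteractionRecord:
    """One hydrogen bond or native contact.

    ``participants`` is a pair of ``(chain_id, residue_position)`` for
    contacts or ``(chain_id, residue_position, atom_name)`` for hydrogen
    bonds.  ``interaction_class`` is ``interstrand``/``intersheet`` per the
    topology pair lists, ``intrastrand`` for same-strand nonadjacent
    contacts (excluded from both classes), or ``unlisted`` for strand pairs
    the topology does not enumerate.
    """

    kind: str  # "hbond" | "contact"
    interaction_class: str
    participants: tuple
    native_distance: float
    cutoff: float
    presence: np.ndarray | None = None  # bool per frame, filled by populations
    population: float | None = None

    def label(self) -> str:
        parts = []
        for p in self.participants:
            parts.append(":".join(str(x) for x in p))
        return "--".join(parts)


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------


def kabsch_superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``reference``.  The rotation is proper (determinant +1): a reflection is
    never returned, per the SVD sign-correction of the Kabsch algorithm.

    Both inputs are ``(n, 3)`` with equal ``n >= 3`` and must not be
    collinear (the in-plane rotation would be undetermined).
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise ValueError(
            f"selection size mismatch: {reference.shape} vs {mobile.shape}"
        )
    if reference.ndim != 2 or reference.shape[1] != 3 or reference.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    p = mobile - mob_c
    q = reference - ref_c
    for pts in (p, q):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) selection")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = p @ rotation.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def _ca_coords(structure: Structure, coords: np.ndarray | None = None) -> np.ndarray:
    idx = structure.ca_indices()
    if idx.size == 0:
        raise ValueError("no CA atoms found")
    per_res = {(a.chain_id, a.residue_position) for a in structure.atoms}
    have = {
        (a.chain_id, a.residue_position)
        for a in structure.atoms
        if a.name == "CA"
    }
    missing = per_res - have
    if missing:
        ch, pos = sorted(missing)[0]
        raise ValueError(f"missing CA atom in chain {ch} residue {pos}")
    if coords is None:
        coords = structure.coords
    return coords[idx]


def ca_rmsd(trajectory: Trajectory, reference: Structure | None = None) -> np.ndarray:
    """Per-frame CA RMSD (A) after Kabsch superposition onto the reference.

    The reference defaults to the trajectory's template structure (the
    initial/native state).
    """
    reference = reference or trajectory.structure
    ref_ca = _ca_coords(reference)
    idx = trajectory.structure.ca_indices()
    _ca_coords(trajectory.structure)  # validates CA completeness
    out = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        _, _, rmsd = kabsch_superpose(ref_ca, trajectory.coords[t, idx])
        out[t] = rmsd
    return out


def ca_rmsf(
    trajectory: Trajectory,
    reference: Structure | None = None,
    superpose: bool = True,
    reference_mode: str = "initial",
) -> pd.DataFrame:
    """Per-residue-per-chain CA RMSF (A).

    Each frame's CA set is first superposed onto the reference (disable
    with ``superpose=False`` for fixed-frame ensembles); the fluctuation of
    residue i is then ``sqrt(mean_t |r_i(t) - r_i(ref)|^2)``.  With
    ``reference_mode="mean"`` the post-superposition ensemble mean replaces
    the reference positions in that formula.

    Returns a DataFrame with columns ``chain_id``, ``residue_position``,
    ``rmsf``.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    reference = reference or trajectory.structure
    ref_ca = _ca_coords(reference)
    idx = trajectory.structure.ca_indices()
    fitted = np.empty((trajectory.n_frames, len(idx), 3))
    for t in range(trajectory.n_frames):
        mob = trajectory.coords[t, idx]
        if superpose:
            rot, trans, _ = kabsch_superpose(ref_ca, mob)
            mob = mob @ rot.T + trans
        fitted[t] = mob
    if reference_mode == "mean":
        target = fitted.mean(axis=0)
    elif reference_mode == "initial":
        target = ref_ca
    else:
        raise ValueError("reference_mode must be 'initial' or 'mean'")
    sq = np.sum((fitted - target) ** 2, axis=2)  # (frames, residues)
    rmsf = np.sqrt(sq.mean(axis=0))
    ca_atoms = [trajectory.structure.atoms[i] for i in idx]
    return pd.DataFrame(
        {
            "chain_id": [a.chain_id for a in ca_atoms],
            "residue_position": [a.residue_position for a in ca_atoms],
            "rmsf": rmsf,
        }
    )


# ---------------------------------------------------------------------------
# Strand bookkeeping
# ---------------------------------------------------------------------------


def strand_of_chain(structure: Structure, topology: ZipperTopology) -> dict[str, int]:
    """Map chain ids to topology strand indices by file order."""
    chains = structure.chain_ids
    if len(chains) != topology.n_strands:
        raise ValueError(
            f"structure has {len(chains)} chains but topology {topology.n_strands} strands"
        )
    return {ch: topology.strand_ids[k] for k, ch in enumerate(chains)}


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    structure: Structure,
    topology: ZipperTopology,
    cutoff: float = HBOND_CUTOFF,
) -> list[InteractionRecord]:
    """Distance-only hydrogen bonds: N/O atom pairs from different strands
    closer than ``cutoff`` (strict).  Donor and acceptor roles are not
    distinguished; (A,B)/(B,A) duplicates are collapsed.
    """
    strand_map = strand_of_chain(structure, topology)
    polar = [
        (i, a) for i, a in enumerate(structure.atoms) if a.element.upper() in ("N", "O")
    ]
    coords = np.array([a.coords for _, a in polar])
    records: list[InteractionRecord] = []
    if len(polar) == 0:
        return records
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(r=cutoff)):
        ai, aj = polar[i][1], polar[j][1]
        if ai.chain_id == aj.chain_id:
            continue
        dist = float(np.linalg.norm(ai.coords - aj.coords))
        if not dist < cutoff:
            continue
        sa, sb = strand_map[ai.chain_id], strand_map[aj.chain_id]
        part = tuple(
            sorted(
                [
                    (ai.chain_id, ai.residue_position, ai.name),
                    (aj.chain_id, aj.residue_position, aj.name),
                ]
            )
        )
        records.append(
            InteractionRecord(
                kind="hbond",
                interaction_class=topology.classify_pair(sa, sb),
                participants=part,
                native_distance=dist,
                cutoff=cutoff,
            )
        )
    records.sort(key=lambda r: r.participants)
    return records


# ---------------------------------------------------------------------------
# Native contacts and Qf
# ---------------------------------------------------------------------------


def _sidechain_com_operator(
    structure: Structure,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Residue keys and a weight matrix W with COM = W @ coords.

    Side-chain heavy atoms, mass weighted; glycine (or any residue without
    side-chain heavy atoms) falls back to its CA atom.
    """
    keys: list[tuple[str, int]] = []
    seen: dict[tuple[str, int], int] = {}
    for a in structure.atoms:
        key = (a.chain_id, a.residue_position)
        if key not in seen:
            seen[key] = len(keys)
            keys.append(key)
    w = np.zeros((len(keys), structure.n_atoms))
    has_side = np.zeros(len(keys), dtype=bool)
    for i, a in enumerate(structure.atoms):
        if is_sidechain(a):
            r = seen[(a.chain_id, a.residue_position)]
            w[r, i] = a.mass
            has_side[r] = True
    for i, a in enumerate(structure.atoms):
        if a.name == "CA":
            r = seen[(a.chain_id, a.residue_position)]
            if not has_side[r]:
                w[r, i] = 1.0
    norm = w.sum(axis=1)
    if np.any(norm == 0):
        r = int(np.argmin(norm))
        raise ValueError(f"residue {keys[r]} has neither side-chain atoms nor CA")
    return keys, w / norm[:, None]


def detect_native_contacts(
    native: Structure,
    topology: ZipperTopology,
    cutoff: float = CONTACT_CUTOFF,
    intersheet_cutoff: float | None = None,
) -> list[InteractionRecord]:
    """Side-chain COM contacts between nonadjacent residues in the native state.

    Residue pairs that are sequence-adjacent within one chain (|i - j| <= 1)
    are never contacts.  Each contact is classified through the topology's
    strand-pair lists; same-strand nonadjacent contacts are labelled
    ``intrastrand`` and belong to neither class.  ``intersheet_cutoff``
    optionally overrides the cutoff for intersheet pairs (the analysis
    tradition uses 6.5 A overall but 6.0 A for the sheet interface).
    """
    strand_map = strand_of_chain(native, topology)
    keys, w = _sidechain_com_operator(native)
    coms = w @ native.coords
    records: list[InteractionRecord] = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            (ch_i, pos_i), (ch_j, pos_j) = keys[i], keys[j]
            if ch_i == ch_j and abs(pos_i - pos_j) <= 1:
                continue
            if ch_i == ch_j:
                klass = "intrastrand"
                eff_cutoff = cutoff
            else:
                klass = topology.classify_pair(strand_map[ch_i], strand_map[ch_j])
                eff_cutoff = (
                    intersheet_cutoff
                    if (klass == "intersheet" and intersheet_cutoff is not None)
                    else cutoff
                )
            dist = float(np.linalg.norm(coms[i] - coms[j]))
            if dist < eff_cutoff:
                records.append(
                    InteractionRecord(
                        kind="contact",
                        interaction_class=klass,
                        participants=(keys[i], keys[j]),
                        native_distance=dist,
                        cutoff=eff_cutoff,
                    )
                )
    return records


def _contact_distances(
    trajectory: Trajectory, records: Sequence[InteractionRecord]
) -> np.ndarray:
    """(n_frames, n_records) COM distances for contact records."""
    keys, w = _sidechain_com_operator(trajectory.structure)
    index = {k: i for i, k in enumerate(keys)}
    coms = np.einsum("rn,fnc->frc", w, trajectory.coords)
    ii = np.array([index[r.participants[0]] for r in records])
    jj = np.array([index[r.participants[1]] for r in records])
    return np.linalg.norm(coms[:, ii, :] - coms[:, jj, :], axis=2)


def qf(frame: Structure, records: Sequence[InteractionRecord]) -> float:
    """Fraction of native contacts still formed in a frame (in [0, 1])."""
    if not records:
        raise ValueError("native contact list is empty")
    keys, w = _sidechain_com_operator(frame)
    index = {k: i for i, k in enumerate(keys)}
    coms = w @ frame.coords
    formed = 0
    for r in records:
        i, j = index[r.participants[0]], index[r.participants[1]]
        if np.linalg.norm(coms[i] - coms[j]) < r.cutoff:
            formed += 1
    return formed / len(records)


def qf_series(
    trajectory: Trajectory, records: Sequence[InteractionRecord]
) -> np.ndarray:
    """Per-frame Qf over a trajectory (vectorized)."""
    if not records:
        raise ValueError("native contact list is empty")
    dists = _contact_distances(trajectory, records)
    cutoffs = np.array([r.cutoff for r in records])
    return (dists < cutoffs[None, :]).mean(axis=1)


# ---------------------------------------------------------------------------
# Interstrand / intersheet distances
# ---------------------------------------------------------------------------


def _register_pairs(
    topology: ZipperTopology, a: int, b: int, n_res: int
) -> list[tuple[int, int]]:
    """Residue register pairing for an interstrand pair: i<->i for parallel
    neighbours, i<->(n+1-i) for antiparallel ones."""
    if topology.strand_direction[a] == topology.strand_direction[b]:
        return [(i, i) for i in range(1, n_res + 1)]
    return [(i, n_res + 1 - i) for i in range(1, n_res + 1)]


def _ca_lookup(structure: Structure) -> dict[tuple[str, int], int]:
    return {
        (a.chain_id, a.residue_position): i
        for i, a in enumerate(structure.atoms)
        if a.name == "CA"
    }


def interstrand_distance(
    frame_or_traj: Structure | Trajectory,
    topology: ZipperTopology,
) -> float | np.ndarray:
    """Mean CA-CA distance between register-paired residues of the
    topology's interstrand (stacked-neighbour) pairs, averaged over pairs.

    Returns NaN (per frame for a trajectory) when the topology defines no
    interstrand pairs — e.g. the 1-1 dimer — as an explicit not-applicable
    marker.
    """
    traj = (
        frame_or_traj
        if isinstance(frame_or_traj, Trajectory)
        else Trajectory(structure=frame_or_traj, coords=frame_or_traj.coords[None])
    )
    scalar = not isinstance(frame_or_traj, Trajectory)
    if not topology.interstrand_pairs:
        out = np.full(traj.n_frames, np.nan)
        return float(out[0]) if scalar else out
    structure = traj.structure
    strand_map = strand_of_chain(structure, topology)
    chain_of_strand = {s: ch for ch, s in strand_map.items()}
    ca = _ca_lookup(structure)
    n_res = max(a.residue_position for a in structure.atoms)
    idx_a, idx_b, pair_id = [], [], []
    for p, (sa, sb) in enumerate(sorted(topology.interstrand_pairs)):
        cha, chb = chain_of_strand[sa], chain_of_strand[sb]
        for i, j in _register_pairs(topology, sa, sb, n_res):
            idx_a.append(ca[(cha, i)])
            idx_b.append(ca[(chb, j)])
            pair_id.append(p)
    idx_a, idx_b, pair_id = map(np.array, (idx_a, idx_b, pair_id))
    d = np.linalg.norm(traj.coords[:, idx_a] - traj.coords[:, idx_b], axis=2)
    n_pairs = pair_id.max() + 1
    per_pair = np.stack([d[:, pair_id == p].mean(axis=1) for p in range(n_pairs)])
    out = per_pair.mean(axis=0)
    return float(out[0]) if scalar else out


def intersheet_distance(
    frame_or_traj: Structure | Trajectory,
    topology: ZipperTopology,
) -> float | np.ndarray:
    """Distance between the CA centroids of sheet 1 and sheet 2 (A).

    Returns NaN for single-sheet topologies (3-0, 2-0) as an explicit
    not-applicable marker.
    """
    traj = (
        frame_or_traj
        if isinstance(frame_or_traj, Trajectory)
        else Trajectory(structure=frame_or_traj, coords=frame_or_traj.coords[None])
    )
    scalar = not isinstance(frame_or_traj, Trajectory)
    sheet1 = topology.sheet_members(1)
    sheet2 = topology.sheet_members(2)
    if not sheet1 or not sheet2:
        out = np.full(traj.n_frames, np.nan)
        return float(out[0]) if scalar else out
    structure = traj.structure
    strand_map = strand_of_chain(structure, topology)
    masks = {}
    for sheet, members in ((1, sheet1), (2, sheet2)):
        masks[sheet] = np.array(
            [
                a.name == "CA" and strand_map[a.chain_id] in members
                for a in structure.atoms
            ]
        )
    c1 = traj.coords[:, masks[1]].mean(axis=1)
    c2 = traj.coords[:, masks[2]].mean(axis=1)
    out = np.linalg.norm(c1 - c2, axis=1)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Populations and per-residue averages
# ---------------------------------------------------------------------------


def presence_matrix(
    trajectory: Trajectory, records: Sequence[InteractionRecord]
) -> np.ndarray:
    """(n_frames, n_records) boolean presence of each interaction per frame."""
    if not records:
        return np.zeros((trajectory.n_frames, 0), dtype=bool)
    kinds = {r.kind for r in records}
    out = np.zeros((trajectory.n_frames, len(records)), dtype=bool)
    if "contact" in kinds:
        sel = [k for k, r in enumerate(records) if r.kind == "contact"]
        sub = [records[k] for k in sel]
        dists = _contact_distances(trajectory, sub)
        cutoffs = np.array([r.cutoff for r in sub])
        out[:, sel] = dists < cutoffs[None, :]
    if "hbond" in kinds:
        sel = [k for k, r in enumerate(records) if r.kind == "hbond"]
        idx = {
            (a.chain_id, a.residue_position, a.name): i
            for i, a in enumerate(trajectory.structure.atoms)
        }
        ii = np.array([idx[records[k].participants[0]] for k in sel])
        jj = np.array([idx[records[k].participants[1]] for k in sel])
        d = np.linalg.norm(
            trajectory.coords[:, ii] - trajectory.coords[:, jj], axis=2
        )
        cutoffs = np.array([records[k].cutoff for k in sel])
        out[:, sel] = d < cutoffs[None, :]
    return out


def interaction_population(
    trajectories: Iterable[Trajectory],
    records: Sequence[InteractionRecord],
    burn_in: float = 0.0,
) -> pd.DataFrame:
    """Fraction of frames (pooled over trajectories with equal frame weight)
    in which each interaction is present.

    ``burn_in`` discards the leading fraction of each trajectory before
    pooling (equilibration discard).  Fills each record's ``presence`` (from
    the last trajectory) and ``population``; returns a table sorted by
    descending population with a strict ``stable = population > 0.40`` flag.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    present = np.zeros(len(records))
    total = 0
    for traj in trajectories:
        start = int(np.floor(burn_in * traj.n_frames))
        pres = presence_matrix(traj, records)[start:]
        present += pres.sum(axis=0)
        total += pres.shape[0]
        for r, col in zip(records, pres.T):
            r.presence = col
    pops = present / total if total else np.zeros(len(records))
    for r, p in zip(records, pops):
        r.population = float(p)
    table = pd.DataFrame(
        {
            "interaction": [r.label() for r in records],
            "kind": [r.kind for r in records],
            "class": [r.interaction_class for r in records],
            "native_distance": [r.native_distance for r in records],
            "population": pops,
            "stable": pops > STABLE_POPULATION,
        }
    )
    return table.sort_values(
        "population", ascending=False, kind="stable"
    ).reset_index(drop=True)


def per_residue_average(
    records: Sequence[InteractionRecord],
    n_chains: int,
    n_frames: int | None = None,
) -> np.ndarray:
    """Per-residue-position interaction average, normalized by peptide count.

    For residue position r in 1..6: the time-averaged number of present
    interactions in which a residue at position r (on any chain)
    participates, divided by ``n_chains``.  Each endpoint of an interaction
    counts, so a contact between position 1 of one chain and position 1 of
    another adds two participations to position 1.  Records must carry
    ``presence`` (see :func:`interaction_population`); a record without
    presence counts as always present over ``n_frames``.
    """
    out = np.zeros(6)
    for r in records:
        if r.presence is not None:
            avg = float(np.mean(r.presence)) if len(r.presence) else 0.0
        else:
            avg = 1.0
        for p in r.participants:
            pos = p[1]
            out[pos - 1] += avg
    return out / n_chains


# ---------------------------------------------------------------------------
# Bundled series
# ---------------------------------------------------------------------------


@dataclass
class MetricSeries:
    """Per-frame metric traces of one trajectory."""

    times: np.ndarray
    rmsd: np.ndarray
    qf: np.ndarray
    interstrand: np.ndarray
    intersheet: np.ndarray
    rmsf: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "rmsd": self.rmsd,
                "qf": self.qf,
                "interstrand_distance": self.interstrand,
                "intersheet_distance": self.intersheet,
            }
        )


def compute_metric_series(
    trajectory: Trajectory,
    topology: ZipperTopology | None = None,
    reference: Structure | None = None,
    native_contacts: Sequence[InteractionRecord] | None = None,
    contact_cutoff: float = CONTACT_CUTOFF,
    intersheet_cutoff: float | None = None,
) -> MetricSeries:
    """RMSD, Qf, interstrand/intersheet distances and RMSF for one trajectory.

    Native contacts default to those of the reference (initial) structure.
    """
    topology = topology or trajectory.topology
    if topology is None:
        raise ValueError("a topology is required")
    reference = reference or trajectory.structure
    if native_contacts is None:
        native_contacts = detect_native_contacts(
            reference, topology, cutoff=contact_cutoff, intersheet_cutoff=intersheet_cutoff
        )
    return MetricSeries(
        times=trajectory.times.copy(),
        rmsd=ca_rmsd(trajectory, reference),
        qf=qf_series(trajectory, native_contacts),
        interstrand=np.atleast_1d(interstrand_distance(trajectory, topology)),
        intersheet=np.atleast_1d(intersheet_distance(trajectory, topology)),
        rmsf=ca_rmsf(trajectory, reference),
    )
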