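"""Steric-zipper topology: strands, sheets, pair classification and glycine mutants.

A cross-beta steric zipper is built from two beta-sheets of stacked short
peptide strands.  Interactions fall into two classes: *interstrand*
(between strands stacked within one sheet, i.e. along the fibril axis) and
*intersheet* (between strands on opposite sheets of the zipper).  The
canonical system here is the VEALYL hexamer: two sheets of three strands
each, organization label ``"3-3"``.

Strand numbering convention: strands 1-3 form sheet 1, strands 4-6 sheet 2.
This assignment is forced by the canonical pair lists (1-2, 2-3, 4-5, 5-6
interstrand; 1-4, 1-5, 2-5, 2-6, 3-6 intersheet): it is the unique
two-colouring under which every interstrand pair is monochromatic and every
intersheet pair bichromatic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .pdbio import BACKBONE_ATOM_NAMES, Atom, Structure

__all__ = [
    "ZipperTopology",
    "OligomerScheme",
    "MutationSpec",
    "SCHEME_LABELS",
    "DEFAULT_SCHEME_SELECTIONS",
    "WILD_TYPE_SEQUENCE",
    "build_hexamer_topology",
    "extract_oligomer",
    "extract_structure",
    "mutate_to_glycine",
]

Pair = tuple[int, int]

WILD_TYPE_SEQUENCE = "VEALYL"

#: The eight oligomer organization labels "m-n" (m strands on one sheet, n on
#: the other, m >= n): hexamer 3-3, pentamer 3-2, tetramers 3-1/2-2,
#: trimers 3-0/2-1, dimers 2-0/1-1.
SCHEME_LABELS = ("1-1", "2-0", "2-1", "3-0", "2-2", "3-1", "3-2", "3-3")

#: Default strand selections used when carving a sub-oligomer out of the
#: hexamer.  The source analysis never states which strands were deleted;
#: these keep edge strands 1,2,3 of sheet 1 and 4,5 of sheet 2 and are
#: overridable via the ``selection`` argument of :func:`extract_oligomer`.
DEFAULT_SCHEME_SELECTIONS: dict[str, tuple[int, ...]] = {
    "1-1": (1, 4),
    "2-0": (1, 2),
    "2-1": (1, 2, 4),
    "3-0": (1, 2, 3),
    "2-2": (1, 2, 4, 5),
    "3-1": (1, 2, 3, 4),
    "3-2": (1, 2, 3, 4, 5),
    "3-3": (1, 2, 3, 4, 5, 6),
}


def _norm_pair(pair: Iterable[int]) -> Pair:
    a, b = sorted(pair)
    return (a, b)


@dataclass(frozen=True)
class ZipperTopology:
    """Strand/sheet membership and classified strand-pair lists of a zipper.

    Parameters
    ----------
    sheet_of_strand : mapping
        Strand index -> sheet index (1 or 2).  Strand indices need not be
        contiguous (sub-oligomers keep their hexamer indices).
    interstrand_pairs : set of pairs
        Unordered strand pairs stacked within one sheet.
    intersheet_pairs : set of pairs
        Unordered strand pairs across the two sheets.
    strand_direction : mapping
        Strand index -> +1/-1 orientation flag; strands with opposite signs
        are in antiparallel register.
    """

    sheet_of_strand: Mapping[int, int]
    interstrand_pairs: frozenset[Pair]
    intersheet_pairs: frozenset[Pair]
    strand_direction: Mapping[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sheets = set(self.sheet_of_strand.values())
        if not sheets <= {1, 2}:
            raise ValueError(f"sheet indices must be 1 or 2, got {sorted(sheets)}")
        if self.strand_direction is None:
            object.__setattr__(
                self, "strand_direction", {s: 1 for s in self.sheet_of_strand}
            )
        inter = frozenset(_norm_pair(p) for p in self.interstrand_pairs)
        cross = frozenset(_norm_pair(p) for p in self.intersheet_pairs)
        object.__setattr__(self, "interstrand_pairs", inter)
        object.__setattr__(self, "intersheet_pairs", cross)
        if inter & cross:
            raise ValueError("a strand pair cannot be both interstrand and intersheet")
        for a, b in inter:
            if self.sheet_of_strand[a] != self.sheet_of_strand[b]:
                raise ValueError(f"interstrand pair {(a, b)} spans two sheets")
        for a, b in cross:
            if self.sheet_of_strand[a] == self.sheet_of_strand[b]:
                raise ValueError(f"intersheet pair {(a, b)} lies within one sheet")

    # -- derived views ----------------------------------------------------

    @property
    def strand_ids(self) -> tuple[int, ...]:
        """Strand indices in ascending order; position k maps to chain k of a structure."""
        return tuple(sorted(self.sheet_of_strand))

    @property
    def n_strands(self) -> int:
        return len(self.sheet_of_strand)

    def sheet_members(self, sheet: int) -> tuple[int, ...]:
        return tuple(s for s in self.strand_ids if self.sheet_of_strand[s] == sheet)

    @property
    def organization(self) -> str:
        """The "m-n" label, m >= n."""
        m = len(self.sheet_members(1))
        n = len(self.sheet_members(2))
        hi, lo = max(m, n), min(m, n)
        return f"{hi}-{lo}"

    def classify_pair(self, a: int, b: int) -> str:
        """Classify a strand pair as interstrand / intersheet / unlisted."""
        p = _norm_pair((a, b))
        if p in self.interstrand_pairs:
            return "interstrand"
        if p in self.intersheet_pairs:
            return "intersheet"
        return "unlisted"

    def relabel(self, mapping: Mapping[int, int]) -> "ZipperTopology":
        """Rename strands; pair classification and directions follow the mapping."""
        return ZipperTopology(
            sheet_of_strand={mapping[s]: h for s, h in self.sheet_of_strand.items()},
            interstrand_pairs=frozenset(
                _norm_pair((mapping[a], mapping[b])) for a, b in self.interstrand_pairs
            ),
            intersheet_pairs=frozenset(
                _norm_pair((mapping[a], mapping[b])) for a, b in self.intersheet_pairs
            ),
            strand_direction={mapping[s]: d for s, d in self.strand_direction.items()},
        )

    def renumbered(self) -> "ZipperTopology":
        """Relabel strands to contiguous 1..n preserving order (for extracted structures)."""
        mapping = {s: k + 1 for k, s in enumerate(self.strand_ids)}
        return self.relabel(mapping)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "organization": self.organization,
            "sheets": [list(self.sheet_members(1)), list(self.sheet_members(2))],
            "interstrand_pairs": sorted(map(list, self.interstrand_pairs)),
            "intersheet_pairs": sorted(map(list, self.intersheet_pairs)),
            "strand_direction": {str(s): d for s, d in self.strand_direction.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ZipperTopology":
        payload = json.loads(text)
        sheet_of_strand: dict[int, int] = {}
        for sheet_idx, members in enumerate(payload["sheets"], start=1):
            for s in members:
                sheet_of_strand[int(s)] = sheet_idx
        direction = {
            int(s): int(d) for s, d in payload.get("strand_direction", {}).items()
        }
        return cls(
            sheet_of_strand=sheet_of_strand,
            interstrand_pairs=frozenset(
                _norm_pair(p) for p in payload["interstrand_pairs"]
            ),
            intersheet_pairs=frozenset(
                _norm_pair(p) for p in payload["intersheet_pairs"]
            ),
            strand_direction=direction or None,
        )


@dataclass(frozen=True)
class OligomerScheme:
    """An "m-n" sub-oligomer and the hexamer strands it retains."""

    label: str
    strand_selection: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.label not in SCHEME_LABELS:
            raise ValueError(
                f"unknown scheme label {self.label!r}; valid labels: "
                + ", ".join(SCHEME_LABELS)
            )
        m, n = (int(x) for x in self.label.split("-"))
        if len(self.strand_selection) != m + n:
            raise ValueError(
                f"scheme {self.label} needs {m + n} strands, got "
                f"{len(self.strand_selection)}"
            )


@dataclass(frozen=True)
class MutationSpec:
    """Glycine substitution at one or more positions of the 6-residue peptide."""

    positions: frozenset[int]

    def __init__(self, positions: Iterable[int]) -> None:
        object.__setattr__(self, "positions", frozenset(int(p) for p in positions))
        bad = [p for p in self.positions if not 1 <= p <= 6]
        if bad:
            raise ValueError(f"mutation positions must be in 1..6, got {sorted(bad)}")

    @property
    def resulting_sequence(self) -> str:
        """Wild-type VEALYL with G at each mutated position (e.g. {5} -> VEALGL)."""
        return "".join(
            "G" if i + 1 in self.positions else aa
            for i, aa in enumerate(WILD_TYPE_SEQUENCE)
        )

    @property
    def label(self) -> str:
        """Conventional mutant name, e.g. Y5G or A3GL4G; 'WT' for no mutation."""
        if not self.positions:
            return "WT"
        return "".join(
            f"{WILD_TYPE_SEQUENCE[p - 1]}{p}G" for p in sorted(self.positions)
        )


def build_hexamer_topology(antiparallel: bool = False) -> ZipperTopology:
    """Canonical 3-3 hexamer: sheet 1 = strands {1,2,3}, sheet 2 = {4,5,6}.

    Interstrand pairs are the stacked neighbours 1-2, 2-3, 4-5, 5-6;
    intersheet pairs are the zipper-interface pairs 1-4, 1-5, 2-5, 2-6, 3-6.
    With ``antiparallel=True`` strand orientations alternate with stacking
    level within each sheet (1,3,4,6 forward; 2,5 reversed).
    """
    sheet_of_strand = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}
    if antiparallel:
        direction = {1: 1, 2: -1, 3: 1, 4: 1, 5: -1, 6: 1}
    else:
        direction = {s: 1 for s in sheet_of_strand}
    return ZipperTopology(
        sheet_of_strand=sheet_of_strand,
        interstrand_pairs=frozenset({(1, 2), (2, 3), (4, 5), (5, 6)}),
        intersheet_pairs=frozenset({(1, 4), (1, 5), (2, 5), (2, 6), (3, 6)}),
        strand_direction=direction,
    )


def extract_oligomer(
    topology: ZipperTopology,
    scheme_label: str,
    selection: Iterable[int] | None = None,
) -> ZipperTopology:
    """Restrict a topology to the strands of an "m-n" sub-oligomer.

    Strands keep their original indices; pair lists are restricted to pairs
    whose members are both retained, so classification is preserved.  The
    default selections are :data:`DEFAULT_SCHEME_SELECTIONS`.
    """
    if scheme_label not in SCHEME_LABELS:
        raise ValueError(
            f"unknown scheme label {scheme_label!r}; valid labels: "
            + ", ".join(SCHEME_LABELS)
        )
    if selection is None:
        selection = DEFAULT_SCHEME_SELECTIONS[scheme_label]
    keep = set(int(s) for s in selection)
    missing = keep - set(topology.sheet_of_strand)
    if missing:
        raise ValueError(f"selection strands {sorted(missing)} not in topology")
    scheme = OligomerScheme(scheme_label, tuple(sorted(keep)))
    sub = ZipperTopology(
        sheet_of_strand={s: h for s, h in topology.sheet_of_strand.items() if s in keep},
        interstrand_pairs=frozenset(
            p for p in topology.interstrand_pairs if set(p) <= keep
        ),
        intersheet_pairs=frozenset(
            p for p in topology.intersheet_pairs if set(p) <= keep
        ),
        strand_direction={s: d for s, d in topology.strand_direction.items() if s in keep},
    )
    m, n = (int(x) for x in scheme.label.split("-"))
    sizes = sorted(
        (len(sub.sheet_members(1)), len(sub.sheet_members(2))), reverse=True
    )
    if sizes != [m, n]:
        raise ValueError(
            f"selection {sorted(keep)} has sheet sizes {sizes}, "
            f"incompatible with scheme {scheme_label}"
        )
    return sub


def extract_structure(structure: Structure, topology_subset: ZipperTopology) -> Structure:
    """Keep only the chains whose strand indices appear in ``topology_subset``.

    Chain order (hence 1-based strand numbering of the resulting structure)
    is preserved; pair it with ``topology_subset.renumbered()``.
    """
    keep_chains = {
        structure.chain_ids[k - 1] for k in topology_subset.strand_ids
    }
    atoms = [a for a in structure.atoms if a.chain_id in keep_chains]
    return Structure(atoms=atoms)


def mutate_to_glycine(structure: Structure, spec: MutationSpec) -> Structure:
    """Substitute glycine at the given positions in every chain.

    All side-chain atoms (everything beyond the backbone N, CA, C, O and the
    backbone hydrogens) of a mutated residue are removed and the residue name
    set to GLY; the backbone is untouched, so no rotamer modelling is needed.
    Idempotent: mutating an already-Gly position changes nothing.
    """
    keep = BACKBONE_ATOM_NAMES | {"H", "HA", "HA2", "HA3", "H1", "H2", "H3"}
    out: list[Atom] = []
    for atom in structure.atoms:
        if atom.residue_position in spec.positions:
            if atom.name not in keep:
                continue
            atom = replace(atom, residue_name="GLY")
        out.append(atom)
    return Structure(atoms=out)
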