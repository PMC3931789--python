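"""Protein structures with Sybyl-style atom types, and the geometric primitives
(rmsd, center of mass, rigid transforms, molecular weight) the rest of the
package is built on.

Structures are heavy-atom only: the pair potentials are derived from
crystallographic knowledge bases in which hydrogen positions are unobserved,
so hydrogens are dropped at parse time and never re-enter.  Coordinates are in
Angstrom throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    CorrespondenceError,
    EmptyStructureError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Heavy-atom monoisotopic-free standard atomic weights (Da).
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
    "P": 30.974,
}

# Element van der Waals radii (A) used for solvent-accessible surface area.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

CANONICAL_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

UNTYPED = "untyped"

# The 11-label type alphabet; 11 x 11 = 121 ordered pair potentials.
DEFAULT_ALPHABET = (
    "C.2", "C.3", "C.ar", "N.3", "N.am", "N.ar", "N.pl3",
    "O.2", "O.3", "O.co2", "S.3",
)


@dataclass(frozen=True)
class Pose:
    """A rigid-body transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        trans = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(rot), 1.0, atol=1e-8
        ):
            raise ValidationError("pose rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, quat_wxyz: Sequence[float], translation=(0.0, 0.0, 0.0)) -> "Pose":
        w, x, y, z = quat_wxyz
        rot = Rotation.from_quat([x, y, z, w]).as_matrix()
        pose = cls(rot, np.asarray(translation, dtype=float))
        # cache the exact input so save -> load -> save is byte-identical
        object.__setattr__(pose, "_quat", np.array([w, x, y, z], dtype=float))
        return pose

    def quaternion(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z) with non-negative w."""
        cached = getattr(self, "_quat", None)
        if cached is not None:
            return cached.copy()
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q

    def inverse(self) -> "Pose":
        rot_inv = self.rotation.T
        return Pose(rot_inv, -rot_inv @ self.translation)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class Atom:
    """One heavy atom; a read-only view into a :class:`TypedStructure`."""

    serial: int
    name: str
    residue_name: str
    residue_id: tuple  # (chain id, residue number, insertion code)
    element: str
    coords: np.ndarray
    atom_type: str = UNTYPED


class TypedStructure:
    """An ordered collection of heavy atoms, array-backed for vector math.

    Parallel arrays keep per-atom fields; :meth:`atoms` yields ``Atom`` views
    for element-wise access.  A structure is "typed" once every atom carries a
    label from the configured type alphabet (see :func:`assign_atom_types`).
    """

    def __init__(self, serial, name, residue_name, chain, residue_number,
                 insertion_code, element, coords, atom_type=None, provenance=""):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U4")
        self.residue_name = np.asarray(residue_name, dtype="U3")
        self.chain = np.asarray(chain, dtype="U4")
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.insertion_code = np.asarray(insertion_code, dtype="U1")
        self.element = np.asarray(element, dtype="U2")
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if atom_type is None:
            atom_type = [UNTYPED] * n
        self.atom_type = np.asarray(atom_type, dtype="U8")
        self.provenance = provenance
        if n and not np.all(np.isfinite(self.coords)):
            raise ValidationError("atom coordinates must be finite")

    def __len__(self) -> int:
        return len(self.serial)

    def atoms(self) -> Iterable[Atom]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            residue_name=str(self.residue_name[i]),
            residue_id=(str(self.chain[i]), int(self.residue_number[i]),
                        str(self.insertion_code[i])),
            element=str(self.element[i]),
            coords=self.coords[i].copy(),
            atom_type=str(self.atom_type[i]),
        )

    @property
    def is_typed(self) -> bool:
        return len(self) > 0 and not np.any(self.atom_type == UNTYPED)

    @property
    def chains(self) -> dict:
        """Partition of atom indices by chain id (insertion-order)."""
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.chain):
            out.setdefault(str(c), []).append(i)
        return out

    def residue_keys(self) -> list[tuple]:
        """(chain, residue number, insertion code, residue name) per atom."""
        return [
            (str(self.chain[i]), int(self.residue_number[i]),
             str(self.insertion_code[i]), str(self.residue_name[i]))
            for i in range(len(self))
        ]

    def select(self, mask: np.ndarray, provenance: str | None = None) -> "TypedStructure":
        mask = np.asarray(mask)
        return TypedStructure(
            self.serial[mask], self.name[mask], self.residue_name[mask],
            self.chain[mask], self.residue_number[mask],
            self.insertion_code[mask], self.element[mask], self.coords[mask],
            self.atom_type[mask],
            provenance if provenance is not None else self.provenance,
        )

    def with_coords(self, coords: np.ndarray) -> "TypedStructure":
        out = self.select(np.ones(len(self), dtype=bool))
        out.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        return out

    def copy(self) -> "TypedStructure":
        return self.select(np.ones(len(self), dtype=bool))


class AtomTypeTable:
    """Mapping (residue name, atom name) -> Sybyl-style atom type.

    Rows with residue ``*`` apply to every canonical residue (backbone atoms
    and the C-terminal OXT).  The table ships as an editable TSV so the typing
    scheme can be swapped without touching code.
    """

    def __init__(self, mapping: dict[tuple[str, str], str], alphabet: Sequence[str] | None = None):
        self.mapping = dict(mapping)
        if alphabet is None:
            alphabet = tuple(sorted(set(self.mapping.values())))
        self.alphabet = tuple(alphabet)

    @classmethod
    def from_file(cls, path) -> "AtomTypeTable":
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
                res, atom, typ = parts
                mapping[(res, atom)] = typ
        return cls(mapping)

    @classmethod
    def default(cls) -> "AtomTypeTable":
        with resources.as_file(resources.files("pairdock.data") / "atom_types.tsv") as p:
            table = cls.from_file(p)
        return cls(table.mapping, DEFAULT_ALPHABET)

    def lookup(self, residue_name: str, atom_name: str) -> str | None:
        typ = self.mapping.get((residue_name, atom_name))
        if typ is None and residue_name in CANONICAL_RESIDUES:
            typ = self.mapping.get(("*", atom_name))
        return typ

    def n_pair_potentials(self) -> int:
        return len(self.alphabet) ** 2


# ---------------------------------------------------------------------------
# PDB i/o


def read_pdb(path) -> TypedStructure:
    """Read a PDB file into an (untyped) heavy-atom structure.

    HETATM records, waters and hydrogens are excluded.  Alternate locations
    are resolved to a single conformer: highest occupancy wins, ties go to the
    alphabetically first altloc label.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    rows = {"serial": [], "name": [], "resname": [], "chain": [], "resnum": [],
            "icode": [], "element": [], "coords": []}
    # altloc groups: (chain, seqid, icode, atom name) -> best (occ, altloc, record)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                       res.name, atom.name)
                rec = (atom.serial, atom.name, res.name, chain.name,
                       res.seqid.num, res.seqid.icode.strip(),
                       atom.element.name.upper(),
                       (atom.pos.x, atom.pos.y, atom.pos.z))
                alt = atom.altloc or ""
                cand = (atom.occ, alt, rec)
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    occ0, alt0, _ = best[key]
                    if cand[0] > occ0 or (cand[0] == occ0 and alt < alt0):
                        best[key] = cand
    for key in order:
        _, _, rec = best[key]
        serial, name, resname, ch, resnum, icode, element, xyz = rec
        rows["serial"].append(serial)
        rows["name"].append(name)
        rows["resname"].append(resname)
        rows["chain"].append(ch)
        rows["resnum"].append(resnum)
        rows["icode"].append(icode)
        rows["element"].append(element)
        rows["coords"].append(xyz)
    if not rows["serial"]:
        raise EmptyStructureError(f"{path} contains no protein ATOM records")
    return TypedStructure(
        rows["serial"], rows["name"], rows["resname"], rows["chain"],
        rows["resnum"], rows["icode"], rows["element"],
        np.array(rows["coords"]), provenance=str(path),
    )


def write_pdb(structure: TypedStructure, path) -> None:
    """Write fixed-column ATOM records (chain ids must be single characters)."""
    with open(path, "w") as fh:
        for i in range(len(structure)):
            name = str(structure.name[i])
            # PDB column convention: 1-letter elements start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = structure.coords[i]
            fh.write(
                "ATOM  {serial:>5d} {name:4s}{alt:1s}{res:>3s} {chain:1s}"
                "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{b:6.2f}          {el:>2s}\n".format(
                    serial=int(structure.serial[i]) % 100000, name=padded,
                    alt=" ", res=str(structure.residue_name[i]),
                    chain=str(structure.chain[i])[:1] or "A",
                    resnum=int(structure.residue_number[i]) % 10000,
                    icode=str(structure.insertion_code[i]) or " ",
                    x=x, y=y, z=z, occ=1.0, b=0.0,
                    el=str(structure.element[i]),
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# typing


def assign_atom_types(structure: TypedStructure, table: AtomTypeTable | None = None) -> TypedStructure:
    """Assign a type to every heavy atom of a canonical residue.

    Atoms of non-canonical residues (and canonical-residue atoms missing from
    the table) are dropped with a logged warning; the operation is total and
    idempotent on canonical-residue structures.
    """
    if table is None:
        table = AtomTypeTable.default()
    keep = np.zeros(len(structure), dtype=bool)
    types = np.empty(len(structure), dtype="U8")
    skipped: dict[str, int] = {}
    for i in range(len(structure)):
        res = str(structure.residue_name[i])
        typ = table.lookup(res, str(structure.name[i]))
        if typ is None:
            skipped[res] = skipped.get(res, 0) + 1
            continue
        keep[i] = True
        types[i] = typ
    if skipped:
        logger.warning("assign_atom_types dropped atoms of unknown residues/atoms: %s", skipped)
    out = structure.select(keep)
    out.atom_type = types[keep]
    return out


# ---------------------------------------------------------------------------
# geometric primitives


_SELECTIONS: dict[str, Callable[[TypedStructure], np.ndarray]] = {
    "all": lambda s: np.ones(len(s), dtype=bool),
    "backbone": lambda s: np.isin(s.name, BACKBONE_ATOMS),
    "ca": lambda s: s.name == "CA",
}


def selection_mask(structure: TypedStructure, selection) -> np.ndarray:
    if selection is None:
        selection = "all"
    if isinstance(selection, str):
        try:
            return _SELECTIONS[selection](structure)
        except KeyError:
            raise ValidationError(f"unknown selection {selection!r}") from None
    if callable(selection):
        return np.array([bool(selection(a)) for a in structure.atoms()])
    return np.asarray(selection, dtype=bool)


def _paired_coords(a: TypedStructure, b: TypedStructure, selection) -> tuple[np.ndarray, np.ndarray]:
    ma, mb = selection_mask(a, selection), selection_mask(b, selection)
    sa, sb = a.select(ma), b.select(mb)
    if len(sa) != len(sb):
        raise CorrespondenceError(
            f"selection sizes differ: {len(sa)} vs {len(sb)} atoms"
        )
    if len(sa) == 0:
        raise CorrespondenceError("empty selection")
    mismatch = (sa.name != sb.name) | (sa.residue_name != sb.residue_name)
    if np.any(mismatch):
        i = int(np.argmax(mismatch))
        raise CorrespondenceError(
            f"atom mismatch at position {i}: "
            f"{sa.residue_name[i]}/{sa.name[i]} vs {sb.residue_name[i]}/{sb.name[i]}"
        )
    return sa.coords, sb.coords


def rmsd(a: TypedStructure, b: TypedStructure, selection=None, superpose: bool = False) -> float:
    """Root-mean-square deviation between corresponding atoms (A).

    With ``superpose`` the deviation is measured after optimal least-squares
    rigid superposition of ``b`` onto ``a`` (Kabsch).
    """
    xa, xb = _paired_coords(a, b, selection)
    if superpose:
        ca, cb = xa.mean(axis=0), xb.mean(axis=0)
        _, rssd = Rotation.align_vectors(xa - ca, xb - cb)
        return float(rssd / np.sqrt(len(xa)))
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def superposition_onto(a: TypedStructure, b: TypedStructure, selection=None) -> Pose:
    """Pose that maps ``b``'s frame onto ``a``'s (least-squares on the selection)."""
    xa, xb = _paired_coords(a, b, selection)
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    rot, _ = Rotation.align_vectors(xa - ca, xb - cb)
    rmat = rot.as_matrix()
    return Pose(rmat, ca - rmat @ cb)


def center_of_mass(structure: TypedStructure) -> np.ndarray:
    """Mass-weighted mean coordinate (A)."""
    if len(structure) == 0:
        raise EmptyStructureError("center_of_mass of an empty structure")
    masses = _masses(structure)
    return (structure.coords * masses[:, None]).sum(axis=0) / masses.sum()


def _masses(structure: TypedStructure) -> np.ndarray:
    masses = np.empty(len(structure))
    for i, el in enumerate(structure.element):
        try:
            masses[i] = ATOMIC_MASSES[str(el).upper()]
        except KeyError:
            raise ValidationError(
                f"unknown element {el!r} for atom {structure.name[i]} "
                f"(serial {structure.serial[i]})"
            ) from None
    return masses


def molecular_weight(structure: TypedStructure) -> float:
    """Heavy-atom mass sum in Da (the package's molecular-weight convention)."""
    if len(structure) == 0:
        return 0.0
    return float(_masses(structure).sum())


def apply_pose(structure: TypedStructure, pose: Pose) -> TypedStructure:
    """Rigidly transform a structure; intra-structure distances are preserved."""
    return structure.with_coords(pose.apply(structure.coords))
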