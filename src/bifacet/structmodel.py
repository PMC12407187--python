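"""Core structural data model, coordinate I/O and rigid-body primitives.

The model is deliberately backbone-centric: every residue must carry a CA
atom, and all geometry (docking scores, symmetry closure, superposition)
operates on CA coordinates unless an operation states otherwise.  Coordinates
are in Angstrom, residue indices are 1-based and ranges are inclusive on both
ends.  The principal symmetry axis of every assembly is +z through the origin.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AxisMismatchError,
    CapacityError,
    ConditioningError,
    FormatError,
    ValidationError,
)

EntityRole = Literal["A", "B", "C", "D", "other"]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}

# Single-character chain-id alphabet of the strict PDB dialect.
PDB_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class Atom:
    """One atom: label, element and position (Angstrom)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """A residue: 1-based index within its chain, one-letter code, atoms."""

    index: int
    amino_acid: str
    atoms: list[Atom]

    def __post_init__(self):
        if self.amino_acid not in set(AA_LETTERS) | {"X"}:
            raise ValidationError(
                f"residue {self.index}: amino_acid {self.amino_acid!r} is not a "
                "canonical one-letter code or 'X'"
            )
        if self.ca is None:
            raise ValidationError(f"residue {self.index} has no CA atom")

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass
class ChainModel:
    """An ordered chain of residues with an entity role and helix annotations.

    ``entity_role`` labels the subunit identity (A/B/C/D) used throughout the
    bifaceted architecture; ``helix_ranges`` are inclusive 1-based (start, end)
    residue intervals.  ``trimer_index`` and ``face`` are assembly bookkeeping:
    which heterotrimer copy within a ring and which ring of a dihedral pair
    the chain belongs to.
    """

    chain_id: str
    entity_role: EntityRole
    residues: list[Residue]
    helix_ranges: list[tuple[int, int]] = field(default_factory=list)
    trimer_index: int | None = None
    face: int | None = None

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(f"chain {self.chain_id}: residue indices not strictly increasing")
        self._check_helix_ranges()

    def _check_helix_ranges(self):
        if not self.helix_ranges:
            return
        idx = {r.index for r in self.residues}
        prev_end = -math.inf
        for start, end in self.helix_ranges:
            if start > end or start <= prev_end:
                raise ValidationError(
                    f"chain {self.chain_id}: helix_ranges must be ordered and disjoint"
                )
            if start not in idx or end not in idx:
                raise ValidationError(
                    f"chain {self.chain_id}: helix range ({start}, {end}) outside residue bounds"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of CA positions in residue order."""
        return np.array([r.ca.position for r in self.residues], dtype=float)

    def copy(self) -> "ChainModel":
        return ChainModel(
            chain_id=self.chain_id,
            entity_role=self.entity_role,
            residues=[
                Residue(r.index, r.amino_acid, [Atom(a.name, a.element, a.position.copy()) for a in r.atoms])
                for r in self.residues
            ],
            helix_ranges=list(self.helix_ranges),
            trimer_index=self.trimer_index,
            face=self.face,
        )


@dataclass
class StructureModel:
    """An ordered collection of chains; the principal symmetry axis is +z."""

    chains: list[ChainModel]
    symmetry_axis_convention: str = "+z"
    # Set by realize_dock: the two-fold operation placing the second ring.
    dihedral_operation: "RigidTransform | None" = None

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate chain_ids: {sorted(ids)}")

    def __len__(self) -> int:
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chains_by_role(self, role: EntityRole, face: int | None = None) -> list[ChainModel]:
        return [
            c for c in self.chains
            if c.entity_role == role and (face is None or c.face == face)
        ]

    def ca_coords(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 3))
        return np.vstack([c.ca_coords() for c in self.chains])

    def copy(self) -> "StructureModel":
        return StructureModel(
            chains=[c.copy() for c in self.chains],
            symmetry_axis_convention=self.symmetry_axis_convention,
            dihedral_operation=self.dihedral_operation,
        )


# ---------------------------------------------------------------------------
# Rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> rotation @ p + translation (Angstrom).

    The rotation must be orthonormal with determinant +1 (tolerance 1e-8).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or not math.isclose(
            float(np.linalg.det(rot)), 1.0, abs_tol=1e-8
        ):
            raise ValidationError("rotation is not orthonormal with det +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, axis: Sequence[float], angle_deg: float,
                        translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    @classmethod
    def rotation_about_z(cls, angle_deg: float) -> "RigidTransform":
        return cls.from_rotvec_deg((0, 0, 1), angle_deg)

    @classmethod
    def translation_along_z(cls, dz: float) -> "RigidTransform":
        return cls(np.eye(3), np.array([0.0, 0.0, dz]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


def apply_transform(s: StructureModel, t: RigidTransform) -> StructureModel:
    """Apply a rigid transform to every atom, returning a new structure."""
    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            res.atoms = [
                Atom(a.name, a.element, t.apply(a.position)) for a in res.atoms
            ]
    return out


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    Points correspond positionally.  Returns the optimal proper rigid
    transform and the post-fit RMSD in Angstrom.  Raises ConditioningError
    for fewer than three points or collinear sets, for which the rotation is
    not uniquely determined.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValidationError("point sets must be equal-shape (N, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ConditioningError("superposition requires at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # Collinear sets leave a rotational degree of freedom about the line.
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(tgt_c, tol=1e-8) < 2:
        raise ConditioningError("point sets are collinear; rotation underdetermined")
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    rmat = rot.as_matrix()
    translation = tgt.mean(axis=0) - rmat @ mob.mean(axis=0)
    transform = RigidTransform(rmat, translation)
    moved = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return transform, rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("RMSD requires equal-shape coordinate sets")
    if a.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_angle_about_axis(t: RigidTransform, axis: Sequence[float]) -> float:
    """Rotation angle of ``t`` about the given unit axis, in [0, 360) degrees.

    Raises AxisMismatchError when t's rotation axis is not parallel (either
    sense) to the requested axis within 1e-6.
    """
    ax = np.asarray(axis, dtype=float)
    if not math.isclose(float(np.linalg.norm(ax)), 1.0, abs_tol=1e-6):
        raise ValidationError("axis must be unit-norm")
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return 0.0
    raxis = rotvec / angle
    dot = float(np.dot(raxis, ax))
    if abs(abs(dot) - 1.0) > 1e-6:
        raise AxisMismatchError(
            f"rotation axis {raxis} not parallel to requested axis {ax}"
        )
    deg = math.degrees(angle)
    if dot < 0:
        deg = 360.0 - deg
    return deg % 360.0


# ---------------------------------------------------------------------------
# Coordinate file I/O (PDB via biotite; mmCIF via biotite's pdbx reader)

_ROLE_REMARK = "REMARK 250 BIFACET ROLE"
_HELIX_REMARK = "REMARK 250 BIFACET HELIX"
_RELABEL_REMARK = "REMARK 250 BIFACET RELABEL"


def _to_atom_array(s: StructureModel, chain_ids: dict[str, str]):
    import biotite.structure as struc

    n_atoms = sum(len(r.atoms) for c in s.chains for r in c.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for chain in s.chains:
        cid = chain_ids[chain.chain_id]
        for res in chain.residues:
            res_name = _AA_1TO3.get(res.amino_acid, "UNK")
            for atom in res.atoms:
                arr.coord[i] = atom.position
                arr.chain_id[i] = cid
                arr.res_id[i] = res.index
                arr.res_name[i] = res_name
                arr.atom_name[i] = atom.name
                arr.element[i] = atom.element
                arr.hetero[i] = False
                i += 1
    return arr


def _relabel_for_pdb(s: StructureModel, allow_relabel: bool) -> dict[str, str]:
    """Deterministic two-pass chain relabeling into the 62-character alphabet."""
    ids = [c.chain_id for c in s.chains]
    if len(ids) > len(PDB_CHAIN_ALPHABET):
        raise CapacityError(
            f"{len(ids)} chains exceed the {len(PDB_CHAIN_ALPHABET)}-chain "
            "capacity of the strict PDB dialect; write mmCIF instead"
        )
    if all(len(i) == 1 and i in PDB_CHAIN_ALPHABET for i in ids):
        return {i: i for i in ids}
    if not allow_relabel:
        raise CapacityError(
            "chain ids exceed single-character PDB space and relabeling is disabled"
        )
    # Pass 1: keep usable single-char ids. Pass 2: assign the rest in order.
    mapping: dict[str, str] = {}
    used = set()
    for i in ids:
        if len(i) == 1 and i in PDB_CHAIN_ALPHABET:
            mapping[i] = i
            used.add(i)
    free = iter(c for c in PDB_CHAIN_ALPHABET if c not in used)
    for i in ids:
        if i not in mapping:
            mapping[i] = next(free)
    return mapping


def write_structure(s: StructureModel, path, format: str = "pdb",
                    allow_relabel: bool = True) -> None:
    """Write a structure as PDB (strict columnar, ATOM records only) or mmCIF.

    Role, helix-range and chain-relabel metadata are recorded in REMARK 250
    lines of the PDB dialect so that files round-trip through
    :func:`read_structure`.
    """
    if not s.chains or s.n_residues == 0:
        raise ValidationError("refusing to write an empty structure")
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        mapping = _relabel_for_pdb(s, allow_relabel)
        arr = _to_atom_array(s, mapping)
        pdb = PDBFile()
        pdb.set_structure(arr)
        remarks = []
        for old, new in mapping.items():
            if old != new:
                remarks.append(f"{_RELABEL_REMARK} {new} {old}")
        for chain in s.chains:
            cid = mapping[chain.chain_id]
            role = chain.entity_role
            tri = "-" if chain.trimer_index is None else chain.trimer_index
            face = "-" if chain.face is None else chain.face
            remarks.append(f"{_ROLE_REMARK} {cid} {role} {tri} {face}")
            for start, end in chain.helix_ranges:
                remarks.append(f"{_HELIX_REMARK} {cid} {start} {end}")
        pdb.lines = remarks + pdb.lines
        pdb.write(str(path))
    elif format == "mmcif":
        import biotite.structure.io.pdbx as pdbx

        mapping = {c.chain_id: c.chain_id for c in s.chains}
        arr = _to_atom_array(s, mapping)
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, arr)
        cif.write(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_structure(path, format: str = "pdb") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Residue indices follow author numbering; every residue must have a CA
    atom.  Heteroatoms are ignored (backbone-only model).
    """
    import biotite.structure as struc

    roles: dict[str, str] = {}
    trimers: dict[str, int] = {}
    faces: dict[str, int] = {}
    helices: dict[str, list[tuple[int, int]]] = {}
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith(_ROLE_REMARK):
                cid, role, tri, face = line.split()[4:8]
                roles[cid] = role
                if tri != "-":
                    trimers[cid] = int(tri)
                if face != "-":
                    faces[cid] = int(face)
            elif line.startswith(_HELIX_REMARK):
                cid, start, end = line.split()[4:7]
                helices.setdefault(cid, []).append((int(start), int(end)))
        try:
            pdb = PDBFile.read(io.StringIO(text))
            arr = pdb.get_structure(model=1)
        except Exception as exc:  # biotite raises various parse errors
            raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    elif format == "mmcif":
        import biotite.structure.io.pdbx as pdbx

        try:
            cif = pdbx.CIFFile.read(str(path))
            arr = pdbx.get_structure(cif, model=1)
        except Exception as exc:
            raise FormatError(f"{path}: not parseable as mmCIF: {exc}") from exc
    else:
        raise ValueError(f"unknown format {format!r}")

    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no ATOM records")

    chains: list[ChainModel] = []
    missing_ca: list[str] = []
    for cid in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == cid]
        residues = []
        # preserve file order of residues within the chain
        _, first_idx = np.unique(sub.res_id, return_index=True)
        for rid in sub.res_id[np.sort(first_idx)]:
            ratoms = sub[sub.res_id == rid]
            atoms = [
                Atom(str(a.atom_name), str(a.element).capitalize() or "C", a.coord)
                for a in ratoms
            ]
            if not any(a.name == "CA" for a in atoms):
                missing_ca.append(f"{cid}/{int(rid)}")
                continue
            aa = _AA_3TO1.get(str(ratoms.res_name[0]), "X")
            residues.append(Residue(int(rid), aa, atoms))
        role = roles.get(str(cid), "other")
        if role not in ("A", "B", "C", "D"):
            role = "other"
        chains.append(
            ChainModel(
                chain_id=str(cid),
                entity_role=role,  # type: ignore[arg-type]
                residues=residues,
                helix_ranges=helices.get(str(cid), []),
                trimer_index=trimers.get(str(cid)),
                face=faces.get(str(cid)),
            )
        )
    if missing_ca:
        raise ValidationError(
            f"{path}: residues without CA atoms: {', '.join(missing_ca)}"
        )
    return StructureModel(chains=chains)
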