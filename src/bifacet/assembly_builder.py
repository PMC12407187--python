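"""Hierarchical composition and analysis of bifaceted assemblies.

A full bifaceted model is two 15-chain crowns docked across a dihedral
two-fold: the (ABC)5 ring and an (ABD)5 ring whose interface subunits are
relabeled D.  Interface-class analysis enumerates which subunit-role pairs
the architecture requires to be designed — the cyclic ring-seam interface
inherited from the building block and the new dihedral interface — and
whether each is symmetric or asymmetric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .axial_dock import DockPose, realize_dock
from .errors import ValidationError
from .structmodel import StructureModel
from .symmetry import CyclicSpec, verify_symmetry


@dataclass(frozen=True)
class InterfaceClass:
    """One designed interface class between subunit roles."""

    role_pair: tuple[str, str]  # sorted
    relation: str  # intra_trimer | cyclic | dihedral
    symmetry: str  # symmetric | asymmetric
    equivalent_role_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.relation not in ("intra_trimer", "cyclic", "dihedral"):
            raise ValidationError(f"unknown relation {self.relation!r}")
        if self.symmetry not in ("symmetric", "asymmetric"):
            raise ValidationError(f"unknown symmetry {self.symmetry!r}")


@dataclass
class AssemblyModel:
    """A composed bifaceted model with its dock parameters."""

    structure: StructureModel
    component_rings: tuple[str, str]
    pose: DockPose
    addressable_roles: tuple[str, ...]

    def __post_init__(self):
        if len(self.structure.chains) != 30:
            raise ValidationError(
                f"a full bifaceted model has 30 chains, got {len(self.structure.chains)}"
            )


def build_bifaceted(
    ring_abc: StructureModel, ring_abd: StructureModel, pose: DockPose
) -> AssemblyModel:
    """Dock two 15-chain crowns into a 30-chain bifaceted assembly.

    Roles on the second ring are tracked per face, so the six addressable
    identities (A, B, C on one face; A', B', D on the other) stay distinct
    even when sequences coincide.
    """
    for name, ring in (("ring_abc", ring_abc), ("ring_abd", ring_abd)):
        if len(ring.chains) != 15:
            raise ValidationError(f"{name} must be a 15-chain crown")
    if not pose.is_scored:
        raise ValidationError("pose must be scored before realization")
    structure = realize_dock(ring_abc, ring_abd, pose)
    return AssemblyModel(
        structure=structure,
        component_rings=("ABC5", "ABD5"),
        pose=pose,
        addressable_roles=("A", "B", "C", "A'", "B'", "D"),
    )


def _chain_contacts(structure: StructureModel, cutoff: float) -> list[tuple[int, int]]:
    coords = [c.ca_coords() for c in structure.chains]
    trees = [cKDTree(c) for c in coords]
    hits = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if any(trees[i].query_ball_tree(trees[j], cutoff)):
                hits.append((i, j))
    return hits


def count_designed_interface_classes(
    a: AssemblyModel | StructureModel,
    contact_cutoff: float = 8.0,
    merge_equivalent_cyclic: bool = True,
) -> list[InterfaceClass]:
    """Enumerate designed interface classes across distinct trimers.

    Contacts within one heterotrimer are inherited from the building block
    and excluded.  Cyclic classes (within one ring) that are images of the
    same ring-seam interface under the ring's backbone rotational symmetry
    are merged into a single class labelled by the lexicographically
    smallest role pair, with the equivalents recorded; the dihedral class
    (across rings) is reported separately.  A class is asymmetric when the
    two partners' roles or sequences differ.
    """
    structure = a.structure if isinstance(a, AssemblyModel) else a
    chains = structure.chains
    if any(c.entity_role == "other" for c in chains):
        raise ValidationError("all chains must carry entity roles")
    if any(c.trimer_index is None for c in chains):
        raise ValidationError("all chains must carry trimer bookkeeping")

    found: dict[tuple[tuple[str, str], str], str] = {}
    for i, j in _chain_contacts(structure, contact_cutoff):
        ci, cj = chains[i], chains[j]
        same_face = (ci.face or 0) == (cj.face or 0)
        if same_face and ci.trimer_index == cj.trimer_index:
            continue  # inherited intra-trimer interface
        relation = "cyclic" if same_face else "dihedral"
        role_pair = tuple(sorted((ci.entity_role, cj.entity_role)))
        asym = ci.entity_role != cj.entity_role or ci.sequence != cj.sequence
        symmetry = "asymmetric" if asym else "symmetric"
        key = (role_pair, relation)
        if found.get(key) != "asymmetric":
            found[key] = symmetry

    classes: list[InterfaceClass] = []
    cyclic = sorted(k for k in found if k[1] == "cyclic")
    if merge_equivalent_cyclic and len(cyclic) > 1:
        # In a backbone-Cn ring every ring-seam contact is an image of one
        # designed interface; report one class for the whole orbit.
        rep = cyclic[0]
        symmetry = (
            "asymmetric"
            if any(found[k] == "asymmetric" for k in cyclic)
            else "symmetric"
        )
        classes.append(InterfaceClass(
            role_pair=rep[0], relation="cyclic", symmetry=symmetry,
            equivalent_role_pairs=tuple(k[0] for k in cyclic[1:]),
        ))
    else:
        for k in cyclic:
            classes.append(InterfaceClass(role_pair=k[0], relation="cyclic",
                                          symmetry=found[k]))
    for k in sorted(k for k in found if k[1] == "dihedral"):
        classes.append(InterfaceClass(role_pair=k[0], relation="dihedral",
                                      symmetry=found[k]))
    return classes


def assembly_report(a: AssemblyModel | StructureModel,
                    contact_cutoff: float = 8.0) -> dict:
    """Structured, JSON-serializable summary of an assembly."""
    structure = a.structure if isinstance(a, AssemblyModel) else a
    role_counts: dict[str, int] = {}
    residue_counts: dict[str, int] = {}
    for c in structure.chains:
        key = c.entity_role if c.face in (None, 0) else f"{c.entity_role}'"
        if c.entity_role == "D":
            key = "D"
        role_counts[key] = role_counts.get(key, 0) + 1
        residue_counts[key] = residue_counts.get(key, 0) + len(c)
    try:
        sym = verify_symmetry(structure, CyclicSpec(order_n=5), tol=1e-3)
        sym_d = {
            "cyclic_closure_rmsd": sym.cyclic_closure_rmsd,
            "dihedral_backbone_rmsd": sym.dihedral_backbone_rmsd,
            "is_pseudo": sym.is_pseudo,
        }
    except Exception as exc:
        sym_d = {"error": str(exc)}
    try:
        classes = [
            {"role_pair": list(c.role_pair), "relation": c.relation,
             "symmetry": c.symmetry}
            for c in count_designed_interface_classes(a, contact_cutoff)
        ]
    except ValidationError as exc:
        classes = [{"error": str(exc)}]
    report = {
        "n_chains": len(structure.chains),
        "n_residues": structure.n_residues,
        "chains_per_role": role_counts,
        "residues_per_role": residue_counts,
        "symmetry": sym_d,
        "interface_classes": classes,
    }
    if isinstance(a, AssemblyModel):
        report["pose"] = {
            "phi": a.pose.phi, "z_offset": a.pose.z_offset,
            "truncation": a.pose.truncation, "score": a.pose.score,
        }
        report["addressable_roles"] = list(a.addressable_roles)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
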