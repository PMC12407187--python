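"""Cyclic and dihedral symmetry generation and verification.

A crown-like ring is built by expanding an asymmetric unit about +z; the
opposing ring of a dihedral pair is generated by a 180-degree flip about the
x axis followed by a rotation ``phi`` about z and a translation ``z_offset``
along z.  ``phi`` is canonicalized modulo 360/n since larger values are
symmetry-equivalent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import PartitionError, ValidationError
from .structmodel import (
    PDB_CHAIN_ALPHABET,
    ChainModel,
    RigidTransform,
    StructureModel,
    apply_transform,
)


@dataclass(frozen=True)
class CyclicSpec:
    """Cyclic symmetry of order ``order_n`` about +z."""

    order_n: int
    axis: str = "+z"

    def __post_init__(self):
        if self.order_n < 2:
            raise ValidationError("cyclic order must be >= 2")


@dataclass(frozen=True)
class SymmetryReport:
    """Closure RMSDs under the cyclic and dihedral operations.

    ``is_pseudo`` is set when the backbone closes within tolerance under an
    operation while the amino-acid sequences of the paired chains differ —
    the defining property of a pseudosymmetric assembly.
    """

    cyclic_closure_rmsd: float
    dihedral_backbone_rmsd: float
    n_chains: int
    is_pseudo: bool

    def __post_init__(self):
        if self.cyclic_closure_rmsd < 0 or self.dihedral_backbone_rmsd < 0:
            raise ValidationError("rmsd fields must be >= 0")


def canonical_phi(phi: float, order_n: int) -> float:
    """Reduce a z-rotation to the canonical [0, 360/order_n) range."""
    period = 360.0 / order_n
    return phi % period


def relabel_chains(chains: list[ChainModel]) -> list[ChainModel]:
    """Assign deterministic chain ids (A, B, C, ... then A1, B1, ...)."""
    out = []
    for i, chain in enumerate(chains):
        c = chain.copy()
        if i < len(PDB_CHAIN_ALPHABET):
            c.chain_id = PDB_CHAIN_ALPHABET[i]
        else:
            c.chain_id = f"{PDB_CHAIN_ALPHABET[i % len(PDB_CHAIN_ALPHABET)]}{i // len(PDB_CHAIN_ALPHABET)}"
        out.append(c)
    return out


def expand_cyclic(asu: StructureModel, spec: CyclicSpec) -> StructureModel:
    """Expand an asymmetric unit into ``order_n`` copies about +z.

    Copy k is rotated by k*(360/order_n) degrees; chains are relabeled
    deterministically and each copy's ``trimer_index`` is set to k.
    """
    copies: list[ChainModel] = []
    for k in range(spec.order_n):
        rot = RigidTransform.rotation_about_z(k * 360.0 / spec.order_n)
        moved = apply_transform(asu, rot)
        for chain in moved.chains:
            chain.trimer_index = k
            copies.append(chain)
    return StructureModel(chains=relabel_chains(copies))


def dihedral_flip_transform(phi: float, z_offset: float) -> RigidTransform:
    """The two-fold operation: flip 180 about x, rotate phi about z, lift by z."""
    flip = RigidTransform.from_rotvec_deg((1, 0, 0), 180.0)
    rot = RigidTransform.rotation_about_z(phi)
    lift = RigidTransform.translation_along_z(z_offset)
    return lift.compose(rot.compose(flip))


def dihedral_partner(ring: StructureModel, phi: float, z_offset: float) -> StructureModel:
    """Return the opposing ring of a dihedral pair; the input is unmodified."""
    return apply_transform(ring, dihedral_flip_transform(phi, z_offset))


def _greedy_chain_pairing(
    moved: list[np.ndarray], original: list[np.ndarray]
) -> list[tuple[int, int]]:
    """Pair transformed chains with original chains by nearest centroid.

    Greedy global-minimum matching; only chains with equal residue counts
    may pair.  Validated against exhaustive permutation search in the tests.
    """
    cm = [c.mean(axis=0) for c in moved]
    co = [c.mean(axis=0) for c in original]
    candidates = []
    for i, j in itertools.product(range(len(moved)), range(len(original))):
        if moved[i].shape[0] == original[j].shape[0]:
            candidates.append((float(np.linalg.norm(cm[i] - co[j])), i, j))
    candidates.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        pairs.append((i, j))
        used_i.add(i)
        used_j.add(j)
    return pairs


def _closure_rmsd(
    s: StructureModel, op: RigidTransform
) -> tuple[float, list[tuple[int, int]]]:
    """CA-RMSD between s and op(s) under optimal chain re-pairing."""
    coords = [c.ca_coords() for c in s.chains]
    moved = [op.apply(c) for c in coords]
    pairs = _greedy_chain_pairing(moved, coords)
    if len(pairs) < len(coords):
        return float("inf"), pairs
    sq = 0.0
    n = 0
    for i, j in pairs:
        d = moved[i] - coords[j]
        sq += float(np.sum(d * d))
        n += d.shape[0]
    return math.sqrt(sq / n), pairs


def verify_symmetry(s: StructureModel, spec: CyclicSpec, tol: float = 0.5) -> SymmetryReport:
    """Measure cyclic and dihedral backbone closure of an assembly.

    The cyclic check rotates the assembly by 360/order_n about z and measures
    the CA-RMSD to itself under optimal chain re-pairing.  The dihedral check
    flips the assembly 180 degrees about an in-plane axis (after recentering
    along z) and searches the residual z-rotation freedom over chain-centroid
    candidate angles, reporting the best closure.
    """
    if not s.chains:
        raise ValidationError("empty structure")
    if len(s.chains) % spec.order_n != 0:
        raise PartitionError(
            f"{len(s.chains)} chains not divisible by order {spec.order_n}"
        )
    rot = RigidTransform.rotation_about_z(360.0 / spec.order_n)
    cyc_rmsd, cyc_pairs = _closure_rmsd(s, rot)

    # Recenter along z so the putative two-fold axes lie in the z=0 plane.
    zc = float(s.ca_coords()[:, 2].mean())
    center = RigidTransform.translation_along_z(-zc)
    recentered = apply_transform(s, center)
    flip = RigidTransform.from_rotvec_deg((1, 0, 0), 180.0)
    coords = [c.ca_coords() for c in recentered.chains]
    flipped0 = [flip.apply(c) for c in coords]
    # Candidate residual z-rotations: azimuth differences between the first
    # flipped chain's centroid and every original chain centroid.
    ref = flipped0[0].mean(axis=0)
    ref_az = math.atan2(ref[1], ref[0])
    best = (float("inf"), [])
    seen: set[float] = set()
    for c in coords:
        cen = c.mean(axis=0)
        ang = math.degrees(math.atan2(cen[1], cen[0]) - ref_az) % 360.0
        key = round(ang, 6)
        if key in seen:
            continue
        seen.add(key)
        op = RigidTransform.rotation_about_z(ang).compose(flip)
        r, p = _closure_rmsd(recentered, op)
        if r < best[0]:
            best = (r, p)
    dih_rmsd, dih_pairs = best

    def _pseudo(rmsd: float, pairs: list[tuple[int, int]]) -> bool:
        if rmsd > tol:
            return False
        return any(
            s.chains[i].sequence != s.chains[j].sequence for i, j in pairs
        )

    is_pseudo = _pseudo(cyc_rmsd, cyc_pairs) or _pseudo(dih_rmsd, dih_pairs)
    return SymmetryReport(
        cyclic_closure_rmsd=cyc_rmsd,
        dihedral_backbone_rmsd=dih_rmsd,
        n_chains=len(s.chains),
        is_pseudo=is_pseudo,
    )
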