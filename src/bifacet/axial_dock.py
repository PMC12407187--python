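"""Axial dihedral docking: enumerate and score docks of two rings.

Sampling is restricted to the degrees of freedom of a dihedral arrangement
about a shared symmetry axis: a rotation phi about z (canonical range
[0, 360/n)), a translation z along z, and the C-subunit truncation level of
the building block.  Each pose is scored with a transparent
contacts-minus-weighted-clashes function on CA atoms: contacts are counted
only between C-role chains (the designable interface) while clashes are
counted over all chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structmodel import StructureModel
from .symmetry import dihedral_partner, relabel_chains
from .synthetic_blocks import truncate_c_subunit


@dataclass(frozen=True)
class ScoreParams:
    """Cutoffs (Angstrom) and clash weight of the dock score."""

    contact_cutoff: float = 8.0
    clash_cutoff: float = 3.5
    clash_weight: float = 10.0

    def __post_init__(self):
        if not self.clash_cutoff < self.contact_cutoff:
            raise ValidationError("clash_cutoff must be < contact_cutoff")
        if self.clash_weight <= 0:
            raise ValidationError("clash_weight must be > 0")


@dataclass(frozen=True)
class DockPose:
    """One sampled (phi, z, truncation) triple with score components."""

    phi: float
    z_offset: float
    truncation: int
    n_contacts: int | None = None
    n_clashes: int | None = None
    score: float | None = None

    def __post_init__(self):
        for v in (self.n_contacts, self.n_clashes):
            if v is not None and v < 0:
                raise ValidationError("contact/clash counts must be >= 0")

    @property
    def is_scored(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class DockGrid:
    """The sampled grid: phi values, z offsets and truncation levels."""

    phi_values: tuple[float, ...]
    z_values: tuple[float, ...]
    truncation_levels: tuple[int, ...] = (0,)
    cyclic_order: int = 5

    def __post_init__(self):
        if not (self.phi_values and self.z_values and self.truncation_levels):
            raise ValidationError("grid lists must be nonempty")
        period = 360.0 / self.cyclic_order
        for phi in self.phi_values:
            if not (0.0 <= phi < period):
                raise ValidationError(
                    f"phi {phi} outside canonical range [0, {period})"
                )


def enumerate_docks(ring: StructureModel, grid: DockGrid) -> list[DockPose]:
    """One unscored pose per (phi, z, truncation) grid point."""
    if not ring.chains:
        raise ValidationError("empty ring")
    return [
        DockPose(phi=phi, z_offset=z, truncation=t)
        for t in grid.truncation_levels
        for phi in grid.phi_values
        for z in grid.z_values
    ]


def count_interface_pairs(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float, strict: bool = False
) -> int:
    """Number of cross-set CA pairs within ``cutoff`` (<= or < when strict)."""
    if coords_a.size == 0 or coords_b.size == 0:
        return 0
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, cutoff)
    if not strict:
        return int(sum(len(p) for p in pairs))
    n = 0
    for i, idxs in enumerate(pairs):
        for j in idxs:
            if np.linalg.norm(coords_a[i] - coords_b[j]) < cutoff:
                n += 1
    return n


def score_pose(
    ring: StructureModel, pose: DockPose, params: ScoreParams = ScoreParams()
) -> DockPose:
    """Score a pose: contacts on the C-C' interface minus weighted clashes."""
    truncated = truncate_c_subunit(ring, pose.truncation)
    partner = dihedral_partner(truncated, pose.phi, pose.z_offset)

    c_a = np.vstack([c.ca_coords() for c in truncated.chains if c.entity_role == "C"])
    c_b = np.vstack([c.ca_coords() for c in partner.chains if c.entity_role == "C"])
    all_a = truncated.ca_coords()
    all_b = partner.ca_coords()

    n_contacts = count_interface_pairs(c_a, c_b, params.contact_cutoff)
    n_clashes = count_interface_pairs(all_a, all_b, params.clash_cutoff, strict=True)
    score = n_contacts - params.clash_weight * n_clashes
    return replace(pose, n_contacts=n_contacts, n_clashes=n_clashes, score=score)


def rank_docks(poses: list[DockPose], top_k: int) -> list[DockPose]:
    """Rank scored poses: descending score, then fewer clashes, more contacts,
    smaller |z|, smaller phi.  Deterministic for any input order."""
    for p in poses:
        if not p.is_scored:
            raise ValidationError(f"unscored pose in ranking input: {p}")
    ordered = sorted(
        poses,
        key=lambda p: (-p.score, p.n_clashes, -p.n_contacts, abs(p.z_offset), p.phi),
    )
    return ordered[:top_k]


def realize_dock(
    ring_c: StructureModel, ring_d: StructureModel, pose: DockPose
) -> StructureModel:
    """Compose the two-ring assembly defined by a scored pose.

    The second ring is truncated per the pose, placed by the dihedral flip,
    its C-role chains relabeled to role D, and all chains get fresh ids and
    face bookkeeping (0 = first ring, 1 = second).  The two-fold operation
    is stored on the result for downstream interface pairing.
    """
    from .symmetry import dihedral_flip_transform

    top = truncate_c_subunit(ring_c, pose.truncation)
    bottom = dihedral_partner(truncate_c_subunit(ring_d, pose.truncation),
                              pose.phi, pose.z_offset)
    chains = []
    for c in top.chains:
        c = c.copy()
        c.face = 0
        chains.append(c)
    for c in bottom.chains:
        c = c.copy()
        c.face = 1
        if c.entity_role == "C":
            c.entity_role = "D"
        chains.append(c)
    out = StructureModel(chains=relabel_chains(chains))
    out.dihedral_operation = dihedral_flip_transform(pose.phi, pose.z_offset)
    return out
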