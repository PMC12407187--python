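"""Idealized pseudosymmetric building blocks and docking preprocessing.

The generator emulates the geometry of a crown-like ring: a pseudosymmetric
heterotrimer whose three chains share one backbone related by 120-degree
rotations about z, expanded five-fold into a 15-subunit ring.  Each subunit
is an up-down bundle of ideal CA-trace helices arranged along the radial
direction, so the chain's C-terminal helix end points away from the ring
axis and is free for interface design.  Sequences are drawn from a seeded
pseudo-random stream, distinct per chain — backbone symmetry with sequence
asymmetry is exactly the pseudosymmetry the design strategy exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BifacetError, ValidationError
from .structmodel import (
    AA_LETTERS,
    Atom,
    ChainModel,
    Residue,
    RigidTransform,
    StructureModel,
    apply_transform,
)
from .symmetry import CyclicSpec, expand_cyclic


@dataclass(frozen=True)
class HelixParams:
    """Idealized alpha-helix CA-trace geometry.

    Defaults (rise 1.5 A/residue, twist 100 deg/residue, radius 2.3 A) give
    the canonical 3.8 A consecutive CA-CA distance and ~5.4 A i->i+3 distance.
    """

    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3

    def __post_init__(self):
        if min(self.rise_per_residue, self.twist_per_residue, self.radius) <= 0:
            raise ValidationError("helix parameters must be positive")


@dataclass(frozen=True)
class BlockRecipe:
    """Recipe for an idealized heterotrimer / crown fixture."""

    n_helices_per_subunit: int = 6
    helix_length: int = 12
    ring_radius: float = 35.0
    seed: int = 0
    helix_spacing: float = 7.0
    loop_length: int = 3

    def __post_init__(self):
        if self.n_helices_per_subunit < 2:
            raise ValidationError("need >= 2 helices per subunit")
        if self.helix_length < 7:
            raise ValidationError("helix_length must be >= 7")


def _helix_ca_trace(n_res: int, params: HelixParams) -> np.ndarray:
    i = np.arange(n_res)
    theta = np.radians(params.twist_per_residue) * i
    return np.column_stack(
        [
            params.radius * np.cos(theta),
            params.radius * np.sin(theta),
            params.rise_per_residue * i,
        ]
    )


def make_ideal_helix(n_res: int, params: HelixParams = HelixParams(),
                     sequence: str | None = None) -> ChainModel:
    """A single chain whose CA trace is a regular helix along +z."""
    if n_res < 4:
        raise ValidationError("an ideal helix needs at least 4 residues")
    coords = _helix_ca_trace(n_res, params)
    seq = sequence if sequence is not None else "A" * n_res
    residues = [
        Residue(i + 1, seq[i], [Atom("CA", "C", coords[i])]) for i in range(n_res)
    ]
    return ChainModel("A", "other", residues, helix_ranges=[(1, n_res)])


def _subunit_backbone(recipe: BlockRecipe, params: HelixParams) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """CA trace of one subunit: a radial row of alternating up/down helices.

    Helix h sits at x = ring_radius + h*helix_spacing; helices are connected
    by short straight loops.  Returns coordinates and helix intervals.
    """
    coords: list[np.ndarray] = []
    helix_ranges: list[tuple[int, int]] = []
    n = recipe.helix_length
    pos = 0
    for h in range(recipe.n_helices_per_subunit):
        trace = _helix_ca_trace(n, params)
        if h % 2 == 1:  # antiparallel: run this helix downward
            trace[:, 2] = trace[::-1, 2]
        trace[:, 0] += recipe.ring_radius + h * recipe.helix_spacing
        if coords:
            # straight loop from previous helix end to this helix start
            loop = np.linspace(coords[-1][-1], trace[0], recipe.loop_length + 2)[1:-1]
            coords.append(loop)
            pos += recipe.loop_length
        helix_ranges.append((pos + 1, pos + n))
        coords.append(trace)
        pos += n
    return np.vstack(coords), helix_ranges


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_LETTERS), size=n))


def make_pseudo_heterotrimer(recipe: BlockRecipe) -> StructureModel:
    """Three chains A/B/C: one backbone, 120-degree rotated, distinct sequences."""
    params = HelixParams()
    coords, helix_ranges = _subunit_backbone(recipe, params)
    rng = np.random.default_rng(recipe.seed)
    sequences = []
    while len(sequences) < 3:
        seq = _random_sequence(rng, coords.shape[0])
        if seq not in sequences:
            sequences.append(seq)
    chains = []
    for j, (cid, role) in enumerate([("A", "A"), ("B", "B"), ("C", "C")]):
        rot = RigidTransform.rotation_about_z(120.0 * j)
        pts = rot.apply(coords)
        residues = [
            Residue(i + 1, sequences[j][i], [Atom("CA", "C", pts[i])])
            for i in range(pts.shape[0])
        ]
        chains.append(
            ChainModel(cid, role, residues, helix_ranges=list(helix_ranges),
                       trimer_index=0)
        )
    return StructureModel(chains=chains)


def make_crown(recipe: BlockRecipe = BlockRecipe()) -> StructureModel:
    """A 15-chain, five-fold crown of pseudosymmetric heterotrimers.

    Raises a generation error when the recipe produces inter-trimer CA
    contacts closer than 2.5 A (the fixture must be clash-free).
    """
    trimer = make_pseudo_heterotrimer(recipe)
    crown = expand_cyclic(trimer, CyclicSpec(order_n=5))
    if _min_inter_trimer_distance(crown) < 2.5:
        raise BifacetError(
            "recipe produces inter-trimer clashes; increase ring_radius"
        )
    return crown


def _min_inter_trimer_distance(s: StructureModel) -> float:
    from scipy.spatial import cKDTree

    best = float("inf")
    coords = [(c.trimer_index, c.ca_coords()) for c in s.chains]
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if coords[i][0] == coords[j][0]:
                continue
            d = cKDTree(coords[i][1]).query(coords[j][1])[0].min()
            best = min(best, float(d))
    return best


def segment_helices(chain: ChainModel) -> list[tuple[int, int]]:
    """Helix intervals of a chain, from annotation or CA geometry.

    Annotated ``helix_ranges`` are returned verbatim.  Otherwise maximal runs
    of >= 6 residues whose CA(i)->CA(i+3) distance lies in [4.5, 6.5] A are
    called helix; an ideal alpha-helix scores ~5.4 A and an extended chain
    ~11.4 A, so the window separates the two cleanly.
    """
    if len(chain) < 7:
        raise ValidationError("helix segmentation needs >= 7 residues")
    if chain.helix_ranges:
        return list(chain.helix_ranges)
    coords = chain.ca_coords()
    n = coords.shape[0]
    d13 = np.linalg.norm(coords[3:] - coords[:-3], axis=1)
    helical = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        if 4.5 <= d13[i] <= 6.5:
            helical[i : i + 4] = True
    intervals: list[tuple[int, int]] = []
    i = 0
    idx = [r.index for r in chain.residues]
    while i < n:
        if helical[i]:
            j = i
            while j + 1 < n and helical[j + 1]:
                j += 1
            if j - i + 1 >= 6:
                intervals.append((idx[i], idx[j]))
            i = j + 1
        else:
            i += 1
    return intervals


def truncate_c_subunit(s: StructureModel, n_helices: int) -> StructureModel:
    """Remove the last ``n_helices`` helices (plus trailing loops) of each
    C-role chain, so a helix terminus becomes the new C terminus.

    ``n_helices=0`` is the identity.  Other chains are untouched.
    """
    if n_helices == 0:
        return s.copy()
    out = s.copy()
    for chain in out.chains:
        if chain.entity_role != "C":
            continue
        helices = segment_helices(chain)
        if n_helices >= len(helices):
            raise ValidationError(
                f"cannot truncate {n_helices} of {len(helices)} helices"
            )
        kept = helices[: len(helices) - n_helices]
        last_res = kept[-1][1]
        chain.residues = [r for r in chain.residues if r.index <= last_res]
        chain.helix_ranges = kept
    return out


def enumerate_truncation_variants(
    s: StructureModel, max_truncation: int = 4
) -> list[StructureModel]:
    """Variants truncated by 1..max_truncation helices (full-length excluded)."""
    if max_truncation < 1:
        raise ValidationError("max_truncation must be >= 1")
    return [truncate_c_subunit(s, k) for k in range(1, max_truncation + 1)]


def concatenate_chains(
    s: StructureModel, order: list[str]
) -> tuple[StructureModel, dict[tuple[str, int], int]]:
    """Join all chains into one, renumbered 1..N, coordinates unchanged.

    Returns the single-chain structure and the mapping from
    (old chain_id, old residue index) to the new index.
    """
    if sorted(order) != sorted(c.chain_id for c in s.chains):
        raise ValidationError("order must cover all chains exactly once")
    mapping: dict[tuple[str, int], int] = {}
    residues: list[Residue] = []
    new_idx = 0
    for cid in order:
        chain = s.chain(cid)
        for r in chain.residues:
            new_idx += 1
            mapping[(cid, r.index)] = new_idx
            residues.append(
                Residue(new_idx, r.amino_acid,
                        [Atom(a.name, a.element, a.position.copy()) for a in r.atoms])
            )
    merged = ChainModel("A", "other", residues)
    return StructureModel(chains=[merged]), mapping
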