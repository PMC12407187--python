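"""Extended, rotated and terminus-reoriented target architectures.

Size and shape edits keep the designed asymmetric C-D interface intact: the
loop preceding the last two helices of each C subunit is cut, and everything
on the (ABC)5 side except those interface helices is translated along the
five-fold axis (optionally also rotated about it).  The gap is specified for
an external backbone-diffusion tool as a contig specification with an
insert-length range per target.  Terminus reorientation targets are declared
as helix permutations plus a block-adjacency matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .structmodel import (
    Atom,
    ChainModel,
    RigidTransform,
    StructureModel,
    rotation_angle_about_axis,
)
from .synthetic_blocks import segment_helices

# Insert-length ranges (residues) per (distance d [A], rotation rho [deg]).
CONTIG_INSERT_RANGES: dict[tuple[float, float], tuple[int, int]] = {
    (25.0, 0.0): (50, 150),
    (50.0, 0.0): (100, 250),
    (75.0, 0.0): (150, 350),
    (100.0, 0.0): (250, 400),
    (50.0, 25.0): (150, 350),
}

Selection = tuple[tuple[str, tuple[int, ...]], ...]  # ((chain_id, residue indices), ...)


@dataclass(frozen=True)
class ExtensionTarget:
    """A translated (and optionally rotated) architecture target."""

    distance_d: float
    rotation_rho: float
    cut_point: int
    moved_selection: Selection

    def __post_init__(self):
        if self.distance_d < 0:
            raise ValidationError("distance_d must be >= 0")


@dataclass(frozen=True)
class ContigSpec:
    """Fixed segments plus the variable-length insert for diffusion."""

    fixed_segments: tuple[tuple[str, int, int], ...]
    insert_length_range: tuple[int, int]
    reduced_input_selection: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        lo, hi = self.insert_length_range
        if lo > hi:
            raise ValidationError("insert range min must be <= max")
        segs = sorted(self.fixed_segments)
        for (c1, s1, e1), (c2, s2, e2) in zip(segs, segs[1:]):
            if c1 == c2 and s2 <= e1:
                raise ValidationError("fixed segments overlap")

    def to_contig_string(self) -> str:
        """Render in the segment/insert grammar of the diffusion tool:
        fixed segments as <chain><start>-<end>, the insert as min-max."""
        parts = []
        lo, hi = self.insert_length_range
        for i, (chain, start, end) in enumerate(self.fixed_segments):
            parts.append(f"{chain}{start}-{end}")
            if i == 0:
                parts.append(f"{lo}-{hi}")
        return "/".join(parts)


@dataclass(frozen=True)
class AdjacencyTarget:
    """Helix reordering with one inserted helix and a contact matrix."""

    helix_order: tuple[int, ...]
    new_helix_length: int
    adjacency: np.ndarray
    deleted_loops: tuple[tuple[int, int], ...]

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=int)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValidationError("adjacency must be symmetric with zero diagonal")
        object.__setattr__(self, "adjacency", adj)


def cut_terminal_loop(
    c_chain: ChainModel,
) -> tuple[list[int], list[int], int]:
    """Cut the loop preceding the last two helices of a C subunit.

    Returns (body residue indices, interface-fragment residue indices,
    cut_point).  The fragment is the last two helices plus anything
    C-terminal of them; the cut point is the midpoint residue of the severed
    loop, so body and fragment partition the chain at a reproducible spot.
    """
    helices = segment_helices(c_chain)
    if len(helices) < 3:
        raise ValidationError("need >= 3 helices with a loop before the last two")
    loop_start = helices[-3][1] + 1
    loop_end = helices[-2][0] - 1
    if loop_start > loop_end:
        raise ValidationError("no loop between the last-two helices and the rest")
    cut_point = (loop_start + loop_end) // 2
    idx = [r.index for r in c_chain.residues]
    body = [i for i in idx if i <= cut_point]
    fragment = [i for i in idx if i > cut_point]
    return body, fragment, cut_point


def make_extension_target(
    assembly: StructureModel, d: float, rho: float = 0.0
) -> tuple[ExtensionTarget, StructureModel]:
    """Translate (and optionally rotate) the (ABC)5 substructure along z.

    The moved selection is every atom of the face-0 ring except the
    interface fragments (last two helices) of the five C subunits; the
    transform is a rotation ``rho`` about z composed with a translation
    (0, 0, +d).  Interface-fragment coordinates are bit-identical before and
    after.
    """
    if d < 0:
        raise ValidationError("extension distance must be >= 0")
    face0 = [c for c in assembly.chains if c.face == 0]
    if not face0:
        raise ValidationError("assembly has no face-0 ring (need a realized dock)")
    moved: list[tuple[str, tuple[int, ...]]] = []
    cut_point = -1
    for chain in face0:
        if chain.entity_role == "C":
            body, _, cut_point = cut_terminal_loop(chain)
            moved.append((chain.chain_id, tuple(body)))
        else:
            moved.append((chain.chain_id, tuple(r.index for r in chain.residues)))
    transform = RigidTransform.translation_along_z(d).compose(
        RigidTransform.rotation_about_z(rho)
    )
    out = assembly.copy()
    moved_map = dict(moved)
    for chain in out.chains:
        sel = moved_map.get(chain.chain_id)
        if sel is None:
            continue
        sel_set = set(sel)
        for res in chain.residues:
            if res.index in sel_set:
                res.atoms = [
                    Atom(a.name, a.element, transform.apply(a.position))
                    for a in res.atoms
                ]
    target = ExtensionTarget(
        distance_d=d, rotation_rho=rho, cut_point=cut_point,
        moved_selection=tuple(moved),
    )
    return target, out


def emit_contig_spec(
    target: ExtensionTarget,
    assembly: StructureModel | None = None,
    insert_range: tuple[int, int] | None = None,
) -> ContigSpec:
    """Contig specification for one extension target.

    The insert-length range is looked up from the preset table by (d, rho);
    targets outside the table require an explicit ``insert_range``.  The
    reduced diffusion input is the last four helices of the translated body
    of one C subunit plus its two interface helices.
    """
    key = (float(target.distance_d), float(target.rotation_rho))
    if insert_range is None:
        if key not in CONTIG_INSERT_RANGES:
            raise ValidationError(
                f"no preset insert range for (d={key[0]}, rho={key[1]}); "
                "pass insert_range explicitly"
            )
        insert_range = CONTIG_INSERT_RANGES[key]

    fixed: list[tuple[str, int, int]] = []
    reduced: list[tuple[str, int, int]] = []
    if assembly is not None:
        c_chain = next(
            c for c in assembly.chains if c.face == 0 and c.entity_role == "C"
        )
        helices = segment_helices(c_chain)
        body_helices = [h for h in helices if h[1] <= target.cut_point]
        iface_helices = [h for h in helices if h[0] > target.cut_point]
        fixed = [
            (c_chain.chain_id, 1, target.cut_point),
            (c_chain.chain_id, target.cut_point + 1,
             c_chain.residues[-1].index),
        ]
        reduced = [
            (c_chain.chain_id, h[0], h[1]) for h in body_helices[-4:]
        ] + [(c_chain.chain_id, h[0], h[1]) for h in iface_helices[-2:]]
    return ContigSpec(
        fixed_segments=tuple(fixed),
        insert_length_range=tuple(insert_range),
        reduced_input_selection=tuple(reduced),
    )


def geometric_helix_contact_map(chain: ChainModel, cutoff: float = 10.0) -> np.ndarray:
    """Binary helix-helix contact map: minimum CA-CA distance < cutoff."""
    helices = segment_helices(chain)
    coords = chain.ca_coords()
    idx = {r.index: i for i, r in enumerate(chain.residues)}
    segs = [
        coords[[idx[i] for i in range(s, e + 1) if i in idx]]
        for s, e in helices
    ]
    h = len(segs)
    adj = np.zeros((h, h), dtype=int)
    for i in range(h):
        for j in range(i + 1, h):
            dmin = np.min(
                np.linalg.norm(segs[i][:, None, :] - segs[j][None, :, :], axis=-1)
            )
            if dmin < cutoff:
                adj[i, j] = adj[j, i] = 1
    return adj


def make_adjacency_target(
    chain: ChainModel,
    new_order: list[int],
    new_helix_length: int = 14,
    contacts: list[tuple[int, int]] | None = None,
) -> AdjacencyTarget:
    """Declare a helix-reordering target with a block-adjacency matrix.

    Helices are numbered 1..H in original order; ``new_order`` permutes them
    and, when a new helix is inserted, it takes index H+1.  ``contacts`` are
    required helix-helix contacts (1-based pairs); when omitted and no helix
    is inserted, the matrix defaults to the geometric contact map of the
    unmodified chain.  Deleted loops are those flanking any helix whose
    position changed.
    """
    helices = segment_helices(chain)
    h = len(helices)
    has_new = len(new_order) == h + 1
    expected = set(range(1, h + 1)) | ({h + 1} if has_new else set())
    if set(new_order) != expected or len(new_order) != len(set(new_order)):
        raise ValidationError(
            f"new_order must be a permutation of 1..{h}"
            + (f" plus {h + 1}" if has_new else "")
        )
    size = h + 1 if has_new else h
    if contacts is None:
        if has_new:
            raise ValidationError("contacts required when inserting a new helix")
        adj = geometric_helix_contact_map(chain)
    else:
        adj = np.zeros((size, size), dtype=int)
        for a, b in contacts:
            if a == b:
                raise ValidationError(f"self-contact ({a}, {a}) is not allowed")
            if not (1 <= a <= size and 1 <= b <= size):
                raise ValidationError(f"contact ({a}, {b}) references unknown helix")
            adj[a - 1, b - 1] = adj[b - 1, a - 1] = 1

    moved = {
        orig for pos, orig in enumerate(new_order, start=1)
        if orig <= h and pos != orig
    }
    deleted: list[tuple[int, int]] = []
    for k in range(h - 1):
        loop = (helices[k][1] + 1, helices[k + 1][0] - 1)
        if loop[0] > loop[1]:
            continue
        if (k + 1) in moved or (k + 2) in moved:
            deleted.append(loop)
    return AdjacencyTarget(
        helix_order=tuple(new_order),
        new_helix_length=new_helix_length,
        adjacency=adj,
        deleted_loops=tuple(deleted),
    )


def write_adjacency_matrix(target: AdjacencyTarget, path) -> None:
    """Whitespace-delimited 0/1 matrix with a helix-index header row."""
    adj = target.adjacency
    n = adj.shape[0]
    lines = ["# helix " + " ".join(str(i + 1) for i in range(n))]
    for row in adj:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def emit_diffusion_job(
    target: "ExtensionTarget | AdjacencyTarget",
    n_backbones: int = 100,
    input_pdb: str = "",
    spec_path: str = "",
) -> dict:
    """One backbone-diffusion job manifest entry for a target."""
    if isinstance(target, ExtensionTarget):
        kind = "extension"
        desc = f"d={target.distance_d},rho={target.rotation_rho}"
    elif isinstance(target, AdjacencyTarget):
        kind = "adjacency"
        desc = "order=" + "-".join(str(i) for i in target.helix_order)
    else:
        raise ValidationError(f"unknown target type {type(target).__name__}")
    return {
        "kind": kind, "target": desc, "input_pdb": input_pdb,
        "spec_file": spec_path, "n_backbones": n_backbones,
    }


def write_diffusion_manifest(jobs: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(jobs).to_csv(path, sep="\t", index=False)


def read_diffusion_manifest(path) -> list[dict]:
    import pandas as pd

    return pd.read_csv(path, sep="\t", keep_default_na=False).to_dict(orient="records")
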