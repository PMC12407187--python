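"""Asymmetric C-D interface design specifications.

This module identifies the residue positions that face each other across the
dihedral two-fold of a docked assembly and emits the inputs an external
sequence-design network consumes: per-position amino-acid bias dictionaries
(three complementarity schemes at five bias levels), job manifests spanning
the sampling-temperature grid, and multistate specifications that weight the
on-target C-D interface positively and the off-target C-C / D-D homodimer
states negatively.  The network itself is out of scope; only its input files
are produced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structmodel import (
    AA_LETTERS,
    ChainModel,
    RigidTransform,
    StructureModel,
)
from .synthetic_blocks import segment_helices

# Amino-acid categories used by the biasing schemes.
SMALL = frozenset("STNQVIL")
BULKY = frozenset("FYW")
NEGATIVE = frozenset("DE")
POSITIVE = frozenset("RHK")  # H counted as positively charged; no pH model

BIAS_SCHEMES = ("charges", "clashes", "charges-clashes")
BIAS_LEVELS = (0.1, 0.2, 0.69, 1.1, 3.9)
# Approximate fold-increase labels for the additive-logit levels; 3.9 is kept
# as specified by its "four-fold" label even though exp(3.9) is far larger.
LEVEL_LABELS = {0.69: "two-fold", 1.1: "three-fold", 3.9: "four-fold"}
DESIGN_TEMPERATURES = (0.1, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0)
MULTISTATE_BETAS = (-1.0, -0.5, -0.25)

# Favoured letter sets per scheme: (first side, second side).
SCHEME_SIDES: dict[str, tuple[frozenset, frozenset]] = {
    "charges": (POSITIVE, NEGATIVE),
    "clashes": (SMALL, BULKY),
    "charges-clashes": (POSITIVE | BULKY, NEGATIVE | SMALL),
}

Position = tuple[str, int]  # (chain_id, residue_index)


@dataclass(frozen=True)
class InterfacePairMap:
    """C-side/D-side position pairs across the dihedral two-fold."""

    pairs: tuple[tuple[Position, Position], ...]
    pairing_rmsd: float

    def __post_init__(self):
        seen_c: set[Position] = set()
        seen_d: set[Position] = set()
        for c_pos, d_pos in self.pairs:
            if c_pos in seen_c or d_pos in seen_d:
                raise ValidationError("a position appears in more than one pair")
            seen_c.add(c_pos)
            seen_d.add(d_pos)

    @property
    def c_positions(self) -> list[Position]:
        return [p[0] for p in self.pairs]

    @property
    def d_positions(self) -> list[Position]:
        return [p[1] for p in self.pairs]


@dataclass(frozen=True)
class BiasSpec:
    """Per-position additive-logit biases for one side of the interface."""

    entries: dict[Position, dict[str, float]]
    scheme: str
    level: float

    def total_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_bias_dict(self) -> dict:
        """Serialize as a position-keyed per-chain 20-letter vector
        (zeros for unbiased letters): {chain: {resi: {letter: bias}}}."""
        out: dict[str, dict[str, dict[str, float]]] = {}
        for (cid, resi), letters in self.entries.items():
            vec = {aa: letters.get(aa, 0.0) for aa in AA_LETTERS}
            out.setdefault(cid, {})[str(resi)] = vec
        return out

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"scheme": self.scheme, "level": self.level, "bias": self.to_bias_dict()},
            indent=1, sort_keys=True))


@dataclass(frozen=True)
class MultistateSpec:
    """One on-target state plus negatively weighted off-target states."""

    on_target_state: dict
    off_target_states: tuple[dict, ...]
    beta: float

    def __post_init__(self):
        if self.beta >= 0:
            raise ValidationError("beta must be < 0")
        if not self.off_target_states:
            raise ValidationError("off_target_states must be nonempty")

    def to_json(self) -> str:
        states = [dict(self.on_target_state, weight=1.0)] + [
            dict(s, weight=self.beta) for s in self.off_target_states
        ]
        return json.dumps({"beta": self.beta, "states": states}, indent=1,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MultistateSpec":
        obj = json.loads(text)
        states = obj["states"]
        on = {k: v for k, v in states[0].items() if k != "weight"}
        off = tuple({k: v for k, v in s.items() if k != "weight"} for s in states[1:])
        return cls(on_target_state=on, off_target_states=off, beta=obj["beta"])


def find_interface_pairs(
    assembly: StructureModel,
    cutoff: float = 8.0,
    flip: RigidTransform | None = None,
) -> InterfacePairMap:
    """Collect C-side/D-side position pairs across the dihedral two-fold.

    A position is at the interface when any cross-interface CA lies within
    ``cutoff``.  Each C-side position is paired with the D-side position
    nearest to its image under the assembly's two-fold operation; the RMS of
    those image displacements is reported as ``pairing_rmsd``.
    """
    if flip is None:
        flip = assembly.dihedral_operation
    if flip is None:
        raise ValidationError(
            "assembly carries no dihedral operation; pass flip= explicitly"
        )
    c_chains = assembly.chains_by_role("C")
    d_chains = assembly.chains_by_role("D")
    if not c_chains or not d_chains:
        raise ValidationError("assembly must contain C-role and D-role chains")

    c_pos = [(c.chain_id, r.index) for c in c_chains for r in c.residues]
    c_xyz = np.vstack([c.ca_coords() for c in c_chains])
    d_pos = [(c.chain_id, r.index) for c in d_chains for r in c.residues]
    d_xyz = np.vstack([c.ca_coords() for c in d_chains])

    d_tree = cKDTree(d_xyz)
    contacting = [
        i for i, hits in enumerate(d_tree.query_ball_point(c_xyz, cutoff))
        if hits
    ]
    if not contacting:
        import warnings

        warnings.warn("no cross-interface contacts within cutoff; empty pair map")
        return InterfacePairMap(pairs=(), pairing_rmsd=0.0)

    images = flip.apply(c_xyz[contacting])
    dists, nearest = d_tree.query(images)
    # at most one pair per position: keep the closest claim on each D position
    best: dict[int, tuple[float, int]] = {}
    for ci, dist, di in zip(contacting, dists, nearest):
        if di not in best or dist < best[di][0]:
            best[di] = (float(dist), ci)
    pairs = tuple(
        sorted((c_pos[ci], d_pos[di]) for di, (_, ci) in best.items())
    )
    disp = np.array([d for d, _ in best.values()])
    return InterfacePairMap(pairs=pairs, pairing_rmsd=float(np.sqrt(np.mean(disp ** 2))))


def make_bias_spec(
    pairs: InterfacePairMap,
    scheme: str,
    level: float,
    side_assignment: str = "C_first",
) -> tuple[BiasSpec, BiasSpec]:
    """Emit the two per-side bias specs for one scheme and level.

    Every interface position on a side receives +level for each letter of
    that side's favoured set; no negative biases are emitted.  The two sides'
    favoured sets are disjoint for every scheme.
    """
    if scheme not in BIAS_SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if level not in BIAS_LEVELS:
        raise ValidationError(f"unknown bias level {level!r}")
    if side_assignment not in ("C_first", "D_first"):
        raise ValidationError(f"unknown side_assignment {side_assignment!r}")
    first_letters, second_letters = SCHEME_SIDES[scheme]
    c_letters, d_letters = (
        (first_letters, second_letters)
        if side_assignment == "C_first"
        else (second_letters, first_letters)
    )
    c_spec = BiasSpec(
        entries={p: {aa: level for aa in sorted(c_letters)} for p in pairs.c_positions},
        scheme=scheme, level=level,
    )
    d_spec = BiasSpec(
        entries={p: {aa: level for aa in sorted(d_letters)} for p in pairs.d_positions},
        scheme=scheme, level=level,
    )
    return c_spec, d_spec


def enumerate_design_jobs(
    pairs: InterfacePairMap,
    schemes: tuple[str, ...] = BIAS_SCHEMES,
    levels: tuple[float, ...] = BIAS_LEVELS,
    temperatures: tuple[float, ...] = DESIGN_TEMPERATURES,
    n_seq: int = 100,
    out_dir=None,
) -> list[dict]:
    """Manifest of biased (scheme x level x temperature) jobs plus an
    unbiased job per temperature, each requesting ``n_seq`` sequences.

    When ``out_dir`` is given the per-side bias spec files are written there
    and their paths recorded on the manifest entries.
    """
    jobs: list[dict] = []
    job_id = 0
    for scheme in schemes:
        for level in levels:
            c_file = d_file = ""
            if out_dir is not None:
                c_spec, d_spec = make_bias_spec(pairs, scheme, level)
                base = f"bias_{scheme}_{level}".replace(".", "p")
                c_file = str(Path(out_dir) / f"{base}_sideC.json")
                d_file = str(Path(out_dir) / f"{base}_sideD.json")
                c_spec.write(c_file)
                d_spec.write(d_file)
            for temp in temperatures:
                jobs.append({
                    "job_id": job_id, "scheme": scheme, "level": level,
                    "temperature": temp, "n_seq": n_seq,
                    "bias_file_c": c_file, "bias_file_d": d_file,
                })
                job_id += 1
    for temp in temperatures:
        jobs.append({
            "job_id": job_id, "scheme": "unbiased", "level": 0.0,
            "temperature": temp, "n_seq": n_seq,
            "bias_file_c": "", "bias_file_d": "",
        })
        job_id += 1
    return jobs


def write_job_manifest(jobs: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(jobs).to_csv(path, sep="\t", index=False)


def read_job_manifest(path) -> list[dict]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df.to_dict(orient="records")


def emit_multistate_spec(
    assembly: StructureModel,
    pairs: InterfacePairMap,
    beta: float,
    path=None,
) -> MultistateSpec:
    """Multistate design spec: on-target C-D plus off-target C-C and D-D.

    Off-target state geometries pair each side with its own two-fold image
    (the homodimeric interface each ring would form on its own); the
    on-target state carries weight +1 and each off-target state weight beta.
    """
    if beta not in MULTISTATE_BETAS:
        raise ValidationError(
            f"beta must be one of {MULTISTATE_BETAS}, got {beta}"
        )
    c_ids = sorted({p[0] for p in pairs.c_positions})
    d_ids = sorted({p[0] for p in pairs.d_positions})
    spec = MultistateSpec(
        on_target_state={
            "name": "CD_on_target",
            "chains_first": c_ids, "chains_second": d_ids,
            "construction": "as_docked",
        },
        off_target_states=(
            {
                "name": "CC_off_target",
                "chains_first": c_ids, "chains_second": c_ids,
                "construction": "pair_with_own_twofold_image",
            },
            {
                "name": "DD_off_target",
                "chains_first": d_ids, "chains_second": d_ids,
                "construction": "pair_with_own_twofold_image",
            },
        ),
        beta=beta,
    )
    if path is not None:
        Path(path).write_text(spec.to_json())
    return spec


def extract_terminal_fragment(chain: ChainModel, n_helices: int = 5) -> ChainModel:
    """The C-terminal fragment from the n-th-from-last helix to the terminus.

    Residues are renumbered from 1 and helix annotations carried over; this
    is the fragment whose structure prediction drives interface filtering.
    """
    helices = segment_helices(chain)
    if len(helices) < n_helices:
        raise ValidationError(
            f"chain has {len(helices)} helices, need >= {n_helices}"
        )
    start = helices[-n_helices][0]
    kept = [r for r in chain.residues if r.index >= start]
    offset = start - 1
    from .structmodel import Atom, Residue

    residues = [
        Residue(r.index - offset, r.amino_acid,
                [Atom(a.name, a.element, a.position.copy()) for a in r.atoms])
        for r in kept
    ]
    ranges = [(s - offset, e - offset) for s, e in helices[-n_helices:]]
    return ChainModel(chain.chain_id, chain.entity_role, residues,
                      helix_ranges=ranges, trimer_index=chain.trimer_index,
                      face=chain.face)
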