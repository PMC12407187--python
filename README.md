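# bifacet

Design toolkit for **bifaceted (Janus-like) protein nanomaterials** with
pseudo-dihedral symmetry.

Most designed protein nanoparticles obey strict point-group symmetry, which
makes their surfaces uniform: there is no way to decorate two sides of the
particle with different functional proteins.  A bifaceted architecture fixes
this by docking two cyclic rings of pseudosymmetric heterotrimers —
(ABC)5 and (ABD)5 — back-to-back along a shared five-fold axis and
*asymmetrizing* the ring-to-ring interface, so the C subunits of one ring
pair with the D subunits of the other.  Neither ring can homodimerize, the
particle assembles only when the two components are mixed, and each of the
six subunit identities is independently addressable.

`bifacet` implements the computational machinery of this strategy for
structural-bioinformatics users:

- **structmodel** — backbone (CA) structural model, PDB/mmCIF I/O, rigid
  transforms, Kabsch superposition.
- **symmetry** — cyclic expansion about +z, dihedral partner generation
  (flip about x, rotate phi, translate z), closure verification with chain
  re-pairing, pseudosymmetry detection.
- **synthetic_blocks** — idealized pseudosymmetric heterotrimers and
  15-subunit crowns used as fixtures; helix segmentation, C-subunit
  truncation (1-4 helices), chain concatenation for single-chain docking
  inputs.
- **axial_dock** — enumerate (phi, z, truncation) docks, score them with a
  transparent contacts-minus-weighted-clashes function on CA atoms
  (`score = n_contacts − w·n_clashes`, contacts restricted to the designable
  C-C' interface), rank deterministically, realize the 30-chain assembly.
- **asym_interface** — interface-position pairing across the dihedral
  two-fold; per-residue amino-acid bias dictionaries (charges / clashes /
  charges-clashes schemes at levels 0.1-3.9), job manifests over seven
  sampling temperatures, multistate specs weighting off-target C-C / D-D
  states with beta < 0 — inputs for an external sequence-design network.
- **design_filter** — the negative-design decision procedure over predicted
  metrics: on-target rmsd < 2.0 A, mean interchain pAE < 10, pLDDT > 90;
  off-target C-C/D-D not confidently predicted; pAE gap > 10.
- **architecture_edit** — extension targets (translate the (ABC)5 body
  25-100 A along the axis, optionally rotate 25 deg, keeping the C-D
  interface fixed), contig specifications with per-target insert ranges,
  and block-adjacency targets for terminus reorientation — inputs for an
  external backbone-diffusion tool.
- **assembly_builder** — hierarchical (ABC)5–(ABD)5 composition,
  interface-class analysis, JSON reports.
- **colocalize** — the bead-colocalization statistic (centroid distance
  < 7.5 um, strict) used to quantify face-specific binding.

ML inference itself (sequence design, structure prediction, backbone
diffusion) is out of scope: the package writes the input specifications
those tools consume and reads the metric tables they emit.

## Worked example

```python
import numpy as np
from bifacet import (
    BlockRecipe, make_crown, DockGrid, DockPose, enumerate_docks,
    score_pose, rank_docks, build_bifaceted, find_interface_pairs,
    make_bias_spec, count_designed_interface_classes,
)

# two crown components with distinct sequences
abc = make_crown(BlockRecipe(seed=1))
abd = make_crown(BlockRecipe(seed=2))
print(len(abc.chains))                     # 15

# sample docks along the shared five-fold axis, keep the best clash-free one
grid = DockGrid(phi_values=tuple(np.arange(0.0, 72.0, 4.0)),
                z_values=tuple(np.arange(24.0, 56.0, 2.0)))
scored = [score_pose(abc, p) for p in enumerate_docks(abc, grid)]
best = rank_docks([p for p in scored if p.n_clashes == 0], top_k=1)[0]
print(best.phi, best.z_offset, best.n_contacts, best.n_clashes)
                                           # 44.0 36.0 700 0

# realize the bifaceted model and inspect its designed interfaces
model = build_bifaceted(abc, abd, best)
print(len(model.structure.chains))         # 30
for cls in count_designed_interface_classes(model):
    print(cls.role_pair, cls.relation, cls.symmetry)
                                           # ('A', 'B') dihedral asymmetric
                                           # ('C', 'D') dihedral asymmetric

# emit bias dictionaries for the asymmetric C-D interface
pairs = find_interface_pairs(model.structure)
c_spec, d_spec = make_bias_spec(pairs, "charges", 0.69)
print(len(pairs.pairs), c_spec.total_entries(), d_spec.total_entries())
                                           # 140 420 280
```

The dock places the second ring by a two-fold flip at phi = 44 deg,
z = 36 A with 700 designable C-C' contacts and no clashes; the realized
model has the full 30 subunits, the analysis reports the asymmetric
dihedral C-D interface, and the bias spec favours positive charges (R/H/K,
3 letters x 140 positions) on the C side and negative (D/E, 2 x 140) on
the D side at the two-fold-likelihood level 0.69.

A thin CLI wraps the same functions: `bifacet fixtures crown`,
`bifacet dock`, `bifacet assemble`, `bifacet filter interfaces`,
`bifacet coloc` (see `bifacet --help`).

## Documentation

The model, parameter choices, numerical conventions and known limitations
are described in [docs/methods.md](docs/methods.md).
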