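# Methods

## Scope and model

`bifacet` implements the computational side of a dock-and-design strategy for
bifaceted (Janus-like) protein nanomaterials with pseudo-dihedral symmetry.
The object of study is an (ABC)5–(ABD)5 architecture: two cyclic rings of
pseudosymmetric heterotrimers docked back-to-back along a shared five-fold
axis, with the ring-to-ring interface asymmetrized (C on one face, D on the
other) so that the two faces assemble only when mixed and every one of the
six subunit identities is independently addressable.

The package owns the geometry and the decision procedures: symmetry
generation and verification, axial docking and its replacement score,
interface-position pairing, bias/multistate specification emission,
confidence-metric filtering, architecture editing and the bead-colocalization
statistic.  Heavy ML inference (sequence design, structure prediction,
backbone diffusion) is interfaced through files — the package emits the
inputs those tools consume and consumes the metric tables they produce, and
never re-implements them.

## Structural model and conventions

Structures are backbone-only: every residue carries a CA atom and all
geometry (closure RMSD, dock scores, interface cutoffs) is computed on CA
coordinates.  Coordinates are in Angstrom, residue indices 1-based,
intervals inclusive on both ends, and the principal symmetry axis is +z
through the origin.  Rigid transforms require an orthonormal rotation with
det +1 (tolerance 1e-8); superposition is closed-form least squares with
reflections excluded, and collinear or sub-3-point inputs are rejected as
underdetermined.  PDB output is strict columnar ATOM records; entity roles,
helix annotations and chain-relabel maps ride along in `REMARK 250` lines so
files round-trip.  Chains beyond the 62-character PDB id space are an error
in the PDB dialect; mmCIF has no such limit but carries no remark metadata.

## Synthetic building blocks

Real crown coordinates are not bundled; an idealized generator stands in for
them and defines the conditions all tests run under.  One subunit is an
up-down bundle of ideal CA-trace helices (rise 1.5 A/residue, twist
100 deg/residue, helix radius 2.3 A, giving the canonical 3.8 A CA-CA
spacing) arranged along the radial direction so the C-terminal helix points
away from the ring axis, free for interface design.  A heterotrimer is three
copies of this backbone related by 120-degree rotations about z with
distinct, seeded random sequences — backbone symmetry plus sequence
asymmetry is exactly the pseudosymmetry the strategy exploits.  Five-fold
expansion yields a 15-subunit crown whose chains sit on a 24-degree angular
grid (the 72-degree and 120-degree rotations together generate a backbone
C15).  Defaults: 6 helices per subunit, 12 residues per helix, 3-residue
loops, ring radius 35 A — large enough that subunits on neighbouring spokes
stay clash-free (the generator enforces a 2.5 A minimum inter-trimer CA
distance and rejects recipes that violate it).

What the fixture does **not** emulate: real packing interfaces (in-ring
neighbours at radius 35 A sit ~14 A apart, so the ring is held together
conceptually, not sterically), side chains, loop geometry compatible with
real polypeptides, and realistic helix-helix packing angles.  Passing tests
therefore demonstrate the correctness of the geometric operations and
decision rules, not the designability of any particular protein.

## Docking

Sampling is restricted to the dihedral degrees of freedom: rotation phi
about z (canonicalized modulo 360/n, i.e. [0, 72) for n = 5), translation z
along z, and the C-subunit truncation level (0-4 helices removed from the C
terminus, trailing loops removed with them so a helix end is always the new
terminus).  The opposing ring is generated by a 180-degree flip about x
followed by the phi rotation and z translation; fixing the flip axis to x
makes poses comparable, with phi absorbing the remaining freedom.

The original strategy ranked docks with a motif-hash shape-complementarity
score; that scorer is external machinery, and this package deliberately
replaces it with a transparent, fully testable function:

    score = n_contacts − w · n_clashes

with contacts counted as inter-ring CA pairs within 8 A **restricted to
C-role chains** (the designable interface), clashes as any inter-ring CA
pair closer than 3.5 A, and w = 10.  The replacement preserves the contract
— rank docks by interface quality, reject clashing docks — and its counts
are verified against an O(N^2) all-pairs oracle.  Ranking is deterministic:
descending score, then fewer clashes, more contacts, smaller |z|, smaller
phi.  The end-to-end workflow selects the best pose among clash-free docks.
Grid resolution is a user choice; the acceptance workflow uses 4-degree /
2 A steps to keep runtimes in seconds.

In the idealized geometry an instructive consequence of the backbone C15 is
that a clash-free dock aligns opposing spokes so that role pairs across the
two-fold are (A, B) and (C, C): the interface-class analysis of a
single-building-block dihedral assembly reports exactly the two designed
interfaces the architecture requires — one asymmetric, one symmetric.
Cyclic ring-seam contacts, when a generous cutoff makes them visible, are
all images of one designed interface under the ring's backbone symmetry;
the classifier therefore merges equivalent cyclic classes into a single
class (labelled by the lexicographically smallest role pair, equivalents
recorded), switchable via `merge_equivalent_cyclic`.

## Asymmetric interface specification

Positions are interface members when any cross-interface CA lies within
8 A (position-level membership; a position contacting several partners gets
one bias entry).  Each C-side position pairs with the D-side position
nearest its image under the assembly's stored two-fold operation; the RMS
image displacement is reported as a pairing quality.

Bias specs use four fixed amino-acid categories — small {S,T,N,Q,V,I,L},
bulky {F,Y,W}, negative {D,E}, positive {R,H,K} (H counted positive; no pH
model) — combined in three complementarity schemes: charges (positive vs
negative), clashes (small vs bulky), charges-clashes (positive+bulky vs
negative+small).  Five additive-logit levels are emitted: 0.1, 0.2, 0.69,
1.1, 3.9.  Under a softmax-logit reading exp(0.69) ≈ 2 and exp(1.1) ≈ 3
match their nominal two-/three-fold likelihood labels; the "four-fold" level
3.9 does not (exp(3.9) ≈ 49) but is emitted as specified rather than
corrected, with the label kept nominal.  Only positive biases are emitted,
for both sides.  The job manifest enumerates 3 schemes x 5 levels x 7
sampling temperatures (0.1-1.0) at 100 sequences per job, plus 7 unbiased
jobs.  Multistate specs weight the on-target C-D state +1 (a convention of
this package; only the off-target weight is externally specified) and the
off-target C-C and D-D states beta ∈ {−1, −0.5, −0.25}, each off-target
geometry pairing a side with its own two-fold image.

## Filtering

The decision procedure over structure-prediction confidence metrics, per
design (three records: CD, CC, DD):

- on-target: rmsd < 2.0 A, mean interchain pAE < 10, pLDDT > 90;
- off-target rejection: a design is discarded when C-C or D-D is itself
  confidently predicted (rmsd < 2.0 A, pAE < 10, pLDDT > 95);
- specificity gap: pAE(off) − pAE(on) > 10.

All comparisons are strict, so boundary values fail.  The gap rule is
applied against **both** off-targets by default — the stricter reading of
"either", consistent with the negative-design goal; `gap_mode="any"`
exposes the alternative.  pLDDT tables on a 0-1 scale are auto-detected
(all values ≤ 1) and rescaled with a logged warning.  On-target pLDDT is
treated as a supplied scalar, with no assumption about whether it is
interface-restricted.  The extension filter is pLDDT > 90 and rmsd to the
diffused backbone < 1.5 A, also strict.

## Architecture editing

Extensions cut the loop preceding the last two helices of each C subunit
(cut point = loop midpoint, recorded for reproducible numbering) and move
everything on the (ABC)5 side except those interface helices by a rotation
rho about z composed with a translation d along z (the two commute for
rotations about the translation axis; rotation-first is fixed and
documented).  Presets: d ∈ {25, 50, 75, 100} A at rho = 0, plus (50 A,
25 deg).  d = 0 with rho = 0 is the identity and is accepted as an explicit
override; negative d is an error.  Insert-length ranges for the diffusion
contig are a total lookup over the five presets — 50-150, 100-250, 150-350,
250-400 residues for 25/50/75/100 A, and 150-350 for the rotated target
(kept as its own entry rather than aliased to the 75 A row) — anything else
requires an explicit range.  The reduced diffusion input is the four body
helices nearest the cut plus the two interface helices, the defensible
reading of "four helices of the translated portion" since proximity to the
rebuilt region is what matters.

Terminus reorientation targets are declared as a permutation of helix
indices with one inserted helix (placeholder length 14 residues when
unspecified), a symmetric 0/1 block-adjacency matrix over helices (with
requested contacts; the geometric 10 A contact map is the default when no
helix is inserted), and the list of deleted loops — every loop flanking a
helix whose position changed.

## Colocalization statistic

A reference particle is interacting when any opposite-channel centroid is
strictly closer than 7.5 um (about twice the particle radius); the
percentage is interacting over total per channel.  Matching is
any-neighbour, not one-to-one.  Across fields of view both the pooled
percentage (summed counts) and the mean of per-field percentages are
reported, since the field convention is ambiguous between them.

## Numerical choices and problem sizes

Closure verification re-pairs chains by greedy nearest-centroid matching
(validated against exhaustive permutation search on up to 6 chains); the
dihedral check recenters along z and scans the residual z-rotation over
chain-centroid candidate angles.  Tolerances: 1e-8 for transform group laws
and isometry, 1e-6 for symmetry closure of constructed fixtures, 1e-3 A for
file round trips (PDB fixed-width precision).  Helix segmentation uses a
CA-only i to i+3 distance window of [4.5, 6.5] A, accepting the ideal helix
(~5.4 A) and rejecting extended chain (~11.4 A); annotations take precedence
when present.  Test fixtures use crowns of ~450-1300 CA atoms and docking
grids of a few hundred poses, keeping every brute-force oracle comparison
and the full suite in seconds.

## Known limitations

- The dock score is a contact/clash count, not a packing or energy model;
  scores are not comparable across building blocks of different sizes.
- The fixture's ring holds no real in-ring interface (spokes are separated);
  analyses that depend on authentic ring-seam packing see the merged-class
  convention rather than measured contacts at the default cutoff.
- Pseudosymmetry detection compares sequences exactly; near-identical
  sequences count as different.
- mmCIF round trips lose role/helix metadata (PDB remarks carry it).
- The multistate and contig emissions target one external tool dialect
  each; other tools need adapters.
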