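# Methods

## The packing statistic

A crystal form's packing is summarized by one vector: the inter-dimer Cα
distance fingerprint. The dimeric packing unit is reconstructed, its closest
neighbouring image in the lattice located, and the Cα–Cα distances between
reference and neighbour recorded in a canonical residue-label order. Two
crystal forms are compared by restricting both fingerprints to their shared
labels and computing

    RMSD = sqrt( Σᵢ (xᵢ − yᵢ)² / n )        [Å]
    r    = Pearson correlation of (x, y)

over the n corresponding entries. The statistic is frame-free (distances are
invariant under any rigid motion of a whole form), scales linearly with a
uniform cell inflation while leaving r at 1, and is exactly (0, 1) under
self-comparison — the test suite asserts each of these.

Two pairing conventions are plausible readings of "the distance between the
Cα atoms of each residue and the residues of the closest neighbouring
dimer": all cross pairs over common residues, or each reference residue's
minimum distance to the neighbour. Both are implemented; `all-pairs` is the
default (the statistic's n is described as a count of atomic *pairs*) and the
CLI reports both so the convention is always visible next to the number.
Whether to average over several neighbours is a further open choice; this
implementation uses the single closest neighbour, chosen independently per
form, with an option to force a specific (operator, shift).

## Dimer reconstruction

With two protein chains in the asymmetric unit, they are the dimer. With one
chain, all images under operators with rot² = I, rot ≠ I, det(rot) = +1
(2-folds and 2₁ screws) and lattice shifts in [−2, 2]³ are scanned; images
with any heavy atom within 5 Å are candidates and the one maximizing the
number of inter-chain Cα pairs within 8 Å wins, ties broken on (operator
index, shift). The 5 Å contact and ±2 shift ranges are configurable; two
shells suffice because the cells handled here are larger than the motif.
More than two chains (higher oligomers) are out of scope.

Neighbour images of the dimer are generated the same way over the whole
group, deduplicated on the unordered pair of chain Cα centroids (an
operator that maps the dimer onto itself — its own internal 2-fold —
reproduces the reference and is excluded), and sorted by centroid distance
with (operator index, shift) as the deterministic tie-break. The default
search radius is the largest cell edge, which always reaches the nearest
lattice translate.

## Orientation and the lattice degeneration

Dimers of two forms are superposed over their common Cα set (Kabsch, SVD,
proper rotation enforced). All four within-dimer chain mappings are tried
and the minimum-RMSD one kept; because a symmetric dimer makes two mappings
degenerate at RMSD ≈ 0, ties resolve toward the smaller total rotation. The
reported rotation carries form 1's dimer onto form 2's (right-handed about
+c).

The twist about the c axis is extracted by quaternion swing–twist
decomposition — project the quaternion's vector part onto the axis and
renormalize — which is numerically stable near 0°, where Euler-angle
decompositions lose precision. Total angles are computed from the quaternion
as 2·atan2(|v|, |w|), stable near both 0° and 180°.

A primitive tetragonal lattice (a = b) can degenerate to a C-centred
orthorhombic one whose a′, b′ axes run along the diagonals a+b and a−b.
That relation is a fixed 45° rotation about c between the two cell settings:
with `frame="crystal"` it is removed analytically (both signs are formed and
the smaller residual twist kept — the sign of the setting is a convention,
not a parameter) and only the residual is reported as dimer re-orientation.
The accompanying cell check computes |a±b| from the metric tensor,
√(a² + b² ± 2ab cos γ), and compares |a+b| with mean(a′, b′) at a 2 Å
default tolerance. The printed two-decimal value of the mean is *truncated*,
not rounded (e.g. (52.04 + 55.95)/2 = 53.995 prints as 53.99, matching
crystallographic table convention); full precision is always carried in the
JSON.

## Interface analysis

SASA is Shrake–Rupley with a deterministic generalized-Fibonacci spiral
point set (default 960 points/atom, probe 1.4 Å), so areas are
bit-reproducible. Van der Waals radii are fixed at C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, Se 1.90 Å. Buried area per monomer is
(SASA(A) + SASA(B) − SASA(AB))/2 and the fraction is relative to the mean
isolated-monomer surface. Doubling the point count changes a typical chain
total by well under 1 % (asserted in the suite).

Hydrogen bonds across the dimer interface use a distance-only criterion on
donor/acceptor heavy atoms: models at ~2 Å resolution carry no hydrogens, so
no angle term is defensible. The default 3.9 Å cutoff comfortably includes
the longest published interface contacts of the reference dimer (3.74 Å).
Backbone N donates (except proline), backbone O/OXT accepts; side-chain
roles follow standard chemistry, with Cys SG, Tyr OH, Ser/Thr OG and His
ring nitrogens dual-role and charged pairs (Lys NZ → Asp/Glu carboxylate)
counted as hydrogen bonds. A pair of dual-role atoms is counted once
(deduplication on the unordered atom pair). Water-mediated bonds are not
enumerated; interface free-energy and complexation-significance scores are
deliberately out of scope (they belong to a proprietary energy model).

## Synthetic crystals

The generator emulates the inputs the analysis consumes: a rigid helical
poly-alanine motif (ideal Cα helix — 1.5 Å rise, 100°/residue, 2.3 Å radius,
so consecutive Cα sit 3.8 Å apart — decorated with approximate N, C, O, CB
positions and 0.01 Å seeded jitter), placed in a cell under one of the
shipped space groups with a 2 Å heavy-atom clash check against all images in
one shell. Two-chain motifs are related by an exact 180° rotation and
positioned in contact, giving a true local 2-fold. A "form pair" writes two
PDB files whose dimers differ by a known twist about c — in the same cell,
or re-indexed from P4₁22 (a = b) to C222₁ with the analytic −45° lattice
rotation folded into the coordinates — together with a ground-truth JSON
sidecar. Default sizes (10 residues/chain, P1 26×34×40 Å for plain pairs,
36×36×80 Å tetragonal for re-indexed pairs) keep every fixture clash-free
and the full suite fast.

What the fixtures do *not* emulate: side-chain diversity, solvent, B-factor
structure, alternate conformers beyond parser unit tests, or realistic
inter-chain chemistry (the poly-alanine interface buries only ~47 Å² and
forms no hydrogen bonds). Passing tests therefore demonstrate the geometry
and bookkeeping — symmetry expansion, neighbour choice, fingerprint algebra,
twist recovery to <0.01°, SASA numerics — not biological interface
composition; the interface chemistry is exercised by targeted hand-built
fixtures (known donor/acceptor pairs at known distances) and, when the
deposited coordinate files are supplied under `tests/data/deposited/`, by
the acceptance checks on the real dimer.

## Numerical choices and edge cases

- Orthogonalization follows the PDB convention (a along x, b in the x–y
  plane); fractional↔orthogonal transforms are mutually inverse to 1e-10.
- Space-group operators ship as an embedded xyz-triplet table (P1, P2₁,
  C2, P2₁2₁2₁, P4₁22, C222₁, P3₁21), parsed into integer rotation +
  rational translation; group closure, inverses and agreement with an
  independent crystallographic library are asserted in tests. Symbols are
  accepted spaced, condensed or with Unicode subscripts.
- Alternate conformers reduce to one: blank altloc wins; otherwise highest
  occupancy, ties to "A". Hydrogens and waters are kept on parse but
  excluded from fingerprints, SASA and the hydrogen-bond census.
- A constant distance vector makes Pearson r undefined; it is reported as an
  explicit undefined flag, never coerced to 0.
- Residue correspondence across forms is by (chain slot, residue number);
  insertion codes are not supported in comparisons.
- Exact centroid-distance ties (symmetry-equivalent neighbours) resolve by
  (operator index, shift), lexicographically, making every result
  deterministic; all stochastic tests run under fixed seeds.

## Known limitations

- Only 1- or 2-chain asymmetric units; no trimer+ packing units.
- The operator table covers the seven groups above; other groups raise a
  lookup error naming the symbol rather than falling back to a library.
- The distance-only H-bond criterion over-counts relative to angle-aware
  detectors on borderline geometry; the census is meant for interface
  comparison at a stated cutoff, not for publication-grade bond assignment.
- Fingerprint comparability assumes consistent residue numbering between
  forms of the same protein.
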