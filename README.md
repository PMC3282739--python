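# packalyze

Quantitative comparison of protein crystal packing across space groups.

Some proteins crystallize in several space groups, and the question of
whether the different lattices arrange the same oligomer in the same way is
usually answered by eye. `packalyze` makes it a number. It was built around a
concrete case — a small all-helical bacterial dimer that crystallized in
P4₁22, C222₁ and P2₁2₁2₁, where the tetragonal lattice degenerates into the
C-centred orthorhombic one (a′ = **a**+**b**, b′ = **a**−**b**) with only a
small rotation of the dimer about **c** — but every step is generic.

The pipeline:

1. **Dimer reconstruction.** Parse a PDB/mmCIF file with its CRYST1 cell and
   Hermann–Mauguin symbol. Two protein chains in the asymmetric unit are the
   dimer; a single chain is paired with the touching symmetry mate generated
   by an order-2 rotation (2-fold or 2₁) that maximizes the Cα contact count.
2. **Packing fingerprint.** Find the closest neighbouring dimer image in the
   lattice and record the ordered vector of Cα–Cα distances between the
   reference dimer and that neighbour (all cross pairs, or per-residue
   minima).
3. **Comparison.** For two crystal forms with fingerprints *x*, *y* over *n*
   corresponding residue pairs:

       RMSD = √( Σᵢ (xᵢ − yᵢ)² / n ),    r = Pearson correlation of (x, y)

   Identical packing gives RMSD 0 / r 1; unrelated packing gives a large
   RMSD and r near 0. Chain naming is arbitrary, so the four within-dimer
   chain relabelings are scanned and the minimum-RMSD mapping reported.
4. **Orientation.** Kabsch superposition of the dimers of two forms, with the
   rotation decomposed by quaternion swing–twist into its component about
   the **c** axis; for a tetragonal-P vs C-orthorhombic pair the analytic
   45° lattice rotation is removed first. Cell consistency (|**a**+**b**| vs
   mean(a′, b′)) is checked from the metric tensor.
5. **Interface.** Buried area per monomer, (SASA(A)+SASA(B)−SASA(AB))/2,
   from a deterministic Shrake–Rupley SASA, and a distance-only
   hydrogen-bond census over donor/acceptor heavy atoms across the interface.

A synthetic-crystal generator (`packalyze.synthetic_crystals`) builds
poly-alanine helical motifs in chosen cells and space groups and writes valid
PDB files, including *form pairs* that differ by a known twist about **c** —
so every algorithm is testable against ground truth with no downloads.

## Worked example

Generate a synthetic form pair whose dimers differ by a 2.69° twist about
**c**, then compare the two forms:

```sh
packalyze make-fixture --preset form-pair --twist 2.69 --seed 7 --outdir fixtures/
packalyze orientation fixtures/form1.pdb fixtures/form2.pdb --out orient.json
packalyze compare fixtures/form1.pdb fixtures/form2.pdb --mode all-pairs --out report.json
packalyze interface fixtures/form1.pdb --out iface.json
```

which prints (numbers from this exact invocation):

```
total rotation 2.69°, twist about c 2.69°, superposition RMSD 0.00 Å
# pairing mode: all-pairs
	form1.pdb	form2.pdb
form1.pdb	-	0.33/0.99
form2.pdb	0.33/0.99	-
buried area/monomer 47 Å² (5.1%), 0 H-bonds
```

Reading: the superposition recovers the injected 2.69° exactly; the packing
fingerprints of the two forms differ by 0.33 Å RMSD with correlation 0.99 —
a small rotation leaves the 3-D packing nearly intact. Re-running with
`--twist 60` drives the RMSD up and the correlation down: a large
re-orientation destroys the packing relationship. (The tiny buried area is
expected — the synthetic poly-alanine dimer touches along a single helix
face and its backbone-only contact forms no hydrogen bonds.)

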