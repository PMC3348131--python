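# ensemblepockets

Transient-pocket discovery on protein conformational ensembles.

Druggable surface pockets on a protein are not static: in solution they
breathe, merge, and sometimes exist only in a fraction of the conformational
ensemble, invisible in any single crystal structure.  `ensemblepockets`
implements the multi-conformer pocket-analysis workflow used to hunt for
such transient, druggable sites (the motivating system is the metastable
serpin α₁-antitrypsin, where a cryptic hydrophobic site between the A- and
H-helices is a candidate target for polymerisation inhibitors):

1. **Clean** a PDB structure — keep one protein chain, resolve altlocs,
   strip waters/ligands/hydrogens (`structure_io`).
2. **Generate a native-like ensemble** from the single structure with a
   distance-constraint sampler: every observed interatomic distance becomes
   a bound (covalent tightest → nonbonded loosest), random perturbations
   are corrected by iterative pairwise projection, and candidates violating
   the bounds by more than 30 Å in total are rejected (`conformer_gen`).
3. **Detect and score pockets** on every conformer with a 1.0 Å probe grid:
   clusters of ≥ 15 buried grid points become pockets, scored by

   ```
   SiteScore = 0.0733·√min(n, 100) + 0.6688·e − 0.20·min(p, 1)
   Dscore    = 0.094 ·√min(n, 100) + 0.60  ·e − 0.324·p
   ```

   with *n* the site-point count, *e* the enclosure, *p* the
   hydrophilicity; SiteScore ≥ 0.80 marks a drug-binding candidate
   (`pocket_detect`).
4. **Track pocket identity** across the superposed ensemble by
   geometric-center matching: ≤ 3.75 Å to a reference site ⇒ assigned
   (two references in range ⇒ a merged label such as `C_E`), 3.75–10 Å ⇒
   flagged ambiguous for review, > 10 Å ⇒ new.  Persistence = fraction of
   conformers containing each labelled site (`pocket_track`).
5. **Provar propensities** — each residue's probability of lining a pocket
   across the ensemble (within 3.75 Å of any site sphere, summed and
   divided by the ensemble size), written to the B-factor column for
   white-to-red rendering between the first and third quartiles (`provar`).
6. **Report** per-site property distributions (five-number boxplot
   summaries of SiteScore, Dscore, volume, balance), overlay external
   crystal-structure values, and pick the docking receptor conformer — the
   highest-volume pocket among the top five SiteScores (`ensemble_report`).

Everything is testable offline: the `fixtures` module builds synthetic
structures with analytic ground truth (a shell-with-cavity of known volume,
a flat slab with zero pockets, a two-cavity dumbbell, an ideal-geometry
α-helix bundle, and sphere ensembles with exactly known lining
propensities).

## Worked example

```python
from ensemblepockets import fixtures, detect_pockets

structure, analytic = fixtures.make_shell_cavity(inner_radius=6.0,
                                                 aperture=60.0, seed=1)
pockets = detect_pockets(structure)
p = pockets[0]
print(f"pockets found: {len(pockets)}")
print(f"site points  : {p.n}")
print(f"volume       : {p.volume:.0f} A^3  (analytic cavity: {analytic:.0f} A^3)")
print(f"enclosure e  : {p.enclosure:.2f}")
print(f"balance h/p  : {p.balance:.1f}")
print(f"SiteScore    : {p.site_score:.2f}   Dscore: {p.d_score:.2f}")
print(f"druggable    : {p.druggable}")
```

prints

```
pockets found: 1
site points  : 1001
volume       : 1001 A^3  (analytic cavity: 893 A^3)
enclosure e  : 0.94
balance h/p  : 5.6
SiteScore    : 1.33   Dscore: 1.45
druggable    : True
```

The detector recovers the single engineered cavity: ~1000 grid cells
(1 Å³ each) against an analytic volume of 893 Å³ (the excess is the open
aperture mouth), high enclosure, a strongly hydrophobic balance (the shell
is built from apolar carbons), and scores well above the 0.80 druggability
cut-off.

The same pipeline from the shell:

```sh
ensemblepockets fixtures --kind shell_cavity --out fx --seed 1
ensemblepockets conformers --in fx/shell_cavity.pdb --n 100 --seed 1 --out ens.pdb
ensemblepockets pockets --in fx/shell_cavity.pdb --grid 1.0 --min-points 15 --top 10
ensemblepockets provar --ref fx/shell_cavity.pdb --spheres spheres/ --cutoff 3.75
```

## Scope

The package analyses single protein chains in PDB format.  It does not do
docking, ligand preparation, energy minimisation, or mmCIF/nucleic-acid
input; pocket scores are empirical descriptors, not binding-affinity
predictions.  See `docs/methods.md` for the model, parameter defaults and
known limitations.
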