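# Methods

This note documents the models and numerical choices behind
`ensemblepockets`, in the order of the pipeline.

## Structure handling

Input PDB files are reduced to a single protein chain.  When no chain is
requested, the first chain with ≥ 50 standard amino-acid residues is used,
falling back to the first chain with any standard residue.  Alternate
locations are resolved to the highest-occupancy copy (first listed on
ties).  Cleanup removes all HETATM content (waters, ligands, ions) and all
hydrogens: every downstream geometric quantity is defined on heavy atoms
only, which removes any dependence on protonation placement.  No energy
minimisation is performed — cleanup is deliberately the only preparation
step.  Residue keys are `(chain, number, insertion code, name)`; numbering
is never rewritten.

Superposition is a least-squares rigid fit (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) over a named atom
selection, Cα by default, with the RMSD reported over that selection.

## Conformer generation

The sampler emulates distance-constraint ensemble generation from a single
structure.  The constraint library is built from the template's observed
interatomic distances, with per-category half-widths (Å):

| category            | detection rule                                   | ± tolerance |
|---------------------|--------------------------------------------------|-------------|
| covalent            | d ≤ covalent-radii sum + 0.45 Å                  | 0.05 |
| angle (1-3)         | second neighbours in the bond graph              | 0.10 |
| hydrogen bond       | N/O pairs within 3.5 Å (no angle term)           | 0.30 |
| nonbonded contact   | any remaining pair within 6.0 Å                  | 1.50 |

Stronger interactions get tighter bounds; bounds always bracket the
template distance, so the template itself has zero violation.  The
hydrogen-bond rule is heavy-atom-only by design (no protons exist after
cleanup), so no donor–H–acceptor angle is available; 3.5 Å between N/O is
the standard donor–acceptor distance window.

Each candidate conformer starts from the template plus an isotropic
Gaussian displacement per atom (σ = 0.75 Å by default — conservative,
native-like sampling).  Correction is the classic pairwise-projection
scheme: sweeps over the constraints in randomised order move both atoms of
a violated pair along their separation vector, half a step each, to 0.01 Å
inside the violated bound.  Sweeps run until the *total* violation
Σ max(0, lo−d) + max(0, d−hi) falls below 10⁻⁴ Å or 1000 sweeps elapse.
The tight convergence target (rather than stopping at the rejection
threshold) is what makes individual covalent bounds essentially exactly
satisfied in accepted conformers.  A candidate is rejected when its final
total violation exceeds 30 Å.  The threshold is deliberately permissive —
a 3 Å budget would serve equally, since converged candidates sit orders of
magnitude below either value — and is configurable.  The inner sweep is
compiled with numba.

Distance constraints cannot see handedness: a mirror-flipped side chain
satisfies every pair bound.  After convergence the Cα improper
(signed volume of N−Cα, C−Cα, Cβ−Cα) of every residue is compared with the
template; flipped residues have their Cβ reflected through the N–Cα–C
plane and the correction re-run (up to 10 repair rounds).  Ensembles
additionally reject any conformer preserving < 95% of improper signs —
with repair enabled this is essentially never triggered.

Ensemble generation draws per-candidate sub-seeds deterministically from
the master seed (`SeedSequence(seed, spawn_key=(attempt,))`), so a given
(structure, parameters, seed) triple reproduces the ensemble bitwise.
Accepted conformers are superposed back onto the template (Cα fit) and
their Cα RMSD recorded.  On the 300-atom helix-bundle fixture the default
ensemble of 100 conformers generates in seconds; samples stay within
~0.5 Å Cα RMSD of the template.  The sampler makes no attempt to
reproduce any particular external sampler's RMSD spread.

## Pocket detection

A cubic probe grid (1.0 Å default) is laid over the structure in a
canonical frame (centroid origin, sign-fixed principal axes), which makes
detection invariant under rigid motion of the input up to grid
discretisation (a world-aligned grid would not be).  A grid point is a
candidate *site point* when:

* it lies outside every atom's van der Waals sphere (C 1.70, N 1.55,
  O 1.52, S 1.80 Å);
* it is within 8 Å of the vdW surface (nearest-atom estimate); and
* its **buriedness** — the fraction of 33 antipodal ray axes blocked in
  *both* directions within the ray range — is at least 0.35.

Buriedness, not the plain blocked-ray fraction, is the candidate
criterion: a point hovering over a flat surface has a blocked fraction
near 0.5 (every downward ray hits) but buriedness near zero (every axis
has an open direction), so open surface never yields spurious pockets,
while cavity interiors score near 1.  The reported **enclosure e** of a
pocket remains the mean blocked-ray fraction over its site points, the
conventional "how surrounded is this site" measure.  Rays use 66 fixed
golden-spiral directions (33 ± pairs); a ray is blocked when an atom
sphere intersects it with the atom's projection within the range.  The
range default is 12 Å: it must exceed the diameter of cavities of
interest, otherwise rays from near-wall points pass through the opposite
wall's distance cap and a fully enclosed cavity reads as partially open.

Site points are typed by local chemistry: nearest atom N → donor, O →
acceptor; nearest C/S is *hydrophobic* only under a restrictive rule
(≥ 2 apolar atoms within 4.5 Å), else philic-neutral.  Pocket
hydrophobicity h and hydrophilicity p are the (calibration-scaled,
default 1.0) fractions of hydrophobic and non-hydrophobic points;
balance = h/p with the denominator floored at 0.1 and the ratio capped at
10 to keep the all-hydrophobic limit finite.

Connected components of site points under 26-neighbour grid adjacency
become pockets; components below 15 points are discarded, survivors are
ranked by SiteScore (ties: volume, then lexicographic center) and the top
10 kept.  Volume is one grid cell per site point (n·spacing³).  On the
analytic shell-cavity fixture this recovers the cavity volume to ~12% at
1.0 Å spacing (converging at 0.5 Å); the residual excess is real — grid
cells in the open aperture mouth are legitimately buried.

Scores are linear in √(site points), enclosure and hydrophilicity:
SiteScore caps both n (at 100) and p (at 1.0); Dscore leaves p uncapped so
strongly hydrophilic sites are penalised without bound.  The default
coefficients — (0.0733, 0.6688, 0.20) for SiteScore, (0.094, 0.60, 0.324)
for Dscore — follow the published SiteMap calibration and are exposed in
`PocketConfig` for recalibration.  SiteScore ≥ 0.80 annotates a pocket as
a drug-binding candidate.

## Pocket tracking

Assignment is a pure function of the distances between a pocket's
geometric center and the reference centers: d ≤ 3.75 Å ⇒ assigned
(all references within the cutoff joined alphabetically with "_" when two
or more qualify, e.g. `C_E`); 3.75 < d ≤ 10 Å ⇒ *ambiguous*, carrying the
nearest label as a suggestion but never counted as assigned — matches in
this band traditionally need human inspection, so automation exposes an
explicit review queue rather than silently guessing; d > 10 Å everywhere
⇒ *new*.  Both boundaries are inclusive on the lower-status side (3.75
assigns, 10.0 is still ambiguous) — a declared convention.  Persistence counts a conformer once per label
regardless of how many of its pockets share the label; merged labels are
distinct rows.  Tracking refuses input not flagged as superposed.

## Provar propensities

For each conformer, a residue scores 1 when any of its atoms lies within
3.75 Å (inclusive) of any site-sphere center, else 0; the profile is the
elementwise mean over conformers, so a residue lining pockets in 92 of
100 conformers scores exactly 0.92.  Distances are taken to sphere
*centers* (radii are not subtracted — a declared convention, since sphere
dialects disagree about radii).  Colour limits for rendering are the first
and third quartiles of the per-residue probability distribution under the
linear-interpolation ("type 7") quantile convention, which is stated here
because quartile conventions differ; note type-7 quartiles are only
duplication-invariant when they land on order statistics.  Annotation
writes each residue's probability into the B-factor column (two decimals)
of every atom of that residue.

## Ensemble reporting

Per-site property distributions collect one value per conformer — from the
conformer's highest-SiteScore pocket when a label occurs twice — and
summarise as (min, Q1, median, Q3, max) with the same quantile convention
as above.  External per-structure values join on (label, property) and are
flagged within/above/below the ensemble range.  The docking receptor for a
site is the conformer with the highest pocket volume among those holding
the top five SiteScores; score ties at rank five admit all tied
candidates before the volume test, and remaining ties go to the lowest
conformer id, making the pick order-independent.

## Synthetic fixtures and what they do (not) show

The fixture generators provide exact ground truth: the shell cavity's
analytic volume (sphere minus the aperture's spherical cap, with atom
centers at inner radius + vdW so the cavity wall sits on the vdW
envelope), the slab's guaranteed zero pockets, the two-cavity dumbbell's
count, the helix bundle's ideal peptide geometry (NeRF-built N/Cα/C/O/Cβ
with α-helical torsions — 300 atoms at the default 4 × 15 residues), and
mask ensembles whose residues-on-an-8 Å-grid layout makes lining
propensities exactly k/n by construction.  All are byte-reproducible from
(parameters, seed).

Passing on these fixtures validates the geometry, bookkeeping and
determinism of every stage.  It does *not* show that the detector's scores
rank real binding sites correctly (the fixtures' chemistry is a toy), nor
that the conformer sampler reproduces the conformational spread of a real
protein — the problem sizes here (hundreds of atoms, single cavities) are
chosen as the smallest systems that exercise every code path with exact
ground truth.

## Known limitations

* Heavy atoms only; no protonation states, so hydrogen-bond constraints
  and donor typing are distance-based approximations.
* Grid detection is resolution-limited: pocket volumes carry O(spacing)
  surface error, and rigid-motion invariance holds only to discretisation
  (and to principal-axes stability for highly symmetric inputs).
* The score coefficients are adopted from an external calibration, not
  refit; absolute score values on non-protein toys (e.g. the all-carbon
  shell) are outside that calibration's domain.
* Single-chain analysis only; inter-chain pockets are out of scope.
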