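"""Distance-constraint conformer ensemble generation.

From a single structure, a library of interatomic distance constraints is
built: every pair observed at a given distance must stay inside
``[observed − tol, observed + tol]``, with the tolerance set by how strong
the interaction is (covalent bonds tightest, then 1-3 angle pairs, hydrogen
bonds, and generic nonbonded contacts loosest).  New conformers are produced
by perturbing the template coordinates and iteratively correcting violated
pairs with pairwise projection sweeps until the constraint set is satisfied;
candidates whose total violation stays above a rejection threshold are
discarded and re-sampled.  The result is a conservative, native-like
ensemble around the input structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial import cKDTree

from .structure_io import MolecularStructure, superpose

__all__ = [
    "TolerancePolicy",
    "DistanceConstraint",
    "ConstraintSet",
    "Conformer",
    "Rejection",
    "Ensemble",
    "build_constraints",
    "total_violation",
    "generate_conformer",
    "generate_ensemble",
    "chirality_fraction",
    "EnsembleGenerationError",
]

COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
                  "SE": 1.20, "H": 0.31}
BOND_SLOP = 0.45  # Å added to the covalent-radii sum when detecting bonds

CATEGORIES = ("covalent", "angle-1-3", "hbond", "nonbonded-contact")


@dataclass(frozen=True)
class TolerancePolicy:
    """Per-category half-widths of the distance bounds, in Å.

    Stronger interactions get tighter constraints; the contact cutoff sets
    how far apart two atoms may be while still generating a nonbonded
    constraint.
    """

    covalent: float = 0.05
    angle_1_3: float = 0.10
    hbond: float = 0.30
    nonbonded: float = 1.50
    contact_cutoff: float = 6.0
    hbond_cutoff: float = 3.5

    def tolerance(self, category: str) -> float:
        return {
            "covalent": self.covalent,
            "angle-1-3": self.angle_1_3,
            "hbond": self.hbond,
            "nonbonded-contact": self.nonbonded,
        }[category]


@dataclass(frozen=True)
class DistanceConstraint:
    atom_i: int
    atom_j: int
    lower: float
    upper: float
    category: str

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("constraint must involve two distinct atoms")
        if not (0.0 < self.lower <= self.upper):
            raise ValueError(f"invalid bounds [{self.lower}, {self.upper}]")


@dataclass
class ConstraintSet:
    """Distance-bound library for one template structure."""

    template: MolecularStructure
    constraints: list[DistanceConstraint]
    policy: TolerancePolicy

    # packed arrays for the numeric kernels
    _i: np.ndarray = field(init=False, repr=False)
    _j: np.ndarray = field(init=False, repr=False)
    _lower: np.ndarray = field(init=False, repr=False)
    _upper: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._i = np.array([c.atom_i for c in self.constraints], dtype=np.int64)
        self._j = np.array([c.atom_j for c in self.constraints], dtype=np.int64)
        self._lower = np.array([c.lower for c in self.constraints], dtype=np.float64)
        self._upper = np.array([c.upper for c in self.constraints], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.constraints)

    def by_category(self, category: str) -> list[DistanceConstraint]:
        return [c for c in self.constraints if c.category == category]

    def pair_distances(self, coords: np.ndarray) -> np.ndarray:
        return np.linalg.norm(coords[self._j] - coords[self._i], axis=1)

    def per_constraint_violation(self, coords: np.ndarray) -> np.ndarray:
        d = self.pair_distances(coords)
        return np.maximum(0.0, self._lower - d) + np.maximum(0.0, d - self._upper)


@dataclass
class Conformer:
    coordinates: np.ndarray
    seed: int
    iterations_used: int
    total_violation: float
    ca_rmsd: float | None = None


@dataclass
class Rejection:
    """Outcome for a candidate that failed to satisfy the constraints."""

    seed: int
    iterations_used: int
    total_violation: float
    reason: str = "total violation above threshold"


@dataclass
class Ensemble:
    template: MolecularStructure
    conformers: list[Conformer]
    superposed: bool = False

    def coordinate_sets(self) -> list[np.ndarray]:
        return [c.coordinates for c in self.conformers]

    def diagnostics(self) -> pd.DataFrame:
        """Per-conformer seed / iteration / violation / RMSD table."""
        return pd.DataFrame(
            {
                "conformer": np.arange(len(self.conformers)),
                "seed": [c.seed for c in self.conformers],
                "iterations": [c.iterations_used for c in self.conformers],
                "total_violation": [c.total_violation for c in self.conformers],
                "ca_rmsd": [c.ca_rmsd for c in self.conformers],
            }
        )


class EnsembleGenerationError(RuntimeError):
    pass


def build_constraints(
    s: MolecularStructure, policy: TolerancePolicy | None = None
) -> ConstraintSet:
    """Build the distance-constraint library for a template structure.

    Pair categories, from tightest to loosest tolerance:

    * covalent — heavy-atom pairs within the element covalent-radii sum
      (+0.45 Å slop); every such pair appears exactly once.
    * angle-1-3 — second neighbours in the bond graph.
    * hbond — N/O donor–acceptor pairs within 3.5 Å, not already covered.
    * nonbonded-contact — any remaining pair within the contact cutoff.

    Bounds bracket the observed distance: ``observed ± tolerance``.
    """
    if s.n_atoms < 2:
        raise ValueError("need at least 2 atoms to build constraints")
    policy = policy or TolerancePolicy()
    coords = s.coordinates()
    elements = [e.upper() for e in s.elements()]
    radii = np.array([COVALENT_RADII.get(e, 0.77) for e in elements])
    tree = cKDTree(coords)

    max_bond = 2 * radii.max() + BOND_SLOP
    pairs = tree.query_pairs(r=max(max_bond, policy.contact_cutoff),
                             output_type="ndarray")
    d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)

    bonded_mask = d <= radii[pairs[:, 0]] + radii[pairs[:, 1]] + BOND_SLOP
    bonded = {tuple(p) for p in pairs[bonded_mask]}

    adjacency: dict[int, set[int]] = {}
    for i, j in bonded:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    one_three: set[tuple[int, int]] = set()
    for mid, nbrs in adjacency.items():
        nb = sorted(nbrs)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                pair = (nb[a], nb[b])
                if pair not in bonded:
                    one_three.add(pair)

    constraints: list[DistanceConstraint] = []

    def add(i: int, j: int, dist: float, category: str) -> None:
        tol = policy.tolerance(category)
        constraints.append(
            DistanceConstraint(
                atom_i=int(i),
                atom_j=int(j),
                lower=max(dist - tol, 1e-3),
                upper=dist + tol,
                category=category,
            )
        )

    taken: set[tuple[int, int]] = set()
    for (i, j), dist in zip(pairs, d):
        key = (int(i), int(j))
        if key in bonded:
            add(i, j, dist, "covalent")
            taken.add(key)
    for i, j in sorted(one_three):
        dist = float(np.linalg.norm(coords[j] - coords[i]))
        add(i, j, dist, "angle-1-3")
        taken.add((i, j))
    no = np.array([e in ("N", "O") for e in elements])
    for (i, j), dist in zip(pairs, d):
        key = (int(i), int(j))
        if key in taken:
            continue
        if no[i] and no[j] and dist <= policy.hbond_cutoff:
            add(i, j, dist, "hbond")
            taken.add(key)
    for (i, j), dist in zip(pairs, d):
        key = (int(i), int(j))
        if key in taken or dist > policy.contact_cutoff:
            continue
        add(i, j, dist, "nonbonded-contact")
        taken.add(key)

    return ConstraintSet(template=s, constraints=constraints, policy=policy)


def total_violation(coords: np.ndarray, cs: ConstraintSet) -> float:
    """Total constraint violation in Å: Σ max(0, lo−d) + max(0, d−hi)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (cs.template.n_atoms, 3):
        raise ValueError(
            f"coordinates shape {coords.shape} does not match template "
            f"({cs.template.n_atoms} atoms)"
        )
    return float(cs.per_constraint_violation(coords).sum())


@njit(cache=True)
def _projection_sweep(coords, pi, pj, lower, upper, order, slack):  # pragma: no cover
    """One pass of pairwise projection over constraints in the given order.

    A violated pair is moved along its separation vector, half-step each
    atom, to ``slack`` inside the violated bound.
    """
    for k in range(order.shape[0]):
        idx = order[k]
        i = pi[idx]
        j = pj[idx]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d > upper[idx]:
            target = upper[idx] - slack
        elif d < lower[idx]:
            target = lower[idx] + slack
            if target > upper[idx]:
                target = 0.5 * (lower[idx] + upper[idx])
        else:
            continue
        if d < 1e-9:
            # coincident atoms: push apart along x
            dx, dy, dz, d = 1.0, 0.0, 0.0, 1.0
        f = 0.5 * (d - target) / d
        coords[i, 0] += f * dx
        coords[i, 1] += f * dy
        coords[i, 2] += f * dz
        coords[j, 0] -= f * dx
        coords[j, 1] -= f * dy
        coords[j, 2] -= f * dz


def _improper_quads(template: MolecularStructure) -> np.ndarray:
    """(k, 4) atom indices (N, CA, C, CB) per residue that has all four."""
    by_res: dict[tuple, dict[str, int]] = {}
    for idx, a in enumerate(template.atoms):
        if a.atom_name in ("N", "CA", "C", "CB"):
            by_res.setdefault(a.residue_key, {})[a.atom_name] = idx
    quads = [
        [names[n] for n in ("N", "CA", "C", "CB")]
        for names in by_res.values()
        if len(names) == 4
    ]
    return np.array(quads, dtype=int).reshape(-1, 4)


def _improper_signs(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    v1 = coords[quads[:, 0]] - coords[quads[:, 1]]
    v2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    v3 = coords[quads[:, 3]] - coords[quads[:, 1]]
    return np.sign(np.einsum("ij,ij->i", np.cross(v1, v2), v3))


def generate_conformer(
    cs: ConstraintSet,
    seed: int,
    start_magnitude: float = 0.75,
    max_iter: int = 1000,
    reject_threshold: float = 30.0,
    converge_tol: float = 1e-4,
    projection_slack: float = 0.01,
    fix_chirality: bool = True,
) -> Conformer | Rejection:
    """Generate one candidate conformer from a seeded random perturbation.

    Starting coordinates are the template plus an isotropic Gaussian
    displacement of scale ``start_magnitude`` per atom.  Correction sweeps
    (pairwise projection in randomised constraint order) run until the total
    violation drops to ``converge_tol`` or ``max_iter`` sweeps elapse.
    Distance constraints are mirror-invariant, so residues whose Cα improper
    flips handedness are repaired (Cβ reflected through the N–Cα–C plane)
    and the correction re-run.  The candidate is returned as a
    :class:`Conformer` if its final total violation is at most
    ``reject_threshold``, else as a :class:`Rejection`.  Identical seeds give
    bitwise-identical output.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if start_magnitude < 0:
        raise ValueError("start_magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    coords = cs.template.coordinates()
    if start_magnitude > 0:
        coords = coords + rng.normal(0.0, start_magnitude, size=coords.shape)
    tv = float(cs.per_constraint_violation(coords).sum())
    iterations = 0
    n_con = len(cs)

    def converge() -> None:
        nonlocal tv, iterations
        while tv > converge_tol and iterations < max_iter:
            order = rng.permutation(n_con)
            _projection_sweep(coords, cs._i, cs._j, cs._lower, cs._upper, order,
                              projection_slack)
            tv = float(cs.per_constraint_violation(coords).sum())
            iterations += 1

    converge()
    if fix_chirality:
        quads = _improper_quads(cs.template)
        if len(quads):
            ref_signs = _improper_signs(cs.template.coordinates(), quads)
            for _ in range(10):
                flipped = np.nonzero(_improper_signs(coords, quads) * ref_signs < 0)[0]
                if len(flipped) == 0 or iterations >= max_iter:
                    break
                for q in quads[flipped]:
                    n_pos, ca_pos, c_pos, cb_pos = coords[q]
                    normal = np.cross(n_pos - ca_pos, c_pos - ca_pos)
                    norm = np.linalg.norm(normal)
                    if norm < 1e-9:
                        continue
                    normal /= norm
                    coords[q[3]] = cb_pos - 2.0 * np.dot(cb_pos - ca_pos,
                                                         normal) * normal
                tv = float(cs.per_constraint_violation(coords).sum())
                converge()
    if tv <= reject_threshold:
        return Conformer(
            coordinates=coords, seed=seed, iterations_used=iterations,
            total_violation=tv,
        )
    return Rejection(seed=seed, iterations_used=iterations, total_violation=tv)


def chirality_fraction(template: MolecularStructure, coords: np.ndarray) -> float:
    """Fraction of residues whose Cα improper sign matches the template.

    The improper is the signed volume of (N−CA, C−CA, CB−CA); its sign
    encodes L/D handedness.  Residues lacking any of N/CA/C/CB are skipped;
    returns 1.0 when no residue is checkable.
    """
    ref = template.coordinates()
    by_res: dict[tuple, dict[str, int]] = {}
    for idx, a in enumerate(template.atoms):
        if a.atom_name in ("N", "CA", "C", "CB"):
            by_res.setdefault(a.residue_key, {})[a.atom_name] = idx
    total = 0
    preserved = 0
    for names in by_res.values():
        if len(names) < 4:
            continue
        ids = [names[n] for n in ("N", "CA", "C", "CB")]

        def signed_volume(x):
            v1 = x[ids[0]] - x[ids[1]]
            v2 = x[ids[2]] - x[ids[1]]
            v3 = x[ids[3]] - x[ids[1]]
            return float(np.dot(np.cross(v1, v2), v3))

        total += 1
        if signed_volume(ref) * signed_volume(coords) > 0:
            preserved += 1
    return preserved / total if total else 1.0


def generate_ensemble(
    s: MolecularStructure,
    n: int = 100,
    seed: int = 1,
    start_magnitude: float = 0.75,
    max_iter: int = 1000,
    reject_threshold: float = 30.0,
    policy: TolerancePolicy | None = None,
    min_chirality: float = 0.95,
    max_attempts_per_conformer: int = 20,
) -> Ensemble:
    """Generate an ensemble of ``n`` accepted conformers.

    Candidates are drawn with sub-seeds derived deterministically from the
    master seed; rejections (violation above threshold or a chirality-check
    failure) are re-sampled.  Accepted conformers are superposed onto the
    template (Cα fit when Cα atoms exist, all atoms otherwise) and their Cα
    RMSD to the template recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cs = build_constraints(s, policy)
    fit_selection = "CA" if len(s.select("CA")) >= 3 else None
    accepted: list[Conformer] = []
    attempt = 0
    max_attempts = n * max_attempts_per_conformer
    while len(accepted) < n:
        if attempt >= max_attempts:
            raise EnsembleGenerationError(
                f"accepted only {len(accepted)}/{n} conformers after "
                f"{attempt} attempts (seed={seed}, sigma={start_magnitude}, "
                f"reject_threshold={reject_threshold})"
            )
        sub_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
            .generate_state(1)[0]
        )
        attempt += 1
        out = generate_conformer(
            cs,
            seed=sub_seed,
            start_magnitude=start_magnitude,
            max_iter=max_iter,
            reject_threshold=reject_threshold,
        )
        if isinstance(out, Rejection):
            continue
        if chirality_fraction(s, out.coordinates) < min_chirality:
            continue
        fitted, _ = superpose(
            s.with_coordinates(out.coordinates), s, selection=fit_selection
        )
        out.coordinates = fitted.coordinates()
        ca = s.select("CA")
        if len(ca) >= 1:
            ref = s.coordinates()[ca]
            out.ca_rmsd = float(
                np.sqrt(np.mean(np.sum((out.coordinates[ca] - ref) ** 2, axis=1)))
            )
        accepted.append(out)
    return Ensemble(template=s, conformers=accepted, superposed=True)
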