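"""Deterministic synthetic structures with known pocket ground truth.

Real crystal structures need downloads and carry no analytic truth; these
generators build toy "proteins" whose cavity geometry is known exactly, so
every pipeline stage can be validated end to end:

* ``make_shell_cavity`` — a spherical shell of pseudo-atoms with a circular
  aperture; the interior is one enclosed cavity of known analytic volume.
* ``make_slab`` — a flat atom sheet with no concavity (zero-pocket truth).
* ``make_two_cavity`` — two well-separated shell cavities (two-pocket truth).
* ``make_helix_bundle`` — an ideal-geometry α-helix bundle with real backbone
  chemistry (N/CA/C/O/CB), the substrate for conformer generation.
* ``make_mask_ensemble`` — a residue field plus per-conformer sphere sets
  engineered so that pocket-lining propensities are known exactly.

Every fixture is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .structure_io import AtomRecord, MolecularStructure

__all__ = [
    "FixtureSpec",
    "make_shell_cavity",
    "make_slab",
    "make_two_cavity",
    "make_helix_bundle",
    "make_mask_ensemble",
]

CARBON_VDW = 1.70  # Å, used to place shell atoms so the cavity wall sits on the vdW envelope


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters identifying a synthetic fixture (for sidecar metadata)."""

    kind: str
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atoms_from_points(
    points: np.ndarray,
    element: str = "C",
    atom_name: str = "CB",
    residue_name: str = "ALA",
    chain_id: str = "A",
    first_residue: int = 1,
) -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=i + 1,
            atom_name=atom_name,
            residue_name=residue_name,
            chain_id=chain_id,
            residue_number=first_residue + i,
            insertion_code="",
            element=element,
            position=(float(x), float(y), float(z)),
        )
        for i, (x, y, z) in enumerate(points)
    ]


def _shell_points(
    inner_radius: float, aperture: float, atom_spacing: float, rng: np.random.Generator
) -> np.ndarray:
    shell_radius = inner_radius + CARBON_VDW
    n = max(8, int(round(4.0 * math.pi * shell_radius**2 / atom_spacing**2)))
    dirs = _fibonacci_sphere(n)
    if aperture > 0:
        half = math.radians(aperture) / 2.0
        dirs = dirs[dirs[:, 2] < math.cos(half)]  # aperture opens toward +z
    points = dirs * shell_radius
    # small seeded jitter so fixtures are not pathologically regular
    points = points + rng.normal(0.0, 0.02, size=points.shape)
    return points


def cavity_volume(inner_radius: float, aperture: float) -> float:
    """Analytic cavity volume: sphere minus the aperture's spherical cap."""
    full = 4.0 / 3.0 * math.pi * inner_radius**3
    if aperture <= 0:
        return full
    half = math.radians(aperture) / 2.0
    h = inner_radius * (1.0 - math.cos(half))
    cap = math.pi * h * h * (3.0 * inner_radius - h) / 3.0
    return full - cap


def make_shell_cavity(
    inner_radius: float = 6.0,
    aperture: float = 60.0,
    atom_spacing: float = 1.8,
    seed: int = 0,
) -> tuple[MolecularStructure, float]:
    """Spherical shell of apolar pseudo-atoms enclosing one cavity.

    Atom centres sit at ``inner_radius + vdW(C)`` so that the cavity wall
    (the inner van der Waals envelope) lies at ``inner_radius``.  The
    aperture is a circular hole of the given full opening angle (degrees)
    centred on +z; ``aperture=0`` closes the shell completely.

    Returns the structure and the analytic cavity volume in Å³.
    """
    if not 0 <= aperture < 180:
        raise ValueError("aperture must be in [0, 180) degrees")
    if atom_spacing <= 0 or inner_radius <= 0:
        raise ValueError("lengths must be positive")
    if atom_spacing > 2.0 * CARBON_VDW:
        raise ValueError(
            f"atom_spacing {atom_spacing} Å leaves gaps wider than two vdW radii; "
            "the shell would not close"
        )
    rng = np.random.default_rng(seed)
    points = _shell_points(inner_radius, aperture, atom_spacing, rng)
    s = MolecularStructure(
        _atoms_from_points(points), source_id=f"shell_cavity_seed{seed}"
    )
    return s, cavity_volume(inner_radius, aperture)


def make_slab(
    nx: int = 10, ny: int = 10, atom_spacing: float = 1.8, seed: int = 0
) -> MolecularStructure:
    """Planar atom grid with no concavity; ground truth is zero pockets."""
    if nx < 3 or ny < 3:
        raise ValueError("slab needs nx, ny >= 3")
    rng = np.random.default_rng(seed)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * atom_spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * atom_spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    points = points + rng.normal(0.0, 0.02, size=points.shape)
    return MolecularStructure(
        _atoms_from_points(points), source_id=f"slab_{nx}x{ny}_seed{seed}"
    )


def make_two_cavity(
    inner_radius: float = 6.0,
    aperture: float = 60.0,
    atom_spacing: float = 1.8,
    separation: float = 30.0,
    seed: int = 0,
) -> tuple[MolecularStructure, float]:
    """Two shell cavities ``separation`` Å apart; ground truth is two pockets."""
    rng = np.random.default_rng(seed)
    p1 = _shell_points(inner_radius, aperture, atom_spacing, rng)
    p2 = _shell_points(inner_radius, aperture, atom_spacing, rng)
    p1 = p1 + np.array([-separation / 2.0, 0.0, 0.0])
    p2 = p2 + np.array([separation / 2.0, 0.0, 0.0])
    atoms = _atoms_from_points(np.vstack([p1, p2]))
    s = MolecularStructure(atoms, source_id=f"two_cavity_seed{seed}")
    return s, cavity_volume(inner_radius, aperture)


# --- ideal-geometry helix bundle -------------------------------------------

# bond lengths (Å) and angles (deg) of ideal peptide geometry
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0  # ideal α-helix


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position a new atom from three predecessors + internal coords."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_helix(n_res: int) -> list[dict[str, np.ndarray]]:
    """Backbone + CB + O coordinates of an ideal α-helix, one dict per residue."""
    # bootstrap the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = residues[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca = _place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        residues.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(residues):
        # carbonyl O in the peptide plane, trans to the next N
        if i + 1 < len(residues):
            res["O"] = _place_atom(residues[i + 1]["N"], res["CA"], res["C"],
                                   _B_C_O, 120.8, 180.0)
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, 120.8,
                                   _PSI + 180.0)
        # CB from tetrahedral geometry (L-amino acid chirality)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], _B_CA_CB, 110.5,
                                122.5)
    return residues


def make_helix_bundle(
    n_helices: int = 4,
    residues_per_helix: int = 15,
    helix_separation: float = 10.0,
    seed: int = 0,
) -> MolecularStructure:
    """Parallel bundle of ideal α-helices with full heavy-atom backbones.

    Each residue carries N, CA, C, O, CB (alanine), so covalent, 1-3,
    hydrogen-bond and contact constraint categories, plus the Cα-improper
    chirality check, are all exercised.  Defaults give 4 × 15 × 5 = 300 atoms.
    """
    rng = np.random.default_rng(seed)
    helix = _ideal_helix(residues_per_helix)
    coords0 = np.array([[r[a] for a in ("N", "CA", "C", "O", "CB")] for r in helix])
    axis_dir = coords0[-1, 1] - coords0[0, 1]
    axis_dir /= np.linalg.norm(axis_dir)
    # rotate the helix axis onto z
    v = np.cross(axis_dir, [0.0, 0.0, 1.0])
    sv, cv = np.linalg.norm(v), float(axis_dir @ [0.0, 0.0, 1.0])
    if sv > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - cv) / sv**2)
    else:
        R = np.eye(3)
    flat = coords0.reshape(-1, 3) @ R.T
    flat -= flat.mean(axis=0)

    atoms: list[AtomRecord] = []
    serial = 1
    resnum = 1
    for h in range(n_helices):
        theta = 2.0 * math.pi * h / n_helices
        if n_helices > 1:
            # helix_separation = distance between adjacent helix axes
            radius = helix_separation / (2.0 * math.sin(math.pi / n_helices))
            offset = np.array(
                [radius * math.cos(theta), radius * math.sin(theta), 0.0]
            )
        else:
            offset = np.zeros(3)
        spin = rng.uniform(0.0, 2.0 * math.pi)
        Rz = np.array(
            [
                [math.cos(spin), -math.sin(spin), 0.0],
                [math.sin(spin), math.cos(spin), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        placed = (flat @ Rz.T + offset).reshape(residues_per_helix, 5, 3)
        for r in range(residues_per_helix):
            for name, pos in zip(("N", "CA", "C", "O", "CB"), placed[r]):
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        residue_name="ALA",
                        chain_id="A",
                        residue_number=resnum,
                        insertion_code="",
                        element=name[0],
                        position=tuple(float(x) for x in pos),
                    )
                )
                serial += 1
            resnum += 1
    return MolecularStructure(atoms, source_id=f"helix_bundle_seed{seed}")


def make_mask_ensemble(
    n_residues: int = 100,
    n_conformers: int = 100,
    lining_set: tuple[int, ...] = (10, 11, 12, 40, 41),
    k_present: int = 92,
    seed: int = 0,
) -> tuple[MolecularStructure, list[np.ndarray]]:
    """Residue field + per-conformer sphere sets with exact lining truth.

    Residues are single pseudo-atoms on a coarse 8 Å grid, so a sphere placed
    2 Å above a designated residue is within 3.75 Å of that residue only.
    In exactly ``k_present`` of the ``n_conformers`` sphere sets the spheres
    sit on the ``lining_set`` residues; in the rest they are placed > 10 Å
    from every atom.  The exact pocket-lining propensity is therefore
    ``k_present / n_conformers`` on ``lining_set`` and 0 elsewhere.

    ``lining_set`` holds 0-based residue indices.
    """
    if not 0 <= k_present <= n_conformers:
        raise ValueError("k_present must be in [0, n_conformers]")
    if max(lining_set, default=-1) >= n_residues:
        raise ValueError("lining_set index out of range")
    spacing = 8.0
    side = max(2, math.ceil(n_residues ** (1.0 / 3.0)))
    idx = np.arange(n_residues)
    pts = np.column_stack(
        [(idx // (side * side)), (idx // side) % side, idx % side]
    ).astype(float) * spacing
    structure = MolecularStructure(
        _atoms_from_points(pts), source_id=f"mask_field_seed{seed}"
    )
    rng = np.random.default_rng(seed)
    present = np.zeros(n_conformers, dtype=bool)
    present[rng.permutation(n_conformers)[:k_present]] = True
    far = pts.max(axis=0) + 100.0
    sphere_sets: list[np.ndarray] = []
    for conf in range(n_conformers):
        if present[conf]:
            spheres = pts[list(lining_set)] + np.array([0.0, 0.0, 2.0])
        else:
            spheres = far[None, :] + rng.normal(0.0, 0.5, size=(1, 3))
        sphere_sets.append(spheres)
    return structure, sphere_sets
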