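"""Grid-based surface-pocket detection and druggability scoring.

A 1.0 Å probe grid is laid over the structure.  Grid points that sit outside
the protein's van der Waals envelope but are well surrounded by it become
*site points*; connected clusters of at least 15 site points are *pockets*.
Each pocket gets the classic druggability descriptors:

* ``n`` — site-point count (capped at 100 inside the scores),
* ``e`` — enclosure: mean fraction of rays cast from the site points that
  hit protein within range,
* ``p`` / ``h`` — hydrophilic / hydrophobic character from site-point typing,
* ``balance`` — h/p,
* ``volume`` — one grid cell per site point,

and two scores::

    SiteScore = a_n·√min(n, 100) + a_e·e − a_p·min(p, 1)
    Dscore    = a_n·√min(n, 100) + a_e·e − a_p·p        (p uncapped)

A SiteScore of at least 0.80 marks a pocket as a drug-binding candidate.

Candidate site points are selected by *buriedness* — the fraction of
antipodal ray axes blocked in both directions — which is ≈1 inside a cavity,
≈0 over a flat or convex surface, so open surface never clusters into
spurious pockets.  Reported enclosure remains the plain blocked-ray
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, MolecularStructure, ResidueKey, write_pdb

__all__ = [
    "SitePoint",
    "Pocket",
    "ScoreCoefficients",
    "PocketConfig",
    "grid_sites",
    "cluster_site_points",
    "site_score",
    "d_score",
    "detect_pockets",
    "pockets_to_sphere_pdb",
    "pockets_to_table",
    "DRUGGABLE_SITESCORE_CUTOFF",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

#: SiteScore at or above which a pocket is a drug-binding candidate.
DRUGGABLE_SITESCORE_CUTOFF = 0.80

CHARACTERS = ("hydrophobic", "donor", "acceptor", "philic-neutral")


@dataclass(frozen=True)
class ScoreCoefficients:
    """Weights of the √n, enclosure and hydrophilicity terms of a score.

    ``a_p`` is entered as a penalty magnitude (subtracted).  Defaults follow
    the published SiteMap calibration: SiteScore (0.0733, 0.6688, 0.20) and
    Dscore (0.094, 0.60, 0.324).
    """

    a_n: float
    a_e: float
    a_p: float

    def __post_init__(self) -> None:
        if self.a_n <= 0 or self.a_e <= 0 or self.a_p <= 0:
            raise ValueError("score coefficients must be positive")


SITESCORE_DEFAULT = ScoreCoefficients(0.0733, 0.6688, 0.20)
DSCORE_DEFAULT = ScoreCoefficients(0.094, 0.60, 0.324)


@dataclass(frozen=True)
class SitePoint:
    """A favourable probe position outside the protein vdW envelope."""

    position: tuple[float, float, float]
    character: str
    enclosure: float = 0.0  # blocked-ray fraction at this point
    buriedness: float = 0.0  # both-way-blocked axis fraction

    def __post_init__(self) -> None:
        if self.character not in CHARACTERS:
            raise ValueError(f"unknown site-point character {self.character!r}")


@dataclass
class Pocket:
    """A cluster of site points with its descriptors and scores."""

    site_points: list[SitePoint]
    n: int
    volume: float
    enclosure: float
    hydrophilicity: float
    hydrophobicity: float
    balance: float
    center: tuple[float, float, float]
    site_score: float
    d_score: float
    lining_residues: tuple[ResidueKey, ...] = ()
    druggable: bool = False

    def positions(self) -> np.ndarray:
        return np.array([sp.position for sp in self.site_points], dtype=float)


@dataclass(frozen=True)
class PocketConfig:
    """Tunable parameters of pocket detection (defaults follow the method)."""

    spacing: float = 1.0          # Å, probe grid spacing
    margin: float = 2.0           # Å, bounding-box padding
    min_site_points: int = 15     # smallest reportable pocket
    top_n: int = 10               # pockets kept after ranking
    n_ray_axes: int = 33          # 33 axes = 66 rays per site point
    ray_range: float = 12.0       # Å, maximum ray length; must exceed the
                                  # diameter of cavities of interest, else
                                  # rays escape through the far wall
    buriedness_floor: float = 0.35  # candidate threshold (axis fraction)
    surface_reach: float = 8.0    # Å, max distance from the vdW surface
    hydrophobic_neighbor_radius: float = 4.5  # Å, restrictive apolar test
    hydrophobic_min_neighbors: int = 2
    lining_cutoff: float = 3.75   # Å, pocket-lining residue threshold
    balance_floor: float = 0.1    # lower clamp of the balance denominator
    balance_cap: float = 10.0
    h_scale: float = 1.0          # calibration of hydrophobic fraction
    p_scale: float = 1.0          # calibration of hydrophilic fraction
    site_coeffs: ScoreCoefficients = SITESCORE_DEFAULT
    d_coeffs: ScoreCoefficients = DSCORE_DEFAULT


def _vdw_radii(elements: list[str]) -> np.ndarray:
    return np.array([VDW_RADII.get(e.upper(), DEFAULT_VDW) for e in elements])


def _ray_axes(n_axes: int) -> np.ndarray:
    """n_axes roughly uniform unit vectors (one hemisphere of a golden spiral)."""
    i = np.arange(n_axes, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = (i + 0.5) / n_axes  # upper hemisphere only; the ± pair covers the rest
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _blocked_rays(
    points: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    axes: np.ndarray,
    ray_range: float,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point blocked-ray fraction and buriedness.

    A ray from a point along direction u is blocked when some atom sphere
    intersects it with the (positive) projection of the atom centre on the
    ray within ``ray_range``.  Buriedness is the fraction of the ``axes``
    whose +u and −u rays are both blocked.
    """
    dirs = np.vstack([axes, -axes])  # (2k, 3), antipodal pairs aligned
    k = len(axes)
    r2 = radii**2
    enclosure = np.empty(len(points))
    buried = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start:start + chunk]  # (m, 3)
        rel = coords[None, :, :] - p[:, None, :]  # (m, A, 3)
        proj = np.einsum("mak,dk->mad", rel, dirs)  # (m, A, 2k)
        dist2 = np.einsum("mak,mak->ma", rel, rel)  # (m, A)
        perp2 = dist2[:, :, None] - proj**2
        hit = (proj > 0.0) & (proj <= ray_range) & (perp2 <= r2[None, :, None])
        blocked = hit.any(axis=1)  # (m, 2k)
        enclosure[start:start + chunk] = blocked.mean(axis=1)
        buried[start:start + chunk] = (blocked[:, :k] & blocked[:, k:]).mean(axis=1)
    return enclosure, buried


def _type_points(
    points: np.ndarray,
    coords: np.ndarray,
    elements: list[str],
    config: PocketConfig,
) -> list[str]:
    """Assign probe character from the chemistry of the nearest heavy atom.

    Nearest N → donor, nearest O → acceptor; nearest C/S is hydrophobic only
    under the restrictive rule (at least ``hydrophobic_min_neighbors`` apolar
    atoms within ``hydrophobic_neighbor_radius``), otherwise philic-neutral.
    """
    tree = cKDTree(coords)
    _, nearest = tree.query(points)
    apolar = np.array([e.upper() in ("C", "S") for e in elements])
    apolar_tree = cKDTree(coords[apolar]) if apolar.any() else None
    chars: list[str] = []
    for pt, idx in zip(points, nearest):
        el = elements[idx].upper()
        if el == "N":
            chars.append("donor")
        elif el == "O":
            chars.append("acceptor")
        elif el in ("C", "S"):
            n_apolar = (
                len(apolar_tree.query_ball_point(pt, config.hydrophobic_neighbor_radius))
                if apolar_tree is not None
                else 0
            )
            chars.append(
                "hydrophobic"
                if n_apolar >= config.hydrophobic_min_neighbors
                else "philic-neutral"
            )
        else:
            chars.append("philic-neutral")
    return chars


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Structure-anchored frame: centroid origin, sign-fixed principal axes.

    Laying the probe grid (and ray directions) in this frame makes pocket
    detection invariant under rigid motion of the input, up to grid
    discretisation and eigenvector stability for near-symmetric shapes.
    """
    c0 = coords.mean(axis=0)
    centred = coords - c0
    cov = centred.T @ centred / len(coords)
    _, vecs = np.linalg.eigh(cov)
    R = vecs[:, ::-1]  # descending variance
    for k in range(3):
        lead = np.argmax(np.abs(R[:, k]))
        if R[lead, k] < 0:
            R[:, k] = -R[:, k]
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return c0, R


def grid_sites(
    s: MolecularStructure,
    spacing: float = 1.0,
    config: PocketConfig | None = None,
) -> list[SitePoint]:
    """Candidate site points on a regular grid around the structure.

    The grid is laid in the structure's canonical (principal-axes) frame.
    A grid point qualifies when it lies outside every atom's vdW sphere,
    within ``surface_reach`` of the vdW surface, and its buriedness clears
    the candidate floor.  Each candidate is typed by its local chemistry.
    Returned positions are in the input frame.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    config = config or PocketConfig()
    if spacing != config.spacing:
        config = replace(config, spacing=spacing)
    world_coords = s.coordinates()
    elements = s.elements()
    radii = _vdw_radii(elements)
    c0, frame = _canonical_frame(world_coords)
    coords = (world_coords - c0) @ frame

    lo = coords.min(axis=0) - config.margin
    hi = coords.max(axis=0) + config.margin
    grids = [np.arange(lo[d], hi[d] + 1e-9, config.spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(coords)
    max_r = radii.max()
    d_near, i_near = tree.query(points)
    maybe_inside = d_near <= max_r + 1e-9
    inside = np.zeros(len(points), dtype=bool)
    if maybe_inside.any():
        for k in np.nonzero(maybe_inside)[0]:
            for a in tree.query_ball_point(points[k], max_r):
                if np.linalg.norm(points[k] - coords[a]) <= radii[a]:
                    inside[k] = True
                    break
    surface_dist = d_near - radii[i_near]  # nearest-atom surface estimate
    keep = ~inside & (surface_dist <= config.surface_reach)
    points = points[keep]
    if len(points) == 0:
        return []

    axes = _ray_axes(config.n_ray_axes)
    enclosure, buried = _blocked_rays(points, coords, radii, axes,
                                      config.ray_range)
    ok = buried >= config.buriedness_floor
    points, enclosure, buried = points[ok], enclosure[ok], buried[ok]
    chars = _type_points(points, coords, elements, config)
    points = points @ frame.T + c0  # back to the input frame
    return [
        SitePoint(
            position=(float(x), float(y), float(z)),
            character=c,
            enclosure=float(e),
            buriedness=float(b),
        )
        for (x, y, z), c, e, b in zip(points, chars, enclosure, buried)
    ]


def site_score(
    n: int, e: float, p: float, c: ScoreCoefficients = SITESCORE_DEFAULT
) -> float:
    """SiteScore: a_n·√min(n,100) + a_e·e − a_p·min(p,1)."""
    return c.a_n * math.sqrt(min(n, 100)) + c.a_e * e - c.a_p * min(p, 1.0)


def d_score(
    n: int, e: float, p: float, c: ScoreCoefficients = DSCORE_DEFAULT
) -> float:
    """Dscore: as SiteScore but with the hydrophilicity p uncapped."""
    return c.a_n * math.sqrt(min(n, 100)) + c.a_e * e - c.a_p * p


def _pocket_from_points(
    pts: list[SitePoint],
    s: MolecularStructure,
    config: PocketConfig,
) -> Pocket:
    positions = np.array([sp.position for sp in pts])
    n = len(pts)
    center = positions.mean(axis=0)
    enclosure = float(np.mean([sp.enclosure for sp in pts]))
    counts = {c: 0 for c in CHARACTERS}
    for sp in pts:
        counts[sp.character] += 1
    h = config.h_scale * counts["hydrophobic"] / n
    p = config.p_scale * (n - counts["hydrophobic"]) / n
    balance = min(h / max(p, config.balance_floor), config.balance_cap)
    volume = n * config.spacing**3
    ss = site_score(n, enclosure, p, config.site_coeffs)
    ds = d_score(n, enclosure, p, config.d_coeffs)

    atom_tree = cKDTree(s.coordinates())
    lining_idx: set[int] = set()
    for hits in atom_tree.query_ball_point(positions, config.lining_cutoff):
        lining_idx.update(hits)
    residues = s.residues
    res_of_atom = s.residue_index_per_atom()
    lining = tuple(
        residues[i]
        for i in sorted({int(res_of_atom[a]) for a in lining_idx})
    )
    return Pocket(
        site_points=pts,
        n=n,
        volume=volume,
        enclosure=enclosure,
        hydrophilicity=p,
        hydrophobicity=h,
        balance=balance,
        center=tuple(float(x) for x in center),
        site_score=ss,
        d_score=ds,
        lining_residues=lining,
        druggable=ss >= DRUGGABLE_SITESCORE_CUTOFF,
    )


def cluster_site_points(
    points: list[SitePoint],
    s: MolecularStructure,
    min_site_points: int = 15,
    config: PocketConfig | None = None,
) -> list[Pocket]:
    """Partition site points into pockets by 26-neighbour grid adjacency.

    Components smaller than ``min_site_points`` are discarded; survivors are
    ranked by SiteScore (ties: volume, then lowest center lexicographically)
    and at most ``config.top_n`` are returned.
    """
    config = config or PocketConfig()
    if not points:
        return []
    positions = np.array([sp.position for sp in points])
    link = config.spacing * math.sqrt(3.0) * 1.001
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=link, output_type="ndarray")
    m = len(points)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    n_comp, labels = connected_components(adj, directed=False)
    pockets: list[Pocket] = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        if len(idx) < min_site_points:
            continue
        pockets.append(
            _pocket_from_points([points[i] for i in idx], s, config)
        )
    pockets.sort(key=lambda p: (-p.site_score, -p.volume, p.center))
    return pockets[: config.top_n]


def detect_pockets(
    s: MolecularStructure, config: PocketConfig | None = None
) -> list[Pocket]:
    """Full pocket detection: grid probes → clustering → properties/scores.

    Deterministic for a fixed structure and configuration.  Pockets whose
    SiteScore reaches 0.80 carry ``druggable=True``.
    """
    config = config or PocketConfig()
    points = grid_sites(s, spacing=config.spacing, config=config)
    return cluster_site_points(points, s, config.min_site_points, config)


def pockets_to_sphere_pdb(pockets: list[Pocket]) -> str:
    """Pocket-sphere PDB: one HETATM per site point, one SIT residue per pocket."""
    atoms: list[AtomRecord] = []
    serial = 1
    for rank, pocket in enumerate(pockets, start=1):
        for sp in pocket.site_points:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name="PRB",
                    residue_name="SIT",
                    chain_id="Z",
                    residue_number=rank,
                    insertion_code="",
                    element="C",
                    position=sp.position,
                    het=True,
                )
            )
            serial += 1
    if not atoms:
        return "END\n"
    return write_pdb(MolecularStructure(atoms, source_id="site-spheres"))


def pockets_to_table(pockets: list[Pocket]) -> pd.DataFrame:
    """One row per pocket: descriptors, scores and center."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(pockets) + 1),
            "n_site_points": [p.n for p in pockets],
            "volume": [p.volume for p in pockets],
            "enclosure": [p.enclosure for p in pockets],
            "hydrophilicity": [p.hydrophilicity for p in pockets],
            "hydrophobicity": [p.hydrophobicity for p in pockets],
            "balance": [p.balance for p in pockets],
            "site_score": [p.site_score for p in pockets],
            "d_score": [p.d_score for p in pockets],
            "druggable": [p.druggable for p in pockets],
            "center_x": [p.center[0] for p in pockets],
            "center_y": [p.center[1] for p in pockets],
            "center_z": [p.center[2] for p in pockets],
        }
    )
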