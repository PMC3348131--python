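"""Pocket identity across conformers by geometric-center matching.

A catalog maps reference site labels (A–I style) to geometric centers in a
common superposed frame.  A pocket in any conformer is assigned the label of
a reference site whose center lies within the automatic cutoff (3.75 Å); if
two or more reference centers fall inside the cutoff the pocket straddles
them and gets a merged label such as ``C_E``.  Pockets whose nearest
reference center sits in the 3.75–10 Å band are flagged *ambiguous* with the
nearest label as a suggestion for human review — they are never silently
assigned.  Beyond 10 Å to every reference center, the pocket is *new*.

Persistence of a label is the fraction of conformers containing at least
one pocket assigned that label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pocket_detect import Pocket

__all__ = [
    "ReferenceSiteCatalog",
    "SiteAssignment",
    "PersistenceTable",
    "AUTO_CUTOFF",
    "NEW_CUTOFF",
    "assign_site",
    "build_catalog",
    "track_ensemble",
]

AUTO_CUTOFF = 3.75  # Å, automatic assignment radius
NEW_CUTOFF = 10.0   # Å, beyond this to every reference center → new site

NEW_LABEL = "NEW"


@dataclass
class ReferenceSiteCatalog:
    """Label → reference geometric center, in the common superposed frame."""

    entries: dict[str, tuple[float, float, float]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("catalog must contain at least one site")
        for label, c in self.entries.items():
            if not np.all(np.isfinite(c)):
                raise ValueError(f"non-finite center for site {label!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def centers(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l, *c) for l, c in self.entries.items()],
            columns=["label", "x", "y", "z"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "ReferenceSiteCatalog":
        return cls(
            {r.label: (r.x, r.y, r.z) for r in df.itertuples()}, source=source
        )


@dataclass(frozen=True)
class SiteAssignment:
    conformer_id: int
    pocket_rank: int
    label: str
    status: str  # assigned | ambiguous | new
    match_distance: float | None  # None for new

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "ambiguous", "new"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass
class PersistenceTable:
    """Per-label fraction of conformers in which the label occurs."""

    fractions: dict[str, float]
    ensemble_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.fractions.items()),
            columns=["label", "persistence"],
        )


def assign_site(
    pocket: Pocket | Sequence[float],
    catalog: ReferenceSiteCatalog,
    auto_cutoff: float = AUTO_CUTOFF,
    new_cutoff: float = NEW_CUTOFF,
    conformer_id: int = 0,
    pocket_rank: int = 0,
) -> SiteAssignment:
    """Assign one pocket (or a bare center) to a reference site label.

    Distance rules, inclusive on the lower-status side: nearest reference
    distance d ≤ ``auto_cutoff`` → assigned (merged alphabetical label when
    several centers qualify); ``auto_cutoff`` < d ≤ ``new_cutoff`` →
    ambiguous with the nearest label suggested; d > ``new_cutoff`` to every
    center → new.
    """
    center = np.asarray(getattr(pocket, "center", pocket), dtype=float)
    d = np.linalg.norm(catalog.centers() - center, axis=1)
    labels = catalog.labels
    within = np.nonzero(d <= auto_cutoff)[0]
    nearest = int(np.argmin(d))
    if len(within) >= 2:
        label = "_".join(sorted(labels[i] for i in within))
        return SiteAssignment(conformer_id, pocket_rank, label, "assigned",
                              float(d[nearest]))
    if len(within) == 1:
        return SiteAssignment(conformer_id, pocket_rank, labels[within[0]],
                              "assigned", float(d[within[0]]))
    if d[nearest] <= new_cutoff:
        return SiteAssignment(conformer_id, pocket_rank, labels[nearest],
                              "ambiguous", float(d[nearest]))
    return SiteAssignment(conformer_id, pocket_rank, NEW_LABEL, "new", None)


def build_catalog(
    labelled_pockets: Mapping[str, Pocket | Sequence[float]],
    source: str = "template",
) -> ReferenceSiteCatalog:
    """Catalog from labelled template pockets (label → geometric center)."""
    entries: dict[str, tuple[float, float, float]] = {}
    for label, pocket in labelled_pockets.items():
        if label in entries:
            raise ValueError(f"duplicate label {label!r}")
        entries[label] = tuple(
            float(x) for x in getattr(pocket, "center", pocket)
        )
    return ReferenceSiteCatalog(entries, source=source)


def track_ensemble(
    ensemble_pockets: Sequence[Sequence[Pocket]],
    catalog: ReferenceSiteCatalog,
    auto_cutoff: float = AUTO_CUTOFF,
    new_cutoff: float = NEW_CUTOFF,
    superposed: bool = True,
) -> tuple[list[SiteAssignment], PersistenceTable]:
    """Assign every pocket of every conformer and tabulate persistence.

    ``ensemble_pockets[i]`` is the ranked pocket list of conformer ``i``;
    all conformers must already be in the catalog's superposed frame.
    Persistence of a label counts conformers with at least one *assigned*
    pocket of that label; ambiguous assignments are reported but never
    counted.
    """
    if not superposed:
        raise ValueError(
            "conformers must be superposed onto the catalog frame before tracking"
        )
    assignments: list[SiteAssignment] = []
    occurrence: dict[str, set[int]] = {}
    n = len(ensemble_pockets)
    for conf_id, pockets in enumerate(ensemble_pockets):
        for rank, pocket in enumerate(pockets, start=1):
            a = assign_site(
                pocket, catalog, auto_cutoff, new_cutoff,
                conformer_id=conf_id, pocket_rank=rank,
            )
            assignments.append(a)
            if a.status == "assigned":
                occurrence.setdefault(a.label, set()).add(conf_id)
    fractions = {label: len(ids) / n for label, ids in occurrence.items()}
    for label in catalog.labels:  # report zero persistence explicitly
        fractions.setdefault(label, 0.0)
    return assignments, PersistenceTable(fractions, ensemble_size=n)


def assignments_to_frame(assignments: Sequence[SiteAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "conformer_id": [a.conformer_id for a in assignments],
            "pocket_rank": [a.pocket_rank for a in assignments],
            "label": [a.label for a in assignments],
            "status": [a.status for a in assignments],
            "distance": [a.match_distance for a in assignments],
        }
    )
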