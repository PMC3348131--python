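"""Per-site property distributions across the ensemble and docking picks.

For every tracked site label this module collects one value per conformer of
each pocket property (SiteScore, Dscore, volume, balance) — using the
conformer's best-scoring pocket when a label occurs more than once — and
summarises them as five-number (min, Q1, median, Q3, max) boxplot
statistics.  It also implements the conformer-selection rule used to pick a
receptor for rigid docking: among the conformers with the top five
SiteScores for a site, take the one whose pocket has the highest volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pocket_detect import Pocket
from .pocket_track import SiteAssignment

__all__ = [
    "PropertyDistribution",
    "DockingPick",
    "PROPERTIES",
    "property_distributions",
    "select_docking_conformer",
    "crystal_compare",
    "distributions_to_frames",
]

PROPERTIES = ("site_score", "d_score", "volume", "balance")


@dataclass
class PropertyDistribution:
    label: str
    property: str
    conformer_ids: np.ndarray
    values: np.ndarray

    @property
    def summary(self) -> tuple[float, float, float, float, float]:
        """(min, Q1, median, Q3, max) under linear-interpolation quartiles."""
        v = np.asarray(self.values, dtype=float)
        q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
        return (float(v.min()), float(q1), float(med), float(q3), float(v.max()))


@dataclass(frozen=True)
class DockingPick:
    """Receptor conformer chosen for a site: highest volume in the SiteScore top five."""

    label: str
    conformer_id: int
    site_score: float
    volume: float


def _best_pocket_per_conformer(
    label: str,
    assignments: Sequence[SiteAssignment],
    pockets: Sequence[Sequence[Pocket]],
) -> dict[int, Pocket]:
    """Highest-SiteScore pocket carrying ``label`` for each conformer."""
    best: dict[int, Pocket] = {}
    for a in assignments:
        if a.status != "assigned" or a.label != label:
            continue
        pocket = pockets[a.conformer_id][a.pocket_rank - 1]
        prev = best.get(a.conformer_id)
        if prev is None or pocket.site_score > prev.site_score:
            best[a.conformer_id] = pocket
    return best


def property_distributions(
    assignments: Sequence[SiteAssignment],
    pockets: Sequence[Sequence[Pocket]],
) -> list[PropertyDistribution]:
    """Per-label, per-property value collections with boxplot summaries."""
    labels = sorted({a.label for a in assignments if a.status == "assigned"})
    out: list[PropertyDistribution] = []
    for label in labels:
        best = _best_pocket_per_conformer(label, assignments, pockets)
        if not best:
            continue
        conf_ids = np.array(sorted(best), dtype=int)
        for prop in PROPERTIES:
            values = np.array(
                [getattr(best[c], prop if prop != "balance" else "balance")
                 for c in conf_ids],
                dtype=float,
            )
            out.append(PropertyDistribution(label, prop, conf_ids, values))
    return out


def select_docking_conformer(
    label: str,
    assignments: Sequence[SiteAssignment],
    pockets: Sequence[Sequence[Pocket]],
) -> DockingPick:
    """Pick the docking receptor conformer for a site.

    Rule: restrict to the conformers holding the top five SiteScores for the
    label (score ties at rank five admit all tied candidates), then take the
    one with the highest pocket volume; remaining ties go to the lowest
    conformer id.
    """
    best = _best_pocket_per_conformer(label, assignments, pockets)
    if not best:
        raise KeyError(f"label {label!r} not present in any conformer")
    rows = [(cid, p.site_score, p.volume) for cid, p in best.items()]
    scores = sorted((s for _, s, _ in rows), reverse=True)
    threshold = scores[min(4, len(scores) - 1)]
    candidates = [r for r in rows if r[1] >= threshold]
    cid, score, volume = min(candidates, key=lambda r: (-r[2], r[0]))
    return DockingPick(label=label, conformer_id=cid, site_score=score,
                       volume=volume)


def crystal_compare(
    reference_values: pd.DataFrame,
    distributions: Sequence[PropertyDistribution],
) -> pd.DataFrame:
    """Overlay externally supplied per-structure values on ensemble summaries.

    ``reference_values`` needs columns ``structure``, ``label``,
    ``property``, ``value``.  Each row is flagged ``within``, ``above`` or
    ``below`` the ensemble [min, max] for its (label, property); rows with a
    label/property absent from the distributions are skipped with a warning.
    """
    index = {(d.label, d.property): d for d in distributions}
    rows = []
    for r in reference_values.itertuples():
        dist = index.get((r.label, r.property))
        if dist is None:
            warnings.warn(
                f"no ensemble distribution for ({r.label!r}, {r.property!r}); "
                "row skipped",
                stacklevel=2,
            )
            continue
        lo, q1, med, q3, hi = dist.summary
        flag = "within"
        if r.value > hi:
            flag = "above"
        elif r.value < lo:
            flag = "below"
        rows.append(
            {
                "structure": r.structure,
                "label": r.label,
                "property": r.property,
                "value": r.value,
                "ensemble_min": lo,
                "ensemble_max": hi,
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure", "label", "property", "value",
            "ensemble_min", "ensemble_max", "flag",
        ],
    )


def distributions_to_frames(
    distributions: Sequence[PropertyDistribution],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(long-format values, five-number summaries) as tidy DataFrames."""
    long_rows = []
    summary_rows = []
    for d in distributions:
        for cid, v in zip(d.conformer_ids, d.values):
            long_rows.append(
                {"label": d.label, "property": d.property,
                 "conformer_id": int(cid), "value": float(v)}
            )
        lo, q1, med, q3, hi = d.summary
        summary_rows.append(
            {"label": d.label, "property": d.property, "min": lo, "q1": q1,
             "median": med, "q3": q3, "max": hi, "n": len(d.values)}
        )
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)
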