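"""Per-residue pocket-lining propensities over a conformational ensemble.

For each conformer, a residue is *pocket-lining* (score 1) when any of its
atoms lies within 3.75 Å of any predicted site sphere, else 0.  Summing the
indicator over the ensemble and dividing by the number of conformers gives
each residue a probability of bordering a predicted pocket.  The profile is
written to the B-factor column of a reference structure for visualisation,
with the first and third quartiles of the probability distribution reported
as the suggested white/red colour limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import MolecularStructure, ResidueKey, write_pdb

__all__ = [
    "LiningMask",
    "ProvarProfile",
    "LINING_CUTOFF",
    "lining_mask",
    "propensity",
    "scale_limits",
    "annotate",
]

LINING_CUTOFF = 3.75  # Å, atom-to-sphere-center threshold


@dataclass
class LiningMask:
    """0/1 pocket-lining indicator per residue of the reference structure."""

    conformer_id: int
    residues: tuple[ResidueKey, ...]
    values: np.ndarray  # uint8, aligned with residues

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.residues),):
            raise ValueError("mask length must equal residue count")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")


@dataclass
class ProvarProfile:
    """Per-residue pocket-lining probability across the ensemble."""

    residues: tuple[ResidueKey, ...]
    probabilities: np.ndarray
    ensemble_size: int
    distance_threshold: float = LINING_CUTOFF

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.residues),):
            raise ValueError("profile length must equal residue count")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def as_mapping(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residues, self.probabilities))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "residue_number": [r[1] for r in self.residues],
                "insertion_code": [r[2] for r in self.residues],
                "residue_name": [r[3] for r in self.residues],
                "probability": self.probabilities,
            }
        )


def lining_mask(
    s: MolecularStructure,
    spheres: np.ndarray,
    cutoff: float = LINING_CUTOFF,
    conformer_id: int = 0,
) -> LiningMask:
    """Flag residues with any atom within ``cutoff`` of any sphere center.

    ``spheres`` is an (m, 3) array of site-sphere positions (may be empty).
    The distance test is atom-to-sphere-center and the cutoff is inclusive.
    """
    residues = tuple(s.residues)
    values = np.zeros(len(residues), dtype=np.uint8)
    spheres = np.asarray(spheres, dtype=float).reshape(-1, 3)
    if len(spheres):
        tree = cKDTree(spheres)
        d, _ = tree.query(s.coordinates())
        res_idx = s.residue_index_per_atom()
        values[np.unique(res_idx[d <= cutoff])] = 1
    return LiningMask(conformer_id=conformer_id, residues=residues, values=values)


def propensity(masks: list[LiningMask]) -> ProvarProfile:
    """Elementwise mean of lining masks: (Σ masks) / ensemble size."""
    if not masks:
        raise ValueError("need at least one mask")
    residues = masks[0].residues
    for m in masks[1:]:
        if m.residues != residues:
            raise ValueError("masks cover different residue sets")
    stack = np.array([m.values for m in masks], dtype=float)
    return ProvarProfile(
        residues=residues,
        probabilities=stack.sum(axis=0) / len(masks),
        ensemble_size=len(masks),
    )


def scale_limits(profile: ProvarProfile) -> tuple[float, float]:
    """(Q1, Q3) of the probability distribution — the white/red colour limits.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention).
    """
    q1, q3 = np.percentile(profile.probabilities, [25.0, 75.0])
    return float(q1), float(q3)


def annotate(s: MolecularStructure, profile: ProvarProfile) -> str:
    """Write the profile into the B-factor column of ``s`` (PDB text).

    Every residue of ``s`` must be covered by the profile.
    """
    mapping = profile.as_mapping()
    missing = [r for r in s.residues if r not in mapping]
    if missing:
        raise ValueError(
            f"profile does not cover {len(missing)} residues, e.g. {missing[0]!r}"
        )
    return write_pdb(s, residue_values={r: mapping[r] for r in s.residues})
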