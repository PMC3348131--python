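"""Reading, cleaning, superposing and writing protein structures in PDB format.

The in-memory representation is a flat, ordered list of heavy-atom records
(:class:`AtomRecord`) wrapped in :class:`MolecularStructure`.  Parsing and
serialisation are delegated to :mod:`gemmi`; this module owns chain selection,
altloc resolution, heteroatom stripping, Kabsch superposition and the
B-factor-annotated write-out used for per-residue value maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "PDBError",
    "ChainNotFoundError",
    "EmptyStructureError",
    "parse_pdb",
    "parse_pdb_file",
    "strip_heteroatoms",
    "superpose",
    "write_pdb",
    "write_multi_model_pdb",
    "read_sphere_pdb",
]

#: Three-letter codes treated as standard amino acids.
STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE""".split()
)

#: Minimum number of standard residues for a chain to be auto-selected.
AUTO_CHAIN_MIN_RESIDUES = 50


class PDBError(ValueError):
    """Malformed or unusable PDB input."""


class ChainNotFoundError(PDBError):
    """The requested chain id is absent from the file."""


class EmptyStructureError(PDBError):
    """An operation produced or received a structure with no atoms."""


ResidueKey = tuple[str, int, str, str]  # (chain_id, residue_number, icode, resname)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom record of a PDB file."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.residue_name)


@dataclass
class MolecularStructure:
    """An ordered collection of atom records from a single chain.

    ``residues`` is derived: one key per residue, in order of first
    appearance in the atom list.
    """

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure must contain at least one atom")

    @property
    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_index_per_atom(self) -> np.ndarray:
        """Index into :attr:`residues` for every atom."""
        order = {k: i for i, k in enumerate(self.residues)}
        return np.array([order[a.residue_key] for a in self.atoms], dtype=int)

    def with_coordinates(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            replace(a, position=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return MolecularStructure(atoms, source_id=self.source_id)

    def select(self, atom_name: str) -> np.ndarray:
        """Indices of atoms with the given name (e.g. ``"CA"``)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name == atom_name],
            dtype=int,
        )


def _is_protein_chain(chain: gemmi.Chain) -> int:
    """Number of standard amino-acid residues in a gemmi chain."""
    return sum(1 for res in chain if res.name in STANDARD_RESIDUES)


def _pick_chain(model: gemmi.Model, chain: str | None) -> gemmi.Chain:
    if chain is not None:
        for ch in model:
            if ch.name == chain:
                return ch
        raise ChainNotFoundError(f"chain {chain!r} not found in structure")
    protein_chains = [ch for ch in model if _is_protein_chain(ch) > 0]
    if not protein_chains:
        # fall back to any chain with atoms (e.g. synthetic fixtures)
        for ch in model:
            if len(ch) > 0:
                return ch
        raise PDBError("no ATOM records found")
    for ch in protein_chains:
        if _is_protein_chain(ch) >= AUTO_CHAIN_MIN_RESIDUES:
            return ch
    return protein_chains[0]


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, first-listed tie-break."""
    best: dict[str, int] = {}
    atoms = list(res)
    for i, atom in enumerate(atoms):
        j = best.get(atom.name)
        if j is None or atom.occ > atoms[j].occ + 1e-9:
            best[atom.name] = i
    winners = sorted(best.values())  # preserve file order
    return [atoms[i] for i in winners]


def parse_pdb(text: str, chain: str | None = None,
              source_id: str = "") -> MolecularStructure:
    """Parse PDB-format text into a single-chain :class:`MolecularStructure`.

    Parameters
    ----------
    text:
        PDB-format string with at least one ATOM record.
    chain:
        Chain id to extract.  When ``None`` the first protein chain with at
        least 50 standard residues is used, falling back to the first chain
        that has any standard residue (or any atoms at all).

    Altloc duplicates are resolved to a single atom per name per residue
    (highest occupancy, ties broken by file order).
    """
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBError("no models in PDB input")
    model = st[0]
    ch = _pick_chain(model, chain)
    atoms: list[AtomRecord] = []
    for res in ch:
        het = res.het_flag == "H"
        for atom in _resolve_altlocs(res):
            atoms.append(
                AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    residue_name=res.name,
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ),
                    b_factor=float(atom.b_iso),
                    het=het,
                )
            )
    if not atoms:
        raise PDBError("selected chain contains no atoms")
    return MolecularStructure(atoms, source_id=source_id or st.name)


def parse_pdb_file(path, chain: str | None = None) -> MolecularStructure:
    with open(path) as fh:
        return parse_pdb(fh.read(), chain=chain, source_id=str(path))


def strip_heteroatoms(s: MolecularStructure) -> MolecularStructure:
    """Remove waters, ligands, other HETATM content and hydrogens.

    Only heavy atoms of standard amino-acid residues remain; all downstream
    geometry is defined on heavy atoms.
    """
    kept = [
        a
        for a in s.atoms
        if a.residue_name in STANDARD_RESIDUES
        and not a.het
        and a.element not in ("H", "D")
    ]
    if not kept:
        raise EmptyStructureError("no standard protein atoms remain after cleanup")
    return MolecularStructure(kept, source_id=s.source_id)


def _kabsch_transform(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid transform (R, t) minimising |R·m + t − r|²."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    return R, t


def superpose(
    mobile: MolecularStructure,
    reference: MolecularStructure,
    selection: str | None = "CA",
) -> tuple[MolecularStructure, float]:
    """Rigidly superpose ``mobile`` onto ``reference``.

    The least-squares fit is computed over atoms named ``selection``
    (default Cα); pass ``None`` to fit over all atoms.  Returns the
    transformed structure and the RMSD over the selection.
    """
    if selection is None:
        mi = np.arange(mobile.n_atoms)
        ri = np.arange(reference.n_atoms)
    else:
        mi = mobile.select(selection)
        ri = reference.select(selection)
    if len(mi) != len(ri):
        raise ValueError(
            f"selection size mismatch: {len(mi)} (mobile) vs {len(ri)} (reference)"
        )
    if len(mi) < 3:
        raise ValueError("superposition needs at least 3 selected atom pairs")
    mcoords = mobile.coordinates()
    rcoords = reference.coordinates()
    R, t = _kabsch_transform(mcoords[mi], rcoords[ri])
    moved = mcoords @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved[mi] - rcoords[ri]) ** 2, axis=1))))
    return mobile.with_coordinates(moved), rmsd


def _to_gemmi(s: MolecularStructure,
              residue_values: Mapping[ResidueKey, float] | None) -> gemmi.Structure:
    if residue_values is not None:
        known = set(s.residues)
        for key, value in residue_values.items():
            if key not in known:
                raise KeyError(f"residue key {key!r} not present in structure")
            if not (-999.99 <= float(value) <= 999.99):
                raise ValueError(
                    f"value {value!r} for {key!r} does not fit the B-factor field"
                )
    st = gemmi.Structure()
    st.name = s.source_id or "ensemblepockets"
    model = gemmi.Model(1)
    chain_obj: gemmi.Chain | None = None
    res_obj: gemmi.Residue | None = None
    current_key: ResidueKey | None = None
    for a in s.atoms:
        if chain_obj is None or chain_obj.name != a.chain_id:
            chain_obj = gemmi.Chain(a.chain_id)
            model.add_chain(chain_obj)
            chain_obj = model[-1]
            current_key = None
        if a.residue_key != current_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.het else "A"
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
            current_key = a.residue_key
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        b = a.b_factor
        if residue_values is not None and a.residue_key in residue_values:
            b = float(residue_values[a.residue_key])
        atom.b_iso = b
        atom.serial = a.serial
        res_obj.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(
    s: MolecularStructure,
    residue_values: Mapping[ResidueKey, float] | None = None,
) -> str:
    """Serialise to PDB format, optionally annotating B-factors.

    When ``residue_values`` maps residue keys to numbers, every atom of an
    annotated residue carries that value in its B-factor column (two
    decimals); other atoms keep their original B-factors.
    """
    st = _to_gemmi(s, residue_values)
    return st.make_pdb_string()


def write_multi_model_pdb(
    template: MolecularStructure, coordinate_sets: Iterable[np.ndarray]
) -> str:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    blocks: list[str] = []
    n = 0
    for i, coords in enumerate(coordinate_sets, start=1):
        body = write_pdb(template.with_coordinates(coords))
        lines = [
            ln
            for ln in body.splitlines()
            if ln.startswith(("ATOM", "HETATM", "TER"))
        ]
        blocks.append(f"MODEL     {i:4d}\n" + "\n".join(lines) + "\nENDMDL")
        n = i
    if n == 0:
        raise ValueError("no coordinate sets supplied")
    return "\n".join(blocks) + "\nEND\n"


def read_sphere_pdb(text: str) -> np.ndarray:
    """Read site-sphere centres from a pocket-sphere PDB file.

    Accepts this package's sphere dialect (HETATM records, residue ``SIT``)
    as well as generic HETATM-only files from external tools.  Returns an
    (n, 3) array of positions; ATOM records are used only when the file has
    no HETATM records.
    """
    st = gemmi.read_pdb_string(text)
    het: list[Sequence[float]] = []
    other: list[Sequence[float]] = []
    for model in st:
        for ch in model:
            for res in ch:
                target = het if res.het_flag == "H" else other
                for atom in res:
                    target.append((atom.pos.x, atom.pos.y, atom.pos.z))
        break
    chosen = het if het else other
    return np.array(chosen, dtype=float).reshape(-1, 3)
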