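"""Structure I/O: PDB reading/writing, atoms, residues, ligands, VdW radii.

Protein chains become a :class:`StructureModel`; HETATM groups (and short
peptide chains in templates) become candidate :class:`LigandInstance` objects.
Reading goes through gemmi; writing uses fixed-column PDB formatting so that
output is byte-deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

# ---------------------------------------------------------------------------
# Constants

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_RESNAMES = frozenset(AA3_TO_1)

#: Crystallisation additives and solvent excluded from "biologically relevant"
#: ligands by default.  User-overridable.
DEFAULT_EXCLUSION = frozenset({
    "HOH", "DOD", "GOL", "EDO", "PEG", "MPD", "PG4", "ACT", "DMS",
    "FMT", "TRS", "BME", "MES", "EPE", "SO4", "PO4", "NO3",
})

#: Protein chains no longer than this many standard residues in a *template*
#: are treated as peptide ligands rather than part of the structure.
PEPTIDE_LIGAND_MAX_LEN = 20

#: Bondi van der Waals radii (Angstrom) for common elements.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "FE": 2.05, "MN": 2.05,
    "CU": 1.40, "NI": 1.63, "CO": 2.00, "CD": 1.58, "NA": 2.27,
    "K": 2.75, "SE": 1.90,
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed or contains no protein atoms."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class VdwTable:
    """Element -> van der Waals radius (Angstrom), with a fallback default."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.70

    def radius(self, element: str) -> float:
        return self.radii.get(element.strip().upper(), self.default_radius)


def vdw_radius(element: str, table: VdwTable | None = None) -> float:
    """Van der Waals radius for *element*; unknown elements get the default."""
    return (table or VdwTable()).radius(element)


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_name: str
    residue_seq: int
    chain_id: str
    is_hetero: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates")


@dataclass
class Residue:
    seq: int
    name: str
    atoms: list[AtomRecord]
    chain_id: str = "A"
    icode: str = ""

    @property
    def key(self) -> int:
        return self.seq

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def ca(self) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.strip().upper() != "H"]


@dataclass
class StructureModel:
    """A protein model: ordered standard residues from one or more chains."""

    id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue_by_seq(self, seq: int) -> Residue | None:
        for r in self.residues:
            if r.seq == seq:
                return r
        return None

    def ca_coords(self) -> np.ndarray:
        """L x 3 array of C-alpha coordinates (NaN rows where CA is absent)."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca()
            if ca is not None:
                out[i] = ca.coords
        return out

    def centroid(self) -> np.ndarray:
        pts = np.vstack([a.coords for r in self.residues for a in r.atoms])
        return pts.mean(axis=0)


@dataclass
class LigandInstance:
    """One HETATM group (or short peptide chain) from a template."""

    ligand_id: str
    atoms: list[AtomRecord]
    resname: str
    source_template: str = ""
    ltype: str | None = None  # one of I, O, N, P once classified

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"ligand {self.ligand_id} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([a.coords for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandInstance":
        new = copy.deepcopy(self)
        for a in new.atoms:
            a.coords = rotation @ a.coords + translation
        return new

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


# ---------------------------------------------------------------------------
# Reading


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; tie -> first in file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ + 1e-9:
            best = a
    return best


def _convert_residue(res: gemmi.Residue, chain_id: str, hetero: bool) -> Residue:
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in res:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    atoms = []
    for name in order:
        a = _pick_altloc(by_name[name])
        atoms.append(AtomRecord(
            serial=a.serial,
            name=name,
            element=a.element.name.upper(),
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            residue_name=res.name,
            residue_seq=res.seqid.num,
            chain_id=chain_id,
            is_hetero=hetero,
            icode=(res.seqid.icode or "").strip(),
        ))
    return Residue(seq=res.seqid.num, name=res.name, atoms=atoms,
                   chain_id=chain_id, icode=(res.seqid.icode or "").strip())


def read_pdb(path: str | Path) -> tuple[StructureModel, list[LigandInstance]]:
    """Parse a PDB file into a protein model plus candidate ligands.

    Standard amino-acid residues on long chains form the
    :class:`StructureModel`.  Every HETATM group (waters included — filter
    later with :func:`filter_relevant_ligands`) becomes a candidate
    :class:`LigandInstance`, as does any protein chain of at most
    ``PEPTIDE_LIGAND_MAX_LEN`` standard residues (a putative peptide ligand).
    Alternate locations keep the highest-occupancy conformer (tie: first).
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    return structure_from_gemmi(st, model_id=path.stem)


def structure_from_gemmi(st: gemmi.Structure, model_id: str) -> tuple[StructureModel, list[LigandInstance]]:
    if len(st) == 0:
        raise PDBParseError(f"{model_id}: no models in file")
    model = st[0]
    protein_residues: list[Residue] = []
    ligands: list[LigandInstance] = []
    # short all-standard chains are peptide ligands only when a longer
    # protein chain exists; otherwise the longest chain IS the protein
    longest_std = max((sum(1 for r in chain if r.name in STANDARD_RESNAMES)
                       for chain in model), default=0)
    for chain in model:
        std = [r for r in chain if r.name in STANDARD_RESNAMES]
        het = [r for r in chain if r.name not in STANDARD_RESNAMES]
        is_peptide_ligand = (0 < len(std) <= PEPTIDE_LIGAND_MAX_LEN
                             and longest_std > PEPTIDE_LIGAND_MAX_LEN)
        if is_peptide_ligand:
            atoms: list[AtomRecord] = []
            for r in std:
                atoms.extend(_convert_residue(r, chain.name, hetero=True).atoms)
            first = std[0]
            ligands.append(LigandInstance(
                ligand_id=f"{model_id}:PEPTIDE:{first.seqid.num}:{chain.name}",
                atoms=atoms, resname="PEP", source_template=model_id, ltype="P"))
        else:
            protein_residues.extend(
                _convert_residue(r, chain.name, hetero=False) for r in std)
        for r in het:
            res = _convert_residue(r, chain.name, hetero=True)
            ligands.append(LigandInstance(
                ligand_id=f"{model_id}:{r.name}:{r.seqid.num}:{chain.name}",
                atoms=res.atoms, resname=r.name, source_template=model_id))
    if not protein_residues and not ligands:
        raise PDBParseError(f"{model_id}: no ATOM or HETATM records")
    if not protein_residues:
        raise PDBParseError(f"{model_id}: no protein ATOM records")
    return StructureModel(id=model_id, residues=protein_residues), ligands


# ---------------------------------------------------------------------------
# Writing


def _format_atom_line(a: AtomRecord, serial: int, record: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    icode = a.icode[:1] if a.icode else " "
    elem = a.element.strip().upper()
    elem = elem.rjust(2)[:2]
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {a.residue_name:>3s} "
        f"{a.chain_id[:1]}{a.residue_seq:>4d}{icode}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
    )


def write_pdb(model: StructureModel, ligands: Sequence[LigandInstance] | None,
              path: str | Path, ligand_chain: str = "Z") -> None:
    """Write a model (ATOM records) and optional ligands (HETATM) to *path*."""
    lines: list[str] = []
    serial = 0
    last_chain = None
    for res in model.residues:
        for a in res.atoms:
            serial += 1
            lines.append(_format_atom_line(a, serial, "ATOM"))
        last_chain = res.chain_id
    if model.residues:
        serial += 1
        lines.append(f"TER   {serial:>5d}      {model.residues[-1].name:>3s} "
                     f"{last_chain[:1]}{model.residues[-1].seq:>4d}")
    # ligand residues are renumbered on one chain so that distinct ligands
    # never collide on (chain, resseq) when the file is re-read
    lig_seq = 900
    for lig in ligands or []:
        seq_map: dict[tuple[str, int, str], int] = {}
        for a in lig.atoms:
            key = (a.chain_id, a.residue_seq, a.icode)
            if key not in seq_map:
                lig_seq += 1
                seq_map[key] = lig_seq
            serial += 1
            b = copy.copy(a)
            b.chain_id = ligand_chain
            b.residue_seq = seq_map[key]
            b.icode = ""
            lines.append(_format_atom_line(b, serial, "HETATM"))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ligand relevance filter


def filter_relevant_ligands(ligands: Iterable[LigandInstance],
                            exclusion: frozenset[str] | set[str] = DEFAULT_EXCLUSION,
                            ) -> list[LigandInstance]:
    """Drop crystallisation additives/solvent; keep order. Pure filter."""
    return [l for l in ligands if l.resname not in exclusion]
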