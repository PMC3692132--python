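"""Ligand typing (Ion / Organic / Nucleotide / Peptide) and ligand-type
propensities.

Per-residue propensity of binding each ligand type is the model-quality score
times the fraction of pocket ligands of that type in contact with the
residue; the global propensity of a pocket is the fraction of its ligands of
each type.  Both are in [0,1] and a single-type pocket gives exact zeros for
the other three types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sitepredict import ContactParams, LigandCluster, residue_contacts_ligand
from .structio import LigandInstance, Residue, STANDARD_RESNAMES

LIGAND_TYPES = ("I", "O", "N", "P")

#: single-atom metals / halides
DEFAULT_ION_RESNAMES = frozenset({
    "ZN", "MG", "CA", "MN", "FE", "NA", "K", "CL", "CU", "NI", "CO",
    "CD", "IOD", "BR", "FE2", "CU1", "MN3", "LI", "CS", "SR", "BA", "F",
})

#: nucleotides and common nucleotide cofactors
DEFAULT_NUCLEOTIDE_RESNAMES = frozenset({
    "ATP", "ADP", "AMP", "GTP", "GDP", "GMP", "ANP", "GNP", "UTP", "CTP",
    "UDP", "UMP", "CDP", "CMP", "TTP", "NAD", "NAP", "NDP", "FAD", "FMN",
    "A", "C", "G", "U", "DA", "DC", "DG", "DT",
})


@dataclass
class LigandTypeRules:
    ion_resnames: frozenset[str] = DEFAULT_ION_RESNAMES
    nucleotide_resnames: frozenset[str] = DEFAULT_NUCLEOTIDE_RESNAMES
    peptide_max_len: int = 20
    default: str = "O"


@dataclass
class PropensityRecord:
    resseq: int
    resname: str
    p_I: float = 0.0
    p_O: float = 0.0
    p_N: float = 0.0
    p_P: float = 0.0

    def get(self, t: str) -> float:
        return getattr(self, f"p_{t}")


def classify_ligand(lig: LigandInstance,
                    rules: LigandTypeRules | None = None) -> str:
    """Assign one of I, O, N, P.  The categories are exhaustive: anything not
    an ion, nucleotide or standard-amino-acid peptide is Organic."""
    rules = rules or LigandTypeRules()
    if lig.ltype == "P":  # peptide chains are flagged at parse time
        return "P"
    if lig.resname in rules.ion_resnames:
        return "I"
    if lig.resname in rules.nucleotide_resnames:
        return "N"
    resnames = {a.residue_name for a in lig.atoms}
    if resnames and resnames <= STANDARD_RESNAMES:
        n_res = len({(a.chain_id, a.residue_seq) for a in lig.atoms})
        if n_res <= rules.peptide_max_len:
            return "P"
    return rules.default


def classify_all(ligands: list[LigandInstance],
                 rules: LigandTypeRules | None = None) -> list[LigandInstance]:
    for lig in ligands:
        lig.ltype = classify_ligand(lig, rules)
    return ligands


def global_propensities(pocket: LigandCluster | None) -> dict[str, float]:
    """Fraction of pocket ligands of each type; zeros for an empty pocket."""
    if pocket is None or pocket.size == 0:
        return {t: 0.0 for t in LIGAND_TYPES}
    counts = pocket.type_counts
    n = pocket.size
    return {t: counts[t] / n for t in LIGAND_TYPES}


def residue_propensities(residues: list[Residue], pocket: LigandCluster | None,
                         model_quality: float,
                         p: ContactParams | None = None,
                         ) -> list[PropensityRecord]:
    """Per-residue propensity p_t(r) = quality * (#type-t ligands touching r)/N."""
    if pocket is None or pocket.size == 0:
        return []
    p = p or ContactParams()
    q = min(max(model_quality, 0.0), 1.0)
    out = []
    for res in residues:
        counts = {t: 0 for t in LIGAND_TYPES}
        for lig in pocket.members:
            if residue_contacts_ligand(res, lig, p):
                counts[lig.ltype or "O"] += 1
        rec = PropensityRecord(resseq=res.seq, resname=res.name)
        for t in LIGAND_TYPES:
            setattr(rec, f"p_{t}",
                    min(1.0, q * counts[t] / pocket.size))
        out.append(rec)
    return out
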