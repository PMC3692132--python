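"""Result serialisation: CASP-FN-style and CAMEO-LB-style text outputs, an
annotated PDB with the transferred pocket ligands, and a JSON manifest.

The exact community grammars are not pinned down here; this module defines a
fixed dialect of each format and guarantees its own round-trip: residue sets
and propensities are recovered exactly from the machine-readable files and
ligand coordinates to 3 decimals from the PDB writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ligtype import LIGAND_TYPES, PropensityRecord
from .sitepredict import LigandCluster, SitePrediction
from .siteqa import QualityEstimate
from .structio import StructureModel, write_pdb

#: lowercase full amino-acid names used in the per-residue display lines
AA_FULL_NAMES = {
    "ALA": "alanine", "ARG": "arginine", "ASN": "asparagine",
    "ASP": "aspartic acid", "CYS": "cysteine", "GLN": "glutamine",
    "GLU": "glutamic acid", "GLY": "glycine", "HIS": "histidine",
    "ILE": "isoleucine", "LEU": "leucine", "LYS": "lysine",
    "MET": "methionine", "PHE": "phenylalanine", "PRO": "proline",
    "SER": "serine", "THR": "threonine", "TRP": "tryptophan",
    "TYR": "tyrosine", "VAL": "valine",
}


@dataclass
class ResultBundle:
    target_id: str
    prediction: SitePrediction
    quality: QualityEstimate | None = None
    propensities: list[PropensityRecord] = field(default_factory=list)
    global_propensities: dict[str, float] = field(default_factory=dict)
    status: str = "ok"

    def __post_init__(self) -> None:
        if (self.status == "ok") != (not self.prediction.is_empty):
            raise ValueError("status 'ok' requires a non-empty prediction "
                             "and vice versa")


# ---------------------------------------------------------------------------
# CASP-FN dialect


def write_casp_fn(bundle: ResultBundle, path: str | Path) -> None:
    """Header, one site block (ligand codes + ascending residue numbers), END."""
    lines = ["PFRMAT FN", f"TARGET {bundle.target_id}", "MODEL 1"]
    if bundle.prediction.is_empty:
        lines.append(f"REMARK no prediction ({bundle.status})")
    else:
        resnames = sorted(bundle.prediction.ligand_resnames_with_counts)
        lines.append("SITE 1 " + " ".join(resnames))
        lines.append("RES " + " ".join(
            str(s) for s in sorted(bundle.prediction.residue_seqs)))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_casp_fn(path: str | Path) -> tuple[str, list[str], list[int]]:
    """Return (target id, ligand codes, residue numbers) from the dialect."""
    target, ligands, residues = "", [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("TARGET "):
            target = line.split(None, 1)[1]
        elif line.startswith("SITE "):
            ligands = line.split()[2:]
        elif line.startswith("RES "):
            residues = [int(x) for x in line.split()[1:]]
    return target, ligands, residues


# ---------------------------------------------------------------------------
# CAMEO-LB dialect


def _display_value(v: float) -> str:
    # zeros are rendered as 000 in the human-readable file
    return "000" if v == 0 else f"{v:.3f}"


def write_cameo_lb(bundle: ResultBundle, path: str | Path) -> Path:
    """Human-readable per-residue propensity lines plus a tab-separated twin
    (written next to *path* with a .tsv suffix) that round-trips exactly.

    Display line shape:
    ``r = histidine (HIS); n = 277; | I = 0.212; O = 000; N = 000; P = 000``
    """
    path = Path(path)
    lines = []
    for rec in bundle.propensities:
        full = AA_FULL_NAMES.get(rec.resname, rec.resname.lower())
        props = "; ".join(f"{t} = {_display_value(rec.get(t))}"
                          for t in LIGAND_TYPES)
        lines.append(f"r = {full} ({rec.resname}); n = {rec.resseq}; | {props}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))

    tsv_path = path.with_suffix(path.suffix + ".tsv")
    rows = ["resname\tresseq\tp_I\tp_O\tp_N\tp_P"]
    for rec in bundle.propensities:
        rows.append("\t".join([rec.resname, str(rec.resseq)] +
                              [repr(rec.get(t)) for t in LIGAND_TYPES]))
    tsv_path.write_text("\n".join(rows) + "\n")
    return tsv_path


def read_cameo_tsv(path: str | Path) -> list[PropensityRecord]:
    out = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        resname, resseq, pi, po, pn, pp = line.split("\t")
        out.append(PropensityRecord(
            resseq=int(resseq), resname=resname, p_I=float(pi),
            p_O=float(po), p_N=float(pn), p_P=float(pp)))
    return out


# ---------------------------------------------------------------------------
# Annotated PDB and manifest


def write_annotated_pdb(model: StructureModel, pocket: LigandCluster | None,
                        path: str | Path) -> None:
    """Model ATOM records followed by the pocket ligands as HETATM on their
    own chain."""
    write_pdb(model, pocket.members if pocket else [], path, ligand_chain="Z")


def write_manifest(bundle: ResultBundle, path: str | Path) -> None:
    pred = bundle.prediction
    blob = {
        "target_id": bundle.target_id,
        "status": bundle.status,
        "low_confidence": pred.low_confidence,
        "residues": [[r.seq, r.name] for r in pred.residues],
        "ligand_resnames_with_counts": pred.ligand_resnames_with_counts,
        "all_clusters": [
            {"size": c.size, "type_counts": c.type_counts,
             "resname_counts": c.resname_counts}
            for c in pred.all_clusters
        ],
        "global_propensities": bundle.global_propensities,
        "propensities": [
            {"resseq": p.resseq, "resname": p.resname,
             **{f"p_{t}": p.get(t) for t in LIGAND_TYPES}}
            for p in bundle.propensities
        ],
    }
    if bundle.quality is not None:
        blob["predicted_mcc"] = bundle.quality.predicted_mcc
        blob["predicted_bdt"] = bundle.quality.predicted_bdt
        blob["features"] = {
            n: getattr(bundle.quality.features, n)
            for n in ("bdtalign", "identity", "blosum_rescaled", "erld",
                      "model_quality")
        }
    Path(path).write_text(json.dumps(blob, indent=1, sort_keys=True) + "\n")
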