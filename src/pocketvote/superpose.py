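"""Rigid superposition of templates onto a target model.

The correspondence between model and template residues comes from a global
sequence alignment (BLOSUM62, affine gaps) unless the caller supplies one.
The superposition itself is an iterative Kabsch fit with distance-based pair
rejection (cutoff annealed 8 -> 4 Angstrom), and each template is scored with
the standard length-normalised TM-score.  Templates with TM-score >= 0.4 pass
the gate; the threshold marks the empirical transition from unrelated to
significantly related folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structio import LigandInstance, StructureModel

logger = logging.getLogger("pocketvote")

TM_THRESHOLD_DEFAULT = 0.4
REJECT_CUTOFF_START = 8.0  # Angstrom
REJECT_CUTOFF_END = 4.0
MAX_ITERATIONS = 10


class SuperpositionError(ValueError):
    """Raised when a rigid fit cannot be computed (too few point pairs)."""


@dataclass
class Correspondence:
    """Monotone residue-number pairing between model and template chains."""

    pairs: list[tuple[int, int]]
    source: str = "sequence-alignment"

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("correspondence pairs must be strictly "
                                 "increasing in both columns")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperposedTemplate:
    template_id: str
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # (3,)
    tm_score: float
    rmsd: float
    correspondence: Correspondence
    ligands: list[LigandInstance]
    template: StructureModel | None = None  # residues in model frame


# ---------------------------------------------------------------------------
# Kabsch


def kabsch(model_pts: np.ndarray, template_pts: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation mapping template onto model.

    Returns ``(R, t, rmsd)`` minimising ``||model - (R @ template + t)||``
    over rigid transforms.  Degenerate (collinear) point sets are flagged via
    the logger but a fit is still returned.
    """
    P = np.asarray(model_pts, dtype=float)
    Q = np.asarray(template_pts, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must both be N x 3")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9:
        logger.debug("kabsch: near-collinear point set (singular values %s)", S)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Sequence alignment -> correspondence

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
        _ALIGNER = al
    return _ALIGNER


def align_sequences(model: StructureModel, template: StructureModel) -> Correspondence:
    """Global BLOSUM62 alignment; aligned non-gap columns become residue pairs."""
    seq_m, seq_t = model.sequence, template.sequence
    if not seq_m or not seq_t:
        raise ValueError("cannot align an empty sequence")
    # BLOSUM62 has no 'X' column issues in Biopython (X is in the alphabet)
    aln = _aligner().align(seq_m, seq_t)[0]
    pairs: list[tuple[int, int]] = []
    for (ms, me), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(ms, me), range(ts, te)):
            pairs.append((model.residues[i].seq, template.residues[j].seq))
    return Correspondence(pairs=pairs, source="sequence-alignment")


def read_correspondence(path: str | Path) -> Correspondence:
    """Read a two-column residue-number pairing; '#' starts a comment."""
    pairs = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 2:
            raise ValueError(f"{path}:{ln}: expected two residue numbers")
        pairs.append((int(cols[0]), int(cols[1])))
    return Correspondence(pairs=pairs, source="user-supplied")


# ---------------------------------------------------------------------------
# TM-score


def tm_d0(l_target: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 Angstrom."""
    if l_target > 15:
        return max(0.5, 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8)
    return 0.5


def tm_score(corr_distances: Sequence[float], l_target: int) -> float:
    """TM = (1/L) * sum_i 1/(1 + (d_i/d0)^2), normalised by target length."""
    d = np.asarray(corr_distances, dtype=float)
    if d.size == 0 or l_target <= 0:
        return 0.0
    d0 = tm_d0(l_target)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


# ---------------------------------------------------------------------------
# Iterative superposition


def _ca_map(s: StructureModel) -> dict[int, np.ndarray]:
    out = {}
    for r in s.residues:
        ca = r.ca()
        if ca is not None:
            out[r.seq] = ca.coords
    return out


def iterative_superpose(model: StructureModel, template: StructureModel,
                        corr: Correspondence | None = None,
                        ligands: Sequence[LigandInstance] = (),
                        ) -> SuperposedTemplate:
    """Superpose *template* onto *model* by iterative Kabsch with rejection.

    Alternates a Kabsch fit on the current pair set with rejection of pairs
    whose C-alpha distance exceeds a cutoff annealed from 8 to 4 Angstrom,
    for at most 10 iterations or until the pair set is stable.  The final
    TM-score is computed over all correspondence pairs, normalised by the
    model length.  Template ligand coordinates are transformed into the model
    frame.
    """
    if corr is None:
        corr = align_sequences(model, template)
    ca_m, ca_t = _ca_map(model), _ca_map(template)
    all_pairs = [(a, b) for a, b in corr.pairs if a in ca_m and b in ca_t]
    if len(all_pairs) < 3:
        raise SuperpositionError(
            f"{template.id}: fewer than 3 usable correspondence pairs")
    P_all = np.array([ca_m[a] for a, _ in all_pairs])
    Q_all = np.array([ca_t[b] for _, b in all_pairs])

    active = np.ones(len(all_pairs), dtype=bool)
    R = np.eye(3)
    t = np.zeros(3)
    rmsd = 0.0
    for it in range(MAX_ITERATIONS):
        cutoff = REJECT_CUTOFF_START + (REJECT_CUTOFF_END - REJECT_CUTOFF_START) \
            * it / (MAX_ITERATIONS - 1)
        R, t, rmsd = kabsch(P_all[active], Q_all[active])
        d = np.linalg.norm(P_all - (Q_all @ R.T + t), axis=1)
        new_active = d <= cutoff
        if new_active.sum() < 3:
            raise SuperpositionError(
                f"{template.id}: superposition collapsed below 3 pairs")
        if np.array_equal(new_active, active) and cutoff <= REJECT_CUTOFF_END:
            break
        active = new_active

    d_final = np.linalg.norm(P_all - (Q_all @ R.T + t), axis=1)
    tm = tm_score(d_final, model.length)
    moved = [lig.transformed(R, t) for lig in ligands]

    import copy as _copy
    tmpl_moved = _copy.deepcopy(template)
    for res in tmpl_moved.residues:
        for a in res.atoms:
            a.coords = R @ a.coords + t

    logger.info("superpose %s: TM=%.3f rmsd=%.2f pairs=%d/%d",
                template.id, tm, rmsd, int(active.sum()), len(all_pairs))
    return SuperposedTemplate(
        template_id=template.id, rotation=R, translation=t, tm_score=tm,
        rmsd=rmsd, correspondence=Correspondence(all_pairs, corr.source),
        ligands=moved, template=tmpl_moved)


def gate_templates(superposed: Sequence[SuperposedTemplate],
                   threshold: float = TM_THRESHOLD_DEFAULT,
                   ) -> list[SuperposedTemplate]:
    """Keep templates with TM-score >= threshold (boundary inclusive)."""
    kept = [s for s in superposed if s.tm_score >= threshold]
    for s in superposed:
        logger.info("gate %s: TM=%.3f %s", s.template_id, s.tm_score,
                    "kept" if s.tm_score >= threshold else "rejected")
    return kept
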