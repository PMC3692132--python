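"""Binding-site prediction core: pool superposed ligands, cluster them into
continuous contacting masses, select the largest cluster as the pocket, and
call binding residues by the residue-voting rule.

Two atoms are in contact when their distance is at most the sum of their van
der Waals radii plus a tolerance (default 0.5 Angstrom).  Ligand clusters are
the connected components of the ligand contact graph (single-linkage
agglomeration halted at the contact threshold).  A residue is voted into the
site when it contacts at least 2 ligands and at least 25% of the ligands in
the selected cluster.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .structio import (AtomRecord, LigandInstance, Residue, StructureModel,
                       VdwTable, filter_relevant_ligands, DEFAULT_EXCLUSION)
from .superpose import SuperposedTemplate

logger = logging.getLogger("pocketvote")

VOTE_FRACTION = 0.25
MIN_LIGAND_VOTES = 2


@dataclass
class ContactParams:
    """Contact criterion: d <= r_vdw(a) + r_vdw(b) + tolerance.

    ``sum_radii=False`` switches to the single-radius reading
    (d <= r_vdw(a) + tolerance).
    """

    tolerance: float = 0.5
    vdw: VdwTable = field(default_factory=VdwTable)
    sum_radii: bool = True

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    def threshold(self, elem_a: str, elem_b: str) -> float:
        ra = self.vdw.radius(elem_a)
        if self.sum_radii:
            return ra + self.vdw.radius(elem_b) + self.tolerance
        return ra + self.tolerance


@dataclass
class LigandCluster:
    members: list[LigandInstance]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def type_counts(self) -> dict[str, int]:
        counts = {"I": 0, "O": 0, "N": 0, "P": 0}
        for lig in self.members:
            counts[lig.ltype or "O"] += 1
        return counts

    @property
    def resname_counts(self) -> dict[str, int]:
        return dict(Counter(l.resname for l in self.members))

    def all_coords(self) -> np.ndarray:
        return np.vstack([l.coords for l in self.members])

    def centroid(self) -> np.ndarray:
        return np.vstack([l.centroid() for l in self.members]).mean(axis=0)


@dataclass
class SitePrediction:
    residues: list[Residue]            # sorted by residue number
    pocket: LigandCluster | None
    all_clusters: list[LigandCluster]
    status: str = "ok"                 # ok | no-template | no-ligand-cluster
    low_confidence: bool = False       # singleton-pocket degraded rule

    @property
    def residue_seqs(self) -> list[int]:
        return [r.seq for r in self.residues]

    @property
    def ligand_resnames_with_counts(self) -> dict[str, int]:
        return self.pocket.resname_counts if self.pocket else {}

    @property
    def is_empty(self) -> bool:
        return not self.residues


def empty_prediction(status: str) -> SitePrediction:
    return SitePrediction(residues=[], pocket=None, all_clusters=[],
                          status=status)


# ---------------------------------------------------------------------------
# Contacts


def atoms_in_contact(a: AtomRecord, b: AtomRecord, p: ContactParams) -> bool:
    d = float(np.linalg.norm(a.coords - b.coords))
    return d <= p.threshold(a.element, b.element)


def _atom_arrays(atoms: Sequence[AtomRecord], p: ContactParams,
                 ) -> tuple[np.ndarray, np.ndarray]:
    xyz = np.vstack([a.coords for a in atoms])
    radii = np.array([p.vdw.radius(a.element) for a in atoms])
    return xyz, radii


def _any_contact(atoms1: Sequence[AtomRecord], atoms2: Sequence[AtomRecord],
                 p: ContactParams) -> bool:
    xyz1, r1 = _atom_arrays(atoms1, p)
    xyz2, r2 = _atom_arrays(atoms2, p)
    d = cdist(xyz1, xyz2)
    if p.sum_radii:
        thr = r1[:, None] + r2[None, :] + p.tolerance
    else:
        thr = r1[:, None] + p.tolerance
    return bool(np.any(d <= thr))


def ligands_in_contact(l1: LigandInstance, l2: LigandInstance,
                       p: ContactParams) -> bool:
    """True iff any atom pair across the two ligands is in contact."""
    return _any_contact(l1.atoms, l2.atoms, p)


def residue_contacts_ligand(res: Residue, lig: LigandInstance,
                            p: ContactParams) -> bool:
    """Heavy atoms of the residue (backbone + side chain) vs ligand atoms."""
    heavy = res.heavy_atoms()
    if not heavy:
        return False
    return _any_contact(heavy, lig.atoms, p)


# ---------------------------------------------------------------------------
# Clustering


def cluster_ligands(ligands: Sequence[LigandInstance], p: ContactParams,
                    ) -> list[LigandCluster]:
    """Partition ligands into continuous contacting masses.

    Single-linkage agglomeration halted at the contact threshold equals the
    connected components of the pairwise contact graph.  Clusters are sorted
    by size descending (ties keep first-member input order).
    """
    ligands = list(ligands)
    n = len(ligands)
    if n == 0:
        return []
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if ligands_in_contact(ligands[i], ligands[j], p):
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [LigandCluster(members=[ligands[i] for i in range(n)
                                       if labels[i] == c])
                for c in range(n_comp)]
    order = sorted(range(n_comp),
                   key=lambda c: (-clusters[c].size,
                                  min(i for i in range(n) if labels[i] == c)))
    return [clusters[c] for c in order]


def vote_threshold(n_ligands: int, fraction: float = VOTE_FRACTION,
                   min_votes: int = MIN_LIGAND_VOTES) -> int:
    """Votes needed: max(2, ceil(0.25 N)); a singleton pocket needs 1."""
    if n_ligands <= 1:
        return 1
    return max(min_votes, math.ceil(fraction * n_ligands))


def vote_residues(model: StructureModel, pocket: LigandCluster,
                  p: ContactParams, fraction: float = VOTE_FRACTION,
                  min_votes: int = MIN_LIGAND_VOTES) -> list[Residue]:
    """Residues contacting >= max(2, ceil(0.25 N)) pocket ligands, by number."""
    need = vote_threshold(pocket.size, fraction, min_votes)
    out = []
    for res in model.residues:
        votes = sum(1 for lig in pocket.members
                    if residue_contacts_ligand(res, lig, p))
        if votes >= need:
            out.append(res)
        if votes:
            logger.debug("vote %s%d: %d/%d (need %d)", res.name, res.seq,
                         votes, pocket.size, need)
    return sorted(out, key=lambda r: (r.chain_id, r.seq, r.icode))


def select_pocket(clusters: Sequence[LigandCluster], model: StructureModel,
                  p: ContactParams) -> LigandCluster | None:
    """Largest cluster wins; ties broken by more voting residues, then
    smaller mean ligand-to-model-centroid distance, then input order."""
    clusters = list(clusters)
    if not clusters:
        return None
    best_size = max(c.size for c in clusters)
    tied = [c for c in clusters if c.size == best_size]
    if len(tied) == 1:
        return tied[0]
    centroid = model.centroid()

    def keys(c: LigandCluster) -> tuple[int, float]:
        n_vote = len(vote_residues(model, c, p))
        mean_d = float(np.mean(np.linalg.norm(
            np.vstack([l.centroid() for l in c.members]) - centroid, axis=1)))
        return n_vote, mean_d

    best = tied[0]
    bk = keys(best)
    for c in tied[1:]:
        ck = keys(c)
        if ck[0] > bk[0] or (ck[0] == bk[0] and ck[1] < bk[1] - 1e-12):
            best, bk = c, ck
    return best


def predict_site(model: StructureModel,
                 templates: Sequence[SuperposedTemplate],
                 p: ContactParams | None = None,
                 exclusion: frozenset[str] | set[str] = DEFAULT_EXCLUSION,
                 fraction: float = VOTE_FRACTION,
                 min_votes: int = MIN_LIGAND_VOTES) -> SitePrediction:
    """Full site call: pool ligands -> filter -> cluster -> select -> vote."""
    p = p or ContactParams()
    if not templates:
        return empty_prediction("no-template")
    pooled: list[LigandInstance] = []
    for t in templates:
        pooled.extend(t.ligands)
    relevant = filter_relevant_ligands(pooled, exclusion)
    if not relevant:
        return empty_prediction("no-ligand-cluster")
    clusters = cluster_ligands(relevant, p)
    pocket = select_pocket(clusters, model, p)
    if pocket is None:
        return empty_prediction("no-ligand-cluster")
    residues = vote_residues(model, pocket, p, fraction, min_votes)
    pred = SitePrediction(residues=residues, pocket=pocket,
                          all_clusters=clusters, status="ok",
                          low_confidence=pocket.size == 1)
    if not residues:
        pred.status = "no-ligand-cluster"
    logger.info("site: pocket N=%d of %d clusters, %d residues voted",
                pocket.size, len(clusters), len(residues))
    return pred
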