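"""Synthetic structures with planted ligand pockets.

Generates idealized helical protein models, noisy/mutated/rigidly-moved
template copies carrying ligands at a planted pocket (or at a decoy site),
and labelled corpora for training the quality regressor — so the whole
pipeline is testable without any external structure database.

Geometry is idealized (a regular alpha-helical C-alpha trace with sketched
backbone atoms, no physics): every downstream criterion in the pipeline is
purely distance-based, so distances are all that must be realistic.

Random streams: one root seed per scenario, split into named substreams
(residue names, template plan, per-template noise, corpus example draws) via
``numpy.random.SeedSequence.spawn`` in a fixed documented order, so each
product is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ligtype import classify_all
from .sitepredict import (ContactParams, cluster_ligands, select_pocket,
                          vote_residues)
from .structio import (AA1_TO_3, AA3_TO_1, AtomRecord, LigandInstance,
                       Residue, StructureModel)

HELIX_RADIUS = 2.3       # Angstrom
HELIX_RISE = 1.5         # Angstrom per residue
HELIX_TWIST = 100.0      # degrees per residue
LIGAND_SITE_CA_DIST = 3.3  # target min distance ligand-site -> anchor CAs

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic model/template set."""

    seed: int = 0
    chain_length: int = 60
    pocket_residues: frozenset[int] = frozenset({10, 13, 14})
    n_templates: int = 8
    coord_noise_sigma: float = 0.0      # template coordinate noise, Angstrom
    mutation_rate: float = 0.0          # per-residue substitution probability
    ligand_type_mix: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "O": 0.0, "N": 0.0, "P": 0.0})
    decoy_fraction: float = 0.0         # templates with ligands at a wrong site

    def __post_init__(self) -> None:
        if self.chain_length < 20:
            raise ValueError("chain_length must be >= 20")
        total = sum(self.ligand_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ligand_type_mix proportions must sum to 1")
        if not set(self.pocket_residues) <= set(range(1, self.chain_length + 1)):
            raise ValueError("pocket_residues must lie within the chain")

    def streams(self) -> dict[str, np.random.Generator]:
        # fixed spawn order: names, plan, templates, corpus
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(4)
        keys = ("names", "plan", "templates", "corpus")
        return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


# ---------------------------------------------------------------------------
# Model generation


def _helix_ca(length: int) -> np.ndarray:
    i = np.arange(length)
    ang = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack([HELIX_RADIUS * np.cos(ang),
                            HELIX_RADIUS * np.sin(ang),
                            HELIX_RISE * i])


def make_model(scenario: SyntheticScenario) -> StructureModel:
    """Idealized helical model with N/CA/C/O backbone atoms.

    Deterministic in the scenario seed; consecutive and wrap-around C-alpha
    distances all exceed 3.5 Angstrom by construction.
    """
    rng = scenario.streams()["names"]
    L = scenario.chain_length
    ca = _helix_ca(L)
    letters = rng.choice(list(AA_LETTERS), size=L)
    residues: list[Residue] = []
    serial = 0
    for i in range(L):
        name3 = AA1_TO_3[letters[i]]
        prev_dir = _unit(ca[i - 1] - ca[i]) if i > 0 else _unit(ca[i] - ca[i + 1])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < L - 1 else _unit(ca[i] - ca[i - 1])
        radial = _unit(np.array([ca[i, 0], ca[i, 1], 0.0]))
        positions = {
            "N": ca[i] + 1.45 * prev_dir,
            "CA": ca[i],
            "C": ca[i] + 1.52 * next_dir,
            "O": ca[i] + 1.52 * next_dir + 1.23 * radial,
        }
        atoms = []
        for aname, pos in positions.items():
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=aname,
                element="N" if aname == "N" else ("O" if aname == "O" else "C"),
                coords=pos, residue_name=name3, residue_seq=i + 1,
                chain_id="A"))
        residues.append(Residue(seq=i + 1, name=name3, atoms=atoms))
    return StructureModel(id=f"synth{scenario.seed}", residues=residues)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def ligand_site_point(model: StructureModel, anchors: Sequence[int]) -> np.ndarray:
    """A point outside the helix surface near the anchor residues, placed so
    the closest anchor C-alpha sits at contact range."""
    cas = np.vstack([model.residue_by_seq(a).ca().coords for a in sorted(anchors)])
    centroid = cas.mean(axis=0)
    outward = _unit(np.array([centroid[0], centroid[1], 0.0]))
    best, best_err = centroid, np.inf
    for s in np.arange(0.0, 8.0, 0.05):
        p = centroid + s * outward
        err = abs(np.linalg.norm(cas - p, axis=1).min() - LIGAND_SITE_CA_DIST)
        if err < best_err:
            best, best_err = p, err
    return best


def decoy_site_residues(scenario: SyntheticScenario) -> frozenset[int]:
    L = scenario.chain_length
    return frozenset({L - 10, L - 7, L - 6})


# ---------------------------------------------------------------------------
# Ligand prototypes

_LIGAND_BLUEPRINTS = {
    "I": ("ZN", [("ZN", "ZN", np.zeros(3))]),
    "O": ("LIG", [("C1", "C", np.array([0.0, 0.0, 0.0])),
                  ("C2", "C", np.array([1.4, 0.0, 0.0])),
                  ("C3", "C", np.array([0.7, 1.2, 0.0]))]),
    "N": ("ATP", [("PA", "P", np.array([0.0, 0.0, 0.0])),
                  ("O1A", "O", np.array([1.5, 0.0, 0.0])),
                  ("C5'", "C", np.array([0.0, 1.5, 0.0])),
                  ("N9", "N", np.array([0.8, 0.8, 1.0]))]),
    "P": ("PEP", [("CA", "C", np.array([0.0, 0.0, 0.0])),
                  ("CA", "C", np.array([3.8, 0.0, 0.0]))]),
}


def _prototype_ligand(ltype: str, site: np.ndarray, template_id: str,
                      index: int) -> LigandInstance:
    resname, atoms_spec = _LIGAND_BLUEPRINTS[ltype]
    atoms = []
    for k, (aname, elem, offset) in enumerate(atoms_spec):
        atoms.append(AtomRecord(
            serial=k + 1, name=aname, element=elem, coords=site + offset,
            residue_name="GLY" if ltype == "P" else resname,
            residue_seq=900 + index * 10 + (k if ltype == "P" else 0),
            chain_id="Z", is_hetero=True))
    lig = LigandInstance(
        ligand_id=f"{template_id}:{resname}:{900 + index * 10}:Z",
        atoms=atoms, resname=resname, source_template=template_id,
        ltype=ltype)
    return lig


# ---------------------------------------------------------------------------
# Template plan and generation


def _template_plan(scenario: SyntheticScenario) -> list[tuple[str, bool]]:
    """Per-template (ligand type, is_decoy), from the 'plan' substream."""
    rng = scenario.streams()["plan"]
    types = list(scenario.ligand_type_mix)
    probs = np.array([scenario.ligand_type_mix[t] for t in types])
    n = scenario.n_templates
    chosen = rng.choice(types, size=n, p=probs) if n else []
    n_decoy = int(round(scenario.decoy_fraction * n))
    decoy_idx = set(rng.choice(n, size=n_decoy, replace=False)) if n_decoy else set()
    return [(str(chosen[i]), i in decoy_idx) for i in range(n)]


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # uniform rotation via QR of a Gaussian matrix, forced proper
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Q, t


def make_templates(scenario: SyntheticScenario, model: StructureModel,
                   ) -> list[tuple[StructureModel, list[LigandInstance]]]:
    """Noisy, mutated, rigidly moved copies of *model* carrying one planted
    ligand each (decoy templates carry theirs at a distant surface site)."""
    rng = scenario.streams()["templates"]
    plan = _template_plan(scenario)
    site_true = ligand_site_point(model, scenario.pocket_residues)
    site_decoy = ligand_site_point(model, decoy_site_residues(scenario))
    out = []
    for i, (ltype, is_decoy) in enumerate(plan):
        tid = f"tmpl{scenario.seed}_{i:02d}"
        R, t = _random_rigid(rng)
        sigma = scenario.coord_noise_sigma
        residues = []
        serial = 0
        for res in model.residues:
            name = res.name
            if scenario.mutation_rate > 0 and rng.random() < scenario.mutation_rate:
                choices = [a for a in AA_LETTERS if a != AA3_TO_1[res.name]]
                name = AA1_TO_3[rng.choice(choices)]
            atoms = []
            for a in res.atoms:
                serial += 1
                noisy = a.coords + rng.normal(scale=sigma, size=3) if sigma else a.coords
                atoms.append(AtomRecord(
                    serial=serial, name=a.name, element=a.element,
                    coords=R @ noisy + t, residue_name=name,
                    residue_seq=res.seq, chain_id="A"))
            residues.append(Residue(seq=res.seq, name=name, atoms=atoms))
        tmpl = StructureModel(id=tid, residues=residues)
        site = site_decoy if is_decoy else site_true
        lig = _prototype_ligand(ltype, site, tid, i)
        for a in lig.atoms:
            noisy = a.coords + rng.normal(scale=sigma, size=3) if sigma else a.coords
            a.coords = R @ noisy + t
        out.append((tmpl, [lig]))
    return out


# ---------------------------------------------------------------------------
# Ground truth


def planted_truth(scenario: SyntheticScenario, model: StructureModel,
                  params: ContactParams | None = None) -> list[int]:
    """The planted binding-site residues: the voting rule applied to the
    noiseless prototype ligands in the model frame (what a perfect pipeline
    run recovers at sigma = 0 with no decoys)."""
    params = params or ContactParams()
    plan = _template_plan(scenario)
    site_true = ligand_site_point(model, scenario.pocket_residues)
    ligs = [
        _prototype_ligand(ltype, site_true, f"truth_{i:02d}", i)
        for i, (ltype, is_decoy) in enumerate(plan) if not is_decoy
    ]
    if not ligs:
        return []
    classify_all(ligs)
    clusters = cluster_ligands(ligs, params)
    pocket = select_pocket(clusters, model, params)
    if pocket is None:
        return []
    return sorted(r.seq for r in vote_residues(model, pocket, params))


def degrade_model(model: StructureModel, sigma: float,
                  rng: np.random.Generator) -> StructureModel:
    """Add isotropic Gaussian coordinate noise to every atom."""
    import copy
    out = copy.deepcopy(model)
    out.id = f"{model.id}_s{sigma:g}"
    for res in out.residues:
        for a in res.atoms:
            a.coords = a.coords + rng.normal(scale=sigma, size=3)
    return out


def model_quality_score(degraded: StructureModel, reference: StructureModel) -> float:
    """Global quality of a degraded model: TM-score of its C-alpha trace
    against the reference under the identity residue mapping."""
    from .superpose import kabsch, tm_score
    ca_d = degraded.ca_coords()
    ca_r = reference.ca_coords()
    R, t, _ = kabsch(ca_r, ca_d)
    d = np.linalg.norm(ca_r - (ca_d @ R.T + t), axis=1)
    return tm_score(d, reference.length)


# ---------------------------------------------------------------------------
# QA training corpus

CORPUS_MODEL_SIGMAS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
CORPUS_TEMPLATE_SIGMAS = (0.0, 0.5, 1.0, 2.0, 3.0)
CORPUS_MUTATION_RATES = (0.0, 0.1, 0.2, 0.4)


def make_qa_corpus(scenario: SyntheticScenario, n_examples: int,
                   ) -> list[tuple["QAFeatureVector", float, float]]:
    """Labelled QA training rows: run the pipeline across graded model noise,
    template noise and mutation rates; features + true MCC/BDT per run."""
    from .assess import bdt_score, mcc_score
    from .cli import RunConfig, predict_with_features
    from .siteqa import QAFeatureVector  # noqa: F401 (return type)

    rng = scenario.streams()["corpus"]
    rows = []
    for i in range(n_examples):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sc = SyntheticScenario(
            seed=sub_seed,
            chain_length=scenario.chain_length,
            pocket_residues=scenario.pocket_residues,
            n_templates=max(3, min(scenario.n_templates, 4)),
            coord_noise_sigma=float(rng.choice(CORPUS_TEMPLATE_SIGMAS)),
            mutation_rate=float(rng.choice(CORPUS_MUTATION_RATES)),
            ligand_type_mix=scenario.ligand_type_mix,
            decoy_fraction=0.0,
        )
        true_model = make_model(sc)
        truth = planted_truth(sc, true_model)
        sigma_m = float(rng.choice(CORPUS_MODEL_SIGMAS))
        model = degrade_model(true_model, sigma_m, rng) if sigma_m else true_model
        mq = model_quality_score(model, true_model)
        templates = make_templates(sc, true_model)
        prediction, _, features = predict_with_features(
            model, templates, RunConfig(model_quality=mq))
        pred = set(prediction.residue_seqs)
        true_mcc = max(0.0, mcc_score(pred, set(truth), true_model.length))
        true_bdt = bdt_score(pred, set(truth), true_model)
        rows.append((features, true_mcc, true_bdt))
    return rows


# ---------------------------------------------------------------------------
# Multi-model ranking benchmark


def ranking_experiment(seed: int, n_models: int = 10,
                       regressor=None) -> tuple[float, float]:
    """One multi-model run: predict a site for *n_models* degraded copies of
    one target, then compare the true MCC of the top pick under (a) ranking
    by predicted MCC/BDT and (b) ranking by the (noisy) global model-quality
    score alone.

    The observed model-quality input carries Gaussian error (sd 0.15), as a
    stand-in for an imperfect external quality estimator; the QA ranking can
    outdo it because its other four features measure the site geometry
    directly.  Returns (true MCC of QA-ranked top-1, true MCC of
    quality-only top-1).
    """
    from .assess import mcc_score
    from .cli import RunConfig, predict_with_features
    from .siteqa import predict_quality, rank_predictions

    rng = np.random.default_rng(seed)
    sc = SyntheticScenario(seed=int(rng.integers(0, 2**31 - 1)),
                           n_templates=5, coord_noise_sigma=0.75,
                           mutation_rate=0.1)
    true_model = make_model(sc)
    truth = set(planted_truth(sc, true_model))
    templates = make_templates(sc, true_model)
    sigmas = np.linspace(0.0, 2.5, n_models)
    rng.shuffle(sigmas)
    candidates = []
    for sigma in sigmas:
        model = degrade_model(true_model, float(sigma), rng) if sigma else true_model
        mq_obs = float(np.clip(model_quality_score(model, true_model)
                               + rng.normal(0, 0.15), 0.0, 1.0))
        pred, _, features = predict_with_features(
            model, templates, RunConfig(model_quality=mq_obs))
        quality = predict_quality(features, regressor)
        true_mcc = max(0.0, mcc_score(set(pred.residue_seqs), truth,
                                      true_model.length))
        candidates.append((pred, quality, mq_obs, true_mcc))

    mcc_by_pred = {id(p): m for p, _, _, m in candidates}
    ranked = rank_predictions([(p, q) for p, q, _, _ in candidates])
    qa_top_mcc = mcc_by_pred[id(ranked[0][0])]
    mq_top = max(candidates, key=lambda c: c[2])
    return qa_top_mcc, mq_top[3]
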