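"""Binding-site quality assessment.

Five features describe how well the predicted site is supported by the
superposed templates — BDTalign (kernel on distances between equivalent
model/template residues), Identity and Rescaled BLOSUM62 (sequence agreement
of 3D-equivalent site residues), Equivalent Residue Ligand Distance (do the
equivalent residues sit at the same distance from their respective ligands?)
and the global Model Quality score — and two small feed-forward regressors
(5 inputs, 8 logistic hidden units, 1 output) map them to a predicted MCC
and a predicted BDT of the site call.  Those predicted scores re-rank
alternative predictions, with the top-ranked one reported as final.

All features and predicted scores live in [0,1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.neural_network import MLPRegressor

from .assess import BDT_D0_DEFAULT, distance_kernel
from .sitepredict import ContactParams, SitePrediction
from .structio import Residue, StructureModel
from .superpose import SuperposedTemplate

BLOSUM_MIN, BLOSUM_MAX = -4.0, 11.0
EQUIV_CA_CUTOFF = 3.9  # Angstrom; 3D-equivalence search radius

FEATURE_NAMES = ("bdtalign", "identity", "blosum_rescaled", "erld",
                 "model_quality")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class QAFeatureVector:
    bdtalign: float
    identity: float
    blosum_rescaled: float
    erld: float
    model_quality: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"feature {name}={v} outside [0,1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass
class QualityEstimate:
    predicted_mcc: float
    predicted_bdt: float
    features: QAFeatureVector


# ---------------------------------------------------------------------------
# Per-template features


def _corr_equivalents(prediction: SitePrediction,
                      template: SuperposedTemplate,
                      ) -> list[tuple[Residue, Residue]]:
    """(model residue, template residue) pairs for predicted residues with a
    correspondence partner; template residues are in the model frame."""
    if template.template is None:
        return []
    t_by_seq = {r.seq: r for r in template.template.residues}
    corr = dict(template.correspondence.pairs)
    out = []
    for res in prediction.residues:
        tseq = corr.get(res.seq)
        if tseq is not None and tseq in t_by_seq:
            out.append((res, t_by_seq[tseq]))
    return out


def _nearest_equivalents(prediction: SitePrediction,
                         template: SuperposedTemplate,
                         cutoff: float = EQUIV_CA_CUTOFF,
                         ) -> list[tuple[Residue, Residue | None]]:
    """3D equivalence: nearest superposed template C-alpha within *cutoff*."""
    if template.template is None:
        return [(r, None) for r in prediction.residues]
    t_res = [r for r in template.template.residues if r.ca() is not None]
    if not t_res:
        return [(r, None) for r in prediction.residues]
    t_ca = np.vstack([r.ca().coords for r in t_res])
    out: list[tuple[Residue, Residue | None]] = []
    for res in prediction.residues:
        ca = res.ca()
        if ca is None:
            out.append((res, None))
            continue
        d = np.linalg.norm(t_ca - ca.coords, axis=1)
        i = int(np.argmin(d))
        out.append((res, t_res[i] if d[i] <= cutoff else None))
    return out


def feature_bdtalign(prediction: SitePrediction,
                     template: SuperposedTemplate,
                     d0: float = BDT_D0_DEFAULT) -> float:
    """Mean kernel score of C-alpha distances between equivalent residues.

    Predicted residues without an equivalent contribute 0.
    """
    if prediction.is_empty:
        return 0.0
    pairs = _corr_equivalents(prediction, template)
    total = 0.0
    for res, tres in pairs:
        ca_m, ca_t = res.ca(), tres.ca()
        if ca_m is None or ca_t is None:
            continue
        total += distance_kernel(float(np.linalg.norm(ca_m.coords - ca_t.coords)), d0)
    return total / len(prediction.residues)


def feature_identity(prediction: SitePrediction,
                     template: SuperposedTemplate) -> float:
    """Fraction of predicted residues whose 3D-equivalent template residue
    has the identical amino-acid type."""
    if prediction.is_empty:
        return 0.0
    pairs = _nearest_equivalents(prediction, template)
    same = sum(1 for res, tres in pairs
               if tres is not None and tres.name == res.name)
    return same / len(prediction.residues)


def feature_blosum(prediction: SitePrediction,
                   template: SuperposedTemplate) -> float:
    """Mean rescaled BLOSUM62 score, (s - s_min)/(s_max - s_min), over
    3D-equivalent residue pairs; 0 when no pair exists."""
    if prediction.is_empty:
        return 0.0
    scores = []
    for res, tres in _nearest_equivalents(prediction, template):
        if tres is None:
            continue
        a, b = res.one_letter, tres.one_letter
        try:
            s = float(_BLOSUM62[a, b])
        except (KeyError, IndexError):
            continue
        scores.append((s - BLOSUM_MIN) / (BLOSUM_MAX - BLOSUM_MIN))
    return float(np.mean(scores)) if scores else 0.0


def _min_dist_to_ligands(res: Residue, ligand_coords: np.ndarray) -> float:
    heavy = res.heavy_atoms()
    if not heavy or ligand_coords.size == 0:
        return float("inf")
    xyz = np.vstack([a.coords for a in heavy])
    d = np.linalg.norm(xyz[:, None, :] - ligand_coords[None, :, :], axis=2)
    return float(d.min())


def feature_erld(prediction: SitePrediction, template: SuperposedTemplate,
                 d0: float = BDT_D0_DEFAULT) -> float:
    """Equivalent Residue Ligand Distance: kernel on the mismatch between the
    model residue's distance to the pocket ligands and the equivalent template
    residue's distance to the template's own ligands."""
    if prediction.is_empty or prediction.pocket is None:
        return 0.0
    if not template.ligands:
        return 0.0
    pocket_xyz = prediction.pocket.all_coords()
    tmpl_xyz = np.vstack([l.coords for l in template.ligands])
    scores = []
    for res, tres in _corr_equivalents(prediction, template):
        dm = _min_dist_to_ligands(res, pocket_xyz)
        dt = _min_dist_to_ligands(tres, tmpl_xyz)
        if not np.isfinite(dm) or not np.isfinite(dt):
            continue
        scores.append(distance_kernel(abs(dm - dt), d0))
    return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# Aggregation over templates


def qa_features(prediction: SitePrediction,
                templates: Sequence[SuperposedTemplate],
                model_quality: float) -> QAFeatureVector:
    """Ligand-count-weighted mean of per-template features.

    Templates contributing more ligands to the selected pocket dominate the
    prediction, so they get proportionally more weight; templates with no
    pocket ligand get weight 0 (uniform weights if nobody contributed).
    """
    mq = min(max(model_quality, 0.0), 1.0)
    if prediction.is_empty or not templates:
        return QAFeatureVector(0.0, 0.0, 0.0, 0.0, mq)
    pocket_sources: dict[str, int] = {}
    if prediction.pocket is not None:
        for lig in prediction.pocket.members:
            pocket_sources[lig.source_template] = \
                pocket_sources.get(lig.source_template, 0) + 1
    weights = np.array([pocket_sources.get(t.template_id, 0)
                        for t in templates], dtype=float)
    if weights.sum() == 0:
        weights = np.ones(len(templates))
    weights /= weights.sum()
    vals = np.zeros(4)
    for w, t in zip(weights, templates):
        if w == 0:
            continue
        vals += w * np.array([
            feature_bdtalign(prediction, t),
            feature_identity(prediction, t),
            feature_blosum(prediction, t),
            feature_erld(prediction, t),
        ])
    vals = np.clip(vals, 0.0, 1.0)
    return QAFeatureVector(*vals, mq)


# ---------------------------------------------------------------------------
# Quality regressor


class UntrainedRegressorError(RuntimeError):
    pass


def _forward(x: np.ndarray, coefs: list[np.ndarray],
             intercepts: list[np.ndarray]) -> np.ndarray:
    """Forward pass: logistic hidden layers, linear output, clipped later."""
    h = x
    for W, b in zip(coefs[:-1], intercepts[:-1]):
        h = 1.0 / (1.0 + np.exp(-(h @ W + b)))
    return h @ coefs[-1] + intercepts[-1]


class QARegressor:
    """Two 5-8-1 feed-forward regressors: one targets MCC, one BDT.

    Training uses scikit-learn (lbfgs, fixed seed -> deterministic); the
    prediction path is a plain forward pass over the stored weights so that
    serialized weights are self-contained.
    """

    def __init__(self) -> None:
        self.weights: dict[str, dict[str, list[np.ndarray]]] | None = None

    # -- training ----------------------------------------------------------

    def fit(self, features: np.ndarray, mcc: np.ndarray, bdt: np.ndarray,
            seed: int = 0, hidden: int = 8, max_iter: int = 2000) -> "QARegressor":
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError("features must be (n, 5)")
        self.weights = {}
        for name, y in (("mcc", np.asarray(mcc)), ("bdt", np.asarray(bdt))):
            if np.ptp(y) < 1e-12:
                # degenerate corpus: constant predictor
                import warnings
                warnings.warn(f"constant {name} targets; using mean predictor")
                self.weights[name] = {
                    "coefs": [np.zeros((len(FEATURE_NAMES), 1))],
                    "intercepts": [np.array([float(y.mean())])],
                }
                continue
            net = MLPRegressor(hidden_layer_sizes=(hidden,),
                               activation="logistic", solver="lbfgs",
                               alpha=1e-4, max_iter=max_iter,
                               random_state=seed)
            net.fit(X, y)
            self.weights[name] = {
                "coefs": [np.array(c) for c in net.coefs_],
                "intercepts": [np.array(b) for b in net.intercepts_],
            }
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if self.weights is None:
            raise UntrainedRegressorError("nothing to save; call fit() first")
        blob = {"format": "pocketvote-qa-weights", "version": 1,
                "feature_names": list(FEATURE_NAMES), "nets": {}}
        for name, w in self.weights.items():
            blob["nets"][name] = {
                "coefs": [c.tolist() for c in w["coefs"]],
                "intercepts": [b.tolist() for b in w["intercepts"]],
            }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "QARegressor":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "pocketvote-qa-weights":
            raise ValueError(f"{path}: not a QA weights file")
        reg = cls()
        reg.weights = {
            name: {"coefs": [np.array(c) for c in net["coefs"]],
                   "intercepts": [np.array(b) for b in net["intercepts"]]}
            for name, net in blob["nets"].items()
        }
        return reg

    @classmethod
    def default(cls) -> "QARegressor":
        """Packaged weights, trained on the synthetic corpus (seed 7)."""
        from importlib.resources import files
        return cls.load(files("pocketvote").joinpath("data/qa_weights.json"))

    # -- prediction --------------------------------------------------------

    def predict_scores(self, features: QAFeatureVector) -> tuple[float, float]:
        if self.weights is None:
            raise UntrainedRegressorError(
                "regressor untrained: call fit() or QARegressor.default()")
        x = features.as_array()[None, :]
        out = []
        for name in ("mcc", "bdt"):
            w = self.weights[name]
            y = _forward(x, w["coefs"], w["intercepts"])
            out.append(float(np.clip(y, 0.0, 1.0).ravel()[0]))
        return out[0], out[1]


def train_regressor(corpus: Sequence[tuple[QAFeatureVector, float, float]],
                    seed: int = 0) -> QARegressor:
    """Train both heads on (features, true MCC, true BDT) rows."""
    X = np.vstack([fv.as_array() for fv, _, _ in corpus])
    mcc = np.array([m for _, m, _ in corpus])
    bdt = np.array([b for _, _, b in corpus])
    return QARegressor().fit(X, mcc, bdt, seed=seed)


def predict_quality(features: QAFeatureVector,
                    regressor: QARegressor | None = None) -> QualityEstimate:
    reg = regressor or QARegressor.default()
    pm, pb = reg.predict_scores(features)
    return QualityEstimate(predicted_mcc=pm, predicted_bdt=pb,
                           features=features)


# ---------------------------------------------------------------------------
# Ranking


def rank_predictions(candidates: Sequence[tuple[SitePrediction, QualityEstimate]],
                     ) -> list[tuple[SitePrediction, QualityEstimate]]:
    """Descending by mean(predicted MCC, predicted BDT); ties broken by the
    model-quality feature; stable thereafter."""
    if not candidates:
        return []
    indexed = list(enumerate(candidates))
    indexed.sort(key=lambda iq: (
        -(iq[1][1].predicted_mcc + iq[1][1].predicted_bdt) / 2.0,
        -iq[1][1].features.model_quality,
        iq[0]))
    return [c for _, c in indexed]
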