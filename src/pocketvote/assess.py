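"""Assessment of binding-site predictions against an observed residue set.

Two metrics: the Matthews Correlation Coefficient (MCC) over the binary
binding/non-binding classification of residues, and a distance-aware
binding-site distance test (BDT) in [0,1] that credits near-miss residues
through the kernel k(d) = 1/(1 + (d/d0)^2) on C-alpha distances
(d0 = 3.9 Angstrom, the carbon-carbon contact threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Hashable

import numpy as np

from .structio import StructureModel

BDT_D0_DEFAULT = 3.9  # Angstrom


class AssessmentError(ValueError):
    pass


@dataclass
class AssessmentResult:
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    bdt: float


def distance_kernel(d: float, d0: float = BDT_D0_DEFAULT) -> float:
    """k(d) = 1/(1 + (d/d0)^2): 1 at d=0, 0.5 at d=d0, -> 0 far away."""
    return 1.0 / (1.0 + (d / d0) ** 2)


def confusion(predicted: Collection[Hashable], observed: Collection[Hashable],
              universe_size: int) -> tuple[int, int, int, int]:
    pred, obs = set(predicted), set(observed)
    if universe_size < len(pred | obs):
        raise AssessmentError(
            f"residue universe L={universe_size} smaller than |P u O|="
            f"{len(pred | obs)}")
    tp = len(pred & obs)
    fp = len(pred - obs)
    fn = len(obs - pred)
    tn = universe_size - tp - fp - fn
    return tp, fp, fn, tn


def mcc_score(predicted: Collection[Hashable], observed: Collection[Hashable],
              universe_size: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Any zero factor in the denominator yields 0 by convention.
    """
    tp, fp, fn, tn = confusion(predicted, observed, universe_size)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _ca_lookup(model: StructureModel, seqs: Collection[int]) -> np.ndarray:
    pts = []
    for s in seqs:
        res = model.residue_by_seq(s)
        if res is None:
            raise AssessmentError(f"residue {s} not in model")
        ca = res.ca()
        if ca is None:
            raise AssessmentError(f"residue {res.name}{s} has no C-alpha atom")
        pts.append(ca.coords)
    return np.vstack(pts) if pts else np.empty((0, 3))


def bdt_score(predicted: Collection[int], observed: Collection[int],
              model: StructureModel, d0: float = BDT_D0_DEFAULT) -> float:
    """Symmetric distance-kernel score between predicted and observed sets.

    BDT = [sum_{p in P} k(d(p,O)) + sum_{o in O} k(d(o,P))] / (|P|+|O|)
    where d(x,S) is the minimum C-alpha distance from x to the set S.
    Both sets empty -> 1; exactly one empty -> 0.
    """
    P, O = sorted(set(predicted)), sorted(set(observed))
    if not P and not O:
        return 1.0
    if not P or not O:
        return 0.0
    cp = _ca_lookup(model, P)
    co = _ca_lookup(model, O)
    d = np.linalg.norm(cp[:, None, :] - co[None, :, :], axis=2)
    k = 1.0 / (1.0 + (d / d0) ** 2)
    score = k.max(axis=1).sum() + k.max(axis=0).sum()
    return float(score / (len(P) + len(O)))


def assess(predicted: Collection[int], observed: Collection[int],
           model: StructureModel, d0: float = BDT_D0_DEFAULT,
           ) -> AssessmentResult:
    """Full confusion matrix + MCC + BDT against the model's residue universe."""
    L = model.length
    tp, fp, fn, tn = confusion(predicted, observed, L)
    return AssessmentResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        mcc=mcc_score(predicted, observed, L),
        bdt=bdt_score(predicted, observed, model, d0))
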