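"""Apply a signature to individual samples and evaluate the calls.

Classification is purely within-sample: each pair compares the anchor's
and partner's raw measurements inside one sample, so no normalisation of
any kind is performed (or needed) and the calls are invariant under any
strictly increasing per-sample transform of the data.  The only graded
quantity the classifier produces is the vote fraction (TFP votes / number
of pairs), which therefore also drives the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .matrix import TFN, TFP, validate_expression, validate_labels
from .signature import Signature, _vote_matrix, harmonic_f1, majority_predict


def classify(m: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """Per-sample votes, vote fraction and predicted label.

    Returns a DataFrame indexed by sample id with one ``vote_<partner>``
    boolean column per pair (True = that pair votes TFP), plus
    ``votes_tfp``, ``score`` (vote fraction) and ``predicted``.  All
    signature genes must be present; missing ones are a hard error.
    """
    validate_expression(m)
    missing = sorted(set(sig.genes()) - set(m.index))
    if missing:
        raise KeyError(f"signature genes absent from the matrix: {missing}")
    votes = _vote_matrix(
        m, sig.anchor, sig.partners, [p.direction for p in sig.pairs]
    )
    votes_tfp = votes.sum(axis=0)
    pred = majority_predict(votes_tfp, sig.n_pairs)
    out = pd.DataFrame(
        votes.T,
        index=m.columns,
        columns=[f"vote_{p}" for p in sig.partners],
    )
    out["votes_tfp"] = votes_tfp
    out["score"] = votes_tfp / sig.n_pairs
    out["predicted"] = np.where(pred, TFP, TFN)
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class EvalSummary:
    """Confusion counts and the evaluation statistics (TFP = positive class).

    ``f1`` is the harmonic mean of sensitivity and specificity — not the
    precision/recall F1.  ``auc`` is the trapezoidal area under the ROC of
    the vote-fraction score, or None when constructed from counts alone.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None = None

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "EvalSummary":
        if min(tp, fn, tn, fp) < 0 or (tp + fn) == 0 or (tn + fp) == 0:
            raise ValueError("counts must be nonnegative with both classes present")
        sen = tp / (tp + fn)
        spe = tn / (tn + fp)
        return cls(
            tp=tp, fn=fn, tn=tn, fp=fp,
            sensitivity=sen,
            specificity=spe,
            accuracy=(tp + tn) / (tp + fn + tn + fp),
            f1=harmonic_f1(sen, spe),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
        }


def evaluate(results: pd.DataFrame, labels: pd.Series) -> EvalSummary:
    """Confusion counts, Sen/Spe/accuracy/F-1 and vote-fraction AUC.

    ``results`` is the output of :func:`classify`; every result sample must
    be labelled, and both classes must be present.
    """
    validate_labels(labels)
    unlabelled = results.index.difference(labels.index)
    if len(unlabelled):
        raise ValueError(
            f"unlabelled samples in the results: {sorted(unlabelled.astype(str))}"
        )
    lab = labels.loc[results.index]
    is_tfp = (lab == TFP).to_numpy()
    pred_tfp = (results["predicted"] == TFP).to_numpy()
    tp = int((pred_tfp & is_tfp).sum())
    fn = int((~pred_tfp & is_tfp).sum())
    tn = int((~pred_tfp & ~is_tfp).sum())
    fp = int((pred_tfp & ~is_tfp).sum())
    base = EvalSummary.from_counts(tp, fn, tn, fp)
    points = roc_points(results["score"], lab)
    return EvalSummary(
        **{**base.to_dict(), "auc": float(_trapezoid_auc(points[:, 0], points[:, 1]))}
    )


def roc_points(scores: pd.Series, labels: pd.Series) -> np.ndarray:
    """ROC staircase (fpr, tpr) from (0,0) to (1,1) over distinct thresholds."""
    validate_labels(labels)
    lab = labels.loc[scores.index] if isinstance(scores, pd.Series) else labels
    y = (np.asarray(lab) == TFP).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs both TFP and TFN samples")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc_from_scores(scores: pd.Series, labels: pd.Series) -> float:
    p = roc_points(scores, labels)
    return float(_trapezoid_auc(p[:, 0], p[:, 1]))


def auc_confidence_interval(
    scores: pd.Series,
    labels: pd.Series,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the vote-fraction AUC.

    Samples are resampled with replacement ``n_boot`` times; resamples
    missing a class are redrawn.  The reference method for the published
    intervals is unstated, so this CI is a documented convention rather
    than a reproduction.
    """
    validate_labels(labels)
    s = np.asarray(scores, dtype=float)
    lab = labels.loc[scores.index] if isinstance(scores, pd.Series) else labels
    y = (np.asarray(lab) == TFP).astype(int)
    rng = np.random.default_rng(seed)
    stats = []
    while len(stats) < n_boot:
        idx = rng.integers(0, len(s), len(s))
        if y[idx].min() == y[idx].max():
            continue
        fpr, tpr, _ = roc_curve(y[idx], s[idx], drop_intermediate=False)
        stats.append(_trapezoid_auc(fpr, tpr))
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(stats, [lo, 1.0 - lo]))
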