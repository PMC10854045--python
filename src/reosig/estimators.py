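"""scikit-learn estimators wrapping the signature discovery pipeline.

These follow sklearn conventions — ``fit``/``predict``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes — and
compose with pipelines and model selection.  Because gene identity matters
(the anchor gene must be locatable and signatures name their partners),
``X`` must be a :class:`pandas.DataFrame` of shape (n_samples, n_genes)
with gene identifiers as columns; ``y`` holds the ``"TFP"``/``"TFN"``
class labels.  The genes-x-samples orientation used by the module-level
functions is the transpose of this.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import pairs as _pairs
from . import signature as _signature
from . import stability as _stability
from .classifier import classify, evaluate
from .matrix import TFN, TFP, validate_expression, validate_labels


def _as_matrix(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "X must be a pandas DataFrame (samples x genes) with gene "
            "identifiers as columns; gene identity is part of the model"
        )
    return validate_expression(X.T)


def _as_labels(X: pd.DataFrame, y) -> pd.Series:
    y = pd.Series(np.asarray(y), index=X.index, name="label")
    return validate_labels(y)


class ReferenceGeneSelector(TransformerMixin, BaseEstimator):
    """Select reference (ERG-pairable) genes by fused stability quartiles.

    Fits the five variability metrics per gene, fuses them by mean rank and
    keeps the bottom-quartile (stable) and top-quartile (unstable) genes;
    ``transform`` restricts a matrix to those genes plus the anchor.

    Parameters
    ----------
    quartile : fraction of genes in each tail, default 0.25.
    anchor : gene excluded from selection but retained by transform.
    entropy_bins, iqr_coef : metric knobs (histogram bins; IQR flagging
        coefficient of the outlier sum).
    """

    def __init__(self, quartile=0.25, anchor="ERG", entropy_bins=10, iqr_coef=1.0):
        self.quartile = quartile
        self.anchor = anchor
        self.entropy_bins = entropy_bins
        self.iqr_coef = iqr_coef

    def fit(self, X, y):
        m = _as_matrix(X)
        labels = _as_labels(X, y)
        scores = _stability.stability_scores(
            m, labels, bins=self.entropy_bins, iqr_coef=self.iqr_coef
        )
        table = _stability.fuse_and_select(
            scores, quartile=self.quartile, anchor=self.anchor
        )
        self.scores_ = table
        self.stable_genes_ = list(table.index[table["category"] == _stability.STABLE])
        self.unstable_genes_ = list(table.index[table["category"] == _stability.UNSTABLE])
        self.reference_genes_ = _stability.reference_genes(table)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_genes_")
        keep = [g for g in ([self.anchor] if self.anchor in X.columns else [])]
        keep += [g for g in self.reference_genes_ if g in X.columns]
        missing = set(self.reference_genes_) - set(X.columns)
        if missing:
            raise KeyError(f"reference genes absent from X: {sorted(missing)[:5]}")
        return X[keep]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "reference_genes_")
        chosen = set(self.reference_genes_) | {self.anchor}
        return np.array([g in chosen for g in self.feature_names_in_])


class REOFusionClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end rank-pair fusion-status classifier.

    ``fit`` runs the discovery pipeline on the training cohort: stability
    screening for reference genes, reverse-degree / F-1 pair scoring
    against the anchor, candidate pooling, and seeded greedy forward
    selection of a majority-vote signature.  ``predict`` applies the
    signature to new samples by raw within-sample comparisons only, so
    predictions are invariant to any per-sample monotone transform.

    Alternatively pass a ready-made ``signature`` (e.g.
    :func:`reosig.signature.default_signature`) to skip discovery; ``fit``
    then only records training metrics.

    Attributes (after fit): ``signature_``, ``reference_genes_``,
    ``pair_scores_``, ``candidates_``, ``training_summary_``, ``classes_``.
    """

    def __init__(
        self,
        anchor="ERG",
        quartile=0.25,
        top_frac=0.20,
        top_k=10,
        n_seeds=10,
        max_pairs=20,
        entropy_bins=10,
        iqr_coef=1.0,
        rank_universe="all",
        signature=None,
    ):
        self.anchor = anchor
        self.quartile = quartile
        self.top_frac = top_frac
        self.top_k = top_k
        self.n_seeds = n_seeds
        self.max_pairs = max_pairs
        self.entropy_bins = entropy_bins
        self.iqr_coef = iqr_coef
        self.rank_universe = rank_universe
        self.signature = signature

    def fit(self, X, y):
        m = _as_matrix(X)
        labels = _as_labels(X, y)
        self.classes_ = np.array([TFN, TFP])
        if self.signature is not None:
            sig = self.signature
            self.reference_genes_ = None
            self.pair_scores_ = None
            self.candidates_ = None
        else:
            selector = ReferenceGeneSelector(
                quartile=self.quartile,
                anchor=self.anchor,
                entropy_bins=self.entropy_bins,
                iqr_coef=self.iqr_coef,
            ).fit(X, y)
            self.reference_genes_ = selector.reference_genes_
            self.pair_scores_ = _pairs.score_pairs(
                m,
                labels,
                anchor=self.anchor,
                reference_genes=self.reference_genes_,
                rank_universe=self.rank_universe,
            )
            self.candidates_ = _pairs.candidate_pool(
                self.pair_scores_, top_frac=self.top_frac, top_k=self.top_k
            )
            sig = _signature.forward_select(
                m,
                labels,
                self.candidates_,
                anchor=self.anchor,
                n_seeds=self.n_seeds,
                max_pairs=self.max_pairs,
            )
        self.signature_ = sig
        self.training_summary_ = evaluate(classify(m, sig), labels)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def predict(self, X):
        check_is_fitted(self, "signature_")
        return classify(_as_matrix(X), self.signature_)["predicted"].to_numpy()

    def decision_function(self, X):
        """Vote fraction in [0, 1] — the classifier's only graded score."""
        check_is_fitted(self, "signature_")
        return classify(_as_matrix(X), self.signature_)["score"].to_numpy()

    def predict_proba(self, X):
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])
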