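"""Gene expression stability scoring and reference-gene selection.

Candidate partner ("reference") genes for the anchored pair screen are
chosen by how extreme their expression variability is across the training
cohort.  Five complementary variability metrics are computed per gene:

* **F-statistic** of a one-way ANOVA between the fusion-positive and
  fusion-negative groups — sensitivity to a group mean shift;
* **Shannon entropy** of the expression histogram (equal-width bins,
  log base 2) — spread of the value distribution;
* **coefficient of variation** sigma/mu with the population (n-denominator)
  standard deviation;
* **outlier sum** — the summed absolute median-centred deviation of values
  flagged by the IQR rule (outside ``Q1 - c*IQR`` or ``Q3 + c*IQR``; the
  flagging coefficient defaults to 1, and quartiles use linear, type-7
  interpolation);
* **median absolute deviation** without a consistency constant.

The smaller each metric, the more stably the gene is expressed.  The five
metrics are fused by rank aggregation (stingscore-style, realized as the
mean of the five ascending metric ranks) and genes in the bottom quartile
of the fused score are labelled *stable* (SEGs), the top quartile
*unstable* (USEGs); both tails together form the reference-gene set.  The
anchor gene itself is excluded before the quartile cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import group_columns, validate_expression

#: Finite stand-in for an infinite F ratio (zero within-group variance with
#: distinct group means); large enough to top any realistic F ranking.
F_SENTINEL = 1e12

METRICS = ("f_stat", "entropy", "cv", "outlier_sum", "mad")

STABLE = "stable"
UNSTABLE = "unstable"
NEITHER = "neither"


def f_statistic(group_a, group_b) -> float:
    """One-way ANOVA F between two groups of a gene's per-sample values.

    Zero pooled within-group variance yields 0 when the group means are
    equal and :data:`F_SENTINEL` otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    grand = np.concatenate([a, b]).mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    dfw = len(a) + len(b) - 2
    if ssw == 0.0:
        return 0.0 if a.mean() == b.mean() else F_SENTINEL
    return float(ssb / (ssw / dfw))


def shannon_entropy(values, bins: int = 10) -> float:
    """Histogram entropy in bits over *bins* equal-width bins on [min, max].

    A constant vector occupies a single bin and scores 0.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(values, dtype=float)
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum())


def coefficient_of_variation(values) -> float:
    """Population standard deviation over mean; defined 0 at mean 0."""
    x = np.asarray(values, dtype=float)
    mu = x.mean()
    if mu <= 0.0:
        return 0.0
    return float(x.std(ddof=0) / mu)


def outlier_sum(values, iqr_coef: float = 1.0) -> float:
    """Summed |x - median| over IQR-flagged outliers; 0 if none flagged."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("outlier sum needs at least 4 values")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear (type-7)
    iqr = q3 - q1
    flagged = (x < q1 - iqr_coef * iqr) | (x > q3 + iqr_coef * iqr)
    return float(np.abs(x[flagged] - med).sum())


def median_absolute_deviation(values) -> float:
    """Raw MAD: median(|x - median(x)|), no consistency constant."""
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("MAD needs at least 1 value")
    return float(np.median(np.abs(x - np.median(x))))


def stability_scores(
    m: pd.DataFrame,
    labels: pd.Series,
    bins: int = 10,
    iqr_coef: float = 1.0,
) -> pd.DataFrame:
    """Per-gene table of the five variability metrics.

    ``m`` is genes x samples; ``labels`` maps samples to TFP/TFN (both
    groups required, >= 2 samples each for the F-statistic).
    """
    validate_expression(m)
    tfn, tfp = group_columns(m, labels)
    if len(tfn) < 2 or len(tfp) < 2:
        raise ValueError("F-statistic needs >= 2 samples per group")
    x = m.to_numpy(dtype=float)
    labelled = x[:, np.concatenate([tfn, tfp])]

    out = pd.DataFrame(index=m.index.copy(), columns=list(METRICS), dtype=float)
    out["f_stat"] = _f_statistic_rows(x[:, tfn], x[:, tfp])
    out["entropy"] = [shannon_entropy(row, bins=bins) for row in labelled]
    mu = labelled.mean(axis=1)
    sd = labelled.std(axis=1, ddof=0)
    out["cv"] = np.where(mu > 0, np.divide(sd, mu, out=np.zeros_like(sd), where=mu > 0), 0.0)
    out["outlier_sum"] = _outlier_sum_rows(labelled, iqr_coef)
    med = np.median(labelled, axis=1)
    out["mad"] = np.median(np.abs(labelled - med[:, None]), axis=1)
    return out


def _f_statistic_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    grand = (na * ma + nb * mb) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    dfw = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / dfw)
    f[ssw == 0.0] = np.where(ma[ssw == 0.0] == mb[ssw == 0.0], 0.0, F_SENTINEL)
    return f


def _outlier_sum_rows(x: np.ndarray, iqr_coef: float) -> np.ndarray:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], axis=1)
    iqr = q3 - q1
    lo = (q1 - iqr_coef * iqr)[:, None]
    hi = (q3 + iqr_coef * iqr)[:, None]
    flagged = (x < lo) | (x > hi)
    return np.where(flagged, np.abs(x - med[:, None]), 0.0).sum(axis=1)


def fuse_and_select(
    scores: pd.DataFrame,
    quartile: float = 0.25,
    anchor: str | None = None,
) -> pd.DataFrame:
    """Fuse the five metric ranks and cut the stability quartiles.

    Each metric becomes an ascending rank (ties averaged); the fused score
    is the mean of the five ranks.  Exactly ``floor(quartile * n)`` genes
    with the smallest fused score are labelled stable and as many with the
    largest unstable; ties across a quartile boundary are broken by gene id
    so the cut is deterministic.  The anchor gene is dropped first.

    Returns the score table with ``fused_score`` and ``category`` columns.
    """
    if not 0 < quartile <= 0.5:
        raise ValueError("quartile must be in (0, 0.5]")
    table = scores.copy() if anchor is None else scores.drop(index=anchor, errors="ignore").copy()
    if table.shape[0] < 8:
        raise ValueError("need at least 8 genes (after excluding the anchor)")
    ranks = table[list(METRICS)].rank(axis=0, method="average", ascending=True)
    table["fused_score"] = ranks.mean(axis=1)
    n_ref = int(np.floor(quartile * table.shape[0]))
    # stable sort on gene id first, then fused score: boundary ties break
    # lexicographically by gene id
    order = (
        table.sort_index(kind="mergesort")
        .sort_values("fused_score", kind="mergesort")
        .index
    )
    table["category"] = NEITHER
    table.loc[order[:n_ref], "category"] = STABLE
    table.loc[order[-n_ref:], "category"] = UNSTABLE
    return table


def reference_genes(selection: pd.DataFrame) -> list[str]:
    """Gene ids categorised stable or unstable, in table order."""
    mask = selection["category"].isin([STABLE, UNSTABLE])
    return list(selection.index[mask])
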