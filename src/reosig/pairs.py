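"""Anchored gene-pair screening: reverse degree, pair F-1, candidate pool.

Every pair couples the anchor gene (ERG by default) with one reference
gene and is scored two ways:

* **reverse degree** — the geometric mean of the two groups' normalised
  absolute summed within-sample rank differences between anchor and
  reference::

      Rbar = sqrt( |sum_i (R_a[N_i] - R_r[N_i])| / m
                   * |sum_j (R_a[P_j] - R_r[P_j])| / n )

  where ``N``/``P`` index the fusion-negative/-positive samples.  Note the
  absolute values sit *outside* each group sum: a pair whose rank gap is
  large but points the same way in both groups also scores high, and
  opposite per-sample gaps inside one group can cancel to zero.  This is
  the statistic as defined; a ``signed=True`` variant multiplies in the
  sign agreement so only true reversals (opposite group signs) score.

* **pair F-1** — each orientation of the within-sample order relation
  (anchor above or below the reference voting fusion-positive) classifies
  every training sample; sensitivity and specificity of that vote give
  ``F1 = 2*Sen*Spe/(Sen+Spe)`` and the better orientation is kept.  Exact
  expression ties vote fusion-negative (no evidence of anchor elevation).

The candidate pool unions the top-k pairs of both rankings with the
intersection of both top-fraction sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import group_columns, rank_within_samples, validate_expression
from .signature import DIR_GT, DIR_LT, harmonic_f1

SCORE_COLUMNS = [
    "partner",
    "direction",
    "reverse_degree",
    "sensitivity",
    "specificity",
    "f1",
]


@dataclass(frozen=True)
class PairScore:
    anchor: str
    partner: str
    reverse_degree: float
    sensitivity: float
    specificity: float
    f1: float
    direction: str


def reverse_degree(
    ranks: pd.DataFrame,
    labels: pd.Series,
    anchor: str,
    ref: str,
    signed: bool = False,
) -> float:
    """Reverse degree of the (anchor, ref) pair from a within-sample rank table."""
    for g in (anchor, ref):
        if g not in ranks.index:
            raise KeyError(f"gene {g!r} not present in the rank profile")
    tfn, tfp = group_columns(ranks, labels)
    diff = ranks.loc[anchor].to_numpy() - ranks.loc[ref].to_numpy()
    sum_n = diff[tfn].sum()
    sum_p = diff[tfp].sum()
    if signed and np.sign(sum_n) == np.sign(sum_p):
        return 0.0
    return float(np.sqrt(abs(sum_n) / len(tfn) * abs(sum_p) / len(tfp)))


def pair_f1(
    m: pd.DataFrame,
    labels: pd.Series,
    anchor: str,
    ref: str,
) -> tuple[float, float, float, str]:
    """(sensitivity, specificity, F-1, direction) of the best orientation.

    Direction ``"gt"`` means *anchor above the reference votes TFP*; a tie
    between orientations keeps ``"gt"`` (the elevated-anchor biology).
    """
    validate_expression(m)
    for g in (anchor, ref):
        if g not in m.index:
            raise KeyError(f"gene {g!r} not present in the expression matrix")
    tfn, tfp = group_columns(m, labels)
    a = m.loc[anchor].to_numpy(dtype=float)
    r = m.loc[ref].to_numpy(dtype=float)
    stats = {}
    for direction in (DIR_GT, DIR_LT):
        votes_tfp = (a > r) if direction == DIR_GT else (a < r)
        sen = float(votes_tfp[tfp].mean())
        spe = float((~votes_tfp)[tfn].mean())
        stats[direction] = (sen, spe, harmonic_f1(sen, spe))
    best = DIR_GT if stats[DIR_GT][2] >= stats[DIR_LT][2] else DIR_LT
    sen, spe, f1 = stats[best]
    return sen, spe, f1, best


def score_pairs(
    m: pd.DataFrame,
    labels: pd.Series,
    anchor: str = "ERG",
    reference_genes: list[str] | None = None,
    rank_universe: str = "all",
    signed: bool = False,
) -> pd.DataFrame:
    """Score every (anchor, reference) pair; one row per reference gene.

    ``rank_universe`` controls which genes define the within-sample ranks
    used by the reverse degree: ``"all"`` (default, the standard REO
    convention) or ``"references"`` (anchor plus reference genes only).
    Rows are returned in canonical order: F-1 descending, then reverse
    degree descending, then partner id.
    """
    validate_expression(m)
    if anchor not in m.index:
        raise KeyError(f"anchor gene {anchor!r} not present in the matrix")
    if reference_genes is None:
        refs = [g for g in m.index if g != anchor]
    else:
        refs = [g for g in reference_genes if g != anchor]
        missing = sorted(set(refs) - set(m.index))
        if missing:
            raise KeyError(f"reference genes absent from the matrix: {missing}")
    if not refs:
        raise ValueError("no reference genes to pair with the anchor")
    if rank_universe == "all":
        ranks = rank_within_samples(m)
    elif rank_universe == "references":
        ranks = rank_within_samples(m.loc[[anchor] + refs])
    else:
        raise ValueError("rank_universe must be 'all' or 'references'")
    tfn, tfp = group_columns(m, labels)

    rk = ranks.to_numpy()
    ai = ranks.index.get_indexer([anchor])[0]
    ri = ranks.index.get_indexer(refs)
    diff = rk[ai] - rk[ri]  # (n_refs, n_samples)
    sum_n = diff[:, tfn].sum(axis=1)
    sum_p = diff[:, tfp].sum(axis=1)
    rdeg = np.sqrt(np.abs(sum_n) / len(tfn) * np.abs(sum_p) / len(tfp))
    if signed:
        rdeg = np.where(np.sign(sum_n) == np.sign(sum_p), 0.0, rdeg)

    x = m.to_numpy(dtype=float)
    mi = m.index.get_indexer(refs)
    a = x[m.index.get_indexer([anchor])[0]]
    gt = a[None, :] > x[mi]
    lt = a[None, :] < x[mi]
    out = []
    for k, ref in enumerate(refs):
        sen_gt = float(gt[k, tfp].mean())
        spe_gt = float((~gt[k, tfn]).mean())
        sen_lt = float(lt[k, tfp].mean())
        spe_lt = float((~lt[k, tfn]).mean())
        f_gt = harmonic_f1(sen_gt, spe_gt)
        f_lt = harmonic_f1(sen_lt, spe_lt)
        if f_gt >= f_lt:
            row = (ref, DIR_GT, float(rdeg[k]), sen_gt, spe_gt, f_gt)
        else:
            row = (ref, DIR_LT, float(rdeg[k]), sen_lt, spe_lt, f_lt)
        out.append(row)
    scores = pd.DataFrame(out, columns=SCORE_COLUMNS)
    scores.attrs["anchor"] = anchor
    return canonical_order(scores)


def canonical_order(scores: pd.DataFrame) -> pd.DataFrame:
    """Deterministic pair ordering: F-1 desc, reverse degree desc, partner id."""
    out = scores.sort_values(
        ["f1", "reverse_degree", "partner"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.attrs.update(scores.attrs)
    return out


def candidate_pool(
    scores: pd.DataFrame, top_frac: float = 0.20, top_k: int = 10
) -> pd.DataFrame:
    """Assemble the candidate pair pool.

    Pool = (top ``top_k`` by reverse degree) ∪ (top ``top_k`` by F-1)
    ∪ (top ``top_frac`` by reverse degree ∩ top ``top_frac`` by F-1),
    deduplicated, in canonical order.  Top-fraction counts round up.
    """
    if len(scores) < top_k:
        raise ValueError(f"need at least top_k={top_k} scored pairs, got {len(scores)}")
    by_f1 = canonical_order(scores)
    by_rd = scores.sort_values(
        ["reverse_degree", "f1", "partner"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    n_frac = int(np.ceil(top_frac * len(scores)))
    pool = (
        set(by_rd["partner"].head(top_k))
        | set(by_f1["partner"].head(top_k))
        | (set(by_rd["partner"].head(n_frac)) & set(by_f1["partner"].head(n_frac)))
    )
    out = by_f1[by_f1["partner"].isin(pool)].reset_index(drop=True)
    out.attrs.update(scores.attrs)
    return out
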