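"""Majority-vote pair signatures and their greedy forward selection.

A signature is an anchor gene plus an ordered set of directed pairs
``(partner, direction)``; a sample is called fusion-positive when at least
half of the pairs vote for it.  ``direction == "gt"`` means the pair votes
fusion-positive when the anchor's expression exceeds the partner's within
the sample (the elevated-anchor biology); ``"lt"`` is the reverse.  Exact
expression ties always vote fusion-negative.

Selection is seeded greedy forward search: each of the top individually
scoring candidate pairs seeds a set that grows by the single pair whose
addition most increases the ensemble F-1 (harmonic mean of sensitivity and
specificity under the majority vote), stopping when no addition strictly
improves; the best of all seeded runs wins, with ties resolved toward
fewer pairs, then earlier seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import group_columns, validate_expression

DIR_GT = "gt"  # anchor > partner votes TFP
DIR_LT = "lt"  # anchor < partner votes TFP
VALID_DIRECTIONS = (DIR_GT, DIR_LT)

#: Minimum ensemble F-1 gain counted as a strict improvement (guards
#: against float noise creating spurious greedy steps).
IMPROVEMENT_EPS = 1e-12


@dataclass(frozen=True)
class SignaturePair:
    partner: str
    direction: str

    def __post_init__(self):
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class Signature:
    """An anchored majority-vote gene-pair signature."""

    anchor: str
    pairs: tuple[SignaturePair, ...]
    rule: str = "majority"
    training: dict | None = None
    trace: list | None = None
    provenance: str | None = None

    def __post_init__(self):
        self.pairs = tuple(
            p if isinstance(p, SignaturePair) else SignaturePair(*p) for p in self.pairs
        )
        if len(self.pairs) < 1:
            raise ValueError("a signature needs at least one pair")
        partners = [p.partner for p in self.pairs]
        if len(set(partners)) != len(partners):
            raise ValueError("partner genes must be unique")
        if self.anchor in partners:
            raise ValueError("the anchor gene cannot be its own partner")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def partners(self) -> list[str]:
        return [p.partner for p in self.pairs]

    def genes(self) -> list[str]:
        return [self.anchor] + self.partners

    def to_dict(self) -> dict:
        d = {
            "anchor": self.anchor,
            "pairs": [{"partner": p.partner, "direction": p.direction} for p in self.pairs],
            "rule": self.rule,
        }
        if self.training is not None:
            d["training"] = self.training
        if self.trace is not None:
            d["trace"] = self.trace
        if self.provenance is not None:
            d["provenance"] = self.provenance
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            anchor=d["anchor"],
            pairs=tuple(SignaturePair(p["partner"], p["direction"]) for p in d["pairs"]),
            rule=d.get("rule", "majority"),
            training=d.get("training"),
            trace=d.get("trace"),
            provenance=d.get("provenance"),
        )


def write_signature(sig: Signature, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sig.to_dict(), indent=2) + "\n")


def read_signature(path: str | Path) -> Signature:
    return Signature.from_dict(json.loads(Path(path).read_text()))


def default_signature() -> Signature:
    """The shipped five-pair ERG signature (5-ERG-mRPs).

    Partner genes TNPO1, EXTL2, DPP4, ANG and CHRNA2 reconstructed from the
    published 5-ERG-mRPs description; the published pair directions are not
    stated, so all pairs default to the elevated-anchor orientation
    (ERG above partner votes fusion-positive).  Override with a user
    signature file where directions are known.
    """
    return Signature(
        anchor="ERG",
        pairs=tuple(
            SignaturePair(p, DIR_GT) for p in ("TNPO1", "EXTL2", "DPP4", "ANG", "CHRNA2")
        ),
        provenance=(
            "reconstructed from the published 5-ERG-mRPs partner list; "
            "directions default to anchor-above-partner"
        ),
    )


def harmonic_f1(sensitivity: float, specificity: float) -> float:
    """2*Sen*Spe/(Sen+Spe) — the harmonic mean of Sen and Spe (0 at 0+0)."""
    s = sensitivity + specificity
    if s == 0.0:
        return 0.0
    return 2.0 * sensitivity * specificity / s


def majority_predict(votes_tfp: np.ndarray, n_pairs: int) -> np.ndarray:
    """TFP iff at least half of the pairs vote TFP (ties vote TFP)."""
    return 2 * votes_tfp >= n_pairs


def _vote_matrix(
    m: pd.DataFrame, anchor: str, partners: list[str], directions: list[str]
) -> np.ndarray:
    """Boolean (n_pairs, n_samples) TFP-vote matrix from raw expression."""
    a = m.loc[anchor].to_numpy(dtype=float)
    rows = []
    for partner, direction in zip(partners, directions):
        p = m.loc[partner].to_numpy(dtype=float)
        rows.append(a > p if direction == DIR_GT else a < p)
    return np.array(rows, dtype=bool)


def _ensemble_stats(votes: np.ndarray, is_tfp: np.ndarray) -> tuple[float, float, float]:
    pred = majority_predict(votes.sum(axis=0), votes.shape[0])
    sen = float(pred[is_tfp].mean())
    spe = float((~pred[~is_tfp]).mean())
    return sen, spe, harmonic_f1(sen, spe)


def forward_select(
    m: pd.DataFrame,
    labels: pd.Series,
    candidates: pd.DataFrame,
    anchor: str = "ERG",
    n_seeds: int = 10,
    max_pairs: int = 20,
) -> Signature:
    """Seeded greedy forward selection of a majority-vote signature.

    ``candidates`` is a pair-score table (``partner``, ``direction``, ``f1``,
    ``reverse_degree`` columns) as produced by
    :func:`reosig.pairs.candidate_pool`.  The ``n_seeds`` candidates with
    the highest individual F-1 each seed one greedy run; each run adds the
    candidate maximising ensemble F-1 while the gain is strict, capped at
    ``max_pairs``.  Ambiguities are deterministic: candidate order is F-1
    desc, reverse degree desc, partner id; among runs, highest F-1, then
    fewer pairs, then seed order.
    """
    if len(candidates) == 0:
        raise ValueError("candidate pool is empty")
    validate_expression(m)
    cand = candidates.sort_values(
        ["f1", "reverse_degree", "partner"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    tfn, tfp = group_columns(m, labels)
    keep = np.concatenate([tfn, tfp])
    is_tfp = np.zeros(len(keep), dtype=bool)
    is_tfp[len(tfn):] = True
    sub = m.iloc[:, keep]
    votes = _vote_matrix(
        sub, anchor, list(cand["partner"]), list(cand["direction"])
    )

    n_seeds = min(n_seeds, len(cand))
    runs = []
    for seed_idx in range(n_seeds):
        selected = [seed_idx]
        sen, spe, f1 = _ensemble_stats(votes[selected], is_tfp)
        trace = [{"added": cand.at[seed_idx, "partner"], "f1": f1}]
        while len(selected) < max_pairs:
            best_j, best = None, (f1, None, None)
            for j in range(len(cand)):
                if j in selected:
                    continue
                s, p, f = _ensemble_stats(votes[selected + [j]], is_tfp)
                if f > best[0] + IMPROVEMENT_EPS:
                    best_j, best = j, (f, s, p)
            if best_j is None:
                break
            selected.append(best_j)
            f1, sen, spe = best[0], best[1], best[2]
            trace.append({"added": cand.at[best_j, "partner"], "f1": f1})
        runs.append((f1, len(selected), seed_idx, selected, sen, spe, trace))

    runs.sort(key=lambda r: (-r[0], r[1], r[2]))
    f1, _, seed_idx, selected, sen, spe, trace = runs[0]
    pairs = tuple(
        SignaturePair(cand.at[j, "partner"], cand.at[j, "direction"]) for j in selected
    )
    return Signature(
        anchor=anchor,
        pairs=pairs,
        training={"f1": f1, "sensitivity": sen, "specificity": spe,
                  "seed_partner": cand.at[seed_idx, "partner"]},
        trace=trace,
        provenance="greedy forward selection",
    )
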