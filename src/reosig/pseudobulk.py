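"""Fusion-status calls for single-cell samples via pseudobulk voting.

A single-cell sample with N tumor cells yields N pseudobulks: for each
n = 1..N a uniform random subset of n tumor cells is drawn without
replacement and its per-gene mean expression forms one synthetic bulk
profile.  Each pseudobulk is classified by the pair signature; the sample
is then called fusion-positive (or -negative) when an exact two-sided
binomial test against a fair coin finds significantly more pseudobulks on
that side, and *indeterminate* otherwise.  Note N must reach 6 before
significance at alpha = 0.05 is attainable at all (2 * 0.5^5 > 0.05).

Pseudobulk means are taken on raw counts; an optional CPM mode normalises
each cell to counts-per-million first.  Tumor-cell identification is
upstream: the module consumes a per-cell tumor flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread
from scipy.stats import binomtest

from .classifier import classify
from .matrix import TFN, TFP
from .signature import Signature

INDETERMINATE = "indeterminate"


@dataclass
class CellMatrix:
    """Gene x cell count matrix with a per-cell tumor flag."""

    counts: np.ndarray | sparse.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    tumor_flag: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self.tumor_flag = np.asarray(self.tumor_flag, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.tumor_flag.shape != (len(self.cell_ids),):
            raise ValueError("tumor_flag must have one entry per cell")

    @property
    def n_tumor(self) -> int:
        return int(self.tumor_flag.sum())

    def tumor_counts(self, cpm: bool = False) -> np.ndarray:
        """Dense gene x tumor-cell count block, optionally CPM-normalised."""
        block = self.counts[:, self.tumor_flag]
        block = np.asarray(block.todense() if sparse.issparse(block) else block, dtype=float)
        if cpm:
            totals = block.sum(axis=0)
            totals[totals == 0] = 1.0
            block = block / totals * 1e6
        return block


def read_cell_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    tumor_flag_path: str | Path | None = None,
    feature_column: int = 0,
) -> CellMatrix:
    """Read Matrix Market counts plus feature/barcode lists (genes as rows).

    ``feature_column`` selects which TSV column of the features file holds
    the gene identifier (0 for the id column, 1 for gene symbols in
    CellRanger-style files).  Without a tumor-flag file all cells are
    treated as tumor cells.
    """
    counts = mmread(str(mtx_path)).tocsc()
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    gene_ids = features[feature_column].tolist()
    cell_ids = barcodes[0].tolist()
    if tumor_flag_path is None:
        flag = np.ones(len(cell_ids), dtype=bool)
    else:
        flags = read_tumor_flags(tumor_flag_path)
        missing = sorted(set(cell_ids) - set(flags.index))
        if missing:
            raise ValueError(f"cells without a tumor flag: {missing[:5]}")
        flag = flags.loc[cell_ids].to_numpy()
    return CellMatrix(counts, gene_ids, cell_ids, flag)


def read_tumor_flags(path: str | Path) -> pd.Series:
    """Two-column TSV: cell barcode, flag (1/0, true/false, tumor/normal)."""
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str)
    truthy = {"1", "true", "tumor", "yes"}
    falsy = {"0", "false", "normal", "no"}
    values = []
    for v in rows[1].str.lower():
        if v in truthy:
            values.append(True)
        elif v in falsy:
            values.append(False)
        else:
            raise ValueError(f"unrecognised tumor flag {v!r}")
    return pd.Series(values, index=rows[0].to_numpy())


def make_pseudobulks(cm: CellMatrix, seed: int, cpm: bool = False) -> pd.DataFrame:
    """N pseudobulk profiles from the N tumor cells of a sample.

    Pseudobulk n (column ``pb_n``) is the per-gene mean of a uniform random
    subset of n tumor cells drawn without replacement; pseudobulk N is the
    mean of all tumor cells.  Reproducible for a fixed seed.
    """
    n = cm.n_tumor
    if n == 0:
        raise ValueError("no tumor cells: cannot build pseudobulks")
    rng = np.random.default_rng(seed)
    block = cm.tumor_counts(cpm=cpm)
    cols = {}
    for size in range(1, n + 1):
        subset = rng.choice(n, size=size, replace=False)
        cols[f"pb_{size}"] = block[:, subset].mean(axis=1)
    return pd.DataFrame(cols, index=cm.gene_ids)


def binomial_call(n_tfp: int, n_total: int, alpha: float = 0.05) -> tuple[float, str]:
    """Exact two-sided binomial test of the pseudobulk vote against 0.5.

    Returns ``(p_value, call)`` where the call is TFP/TFN when the test is
    significant at *alpha* and the majority points that way, else
    indeterminate.
    """
    if not 0 <= n_tfp <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_tfp <= n_total and n_total >= 1")
    p = binomtest(n_tfp, n_total, p=0.5, alternative="two-sided").pvalue
    if p < alpha and n_tfp > n_total / 2:
        return float(p), TFP
    if p < alpha and n_tfp < n_total / 2:
        return float(p), TFN
    return float(p), INDETERMINATE


@dataclass(frozen=True)
class SampleVote:
    sample_id: str
    n_pseudobulks: int
    n_tfp_calls: int
    p_value: float
    call: str


def vote_sample(
    cm: CellMatrix,
    sig: Signature,
    seed: int = 0,
    alpha: float = 0.05,
    sample_id: str = "sample",
    cpm: bool = False,
) -> SampleVote:
    """Classify every pseudobulk of a sample and apply the binomial call."""
    missing = sorted(set(sig.genes()) - set(cm.gene_ids))
    if missing:
        raise KeyError(f"signature genes absent from the cell matrix: {missing}")
    bulks = make_pseudobulks(cm, seed=seed, cpm=cpm)
    results = classify(bulks, sig)
    n_tfp = int((results["predicted"] == TFP).sum())
    p, call = binomial_call(n_tfp, len(results), alpha=alpha)
    return SampleVote(
        sample_id=sample_id,
        n_pseudobulks=len(results),
        n_tfp_calls=n_tfp,
        p_value=p,
        call=call,
    )
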