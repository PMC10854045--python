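"""Core containers and within-sample ranking.

An *expression matrix* is a :class:`pandas.DataFrame` with unique gene
identifiers as the row index and unique sample identifiers as columns.
Values must be finite; they are expected to be nonnegative expression
measurements (intensities, counts, RPKM/FPKM — the method is agnostic to
the scale because it only ever compares values *within* a sample).

A *label set* is a :class:`pandas.Series` mapping sample identifiers to one
of the two fusion-status classes ``"TFP"`` (T2E fusion-positive, the
positive class throughout) and ``"TFN"`` (fusion-negative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TFP = "TFP"
TFN = "TFN"
VALID_LABELS = frozenset({TFP, TFN})


def validate_expression(m: pd.DataFrame, min_genes: int = 2) -> pd.DataFrame:
    """Check expression-matrix invariants and return the matrix.

    Raises ``ValueError`` on duplicate gene or sample identifiers, fewer
    than *min_genes* genes or one sample, or non-finite values.
    """
    if not isinstance(m, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame")
    if m.index.has_duplicates:
        dups = sorted(m.index[m.index.duplicated()].unique().astype(str))
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if m.columns.has_duplicates:
        dups = sorted(m.columns[m.columns.duplicated()].unique().astype(str))
        raise ValueError(f"duplicate sample identifiers: {dups}")
    if m.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {m.shape[0]}")
    if m.shape[1] < 1:
        raise ValueError("need at least 1 sample")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))
        g, s = bad[0]
        raise ValueError(
            f"non-finite value at gene {m.index[g]!r}, sample {m.columns[s]!r}"
            f" ({len(bad)} non-finite cells in total)"
        )
    return m


def validate_labels(labels: pd.Series) -> pd.Series:
    """Check that *labels* maps sample ids to TFP/TFN; return the series."""
    if not isinstance(labels, pd.Series):
        raise TypeError("labels must be a pandas Series (sample id -> TFP/TFN)")
    if labels.index.has_duplicates:
        dups = sorted(labels.index[labels.index.duplicated()].unique().astype(str))
        raise ValueError(f"duplicate sample identifiers in labels: {dups}")
    bad = set(labels.unique()) - VALID_LABELS
    if bad:
        raise ValueError(f"invalid labels {sorted(map(str, bad))}; allowed: TFP, TFN")
    return labels


def group_columns(
    m: pd.DataFrame, labels: pd.Series, require_both: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Column positions of TFN and TFP samples of *m*.

    Every labelled sample must exist in the matrix.  Returns
    ``(tfn_positions, tfp_positions)``.
    """
    validate_labels(labels)
    missing = labels.index.difference(m.columns)
    if len(missing):
        raise ValueError(
            f"labelled samples absent from the matrix: {sorted(missing.astype(str))}"
        )
    pos = {s: i for i, s in enumerate(m.columns)}
    tfn = np.array([pos[s] for s in labels.index[labels == TFN]], dtype=int)
    tfp = np.array([pos[s] for s in labels.index[labels == TFP]], dtype=int)
    if require_both and (len(tfn) == 0 or len(tfp) == 0):
        raise ValueError("both TFP and TFN samples are required")
    return tfn, tfp


def rank_within_samples(m: pd.DataFrame) -> pd.DataFrame:
    """Within-sample ranks of genes (the REO substrate).

    Each column of the result ranks the genes of that sample in ascending
    order (1 = lowest expression), with ties averaged.  Ranks are invariant
    under any strictly increasing per-sample transform of the input, which
    is what makes downstream pair statistics platform-free.
    """
    validate_expression(m)
    ranks = rankdata(m.to_numpy(), axis=0, method="average")
    return pd.DataFrame(ranks, index=m.index, columns=m.columns)
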