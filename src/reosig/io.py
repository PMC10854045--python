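"""Readers and writers for expression matrices, labels and probe maps.

Formats are deliberately plain: TSV/CSV with a header row of sample ids and
gene ids in the first column for expression; two-column TSV for labels and
probe maps.  Signature JSON I/O lives in :mod:`reosig.signature`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import VALID_LABELS, validate_expression, validate_labels

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return _SEPS[dialect]


def read_expression(
    path: str | Path, dialect: str | None = None, transpose: bool = False
) -> pd.DataFrame:
    """Read an expression matrix (genes rows x samples columns).

    The first column holds gene ids, the header row sample ids.  Duplicated
    identifiers and non-numeric or non-finite cells are hard errors, with
    the offending ids/coordinates named.  ``transpose=True`` accepts the
    samples-as-rows orientation.
    """
    sep = _sep_for(path, dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    sample_ids = header[1:]
    dup_cols = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup_cols:
        raise ValueError(f"duplicate sample identifiers: {sorted(dup_cols)}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = sample_ids
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate gene identifiers: {dups}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r},"
                f" sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    m = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    m.index.name = None
    if transpose:
        m = m.T
        m.index.name = None
        m.columns.name = None
    return validate_expression(m)


def write_expression(m: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    validate_expression(m)
    m.to_csv(path, sep=_sep_for(path, dialect), index_label="gene_id")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV; labels must be TFP/TFN."""
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if rows.shape[1] != 2:
        raise ValueError(f"labels file must have exactly 2 columns, got {rows.shape[1]}")
    bad = sorted(set(rows[1]) - VALID_LABELS)
    if bad:
        raise ValueError(f"invalid labels {bad}; allowed: TFP, TFN")
    labels = pd.Series(rows[1].to_numpy(), index=rows[0].to_numpy(), name="label")
    return validate_labels(labels)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    validate_labels(labels)
    labels.to_csv(path, sep="\t", header=False)


def read_probe_map(path: str | Path) -> dict[str, set[str]]:
    """Read probe -> gene mappings from a two-column TSV.

    A probe may appear on several rows, or map several genes on one row
    separated by ``///`` (the GEO platform-file convention); either way the
    result is one id set per probe.  Empty gene fields yield empty sets.
    """
    mapping: dict[str, set[str]] = {}
    rows = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if rows.shape[1] != 2:
        raise ValueError(f"probe map must have exactly 2 columns, got {rows.shape[1]}")
    for probe, genes in rows.itertuples(index=False):
        target = mapping.setdefault(probe, set())
        for g in genes.split("///"):
            g = g.strip()
            if g:
                target.add(g)
    return mapping


def collapse_probes(m: pd.DataFrame, probe_map: dict[str, set[str]]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes mapping exactly one gene are kept; several probes for one gene
    are averaged per sample; probes mapping zero or multiple genes are
    dropped.  Missing (NaN) probe measurements are excluded from the
    average of their sample rather than discarding the probe entirely.
    """
    validate_expression(m.fillna(0.0))  # structural checks; NaN handled below
    gene_of: dict[str, str] = {}
    for probe in m.index:
        genes = probe_map.get(probe, set())
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
    if not gene_of:
        raise ValueError("no probes map to exactly one gene; nothing to collapse")
    kept = m.loc[list(gene_of)]
    collapsed = kept.groupby([gene_of[p] for p in kept.index]).mean()
    collapsed.index.name = m.index.name
    if collapsed.isna().to_numpy().any():
        bad = collapsed.index[collapsed.isna().any(axis=1)]
        raise ValueError(
            f"genes with no measured probe in some sample: {sorted(bad.astype(str))}"
        )
    if collapsed.shape[0] < 2:
        raise ValueError("fewer than 2 genes left after collapsing probes")
    return validate_expression(collapsed)
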