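"""Expression matrices: dense gene x sample TSV tables of non-negative values.

Values are FPKM/RSEM-scale abundances; the readers accept any non-negative
numeric table and leave normalisation to upstream quantification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import strip_version
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """One dataset's gene x sample expression table.

    ``values`` is a float DataFrame indexed by gene_id with sample ids as
    columns; construction validates non-negativity and gene uniqueness.
    """

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in {self.dataset_id}: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError(f"non-finite expression values in {self.dataset_id}")
        if arr.size and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value for gene {self.values.index[gi]} "
                f"sample {self.values.columns[si]} in {self.dataset_id}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        return ExpressionMatrix(self.dataset_id, self.values.loc[keep])


def read_expression(tsv_path, dataset_id: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    First row holds sample ids, first column gene ids, remaining cells
    numeric and non-negative. Gene id version suffixes are stripped.
    Malformed cells, ragged rows and duplicate genes raise
    :class:`ParseError` / :class:`ValidationError` naming the offender.
    """
    tsv_path = Path(tsv_path)
    if dataset_id is None:
        dataset_id = tsv_path.stem
    with tsv_path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty expression file", path=tsv_path, line=1)
        cols = header.split("\t")
        sample_ids = cols[1:]
        n = len(sample_ids)
        if n == 0:
            raise ParseError("no sample columns", path=tsv_path, line=1)
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n + 1:
                raise ParseError(
                    f"ragged row: expected {n + 1} fields, found {len(fields)}",
                    path=tsv_path,
                    line=lineno,
                )
            gene_id = strip_version(fields[0])
            vals = np.empty(n, dtype=float)
            for j, cell in enumerate(fields[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell {cell!r} for gene {gene_id} "
                        f"sample {sample_ids[j]}",
                        path=tsv_path,
                        line=lineno,
                    ) from None
                if not math.isfinite(v):
                    raise ParseError(
                        f"non-finite cell {cell!r} for gene {gene_id} "
                        f"sample {sample_ids[j]}",
                        path=tsv_path,
                        line=lineno,
                    )
                if v < 0:
                    raise ValidationError(
                        f"negative expression value {v} for gene {gene_id} "
                        f"sample {sample_ids[j]} ({tsv_path}:{lineno})"
                    )
                vals[j] = v
            if gene_id in set(gene_ids):
                raise ValidationError(
                    f"duplicate gene row {gene_id} ({tsv_path}:{lineno})"
                )
            gene_ids.append(gene_id)
            rows.append(vals)
    if not rows:
        raise ParseError("no gene rows", path=tsv_path, line=2)
    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    values.index.name = "gene_id"
    logger.info(
        "read expression %s: %d genes x %d samples", dataset_id, len(gene_ids), n
    )
    return ExpressionMatrix(dataset_id=dataset_id, values=values)


def write_expression(matrix: ExpressionMatrix, tsv_path) -> None:
    """Write the matrix in the dialect :func:`read_expression` consumes."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(tsv_path, sep="\t", lineterminator="\n")
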