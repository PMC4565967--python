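"""Gene annotation: GTF reading, biotype classification, name resolution.

Genes are classified into exactly two classes, long non-coding RNA
(LNCRNA) and PROTEIN_CODING; every other biotype (pseudogenes, small
RNAs, ...) is dropped. GENCODE distributes lncRNA annotation both as a
separate GTF file and, in the comprehensive GTF, as a family of
``gene_type`` values; both layouts are supported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: GENCODE "long non-coding" gene_type values (the lncRNA GTF categories).
#: Recent releases collapse these into the single value ``lncRNA``.
DEFAULT_LNC_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "antisense_RNA",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
        "3prime_overlapping_ncrna",
        "bidirectional_promoter_lncRNA",
        "macro_lncRNA",
        "non_coding",
        "processed_transcript",
    }
)

_VERSION_RE = re.compile(r"\.\d+$")
_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG…​.8`` -> ``ENSG…``)."""
    return _VERSION_RE.sub("", gene_id)


class BiotypeClass(str, Enum):
    LNCRNA = "LNCRNA"
    PROTEIN_CODING = "PROTEIN_CODING"


class LncRnaSource(str, Enum):
    """Where the lncRNA/protein-coding split comes from."""

    SEPARATE_GTF = "separate_gtf"
    BIOTYPE_ATTRIBUTE = "biotype_attribute"


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    biotype_class: BiotypeClass


@dataclass
class GeneCatalog:
    """All retained genes with an id index and a (possibly ambiguous) symbol index."""

    records: list[GeneRecord]
    id_index: dict[str, GeneRecord] = field(repr=False)
    symbol_index: dict[str, list[GeneRecord]] = field(repr=False)

    @classmethod
    def from_records(cls, records: Iterable[GeneRecord]) -> "GeneCatalog":
        id_index: dict[str, GeneRecord] = {}
        symbol_index: dict[str, list[GeneRecord]] = {}
        out: list[GeneRecord] = []
        for rec in records:
            if not rec.gene_id:
                raise ValidationError("empty gene_id in catalog record")
            if rec.gene_id in id_index:
                if id_index[rec.gene_id].biotype_class != rec.biotype_class:
                    raise ValidationError(
                        f"gene {rec.gene_id} classified as both "
                        f"{id_index[rec.gene_id].biotype_class.value} and {rec.biotype_class.value}"
                    )
                continue
            id_index[rec.gene_id] = rec
            symbol_index.setdefault(rec.symbol, []).append(rec)
            out.append(rec)
        return cls(records=out, id_index=id_index, symbol_index=symbol_index)

    def __len__(self) -> int:
        return len(self.records)

    def ids_of_class(self, biotype_class: BiotypeClass) -> set[str]:
        return {r.gene_id for r in self.records if r.biotype_class is biotype_class}

    @property
    def lncrna_ids(self) -> set[str]:
        return self.ids_of_class(BiotypeClass.LNCRNA)

    @property
    def protein_coding_ids(self) -> set[str]:
        return self.ids_of_class(BiotypeClass.PROTEIN_CODING)


def _parse_attributes(attr_block: str) -> dict[str, str]:
    return {k: v for k, v in _ATTR_RE.findall(attr_block)}


def iter_gtf_genes(path) -> Iterator[tuple[str, str, str]]:
    """Yield (gene_id, symbol, gene_type) per GTF data line, version-stripped.

    All feature rows are scanned (gene, transcript, exon, ...); callers
    deduplicate by gene_id. Raises :class:`ParseError` with the offending
    line number on malformed rows.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, found {len(fields)}",
                    path=path,
                    line=lineno,
                )
            attrs = _parse_attributes(fields[8])
            gene_id = attrs.get("gene_id", "")
            if not gene_id:
                raise ParseError("missing gene_id attribute", path=path, line=lineno)
            gene_id = strip_version(gene_id)
            symbol = attrs.get("gene_name", gene_id)
            gene_type = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            yield gene_id, symbol, gene_type


def read_gene_catalog(
    gtf_path,
    lncrna_source: LncRnaSource | str = LncRnaSource.BIOTYPE_ATTRIBUTE,
    lncrna_gtf_path=None,
    lnc_biotypes: frozenset[str] = DEFAULT_LNC_BIOTYPES,
) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from GENCODE-style GTF annotation.

    Parameters
    ----------
    gtf_path
        Main annotation GTF. In ``biotype_attribute`` mode this is the only
        input and genes are classified on their ``gene_type`` attribute. In
        ``separate_gtf`` mode it contributes the protein-coding genes only.
    lncrna_source
        ``"biotype_attribute"`` (default) or ``"separate_gtf"``.
    lncrna_gtf_path
        The dedicated lncRNA GTF; required in ``separate_gtf`` mode, where
        every gene it contains is classified LNCRNA regardless of attribute.
    lnc_biotypes
        The ``gene_type`` values treated as long non-coding in
        ``biotype_attribute`` mode.
    """
    lncrna_source = LncRnaSource(lncrna_source)
    records: dict[str, GeneRecord] = {}
    n_seen = 0

    if lncrna_source is LncRnaSource.SEPARATE_GTF:
        if lncrna_gtf_path is None:
            raise ValidationError("separate_gtf mode requires lncrna_gtf_path")
        for gene_id, symbol, _ in iter_gtf_genes(lncrna_gtf_path):
            n_seen += 1
            records.setdefault(
                gene_id, GeneRecord(gene_id, symbol, BiotypeClass.LNCRNA)
            )
        for gene_id, symbol, gene_type in iter_gtf_genes(gtf_path):
            n_seen += 1
            if gene_type != "protein_coding":
                continue
            if gene_id in records:
                # lncRNA file is authoritative on conflicts
                if records[gene_id].biotype_class is BiotypeClass.LNCRNA:
                    logger.warning(
                        "gene %s present in both GTFs; keeping lncRNA classification",
                        gene_id,
                    )
                continue
            records[gene_id] = GeneRecord(gene_id, symbol, BiotypeClass.PROTEIN_CODING)
    else:
        for gene_id, symbol, gene_type in iter_gtf_genes(gtf_path):
            n_seen += 1
            if gene_id in records:
                continue
            if gene_type == "protein_coding":
                records[gene_id] = GeneRecord(gene_id, symbol, BiotypeClass.PROTEIN_CODING)
            elif gene_type in lnc_biotypes:
                records[gene_id] = GeneRecord(gene_id, symbol, BiotypeClass.LNCRNA)

    if not records:
        raise ValidationError(
            f"no lncRNA or protein-coding genes retained from {gtf_path}"
        )
    catalog = GeneCatalog.from_records(records.values())
    logger.info(
        "gene catalog: %d rows scanned, %d genes retained (%d lncRNA, %d protein-coding)",
        n_seen,
        len(catalog),
        len(catalog.lncrna_ids),
        len(catalog.protein_coding_ids),
    )
    return catalog


def resolve_genes(
    names: Iterable[str], catalog: GeneCatalog
) -> tuple[list[str], list[str], list[str]]:
    """Resolve user-supplied names (Ensembl ids or symbols) to gene ids.

    Exact gene_id match wins over symbol match; a symbol shared by several
    genes is reported as ambiguous, never expanded. Returns
    ``(resolved_gene_ids, unresolved_names, ambiguous_names)``.
    """
    resolved: list[str] = []
    unresolved: list[str] = []
    ambiguous: list[str] = []
    for name in names:
        key = strip_version(name)
        if key in catalog.id_index:
            resolved.append(key)
            continue
        hits = catalog.symbol_index.get(name, [])
        if len(hits) == 1:
            resolved.append(hits[0].gene_id)
        elif len(hits) > 1:
            ambiguous.append(name)
        else:
            unresolved.append(name)
    return resolved, unresolved, ambiguous
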