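"""Gene-set collections in Broad GMT dialect (term, description, members...)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .catalog import strip_version
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


class GeneSetCategory(str, Enum):
    GO_BP = "GO_BP"
    GO_CC = "GO_CC"
    GO_MF = "GO_MF"
    KEGG = "KEGG"


@dataclass
class GeneSetCollection:
    """Named terms mapped to (term_name, member gene_id set) for one category."""

    category: GeneSetCategory
    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {term_id} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def all_members(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.terms.values():
            out |= members
        return out


def read_gmt(gmt_path, category: GeneSetCategory | str) -> GeneSetCollection:
    """Read a GMT file: one term per line, ``id<TAB>description<TAB>members...``.

    Members are version-stripped and deduplicated; lines with fewer than
    three fields raise :class:`ParseError` with the line number.
    """
    category = GeneSetCategory(category)
    gmt_path = Path(gmt_path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with gmt_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated fields, found {len(fields)}",
                    path=gmt_path,
                    line=lineno,
                )
            term_id, term_name = fields[0], fields[1]
            if term_id in terms:
                raise ParseError(
                    f"duplicate term id {term_id}", path=gmt_path, line=lineno
                )
            members = frozenset(strip_version(g) for g in fields[2:] if g)
            if not members:
                raise ParseError(
                    f"term {term_id} has no members", path=gmt_path, line=lineno
                )
            terms[term_id] = (term_name, members)
    logger.info("read GMT %s: %d terms (%s)", gmt_path.name, len(terms), category.value)
    return GeneSetCollection(category=category, terms=terms)


def write_gmt(collection: GeneSetCollection, gmt_path) -> None:
    """Write a canonicalized GMT (terms in insertion order, members sorted)."""
    with Path(gmt_path).open("w") as fh:
        for term_id, (term_name, members) in collection.terms.items():
            fh.write("\t".join([term_id, term_name, *sorted(members)]) + "\n")
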