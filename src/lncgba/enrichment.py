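"""Hypergeometric over-representation analysis of CEG sets.

For a universe of N background genes of which K carry a term annotation,
and a CEG set of n universe genes of which k carry it, the enrichment
p-value is the upper tail

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n),

evaluated through the survival function of the hypergeometric
distribution (computed in log space internally). Only over-representation
is tested. Bonferroni and Benjamini-Hochberg corrections are applied per
collection (GO BP/CC/MF and KEGG are separate test families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)


class Correction(str, Enum):
    BONFERRONI = "bonferroni"
    BH = "bh"
    NONE = "none"


class UniverseMode(str, Enum):
    #: background = expressed protein-coding genes carrying >= 1 annotation
    ANNOTATED_EXPRESSED = "annotated"
    #: background = all expressed protein-coding genes
    ALL_EXPRESSED = "all"


@dataclass(frozen=True)
class EnrichmentConfig:
    correction: Correction = Correction.BH
    significance_threshold: float = 0.05
    universe_mode: UniverseMode = UniverseMode.ANNOTATED_EXPRESSED
    min_term_size: int = 5
    max_term_size: int = 1000

    def __post_init__(self):
        if not (0 < self.significance_threshold <= 1):
            raise ValidationError("significance_threshold must lie in (0, 1]")
        if self.min_term_size < 1 or self.min_term_size > self.max_term_size:
            raise ValidationError("need 1 <= min_term_size <= max_term_size")


@dataclass
class EnrichmentResult:
    """One tested term with its overlap counts and p-values.

    ``k`` CEGs overlap a term of ``K`` universe genes; the CEG set
    contributes ``n`` universe genes out of ``N``.
    """

    term_id: str
    term_name: str
    category: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adjusted: float
    overlap_genes: frozenset[str]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid universe counts K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    # sf(k-1) == P(X >= k)
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def adjust_pvalues(
    p_values: Sequence[float], method: Correction | str
) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    Bonferroni: ``min(1, m * p)``. BH: step-up adjusted values (running
    minimum from the largest rank). NONE: identity.
    """
    method = Correction(method)
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if method is Correction.NONE:
        return p.copy()
    sm_method = "bonferroni" if method is Correction.BONFERRONI else "fdr_bh"
    return multipletests(p, method=sm_method)[1]


def enrich(
    ceg_set: Iterable[str],
    collection: GeneSetCollection,
    expressed_pcgs: Iterable[str],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Test a CEG set for over-represented terms of one collection.

    The background universe is either all expressed protein-coding genes
    or their annotated subset (default). Terms are restricted to the
    universe, term-size bounds applied after restriction, one test per
    surviving term, correction within this collection only. The returned
    list holds the significant terms (adjusted p, or raw p when no
    correction is selected) sorted by ascending raw p; zero-overlap terms
    are never significant.
    """
    config = config or EnrichmentConfig()
    ceg_set = set(ceg_set)
    expressed = set(expressed_pcgs)

    stray = ceg_set - expressed
    if stray:
        logger.warning(
            "%d CEGs outside the expressed background dropped from enrichment",
            len(stray),
        )
        ceg_set &= expressed

    if config.universe_mode is UniverseMode.ANNOTATED_EXPRESSED:
        universe = expressed & collection.all_members
    else:
        universe = expressed
    N = len(universe)
    genes = ceg_set & universe
    n = len(genes)
    if N == 0 or n == 0:
        logger.warning(
            "empty universe or CEG set for %s enrichment; no terms tested",
            collection.category.value,
        )
        return []

    rows: list[tuple[str, str, int, frozenset[str]]] = []
    p_raw: list[float] = []
    for term_id in sorted(collection.terms):
        term_name, members = collection.terms[term_id]
        members = frozenset(members & universe)
        K = len(members)
        if K < config.min_term_size or K > config.max_term_size:
            continue
        overlap = frozenset(genes & members)
        k = len(overlap)
        rows.append((term_id, term_name, K, overlap))
        p_raw.append(hypergeom_pvalue(k, K, n, N))

    if not rows:
        logger.warning(
            "no %s terms within size bounds [%d, %d]",
            collection.category.value,
            config.min_term_size,
            config.max_term_size,
        )
        return []

    p_adj = adjust_pvalues(p_raw, config.correction)
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=term_name,
            category=collection.category.value,
            k=len(overlap),
            n=n,
            K=K,
            N=N,
            p_raw=p,
            p_adjusted=float(pa),
            overlap_genes=overlap,
        )
        for (term_id, term_name, K, overlap), p, pa in zip(rows, p_raw, p_adj)
    ]
    p_filter = (
        (lambda r: r.p_raw)
        if config.correction is Correction.NONE
        else (lambda r: r.p_adjusted)
    )
    significant = [
        r
        for r in results
        if r.k > 0 and p_filter(r) <= config.significance_threshold
    ]
    significant.sort(key=lambda r: (r.p_raw, r.term_id))
    logger.info(
        "%s enrichment: %d terms tested, %d significant at %.3g (%s)",
        collection.category.value,
        len(results),
        len(significant),
        config.significance_threshold,
        config.correction.value,
    )
    return significant


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results in the standard report layout."""
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in results],
        }
    )


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(
        path, sep="\t", index=False, float_format="%.8g", lineterminator="\n"
    )
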