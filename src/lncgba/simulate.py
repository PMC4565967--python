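"""Synthetic expression datasets with planted co-expression and enrichment.

The generator emulates the matched lncRNA/protein-coding profiles a
co-expression screen consumes. Each lncRNA is a latent standard Gaussian
across samples; each of its target genes is built as

    target = rho * lnc_latent + sqrt(1 - rho^2) * noise

on the latent scale and every latent is mapped through ``exp`` to a
lognormal, FPKM-like non-negative scale. Correlation is planted on the
latent (Gaussian) scale, where the population Spearman correlation of a
bivariate normal with correlation rho is ``(6/pi) * asin(rho / 2)``;
the monotone ``exp`` map preserves rank-based association exactly while
Pearson correlation is only approximately preserved.

The gene-set collection plants one term per lncRNA (a fraction of its
targets plus random non-target fillers) among decoy terms drawn only
from non-target genes, so recovery of the planted term is unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import BiotypeClass, GeneCatalog, GeneRecord
from .coexpression import spearman_assoc
from .errors import ValidationError
from .expression import ExpressionMatrix, write_expression
from .genesets import GeneSetCategory, GeneSetCollection, write_gmt

logger = logging.getLogger(__name__)


def latent_to_rank_correlation(rho: float) -> float:
    """Population Spearman correlation implied by latent Gaussian rho."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


@dataclass(frozen=True)
class SimulationParams:
    """Study-scale defaults: a 50-sample dataset, two query lncRNAs with 50
    targets each at latent correlation 0.8, and 2000 unassociated genes."""

    n_samples: int = 50
    n_lncrnas: int = 2
    n_pcgs: int = 2100
    targets_per_lnc: int = 50
    target_correlation: float = 0.8
    noise_model: str = "LOGNORMAL"
    #: total GMT terms; the first n_lncrnas are planted, the rest decoys
    n_terms: int = 22
    #: fraction of a lncRNA's targets placed in its planted term
    planted_term_overlap: float = 0.8
    seed: int = 0
    dataset_id: str = "sim"
    category: GeneSetCategory = GeneSetCategory.GO_BP

    def __post_init__(self):
        if self.noise_model != "LOGNORMAL":
            raise ValidationError(f"unknown noise model {self.noise_model}")
        if self.targets_per_lnc * self.n_lncrnas > self.n_pcgs:
            raise ValidationError(
                "targets_per_lnc * n_lncrnas exceeds n_pcgs; infeasible"
            )
        if not (0 < self.target_correlation < 1):
            raise ValidationError("target_correlation must lie in (0, 1)")
        if not (0 < self.planted_term_overlap <= 1):
            raise ValidationError("planted_term_overlap must lie in (0, 1]")
        if self.n_terms < self.n_lncrnas:
            raise ValidationError("need at least one term per lncRNA")
        if min(self.n_samples, self.n_lncrnas, self.n_pcgs) < 1:
            raise ValidationError("counts must be positive")


@dataclass
class GroundTruth:
    planted_edges: set[tuple[str, str]]
    #: planted term per lncRNA
    planted_terms: dict[str, str]
    achieved_correlations: dict[tuple[str, str], float] = field(repr=False)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


def simulate_dataset(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, GeneCatalog, GeneSetCollection, GroundTruth]:
    """Generate one dataset bundle, fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n, rho = params.n_samples, params.target_correlation

    lnc_ids = _gene_ids("SIMLNC", params.n_lncrnas)
    pcg_ids = _gene_ids("SIMPCG", params.n_pcgs)
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]

    latent = np.empty((params.n_lncrnas + params.n_pcgs, n))
    lnc_latent = rng.standard_normal((params.n_lncrnas, n))
    latent[: params.n_lncrnas] = lnc_latent

    targets: dict[str, list[str]] = {}
    planted_edges: set[tuple[str, str]] = set()
    row = params.n_lncrnas
    pcg_cursor = 0
    for i, lnc in enumerate(lnc_ids):
        targets[lnc] = pcg_ids[pcg_cursor : pcg_cursor + params.targets_per_lnc]
        for pcg in targets[lnc]:
            noise = rng.standard_normal(n)
            latent[row] = rho * lnc_latent[i] + math.sqrt(1 - rho * rho) * noise
            planted_edges.add((lnc, pcg))
            row += 1
        pcg_cursor += params.targets_per_lnc
    n_null = params.n_pcgs - pcg_cursor
    latent[row:] = rng.standard_normal((n_null, n))

    values = pd.DataFrame(np.exp(latent), index=lnc_ids + pcg_ids, columns=sample_ids)
    values.index.name = "gene_id"
    matrix = ExpressionMatrix(dataset_id=params.dataset_id, values=values)

    catalog = GeneCatalog.from_records(
        [GeneRecord(g, f"LNCG{i + 1}", BiotypeClass.LNCRNA) for i, g in enumerate(lnc_ids)]
        + [
            GeneRecord(g, f"PCG{i + 1}", BiotypeClass.PROTEIN_CODING)
            for i, g in enumerate(pcg_ids)
        ]
    )

    # gene sets: one planted term per lncRNA + decoys from non-target genes
    non_targets = pcg_ids[pcg_cursor:]
    if not non_targets:
        raise ValidationError("no non-target genes left for decoy terms")
    term_size = max(5, params.targets_per_lnc)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_terms: dict[str, str] = {}
    for i, lnc in enumerate(lnc_ids):
        if targets[lnc]:
            n_in = max(1, round(params.planted_term_overlap * len(targets[lnc])))
            chosen = list(rng.choice(targets[lnc], size=n_in, replace=False))
        else:
            chosen = []
        n_fill = max(0, term_size - len(chosen))
        fillers = list(
            rng.choice(non_targets, size=min(n_fill, len(non_targets)), replace=False)
        )
        term_id = f"TERM_PLANTED_{i + 1:02d}"
        terms[term_id] = (f"planted targets of {lnc}", frozenset(chosen + fillers))
        planted_terms[lnc] = term_id
    for j in range(params.n_terms - params.n_lncrnas):
        members = rng.choice(
            non_targets, size=min(term_size, len(non_targets)), replace=False
        )
        terms[f"TERM_DECOY_{j + 1:02d}"] = (f"decoy set {j + 1}", frozenset(members))
    collection = GeneSetCollection(category=params.category, terms=terms)

    achieved: dict[tuple[str, str], float] = {}
    for lnc, pcg in sorted(planted_edges):
        r, _ = spearman_assoc(
            matrix.values.loc[lnc].to_numpy(), matrix.values.loc[pcg].to_numpy()
        )
        achieved[(lnc, pcg)] = r

    logger.info(
        "simulated %s: %d genes x %d samples, %d planted edges, %d terms",
        params.dataset_id,
        len(values),
        n,
        len(planted_edges),
        len(terms),
    )
    return matrix, catalog, collection, GroundTruth(planted_edges, planted_terms, achieved)


def write_fixture(
    bundle: tuple[ExpressionMatrix, GeneCatalog, GeneSetCollection, GroundTruth],
    out_dir,
    params: SimulationParams | None = None,
) -> dict[str, Path]:
    """Write a bundle in the exact dialects the readers consume.

    Produces ``expression.tsv``, ``genes.gtf``, ``sets.gmt``,
    ``truth_edges.tsv`` and ``truth_terms.tsv`` (plus ``params.yaml``
    when the parameters are supplied); returns the paths by role.
    """
    matrix, catalog, collection, truth = bundle
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "gtf": out_dir / "genes.gtf",
        "gmt": out_dir / "sets.gmt",
        "truth_edges": out_dir / "truth_edges.tsv",
        "truth_terms": out_dir / "truth_terms.tsv",
    }
    write_expression(matrix, paths["expression"])
    biotype = {
        BiotypeClass.LNCRNA: "lncRNA",
        BiotypeClass.PROTEIN_CODING: "protein_coding",
    }
    with paths["gtf"].open("w") as fh:
        for i, rec in enumerate(catalog.records):
            start = 1000 * i + 1
            attrs = (
                f'gene_id "{rec.gene_id}"; gene_name "{rec.symbol}"; '
                f'gene_type "{biotype[rec.biotype_class]}";'
            )
            fh.write(
                f"chr1\tsim\tgene\t{start}\t{start + 500}\t.\t+\t.\t{attrs}\n"
            )
    write_gmt(collection, paths["gmt"])
    pd.DataFrame(
        [
            {"lnc_id": l, "pcg_id": p, "spearman_r": truth.achieved_correlations[(l, p)]}
            for l, p in sorted(truth.planted_edges)
        ]
    ).to_csv(paths["truth_edges"], sep="\t", index=False, float_format="%.8g", lineterminator="\n")
    pd.DataFrame(
        [{"lnc_id": l, "term_id": t} for l, t in sorted(truth.planted_terms.items())]
    ).to_csv(paths["truth_terms"], sep="\t", index=False, lineterminator="\n")
    if params is not None:
        pdict = {
            k: (v.value if isinstance(v, GeneSetCategory) else v)
            for k, v in params.__dict__.items()
        }
        paths["params"] = out_dir / "params.yaml"
        paths["params"].write_text(yaml.safe_dump(pdict, sort_keys=True))
    return paths
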