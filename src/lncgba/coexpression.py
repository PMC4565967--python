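"""lncRNA-mRNA association statistics and co-expressed gene (CEG) extraction.

Two association methods are offered, mirroring common practice in
co-expression screens of RNA-Seq profiles:

* **Simple linear regression** of protein-coding expression on lncRNA
  expression (the lncRNA as putative regulator). The slope
  ``b = Sxy / Sxx`` is tested with a two-sided t statistic on ``n - 2``
  degrees of freedom; for simple OLS this p-value is algebraically
  identical to the two-sided Pearson correlation test. A ``log2(x + 1)``
  transform is applied by default to tame the skew of FPKM-scale values.

* **Spearman rank correlation**: Pearson correlation of mid-ranked values
  (ties receive the mean rank), with a two-sided p-value from
  ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2`` df. The
  t-approximation is used at every n; it is coarse below roughly ten
  samples.

A protein-coding gene is a CEG of a lncRNA in one dataset when its
association record passes every configured threshold: ``|r| >=
coef_threshold`` (correlation-scale effect, so a single threshold serves
both methods) and ``p <= p_threshold``. Either threshold may be left
unset, but not both.

The model/results split follows the convention of statistical modelling
packages: :class:`CoexpressionModel` holds the data and configuration,
``fit()`` returns a :class:`CoexpressionResults` carrying the association
table, CEG extraction, and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


class Method(str, Enum):
    REGRESSION = "regression"
    SPEARMAN = "spearman"


class ExpressionFilterMode(str, Enum):
    #: keep gene iff mean expression > threshold
    MEAN = "mean"
    #: keep gene iff expression > threshold in >= 50% of samples
    FRACTION = "fraction"


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of one co-expression analysis.

    Defaults follow the conventional screen settings: expressed genes are
    those above 0.001 on the FPKM/RSEM scale, association is assessed by
    linear regression, and CEGs require slope significance p <= 0.01.
    """

    method: Method = Method.REGRESSION
    expression_threshold: float = 0.001
    expression_filter_mode: ExpressionFilterMode = ExpressionFilterMode.MEAN
    coef_threshold: float | None = None
    p_threshold: float | None = 0.01
    log_transform: bool = True

    def __post_init__(self):
        if self.expression_threshold < 0:
            raise ValidationError("expression_threshold must be non-negative")
        if self.coef_threshold is not None and self.coef_threshold < 0:
            raise ValidationError("coef_threshold must be non-negative")
        if self.p_threshold is not None and not (0 < self.p_threshold <= 1):
            raise ValidationError("p_threshold must lie in (0, 1]")

    def require_thresholds(self) -> None:
        if self.coef_threshold is None and self.p_threshold is None:
            raise ValidationError(
                "CEG extraction needs at least one of coef_threshold / p_threshold"
            )


@dataclass
class CEGSet:
    """The co-expressed protein-coding genes of one lncRNA in one dataset."""

    lnc_id: str
    dataset_id: str
    members: frozenset[str]
    #: association records that passed the active thresholds
    provenance: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# elementary association statistics


def _check_pair(x: np.ndarray, y: np.ndarray) -> int:
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("association inputs must be 1-D vectors")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError("association needs at least 3 samples")
    return len(x)


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of the correlation t statistic; |r| == 1 maps to p = 0."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, np.minimum(p, 1.0))


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value.

    Returns ``(rho, p_value)``. Constant input vectors leave the
    correlation undefined and raise :class:`ValidationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson(rx, ry)
    return float(rho), float(_t_pvalue(rho, n))


def regression_assoc(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: ``(slope, r, p_value)``.

    ``slope = Sxy / Sxx``; the two-sided slope t-test p on ``n - 2`` df
    equals the Pearson correlation test p. A constant predictor raises
    :class:`ValidationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValidationError("regression undefined for constant predictor")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    if syy == 0:
        # flat response: slope 0, no evidence of association
        return slope, 0.0, 1.0
    r = sxy / np.sqrt(sxx * syy)
    return slope, float(r), float(_t_pvalue(r, n))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _assoc_many(
    x: np.ndarray, ymat: np.ndarray, method: Method
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised association of one predictor against many response rows.

    Returns ``(coefficient, r, p_value, valid)`` over the rows of
    ``ymat``; rows with zero variance are flagged invalid instead of
    erroring, so one flat gene cannot abort a genome-wide screen.
    """
    n = len(x)
    if method is Method.SPEARMAN:
        x = stats.rankdata(x)
        ymat = stats.rankdata(ymat, axis=1)
    xc = x - x.mean()
    yc = ymat - ymat.mean(axis=1, keepdims=True)
    sxx = float(xc @ xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = yc @ xc
    valid = syy > 0
    if sxx == 0:
        raise ValidationError("predictor is constant across samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, sxy / np.sqrt(sxx * np.where(valid, syy, 1.0)), np.nan)
    r = np.clip(r, -1.0, 1.0)
    p = _t_pvalue(r, n)
    coef = r if method is Method.SPEARMAN else sxy / sxx
    return coef, r, p, valid


# ---------------------------------------------------------------------------
# expression filtering


def filter_expressed(matrix: ExpressionMatrix, config: AnalysisConfig) -> ExpressionMatrix:
    """Drop genes below the expression threshold; samples are untouched.

    MEAN mode keeps a gene iff its row mean exceeds the threshold;
    FRACTION mode iff it exceeds the threshold in at least half the
    samples. Removing every gene is an error.
    """
    arr = matrix.values.to_numpy()
    thr = config.expression_threshold
    if config.expression_filter_mode is ExpressionFilterMode.MEAN:
        keep = arr.mean(axis=1) > thr
    else:
        keep = (arr > thr).mean(axis=1) >= 0.5
    if not keep.any():
        raise ValidationError(
            f"expression filter removed every gene of {matrix.dataset_id} "
            f"(threshold {thr}, mode {config.expression_filter_mode.value})"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "%s: expression filter dropped %d/%d genes",
            matrix.dataset_id,
            dropped,
            len(keep),
        )
    return ExpressionMatrix(matrix.dataset_id, matrix.values.loc[keep])


# ---------------------------------------------------------------------------
# model / results


ASSOC_COLUMNS = ["lnc_id", "pcg_id", "method", "coefficient", "r", "p_value", "n_samples"]


class CoexpressionModel:
    """Per-pair association model between lncRNAs and protein-coding genes.

    Parameters
    ----------
    lnc_matrix, pcg_matrix
        Expression matrices of the same dataset sharing identical sample
        ids in identical order.
    lnc_ids
        The lncRNAs to screen; defaults to every gene of ``lnc_matrix``.
    config
        :class:`AnalysisConfig`; governs filtering, method and thresholds.
    """

    def __init__(
        self,
        lnc_matrix: ExpressionMatrix,
        pcg_matrix: ExpressionMatrix,
        lnc_ids: Iterable[str] | None = None,
        config: AnalysisConfig | None = None,
    ):
        if lnc_matrix.sample_ids != pcg_matrix.sample_ids:
            raise ValidationError(
                "lncRNA and protein-coding matrices must share identical "
                "sample ids in identical order"
            )
        if lnc_matrix.dataset_id != pcg_matrix.dataset_id:
            raise ValidationError("matrices belong to different datasets")
        self.lnc_matrix = lnc_matrix
        self.pcg_matrix = pcg_matrix
        self.lnc_ids = list(lnc_ids) if lnc_ids is not None else lnc_matrix.gene_ids
        self.config = config or AnalysisConfig()
        missing = [g for g in self.lnc_ids if g not in set(lnc_matrix.gene_ids)]
        if missing:
            raise ValidationError(f"lncRNAs absent from matrix: {missing[:5]}")

    @classmethod
    def from_dataframes(
        cls,
        lnc_values: pd.DataFrame,
        pcg_values: pd.DataFrame,
        dataset_id: str = "dataset",
        **kwargs,
    ) -> "CoexpressionModel":
        return cls(
            ExpressionMatrix(dataset_id, lnc_values),
            ExpressionMatrix(dataset_id, pcg_values),
            **kwargs,
        )

    def fit(self) -> "CoexpressionResults":
        cfg = self.config
        lnc_expr = filter_expressed(self.lnc_matrix, cfg)
        pcg_expr = filter_expressed(self.pcg_matrix, cfg)

        kept_lnc = [g for g in self.lnc_ids if g in set(lnc_expr.gene_ids)]
        for g in self.lnc_ids:
            if g not in set(kept_lnc):
                logger.warning(
                    "lncRNA %s below expression threshold in %s; excluded",
                    g,
                    self.lnc_matrix.dataset_id,
                )

        pcg_arr = pcg_expr.values.to_numpy()
        if cfg.method is Method.REGRESSION and cfg.log_transform:
            pcg_arr = np.log2(pcg_arr + 1.0)
        pcg_ids = np.asarray(pcg_expr.gene_ids)
        n = pcg_expr.n_samples

        frames: list[pd.DataFrame] = []
        for lnc in kept_lnc:
            x = lnc_expr.values.loc[lnc].to_numpy()
            if cfg.method is Method.REGRESSION and cfg.log_transform:
                x = np.log2(x + 1.0)
            coef, r, p, valid = _assoc_many(x, pcg_arr, cfg.method)
            n_invalid = int((~valid).sum())
            if n_invalid:
                logger.info(
                    "%s: skipped %d constant protein-coding genes for %s",
                    pcg_expr.dataset_id,
                    n_invalid,
                    lnc,
                )
            frames.append(
                pd.DataFrame(
                    {
                        "lnc_id": lnc,
                        "pcg_id": pcg_ids[valid],
                        "method": cfg.method.value,
                        "coefficient": coef[valid],
                        "r": r[valid],
                        "p_value": p[valid],
                        "n_samples": n,
                    }
                )
            )
        associations = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=ASSOC_COLUMNS)
        )
        logger.info(
            "%s: %d association records over %d lncRNAs x %d expressed "
            "protein-coding genes",
            self.lnc_matrix.dataset_id,
            len(associations),
            len(kept_lnc),
            len(pcg_ids),
        )
        return CoexpressionResults(
            associations=associations,
            config=cfg,
            dataset_id=self.lnc_matrix.dataset_id,
            lnc_ids=kept_lnc,
            expressed_pcgs=frozenset(pcg_expr.gene_ids),
            n_samples=n,
        )


@dataclass
class CoexpressionResults:
    """Fitted association table plus CEG extraction and reporting."""

    associations: pd.DataFrame
    config: AnalysisConfig
    dataset_id: str
    lnc_ids: list[str]
    expressed_pcgs: frozenset[str]
    n_samples: int

    def ceg_sets(
        self,
        coef_threshold: float | None = None,
        p_threshold: float | None = None,
    ) -> dict[str, CEGSet]:
        """Threshold the association table into one CEGSet per lncRNA.

        Thresholds default to the analysis config; each configured
        threshold must pass (conjunction) and the coefficient threshold
        applies to the correlation-scale effect ``r``.
        """
        cfg = self.config
        if coef_threshold is not None or p_threshold is not None:
            cfg = replace(
                cfg, coef_threshold=coef_threshold, p_threshold=p_threshold
            )
        cfg.require_thresholds()
        mask = pd.Series(True, index=self.associations.index)
        if cfg.coef_threshold is not None:
            mask &= self.associations["r"].abs() >= cfg.coef_threshold
        if cfg.p_threshold is not None:
            mask &= self.associations["p_value"] <= cfg.p_threshold
        passed = self.associations[mask]
        out: dict[str, CEGSet] = {}
        for lnc in self.lnc_ids:
            prov = passed[passed["lnc_id"] == lnc].reset_index(drop=True)
            prov = prov.assign(dataset_id=self.dataset_id)
            out[lnc] = CEGSet(
                lnc_id=lnc,
                dataset_id=self.dataset_id,
                members=frozenset(prov["pcg_id"]),
                provenance=prov,
            )
        return out

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Co-expression screen",
            "====================",
            f"dataset:            {self.dataset_id}",
            f"method:             {cfg.method.value}",
            f"samples:            {self.n_samples}",
            f"lncRNAs screened:   {len(self.lnc_ids)}",
            f"expressed PCGs:     {len(self.expressed_pcgs)}",
            f"association records: {len(self.associations)}",
            f"coef threshold:     {cfg.coef_threshold}",
            f"p threshold:        {cfg.p_threshold}",
        ]
        if cfg.coef_threshold is not None or cfg.p_threshold is not None:
            for lnc, ceg in self.ceg_sets().items():
                lines.append(f"  CEGs[{lnc}]: {len(ceg.members)}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the association table: lnc_id, pcg_id, method, coefficient, r, p_value, n_samples."""
        self.associations.to_csv(
            path, sep="\t", index=False, float_format="%.8g", lineterminator="\n"
        )


def compute_cegs(
    lnc_matrix: ExpressionMatrix,
    pcg_matrix: ExpressionMatrix,
    lnc_ids: Iterable[str],
    config: AnalysisConfig,
) -> tuple[dict[str, CEGSet], CoexpressionResults]:
    """Screen ``lnc_ids`` against all expressed protein-coding genes.

    Convenience wrapper: builds a :class:`CoexpressionModel`, fits it, and
    extracts CEG sets at the configured thresholds. Each dataset is
    analysed independently; call once per dataset.
    """
    config.require_thresholds()
    model = CoexpressionModel(lnc_matrix, pcg_matrix, list(lnc_ids), config)
    results = model.fit()
    return results.ceg_sets(), results
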