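"""Quality control, normalization and differential expression.

The pipeline stage that turns a raw two-condition UMI count matrix into
per-gene fold changes and FDR-adjusted Wilcoxon p-values, plus the
Fisher exact test that asks whether one direction of dysregulation is
enriched for ferroptosis drivers or suppressors.

Conventions follow the common single-cell toolchain: cells are filtered
before genes, normalization is library-size scaling followed by
log1p, fold changes use the pseudocount form
``log2((mean_a + 1) / (mean_b + 1))`` on de-logged normalized values,
and multiple testing is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, Layer, RegulatorCatalog, Role

logger = logging.getLogger(__name__)

#: Per-group size above which the Wilcoxon rank-sum test switches from
#: exact enumeration to the tie-corrected normal approximation.
EXACT_WILCOXON_MAX_N = 25


@dataclass
class QCThresholds:
    """Quality-control cutoffs for a raw UMI count matrix.

    Defaults: genes kept only if expressed in at least 3 cells; cells
    kept only if they cover at least 200 genes and at most 20% of their
    UMIs come from mitochondrial genes (symbols starting with ``MT-``).
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class DifferentialResult:
    """Per-gene differential-expression table.

    Columns: gene, log2_fc, p_value, fdr, pct_in_a, pct_in_b, direction
    (``up`` / ``down`` / ``ns``).  ``group_a`` is the group of interest
    and ``group_b`` the reference, so positive log2_fc means higher in
    ``group_a``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    lfc_threshold: float
    fdr_threshold: float

    COLUMNS = ("gene", "log2_fc", "p_value", "fdr", "pct_in_a", "pct_in_b", "direction")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def genes_with_direction(self, direction: str) -> list[str]:
        return list(self.table.loc[self.table["direction"] == direction, "gene"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class EnrichmentTestResult:
    """One-sided Fisher exact enrichment test on a 2x2 table."""

    odds_ratio: float
    p_value: float
    contingency: np.ndarray
    continuity_corrected: bool = False
    universe_size: int = 0


def qc_filter(
    matrix: ExpressionMatrix, thresholds: QCThresholds | None = None
) -> ExpressionMatrix:
    """Apply cell- then gene-level QC to a raw count matrix.

    Cells failing either the minimum-genes or maximum-mitochondrial-
    fraction rule are removed first; genes expressed (count > 0) in
    fewer than ``min_cells_per_gene`` of the *surviving* cells are then
    removed.  The cell-then-gene order is fixed.
    """
    if matrix.layer is not Layer.RAW_COUNTS:
        raise ValueError("qc_filter requires the raw_counts layer")
    thresholds = thresholds or QCThresholds()
    counts = matrix.values
    genes_per_cell = (counts > 0).sum(axis=0)
    mito = np.array(
        [g.startswith(thresholds.mito_prefix.upper()) for g in matrix.gene_ids]
    )
    total = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, counts[mito].sum(axis=0) / total, 0.0)
    keep_cells = (genes_per_cell >= thresholds.min_genes_per_cell) & (
        mito_frac <= thresholds.max_mito_fraction
    )
    n_cells = int(keep_cells.sum())
    if n_cells == 0:
        raise ValueError(
            f"no cells survive QC ({matrix.n_obs} in, 0 out at "
            f"min_genes={thresholds.min_genes_per_cell}, "
            f"max_mito={thresholds.max_mito_fraction})"
        )
    surviving = counts[:, keep_cells]
    keep_genes = (surviving > 0).sum(axis=1) >= thresholds.min_cells_per_gene
    n_genes = int(keep_genes.sum())
    if n_genes == 0:
        raise ValueError(
            f"no genes survive QC ({matrix.n_genes} in, 0 out after keeping "
            f"{n_cells}/{matrix.n_obs} cells)"
        )
    logger.info(
        "QC kept %d/%d cells and %d/%d genes", n_cells, matrix.n_obs, n_genes, matrix.n_genes
    )
    return ExpressionMatrix(
        values=surviving[keep_genes].copy(),
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        obs_ids=[o for o, k in zip(matrix.obs_ids, keep_cells) if k],
        condition=None if matrix.condition is None else matrix.condition[keep_cells].copy(),
        layer=Layer.RAW_COUNTS,
    )


def normalize(matrix: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization followed by natural-log transform.

    ``value[g, c] = ln(1 + scale_factor * count[g, c] / colsum[c])``.
    """
    if matrix.layer is not Layer.RAW_COUNTS:
        raise ValueError("normalize requires the raw_counts layer")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    colsum = matrix.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(
            f"observation(s) with zero total counts: "
            f"{', '.join(matrix.obs_ids[i] for i in zero[:5])}"
        )
    values = np.log1p(scale_factor * matrix.values / colsum)
    return ExpressionMatrix(
        values=values,
        gene_ids=list(matrix.gene_ids),
        obs_ids=list(matrix.obs_ids),
        condition=None if matrix.condition is None else matrix.condition.copy(),
        layer=Layer.LOG_NORMALIZED,
    )


def zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene across observations (sample sd, ddof=1).

    Zero-variance genes become all-zero rows (logged); used to put bulk
    cohorts on a comparable scale before signature scoring.
    """
    if matrix.n_obs < 2:
        raise ValueError("z-scoring needs at least 2 observations")
    mu = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("%d zero-variance gene(s) set to all-zero z-scores", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sd > 0, (matrix.values - mu) / sd, 0.0)
    return ExpressionMatrix(
        values=values,
        gene_ids=list(matrix.gene_ids),
        obs_ids=list(matrix.obs_ids),
        condition=None if matrix.condition is None else matrix.condition.copy(),
        layer=Layer.ZSCORE,
    )


def _wilcoxon_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, row-wise.

    Exact enumeration when both groups have <= 25 observations and a row
    has no ties; tie-corrected normal approximation otherwise.
    """
    n_a, n_b = a.shape[1], b.shape[1]
    asym = np.atleast_1d(
        np.asarray(
            scipy.stats.mannwhitneyu(
                a, b, axis=1, alternative="two-sided", method="asymptotic"
            ).pvalue,
            dtype=float,
        )
    )
    if max(n_a, n_b) > EXACT_WILCOXON_MAX_N:
        return asym
    p = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        row = np.concatenate([a[i], b[i]])
        if np.unique(row).size == row.size:
            p[i] = scipy.stats.mannwhitneyu(
                a[i], b[i], alternative="two-sided", method="exact"
            ).pvalue
        else:
            p[i] = asym[i]
    return p


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 0.25,
    fdr_threshold: float = 0.01,
    min_pct: float = 0.1,
) -> DifferentialResult:
    """Per-gene Wilcoxon differential expression between two conditions.

    Genes detected (value > 0) in at least ``min_pct`` of either group
    are tested; log2 fold change uses the pseudocount convention on
    de-logged normalized means; BH FDR is computed across tested genes;
    ``direction`` is ``up`` when log2_fc > ``lfc_threshold`` and fdr <
    ``fdr_threshold``, ``down`` symmetrically, else ``ns``.
    """
    if matrix.layer is not Layer.LOG_NORMALIZED:
        raise ValueError("differential_expression requires the log_normalized layer")
    if matrix.condition is None:
        raise ValueError("matrix has no condition labels")
    labels = set(matrix.condition)
    for g in (group_a, group_b):
        if g not in labels:
            raise ValueError(f"condition label {g!r} not present (have {sorted(labels)})")
    mask_a = matrix.condition == group_a
    mask_b = matrix.condition == group_b
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 observations")
    a = matrix.values[:, mask_a]
    b = matrix.values[:, mask_b]
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not tested.any():
        raise ValueError(f"no genes detected in at least {min_pct:.0%} of either group")
    mean_a = np.expm1(a[tested]).mean(axis=1)
    mean_b = np.expm1(b[tested]).mean(axis=1)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    p = _wilcoxon_pvalues(a[tested], b[tested])
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (log2_fc > lfc_threshold) & (fdr < fdr_threshold),
        "up",
        np.where((log2_fc < -lfc_threshold) & (fdr < fdr_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "gene": [g for g, t in zip(matrix.gene_ids, tested) if t],
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
            "pct_in_a": pct_a[tested],
            "pct_in_b": pct_b[tested],
            "direction": direction,
        }
    )
    return DifferentialResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
    )


def fisher_direction_enrichment(
    diff: DifferentialResult,
    catalog: RegulatorCatalog,
    direction: str,
    role: Role | str,
) -> EnrichmentTestResult:
    """One-sided Fisher exact test: is a DE direction enriched for a role?

    The universe is the set of genes tested in the DE step.  The 2x2
    table crosses direction membership with role membership; the odds
    ratio is the sample cross-product ratio, with a 0.5 continuity
    correction only when a cell is zero (flagged in the result).
    """
    role = Role(role)
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    universe = set(diff.table["gene"])
    if not universe:
        raise ValueError("differential result is empty")
    role_genes = set(catalog.genes_with_role(role)) & universe
    if not set(catalog.entries) & universe:
        raise ValueError("no catalog gene appears in the tested universe")
    dir_genes = set(diff.genes_with_direction(direction))
    n11 = len(dir_genes & role_genes)
    n12 = len(dir_genes - role_genes)
    n21 = len(role_genes - dir_genes)
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]])
    p = scipy.stats.fisher_exact(table, alternative="greater")[1]
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return EnrichmentTestResult(
        odds_ratio=float(odds),
        p_value=float(p),
        contingency=table,
        continuity_corrected=corrected,
        universe_size=len(universe),
    )
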