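"""Resistance-signature derivation and FR20 scoring.

The resistance signature is the intersection of differential-expression
calls with a ferroptosis-regulator catalog: suppressors up-regulated in
the resistant condition enter with weight +1, drivers down-regulated
with weight -1.  The FR20 score of an observation is then the signed
sum of its normalized expression over the signature genes,

    FR20 = sum_i w_i * Exp_i,   w_i = +1 (suppressor), -1 (driver),

so higher scores mean stronger ferroptosis inhibition and, under the
model, higher risk of BET-inhibitor resistance.  The packaged default
signature carries 8 up-regulated suppressors and 12 down-regulated
drivers (n = 20).

Validation helpers compare scores between labelled groups (Wilcoxon,
t-test, ANOVA) and stratify external samples into top/bottom score
quartiles for drug-response comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .core import (
    ExpressionMatrix,
    GeneSet,
    Layer,
    RegulatorCatalog,
    ResponseTable,
    Role,
    read_gmt,
    write_gmt,
)
from .diffexpr import DifferentialResult

logger = logging.getLogger(__name__)

UP_SET_NAME = "FR20_UP_SUPPRESSORS"
DOWN_SET_NAME = "FR20_DOWN_DRIVERS"


@dataclass
class ResistanceSignature:
    """The two arms of the resistance signature and their FR20 weights."""

    up_suppressors: list[str]
    down_drivers: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.up_suppressors = [g.upper() for g in self.up_suppressors]
        self.down_drivers = [g.upper() for g in self.down_drivers]
        overlap = set(self.up_suppressors) & set(self.down_drivers)
        if overlap:
            raise ValueError(f"genes in both arms: {sorted(overlap)}")
        if self.n < 1:
            raise ValueError("signature must contain at least one gene")

    @property
    def n(self) -> int:
        return len(self.up_suppressors) + len(self.down_drivers)

    def weights(self) -> dict[str, int]:
        w = {g: 1 for g in self.up_suppressors}
        w.update({g: -1 for g in self.down_drivers})
        return w

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(
            [
                GeneSet(UP_SET_NAME, self.up_suppressors),
                GeneSet(DOWN_SET_NAME, self.down_drivers),
            ],
            path,
            description=self.provenance or "ferrosig",
        )

    @classmethod
    def from_gmt(cls, path: str | Path) -> "ResistanceSignature":
        sets = {s.name: s.members for s in read_gmt(path)}
        for name in (UP_SET_NAME, DOWN_SET_NAME):
            if name not in sets:
                raise ValueError(f"GMT file {path} lacks the {name} record")
        return cls(
            up_suppressors=sets[UP_SET_NAME],
            down_drivers=sets[DOWN_SET_NAME],
            provenance=f"loaded from {path}",
        )


def default_signature() -> ResistanceSignature:
    """The packaged 20-gene signature (8 suppressors up, 12 drivers down)."""
    ref = resources.files("ferrosig").joinpath("data/signature.gmt")
    with resources.as_file(ref) as path:
        return ResistanceSignature.from_gmt(path)


def default_catalog_path() -> Path:
    """Path to the packaged regulator-catalog fixture."""
    ref = resources.files("ferrosig").joinpath("data/catalog.tsv")
    with resources.as_file(ref) as path:
        return Path(path)


@dataclass
class ScoreResult:
    """Per-observation FR20 scores.

    ``table`` has columns obs_id, fr20 and (when the input carried
    group labels) condition; ``dropped_genes`` lists signature genes
    absent from the scored matrix.
    """

    table: pd.DataFrame
    layer: Layer
    dropped_genes: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class GroupComparison:
    """Result of a between-group score comparison."""

    test_name: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame
    memberships: dict[str, list[str]] | None = None


def derive_signature(
    diff: DifferentialResult, catalog: RegulatorCatalog
) -> ResistanceSignature:
    """Intersect DE calls with the regulator catalog.

    Up-regulated suppressors and down-regulated drivers form the two
    signature arms, each sorted by ascending FDR; thresholds used by the
    DE step are recorded in the provenance string.
    """
    t = diff.table
    by_fdr = t.sort_values(["fdr", "gene"], kind="mergesort")
    roles = catalog.entries
    up = [
        g
        for g in by_fdr.loc[by_fdr["direction"] == "up", "gene"]
        if roles.get(g) is Role.SUPPRESSOR
    ]
    down = [
        g
        for g in by_fdr.loc[by_fdr["direction"] == "down", "gene"]
        if roles.get(g) is Role.DRIVER
    ]
    if not up and not down:
        raise ValueError(
            "no up-regulated suppressors or down-regulated drivers found; "
            "review the DE thresholds or the catalog"
        )
    provenance = (
        f"derived from DE {diff.group_a} vs {diff.group_b} at "
        f"|log2FC|>{diff.lfc_threshold}, FDR<{diff.fdr_threshold}; "
        f"catalog={catalog.source_label or 'unnamed'}"
    )
    return ResistanceSignature(up_suppressors=up, down_drivers=down, provenance=provenance)


def fr20_score(
    matrix: ExpressionMatrix,
    signature: ResistanceSignature,
    missing_policy: str = "drop_and_warn",
) -> ScoreResult:
    """Signed-sum FR20 score per observation.

    The matrix should carry log-normalized values (single-cell) or
    per-gene z-scores (bulk cohorts).  Signature genes absent from the
    matrix are dropped with a warning (``missing_policy="error"``
    raises instead); the dropped genes are listed in the result.
    """
    if missing_policy not in ("error", "drop_and_warn"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    idx = matrix.gene_index()
    weights = signature.weights()
    present = [g for g in weights if g in idx]
    missing = sorted(set(weights) - set(present))
    if missing and missing_policy == "error":
        raise ValueError(f"signature genes absent from matrix: {', '.join(missing)}")
    if not present:
        raise ValueError(
            f"none of the {signature.n} signature genes present in the matrix: "
            f"{', '.join(missing)}"
        )
    if missing:
        logger.warning(
            "dropping %d signature gene(s) absent from matrix: %s",
            len(missing),
            ", ".join(missing),
        )
    rows = np.array([idx[g] for g in present])
    w = np.array([weights[g] for g in present], dtype=float)
    scores = w @ matrix.values[rows]
    table = pd.DataFrame({"obs_id": matrix.obs_ids, "fr20": scores})
    if matrix.condition is not None:
        table["condition"] = matrix.condition
    return ScoreResult(table=table, layer=matrix.layer, dropped_genes=missing)


def _summaries(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": label,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
            for label, vals in groups.items()
        ]
    )


def compare_scores(scores: ScoreResult, test: str = "wilcoxon_two_sided") -> GroupComparison:
    """Compare FR20 scores between labelled groups.

    ``wilcoxon_two_sided`` and ``t_two_tailed`` require exactly two
    groups; ``anova_one_way`` accepts two or more.  Each group needs at
    least 2 observations.
    """
    if "condition" not in scores.table.columns:
        raise ValueError("scores carry no condition labels")
    grouped = {
        str(label): sub["fr20"].to_numpy(float)
        for label, sub in scores.table.groupby("condition", sort=True)
    }
    if any(len(v) < 2 for v in grouped.values()):
        raise ValueError("every group needs at least 2 observations")
    vals = list(grouped.values())
    if test == "wilcoxon_two_sided":
        if len(vals) != 2:
            raise ValueError(f"wilcoxon needs exactly 2 groups, got {len(vals)}")
        stat, p = scipy.stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
    elif test == "t_two_tailed":
        if len(vals) != 2:
            raise ValueError(f"t-test needs exactly 2 groups, got {len(vals)}")
        stat, p = scipy.stats.ttest_ind(vals[0], vals[1])
    elif test == "anova_one_way":
        if len(vals) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        stat, p = scipy.stats.f_oneway(*vals)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
        group_summaries=_summaries(grouped),
    )


def stratify_quartiles(scores: ScoreResult, response: ResponseTable) -> GroupComparison:
    """Compare drug response between top- and bottom-quartile FR20 samples.

    Samples at or above the 75th percentile of FR20 form the high group,
    those at or below the 25th percentile the low group (type-7 linear-
    interpolation percentiles); responses are compared with a two-sided
    Wilcoxon rank-sum test.
    """
    merged = scores.table.merge(
        response.table, left_on="obs_id", right_on="sample_id", how="inner"
    )
    if len(merged) < 8:
        raise ValueError(
            f"need at least 8 samples with both score and response, got {len(merged)}"
        )
    fr20 = merged["fr20"].to_numpy(float)
    q25, q75 = np.percentile(fr20, [25, 75], method="linear")
    if q25 == q75:
        raise ValueError(
            f"quartile boundaries coincide at {q25!r}: tied scores leave no "
            "usable high/low split"
        )
    high = merged[fr20 >= q75]
    low = merged[fr20 <= q25]
    stat, p = scipy.stats.mannwhitneyu(
        high["response_value"], low["response_value"], alternative="two-sided"
    )
    groups = {
        "high_fr20": high["response_value"].to_numpy(float),
        "low_fr20": low["response_value"].to_numpy(float),
    }
    return GroupComparison(
        test_name="wilcoxon_two_sided",
        statistic=float(stat),
        p_value=float(p),
        group_summaries=_summaries(groups),
        memberships={
            "high_fr20": list(high["obs_id"]),
            "low_fr20": list(low["obs_id"]),
        },
    )
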