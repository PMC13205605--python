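"""Connectivity screening of perturbation profiles (D-FR20).

Ranks small-molecule perturbation instances by their predicted ability
to reverse the resistance signature.  For each instance the weighted
Kolmogorov-Smirnov enrichment score (ES) of the up-suppressor arm and
of the down-driver arm is computed against the instance's rank-ordered
differential-expression statistics; a gene-set permutation null gives
the normalized enrichment score (NES) and permutation p-value; BH FDR
is applied per gene set across instances; and the two NES values are
merged into the weighted connectivity score

    WTCS = (NES_up - NES_down) / 2   if sign(NES_up) != sign(NES_down)
         = 0                         otherwise.

A strongly negative WTCS means the perturbation pushes the up-regulated
suppressors down and the down-regulated drivers up -- the reversal
pattern a re-sensitizer should show -- so candidates are the lowest-WTCS
retained instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GeneSet, PerturbationLibrary
from .signature import ResistanceSignature

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """ES/NES/p for one gene set against one ranked profile."""

    instance_id: str
    gene_set_name: str
    es: float
    nes: float
    p_value: float
    set_size_used: int
    fdr: float = float("nan")
    degenerate_null: bool = False
    #: permutations whose null ES shares the sign of the observed ES;
    #: the attainable p-value floor is 1 / (1 + n_null_same_sign)
    n_null_same_sign: int = 0


@dataclass
class ConnectivityResult:
    """Per-instance screening table plus the candidate shortlist.

    ``table`` columns: instance_id, compound_name, es_up, nes_up, p_up,
    fdr_up, es_down, nes_down, p_down, fdr_down, wtcs, retained, rank.
    ``rank`` runs 1..K over retained instances by ascending WTCS and is
    <NA> for unretained ones.
    """

    table: pd.DataFrame
    top_k: int
    params: dict = field(default_factory=dict)

    @property
    def candidates(self) -> pd.DataFrame:
        retained = self.table.dropna(subset=["rank"]).sort_values("rank")
        return retained.head(self.top_k).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def wtcs(nes_up: float, nes_down: float) -> float:
    """Weighted connectivity score of the two arm-level NES values."""
    if nes_up == 0 or nes_down == 0 or np.sign(nes_up) == np.sign(nes_down):
        return 0.0
    return (nes_up - nes_down) / 2.0


def _sorted_profile(
    stats: np.ndarray, genes: list[str]
) -> tuple[np.ndarray, dict[str, int]]:
    """Sort a profile by statistic descending, ties by gene symbol ascending.

    Returns the sorted statistics and a gene -> rank-position map.
    """
    order = sorted(range(len(genes)), key=lambda i: (-stats[i], genes[i]))
    pos = {genes[i]: rank for rank, i in enumerate(order)}
    return stats[np.array(order)], pos


def _es_batch(sorted_abs_w: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Enrichment scores for one sorted profile and a batch of hit masks.

    ``sorted_abs_w`` is ``|stat|**p`` in rank order (length N);
    ``hits`` is a (batch, N) boolean mask of member positions, each row
    with the same member count m < N.
    """
    n = sorted_abs_w.shape[0]
    m = int(hits[0].sum())
    member_w = hits * sorted_abs_w
    denom = member_w.sum(axis=1, keepdims=True)
    # all-zero member statistics: fall back to uniform member weights
    flat = denom[:, 0] == 0
    if flat.any():
        member_w = np.where(flat[:, None], hits.astype(float), member_w)
        denom = member_w.sum(axis=1, keepdims=True)
    walk = np.cumsum(member_w / denom - (~hits) / (n - m), axis=1)
    peak = np.argmax(np.abs(walk), axis=1)
    # clamp rounding spill from the cumulative sum; |ES| <= 1 analytically
    return np.clip(walk[np.arange(walk.shape[0]), peak], -1.0, 1.0)


def enrichment_score(
    profile: pd.Series, gene_set: GeneSet, weight_exponent: float = 1.0
) -> float:
    """Weighted-KS enrichment score of a gene set in a ranked profile.

    Genes are ordered by statistic descending (ties broken by gene
    symbol); the running sum gains ``|stat|**p / sum_set |stat|**p`` at
    member positions and loses ``1/(N-m)`` elsewhere; the ES is the
    signed maximum absolute deviation of the walk from zero.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    genes = [str(g).upper() for g in profile.index]
    if len(genes) < 2:
        raise ValueError("profile needs at least 2 genes")
    stats = profile.to_numpy(float)
    members = set(gene_set.members) & set(genes)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the profile")
    if len(members) == len(genes):
        raise ValueError(f"gene set {gene_set.name!r} covers every profile gene")
    sorted_stats, pos = _sorted_profile(stats, genes)
    hits = np.zeros((1, len(genes)), dtype=bool)
    hits[0, [pos[g] for g in members]] = True
    return float(_es_batch(np.abs(sorted_stats) ** weight_exponent, hits)[0])


def _null_hits(
    rng: np.random.Generator, n_perm: int, n_genes: int, m: int
) -> np.ndarray:
    """Boolean masks of ``n_perm`` random m-gene sets in rank-position space."""
    keys = rng.random((n_perm, n_genes))
    idx = np.argpartition(keys, m, axis=1)[:, :m]
    hits = np.zeros((n_perm, n_genes), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    return hits


def _nes_p_from_null(es: float, null_es: np.ndarray) -> tuple[float, float, bool, int]:
    """NES, permutation p and same-sign null count from a gene-set null.

    ES is normalized by the mean |null ES| of the same sign; p is the
    add-one estimator over same-sign permutations.  When no same-sign
    permutation exists, the all-null mean is used and p sits at
    1/(n_perm + 1) (flagged as degenerate).
    """
    n_perm = null_es.shape[0]
    if es == 0:
        return 0.0, 1.0, False, 0
    same = null_es[np.sign(null_es) == np.sign(es)]
    if same.size:
        nes = es / np.abs(same).mean()
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
        return float(nes), float(p), False, int(same.size)
    scale = np.abs(null_es).mean()
    nes = es / scale if scale > 0 else es
    return float(nes), 1.0 / (n_perm + 1.0), True, 0


def normalized_enrichment(
    profile: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
    instance_id: str = "",
) -> EnrichmentResult:
    """ES with a gene-set permutation NES, p-value and effective set size.

    The null draws ``n_perm`` random gene sets of the matched size from
    the profile's genes (seeded) and scores them with the same walk.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    genes = [str(g).upper() for g in profile.index]
    stats = profile.to_numpy(float)
    members = set(gene_set.members) & set(genes)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the profile")
    if len(members) == len(genes):
        raise ValueError(f"gene set {gene_set.name!r} covers every profile gene")
    sorted_stats, pos = _sorted_profile(stats, genes)
    abs_w = np.abs(sorted_stats) ** weight_exponent
    hits = np.zeros((1, len(genes)), dtype=bool)
    hits[0, [pos[g] for g in members]] = True
    es = float(_es_batch(abs_w, hits)[0])
    rng = np.random.default_rng(seed)
    null_es = _es_batch(abs_w, _null_hits(rng, n_perm, len(genes), len(members)))
    nes, p, degenerate, n_same = _nes_p_from_null(es, null_es)
    return EnrichmentResult(
        instance_id=instance_id,
        gene_set_name=gene_set.name,
        es=es,
        nes=nes,
        p_value=p,
        set_size_used=len(members),
        degenerate_null=degenerate,
        n_null_same_sign=n_same,
    )


def screen(
    library: PerturbationLibrary,
    signature: ResistanceSignature,
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    top_k: int = 10,
    weight_exponent: float = 1.0,
    seed: int | None = None,
) -> ConnectivityResult:
    """Rank every library instance by WTCS against the signature.

    Per instance, NES and permutation p-values are computed for the
    up-suppressor and down-driver arms; BH FDR runs separately per arm
    across all instances; an instance is retained when both arms pass
    ``fdr_threshold``; retained instances are ranked by ascending WTCS
    (ties broken by instance id) and the ``top_k`` lowest form the
    candidate shortlist.
    """
    lib_genes = set(library.gene_ids)
    up_members = [g for g in signature.up_suppressors if g in lib_genes]
    down_members = [g for g in signature.down_drivers if g in lib_genes]
    for name, members, full in (
        ("up-suppressor", up_members, signature.up_suppressors),
        ("down-driver", down_members, signature.down_drivers),
    ):
        if not members:
            raise ValueError(f"library covers no gene of the {name} arm")
        dropped = set(full) - set(members)
        if dropped:
            logger.warning(
                "%s arm: dropping %d gene(s) absent from library: %s",
                name,
                len(dropped),
                ", ".join(sorted(dropped)),
            )
    up_set = GeneSet("up_suppressors", up_members)
    down_set = GeneSet("down_drivers", down_members)
    rng = np.random.default_rng(seed)
    rows = []
    for j, inst in enumerate(library.instance_ids):
        profile = pd.Series(library.stat_matrix[:, j], index=library.gene_ids)
        genes = library.gene_ids
        sorted_stats, pos = _sorted_profile(profile.to_numpy(float), genes)
        abs_w = np.abs(sorted_stats) ** weight_exponent
        row = {"instance_id": inst}
        for arm, gs in (("up", up_set), ("down", down_set)):
            hits = np.zeros((1, len(genes)), dtype=bool)
            hits[0, [pos[g] for g in gs.members]] = True
            es = float(_es_batch(abs_w, hits)[0])
            null_es = _es_batch(
                abs_w, _null_hits(rng, n_perm, len(genes), len(gs.members))
            )
            nes, p, _, _ = _nes_p_from_null(es, null_es)
            row[f"es_{arm}"] = es
            row[f"nes_{arm}"] = nes
            row[f"p_{arm}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)
    table["fdr_up"] = multipletests(table["p_up"], method="fdr_bh")[1]
    table["fdr_down"] = multipletests(table["p_down"], method="fdr_bh")[1]
    table["wtcs"] = [
        wtcs(u, d) for u, d in zip(table["nes_up"], table["nes_down"])
    ]
    table["retained"] = (table["fdr_up"] < fdr_threshold) & (
        table["fdr_down"] < fdr_threshold
    )
    compound = library.metadata.set_index("instance_id")["compound_name"]
    table.insert(1, "compound_name", [compound[i] for i in table["instance_id"]])
    table["rank"] = pd.array([pd.NA] * len(table), dtype="Int64")
    retained = table[table["retained"]].sort_values(
        ["wtcs", "instance_id"], kind="mergesort"
    )
    table.loc[retained.index, "rank"] = np.arange(1, len(retained) + 1)
    if retained.empty:
        logger.warning("no instance retained at FDR < %g; candidate list is empty", fdr_threshold)
    cols = [
        "instance_id", "compound_name",
        "es_up", "nes_up", "p_up", "fdr_up",
        "es_down", "nes_down", "p_down", "fdr_down",
        "wtcs", "retained", "rank",
    ]
    return ConnectivityResult(
        table=table[cols],
        top_k=top_k,
        params={
            "n_perm": n_perm,
            "fdr_threshold": fdr_threshold,
            "top_k": top_k,
            "weight_exponent": weight_exponent,
            "seed": seed,
            "fdr_scope": "BH per gene-set arm across instances, AND-combined",
            "set_size_up": len(up_members),
            "set_size_down": len(down_members),
        },
    )
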