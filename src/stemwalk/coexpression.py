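"""Cancer-specific co-expression network construction.

The network is built in four stages: (1) genes in the bottom quantile of
expression variance are removed; (2) Pearson correlation coefficients (PCC)
are computed for all pairs in the four canonical categories (PCG-PCG,
PCG-lncRNA, miRNA-PCG, miRNA-lncRNA; TFs count as PCGs) and ranked per
category — strong correlations of either sign for PCG-PCG/PCG-lncRNA
(descending |PCC|), most-negative-first for miRNA pairs (ascending signed
PCC, matching the repressive role of miRNAs); (3) the top k% of each
category is retained; (4) optionally only pairs touching at least one seed
gene are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    ABS_RANKED_CATEGORIES,
    COEXPRESSION_CATEGORIES,
    ExpressionMatrix,
    SeedSet,
    coexpression_group,
    warn,
)


@dataclass
class RankedPairSet:
    """Scored gene pairs grouped by category.

    ``pairs`` maps category -> DataFrame(gene_a, gene_b, pcc, rank), sorted
    by rank; ``totals`` records the per-category pair count before any
    thresholding so that provenance survives chained operations.
    """

    pairs: dict[str, pd.DataFrame]
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in self.pairs:
            self.totals.setdefault(cat, len(self.pairs[cat]))

    def categories(self) -> list[str]:
        return [c for c in COEXPRESSION_CATEGORIES if c in self.pairs] + [
            c for c in self.pairs if c not in COEXPRESSION_CATEGORIES
        ]

    def n_pairs(self) -> int:
        return sum(len(df) for df in self.pairs.values())

    def unordered_pairs(self) -> set[frozenset]:
        """All retained pairs as unordered gene-id sets (category-blind)."""
        out: set[frozenset] = set()
        for df in self.pairs.values():
            out.update(
                frozenset((a, b)) for a, b in zip(df["gene_a"], df["gene_b"])
            )
        return out


def filter_low_variance(
    expr: ExpressionMatrix, drop_fraction: float = 0.25
) -> ExpressionMatrix:
    """Remove genes in the bottom ``drop_fraction`` of expression variances.

    A gene is retained when its sample variance strictly exceeds the
    empirical ``drop_fraction`` quantile (linear interpolation) of all gene
    variances; with ``drop_fraction = 0`` every gene survives.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if drop_fraction == 0:
        return expr
    variances = expr.values.var(axis=1, ddof=1)
    threshold = float(np.quantile(variances.to_numpy(), drop_fraction))
    keep = variances > threshold
    if not keep.any():
        raise ValueError("variance filter removed every gene")
    dropped = int((~keep).sum())
    if dropped:
        warn(f"variance filter dropped {dropped}/{expr.n_genes} genes")
    return expr.subset_genes(expr.values.index[keep])


def compute_pairs(expr: ExpressionMatrix) -> RankedPairSet:
    """All-pairs PCC in the four canonical categories, ranked per category.

    Requires >= 3 samples and no zero-variance genes (those are undefined
    under PCC and should have been removed by the variance filter).  Ties in
    PCC are broken lexicographically by (gene_a, gene_b) for determinism.
    """
    if expr.n_samples < 3:
        raise ValueError("PCC needs at least 3 samples")
    arr = expr.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        genes = [expr.gene_ids[i] for i in zero[:5]]
        raise ValueError(
            f"zero-variance genes encountered (PCC undefined): {genes}; "
            "apply filter_low_variance first"
        )
    corr = np.corrcoef(arr)
    corr = np.clip(corr, -1.0, 1.0)
    genes = np.asarray(expr.gene_ids, dtype=object)
    groups = np.asarray([coexpression_group(expr.biotype[g]) for g in genes], dtype=object)

    group_idx = {g: np.flatnonzero(groups == g) for g in ("PCG", "lncRNA", "miRNA")}
    members = {
        "PCG-PCG": ("PCG", "PCG"),
        "PCG-lncRNA": ("PCG", "lncRNA"),
        "miRNA-PCG": ("miRNA", "PCG"),
        "miRNA-lncRNA": ("miRNA", "lncRNA"),
    }
    pairs: dict[str, pd.DataFrame] = {}
    for category, (ga, gb) in members.items():
        ia, ib = group_idx[ga], group_idx[gb]
        if ia.size == 0 or ib.size == 0 or (ga == gb and ia.size < 2):
            continue
        if ga == gb:
            iu, ju = np.triu_indices(ia.size, k=1)
            rows, cols = ia[iu], ia[ju]
        else:
            rows = np.repeat(ia, ib.size)
            cols = np.tile(ib, ia.size)
        pcc = corr[rows, cols]
        a_ids, b_ids = genes[rows], genes[cols]
        # canonical unordered orientation: lexicographically smaller id first
        flip = a_ids > b_ids
        a_ids, b_ids = np.where(flip, b_ids, a_ids), np.where(flip, a_ids, b_ids)
        df = pd.DataFrame({"gene_a": a_ids, "gene_b": b_ids, "pcc": pcc})
        key = -np.abs(df["pcc"]) if category in ABS_RANKED_CATEGORIES else df["pcc"]
        df = (
            df.assign(_key=key)
            .sort_values(["_key", "gene_a", "gene_b"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        df["rank"] = np.arange(1, len(df) + 1)
        pairs[category] = df
    return RankedPairSet(pairs=pairs)


def threshold_pairs(ranked: RankedPairSet, cutoff: float) -> RankedPairSet:
    """Retain the top ``ceil(cutoff/100 * count)`` pairs of each category.

    ``cutoff`` is a percentage in (0, 100]; the ceiling convention guarantees
    a non-empty selection even at 0.1% for small categories.
    """
    if not 0 < cutoff <= 100:
        raise ValueError(f"cutoff must be a percentage in (0, 100], got {cutoff}")
    out: dict[str, pd.DataFrame] = {}
    for cat, df in ranked.pairs.items():
        k = math.ceil(cutoff / 100 * len(df))
        out[cat] = df.iloc[:k].reset_index(drop=True)
    return RankedPairSet(pairs=out, totals=dict(ranked.totals))


def retain_seed_edges(ranked: RankedPairSet, seeds: SeedSet) -> RankedPairSet:
    """Keep exactly the pairs with at least one endpoint in the seed set.

    Ranks are reassigned 1..m within category, preserving the original
    ordering.  An empty result is allowed but warned about.
    """
    ids = seeds.seed_ids
    out: dict[str, pd.DataFrame] = {}
    for cat, df in ranked.pairs.items():
        mask = df["gene_a"].isin(ids) | df["gene_b"].isin(ids)
        sub = df.loc[mask].reset_index(drop=True)
        sub["rank"] = np.arange(1, len(sub) + 1)
        out[cat] = sub
    result = RankedPairSet(pairs=out, totals=dict(ranked.totals))
    if result.n_pairs() == 0:
        warn("no pairs touch a seed gene; the seed-filtered pair set is empty")
    return result


def build_network(
    ranked: RankedPairSet,
    biotype: dict[str, str] | None = None,
    provenance: dict | None = None,
) -> nx.Graph:
    """Assemble the undirected co-expression network from retained pairs.

    Nodes are exactly the genes incident to retained pairs.  A pair that
    appears in two categories becomes a single edge carrying both category
    labels (stored as a sorted tuple in the ``categories`` edge attribute).
    """
    net = nx.Graph(**(provenance or {}))
    for cat in ranked.categories():
        df = ranked.pairs[cat]
        for row in df.itertuples(index=False):
            a, b = row.gene_a, row.gene_b
            if net.has_edge(a, b):
                cats = set(net.edges[a, b]["categories"])
                cats.add(cat)
                net.edges[a, b]["categories"] = tuple(sorted(cats))
            else:
                net.add_edge(a, b, categories=(cat,), pcc=float(row.pcc))
    if biotype is not None:
        for node in net.nodes:
            net.nodes[node]["biotype"] = biotype.get(node, "PCG")
    return net
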