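"""End-to-end composition of the pipeline stages.

These helpers wire together variance filtering, pair ranking,
thresholding, seed-edge retention, network assembly, the random walk and
the permutation null, so that the CLI, the tests and downstream scripts
all execute the same path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .coexpression import (
    RankedPairSet,
    build_network,
    compute_pairs,
    filter_low_variance,
    retain_seed_edges,
    threshold_pairs,
)
from .model import ExpressionMatrix, InteractionList, SeedSet
from .propagation import PropagationConfig, PropagationResult
from .regulatory import intersect_regulatory
from .significance import PermutationNull, call_predictions, permutation_null


def coexpression_pairs(
    expr: ExpressionMatrix,
    cutoff: float,
    drop_fraction: float = 0.25,
    seeds: SeedSet | None = None,
) -> RankedPairSet:
    """Variance filter -> all-pairs PCC -> top-k% threshold -> optional
    seed-edge retention."""
    filtered = filter_low_variance(expr, drop_fraction)
    ranked = compute_pairs(filtered)
    kept = threshold_pairs(ranked, cutoff)
    if seeds is not None:
        kept = retain_seed_edges(kept, seeds)
    return kept


def coexpression_network(
    expr: ExpressionMatrix,
    cutoff: float,
    seeds: SeedSet,
    drop_fraction: float = 0.25,
    seed_filter: bool = True,
) -> nx.Graph:
    pairs = coexpression_pairs(
        expr, cutoff, drop_fraction, seeds if seed_filter else None
    )
    return build_network(
        pairs,
        biotype=expr.biotype,
        provenance={"cutoff_percent": cutoff, "seed_filtered": seed_filter},
    )


def regulatory_network(
    expr: ExpressionMatrix,
    interactions: InteractionList,
    cutoff: float,
    drop_fraction: float = 0.25,
    seeds: SeedSet | None = None,
) -> nx.Graph:
    """Curated interactions intersected with (by default unfiltered)
    co-expression pairs at ``cutoff``."""
    pairs = coexpression_pairs(expr, cutoff, drop_fraction, seeds)
    return intersect_regulatory(
        interactions,
        pairs,
        biotype=expr.biotype,
        provenance={"cutoff_percent": cutoff},
    )


@dataclass
class PredictionRun:
    network: nx.Graph
    result: PropagationResult
    null: PermutationNull
    predictions: pd.DataFrame


def predict(
    net: nx.Graph,
    seeds: SeedSet,
    cfg: PropagationConfig | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    level: float = 0.05,
    biotype_filter: set[str] | None = frozenset({"lncRNA", "miRNA"}),
    exclude_seeds: bool = True,
) -> PredictionRun:
    """RWR from the seed set plus the pseudo-seed permutation null, returning
    the significant (by default non-seed ncRNA) predictions."""
    cfg = cfg or PropagationConfig()
    result, null = permutation_null(
        net, seeds, cfg, n_perm=n_perm, rng_seed=rng_seed, level=level
    )
    biotype = nx.get_node_attributes(net, "biotype")
    preds = call_predictions(
        result,
        null,
        seeds=seeds,
        exclude_seeds=exclude_seeds,
        biotype_filter=set(biotype_filter) if biotype_filter else None,
        biotype=biotype,
    )
    return PredictionRun(network=net, result=result, null=null, predictions=preds)
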