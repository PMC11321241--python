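"""Seed selection and cancer-specific regulatory network assembly.

Seeds are protein-coding genes recurring across published stemness
signatures (membership in at least ``min_sets`` collections, default 3),
optionally augmented with curated stemness-associated ncRNAs.  The
regulatory network is the subset of curated regulatory interactions whose
endpoint pair is also a co-expression pair at the chosen cutoff; the
curated direction is discarded for propagation (the walk is undirected) but
the regulatory category is retained as an edge annotation.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .coexpression import RankedPairSet
from .model import GeneSetCollection, InteractionList, SeedSet, warn


def select_stem_seeds(
    sets: GeneSetCollection,
    min_sets: int = 3,
    extra_seeds: Iterable[str] = (),
) -> SeedSet:
    """Genes appearing in at least ``min_sets`` collections, plus any
    explicitly supplied extra seeds (e.g. curated stemness ncRNAs)."""
    if min_sets < 1:
        raise ValueError(f"min_sets must be >= 1, got {min_sets}")
    counts = sets.membership_counts()
    seed_ids = {g for g, c in counts.items() if c >= min_sets}
    seed_ids |= set(extra_seeds)
    if not seed_ids:
        raise ValueError(
            f"no gene appears in >= {min_sets} sets and no extra seeds were given"
        )
    return SeedSet.of(seed_ids)


def intersect_regulatory(
    interactions: InteractionList,
    coex_pairs: RankedPairSet,
    biotype: dict[str, str] | None = None,
    provenance: dict | None = None,
) -> nx.Graph:
    """Regulatory network: curated interactions restricted to co-expressed
    pairs.

    Matching is on unordered endpoint pairs, regardless of the regulatory
    versus co-expression category.  Each retained edge carries the
    regulatory category (or categories, when several curated records share
    an endpoint pair) in its ``categories`` attribute.
    """
    coex = coex_pairs.unordered_pairs()
    net = nx.Graph(**(provenance or {}))
    for rec in interactions.records:
        key = frozenset((rec.source, rec.target))
        if key not in coex:
            continue
        a, b = sorted((rec.source, rec.target))
        if net.has_edge(a, b):
            cats = set(net.edges[a, b]["categories"])
            cats.add(rec.category)
            net.edges[a, b]["categories"] = tuple(sorted(cats))
        else:
            net.add_edge(a, b, categories=(rec.category,))
    if biotype is not None:
        for node in net.nodes:
            net.nodes[node]["biotype"] = biotype.get(node, "PCG")
    if net.number_of_edges() == 0:
        warn("regulatory intersection is empty: no curated interaction is co-expressed")
    return net
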