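"""Pseudo-seed permutation null for RWR scores.

Propagation scores are strongly degree-dependent, so significance is judged
against each node's own null distribution: ``n_perm`` pseudo-seed sets of
the same size as the real seed set are drawn uniformly without replacement
from the network's nodes, the walk is re-run from each, and a node's
empirical p-value is the add-one proportion of null scores at least as
large as its true score,

    p_i = (1 + #{null >= true}) / (m_i + 1),

which is never zero and never exceeds one.  A node is called significant
when p_i <= level (default 0.05, the top-5% rule).  A pooled alternative —
the true score must fall in the top ``level`` fraction of all null scores
pooled across nodes — is available via ``mode="pooled"``.

A node's score explodes in the draws where the node itself happens to be
sampled as a pseudo-seed; leaving those draws in the null would push every
95th percentile above any non-seed score and make the test hopelessly
conservative.  The per-node null therefore conditions on the node not
being a pseudo-seed: ``m_i`` counts only the draws that did not sample
node i, which matches the hypothesis actually tested (how close is this
non-seed gene to the real seeds, relative to random seed sets that do not
contain it) and gives exact level-q calibration under exchangeable seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import SeedSet
from .propagation import (
    PropagationConfig,
    PropagationResult,
    RWRSolver,
    build_transition,
    make_p0,
    rwr_iterate,
)

#: Networks up to this size use the LU-factorized direct solver for the
#: permutation loop; larger ones fall back to power iteration per draw.
_DIRECT_SOLVE_LIMIT = 2000


@dataclass
class PermutationNull:
    """Per-node null score samples, empirical p-values and significance calls."""

    nodes: list[str]
    n_perm: int
    null_scores: np.ndarray  # shape (n_perm, n_nodes)
    empirical_p: np.ndarray
    significant: np.ndarray
    rng_seed: int
    level: float = 0.05
    mode: str = "per_node"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.nodes,
                "empirical_p": self.empirical_p,
                "significant": self.significant,
            }
        )


def _draw_pseudo_seeds(
    rng: np.random.Generator,
    nodes: list[str],
    n: int,
    biotype: dict[str, str] | None,
    seed_biotypes: list[str] | None,
) -> np.ndarray:
    """Index array of a pseudo-seed draw; optionally biotype-stratified to
    preserve the real seed set's biotype composition."""
    if seed_biotypes is None:
        return rng.choice(len(nodes), size=n, replace=False)
    by_type: dict[str, list[int]] = {}
    for i, node in enumerate(nodes):
        by_type.setdefault(biotype.get(node, "PCG"), []).append(i)
    picked: list[int] = []
    counts: dict[str, int] = {}
    for bt in seed_biotypes:
        counts[bt] = counts.get(bt, 0) + 1
    for bt, k in counts.items():
        pool = by_type.get(bt, [])
        if len(pool) < k:
            raise ValueError(
                f"cannot draw {k} pseudo-seeds of biotype {bt!r}: only "
                f"{len(pool)} such nodes in the network"
            )
        picked.extend(rng.choice(pool, size=k, replace=False))
    return np.asarray(picked)


def permutation_null(
    net: nx.Graph,
    seeds: SeedSet,
    cfg: PropagationConfig | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    level: float = 0.05,
    mode: str = "per_node",
    exclude_true_seeds: bool = False,
    stratify_biotype: bool = False,
) -> tuple[PropagationResult, PermutationNull]:
    """Run the true walk plus ``n_perm`` pseudo-seed walks and call
    significance.

    Pseudo-seeds are sampled uniformly without replacement from all network
    nodes (true seeds included, unless ``exclude_true_seeds``); with
    ``stratify_biotype`` each draw preserves the real seed set's biotype
    composition.  Returns the true PropagationResult together with the
    PermutationNull; identical ``rng_seed`` gives identical calls.
    """
    cfg = cfg or PropagationConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    W = build_transition(net, weighted=cfg.weighted)
    nodes = W.nodes
    p0 = make_p0(nodes, seeds)
    n_present = int(np.count_nonzero(p0.p))

    universe = list(range(len(nodes)))
    if exclude_true_seeds:
        universe = [i for i in universe if nodes[i] not in seeds.seed_ids]
    if n_present >= len(universe):
        raise ValueError(
            f"seed count ({n_present}) must be smaller than the pseudo-seed "
            f"universe ({len(universe)} nodes)"
        )

    biotype = nx.get_node_attributes(net, "biotype")
    seed_biotypes = None
    if stratify_biotype:
        seed_biotypes = [
            biotype.get(g, "PCG") for g in nodes if g in seeds.seed_ids
        ]

    use_direct = len(nodes) <= _DIRECT_SOLVE_LIMIT
    solver = RWRSolver(W, cfg.alpha, cfg.literal_update) if use_direct else None

    if use_direct:
        true_scores = solver.solve(p0.p)
        true = PropagationResult(
            nodes=list(nodes),
            scores=true_scores,
            rank=_dense_ranks(nodes, true_scores),
            iterations=0,
            converged=True,
        )
    else:
        true = rwr_iterate(W, p0, cfg)
        true_scores = true.scores

    rng = np.random.default_rng(rng_seed)
    universe_arr = np.asarray(universe)
    null = np.empty((n_perm, len(nodes)))
    was_seed = np.zeros((n_perm, len(nodes)), dtype=bool)
    for t in range(n_perm):
        if seed_biotypes is not None:
            idx = _draw_pseudo_seeds(rng, nodes, n_present, biotype, seed_biotypes)
        else:
            idx = universe_arr[
                rng.choice(len(universe_arr), size=n_present, replace=False)
            ]
        was_seed[t, idx] = True
        q0 = np.zeros(len(nodes))
        q0[idx] = 1.0 / n_present
        if use_direct:
            null[t] = solver.solve(q0)
        else:
            null[t] = rwr_iterate(
                W,
                type(p0)(nodes=list(nodes), p=q0),
                cfg,
            ).scores

    if mode == "per_node":
        usable = ~was_seed
        exceed = ((null >= true_scores[None, :]) & usable).sum(axis=0)
        m = usable.sum(axis=0)
        empirical_p = (1.0 + exceed) / (m + 1.0)
    elif mode == "pooled":
        pool = np.sort(null.ravel())
        exceed = pool.size - np.searchsorted(pool, true_scores, side="left")
        empirical_p = (1.0 + exceed) / (pool.size + 1.0)
    else:
        raise ValueError(f"mode must be 'per_node' or 'pooled', got {mode!r}")
    significant = empirical_p <= level
    return true, PermutationNull(
        nodes=list(nodes),
        n_perm=n_perm,
        null_scores=null,
        empirical_p=empirical_p,
        significant=significant,
        rng_seed=rng_seed,
        level=level,
        mode=mode,
    )


def _dense_ranks(nodes: list[str], scores: np.ndarray) -> np.ndarray:
    order = sorted(range(len(nodes)), key=lambda i: (-scores[i], nodes[i]))
    rank = np.empty(len(nodes), dtype=int)
    rank[order] = np.arange(1, len(nodes) + 1)
    return rank


def call_predictions(
    result: PropagationResult,
    null: PermutationNull,
    seeds: SeedSet | None = None,
    exclude_seeds: bool = True,
    biotype_filter: set[str] | None = None,
    biotype: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Table of significant nodes, optionally excluding seeds and restricted
    to given biotypes (e.g. {'lncRNA', 'miRNA'} for ncRNA predictions)."""
    if list(result.nodes) != list(null.nodes):
        raise ValueError("result and null node sets differ")
    biotype = biotype or {}
    df = pd.DataFrame(
        {
            "gene_id": result.nodes,
            "biotype": [biotype.get(g, "PCG") for g in result.nodes],
            "score": result.scores,
            "rank": result.rank,
            "empirical_p": null.empirical_p,
            "significant": null.significant,
        }
    )
    df = df[df["significant"]]
    if exclude_seeds and seeds is not None:
        df = df[~df["gene_id"].isin(seeds.seed_ids)]
    if biotype_filter is not None:
        df = df[df["biotype"].isin(biotype_filter)]
    return df.sort_values("rank").reset_index(drop=True)
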