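"""Random walk with restart (RWR) over a gene network.

The walk iterates

    p_{t+1} = (1 - alpha) * M @ p_t + alpha * p_0

where ``p_0`` puts mass 1/n on each of n seed nodes and ``alpha`` is the
restart probability.  The transition matrix is the row-normalized binary
adjacency, w(i, j) = A(i, j) / sum_j A(i, j) (zero rows for isolated
nodes).  By default the propagation operator M is the *transpose* of the
row-normalized matrix — i.e. the column-normalized adjacency — so that mass
flows out of each node in proportion to its normalized out-weights and the
total probability is conserved on graphs without isolated nodes.  For
graphs with a symmetric degree profile the transpose and the literal
row-normalized operator coincide; the literal form is available via
``PropagationConfig.literal_update`` for comparison.

The fixed point satisfies (I - (1 - alpha) M) p = alpha p_0, which
``rwr_solve`` computes directly by dense linear solve; the iterative and
direct routes agree to solver precision and serve as mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .model import SeedSet, warn


@dataclass
class PropagationConfig:
    """RWR tuning knobs.

    alpha: restart probability in (0, 1); 0.5 balances seed proximity and
        network smoothing.
    tol: L1 convergence tolerance on successive iterates.
    max_iter: iteration cap; non-convergence yields a warning, not an error.
    literal_update: apply the row-normalized matrix as written instead of
        its transpose (does not conserve probability on asymmetric-degree
        graphs; off by default).
    weighted: use |PCC| edge weights instead of binary adjacency (off by
        default).
    """

    alpha: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1000
    literal_update: bool = False
    weighted: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TransitionMatrix:
    """Row-normalized adjacency with its node ordering (sorted gene ids)."""

    nodes: list[str]
    W: sp.csr_array

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, node: str) -> int:
        return self.nodes.index(node)


@dataclass
class ProbabilityVector:
    nodes: list[str]
    p: np.ndarray


@dataclass
class PropagationResult:
    """Stationary RWR scores with deterministic dense ranks.

    Rank 1 is the highest score; ties are broken lexicographically by gene
    id so that output is identical across runs and platforms.
    """

    nodes: list[str]
    scores: np.ndarray
    rank: np.ndarray
    iterations: int
    converged: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": self.nodes, "score": self.scores, "rank": self.rank}
        ).sort_values("rank").reset_index(drop=True)

    def score_of(self, node: str) -> float:
        return float(self.scores[self.nodes.index(node)])


def build_transition(net: nx.Graph, weighted: bool = False) -> TransitionMatrix:
    """Row-normalize the (binary, or |PCC|-weighted) adjacency of ``net``.

    Node order is sorted gene id.  Isolated nodes keep an all-zero row per
    the zero-degree convention.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot build a transition matrix from an empty network")
    nodes = sorted(net.nodes)
    if weighted:
        for a, b, data in net.edges(data=True):
            net.edges[a, b]["_w"] = abs(data.get("pcc", 1.0))
        A = sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, weight="_w"))
    else:
        A = sp.csr_array(nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None))
    A = A.astype(float)
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum != 0)
    W = sp.csr_array(sp.diags(inv) @ A)
    return TransitionMatrix(nodes=nodes, W=W)


def make_p0(nodes: list[str], seeds: SeedSet) -> ProbabilityVector:
    """Uniform restart vector: 1/n on each seed present in the network.

    Seeds absent from the network are dropped with a warning and n is
    recomputed over the present seeds; no seed present is an error.
    """
    present = [g for g in nodes if g in seeds.seed_ids]
    absent = seeds.seed_ids - set(nodes)
    if absent:
        warn(f"{len(absent)} seed(s) absent from the network were dropped")
    if not present:
        raise ValueError("no seed gene is present in the network")
    p = np.zeros(len(nodes))
    idx = [i for i, g in enumerate(nodes) if g in seeds.seed_ids]
    p[idx] = 1.0 / len(present)
    return ProbabilityVector(nodes=list(nodes), p=p)


def _operator(W: TransitionMatrix, cfg_literal: bool) -> sp.sparray:
    return W.W if cfg_literal else W.W.T


def _ranks(nodes: list[str], scores: np.ndarray) -> np.ndarray:
    order = sorted(range(len(nodes)), key=lambda i: (-scores[i], nodes[i]))
    rank = np.empty(len(nodes), dtype=int)
    rank[order] = np.arange(1, len(nodes) + 1)
    return rank


def rwr_iterate(
    W: TransitionMatrix,
    p0: ProbabilityVector,
    cfg: PropagationConfig | None = None,
) -> PropagationResult:
    """Power-iterate the RWR update to the stationary distribution.

    Stops when the L1 change between successive iterates drops below
    ``cfg.tol`` (geometric contraction at rate <= 1 - alpha guarantees
    convergence) or at ``cfg.max_iter``, in which case the result is
    returned with ``converged = False`` and a warning.
    """
    cfg = cfg or PropagationConfig()
    if len(p0.p) != W.n:
        raise ValueError("p0 dimension does not match transition matrix")
    M = _operator(W, cfg.literal_update)
    p = p0.p.copy()
    restart = cfg.alpha * p0.p
    damp = 1.0 - cfg.alpha
    iterations = 0
    converged = False
    for iterations in range(1, cfg.max_iter + 1):
        p_next = damp * (M @ p) + restart
        if np.abs(p_next - p).sum() < cfg.tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        warn(f"RWR did not converge in {cfg.max_iter} iterations")
    return PropagationResult(
        nodes=list(W.nodes),
        scores=p,
        rank=_ranks(W.nodes, p),
        iterations=iterations,
        converged=converged,
    )


def rwr_solve(
    W: TransitionMatrix,
    p0: ProbabilityVector,
    alpha: float = 0.5,
    literal_update: bool = False,
) -> ProbabilityVector:
    """Exact stationary distribution via dense linear solve.

    Solves (I - (1 - alpha) M) p = alpha p_0; the system is nonsingular for
    alpha in (0, 1) because the propagation operator is substochastic.
    Intended for tests and small networks.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    M = _operator(W, literal_update).toarray()
    A = np.eye(W.n) - (1.0 - alpha) * M
    p = scipy.linalg.solve(A, alpha * p0.p)
    return ProbabilityVector(nodes=list(W.nodes), p=p)


class RWRSolver:
    """Factorized direct solver for repeated RWR runs on one network.

    LU-factorizes (I - (1 - alpha) M) once so that each restart vector
    costs only a pair of triangular solves — the workhorse of the
    permutation null, where thousands of pseudo-seed walks share a network.
    """

    def __init__(
        self,
        W: TransitionMatrix,
        alpha: float = 0.5,
        literal_update: bool = False,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        self.nodes = list(W.nodes)
        self.alpha = alpha
        M = _operator(W, literal_update).toarray()
        self._lu = scipy.linalg.lu_factor(np.eye(W.n) - (1.0 - alpha) * M)

    def solve(self, p0: np.ndarray) -> np.ndarray:
        return scipy.linalg.lu_solve(self._lu, self.alpha * p0)


def rwr_from_network(
    net: nx.Graph, seeds: SeedSet, cfg: PropagationConfig | None = None
) -> PropagationResult:
    """Convenience wrapper: transition matrix + restart vector + iteration."""
    cfg = cfg or PropagationConfig()
    W = build_transition(net, weighted=cfg.weighted)
    p0 = make_p0(W.nodes, seeds)
    return rwr_iterate(W, p0, cfg)
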