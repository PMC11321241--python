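"""Median-split differential expression and enrichment validation.

Samples are split at the median of a per-sample stemness index (ties go to
the high group).  Per gene, the fold change is the ratio of group means
with a pseudocount, log2FC = log2((mean_high + c) / (mean_low + c)), and
the p-value comes from a two-sided Wilcoxon rank-sum test (Welch t-test
available by flag); Benjamini–Hochberg adjustment across all tested genes
yields the FDR.  A gene is differentially expressed when |log2FC| is
strictly above the fold-change threshold AND the FDR is strictly below the
FDR threshold.  Enrichment of a predicted gene set in a DE gene set is the
one-sided hypergeometric upper-tail probability of the observed overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .model import ExpressionMatrix, StemnessIndexVector


@dataclass
class EnrichmentResult:
    """2x2 overlap test: k predicted-and-DE genes out of n predicted, K DE,
    N universe."""

    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p_value: float


def median_split(
    expr: ExpressionMatrix, index: StemnessIndexVector
) -> tuple[list[str], list[str]]:
    """Split samples at the median stemness index.

    Returns (low, high) sample-id lists: low = index < median, high =
    index >= median.  Both sides must end up with at least 2 samples.
    """
    index.check_samples(expr)
    samples = [s for s in expr.sample_ids if s in set(index.sample_ids)]
    vals = index.values.loc[samples].to_numpy(dtype=float)
    med = float(np.median(vals))
    low = [s for s, v in zip(samples, vals) if v < med]
    high = [s for s, v in zip(samples, vals) if v >= med]
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"degenerate median split: {len(low)} low / {len(high)} high "
            "samples (need >= 2 per side)"
        )
    return low, high


def differential_expression(
    expr: ExpressionMatrix,
    groups: tuple[list[str], list[str]],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-gene differential expression between the (low, high) groups.

    Returns a DataFrame indexed by gene id with columns log2fc, p_value,
    fdr, is_de and constant; genes constant across all samples get p = 1 by
    convention and are flagged in ``constant``.
    """
    low, high = groups
    if len(low) < 2 or len(high) < 2:
        raise ValueError("both groups need at least 2 samples")
    lo = expr.values[low].to_numpy(dtype=float)
    hi = expr.values[high].to_numpy(dtype=float)
    mean_lo = lo.mean(axis=1)
    mean_hi = hi.mean(axis=1)
    log2fc = np.log2((mean_hi + pseudocount) / (mean_lo + pseudocount))

    both = np.concatenate([lo, hi], axis=1)
    constant = np.ptp(both, axis=1) == 0

    pvals = np.ones(expr.n_genes)
    active = ~constant
    if active.any():
        if test == "ranksum":
            res = scipy.stats.mannwhitneyu(
                hi[active], lo[active], axis=1, alternative="two-sided"
            )
            pvals[active] = res.pvalue
        elif test == "ttest":
            res = scipy.stats.ttest_ind(
                hi[active], lo[active], axis=1, equal_var=False
            )
            pvals[active] = res.pvalue
        else:
            raise ValueError(f"test must be 'ranksum' or 'ttest', got {test!r}")
    fdr = scipy.stats.false_discovery_control(pvals, method="bh")
    is_de = (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_de": is_de,
            "constant": constant,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def enrichment_test(
    predicted: set[str], de: set[str], universe: set[str]
) -> EnrichmentResult:
    """One-sided hypergeometric upper-tail test of predicted/DE overlap.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with k = |predicted & de|,
    K = |de|, n = |predicted|, N = |universe|.  The odds ratio comes from
    the 2x2 table with a Haldane 0.5 correction when a cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not predicted <= universe:
        raise ValueError("predicted set is not a subset of the universe")
    if not de <= universe:
        raise ValueError("DE set is not a subset of the universe")
    N = len(universe)
    K = len(de)
    n = len(predicted)
    k = len(predicted & de)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    a, b = k, n - k
    c, d = K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return EnrichmentResult(k=k, K=K, n=n, N=N, odds_ratio=float(odds_ratio), p_value=p)
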