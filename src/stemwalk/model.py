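"""Shared domain types for the stemness-ncRNA prediction pipeline.

The pipeline operates on four kinds of molecular players — protein-coding
genes (PCG), transcription factors (TF), long non-coding RNAs (lncRNA) and
microRNAs (miRNA).  TFs are a distinct biotype for regulatory-interaction
validation but are treated as PCGs when co-expression pairs are categorized,
because the co-expression network distinguishes only PCG/lncRNA/miRNA pair
types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

BIOTYPES = ("PCG", "TF", "lncRNA", "miRNA")

#: Pair categories produced when building co-expression networks.
COEXPRESSION_CATEGORIES = ("PCG-PCG", "PCG-lncRNA", "miRNA-PCG", "miRNA-lncRNA")

#: The eight admissible curated regulatory interaction categories.
REGULATORY_CATEGORIES = (
    "TF-miRNA",
    "TF-lncRNA",
    "TF-PCG",
    "miRNA-lncRNA",
    "miRNA-TF",
    "miRNA-PCG",
    "lncRNA-TF",
    "lncRNA-PCG",
)

#: Categories ranked by descending |PCC| (strong co-expression of either sign).
ABS_RANKED_CATEGORIES = frozenset({"PCG-PCG", "PCG-lncRNA"})
#: Categories ranked ascending by signed PCC (most negative first), reflecting
#: the repressive action of miRNAs on their targets.
SIGNED_RANKED_CATEGORIES = frozenset({"miRNA-PCG", "miRNA-lncRNA"})


def coexpression_group(biotype: str) -> str:
    """Collapse a biotype to its co-expression grouping (TF counts as PCG)."""
    if biotype not in BIOTYPES:
        raise ValueError(f"unknown biotype {biotype!r}; expected one of {BIOTYPES}")
    return "PCG" if biotype in ("PCG", "TF") else biotype


def pair_category(biotype_a: str, biotype_b: str) -> str | None:
    """Co-expression category of a gene pair, or None if the pair type is
    not part of the network (lncRNA-lncRNA, miRNA-miRNA, lncRNA-miRNA are
    excluded by construction; only the four canonical pair types are built)."""
    groups = frozenset((coexpression_group(biotype_a), coexpression_group(biotype_b)))
    if groups == frozenset({"PCG"}):
        return "PCG-PCG"
    if groups == frozenset({"PCG", "lncRNA"}):
        return "PCG-lncRNA"
    if groups == frozenset({"miRNA", "PCG"}):
        return "miRNA-PCG"
    if groups == frozenset({"miRNA", "lncRNA"}):
        return "miRNA-lncRNA"
    return None


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus a per-gene biotype annotation.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  Expression units are taken as supplied and assumed to be
    log-scale-comparable; no transformation is applied here.
    """

    values: pd.DataFrame
    biotype: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if len(cols) < 3:
            raise ValueError(
                f"expression matrix needs at least 3 samples, got {len(cols)}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        missing = [g for g in idx if g not in self.biotype]
        if missing:
            raise ValueError(f"genes missing from biotype map: {missing}")
        bad_bt = {g: b for g, b in self.biotype.items() if b not in BIOTYPES}
        if bad_bt:
            raise ValueError(
                f"unknown biotypes {bad_bt}; expected one of {BIOTYPES}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(
            values=self.values.loc[genes],
            biotype={g: self.biotype[g] for g in genes},
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(values=self.values[list(samples)], biotype=dict(self.biotype))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. published stemness signatures) used for seed
    selection."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def membership_counts(self) -> dict[str, int]:
        """Number of sets each gene appears in."""
        counts: dict[str, int] = {}
        for members in self.sets.values():
            for g in members:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass(frozen=True)
class SeedSet:
    """Genes injecting restart probability mass in the random walk."""

    seed_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seed_ids:
            raise ValueError("seed set must be non-empty")

    @property
    def n(self) -> int:
        return len(self.seed_ids)

    @classmethod
    def of(cls, ids: Iterable[str]) -> "SeedSet":
        return cls(frozenset(ids))


class Interaction(NamedTuple):
    source: str
    target: str
    category: str


@dataclass
class InteractionList:
    """Curated regulatory interactions typed by one of the eight categories."""

    records: list[Interaction]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.category not in REGULATORY_CATEGORIES:
                raise ValueError(
                    f"unknown interaction category {rec.category!r}; "
                    f"valid categories: {', '.join(REGULATORY_CATEGORIES)}"
                )
            if rec.source == rec.target:
                raise ValueError(f"self-interaction not allowed: {rec.source!r}")

    def __len__(self) -> int:
        return len(self.records)

    def validate_biotypes(self, biotype: Mapping[str, str]) -> None:
        """Check every record's category against a biotype map.  Genes absent
        from the map are skipped (curated lists routinely exceed any one
        cancer's expression matrix)."""
        for rec in self.records:
            bt_s = biotype.get(rec.source)
            bt_t = biotype.get(rec.target)
            if bt_s is None or bt_t is None:
                continue
            expected = f"{bt_s}-{bt_t}"
            if expected != rec.category:
                raise ValueError(
                    f"interaction {rec.source}->{rec.target} declared "
                    f"{rec.category!r} but biotypes give {expected!r}"
                )


@dataclass
class StemnessIndexVector:
    """Per-sample stemness index in [0, 1]; values near 1 indicate stronger
    stem-cell character.  Computed externally (e.g. mRNAsi); an input here."""

    values: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in stemness index")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("stemness index contains non-finite values")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("stemness index values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def check_samples(self, expr: ExpressionMatrix) -> None:
        extra = set(self.sample_ids) - set(expr.sample_ids)
        if extra:
            raise ValueError(
                f"stemness index samples absent from expression matrix: {sorted(extra)}"
            )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
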