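"""Readers and writers for every on-disk representation the pipeline touches.

Dialect: tab-separated UTF-8 text; lines starting with '#' are comments and
are ignored.  Scores are serialized at 10 significant digits, which makes
every reader/writer pair a lossless round trip at that precision.
"""

from __future__ import annotations

import os
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .model import (
    BIOTYPES,
    ExpressionMatrix,
    GeneSetCollection,
    Interaction,
    InteractionList,
    StemnessIndexVector,
)

FLOAT_FMT = "%.10g"


def _data_lines(handle: TextIO) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    for i, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield i, line


def read_biotypes(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> biotype."""
    biotype: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            gene, bt = fields
            if bt not in BIOTYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown biotype {bt!r} for {gene!r}; "
                    f"valid: {', '.join(BIOTYPES)}"
                )
            if gene in biotype:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            biotype[gene] = bt
    return biotype


def write_biotypes(biotype: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, bt in biotype.items():
            fh.write(f"{gene}\t{bt}\n")


def read_expression(
    path: str | os.PathLike, biotype_path: str | os.PathLike
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV plus its biotype map.

    The TSV has a header row of sample ids; the first column holds gene ids.
    Row and column order are preserved.  Errors name the offending gene,
    sample or cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dup}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            gene = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
    biotype = read_biotypes(biotype_path)
    missing = [g for g in df.index if g not in biotype]
    if missing:
        raise ValueError(f"{path}: genes missing from biotype map: {missing}")
    return ExpressionMatrix(values=df.astype(float), biotype={g: biotype[g] for g in df.index})


def write_expression(
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    biotype_path: str | os.PathLike | None = None,
) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
    if biotype_path is not None:
        write_biotypes(expr.biotype, biotype_path)


def read_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, then member ids,
    tab-separated, one set per line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < 3:
                name = fields[0] if fields else "<unnamed>"
                raise ValueError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_interactions(path: str | os.PathLike) -> InteractionList:
    """Read a regulatory interaction TSV with columns source, target,
    category.  Category strings are validated against the eight admissible
    regulatory relationship types."""
    records: list[Interaction] = []
    with open(path, encoding="utf-8") as fh:
        lines = list(_data_lines(fh))
    if lines and lines[0][1].split("\t")[0] in ("source", "source_id"):
        lines = lines[1:]
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        records.append(Interaction(*fields))
    try:
        return InteractionList(records=records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_interactions(interactions: InteractionList, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tcategory\n")
        for rec in interactions.records:
            fh.write(f"{rec.source}\t{rec.target}\t{rec.category}\n")


def read_stemness_index(path: str | os.PathLike) -> StemnessIndexVector:
    """Read a two-column TSV of sample_id, stemness index in [0, 1]."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample_id", "index"])
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    series = pd.Series(
        pd.to_numeric(df["index"].to_numpy(), errors="raise"),
        index=df["sample_id"].astype(str).to_numpy(),
    )
    return StemnessIndexVector(values=series)


def write_stemness_index(index: StemnessIndexVector, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tindex\n")
        for sid, val in index.values.items():
            fh.write(f"{sid}\t{FLOAT_FMT % val}\n")


def write_results(result, null, biotype: dict[str, str], path: str | os.PathLike) -> None:
    """Write a prediction result table: gene_id, biotype, score, rank,
    empirical_p, significant; sorted by rank ascending.

    ``result`` is a PropagationResult and ``null`` a PermutationNull computed
    over the same node set (a mismatch is an error).
    """
    if null is not None and list(result.nodes) != list(null.nodes):
        raise ValueError("PropagationResult and PermutationNull node sets differ")
    order = np.argsort(result.rank)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tbiotype\tscore\trank\tempirical_p\tsignificant\n")
        for i in order:
            node = result.nodes[i]
            p = FLOAT_FMT % null.empirical_p[i] if null is not None else "NA"
            sig = str(bool(null.significant[i])) if null is not None else "NA"
            fh.write(
                f"{node}\t{biotype.get(node, 'PCG')}\t"
                f"{FLOAT_FMT % result.scores[i]}\t{result.rank[i]}\t{p}\t{sig}\n"
            )


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df


def write_pairs(ranked, path: str | os.PathLike) -> None:
    """Write a RankedPairSet as an edge-list TSV: node_a, node_b, category,
    pcc, rank."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcategory\tpcc\trank\n")
        for category in ranked.categories():
            df = ranked.pairs[category]
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.gene_a}\t{row.gene_b}\t{category}\t"
                    f"{FLOAT_FMT % row.pcc}\t{row.rank}\n"
                )


def read_pairs(path: str | os.PathLike):
    """Read an edge-list TSV back into a RankedPairSet."""
    from .coexpression import RankedPairSet

    df = pd.read_csv(path, sep="\t", comment="#")
    pairs: dict[str, pd.DataFrame] = {}
    for category, sub in df.groupby("category", sort=False):
        pairs[category] = (
            sub[["gene_a", "gene_b", "pcc", "rank"]]
            if "gene_a" in sub.columns
            else sub.rename(columns={"node_a": "gene_a", "node_b": "gene_b"})[
                ["gene_a", "gene_b", "pcc", "rank"]
            ]
        ).sort_values("rank").reset_index(drop=True)
    totals = {cat: len(d) for cat, d in pairs.items()}
    return RankedPairSet(pairs=pairs, totals=totals)
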