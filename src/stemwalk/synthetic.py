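"""Synthetic expression data with a planted stemness program.

The generator emulates the statistical structure the pipeline exploits: a
latent per-sample "stemness" factor z ~ N(0, 1) to which seed PCGs and a
planted subset of ncRNAs are correlated — positively for PCGs and lncRNAs,
negatively for miRNAs (miRNAs repress their targets, so stemness-driving
miRNA loss shows up as anti-correlation).  Signal genes follow

    x = baseline + amplitude * (rho * z + sqrt(1 - rho^2) * eps),   eps ~ N(0, 1)

so any two signal genes share population correlation rho^2 (or -rho^2
across the miRNA sign flip).  Background genes are independent noise,
baseline + amplitude * noise_sd * eps, with noise_sd < 1 by default: genes
driven by a biological program carry an extra variance component on top of
measurement noise, which is what makes the bottom-quantile variance filter
preferentially discard background.  The stemness index is the logistic
squash of z, landing in [0, 1] with values near 1 marking stem-like
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    Interaction,
    InteractionList,
    SeedSet,
    StemnessIndexVector,
)


@dataclass
class SyntheticSpec:
    """Study-condition knobs for the generator.

    effect is the loading rho of signal genes on the latent factor;
    noise_sd scales background-gene noise relative to the signal genes'
    unit marginal (0.8 leaves background variance at 64% of signal
    variance); baseline and amplitude place values on a plausible log2
    expression scale.
    """

    n_samples: int = 200
    n_seed_pcgs: int = 30
    n_true_lnc: int = 10
    n_true_mir: int = 10
    n_noise_genes: int = 400
    effect: float = 0.9
    noise_sd: float = 0.8
    baseline: float = 2.0
    amplitude: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_seed_pcgs", "n_true_lnc", "n_true_mir", "n_noise_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.effect < 1:
            raise ValueError(f"effect (rho) must be in [0, 1), got {self.effect}")


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    index: StemnessIndexVector
    truth: dict[str, bool] = field(repr=False)
    seeds: SeedSet = None

    @property
    def true_ncrnas(self) -> list[str]:
        return [g for g, t in self.truth.items() if t and g not in self.seeds.seed_ids]

    @property
    def noise_ncrnas(self) -> list[str]:
        return [
            g
            for g in self.expr.gene_ids
            if self.expr.biotype[g] in ("lncRNA", "miRNA") and not self.truth[g]
        ]


def _noise_split(n: int) -> tuple[int, int, int]:
    """Background biotype allocation: half PCG, a quarter lncRNA, rest miRNA."""
    n_pcg = n // 2
    n_lnc = n // 4
    return n_pcg, n_lnc, n - n_pcg - n_lnc


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a SyntheticDataset; bit-identical for identical ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    rho = spec.effect
    loading = math.sqrt(1.0 - rho * rho)
    z = rng.standard_normal(spec.n_samples)

    names: list[str] = []
    biotype: dict[str, str] = {}
    truth: dict[str, bool] = {}
    rows: list[np.ndarray] = []

    def signal_row(sign: float) -> np.ndarray:
        eps = rng.standard_normal(spec.n_samples)
        return spec.baseline + spec.amplitude * (sign * rho * z + loading * eps)

    def noise_row() -> np.ndarray:
        eps = rng.standard_normal(spec.n_samples)
        return spec.baseline + spec.amplitude * spec.noise_sd * eps

    seed_ids = []
    for i in range(spec.n_seed_pcgs):
        g = f"SPCG{i + 1:04d}"
        names.append(g)
        biotype[g] = "PCG"
        truth[g] = True
        seed_ids.append(g)
        rows.append(signal_row(+1.0))
    for i in range(spec.n_true_lnc):
        g = f"TLNC{i + 1:04d}"
        names.append(g)
        biotype[g] = "lncRNA"
        truth[g] = True
        rows.append(signal_row(+1.0))
    for i in range(spec.n_true_mir):
        g = f"TMIR{i + 1:04d}"
        names.append(g)
        biotype[g] = "miRNA"
        truth[g] = True
        rows.append(signal_row(-1.0))
    n_pcg, n_lnc, n_mir = _noise_split(spec.n_noise_genes)
    for prefix, bt, count in (
        ("NPCG", "PCG", n_pcg),
        ("NLNC", "lncRNA", n_lnc),
        ("NMIR", "miRNA", n_mir),
    ):
        for i in range(count):
            g = f"{prefix}{i + 1:04d}"
            names.append(g)
            biotype[g] = bt
            truth[g] = False
            rows.append(noise_row())

    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(rows), index=names, columns=samples),
        biotype=biotype,
    )
    index = StemnessIndexVector(
        values=pd.Series(1.0 / (1.0 + np.exp(-z)), index=samples)
    )
    return SyntheticDataset(
        expr=expr, index=index, truth=truth, seeds=SeedSet.of(seed_ids)
    )


def generate_interactions(
    dataset: SyntheticDataset,
    frac_true: float = 1.0,
    frac_decoy: float = 0.0,
    rng_seed: int = 0,
) -> InteractionList:
    """Curated-interaction fixture: a fraction of planted ncRNAs wired to
    seed PCGs, plus decoy records among background genes.

    Record counts follow a floor convention: floor(frac_true * n_planted)
    planted records and floor(frac_decoy * n_background_ncRNA) decoys.
    """
    if not 0 <= frac_true <= 1 or not 0 <= frac_decoy <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    seeds = sorted(dataset.seeds.seed_ids)
    true_nc = dataset.true_ncrnas
    noise_nc = dataset.noise_ncrnas
    noise_pcg = [
        g
        for g in dataset.expr.gene_ids
        if dataset.expr.biotype[g] == "PCG" and not dataset.truth[g]
    ]
    records: list[Interaction] = []

    n_true = math.floor(frac_true * len(true_nc))
    chosen = rng.choice(len(true_nc), size=n_true, replace=False) if n_true else []
    for i in sorted(chosen):
        nc = true_nc[i]
        pcg = seeds[int(rng.integers(len(seeds)))]
        cat = "miRNA-PCG" if dataset.expr.biotype[nc] == "miRNA" else "lncRNA-PCG"
        records.append(Interaction(nc, pcg, cat))

    n_decoy = math.floor(frac_decoy * len(noise_nc))
    chosen = rng.choice(len(noise_nc), size=n_decoy, replace=False) if n_decoy else []
    for i in sorted(chosen):
        nc = noise_nc[i]
        pcg = noise_pcg[int(rng.integers(len(noise_pcg)))]
        cat = "miRNA-PCG" if dataset.expr.biotype[nc] == "miRNA" else "lncRNA-PCG"
        records.append(Interaction(nc, pcg, cat))

    return InteractionList(records=records)
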