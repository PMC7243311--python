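"""Additive Shannon-entropy diversity partitioning of community tables.

Total (gamma) diversity across a set of communities is decomposed as
``gamma = alpha + beta`` where alpha is the weighted mean within-sample
entropy and beta the among-sample component.  Entropy is Shannon (order 1),
in nats; the alpha/beta percentages reported are scale-free, so the log base
is immaterial.  With sample weights ``w_i`` and relative-abundance rows
``p_i``::

    alpha = sum_i w_i H(p_i)
    gamma = H(sum_i w_i p_i)
    beta  = gamma - alpha          (>= 0 by concavity of H)

Weights default to sample-size-proportional (``w_i`` = sample total / grand
total); equal weights are available.  Gamma is computed on the weight-mixed
distribution rather than on pooled raw counts so that additivity is exact
under either weighting scheme.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .tables import FunctionHierarchy, FunctionTable, aggregate_to_tier, relative_abundance

#: beta values smaller than this (relative to gamma + 1) are snapped to zero;
#: they arise from float summation when all rows are identical
_BETA_SNAP = 1e-12


def shannon_entropy(p: Sequence[float] | np.ndarray, atol: float = 1e-9) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a probability vector, in nats.

    ``0 * ln 0`` is taken as 0.  The vector must be non-negative and sum to 1
    within ``atol``.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probability vector has negative entries")
    s = p.sum()
    if abs(s - 1.0) > atol:
        raise ValueError(f"probability vector sums to {s}, not 1")
    return float(-xlogy(p, p).sum())


@dataclass
class DiversityPartition:
    """Alpha/beta/gamma entropies (nats) and percentages for one table level."""

    alpha_entropy: float
    beta_entropy: float
    gamma_entropy: float
    alpha_pct: float
    beta_pct: float
    level: str
    weights: pd.Series

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "alpha_entropy": self.alpha_entropy,
            "beta_entropy": self.beta_entropy,
            "gamma_entropy": self.gamma_entropy,
            "alpha_pct": self.alpha_pct,
            "beta_pct": self.beta_pct,
            "weights": self.weights.to_dict(),
        }


def partition_diversity(
    table: FunctionTable, weighting: str = "size_proportional"
) -> DiversityPartition:
    """Partition a table's Shannon entropy into alpha, beta and gamma.

    ``weighting`` is ``"size_proportional"`` (default) or ``"equal"``.
    ``alpha_pct`` is defined as 100 when gamma = 0 (a single shared category)
    so the report always totals 100.
    """
    if weighting not in ("size_proportional", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    P = relative_abundance(table).to_numpy()
    n = P.shape[0]
    if weighting == "equal":
        w = np.full(n, 1.0 / n)
    else:
        totals = table.sample_totals.to_numpy(dtype=float)
        w = totals / totals.sum()
    alpha = float(np.dot(w, -xlogy(P, P).sum(axis=1)))
    mixed = w @ P
    gamma = float(-xlogy(mixed, mixed).sum())
    beta = gamma - alpha
    if abs(beta) <= _BETA_SNAP * (gamma + 1.0):
        beta = 0.0
        gamma = alpha + beta
    alpha_pct = 100.0 if gamma == 0 else 100.0 * alpha / gamma
    return DiversityPartition(
        alpha_entropy=alpha,
        beta_entropy=beta,
        gamma_entropy=alpha + beta,
        alpha_pct=alpha_pct,
        beta_pct=100.0 - alpha_pct,
        level=table.level,
        weights=pd.Series(w, index=table.sample_ids, name="weight"),
    )


def partition_by_level(
    gene_table: FunctionTable,
    hierarchy: FunctionHierarchy,
    levels: Sequence[str] = ("tier1", "tier2", "tier3", "gene"),
    weighting: str = "size_proportional",
) -> list[DiversityPartition]:
    """One diversity partition per aggregation level of a gene-level table."""
    out = []
    for level in levels:
        agg = aggregate_to_tier(gene_table, hierarchy, level) if level != "gene" else gene_table
        out.append(partition_diversity(agg, weighting=weighting))
    return out


def replicate_robustness(
    table: FunctionTable,
    hierarchy: FunctionHierarchy | None = None,
    levels: Sequence[str] = ("gene",),
    weighting: str = "size_proportional",
    limit: int = 1024,
    seed: int = 0,
) -> tuple[list[dict[str, DiversityPartition]], pd.DataFrame]:
    """Re-partition over all single-sample-per-host subsample combinations.

    Enumerates every way of keeping exactly one sample per host species (the
    full cross-product over hosts with replicates).  When the number of
    combinations exceeds ``limit`` a seeded uniform subsample of combinations
    is evaluated instead.  Returns the per-combination partitions and a
    min/median/max summary of ``beta_pct`` per level.
    """
    groups = table.host_samples()
    choices = [samples for samples in groups.values()]
    n_combo = int(np.prod([len(c) for c in choices]))
    if n_combo <= limit:
        combos: Iterable[tuple[str, ...]] = itertools.product(*choices)
    else:
        rng = np.random.default_rng(seed)
        combos = (
            tuple(c[rng.integers(len(c))] for c in choices) for _ in range(limit)
        )
    results: list[dict[str, DiversityPartition]] = []
    for combo in combos:
        sub = table.subset(list(combo))
        if hierarchy is None:
            parts = {table.level: partition_diversity(sub, weighting=weighting)}
        else:
            parts = {
                p.level: p
                for p in partition_by_level(sub, hierarchy, levels, weighting=weighting)
            }
        results.append(parts)
    rows = []
    for level in results[0]:
        betas = np.array([r[level].beta_pct for r in results])
        rows.append(
            {
                "level": level,
                "n_combinations": len(results),
                "beta_pct_min": betas.min(),
                "beta_pct_median": float(np.median(betas)),
                "beta_pct_max": betas.max(),
            }
        )
    return results, pd.DataFrame(rows).set_index("level")


def diversity_report(partitions: Sequence[DiversityPartition]) -> pd.DataFrame:
    """Two-row report (alpha/beta percentages) with one column per level."""
    return pd.DataFrame(
        {
            p.level: {"Alpha diversity (%)": p.alpha_pct, "Beta diversity (%)": p.beta_pct}
            for p in partitions
        }
    )


def write_diversity_report(
    partitions: Sequence[DiversityPartition], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    diversity_report(partitions).round(1).to_csv(tsv_path, sep="\t", lineterminator="\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([p.to_dict() for p in partitions], fh, indent=2, sort_keys=True)
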