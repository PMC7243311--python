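"""Fixed-margin null models for host filtering of functions and taxa.

Each observed (sample, function) count is compared with its distribution
under randomizations of the count matrix that preserve row (sample) and
column (function) totals.  A cell is flagged ``high`` when the observed
count strictly exceeds at least ceil(upper_quantile * n) of the null draws,
``low`` when it is strictly below at least that many; ties count toward
neither tail, which makes the flags conservative on discrete counts.

Two randomization algorithms are available:

``patefield``
    Uniform sampling over all contingency tables with the given margins
    (Patefield's sequential conditional-hypergeometric construction, via
    ``scipy.stats.random_table``).  The default.
``swap_count``
    Sequential 2x2 unit swaps that additionally preserve matrix fill (the
    number of non-zero cells), for the stricter reading where the number of
    functions present per community is held constant.

Null draws are streamed in batches and reduced to per-cell exceedance
counters; the full null ensemble is never materialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import ceil
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import random_table

from .tables import FunctionHierarchy, FunctionTable, aggregate_to_tier


@dataclass
class NullModelConfig:
    """Parameters of the fixed-margin null model."""

    n_randomizations: int = 9999
    upper_quantile: float = 0.95
    lower_quantile: float = 0.05
    algorithm: str = "patefield"
    seed: int = 0
    batch_size: int = 200
    swap_thin: int | None = None  # swaps between draws; default 4 x cells

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if not (0 < self.lower_quantile < self.upper_quantile < 1):
            raise ValueError("need 0 < lower_quantile < upper_quantile < 1")
        if self.algorithm not in ("patefield", "swap_count"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def patefield_sample(
    row_totals: Sequence[int], col_totals: Sequence[int], seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One contingency table drawn uniformly given exact row/column totals."""
    rows = np.asarray(row_totals, dtype=np.int64)
    cols = np.asarray(col_totals, dtype=np.int64)
    if rows.sum() != cols.sum():
        raise ValueError(f"margin sums differ: rows {rows.sum()} vs columns {cols.sum()}")
    forced = _forced_table(rows, cols)
    if forced is not None:
        return forced
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = random_table(rows, cols).rvs(method="patefield", random_state=rng)
    return np.asarray(draw, dtype=np.int64)


def _forced_table(rows: np.ndarray, cols: np.ndarray) -> np.ndarray | None:
    """The unique table when margins admit only one (single row or column)."""
    if len(rows) == 1:
        return cols[None, :].copy()
    if len(cols) == 1:
        return rows[:, None].copy()
    return None


def _patefield_batches(
    rows: np.ndarray, cols: np.ndarray, n: int, batch: int, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    forced = _forced_table(rows, cols)
    if forced is not None:
        yield np.broadcast_to(forced, (n,) + forced.shape)
        return
    dist = random_table(rows, cols)
    done = 0
    while done < n:
        m = min(batch, n - done)
        draws = np.asarray(dist.rvs(m, method="patefield", random_state=rng), dtype=np.int64)
        if draws.ndim == 2:  # scipy squeezes size-1 batches
            draws = draws[None]
        yield draws
        done += m


def swap_count_sample(
    matrix: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> np.ndarray:
    """Apply ``n_swaps`` accepted 2x2 unit swaps preserving margins and fill.

    A candidate swap picks two rows and two columns and moves one count along
    a diagonal; it is accepted only if no cell would go negative and the
    number of zero cells is unchanged.
    """
    m = matrix.copy()
    nr, nc = m.shape
    accepted = 0
    attempts = 0
    max_attempts = 100 * n_swaps + 1000
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i1, i2 = rng.integers(nr), rng.integers(nr)
        j1, j2 = rng.integers(nc), rng.integers(nc)
        if i1 == i2 or j1 == j2:
            continue
        sign = 1 if rng.integers(2) else -1
        a, b, c, d = m[i1, j1], m[i1, j2], m[i2, j1], m[i2, j2]
        na, nb, nc_, nd = a + sign, b - sign, c - sign, d + sign
        if min(na, nb, nc_, nd) < 0:
            continue
        fill_before = (a > 0) + (b > 0) + (c > 0) + (d > 0)
        fill_after = (na > 0) + (nb > 0) + (nc_ > 0) + (nd > 0)
        if fill_before != fill_after:
            continue
        m[i1, j1], m[i1, j2], m[i2, j1], m[i2, j2] = na, nb, nc_, nd
        accepted += 1
    return m


def _swap_batches(
    observed: np.ndarray, n: int, batch: int, thin: int, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    current = observed
    done = 0
    while done < n:
        m = min(batch, n - done)
        out = np.empty((m,) + observed.shape, dtype=np.int64)
        for i in range(m):
            current = swap_count_sample(current, thin, rng)
            out[i] = current
        yield out
        done += m


@dataclass
class FlagMatrix:
    """Per-cell enrichment flags and null exceedance counts."""

    flags: pd.DataFrame  # values in {"high", "low", "none"}
    exceed_high: pd.DataFrame  # null draws strictly below observed
    exceed_low: pd.DataFrame  # null draws strictly above observed
    n_randomizations: int


def _flags_from_counts(
    below: np.ndarray, above: np.ndarray, n: int, upper_quantile: float
) -> np.ndarray:
    """Tail decision from exceedance counters (pure quantile logic)."""
    threshold = ceil(upper_quantile * n)
    flags = np.full(below.shape, "none", dtype=object)
    flags[below >= threshold] = "high"
    flags[above >= threshold] = "low"
    return flags


def null_flags(table: FunctionTable, config: NullModelConfig | None = None) -> FlagMatrix:
    """Flag per-cell over/under-representation against the fixed-margin null."""
    config = config or NullModelConfig()
    obs = table.matrix
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    rng = np.random.default_rng(config.seed)
    n = config.n_randomizations
    if config.algorithm == "patefield":
        batches = _patefield_batches(rows, cols, n, config.batch_size, rng)
    else:
        thin = config.swap_thin if config.swap_thin is not None else 4 * obs.size
        batches = _swap_batches(obs, n, config.batch_size, thin, rng)
    below = np.zeros(obs.shape, dtype=np.int64)
    above = np.zeros(obs.shape, dtype=np.int64)
    for draws in batches:
        below += (draws < obs).sum(axis=0)
        above += (draws > obs).sum(axis=0)
    flags = _flags_from_counts(below, above, n, config.upper_quantile)
    idx, colix = table.counts.index, table.counts.columns
    return FlagMatrix(
        flags=pd.DataFrame(flags, index=idx, columns=colix),
        exceed_high=pd.DataFrame(below, index=idx, columns=colix),
        exceed_low=pd.DataFrame(above, index=idx, columns=colix),
        n_randomizations=n,
    )


@dataclass
class FlagSummary:
    """Tally of flagged (sample, function) combinations at one level."""

    level: str
    n_high: int
    pct_high: float
    n_low: int
    pct_low: float
    total: int

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_high": self.n_high,
            "pct_high": self.pct_high,
            "n_low": self.n_low,
            "pct_low": self.pct_low,
            "total": self.total,
        }


def tally_flags(flag_matrix: FlagMatrix, level: str = "") -> FlagSummary:
    """Counts and percentages of high/low-flagged combinations."""
    vals = flag_matrix.flags.to_numpy()
    total = vals.size
    n_high = int((vals == "high").sum())
    n_low = int((vals == "low").sum())
    return FlagSummary(
        level=level,
        n_high=n_high,
        pct_high=100.0 * n_high / total,
        n_low=n_low,
        pct_low=100.0 * n_low / total,
        total=total,
    )


def filter_levels(
    gene_table: FunctionTable,
    hierarchy: FunctionHierarchy,
    levels: Sequence[str],
    config: NullModelConfig | None = None,
) -> list[tuple[FlagMatrix, FlagSummary]]:
    """Run the null model at each aggregation level, seeding each level's
    randomization stream separately from the master seed."""
    config = config or NullModelConfig()
    out = []
    for i, level in enumerate(levels):
        agg = aggregate_to_tier(gene_table, hierarchy, level) if level != gene_table.level else gene_table
        level_cfg = replace(config, seed=config.seed + i)
        fm = null_flags(agg, level_cfg)
        out.append((fm, tally_flags(fm, level=level)))
    return out


def summary_table(summaries: Sequence[FlagSummary], round_pct: bool = True) -> pd.DataFrame:
    """Report with one row per level: high/low tallies, percentages, total.

    Percentages are rounded to integers in the display table (full precision
    is preserved in the JSON output)."""
    df = pd.DataFrame([s.to_dict() for s in summaries]).set_index("level")
    if round_pct:
        df["pct_high"] = df["pct_high"].round().astype(int)
        df["pct_low"] = df["pct_low"].round().astype(int)
    return df


def write_filter_outputs(
    results: Sequence[tuple[FlagMatrix, FlagSummary]],
    flags_path: str | Path,
    summary_tsv: str | Path,
    summary_json: str | Path,
) -> None:
    rows = []
    for fm, summary in results:
        stacked = fm.flags.stack()
        eh = fm.exceed_high.stack()
        el = fm.exceed_low.stack()
        for (sample, function), flag in stacked.items():
            rows.append(
                {
                    "level": summary.level,
                    "sample": sample,
                    "function": function,
                    "flag": flag,
                    "n_null_below": int(eh.loc[(sample, function)]),
                    "n_null_above": int(el.loc[(sample, function)]),
                }
            )
    pd.DataFrame(rows).to_csv(flags_path, sep="\t", index=False, lineterminator="\n")
    summaries = [s for _, s in results]
    summary_table(summaries).to_csv(summary_tsv, sep="\t", lineterminator="\n")
    with open(summary_json, "w") as fh:
        json.dump([s.to_dict() for s in summaries], fh, indent=2, sort_keys=True)
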