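"""Core containers and file I/O for community function/taxon tables.

The central object is :class:`FunctionTable`, a samples x functions matrix of
non-negative integer read counts together with a sample -> host-species map.
The same container holds taxon tables (the ``level`` attribute is then a
taxonomic rank).  A four-level functional hierarchy (gene -> Tier 3 -> Tier 2
-> Tier 1, mirroring the KEGG BRITE layout) drives aggregation of gene-level
counts to coarser functional categories.

All tables are read and written as UTF-8 tab-separated text with a header row
of function ids and a header column of sample ids, so that a write -> read
round trip is bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical functional aggregation levels, finest first
FUNCTION_LEVELS = ("gene", "tier3", "tier2", "tier1")

#: taxonomic ranks supported for taxon tables, coarsest first
TAXON_RANKS = ("phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED = "UNCLASSIFIED"


class TableError(ValueError):
    """Raised when a table or hierarchy violates its invariants."""


# ---------------------------------------------------------------------------
# FunctionTable
# ---------------------------------------------------------------------------


@dataclass
class FunctionTable:
    """Samples x functions count matrix with host metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = sample ids, columns =
        function (or taxon) ids.  Stored as int64.
    level
        Aggregation level of the columns, e.g. ``"gene"``, ``"tier3"`` or a
        taxonomic rank.  Free-form string; only used for labelling.
    sample_to_host
        Map sample id -> host species id.  Defaults to the identity map
        (each sample is its own host).
    """

    counts: pd.DataFrame
    level: str = "gene"
    sample_to_host: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0:
            raise TableError("no samples")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate function ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float input only when every cell is integral
            frac = arr != np.floor(arr)
            if np.any(frac):
                i, j = np.argwhere(frac)[0]
                raise TableError(
                    f"non-integer count {arr[i, j]!r} at sample "
                    f"{df.index[i]!r}, function {df.columns[j]!r}"
                )
            df = df.astype(np.int64)
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative count {arr[i, j]} at sample {df.index[i]!r}, "
                f"function {df.columns[j]!r}"
            )
        self.counts = df.astype(np.int64)
        if not self.sample_to_host:
            self.sample_to_host = {s: s for s in df.index}
        missing = [s for s in df.index if s not in self.sample_to_host]
        if missing:
            raise TableError(f"samples without a host species: {missing}")
        # keep only mappings for present samples, in sample order
        self.sample_to_host = {s: self.sample_to_host[s] for s in df.index}

    # -- convenience views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def hosts(self) -> pd.Series:
        """Host species id per sample, aligned with the sample index."""
        return pd.Series(self.sample_to_host, name="host").loc[self.sample_ids]

    def host_samples(self) -> dict[str, list[str]]:
        """Samples grouped by host species, hosts in first-appearance order."""
        groups: dict[str, list[str]] = {}
        for s, h in self.sample_to_host.items():
            groups.setdefault(h, []).append(s)
        return groups

    def subset(self, sample_ids: Sequence[str]) -> "FunctionTable":
        return FunctionTable(
            self.counts.loc[list(sample_ids)].copy(),
            level=self.level,
            sample_to_host={s: self.sample_to_host[s] for s in sample_ids},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FunctionTable):
            return NotImplemented
        return (
            self.level == other.level
            and self.counts.equals(other.counts)
            and self.sample_to_host == other.sample_to_host
        )


# ---------------------------------------------------------------------------
# FunctionHierarchy
# ---------------------------------------------------------------------------


@dataclass
class FunctionHierarchy:
    """Four-level functional hierarchy: gene -> tier3 -> tier2 -> tier1.

    Each child has exactly one parent (the maps are plain dicts); the
    composed map gene -> tier1 must be defined for every gene.
    """

    gene_to_tier3: dict[str, str]
    tier3_to_tier2: dict[str, str]
    tier2_to_tier1: dict[str, str]

    def __post_init__(self) -> None:
        missing3 = {t for t in self.gene_to_tier3.values() if t not in self.tier3_to_tier2}
        if missing3:
            raise TableError(f"tier3 categories without a tier2 parent: {sorted(missing3)}")
        missing2 = {t for t in self.tier3_to_tier2.values() if t not in self.tier2_to_tier1}
        if missing2:
            raise TableError(f"tier2 categories without a tier1 parent: {sorted(missing2)}")

    def ancestor(self, gene: str, target: str) -> str:
        """Map a gene id to its category at ``target`` level."""
        if target == "gene":
            return gene
        t3 = self.gene_to_tier3[gene]
        if target == "tier3":
            return t3
        t2 = self.tier3_to_tier2[t3]
        if target == "tier2":
            return t2
        if target == "tier1":
            return self.tier2_to_tier1[t2]
        raise ValueError(f"unknown hierarchy level: {target!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_tier3)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_function_table(
    path: str | Path,
    mapping_path: str | Path | None = None,
    level: str = "gene",
    sep: str = "\t",
) -> FunctionTable:
    """Read a delimited count table (first row function ids, first column
    sample ids) and optionally a two-column sample -> host mapping file."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise TableError(f"no samples: {path} is empty")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] == 0:
        raise TableError(f"no samples in {path}")
    mapping: dict[str, str] = {}
    if mapping_path is not None:
        mp = pd.read_csv(mapping_path, sep=sep)
        if mp.shape[1] < 2:
            raise TableError(f"mapping file {mapping_path} needs 2 columns (sample, host)")
        mapping = dict(zip(mp.iloc[:, 0].astype(str), mp.iloc[:, 1].astype(str)))
    return FunctionTable(df, level=level, sample_to_host=mapping)


def write_function_table(
    table: FunctionTable,
    path: str | Path,
    mapping_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Exact inverse of :func:`read_function_table` (bit-identical round trip)."""
    table.counts.to_csv(path, sep=sep, lineterminator="\n")
    if mapping_path is not None:
        pd.DataFrame(
            {"sample": table.sample_ids, "host": [table.sample_to_host[s] for s in table.sample_ids]}
        ).to_csv(mapping_path, sep=sep, index=False, lineterminator="\n")


def read_hierarchy(path: str | Path, sep: str = "\t") -> FunctionHierarchy:
    """Read a hierarchy file with columns gene, tier3, tier2, tier1."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["gene", "tier3", "tier2", "tier1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"hierarchy file missing columns: {missing}")
    g3: dict[str, str] = {}
    t32: dict[str, str] = {}
    t21: dict[str, str] = {}
    for gene, t3, t2, t1 in df[required].itertuples(index=False):
        for child, parent, store, lvl in ((gene, t3, g3, "gene"), (t3, t2, t32, "tier3"), (t2, t1, t21, "tier2")):
            if child in store and store[child] != parent:
                raise TableError(
                    f"{lvl} {child!r} has conflicting parents {store[child]!r} and {parent!r}"
                )
            store[child] = parent
    return FunctionHierarchy(g3, t32, t21)


def write_hierarchy(hierarchy: FunctionHierarchy, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for gene in hierarchy.gene_to_tier3:
        t3 = hierarchy.gene_to_tier3[gene]
        t2 = hierarchy.tier3_to_tier2[t3]
        t1 = hierarchy.tier2_to_tier1[t2]
        rows.append((gene, t3, t2, t1))
    pd.DataFrame(rows, columns=["gene", "tier3", "tier2", "tier1"]).to_csv(
        path, sep=sep, index=False, lineterminator="\n"
    )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a host x trait CSV whose host id column is named ``host``.

    Returns a DataFrame indexed by host id; missing values allowed (NaN).
    """
    df = pd.read_csv(path)
    if "host" not in df.columns:
        raise TableError(f"trait table {path} has no 'host' column")
    df["host"] = df["host"].astype(str)
    if df["host"].duplicated().any():
        raise TableError("duplicate host ids in trait table")
    return df.set_index("host").astype(float)


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("host").to_csv(path, lineterminator="\n")


def read_phylogeny(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick phylogeny with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TableError("duplicate tip labels in phylogeny")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TableError("negative branch length in phylogeny")
    return tree


def write_phylogeny(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def aggregate_to_tier(
    table: FunctionTable,
    hierarchy: FunctionHierarchy,
    target: str,
    unmapped: str = "bucket",
) -> FunctionTable:
    """Sum gene counts into their ``target``-level ancestor categories.

    Per-sample totals are conserved exactly.  Genes absent from the hierarchy
    are collected into an explicit ``UNCLASSIFIED`` category under the default
    ``unmapped="bucket"`` policy, or rejected under ``unmapped="strict"``.
    Output columns appear in order of first appearance among input columns.
    """
    if target == table.level:
        return table
    if target not in FUNCTION_LEVELS:
        raise ValueError(f"unknown target level {target!r}")
    unknown = [g for g in table.function_ids if g not in hierarchy.genes]
    if unknown and unmapped == "strict":
        raise TableError(f"genes missing from hierarchy: {unknown}")
    parents = [
        hierarchy.ancestor(g, target) if g in hierarchy.genes else UNCLASSIFIED
        for g in table.function_ids
    ]
    order: list[str] = []
    seen = set()
    for p in parents:
        if p not in seen:
            seen.add(p)
            order.append(p)
    agg = table.counts.T.groupby(pd.Index(parents, name=target)).sum().T[order]
    return FunctionTable(agg, level=target, sample_to_host=dict(table.sample_to_host))


def _rarefy_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement subsample of one sample's reads."""
    return rng.multivariate_hypergeometric(row, depth, method="marginals")


def rarefy(table: FunctionTable, depth: int, seed: int) -> FunctionTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning; an
    error is raised if no sample survives.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals[totals >= depth].index.tolist()
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        if not keep:
            raise TableError(f"all samples below rarefaction depth {depth}")
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
        logger.warning("rarefy: dropped samples below depth %d: %s", depth, dropped)
    sub = table.counts.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    for i, (_, row) in enumerate(sub.iterrows()):
        vals = row.to_numpy()
        out[i] = vals if vals.sum() == depth else _rarefy_row(vals, depth, rng)
    return FunctionTable(
        pd.DataFrame(out, index=sub.index, columns=sub.columns),
        level=table.level,
        sample_to_host={s: table.sample_to_host[s] for s in keep},
    )


def relative_abundance(table: FunctionTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to relative abundances (rows sum to 1)."""
    df = table.counts if isinstance(table, FunctionTable) else table
    totals = df.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise TableError(f"zero-total sample(s): {zero}")
    return df.div(totals, axis=0)


@dataclass
class DedupeResult:
    """Outcome of removing perfectly correlated columns."""

    matrix: pd.DataFrame
    #: kept column -> list of removed columns perfectly correlated with it
    mapping: dict[str, list[str]]
    #: constant (zero-variance) columns, removed outright
    constant: list[str]


def dedupe_correlated(matrix: pd.DataFrame, tol: float = 1e-12) -> DedupeResult:
    """Drop columns pairwise Pearson-correlated at r = 1 (within ``tol``).

    Within each group of perfectly correlated columns only the first by input
    order is retained.  Constant columns have undefined correlation and are
    removed; they are reported separately.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 samples to assess column correlation")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    norms = np.sqrt((Xc**2).sum(axis=0))
    constant_mask = norms == 0
    constant = [c for c, m in zip(matrix.columns, constant_mask) if m]
    cols = [c for c, m in zip(matrix.columns, constant_mask) if not m]
    idx = np.flatnonzero(~constant_mask)
    mapping: dict[str, list[str]] = {}
    kept: list[str] = []
    if idx.size:
        U = Xc[:, idx] / norms[idx]
        R = U.T @ U
        removed = np.zeros(len(idx), dtype=bool)
        for a in range(len(idx)):
            if removed[a]:
                continue
            kept.append(cols[a])
            dup = np.flatnonzero((np.abs(R[a] - 1.0) <= tol) & ~removed)
            dup = dup[dup > a]
            if dup.size:
                mapping[cols[a]] = [cols[b] for b in dup]
                removed[dup] = True
    reduced = matrix[kept]
    if constant:
        logger.info("dedupe: removed %d constant column(s)", len(constant))
    return DedupeResult(matrix=reduced, mapping=mapping, constant=constant)
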