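"""Phylogenetic signal of microbial functions on the host phylogeny.

Implements phylogenetically independent contrasts (PIC) by post-order
pruning, Blomberg's K with both a fast PIC-based path and a slow
covariance-matrix (GLS) path, and a tip-shuffle randomization test whose
statistic is the variance of the standardized contrasts (lower variance =
stronger signal).  Functions whose randomization p-value falls below alpha
(default 0.05, i.e. the top 5% of the signal distribution) are selected and
reported as a host x function matrix of max-scaled relative abundances.

Blomberg's K compares the observed ratio MSE0/MSE to its expectation under
Brownian motion, where, with V the phylogenetic covariance matrix (shared
root-to-node path lengths) and ``a`` the GLS estimate of the root state::

    MSE0 = (x - a)'(x - a) / (n - 1)
    MSE  = (x - a)' V^-1 (x - a) / (n - 1)
    E[MSE0/MSE] = (tr(V) - n / (1'V^-1 1)) / (n - 1)
    K = (MSE0 / MSE) / E[MSE0/MSE]

K = 1 matches the Brownian expectation; K > 1 indicates stronger-than-
Brownian conservatism.  The PIC path exploits the identities that the sum of
squared contrasts equals the GLS quadratic form, the pruning root value
equals the GLS root estimate, and the root's accumulated branch variance
equals 1 / (1'V^-1 1).

Polytomies are resolved deterministically (left-leaning caterpillar in child
order) with zero-length internal branches before pruning; a contrast
denominator of exactly zero (both child branches zero) is perturbed by
``1e-8 x tree depth``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .tables import FunctionTable


def _derive_seed(label: str, master_seed: int) -> int:
    digest = hashlib.blake2b(f"{label}|{master_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# tree preprocessing
# ---------------------------------------------------------------------------


@dataclass
class TreeArrays:
    """Strictly bifurcating post-order array representation of a rooted tree.

    Nodes 0..n-1 are tips (in ``tip_labels`` order); internal nodes follow in
    post-order.  ``child1/child2/blen1/blen2`` describe each internal node's
    two children and the branch lengths leading to them.
    """

    tip_labels: list[str]
    child1: np.ndarray
    child2: np.ndarray
    blen1: np.ndarray
    blen2: np.ndarray
    tip_depths: np.ndarray  # root-to-tip path lengths
    epsilon: float

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


def tree_to_arrays(tree: dendropy.Tree) -> TreeArrays:
    """Convert a dendropy tree to :class:`TreeArrays`, resolving polytomies.

    Polytomies are resolved into left-leaning caterpillars (deterministic, by
    child order) with zero-length connecting branches, which leaves the
    induced tip-tip covariance unchanged.
    """
    tips: list = []
    labels: list[str] = []
    for leaf in tree.leaf_node_iter():
        tips.append(leaf)
        labels.append(leaf.taxon.label if leaf.taxon else str(leaf))
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    n = len(labels)
    index = {id(leaf): i for i, leaf in enumerate(tips)}
    child1, child2, blen1, blen2 = [], [], [], []
    counter = n

    def visit(node) -> tuple[int, float]:
        """Return (array index, branch length above node)."""
        nonlocal counter
        blen = node.edge.length if node.edge.length is not None else 0.0
        children = node.child_nodes()
        if not children:
            return index[id(node)], blen
        resolved = [visit(c) for c in children]
        # fold >2 children into a caterpillar with zero-length internal edges
        idx, b = resolved[0]
        for cidx, cb in resolved[1:]:
            child1.append(idx)
            child2.append(cidx)
            blen1.append(b)
            blen2.append(cb)
            idx, b = counter, 0.0
            counter += 1
        return idx, blen

    root_children = tree.seed_node.child_nodes()
    if not root_children:
        raise ValueError("tree has no internal structure")
    visit(tree.seed_node)
    depths = np.zeros(n)
    for leaf in tips:
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[index[id(leaf)]] = d
    arrays = TreeArrays(
        tip_labels=labels,
        child1=np.asarray(child1, dtype=np.intp),
        child2=np.asarray(child2, dtype=np.intp),
        blen1=np.asarray(blen1, dtype=float),
        blen2=np.asarray(blen2, dtype=float),
        tip_depths=depths,
        epsilon=1e-8 * max(depths.max(), 1e-30),
    )
    if len(arrays.child1) != n - 1:
        raise ValueError("tree did not resolve to n-1 internal nodes")
    return arrays


def phylo_covariance(arrays: TreeArrays) -> np.ndarray:
    """Tip covariance matrix V: V_ij = shared root-to-MRCA path length."""
    n = arrays.n_tips
    total = 2 * n - 1
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    height = np.zeros(total)  # root-to-node path length
    V = np.zeros((n, n))
    # accumulate: start with tip variances on the diagonal, then at each join
    # record the shared depth of the two clades
    # compute node heights top-down: need parent info; instead do bottom-up
    # using the fact that tip depth = height(node) for tips.
    # height of internal node k = depth(tip in clade) - path(tip->k); easier:
    # derive via pruning: height(k) = height(child) - blen(child). Use child1.
    for i in range(n):
        height[i] = arrays.tip_depths[i]
    for k in range(n - 1):
        node = n + k
        c1, c2 = arrays.child1[k], arrays.child2[k]
        height[node] = height[c1] - arrays.blen1[k]
        m1, m2 = members[c1], members[c2]
        V[np.ix_(m1, m2)] = height[node]
        V[np.ix_(m2, m1)] = height[node]
        members.append(np.concatenate([m1, m2]))
    np.fill_diagonal(V, arrays.tip_depths)
    return V


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------


def _pic_matrix(arrays: TreeArrays, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Contrasts for a (n_tips, m) matrix of traits in one pruning pass.

    Returns (contrasts (n-1, m), root values (m,), root branch variance
    1/(1'V^-1 1)).  The branch-length arithmetic is trait-independent, so all
    columns share one pass.
    """
    n = arrays.n_tips
    total = 2 * n - 1
    m = X.shape[1]
    vals = np.empty((total, m))
    vals[:n] = X
    ext = np.zeros(total)  # accumulated extra branch variance per node
    contrasts = np.empty((n - 1, m))
    for k in range(n - 1):
        c1, c2 = arrays.child1[k], arrays.child2[k]
        v1 = arrays.blen1[k] + ext[c1]
        v2 = arrays.blen2[k] + ext[c2]
        if v1 + v2 == 0.0:
            v1 = v2 = arrays.epsilon
        contrasts[k] = (vals[c1] - vals[c2]) / np.sqrt(v1 + v2)
        vals[n + k] = (vals[c1] * v2 + vals[c2] * v1) / (v1 + v2)
        ext[n + k] = v1 * v2 / (v1 + v2)
    return contrasts, vals[-1], ext[-1]


def _align(arrays: TreeArrays, x: pd.Series | Mapping[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, Mapping):
        have, want = set(x), set(arrays.tip_labels)
        if have != want:
            raise ValueError(
                f"tip/value id mismatch; only in values: {sorted(have - want)}, "
                f"only in tree: {sorted(want - have)}"
            )
        return np.array([float(x[t]) for t in arrays.tip_labels])
    x = np.asarray(x, dtype=float)
    if x.shape[0] != arrays.n_tips:
        raise ValueError(f"{x.shape[0]} values for {arrays.n_tips} tips")
    return x


def pic(tree: dendropy.Tree | TreeArrays, x) -> pd.Series:
    """Standardized phylogenetically independent contrasts (n - 1 values)."""
    arrays = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
    vec = _align(arrays, x)
    contrasts, _, _ = _pic_matrix(arrays, vec[:, None])
    return pd.Series(contrasts[:, 0], name="contrast")


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


@dataclass
class SignalResult:
    """Blomberg's K and randomization-test outcome for one function."""

    function_id: str
    K: float
    mse_ratio_obs: float
    mse_ratio_exp: float
    pic_variance_obs: float
    p_value: float | None = None
    n_randomizations: int = 0


def _k_components(arrays: TreeArrays, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Vectorized K over trait columns via the PIC fast path.

    Returns (K, mse_ratio_obs, mse_ratio_exp, pic_variance) per column.
    """
    n = arrays.n_tips
    contrasts, root_vals, root_var = _pic_matrix(arrays, X)
    ss_contrast = (contrasts**2).sum(axis=0)
    mse = ss_contrast / (n - 1)
    dev = X - root_vals
    mse0 = (dev**2).sum(axis=0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_obs = mse0 / mse
    ratio_exp = (arrays.tip_depths.sum() - n * root_var) / (n - 1)
    K = ratio_obs / ratio_exp
    pic_var = ss_contrast / (n - 1)
    return K, ratio_obs, ratio_exp, pic_var


def blomberg_k(
    tree: dendropy.Tree | TreeArrays, x, method: str = "pic", function_id: str = ""
) -> SignalResult:
    """Blomberg's K for one trait via PIC (fast) or the V matrix (slow GLS)."""
    arrays = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
    vec = _align(arrays, x)
    if np.ptp(vec) == 0:
        raise ValueError("signal undefined for a constant trait")
    n = arrays.n_tips
    if method == "pic":
        K, ro, re, pv = _k_components(arrays, vec[:, None])
        return SignalResult(function_id, float(K[0]), float(ro[0]), float(re), float(pv[0]))
    if method != "vcv":
        raise ValueError(f"unknown method {method!r}")
    V = phylo_covariance(arrays)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    a = (ones @ Vinv @ vec) / denom
    dev = vec - a
    mse0 = dev @ dev / (n - 1)
    mse = dev @ Vinv @ dev / (n - 1)
    ratio_exp = (np.trace(V) - n / denom) / (n - 1)
    ratio_obs = mse0 / mse
    contrasts, _, _ = _pic_matrix(arrays, vec[:, None])
    pic_var = float((contrasts**2).mean() * (n - 1) / (n - 1))
    return SignalResult(function_id, ratio_obs / ratio_exp, ratio_obs, ratio_exp, pic_var)


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------


def signal_test(
    tree: dendropy.Tree | TreeArrays,
    x,
    n_rand: int = 9999,
    seed: int = 0,
    function_id: str = "",
) -> SignalResult:
    """Tip-shuffle randomization test of phylogenetic signal.

    The statistic is the variance of the standardized contrasts (mean squared
    contrast); low variance means close relatives have similar values, i.e.
    strong signal.  The null shuffles trait values across the tips.  The
    p-value uses the add-one rule (1 + #{null <= observed}) / (n_rand + 1),
    so p >= 1/(n_rand + 1).  Deterministic given ``seed``.
    """
    arrays = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
    vec = _align(arrays, x)
    if np.ptp(vec) == 0:
        raise ValueError("signal undefined for a constant trait")
    result = blomberg_k(arrays, vec, function_id=function_id)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(vec, (n_rand, 1)), axis=1).T  # (n, n_rand)
    contrasts, _, _ = _pic_matrix(arrays, perms)
    null_var = (contrasts**2).mean(axis=0)
    p = (1 + int((null_var <= result.pic_variance_obs).sum())) / (n_rand + 1)
    result.p_value = p
    result.n_randomizations = n_rand
    return result


def signal_all(
    tree: dendropy.Tree | TreeArrays,
    host_table: pd.DataFrame,
    n_rand: int = 9999,
    seed: int = 0,
    transform: str = "none",
) -> list[SignalResult]:
    """Randomization signal test for every column of a host x function table.

    Trait values are the per-host abundances, untransformed by default
    (``transform="log1p"`` applies log(1 + x) first).  Per-function RNG
    streams are derived by hashing (function id, master seed), so results do
    not depend on column order.  Constant functions are skipped with a
    warning.
    """
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    arrays = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
    if transform == "log1p":
        host_table = np.log1p(host_table)
    results: list[SignalResult] = []
    for fid in host_table.columns:
        vals = host_table[fid]
        if np.ptp(vals.to_numpy(dtype=float)) == 0:
            warnings.warn(f"function {fid!r} constant across hosts; skipped", stacklevel=2)
            continue
        results.append(
            signal_test(arrays, vals, n_rand=n_rand, seed=_derive_seed(str(fid), seed), function_id=str(fid))
        )
    return results


def one_sample_per_species(table: FunctionTable, seed: int) -> FunctionTable:
    """Keep one uniformly random sample per host species; rows relabeled to
    host ids.  Hosts are processed in sorted order so the choice is
    deterministic given ``seed`` and independent of sample order."""
    rng = np.random.default_rng(seed)
    groups = table.host_samples()
    chosen: dict[str, str] = {}
    for host in sorted(groups):
        samples = groups[host]
        chosen[host] = samples[int(rng.integers(len(samples)))]
    counts = table.counts.loc[[chosen[h] for h in chosen]]
    counts.index = list(chosen)
    return FunctionTable(counts, level=table.level, sample_to_host={h: h for h in chosen})


def select_signal_functions(
    results: Sequence[SignalResult],
    alpha: float = 0.05,
    abundance: pd.DataFrame | None = None,
) -> tuple[list[SignalResult], pd.DataFrame | None]:
    """Functions with randomization p < alpha, sorted by K descending.

    When a host x function abundance table is supplied, also returns the
    host x selected-function matrix of scaled relative abundances (each
    column divided by its maximum, so column maxima are exactly 1).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    selected = sorted(
        (r for r in results if r.p_value is not None and r.p_value < alpha),
        key=lambda r: (-r.K, r.function_id),
    )
    matrix = None
    if abundance is not None:
        ids = [r.function_id for r in selected]
        sub = abundance[ids].astype(float)
        maxima = sub.max(axis=0).replace(0, 1.0)
        matrix = sub / maxima
    return selected, matrix


def signal_table(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Per-function report with a Benjamini-Hochberg q-value column
    (informational only; selection uses raw p)."""
    df = pd.DataFrame(
        {
            "K": [r.K for r in results],
            "mse_ratio_obs": [r.mse_ratio_obs for r in results],
            "mse_ratio_exp": [r.mse_ratio_exp for r in results],
            "pic_variance": [r.pic_variance_obs for r in results],
            "p_value": [r.p_value for r in results],
            "n_randomizations": [r.n_randomizations for r in results],
        },
        index=pd.Index([r.function_id for r in results], name="function"),
    )
    if df["p_value"].notna().all() and len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p, kind="stable")
        m = len(p)
        q = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            prev = min(prev, p[i] * m / (rank + 1))
            q[i] = prev
        df["bh_q"] = q
    return df
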