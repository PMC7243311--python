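"""Ordination of functional composition and plant-trait fitting.

Principal component analysis of the samples x functions relative-abundance
matrix (correlation-matrix PCA by default: columns centered and scaled to
unit variance), identification of the functions contributing most to the
leading axes, least-squares fitting of external host traits onto the
ordination plane with a permutation test (envfit-style), a redundancy-style
estimate of the total compositional variance explained by the trait set, and
symmetric Procrustes superposition of paired sample configurations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)


def _derive_seed(label: str, master_seed: int) -> int:
    """Stable per-label RNG seed, independent of evaluation order."""
    digest = hashlib.blake2b(f"{label}|{master_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """PCA result: scores (samples x axes), unit loadings (functions x axes),
    eigenvalues, percent variance per axis and per-axis contributions (%)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    contributions: pd.DataFrame

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)


def pca(matrix: pd.DataFrame, scale_unit: bool = True) -> Ordination:
    """Principal component analysis of a samples x functions matrix.

    Columns are centered, and scaled to unit variance when ``scale_unit``
    (the default; PCA on the correlation matrix).  Scores are ``U @ S`` and
    loadings the unit right singular vectors, so ``scores @ loadings.T``
    reconstructs the transformed data.  Eigenvalues are singular values
    squared over (n - 1).  Each axis is oriented so its largest-magnitude
    loading is positive.  contributions(f, axis) = 100 * loading^2 (unit
    loadings sum to 1 per axis).
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale_unit:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) cannot be unit-scaled: "
                f"{[matrix.columns[j] for j in zero]}"
            )
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    # deterministic axis orientation: largest-|loading| positive
    for j in range(r):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigenvalues = s**2 / (X.shape[0] - 1)
    axes = [f"PC{j + 1}" for j in range(r)]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=axes)
    total = eigenvalues.sum()
    pct = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    contributions = pd.DataFrame(
        100.0 * Vt.T**2 / (Vt**2).sum(axis=1), index=matrix.columns, columns=axes
    )
    return Ordination(scores, loadings, eigenvalues, pct, contributions)


def top_contributors(
    ordination: Ordination, k: int = 20, axes: Sequence[int] = (1, 2)
) -> pd.DataFrame:
    """Functions ranked by summed contribution over the requested axes.

    ``axes`` are 1-based axis numbers.  Ties break lexicographically by
    function id.  If ``k`` exceeds the number of functions all are returned
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = [f"PC{a}" for a in axes]
    contrib = ordination.contributions[cols].sum(axis=1)
    if k > len(contrib):
        warnings.warn(f"k={k} exceeds {len(contrib)} functions; returning all", stacklevel=2)
        k = len(contrib)
    df = pd.DataFrame({"contribution": contrib})
    # descending contribution, ties broken lexicographically by function id
    order = np.lexsort((df.index.astype(str), -df["contribution"].to_numpy()))
    return df.iloc[order].head(k)


# ---------------------------------------------------------------------------
# trait fitting (envfit-style)
# ---------------------------------------------------------------------------


@dataclass
class TraitFit:
    """Least-squares fit of one host trait onto the ordination plane."""

    trait_id: str
    direction: np.ndarray  # unit vector in the fitted axis plane
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int


def _trait_values_per_sample(
    traits: pd.DataFrame, trait: str, samples: Sequence[str], sample_to_host: Mapping[str, str]
) -> pd.Series:
    hosts = [sample_to_host.get(s, s) for s in samples]
    vals = traits[trait].reindex(hosts)
    vals.index = list(samples)
    return vals


def fit_traits(
    ordination: Ordination,
    traits: pd.DataFrame,
    sample_to_host: Mapping[str, str] | None = None,
    axes: Sequence[int] = (1, 2),
    n_perm: int = 999,
    seed: int = 0,
) -> list[TraitFit]:
    """Fit each trait onto the selected score axes by ordinary least squares.

    The direction is the normalized coefficient vector (the orientation in
    the ordination plane maximizing correlation with the trait); r_squared is
    the regression R^2.  Significance is assessed by permuting trait values
    across samples, with the add-one rule p = (1 + #{R^2_perm >= R^2_obs}) /
    (n_perm + 1).  Missing trait values are dropped per trait
    (complete-case); constant traits are skipped with a warning.
    Deterministic given ``seed`` and independent of trait order.
    """
    if sample_to_host is None:
        sample_to_host = {}
    cols = [f"PC{a}" for a in axes]
    samples = list(ordination.scores.index)
    fits: list[TraitFit] = []
    for trait in traits.columns:
        vals = _trait_values_per_sample(traits, trait, samples, sample_to_host)
        mask = vals.notna()
        if mask.sum() < 3:
            warnings.warn(f"trait {trait!r}: fewer than 3 non-missing samples; skipped", stacklevel=2)
            continue
        y = vals[mask].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"trait {trait!r} is constant; R^2 undefined, skipped", stacklevel=2)
            continue
        S = ordination.scores.loc[mask[mask].index, cols].to_numpy()
        S = S - S.mean(axis=0)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(S, yc, rcond=None)
        # orthonormal basis of the score subspace for fast permutation R^2
        Q, _ = np.linalg.qr(S)
        sst = float(yc @ yc)
        r2 = float(((Q.T @ yc) ** 2).sum() / sst)
        rng = np.random.default_rng(_derive_seed(str(trait), seed))
        perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)  # (n_perm, n)
        proj = perms @ Q  # (n_perm, n_axes)
        r2_perm = (proj**2).sum(axis=1) / sst
        p = (1 + int((r2_perm >= r2).sum())) / (n_perm + 1)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        fits.append(
            TraitFit(
                trait_id=str(trait),
                direction=direction,
                r_squared=r2,
                p_value=p,
                n_permutations=n_perm,
                n_samples=int(mask.sum()),
            )
        )
    return fits


def trait_fit_table(fits: Sequence[TraitFit]) -> pd.DataFrame:
    rows = {}
    for f in fits:
        row = {f"direction_{i + 1}": d for i, d in enumerate(f.direction)}
        row.update(r_squared=f.r_squared, p_value=f.p_value, n_permutations=f.n_permutations, n_samples=f.n_samples)
        rows[f.trait_id] = row
    return pd.DataFrame(rows).T.rename_axis("trait")


# ---------------------------------------------------------------------------
# total variance explained by the trait set
# ---------------------------------------------------------------------------


@dataclass
class TraitVariance:
    """Fraction of compositional variance explained by the trait design."""

    raw: float
    adjusted: float  # Ezekiel-adjusted
    n_samples: int
    traits_used: list[str]
    traits_dropped: list[str]


def variance_explained_by_traits(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    sample_to_host: Mapping[str, str] | None = None,
    scale_unit: bool = True,
) -> TraitVariance:
    """Redundancy-analysis-style fraction of variance explained by all traits.

    With Y the centered (and unit-scaled) function matrix and Yhat its
    orthogonal projection onto the centered trait design matrix, the raw
    statistic is tr(Yhat' Yhat) / tr(Y' Y).  Samples with any missing trait
    are dropped listwise; collinear trait columns are dropped with a warning.
    The Ezekiel adjustment 1 - (1 - R^2)(n - 1)/(n - p - 1) is also reported.
    """
    if sample_to_host is None:
        sample_to_host = {}
    samples = list(matrix.index)
    design = pd.DataFrame(
        {t: _trait_values_per_sample(traits, t, samples, sample_to_host) for t in traits.columns}
    )
    complete = design.dropna().index
    n = len(complete)
    X = design.loc[complete].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    # rank-revealing QR to drop collinear (or constant) trait columns
    used: list[str] = []
    dropped: list[str] = []
    if X.shape[1]:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)).sum())
        keep = sorted(piv[:rank])
        used = [design.columns[j] for j in keep]
        dropped = [c for c in design.columns if c not in used]
        if dropped:
            warnings.warn(f"dropping collinear/constant trait column(s): {dropped}", stacklevel=2)
        X = X[:, keep]
    p = X.shape[1]
    if p == 0:
        return TraitVariance(0.0, 0.0, n, [], list(design.columns))
    if n < p + 2:
        raise ValueError(
            f"only {n} complete-case samples for {p} traits; need >= {p + 2} "
            "(fit a trait subset)"
        )
    Y = matrix.loc[complete].to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    if scale_unit:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant response columns contribute no variance
        Y = Y / sd
    Q, _ = np.linalg.qr(X)
    Yhat = Q @ (Q.T @ Y)
    total = float((Y**2).sum())
    raw = float((Yhat**2).sum() / total) if total > 0 else 0.0
    adjusted = max(0.0, 1.0 - (1.0 - raw) * (n - 1) / (n - p - 1)) if n - p - 1 > 0 else float("nan")
    return TraitVariance(raw=raw, adjusted=adjusted, n_samples=n, traits_used=used, traits_dropped=dropped)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes superposition of two matched configurations."""

    m_squared: float
    correlation: float  # sqrt(1 - m^2)
    rotation: np.ndarray
    scaling: float
    translation_a: np.ndarray
    translation_b: np.ndarray

    def to_dict(self) -> dict:
        return {
            "m_squared": self.m_squared,
            "correlation": self.correlation,
            "rotation": self.rotation.tolist(),
            "scaling": self.scaling,
            "translation_a": self.translation_a.tolist(),
            "translation_b": self.translation_b.tolist(),
        }


def procrustes(A: pd.DataFrame | np.ndarray, B: pd.DataFrame | np.ndarray) -> ProcrustesResult:
    """Symmetric Procrustes analysis of two row-matched configurations.

    Both configurations are centered and scaled to unit sum of squares; the
    optimal rotation comes from the singular decomposition of A'B.  Then
    ``m_squared = 1 - (sum of singular values)^2`` and ``correlation =
    sqrt(1 - m_squared)``.  DataFrames are aligned on their (identical) row
    sets; arrays must already be row-matched.
    """
    if isinstance(A, pd.DataFrame) and isinstance(B, pd.DataFrame):
        if set(A.index) != set(B.index):
            raise ValueError("configurations have different row sets")
        B = B.loc[A.index]
        A, B = A.to_numpy(dtype=float), B.to_numpy(dtype=float)
    else:
        A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 2:
        raise ValueError("Procrustes needs >= 2 rows")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - mu_a, B - mu_b
    na, nb = np.linalg.norm(A0), np.linalg.norm(B0)
    if na == 0 or nb == 0:
        raise ValueError("degenerate configuration (all rows identical)")
    A0, B0 = A0 / na, B0 / nb
    rotation, scale = scipy.linalg.orthogonal_procrustes(B0, A0)
    m2 = float(np.clip(1.0 - scale**2, 0.0, 1.0))
    return ProcrustesResult(
        m_squared=m2,
        correlation=float(np.sqrt(1.0 - m2)),
        rotation=rotation,
        scaling=float(scale),
        translation_a=mu_a,
        translation_b=mu_b,
    )


def write_procrustes(result: ProcrustesResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
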