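"""Multi-trait meta-analysis of signed t-values with empirical FDR control.

For each marker let t be the q-vector of signed single-trait statistics and
C the q x q correlation matrix of t-values across genome-wide markers.  The
composite statistic t' C^-1 t is referred to a chi-square with q degrees of
freedom.  Because traits with high average correlation can otherwise produce
large composite scores from collectively weak single-trait evidence, the
diagonal of C is inflated before inversion: C_adj[i,i] = 1 + mean of row i's
off-diagonal correlations (off-diagonals unchanged).  This makes the
statistic conservative relative to chi-square(q).

The significance threshold is selected by the empirical FDR rule: for target
FDR f, sort the m p-values ascending, set s to the largest rank i with
p_(i) <= f*i/m, and declare significant every test with p < alpha = f*s/m
(strictly).  Up to ties at the boundary this is the Benjamini-Hochberg
step-up rejection set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitCorrMatrix",
    "FdrSelection",
    "tvalue_correlation",
    "stack_t_matrix",
    "meta_statistic",
    "meta_scan",
    "select_fdr_threshold",
    "mean_offdiagonal",
]


@dataclass
class TraitCorrMatrix:
    """Raw and diagonal-adjusted cross-trait t-value correlation matrices."""

    trait_ids: tuple[str, ...]
    C_raw: np.ndarray = field(repr=False)
    C_adj: np.ndarray = field(repr=False)
    row_means: np.ndarray = field(repr=False)

    @property
    def q(self) -> int:
        return len(self.trait_ids)


@dataclass
class FdrSelection:
    f: float
    m: int
    s: int
    alpha: float
    significant: np.ndarray = field(repr=False)  # boolean mask, input order

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def stack_t_matrix(assoc_tables: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, np.ndarray]:
    """Align per-trait association tables into an m x q signed-t matrix.

    All tables must share the same marker set and order.  Markers flagged in
    any trait (degenerate tests) are dropped (complete-case across traits).
    Returns the marker frame (marker_id, chrom, bp) and the t matrix.
    """
    if len(assoc_tables) < 2:
        raise ValueError("need at least two traits for meta-analysis")
    items = list(assoc_tables.items())
    ref = items[0][1]["marker_id"].to_numpy()
    for trait_id, tab in items[1:]:
        ids = tab["marker_id"].to_numpy()
        if len(ids) != len(ref) or not np.array_equal(ids, ref):
            extra = set(ids) ^ set(ref)
            raise ValueError(
                f"marker sets differ between traits (trait {trait_id}); "
                f"{len(extra)} discordant ids, e.g. {sorted(extra)[:5]}"
            )
    T = np.column_stack([tab["t"].to_numpy(dtype=float) for _, tab in items])
    ok = np.ones(len(ref), dtype=bool)
    for _, tab in items:
        if "reason" in tab.columns:
            ok &= tab["reason"].isna().to_numpy()
    ok &= np.isfinite(T).all(axis=1)
    markers = items[0][1].loc[ok, ["marker_id", "chrom", "bp"]].reset_index(drop=True)
    return markers, T[ok]


def tvalue_correlation(
    assoc_tables: dict[str, pd.DataFrame], diag_mode: str = "signed"
) -> TraitCorrMatrix:
    """Pearson correlations of signed t across markers, diagonal-adjusted.

    ``diag_mode`` selects whether the diagonal inflation uses the signed
    ("signed", default) or absolute ("absolute") mean of each row's
    off-diagonal entries.
    """
    if diag_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown diag_mode {diag_mode!r}")
    _, T = stack_t_matrix(assoc_tables)
    C_raw = np.corrcoef(T.T)
    q = C_raw.shape[0]
    off = C_raw.copy()
    np.fill_diagonal(off, np.nan)
    rows = np.abs(off) if diag_mode == "absolute" else off
    row_means = np.nanmean(rows, axis=1)
    C_adj = C_raw.copy()
    C_adj[np.diag_indices(q)] = 1.0 + row_means
    return TraitCorrMatrix(
        trait_ids=tuple(assoc_tables), C_raw=C_raw, C_adj=C_adj, row_means=row_means
    )


def meta_statistic(t_vec: np.ndarray, corr: TraitCorrMatrix | np.ndarray):
    """Composite statistic t' C_adj^-1 t and its chi-square(q) p-value.

    ``t_vec`` may be a single q-vector or an (m, q) matrix of markers.
    """
    C = corr.C_adj if isinstance(corr, TraitCorrMatrix) else np.asarray(corr)
    t = np.atleast_2d(np.asarray(t_vec, dtype=float))
    q = C.shape[0]
    if t.shape[1] != q:
        raise ValueError(f"t has {t.shape[1]} traits, C is {q} x {q}")
    try:
        sol = np.linalg.solve(C, t.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "adjusted correlation matrix is singular; check the diagonal "
            "adjustment or enable a pseudo-inverse fallback"
        ) from exc
    stat = np.einsum("ij,ji->i", t, sol)
    stat = np.clip(stat, 0.0, None)
    p = stats.chi2.sf(stat, df=q)
    p = np.where(stat == 0.0, 1.0, p)
    if np.asarray(t_vec).ndim == 1:
        return float(stat[0]), float(p[0])
    return stat, p


def meta_scan(
    assoc_tables: dict[str, pd.DataFrame],
    corr: TraitCorrMatrix | None = None,
    f: float = 0.05,
    diag_mode: str = "signed",
) -> tuple[pd.DataFrame, TraitCorrMatrix, FdrSelection]:
    """Full multi-trait scan: statistic, p-value and FDR threshold."""
    markers, T = stack_t_matrix(assoc_tables)
    if corr is None:
        corr = tvalue_correlation(assoc_tables, diag_mode=diag_mode)
    stat, p = meta_statistic(T, corr)
    sel = select_fdr_threshold(p, f=f)
    out = markers.copy()
    out["stat"] = stat
    out["p"] = p
    out["significant"] = sel.significant
    return out, corr, sel


def select_fdr_threshold(p_values: np.ndarray, f: float = 0.05) -> FdrSelection:
    """Empirical FDR threshold: alpha = f*s/m, s the largest rank i with
    p_(i) <= f*i/m; the significant set is {p < alpha} (strict)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    bounds = f * np.arange(1, m + 1) / m
    hits = np.flatnonzero(order <= bounds)
    s = int(hits[-1] + 1) if hits.size else 0
    alpha = f * s / m
    significant = p < alpha
    return FdrSelection(f=f, m=m, s=s, alpha=alpha, significant=significant)


def mean_offdiagonal(corr: np.ndarray) -> float:
    """Arithmetic mean of the upper-triangle off-diagonal entries."""
    M = np.asarray(corr, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if M.shape[0] < 2:
        raise ValueError("need at least a 2 x 2 matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    return float(M[iu].mean())
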