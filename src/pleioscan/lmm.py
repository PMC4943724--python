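"""Weighted polygenic mixed model: GRM, REML null fit and score tests.

The association model per trait is the GBLUP model with heteroscedastic
residuals,

    y = 1 mu + g + e,    g ~ N(0, K sigma2_g),   e ~ N(0, diag(w) sigma2_e),

where y holds deregressed EBVs, K is a genomic relationship matrix and w the
per-record residual weights.  Markers are tested against the fitted null
covariance V = K sigma2_g + diag(w) sigma2_e with the score statistic

    b = (x' V^-1 x)^-1 x' V^-1 y*,   VAR(b) = (x' V^-1 x)^-1,
    t = b / SE(b),                   y* = y - 1 mu,

with x the mean-centred dosage vector.  Genome scans use the
leave-one-chromosome-out (LOCO) scheme: markers on chromosome j are tested
against a null model whose K excludes all chromosome-j markers, avoiding
proximal contamination (the tested signal being absorbed by the random
term).

REML is a 1-D bounded search: after transforming by diag(w)^(-1/2) the
covariance becomes K~ sigma2_g + I sigma2_e, a single eigendecomposition of
K~ makes every likelihood evaluation O(n) in the variance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .weights import TraitData

__all__ = [
    "GRM",
    "NullModelFit",
    "MarkerTest",
    "compute_grm",
    "loco_grms",
    "fit_null",
    "score_test",
    "score_test_batch",
    "gwa_loco",
    "conditional_scan",
]


@dataclass
class GRM:
    """VanRaden (method 1) genomic relationship matrix."""

    K: np.ndarray = field(repr=False)
    sample_ids: np.ndarray
    excluded_chromosome: str | None = None
    n_markers_used: int = 0


@dataclass
class MarkerTest:
    marker_id: str
    b: float
    se: float
    t: float
    p: float
    reason: str | None = None  # set when the test is degenerate


@dataclass
class NullModelFit:
    """Fitted null model and the factorisation used for fast V-solves."""

    trait_id: str
    excluded_chromosome: str | None
    mu: float
    sigma2_g: float
    sigma2_e: float
    weights: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    sample_ids: np.ndarray = field(repr=False)
    reml_loglik: float = np.nan
    opt_trace: list = field(default_factory=list, repr=False)
    # eigendecomposition of K~ = W^(-1/2) K W^(-1/2)
    _U: np.ndarray = field(default=None, repr=False)
    _lam: np.ndarray = field(default=None, repr=False)

    @property
    def y_star(self) -> np.ndarray:
        return self.y - self.mu

    @property
    def h2_marker(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def _d(self) -> np.ndarray:
        """Eigenvalues of the transformed covariance."""
        return self._lam * self.sigma2_g + self.sigma2_e

    @property
    def V(self) -> np.ndarray:
        """Dense V = K sigma2_g + diag(w) sigma2_e (for small-n checks)."""
        sw = np.sqrt(self.weights)
        inner = (self._U * self._d) @ self._U.T
        return sw[:, None] * inner * sw[None, :]

    def solve_V(self, B: np.ndarray) -> np.ndarray:
        """Compute V^-1 B without forming V."""
        sw = np.sqrt(self.weights)
        Bt = self._U.T @ (B / sw[..., None] if B.ndim == 2 else B / sw)
        Bt = Bt / (self._d[:, None] if B.ndim == 2 else self._d)
        out = self._U @ Bt
        return out / (sw[:, None] if B.ndim == 2 else sw)


def compute_grm(
    gm: GenotypeMatrix, exclude_chromosome: str | None = None
) -> GRM:
    """VanRaden method-1 GRM: K = ZZ' / (2 sum p(1-p)) over included markers.

    Missing dosages are mean-imputed per marker and columns centred by twice
    the allele frequency.
    """
    if exclude_chromosome is None:
        idx = np.arange(gm.n_markers)
    else:
        chrom = gm.marker_map["chrom"].to_numpy().astype(str)
        idx = np.flatnonzero(chrom != str(exclude_chromosome))
    if idx.size < 2:
        raise ValueError(
            f"fewer than 2 markers remain after excluding chromosome "
            f"{exclude_chromosome}"
        )
    dos = gm.imputed(idx)
    p = dos.mean(axis=0) / 2.0
    Z = dos - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all included markers are monomorphic")
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    return GRM(K, gm.sample_ids.copy(), exclude_chromosome, idx.size)


def loco_grms(gm: GenotypeMatrix) -> dict[str, GRM]:
    """One GRM per chromosome, each excluding that chromosome's markers.

    Computed by subtracting per-chromosome cross-products from the
    genome-wide cross-product, which is algebraically identical to calling
    :func:`compute_grm` per chromosome.
    """
    dos = gm.imputed()
    p = dos.mean(axis=0) / 2.0
    Z = dos - 2.0 * p
    het = 2.0 * p * (1.0 - p)
    full = Z @ Z.T
    denom_full = het.sum()
    chroms = gm.marker_map["chrom"].astype(str).to_numpy()
    out: dict[str, GRM] = {}
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        Zc = Z[:, on]
        denom = denom_full - het[on].sum()
        if denom <= 0 or (~on).sum() < 2:
            raise ValueError(
                f"cannot build LOCO GRM excluding chromosome {chrom}"
            )
        K = (full - Zc @ Zc.T) / denom
        out[chrom] = GRM(
            0.5 * (K + K.T), gm.sample_ids.copy(), chrom, int((~on).sum())
        )
    return out


def _align(trait: TraitData, grm: GRM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of trait records in GRM order, plus y and w vectors."""
    pos = {sid: i for i, sid in enumerate(grm.sample_ids)}
    ids = trait.records["animal_id"].to_numpy()
    try:
        idx = np.array([pos[a] for a in ids])
    except KeyError as exc:
        raise ValueError(f"animal {exc.args[0]} absent from GRM samples") from exc
    y = trait.records["debv"].to_numpy(dtype=float)
    if "w" not in trait.records.columns:
        raise ValueError(
            f"trait {trait.trait_id}: residual weights missing; "
            "call compute_weights first"
        )
    w = trait.records["w"].to_numpy(dtype=float)
    return idx, y, w


def fit_null(
    trait: TraitData,
    grm: GRM,
    max_iter: int = 200,
    tol: float = 1e-8,
    fixed_ratio: float | None = None,
) -> NullModelFit:
    """REML fit of (sigma2_g, sigma2_e) for V = K sigma2_g + diag(w) sigma2_e.

    ``fixed_ratio`` skips the optimisation and imposes delta =
    sigma2_e / sigma2_g (used when genome-wide variance components are
    re-used across LOCO folds).
    """
    idx, y, w = _align(trait, grm)
    K = grm.K[np.ix_(idx, idx)]
    n = y.size
    sw = np.sqrt(w)
    Kt = K / np.outer(sw, sw)
    lam, U = np.linalg.eigh(Kt)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ (y / sw)
    xt = U.T @ (1.0 / sw)  # transformed intercept column

    def profile(log_delta: float) -> tuple[float, float, float]:
        """Restricted log-likelihood profiled over mu and sigma2_g."""
        delta = np.exp(log_delta)
        d = lam + delta
        xx = np.sum(xt**2 / d)
        mu_t = np.sum(xt * yt / d) / xx
        rss = np.sum((yt - xt * mu_t) ** 2 / d)
        s2g = rss / (n - 1)
        rll = -0.5 * (
            (n - 1) * np.log(s2g) + np.sum(np.log(d)) + np.log(xx) + (n - 1)
        )
        return rll, mu_t, s2g

    trace: list[float] = []
    if fixed_ratio is not None:
        log_delta = float(np.log(fixed_ratio))
        rll, _, _ = profile(log_delta)
        trace.append(rll)
    else:
        best = [-np.inf]

        def objective(ld: float) -> float:
            rll, _, _ = profile(ld)
            if rll > best[0]:
                best[0] = rll
            trace.append(best[0])  # best-so-far: non-decreasing by design
            return -rll

        res = optimize.minimize_scalar(
            objective,
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        if not res.success:
            raise RuntimeError(
                f"REML did not converge for trait {trait.trait_id} "
                f"(chromosome {grm.excluded_chromosome}): {res.message}; "
                f"trace={trace[-5:]}"
            )
        log_delta = float(res.x)

    rll, mu_t, s2g = profile(log_delta)
    delta = np.exp(log_delta)
    s2e = s2g * delta
    mu = float(mu_t)

    return NullModelFit(
        trait_id=trait.trait_id,
        excluded_chromosome=grm.excluded_chromosome,
        mu=mu,
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
        weights=w,
        y=y,
        sample_ids=grm.sample_ids[idx],
        reml_loglik=float(rll),
        opt_trace=trace,
        _U=U,
        _lam=lam,
    )


def _prepare_x(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute and centre dosage columns; flag constant columns."""
    X = np.array(X, dtype=float, ndmin=2)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    Xc = X - X.mean(axis=0)
    constant = (np.abs(Xc).max(axis=0) == 0.0)
    return Xc, constant


def score_test_batch(X: np.ndarray, fit: NullModelFit) -> pd.DataFrame:
    """Vectorised score test of each column of X against the null fit.

    Returns columns ``b``, ``se``, ``t``, ``p`` and ``reason`` (None except
    for degenerate/constant markers, which get b=0, t=0, p=1).
    """
    Xc, constant = _prepare_x(X)
    sw = np.sqrt(fit.weights)
    d = fit._d
    Xt = fit._U.T @ (Xc / sw[:, None])
    yt = fit._U.T @ (fit.y_star / sw)
    xVx = np.sum(Xt**2 / d[:, None], axis=0)
    xVy = Xt.T @ (yt / d)

    bad = constant | (xVx <= 0)
    xVx_safe = np.where(bad, 1.0, xVx)
    b = np.where(bad, 0.0, xVy / xVx_safe)
    se = np.where(bad, np.nan, 1.0 / np.sqrt(xVx_safe))
    t = np.where(bad, 0.0, b / np.where(bad, 1.0, se))
    p = np.where(bad, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
    reason = np.where(bad, "constant_marker", None)
    return pd.DataFrame({"b": b, "se": se, "t": t, "p": p, "reason": reason})


def score_test(x: np.ndarray, fit: NullModelFit, marker_id: str = "") -> MarkerTest:
    """Score test of one marker; see :func:`score_test_batch`."""
    res = score_test_batch(np.asarray(x, dtype=float).reshape(-1, 1), fit).iloc[0]
    return MarkerTest(
        marker_id=marker_id,
        b=float(res["b"]),
        se=float(res["se"]),
        t=float(res["t"]),
        p=float(res["p"]),
        reason=res["reason"],
    )


def _subset_grm(grm: GRM, idx: np.ndarray) -> GRM:
    return GRM(
        grm.K[np.ix_(idx, idx)],
        grm.sample_ids[idx],
        grm.excluded_chromosome,
        grm.n_markers_used,
    )


def _trait_rows(gm: GenotypeMatrix, trait: TraitData) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(gm.sample_ids)}
    try:
        return np.array([pos[a] for a in trait.records["animal_id"]])
    except KeyError as exc:
        raise ValueError(
            f"animal {exc.args[0]} absent from genotype samples"
        ) from exc


def gwa_loco(
    gm: GenotypeMatrix,
    trait: TraitData,
    grms: dict[str, GRM],
    per_loco_reml: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Genome scan for one trait with leave-one-chromosome-out null models.

    ``grms`` maps each chromosome label to a GRM excluding that chromosome
    (as built by :func:`loco_grms`, on the full QC'd sample; rows are
    sub-set here to the trait's records).  When ``per_loco_reml`` is False
    the variance ratio is estimated once genome-wide and re-used per fold.
    """
    chroms = gm.marker_map["chrom"].astype(str).to_numpy()
    rows = _trait_rows(gm, trait)

    fixed_ratio = None
    if not per_loco_reml:
        genome = compute_grm(gm)
        gfit = fit_null(trait, _subset_grm(genome, rows), max_iter, tol)
        fixed_ratio = max(gfit.sigma2_e, 1e-12) / max(gfit.sigma2_g, 1e-12)

    tables = []
    for chrom in pd.unique(chroms):
        if chrom not in grms:
            raise ValueError(f"no LOCO GRM provided for chromosome {chrom}")
        grm = grms[chrom]
        if grm.excluded_chromosome != chrom:
            raise ValueError(
                f"GRM for chromosome {chrom} excludes "
                f"{grm.excluded_chromosome!r} instead"
            )
        fit = fit_null(
            trait, _subset_grm(grm, rows), max_iter, tol, fixed_ratio=fixed_ratio
        )
        on = np.flatnonzero(chroms == chrom)
        res = score_test_batch(gm.dosages[np.ix_(rows, on)], fit)
        res.insert(0, "marker_id", gm.marker_map["marker_id"].to_numpy()[on])
        res.insert(1, "chrom", chrom)
        res.insert(2, "bp", gm.marker_map["bp"].to_numpy()[on])
        res.insert(3, "allele", gm.marker_map["a1"].to_numpy()[on])
        tables.append(res)
    out = pd.concat(tables, ignore_index=True)
    out.attrs["trait_id"] = trait.trait_id
    return out


def _drop_collinear(F: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent subset of columns of F."""
    keep: list[int] = []
    for j in range(F.shape[1]):
        cand = F[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(
            keep
        ) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear fixed covariate column {j}", stacklevel=2
            )
    return np.array(keep, dtype=int)


def conditional_scan(
    gm: GenotypeMatrix,
    trait: TraitData,
    grms: dict[str, GRM],
    fixed_marker_ids: list[str],
    per_loco_reml: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """LOCO scan conditioning on the fixed effects of chosen markers.

    The tested dosage and the phenotype are projected, in the V^-1 inner
    product, onto the orthogonal complement of [1, fixed dosages].  The
    fixed markers themselves (and markers collinear with them) are reported
    with b = 0, t = 0, p = 1 and a reason code.
    """
    mids = gm.marker_map["marker_id"].to_numpy()
    fixed_pos = []
    for fid in fixed_marker_ids:
        hits = np.flatnonzero(mids == fid)
        if hits.size == 0:
            raise ValueError(f"fixed marker {fid!r} not in the marker map")
        fixed_pos.append(hits[0])
    fixed_pos = np.array(fixed_pos, dtype=int)
    fixed_set = set(fixed_marker_ids)

    rows = _trait_rows(gm, trait)
    Ffull, const = _prepare_x(gm.dosages[np.ix_(rows, fixed_pos)])
    if const.any():
        raise ValueError("fixed markers must be non-constant")
    F = np.column_stack([np.ones(rows.size), Ffull])
    keep = _drop_collinear(F)
    F = F[:, keep]

    fixed_ratio = None
    if not per_loco_reml:
        genome = compute_grm(gm)
        gfit = fit_null(
            trait, _subset_grm(genome, rows), max_iter, tol
        )
        fixed_ratio = max(gfit.sigma2_e, 1e-12) / max(gfit.sigma2_g, 1e-12)

    chroms = gm.marker_map["chrom"].astype(str).to_numpy()
    tables = []
    for chrom in pd.unique(chroms):
        fit = fit_null(
            trait, _subset_grm(grms[chrom], rows), max_iter, tol,
            fixed_ratio=fixed_ratio,
        )
        sw = np.sqrt(fit.weights)
        d = fit._d
        U = fit._U
        Ft = U.T @ (F / sw[:, None])
        yt = U.T @ (fit.y / sw)
        M = Ft / d[:, None]
        FVF = Ft.T @ M
        FVF_inv = np.linalg.inv(FVF)
        FVy = M.T @ yt

        on = np.flatnonzero(chroms == chrom)
        Xc, constant = _prepare_x(gm.dosages[np.ix_(rows, on)])
        Xt = U.T @ (Xc / sw[:, None])
        xVx = np.sum(Xt**2 / d[:, None], axis=0)
        xVy = Xt.T @ (yt / d)
        XVF = Xt.T @ M  # m_j x k
        xPx = xVx - np.einsum("ij,jk,ik->i", XVF, FVF_inv, XVF)
        xPy = xVy - XVF @ (FVF_inv @ FVy)

        is_fixed = np.isin(mids[on], list(fixed_set))
        bad = constant | is_fixed | (xPx <= tol * np.maximum(xVx, 1.0))
        xPx_safe = np.where(bad, 1.0, xPx)
        b = np.where(bad, 0.0, xPy / xPx_safe)
        se = np.where(bad, np.nan, 1.0 / np.sqrt(xPx_safe))
        t = np.where(bad, 0.0, b * np.sqrt(xPx_safe))
        p = np.where(bad, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
        reason = np.full(on.size, None, dtype=object)
        reason[constant] = "constant_marker"
        reason[xPx <= tol * np.maximum(xVx, 1.0)] = "collinear_with_fixed"
        reason[is_fixed] = "conditioned_marker"
        res = pd.DataFrame(
            {
                "marker_id": mids[on],
                "chrom": chrom,
                "bp": gm.marker_map["bp"].to_numpy()[on],
                "allele": gm.marker_map["a1"].to_numpy()[on],
                "b": b,
                "se": se,
                "t": t,
                "p": p,
                "reason": reason,
            }
        )
        tables.append(res)
    out = pd.concat(tables, ignore_index=True)
    out.attrs["trait_id"] = trait.trait_id
    return out
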