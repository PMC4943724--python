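"""Gene-based association by summed squared t with an adaptive MC null.

For each trait and gene, markers inside the gene's boundaries expanded by
100 kb are collected, thinned to the maximum subset with all pairwise
squared dosage correlations <= 0.5 (which keeps the local LD matrix D well
conditioned), and the gene statistic is the sum of squared single-marker
t-values.  Its null distribution is approximated by Monte Carlo: draws
z ~ MVN(0, D) give x2 = sum z_i^2, and p is the fraction of draws with
x2 >= observed.  Simulation size escalates adaptively (10^3 -> 10^4 ->
10^5 -> 10^6 whenever p < 1/k), and p-values smaller than 10^-6 are
censored at 10^-6.  Genes containing no markers get p = 1.

A gene is called a pleiotropic candidate when it appears in the p < 0.01
list of at least ``min_traits`` (default 4) traits and is not excluded by a
user-supplied exclusion rule (gene-ID lists, or whole chromosomes with
named exceptions).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "GeneRegion",
    "VegasResult",
    "Exclusions",
    "read_gene_table",
    "assign_markers",
    "prune_r2",
    "vegas_statistic",
    "simulate_null",
    "mc_pvalue",
    "gene_scan",
    "call_pleiotropic",
]

DEFAULT_EXPAND_BP = 100_000
DEFAULT_MAX_R2 = 0.5
DEFAULT_STAGES = (1_000, 10_000, 100_000, 1_000_000)
P_FLOOR = 1e-6


@dataclass
class GeneRegion:
    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    biotype: str = "protein_coding"
    expand_bp: int = DEFAULT_EXPAND_BP
    member_markers: np.ndarray | None = field(default=None, repr=False)
    pruned_markers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end_bp} < start {self.start_bp}"
            )

    @property
    def expanded_start(self) -> int:
        return max(1, self.start_bp - self.expand_bp)

    @property
    def expanded_end(self) -> int:
        return self.end_bp + self.expand_bp


@dataclass
class VegasResult:
    gene_id: str
    trait_id: str
    n_markers: int  # pruned count
    stat: float
    k: int  # simulations used
    p: float
    censored: bool


@dataclass
class Exclusions:
    """Post-hoc gene exclusions for the pleiotropy call.

    ``chromosomes`` drops every gene on those chromosomes except the ones
    named in ``chromosome_exceptions`` (e.g. drop a whole chromosome's LD
    block but keep the lead gene itself).
    """

    gene_ids: set[str] = field(default_factory=set)
    chromosomes: set[str] = field(default_factory=set)
    chromosome_exceptions: set[str] = field(default_factory=set)

    def reason(self, gene_id: str, chrom: str) -> str | None:
        if gene_id in self.gene_ids:
            return "excluded_gene_id"
        if str(chrom) in self.chromosomes and gene_id not in self.chromosome_exceptions:
            return f"excluded_chromosome_{chrom}"
        return None


def read_gene_table(path: str | Path, dialect: str = "1-based") -> pd.DataFrame:
    """Read a BED-like gene table (chrom, start, end, gene_id, biotype).

    dialect="1-based" expects 1-based inclusive coordinates (the native
    convention here); dialect="bed0" converts 0-based half-open starts.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gene_id"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns {sorted(missing)}")
    if "biotype" not in tab.columns:
        tab["biotype"] = "unknown"
    if dialect == "bed0":
        tab["start"] = tab["start"] + 1
    elif dialect != "1-based":
        raise ValueError(f"unknown gene table dialect {dialect!r}")
    return tab


def assign_markers(gene: GeneRegion, marker_map: pd.DataFrame) -> GeneRegion:
    """Fill ``member_markers`` with map indices inside the expanded window
    (both boundaries inclusive)."""
    chrom = marker_map["chrom"].astype(str).to_numpy()
    bp = marker_map["bp"].to_numpy()
    hit = (
        (chrom == str(gene.chromosome))
        & (bp >= gene.expanded_start)
        & (bp <= gene.expanded_end)
    )
    gene.member_markers = np.flatnonzero(hit)
    return gene


def _pairwise_r(dosages: np.ndarray) -> np.ndarray:
    """Signed Pearson correlations of mean-imputed dosage columns."""
    X = dosages.copy()
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X, axis=0)
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(mu, X.shape)[miss]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic markers must be dropped before pruning")
    return np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))


def prune_r2(
    r: np.ndarray, max_r2: float = DEFAULT_MAX_R2, exact_limit: int = 15
) -> np.ndarray:
    """Indices of a maximum subset with all pairwise r^2 <= max_r2.

    Exact (lexicographically first maximum subset) for at most
    ``exact_limit`` markers; otherwise greedy by ascending conflict count
    with lower-index tie-breaking, which always satisfies the constraint and
    is near-optimal on local LD structure.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    m = r.shape[0]
    if m == 0:
        return np.array([], dtype=int)
    conflict = (r**2 > max_r2)
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return np.arange(m)

    if m <= exact_limit:
        bad = [sum(1 << j for j in np.flatnonzero(conflict[i])) for i in range(m)]
        for size in range(m, 0, -1):
            for combo in combinations(range(m), size):
                mask = sum(1 << j for j in combo)
                if all(bad[i] & mask == 0 for i in combo):
                    return np.array(combo, dtype=int)
        return np.array([0], dtype=int)  # unreachable: singletons always feasible

    n_conflicts = conflict.sum(axis=1)
    order = np.lexsort((np.arange(m), n_conflicts))
    chosen: list[int] = []
    for i in order:
        if not any(conflict[i, j] for j in chosen):
            chosen.append(int(i))
    return np.array(sorted(chosen), dtype=int)


def vegas_statistic(t_values: np.ndarray) -> float:
    """Sum of squared t over the pruned marker set."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        raise ValueError("empty marker set; caller handles the p = 1 path")
    return float(np.sum(t**2))


def simulate_null(
    D: np.ndarray,
    k: int,
    seed_or_rng: int | np.random.Generator = 0,
    label: str = "",
) -> np.ndarray:
    """k draws of the gene statistic under the null: sum of squared
    components of z ~ MVN(0, D)."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    L = _repaired_cholesky(D, label=label)
    m = D.shape[0]
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = np.empty(k)
    chunk = max(1_000, 5_000_000 // max(m, 1))
    done = 0
    while done < k:
        take = min(chunk, k - done)
        z = rng.standard_normal((take, m)) @ L.T
        out[done : done + take] = np.einsum("ij,ij->i", z, z)
        done += take
    return out


def _repaired_cholesky(D: np.ndarray, label: str = "") -> np.ndarray:
    D = 0.5 * (D + D.T)
    try:
        return np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(D)
        D2 = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        try:
            return np.linalg.cholesky(0.5 * (D2 + D2.T))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"LD matrix not positive definite after repair ({label})"
            ) from exc


def mc_pvalue(
    stat: float,
    D: np.ndarray,
    seed_or_rng: int | np.random.Generator = 0,
    stages: tuple[int, ...] = DEFAULT_STAGES,
    label: str = "",
) -> tuple[float, int, bool]:
    """Adaptive Monte Carlo p-value of a summed-chi-square statistic.

    Draws z ~ MVN(0, D), scores x2 = sum z^2, and counts draws with
    x2 >= stat (ties inclusive).  Escalates to the next stage while
    p < 1/k; a zero count at the final stage is censored to the floor
    1/k_final (10^-6 at the default schedule).  Returns (p, simulations
    used, censored flag).
    """
    if stat < 0:
        raise ValueError("statistic must be non-negative")
    D = np.atleast_2d(np.asarray(D, dtype=float))
    m = D.shape[0]
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    count, k_done = 0, 0
    for stage in stages:
        need = stage - k_done
        if need > 0:
            x2 = simulate_null(D, need, rng, label=label)
            count += int(np.count_nonzero(x2 >= stat))
            k_done += need
        p = count / k_done
        if p >= 1.0 / k_done:
            return p, k_done, False
    if count == 0:
        return 1.0 / k_done, k_done, True
    return count / k_done, k_done, False


def gene_scan(
    assoc: pd.DataFrame,
    genes: pd.DataFrame,
    gm: GenotypeMatrix,
    trait_id: str,
    seed: int = 0,
    expand_bp: int = DEFAULT_EXPAND_BP,
    max_r2: float = DEFAULT_MAX_R2,
    stages: tuple[int, ...] = DEFAULT_STAGES,
    exact_limit: int = 15,
) -> pd.DataFrame:
    """VEGAS scan of every gene for one trait.

    ``assoc`` must be row-aligned to ``gm.marker_map`` (same marker order,
    as produced by the LOCO scan on the same GenotypeMatrix).  Per-gene
    failures are recorded in the ``error`` column without aborting.
    """
    mids = gm.marker_map["marker_id"].to_numpy()
    aids = assoc["marker_id"].to_numpy()
    if len(aids) != len(mids) or not np.array_equal(aids, mids):
        raise ValueError("association table is not aligned to the marker map")
    t = assoc["t"].to_numpy(dtype=float)
    usable = np.isfinite(t)
    if "reason" in assoc.columns:
        usable &= assoc["reason"].isna().to_numpy()
    maf = gm.maf

    rows = []
    for rec in genes.itertuples(index=False):
        region = GeneRegion(
            gene_id=rec.gene_id,
            chromosome=str(rec.chrom),
            start_bp=int(rec.start),
            end_bp=int(rec.end),
            biotype=getattr(rec, "biotype", "unknown"),
            expand_bp=expand_bp,
        )
        assign_markers(region, gm.marker_map)
        members = region.member_markers
        members = members[usable[members] & (maf[members] > 0)]
        base = {
            "gene_id": region.gene_id,
            "chrom": region.chromosome,
            "start": region.start_bp,
            "end": region.end_bp,
            "biotype": region.biotype,
            "window_start": region.expanded_start,
            "window_end": region.expanded_end,
            "n_members": int(members.size),
        }
        if members.size == 0:
            rows.append(
                base
                | {
                    "n_markers": 0,
                    "stat": 0.0,
                    "k": 0,
                    "p": 1.0,
                    "censored": False,
                    "error": None,
                }
            )
            continue
        try:
            R = _pairwise_r(gm.dosages[:, members])
            kept = prune_r2(R, max_r2=max_r2, exact_limit=exact_limit)
            region.pruned_markers = members[kept]
            D = R[np.ix_(kept, kept)]
            stat = vegas_statistic(t[region.pruned_markers])
            rng = np.random.default_rng(
                [int(seed) & 0x7FFFFFFF,
                 zlib.crc32(region.gene_id.encode()),
                 zlib.crc32(str(trait_id).encode())]
            )
            p, k, censored = mc_pvalue(
                stat, D, rng, stages=stages, label=region.gene_id
            )
            rows.append(
                base
                | {
                    "n_markers": int(kept.size),
                    "stat": stat,
                    "k": k,
                    "p": p,
                    "censored": censored,
                    "error": None,
                }
            )
        except Exception as exc:  # pragma: no cover - defensive per-gene guard
            rows.append(
                base
                | {
                    "n_markers": 0,
                    "stat": np.nan,
                    "k": 0,
                    "p": np.nan,
                    "censored": False,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["trait_id"] = trait_id
    return out


def call_pleiotropic(
    gene_results: dict[str, pd.DataFrame],
    min_traits: int = 4,
    list_alpha: float = 0.01,
    exclusions: Exclusions | None = None,
) -> pd.DataFrame:
    """Cross-trait pleiotropy call from per-trait VEGAS tables.

    A gene is a candidate when strictly p < ``list_alpha`` for at least
    ``min_traits`` traits and no exclusion rule applies.
    """
    if not gene_results:
        raise ValueError("no per-trait gene results supplied")
    exclusions = exclusions or Exclusions()
    trait_ids = list(gene_results)
    first = next(iter(gene_results.values()))
    info = first[["gene_id", "chrom", "biotype"]].drop_duplicates("gene_id")

    listed: dict[str, list[str]] = {g: [] for g in info["gene_id"]}
    for trait_id, tab in gene_results.items():
        hit = tab.loc[tab["p"] < list_alpha, "gene_id"]
        for g in hit:
            listed.setdefault(g, []).append(trait_id)

    rows = []
    for rec in info.itertuples(index=False):
        traits = listed.get(rec.gene_id, [])
        reason = exclusions.reason(rec.gene_id, rec.chrom)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "chrom": rec.chrom,
                "biotype": rec.biotype,
                "n_traits": len(traits),
                "traits_listed": ",".join(traits),
                "excluded": reason is not None,
                "exclusion_reason": reason,
                "is_candidate": len(traits) >= min_traits and reason is None,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["trait_ids"] = trait_ids
    return out
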