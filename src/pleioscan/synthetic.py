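"""Synthetic genotypes, gene maps and dEBV tables for pipeline testing.

The generator emulates the statistical structure the pleiotropy pipeline
assumes in a cattle genomic-selection dataset:

* **Genotypes** — biallelic autosomal markers in LD blocks.  Within a block
  all markers share an allele frequency drawn from ``maf_range`` and each
  haplotype copies the previous marker's allele with probability
  ``within_block_r`` (otherwise drawing fresh), so the expected adjacent
  dosage correlation inside a block equals ``within_block_r`` exactly;
  blocks are mutually independent.
* **Traits** — true breeding values (TBVs) are the sum of a genome-wide
  polygenic background whose per-marker effects are drawn with a common
  cross-trait correlation, plus a handful of shared (pleiotropic) QTLs with
  mixed effect signs across traits.  Total genetic variance per trait is
  normalised to 1.
* **dEBVs** — each record is TBV plus noise with variance
  var(TBV) * (1 - r2) / r2 for a reliability r2 drawn from
  ``reliability_range``, so the squared correlation between dEBV and TBV
  equals the reliability.

Default scale (1,000 individuals, 20,000 markers on 29 autosomes, 9 traits
with heritabilities 0.25-0.37) mirrors a BovineHD bull reference population
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .plink import write_plink
from .weights import TraitData

__all__ = [
    "SyntheticConfig",
    "TrueArchitecture",
    "generate_genotypes",
    "generate_gene_annotation",
    "generate_trait_data",
    "write_dataset",
    "DEFAULT_TRAIT_IDS",
    "DEFAULT_TRAIT_H2",
]

# Nine weight / conformation / precocity / muscling traits recorded at
# weaning and yearling in Nellore evaluations, with their heritabilities.
DEFAULT_TRAIT_IDS = ("BW", "WG", "CW", "PW", "MW", "PG", "CY", "PY", "MY")
DEFAULT_TRAIT_H2 = (0.37, 0.26, 0.25, 0.25, 0.26, 0.33, 0.31, 0.31, 0.30)

# Three pleiotropic QTLs (columns) with mixed signs across the nine traits
# (rows, DEFAULT_TRAIT_IDS order): positive on weight/conformation traits,
# negative on precocity/muscling traits, echoing a PLAG1-like growth locus.
_DEFAULT_QTL_SIGNS = np.array(
    [
        #  Q1  Q2  Q3
        [+1, 0, 0],  # BW
        [+1, +1, +1],  # WG
        [+1, +1, 0],  # CW
        [-1, -1, -1],  # PW
        [-1, -1, -1],  # MW
        [+1, +1, 0],  # PG
        [+1, +1, 0],  # CY
        [-1, 0, -1],  # PY
        [-1, 0, -1],  # MY
    ],
    dtype=float,
)

# independent seed streams so each generator draws from its own substream
_GENO_STREAM, _GENE_STREAM, _TRAIT_STREAM = 11, 13, 17


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic dataset; defaults define the study conditions."""

    n_individuals: int = 1000
    n_markers: int = 20000
    n_chromosomes: int = 29
    block_size: int = 10
    within_block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 200
    n_qtl: int = 3
    qtl_pleiotropy: np.ndarray | None = None  # q x n_qtl signs or effects
    trait_h2: tuple[float, ...] = DEFAULT_TRAIT_H2
    trait_ids: tuple[str, ...] = DEFAULT_TRAIT_IDS
    qtl_var_frac: float = 0.07  # genetic-variance share per QTL per affected trait
    bg_corr: float = 0.45  # cross-trait correlation of polygenic background
    bg_var: float | None = None  # None: fill to unit genetic variance
    reliability_range: tuple[float, float] = (0.15, 0.95)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_markers", "n_chromosomes", "block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        lo, hi = self.reliability_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("reliability_range must satisfy 0 < low <= high <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.bg_corr < 1.0:
            raise ValueError("bg_corr must lie in [0, 1)")
        if not 0.0 <= self.qtl_var_frac < 1.0:
            raise ValueError("qtl_var_frac must lie in [0, 1)")
        h2 = np.asarray(self.trait_h2, dtype=float)
        if np.any((h2 <= 0.0) | (h2 >= 1.0)):
            raise ValueError("trait_h2 entries must lie in (0, 1)")
        if len(self.trait_ids) != len(self.trait_h2):
            raise ValueError("trait_ids and trait_h2 lengths differ")
        if self.qtl_pleiotropy is not None:
            qp = np.asarray(self.qtl_pleiotropy, dtype=float)
            if qp.shape != (self.n_traits, self.n_qtl):
                raise ValueError(
                    f"qtl_pleiotropy must be q x n_qtl = "
                    f"{self.n_traits} x {self.n_qtl}, got {qp.shape}"
                )
            self.qtl_pleiotropy = qp

    @property
    def n_traits(self) -> int:
        return len(self.trait_h2)

    def qtl_sign_matrix(self) -> np.ndarray:
        """q x n_qtl matrix of QTL effect signs / sizes."""
        if self.qtl_pleiotropy is not None:
            return self.qtl_pleiotropy
        if self.n_traits == 9 and self.n_qtl <= 3:
            return _DEFAULT_QTL_SIGNS[:, : self.n_qtl].copy()
        # generic fallback: each QTL hits ceil(q/2)+1 traits, alternating sign
        rng = np.random.default_rng([self.seed, 23])
        q = self.n_traits
        signs = np.zeros((q, self.n_qtl))
        n_hit = min(q, q // 2 + 1)
        for j in range(self.n_qtl):
            hit = rng.choice(q, size=n_hit, replace=False)
            signs[hit, j] = np.where(np.arange(n_hit) % 2 == 0, 1.0, -1.0)
        return signs


@dataclass
class TrueArchitecture:
    """Ground truth of the simulated genetic architecture."""

    qtl_marker_indices: np.ndarray
    effect_matrix: np.ndarray  # q x n_qtl, trait units per minor-allele copy
    true_breeding_values: np.ndarray = field(repr=False)  # n x q
    implied_covariance: np.ndarray = field(repr=False)  # q x q genetic covariance
    trait_ids: tuple[str, ...] = ()


def _chromosome_sizes(n_markers: int, n_chromosomes: int) -> np.ndarray:
    sizes = np.full(n_chromosomes, n_markers // n_chromosomes)
    sizes[: n_markers % n_chromosomes] += 1
    return sizes


def generate_genotypes(config: SyntheticConfig) -> GenotypeMatrix:
    """Draw LD-blocked biallelic dosages with map, per ``config``."""
    rng = np.random.default_rng([config.seed, _GENO_STREAM])
    n, m = config.n_individuals, config.n_markers
    n_hap = 2 * n
    r = config.within_block_r
    lo, hi = config.maf_range

    sizes = _chromosome_sizes(m, config.n_chromosomes)
    chrom_labels = np.repeat(
        [str(c + 1) for c in range(config.n_chromosomes)], sizes
    )

    haps = np.empty((m, n_hap), dtype=np.int8)
    start = 0
    for size in sizes:  # blocks never straddle chromosomes
        for b0 in range(start, start + size, config.block_size):
            b1 = min(b0 + config.block_size, start + size)
            L = b1 - b0
            p = rng.uniform(lo, hi)
            fresh = (rng.random((L, n_hap)) < p).astype(np.int8)
            if r == 0.0 or L == 1:
                haps[b0:b1] = fresh
                continue
            copy = rng.random((L - 1, n_hap)) < r
            prev = fresh[0]
            haps[b0] = prev
            for k in range(1, L):
                prev = np.where(copy[k - 1], prev, fresh[k])
                haps[b0 + k] = prev
        start += size
    dosages = (haps[:, :n] + haps[:, n:]).T.astype(float)

    # 1-based positions, gaps jittered around ~5 kb
    bp = np.empty(m, dtype=int)
    start = 0
    for size in sizes:
        gaps = rng.integers(2000, 8001, size=size)
        bp[start : start + size] = np.cumsum(gaps)
        start += size

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    # orient to the realized minor allele so dosages always count it
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    a1 = np.where(flip, "B", "A")
    a2 = np.where(flip, "A", "B")

    marker_map = pd.DataFrame(
        {
            "chrom": chrom_labels,
            "marker_id": [f"snp{k + 1:06d}" for k in range(m)],
            "bp": bp,
            "a1": a1,
            "a2": a2,
        }
    )
    sample_ids = np.array([f"ind{i + 1:05d}" for i in range(n)])
    return GenotypeMatrix(dosages, sample_ids, marker_map)


def generate_gene_annotation(
    marker_map: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Place non-overlapping gene intervals on the marker map's chromosomes.

    Coordinates are 1-based inclusive.  Roughly one gene in ten is placed in
    a marker desert beyond the last marker of its chromosome (further than
    the VEGAS expansion window), so empty-gene handling is exercised.
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = np.random.default_rng([config.seed, _GENE_STREAM])
    biotypes = np.array(
        ["protein_coding", "pseudogene", "snoRNA", "miRNA", "misc_RNA"]
    )
    bio_p = np.array([0.75, 0.08, 0.07, 0.06, 0.04])

    chroms = marker_map["chrom"].unique()
    max_bp = marker_map.groupby("chrom")["bp"].max()
    n_desert = max(1, config.n_genes // 10)
    n_placed = config.n_genes - n_desert

    # distribute in-map genes across chromosomes proportional to marker count
    counts = marker_map["chrom"].value_counts()
    share = (counts / counts.sum() * n_placed).round().astype(int)
    while share.sum() > n_placed:
        share[share.idxmax()] -= 1
    while share.sum() < n_placed:
        share[share.idxmin()] += 1

    min_len, max_len = 5_000, 50_000
    rows = []
    for chrom in chroms:
        k = int(share.get(chrom, 0))
        if k == 0:
            continue
        span = int(max_bp[chrom])
        slot = span // k
        if slot <= min_len:
            raise ValueError(
                f"chromosome {chrom}: cannot place {k} disjoint genes in "
                f"{span} bp"
            )
        for g in range(k):
            length = int(rng.integers(min_len, min(max_len, slot - 1)))
            lo = g * slot + 1
            start = int(rng.integers(lo, lo + slot - length))
            rows.append((chrom, start, start + length - 1))
    # marker-desert genes: windows (+-100 kb) beyond the last marker
    for g in range(n_desert):
        chrom = chroms[g % len(chroms)]
        base = int(max_bp[chrom]) + 150_000 + 80_000 * (g // len(chroms))
        rows.append((chrom, base, base + 20_000))

    genes = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genes["gene_id"] = [f"gene{i + 1:04d}" for i in range(len(genes))]
    genes["biotype"] = rng.choice(biotypes, size=len(genes), p=bio_p)
    return genes[["chrom", "start", "end", "gene_id", "biotype"]]


def generate_trait_data(
    gm: GenotypeMatrix, config: SyntheticConfig
) -> tuple[dict[str, TraitData], TrueArchitecture]:
    """Simulate correlated TBVs and reliability-noised dEBV tables.

    Returns one :class:`TraitData` per trait (all individuals; the accuracy
    filter is applied downstream) and the ground-truth architecture.
    """
    q = config.n_traits
    rng = np.random.default_rng([config.seed, _TRAIT_STREAM])
    n, m = gm.n_samples, gm.n_markers

    dos = gm.imputed()
    freq = dos.mean(axis=0) / 2.0
    Z = dos - 2.0 * freq

    signs = config.qtl_sign_matrix()
    n_qtl = signs.shape[1]

    # QTL markers: decently polymorphic, spread across the genome
    het = 2.0 * freq * (1.0 - freq)
    eligible = np.flatnonzero(freq >= min(0.1, freq.max() / 2))
    if eligible.size < n_qtl:
        eligible = np.arange(m)
    anchors = np.linspace(0, eligible.size - 1, n_qtl + 2)[1:-1].astype(int)
    qtl_idx = eligible[anchors]

    # effect sizes: indicator matrices are scaled so each QTL explains
    # qtl_var_frac of the (unit) genetic variance of each affected trait
    if np.all(np.isin(signs, (-1.0, 0.0, 1.0))):
        beta = signs * np.sqrt(
            config.qtl_var_frac / np.maximum(het[qtl_idx], 1e-12)[None, :]
        )
    else:
        beta = signs.copy()
    qtl_frac = het[qtl_idx][None, :] * beta**2  # q x n_qtl variance shares

    if config.bg_var is not None:
        var_bg = np.full(q, float(config.bg_var))
    else:
        var_bg = np.clip(1.0 - qtl_frac.sum(axis=1), 0.0, None)
    sd_bg = np.sqrt(var_bg)
    sigma_bg = config.bg_corr * np.outer(sd_bg, sd_bg)
    np.fill_diagonal(sigma_bg, var_bg)

    # polygenic background: per-marker effects ~ MVN(0, sigma_bg / s) on
    # non-QTL markers, so cov(TBV_bg) ~= K * sigma_bg with VanRaden scaling
    bg_mask = np.ones(m, dtype=bool)
    bg_mask[qtl_idx] = False
    s = het[bg_mask].sum()
    tbv = np.zeros((n, q))
    if var_bg.max() > 0 and s > 0:
        try:
            L = np.linalg.cholesky(sigma_bg + 1e-12 * np.eye(q))
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(sigma_bg)
            L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        A = (rng.standard_normal((bg_mask.sum(), q)) / np.sqrt(s)) @ L.T
        tbv += Z[:, bg_mask] @ A
    tbv += Z[:, qtl_idx] @ beta.T

    implied = sigma_bg + (beta * het[qtl_idx][None, :]) @ beta.T

    traits: dict[str, TraitData] = {}
    for t, trait_id in enumerate(config.trait_ids):
        lo, hi = config.reliability_range
        r2 = rng.uniform(lo, hi, size=n)
        var_g = max(implied[t, t], 0.0)
        noise_sd = np.sqrt(var_g * (1.0 - r2) / r2)
        debv = tbv[:, t] + rng.standard_normal(n) * noise_sd
        rec = pd.DataFrame(
            {"animal_id": gm.sample_ids, "debv": debv, "reliability": r2}
        )
        traits[trait_id] = TraitData(
            trait_id=trait_id, h2=config.trait_h2[t], records=rec
        )

    arch = TrueArchitecture(
        qtl_marker_indices=qtl_idx,
        effect_matrix=beta,
        true_breeding_values=tbv,
        implied_covariance=implied,
        trait_ids=tuple(config.trait_ids),
    )
    return traits, arch


def write_dataset(
    outdir: str | Path,
    gm: GenotypeMatrix,
    traits: dict[str, TraitData],
    genes: pd.DataFrame,
    arch: TrueArchitecture | None = None,
    gene_dialect: str = "1-based",
) -> Path:
    """Write PLINK genotypes, trait TSVs, gene table and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(gm, outdir / "genotypes")
    for trait_id, trait in traits.items():
        trait.records.to_csv(
            outdir / f"trait_{trait_id}.tsv", sep="\t", index=False
        )
    gtab = genes.copy()
    if gene_dialect == "bed0":  # 0-based half-open
        gtab["start"] = gtab["start"] - 1
    elif gene_dialect != "1-based":
        raise ValueError(f"unknown gene dialect {gene_dialect!r}")
    gtab.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    if arch is not None:
        truth = pd.DataFrame(
            arch.effect_matrix.T,
            columns=list(arch.trait_ids),
        )
        truth.insert(
            0, "marker_id",
            gm.marker_map["marker_id"].to_numpy()[arch.qtl_marker_indices],
        )
        truth.to_csv(outdir / "true_qtl_effects.tsv", sep="\t", index=False)
        tbv = pd.DataFrame(arch.true_breeding_values, columns=list(arch.trait_ids))
        tbv.insert(0, "animal_id", gm.sample_ids)
        tbv.to_csv(outdir / "true_breeding_values.tsv", sep="\t", index=False)
    return outdir
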