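"""Genotype container and quality-control filters.

Dosages count copies of the minor allele (0/1/2), with ``numpy.nan`` as the
missing sentinel.  QC follows the conventional order for dEBV-based cattle
GWAS: samples are filtered on call rate first, then markers on autosome
membership, call rate and minor allele frequency, with per-marker statistics
recomputed on the retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "filter_samples",
    "filter_markers",
    "gap_summary",
]

MARKER_COLUMNS = ["chrom", "marker_id", "bp", "a1", "a2"]


class GenotypeFormatError(ValueError):
    """Raised when genotype inputs are malformed."""


@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with a marker map.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` float array with values in {0, 1, 2, nan}.
    sample_ids
        Length-n sequence of unique sample labels.
    marker_map
        DataFrame with columns ``chrom`` (str), ``marker_id``, ``bp``
        (1-based int), ``a1`` (counted allele), ``a2``.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.ndim != 2:
            raise GenotypeFormatError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise GenotypeFormatError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.marker_map) != m:
            raise GenotypeFormatError(
                f"marker map has {len(self.marker_map)} rows for {m} markers"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosages[~valid][:5]
            raise GenotypeFormatError(f"dosage codes outside {{0,1,2,nan}}: {bad}")
        self.marker_map = self.marker_map.reset_index(drop=True)

    # -- shape -------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    # -- per-sample / per-marker statistics --------------------------------
    @property
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    @property
    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (a1) allele on non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return freq

    @property
    def maf(self) -> np.ndarray:
        freq = self.allele_frequency
        return np.minimum(freq, 1.0 - freq)

    # -- views -------------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[index, :], self.sample_ids[index], self.marker_map.copy()
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sample_ids,
            self.marker_map.iloc[index].reset_index(drop=True),
        )

    def markers_on(self, chrom: str) -> np.ndarray:
        """Indices of markers on the given chromosome."""
        return np.flatnonzero(self.marker_map["chrom"].to_numpy() == str(chrom))

    def imputed(self, markers: np.ndarray | None = None) -> np.ndarray:
        """Dosages with missing entries replaced by the per-marker mean."""
        sub = self.dosages if markers is None else self.dosages[:, markers]
        sub = sub.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(sub, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        miss = np.isnan(sub)
        sub[miss] = np.broadcast_to(col_mean, sub.shape)[miss]
        return sub


def filter_samples(gm: GenotypeMatrix, min_sample_call: float = 0.90) -> GenotypeMatrix:
    """Retain samples with call rate strictly greater than ``min_sample_call``.

    The threshold is strict (a sample at exactly the threshold is removed),
    matching the convention of reporting samples with call rate *greater
    than* 90%.
    """
    keep = np.flatnonzero(gm.sample_call_rate > min_sample_call)
    if keep.size == 0:
        raise ValueError(
            f"no samples with call rate > {min_sample_call}; check input"
        )
    return gm.take_samples(keep)


def filter_markers(
    gm: GenotypeMatrix,
    autosomes: set[str] | None = None,
    min_marker_call: float = 0.95,
    min_maf: float = 0.02,
) -> GenotypeMatrix:
    """Retain autosomal markers with call rate and MAF at or above thresholds.

    Both marker thresholds are inclusive ("minimum call rate", "MAF of at
    least").  Call rates and MAF are computed on the samples present in
    ``gm``, i.e. after any sample filtering.

    Parameters
    ----------
    autosomes
        Set of chromosome labels to keep.  ``None`` keeps every chromosome
        (useful for fully synthetic autosome-only data).
    """
    keep = (gm.marker_call_rate >= min_marker_call) & (gm.maf >= min_maf)
    if autosomes is not None:
        labels = {str(a) for a in autosomes}
        keep &= gm.marker_map["chrom"].astype(str).isin(labels).to_numpy()
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no markers pass the marker filters")
    return gm.take_markers(idx)


def gap_summary(marker_map: pd.DataFrame) -> tuple[float, float]:
    """Mean and median bp gap between consecutive same-chromosome markers.

    Gaps are never taken across chromosome boundaries.  Raises if no
    chromosome carries at least two markers.
    """
    gaps: list[np.ndarray] = []
    for _, sub in marker_map.groupby("chrom", sort=False):
        bp = np.sort(sub["bp"].to_numpy())
        if bp.size >= 2:
            gaps.append(np.diff(bp))
    if not gaps:
        raise ValueError("need at least one chromosome with >= 2 markers")
    allg = np.concatenate(gaps).astype(float)
    return float(allg.mean()), float(np.median(allg))
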