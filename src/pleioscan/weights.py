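"""Residual weights and accuracy filtering for deregressed breeding values.

Deregressed EBVs (dEBVs) are pseudo-phenotypes with heterogeneous precision:
a record with reliability r2 carries an error variance proportional to
d = (1 - r2) / r2.  The residual weight used in the mixed model is

    w = (d + c) / lambda,        lambda = (1 - h2) / h2,

where h2 is the trait heritability before deregression and c in [0, 1]
balances the contribution of high- and low-reliability records (c = 0.5 by
default).  With c = 0 the weights reduce to d scaled by 1/lambda.

Records are additionally screened on accuracy: by default a record is kept
when its accuracy r = sqrt(r2) is at least 0.50 (i.e. r2 >= 0.25); the
filter can instead be applied to the reliability itself via ``mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TraitData", "residual_weight", "compute_weights", "accuracy_filter"]


@dataclass
class TraitData:
    """Per-trait dEBV records with reliabilities and derived weights.

    ``records`` columns: ``animal_id``, ``debv``, ``reliability`` and, after
    :func:`compute_weights`, ``d`` and ``w``.
    """

    trait_id: str
    h2: float
    records: pd.DataFrame = field(repr=False)
    c: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"trait {self.trait_id}: h2={self.h2} outside (0, 1)")
        if self.c < 0.0:
            raise ValueError(f"trait {self.trait_id}: c={self.c} must be >= 0")
        r2 = self.records["reliability"].to_numpy(dtype=float)
        if np.any((r2 <= 0.0) | (r2 > 1.0)):
            raise ValueError(
                f"trait {self.trait_id}: reliabilities outside (0, 1]"
            )

    @property
    def lam(self) -> float:
        """Variance ratio lambda = (1 - h2) / h2."""
        return (1.0 - self.h2) / self.h2

    @property
    def n_records(self) -> int:
        return len(self.records)


def residual_weight(r2, h2: float, c: float = 0.5):
    """Residual weight w = (d + c) / lambda with d = (1 - r2) / r2.

    Accepts a scalar or array of reliabilities; raises on r2 outside (0, 1]
    or h2 outside (0, 1).
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 <= 0.0) | (r2 > 1.0)):
        raise ValueError("reliability r2 must lie in (0, 1]")
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2={h2} outside (0, 1)")
    if c < 0.0:
        raise ValueError(f"c={c} must be >= 0")
    lam = (1.0 - h2) / h2
    d = (1.0 - r2) / r2
    w = (d + c) / lam
    return w if w.ndim else float(w)


def compute_weights(trait: TraitData) -> TraitData:
    """Return a copy of ``trait`` with ``d`` and ``w`` columns filled in."""
    rec = trait.records.copy()
    r2 = rec["reliability"].to_numpy(dtype=float)
    rec["d"] = (1.0 - r2) / r2
    rec["w"] = residual_weight(r2, trait.h2, trait.c)
    return replace(trait, records=rec)


def accuracy_filter(
    trait: TraitData, min_accuracy: float = 0.50, mode: str = "accuracy"
) -> TraitData:
    """Drop records below the minimum accuracy (inclusive threshold).

    mode="accuracy" keeps records with sqrt(r2) >= min_accuracy (default,
    i.e. r2 >= min_accuracy**2); mode="reliability" applies the threshold to
    r2 directly.
    """
    if mode not in ("accuracy", "reliability"):
        raise ValueError(f"unknown accuracy filter mode {mode!r}")
    if trait.n_records == 0:
        raise ValueError(f"trait {trait.trait_id}: no records to filter")
    r2 = trait.records["reliability"].to_numpy(dtype=float)
    value = np.sqrt(r2) if mode == "accuracy" else r2
    keep = value >= min_accuracy
    if not keep.any():
        raise ValueError(
            f"trait {trait.trait_id}: no records pass accuracy >= {min_accuracy}"
        )
    return replace(trait, records=trait.records.loc[keep].reset_index(drop=True))
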