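"""Minimal PLINK 1 bed/bim/fam reader and writer.

The .bed file is the variant-major 2-bit encoding: after a three-byte header
(0x6c, 0x1b, 0x01) each variant occupies ``ceil(n/4)`` bytes, sample *i*
sitting in bits ``2*(i % 4)`` of byte ``i // 4`` with codes

    00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2.

On read, dosages are oriented to count the minor allele *in the loaded
sample*: if the A1 frequency exceeds 0.5 the marker is recoded (dosage ->
2 - dosage) and the allele columns swapped.  Ties at 0.5 keep A1 as the
counted allele.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeFormatError, GenotypeMatrix

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes((0x6C, 0x1B, 0x01))

# dosage of A1 for each 2-bit code 0..3
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(gm: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as a bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = gm.n_samples, gm.n_markers

    # fam: FID IID father mother sex phenotype
    fam = pd.DataFrame(
        {
            "fid": gm.sample_ids,
            "iid": gm.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": gm.marker_map["chrom"],
            "marker_id": gm.marker_map["marker_id"],
            "cm": 0,
            "bp": gm.marker_map["bp"],
            "a1": gm.marker_map["a1"],
            "a2": gm.marker_map["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # dosage of A1 -> 2-bit code
    dos = gm.dosages
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing (01)
    dt = dos.T
    codes[dt == 2.0] = 0b00
    codes[dt == 1.0] = 0b10
    codes[dt == 0.0] = 0b11

    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a minor-allele-oriented GenotypeMatrix."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise GenotypeFormatError(f"missing PLINK file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].to_numpy()
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    n, m = len(sample_ids), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].tobytes()!r}; "
            "not a variant-major PLINK bed file"
        )
    body = raw[3:]
    bytes_per_variant = (n + 3) // 4
    if body.size != m * bytes_per_variant:
        raise GenotypeFormatError(
            f"{bed_path}: expected {m * bytes_per_variant} data bytes for "
            f"{n} samples x {m} markers, found {body.size}"
        )
    body = body.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # n x m, counting A1

    marker_map = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "marker_id": bim["marker_id"],
            "bp": bim["bp"].astype(int),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    gm = GenotypeMatrix(dosages, sample_ids, marker_map)

    # orient to the minor allele in this sample
    freq = gm.allele_frequency
    flip = freq > 0.5
    if flip.any():
        dos = gm.dosages
        dos[:, flip] = 2.0 - dos[:, flip]
        mm = gm.marker_map
        a1 = mm.loc[flip, "a1"].copy()
        mm.loc[flip, "a1"] = mm.loc[flip, "a2"]
        mm.loc[flip, "a2"] = a1
    return gm
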