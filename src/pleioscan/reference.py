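"""Published reference trait-correlation matrices for Nellore bulls.

Bundled 9 x 9 Pearson correlation matrices among nine weight, conformation,
carcass-finishing-precocity and muscling traits (BW, WG, PG, CW, PW, MW,
CY, PY, MY), as printed for a 995-bull genomic-selection reference
population: one matrix on the dEBV scale and one between genome-wide
signed SNP-effect t-values.  The bracketed (t-value) matrix is reproduced
exactly as printed, including its slight asymmetry; summaries use the upper
triangle.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_correlations"]


def load_reference_correlations() -> dict[str, pd.DataFrame]:
    """Return {'debv': 9x9 DataFrame, 'tvalue': 9x9 DataFrame}."""
    out = {}
    for key, fname in (
        ("debv", "nellore_debv_corr.tsv"),
        ("tvalue", "nellore_tvalue_corr.tsv"),
    ):
        with resources.files("pleioscan.data").joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh, sep="\t", index_col="trait")
    return out
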