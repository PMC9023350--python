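"""AGO1 loading-preference ratios from small-RNA count tables.

Each miRNA is first expressed as a fraction of the total miRNA count in its
sample; the loading ratio is then the IP-sample fraction divided by the
input-sample fraction.  Plain frequency ratios, no pseudocounts: zero-input
miRNAs with IP signal are flagged infinite rather than smoothed, and miRNAs
below ``min_count`` in the input are flagged undetermined.
"""

from __future__ import annotations

import math
import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["loading_ratios", "read_count_table"]


def read_count_table(path: str | os.PathLike) -> pd.Series:
    """TSV with columns ``mirna_id`` and ``count`` -> Series of counts."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str})
    if not {"mirna_id", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mirna_id, count")
    return df.set_index("mirna_id")["count"]


def loading_ratios(
    counts_input: Mapping[str, float] | pd.Series,
    counts_ip: Mapping[str, float] | pd.Series,
    min_count: int = 5,
) -> pd.DataFrame:
    """Per-miRNA AGO1 loading-preference records.

    Returns a DataFrame indexed by miRNA id with columns ``frac_input``,
    ``frac_ip``, ``loading_ratio`` and ``status``
    (ok | undetermined | infinite).  Fractions sum to 1 per sample; ratios
    are invariant to library-size rescaling of either table.
    """
    inp = pd.Series(counts_input, dtype=float)
    ip = pd.Series(counts_ip, dtype=float)
    ids = inp.index.union(ip.index)
    inp = inp.reindex(ids, fill_value=0.0)
    ip = ip.reindex(ids, fill_value=0.0)
    if (inp < 0).any() or (ip < 0).any():
        raise ValueError("counts must be non-negative")
    if inp.sum() <= 0 or ip.sum() <= 0:
        raise ValueError("count tables must have positive totals")
    frac_in = inp / inp.sum()
    frac_ip = ip / ip.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac_ip / frac_in
    status = pd.Series("ok", index=ids)
    status[inp < min_count] = "undetermined"
    status[(frac_in == 0) & (frac_ip > 0)] = "infinite"
    ratio[(frac_in == 0) & (frac_ip > 0)] = math.inf
    ratio[(frac_in == 0) & (frac_ip == 0)] = math.nan
    status[(frac_in == 0) & (frac_ip == 0)] = "undetermined"
    return pd.DataFrame(
        {"frac_input": frac_in, "frac_ip": frac_ip, "loading_ratio": ratio, "status": status}
    ).rename_axis("mirna_id")
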