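"""Gene-level variant tallies and Z-score hotspot calls.

A "variant hotspot" is a gene whose variant count is an extreme outlier
among genes: Z = (count - mean) / sd over the gene count table, flagged
when Z exceeds a normal quantile (default 2.575, the two-sided 99th
percentile, i.e. the upper 0.5% tail). The default background population
is genes carrying at least one variant; pass ``genes`` with
``include_zero=True`` to use all annotated genes instead.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneModel, VariantRecord

log = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.575


def count_variants_per_gene(records: Iterable[VariantRecord],
                            genes: Optional[Sequence[GeneModel]] = None,
                            include_zero: bool = False) -> pd.DataFrame:
    """Tally variants per gene (a variant overlapping two genes counts in both).

    Returns a DataFrame with columns gene_id, variant_count, sorted by
    descending count then gene_id.
    """
    counts: dict[str, int] = {}
    if include_zero:
        if genes is None:
            raise ValueError("include_zero=True requires the gene list")
        counts = {g.gene_id: 0 for g in genes}
    for r in records:
        for gid in r.gene_ids:
            counts[gid] = counts.get(gid, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene_id", "variant_count"])
    return df.sort_values(["variant_count", "gene_id"],
                          ascending=[False, True], ignore_index=True)


def call_hotspots(counts: pd.DataFrame,
                  z_threshold: float = DEFAULT_Z_THRESHOLD,
                  ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene's count and flag hotspots at Z strictly > threshold.

    ``ddof=1`` uses the sample standard deviation (default); ``ddof=0`` the
    population one. With zero spread all Z are reported as 0 and nothing is
    flagged (logged). Fewer than two genes is an error.
    """
    if len(counts) < 2:
        raise ValueError("insufficient genes: need >= 2 for a Z-score")
    values = counts["variant_count"].to_numpy(dtype=float)
    mean = values.mean()
    sd = values.std(ddof=ddof)
    if sd == 0:
        log.warning("all gene variant counts equal (sd = 0); no hotspots callable")
        z = np.zeros_like(values)
    else:
        z = (values - mean) / sd
    out = counts.copy()
    out["z_score"] = z
    out["is_hotspot"] = (z > z_threshold) & (sd != 0)
    return out
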