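"""Case-control contrast maps for the imaging indices.

For each of ALFF, fALFF, ReHo and GMD the pipeline reduces a subject x site
table to a per-site two-sided two-sample t statistic (positive = higher in
cases) with Benjamini-Hochberg control of the false discovery rate across
sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import two_sample_t
from .types import DifferenceMap, GroupImagingDataset


def bh_correct(p: np.ndarray, q: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Parameters
    ----------
    p
        Raw p-values in [0, 1].
    q
        FDR threshold; a test is significant when its adjusted p is
        strictly below ``q``.

    Returns
    -------
    significant, p_adj
        Boolean significance vector and monotone adjusted p-values.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj < q, p_adj


def group_difference_map(
    data: GroupImagingDataset,
    variant: str = "pooled",
    q: float = 0.001,
) -> DifferenceMap:
    """Per-site case-control two-sided t contrast with BH correction.

    ``variant`` selects pooled-variance Student's t (default, the
    conventional neuroimaging group statistic) or Welch's t.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    cases, controls = data.split()
    t, p = two_sample_t(cases, controls, equal_var=(variant == "pooled"))
    significant, p_adj = bh_correct(p, q=q)
    table = pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "significant": significant},
        index=pd.Index(data.values.columns, name="site_id"),
    )
    return DifferenceMap(index_name=data.index_name, table=table)
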