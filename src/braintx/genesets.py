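"""Differential expression, reference-list overlap and hypergeometric
term enrichment with the count/factor filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import two_sample_t


def differential_expression(
    case: pd.DataFrame,
    control: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene two-sided t-test of case vs control sample matrices.

    Both inputs are genes x samples with identical gene indices.  Returns
    only genes with p < ``alpha``, with direction "down" when the case mean
    is below the control mean.
    """
    if not case.index.equals(control.index):
        raise ValueError("case and control matrices must share the same gene index")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >=2 samples per group")
    t, p = two_sample_t(case.to_numpy(float).T, control.to_numpy(float).T)
    diff = case.mean(axis=1) - control.mean(axis=1)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.where(diff.to_numpy() < 0, "down", "up"),
        },
        index=case.index.rename("gene_id"),
    )
    return out[out["p"] < alpha]


def overlap_percentage(class_genes: set[str], reference: set[str]) -> float:
    """100 * |class ∩ reference| / |class|, rounded to two decimals."""
    if not class_genes:
        raise ValueError("empty gene class")
    return round(100.0 * len(set(class_genes) & set(reference)) / len(class_genes), 2)


def overlap_table(
    class_sets: dict[str, set[str]],
    reference: set[str],
) -> pd.DataFrame:
    """Raw overlap counts and percentages per class against one reference list.

    Counts are reported alongside percentages so the arithmetic is auditable.
    """
    rows = []
    for label, genes in class_sets.items():
        if not genes:
            continue
        inter = len(set(genes) & set(reference))
        rows.append(
            {
                "class": label,
                "class_size": len(genes),
                "overlap": inter,
                "percent": overlap_percentage(genes, reference),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def hypergeometric_enrichment(
    selected: set[str],
    terms: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.01,
    min_count: int = 3,
    min_factor: float = 1.5,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail (accumulative) hypergeometric enrichment of annotation terms.

    For each term with ``bg_count`` background genes, the p-value is
    P(X >= count) for X hypergeometric(bg_size, bg_count, set_size).
    The enrichment factor is (count/set_size) / (bg_count/bg_size).
    ``passes`` requires adjusted p < alpha AND count >= min_count AND
    factor > min_factor.
    """
    if not background:
        raise ValueError("empty background")
    stray = set(selected) - set(background)
    if stray:
        raise ValueError(f"selected genes outside background: {sorted(stray)[:5]}")
    bg = set(background)
    sel = set(selected)
    bg_size, set_size = len(bg), len(sel)
    rows = []
    for term_id, genes in terms.items():
        term_bg = set(genes) & bg
        bg_count = len(term_bg)
        count = len(term_bg & sel)
        p = float(stats.hypergeom.sf(count - 1, bg_size, bg_count, set_size)) if bg_count else 1.0
        factor = (
            (count / set_size) / (bg_count / bg_size) if bg_count and set_size else 0.0
        )
        rows.append(
            {
                "term_id": term_id,
                "count": count,
                "set_size": set_size,
                "bg_count": bg_count,
                "bg_size": bg_size,
                "enrichment_factor": factor,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method=method)
        out["p_adj"] = p_adj
        out["passes"] = (
            (out["p_adj"] < alpha)
            & (out["count"] >= min_count)
            & (out["enrichment_factor"] > min_factor)
        )
    else:
        out["p_adj"] = []
        out["passes"] = []
    return out.sort_values("p")
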