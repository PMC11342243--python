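"""Sex-differential expression of depression-related genes.

Genes are tested female vs male across developmental samples restricted to
the periods sampled in both sexes ("corresponding periods"), yielding one
two-sided t-test per gene; per-class percentages of female-high vs
male-high genes and period x region grids of the female-minus-male
difference localize the bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import two_sample_t
from .types import DevExpressionSet

FEMALE_HIGH = "female_high"
MALE_HIGH = "male_high"


def _shared_period_mask(dev: DevExpressionSet) -> pd.Series:
    sex = dev.samples["sex"]
    if not (sex == "female").any() or not (sex == "male").any():
        raise ValueError("both sexes must be present in the developmental set")
    by_period = dev.samples.groupby("period", observed=True)["sex"].agg(lambda s: set(s))
    shared = {p for p, sexes in by_period.items() if {"male", "female"} <= sexes}
    return dev.samples["period"].isin(shared)


def sex_de_genes(
    dev: DevExpressionSet,
    genes: list[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Genes with sex-differential expression at p < ``alpha``.

    Expression is pooled over the periods where both sexes have samples and
    compared female vs male with a two-sided t-test.  Positive t means
    higher expression in females.
    """
    genes = list(dev.gene_ids if genes is None else genes)
    mask = _shared_period_mask(dev)
    sub = dev.expression.loc[mask, genes]
    sex = dev.samples.loc[mask, "sex"]
    f = sub[(sex == "female").to_numpy()].to_numpy(float)
    m = sub[(sex == "male").to_numpy()].to_numpy(float)
    t, p = two_sample_t(f, m)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.where(
                f.mean(axis=0) > m.mean(axis=0), FEMALE_HIGH, MALE_HIGH
            ),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out[out["p"] < alpha]


def sex_bias_percentages(
    records: pd.DataFrame,
    class_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Per class: % of its sex-different genes that are female-high / male-high.

    Classes with no sex-different genes are reported with NaN percentages
    (missing), never dropped silently.
    """
    rows = []
    for label, genes in class_sets.items():
        sub = records.loc[sorted(set(genes) & set(records.index))]
        n = len(sub)
        if n == 0:
            rows.append(
                {"class": label, "n_sexdiff": 0, "percent_female_high": np.nan,
                 "percent_male_high": np.nan}
            )
            continue
        nf = int((sub["direction"] == FEMALE_HIGH).sum())
        rows.append(
            {
                "class": label,
                "n_sexdiff": n,
                "percent_female_high": round(100.0 * nf / n, 2),
                "percent_male_high": round(100.0 * (n - nf) / n, 2),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def sex_overexpression_grid(
    dev: DevExpressionSet,
    sexdiff_genes: set[str],
    control_genes: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Period x region grids contrasting per-gene sex differences.

    Within each cell the female-minus-male mean expression difference is
    computed per gene, then the sexdiff-gene differences are compared with
    the control-gene differences by a two-sided t-test (positive t = the
    sexdiff genes are more female-biased there).  Cells lacking either sex
    are NaN (flagged missing).
    """
    if not sexdiff_genes or not control_genes:
        raise ValueError("both gene groups must be nonempty")
    sd = sorted(sexdiff_genes)
    ctl = sorted(control_genes)
    genes = sorted(set(sd) | set(ctl))
    t_grid = pd.DataFrame(np.nan, index=list(dev.periods), columns=list(dev.regions))
    p_grid = t_grid.copy()
    grouped = dev.expression[genes].groupby(
        [dev.samples["period"], dev.samples["region"], dev.samples["sex"]],
        observed=True,
    ).mean()
    for period in dev.periods:
        for region in dev.regions:
            try:
                fm = grouped.loc[(period, region, "female")]
                mm = grouped.loc[(period, region, "male")]
            except KeyError:
                continue
            diff = fm - mm
            t, p = two_sample_t(
                diff[sd].to_numpy(float)[:, None], diff[ctl].to_numpy(float)[:, None]
            )
            t_grid.loc[period, region] = float(t[0])
            p_grid.loc[period, region] = float(p[0])
    return t_grid, p_grid
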