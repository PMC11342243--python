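"""Temporal-spatial expression specificity: SPI profiles and the dispersion
index (DPI).

For a nonnegative expression profile X = (x_1, ..., x_n), the specificity
index of sample i is the cosine of the angle between X and the vector that
keeps only coordinate i:

    SPI_i = cos(theta_i) = x_i / ||X||_2

so that sum(SPI_i^2) = 1.  The dispersion index condenses the SPI profile
into one number,

    DPI = sqrt( n * sum_i (SPI_i - mean(SPI))^2 / (n - 1) ),

which is 0 for a perfectly uniform profile, exactly 1 when all expression
sits in a single sample, and invariant to positive rescaling of X and to
the number of samples.  Temporal specificity uses the per-period mean
profile (8 levels) and spatial specificity the per-region mean profile
(16 levels); high spatial DPI with low temporal DPI is the signature of a
gene expressed in few regions but across many developmental periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import two_sample_t
from .types import DevExpressionSet

AXES = ("temporal", "spatial")


@dataclass
class SPIProfile:
    """Per-sample specificity values of one expression profile."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean_spi(self) -> float:
        return float(self.values.mean())


def _check_profile(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValueError("profile entries must be nonnegative")
    if not x.any():
        raise ValueError("profile must not be all zero")
    return x


def spi_profile(x: np.ndarray) -> SPIProfile:
    """SPI_i = x_i / ||x||_2 for a nonnegative, not-all-zero profile."""
    x = _check_profile(x)
    return SPIProfile(values=x / np.linalg.norm(x))


def dpi(x: np.ndarray) -> float:
    """Dispersion index of a nonnegative profile; lies in [0, 1]."""
    spi = spi_profile(x).values
    n = spi.size
    return float(np.sqrt(n * np.sum((spi - spi.mean()) ** 2) / (n - 1)))


def _dpi_columns(profiles: np.ndarray) -> np.ndarray:
    """DPI of each column of a levels x genes nonnegative profile matrix.

    All-zero columns yield NaN (specificity undefined for a silent gene).
    """
    norms = np.linalg.norm(profiles, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spi = profiles / norms
        n = profiles.shape[0]
        out = np.sqrt(n * ((spi - spi.mean(axis=0)) ** 2).sum(axis=0) / (n - 1))
    return np.where(norms > 0, out, np.nan)


def axis_profile(dev: DevExpressionSet, gene: str, axis: str) -> pd.Series:
    """Mean expression of ``gene`` per period (temporal) or region (spatial)."""
    table = axis_profiles(dev, [gene], axis)
    return table[gene]


def axis_profiles(dev: DevExpressionSet, genes: list[str], axis: str) -> pd.DataFrame:
    """Levels x genes matrix of per-level mean expression."""
    labels = dev.axis_labels(axis)
    col = dev.axis_column(axis)
    grouped = dev.expression[genes].groupby(dev.samples[col], observed=True).mean()
    empty = [lv for lv in labels if lv not in grouped.index]
    if empty:
        raise ValueError(f"no samples for {axis} level(s): {empty}")
    return grouped.reindex(list(labels))


def gene_dpi(dev: DevExpressionSet, genes: list[str] | None = None, axis: str = "spatial") -> pd.Series:
    """DPI per gene along one axis, computed on per-level mean profiles."""
    genes = list(dev.gene_ids if genes is None else genes)
    profiles = axis_profiles(dev, genes, axis)
    return pd.Series(_dpi_columns(profiles.to_numpy(float)), index=genes, name=f"dpi_{axis}")


def class_dpi_comparison(
    dev: DevExpressionSet,
    class_genes: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene temporal and spatial DPI plus pairwise group t-tests.

    ``class_genes`` maps group label -> gene-id set (e.g. Class1 / Class2 /
    control).  Returns (per-gene DPI table, comparison table with group
    means, t and p per axis and group pair).
    """
    for label, genes in class_genes.items():
        if len(genes) < 2:
            raise ValueError(f"group {label!r} needs >=2 genes")
    all_genes = sorted(set().union(*class_genes.values()))
    table = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"))
    for axis in AXES:
        table[f"dpi_{axis}"] = gene_dpi(dev, all_genes, axis)
    labels = list(class_genes)
    rows = []
    for axis in AXES:
        col = table[f"dpi_{axis}"]
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                va = col.loc[sorted(class_genes[a])].dropna().to_numpy()
                vb = col.loc[sorted(class_genes[b])].dropna().to_numpy()
                t, p = two_sample_t(va[:, None], vb[:, None])
                rows.append(
                    {
                        "axis": axis,
                        "group_a": a,
                        "group_b": b,
                        "mean_a": va.mean(),
                        "mean_b": vb.mean(),
                        "t": float(t[0]),
                        "p": float(p[0]),
                    }
                )
    return table, pd.DataFrame(rows)


def overexpression_grid(
    dev: DevExpressionSet,
    class_genes: set[str],
    control_genes: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Period x region grids of t (positive = class genes higher) and p.

    Within each (period, region) cell every gene's mean expression over the
    cell's samples is computed, then class genes are compared with control
    genes by a two-sided t-test.  Cells without samples are NaN.
    """
    if not class_genes or not control_genes:
        raise ValueError("both gene groups must be nonempty")
    cg = sorted(class_genes)
    ctl = sorted(control_genes)
    t_grid = pd.DataFrame(np.nan, index=list(dev.periods), columns=list(dev.regions))
    p_grid = t_grid.copy()
    cell_means = dev.expression[sorted(set(cg) | set(ctl))].groupby(
        [dev.samples["period"], dev.samples["region"]], observed=True
    ).mean()
    for (period, region), means in cell_means.iterrows():
        t, p = two_sample_t(
            means[cg].to_numpy(float)[:, None], means[ctl].to_numpy(float)[:, None]
        )
        t_grid.loc[period, region] = float(t[0])
        p_grid.loc[period, region] = float(p[0])
    return t_grid, p_grid
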