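"""Shared containers for the pipeline stages.

All tabular data live in pandas DataFrames; the dataclasses here only add
the invariants each stage relies on (unique gene ids, aligned site sets,
nonnegative developmental expression) and a few convenience accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Imaging indices analysed by the pipeline.  ALFF, fALFF and ReHo are
#: resting-state functional measures; GMD (grey matter density) is structural.
INDICES: tuple[str, ...] = ("ALFF", "fALFF", "ReHo", "GMD")
FUNCTIONAL_INDICES: tuple[str, ...] = ("ALFF", "fALFF", "ReHo")
STRUCTURAL_INDEX: str = "GMD"

#: Developmental periods, embryonic development through adulthood.
DEFAULT_PERIODS: tuple[str, ...] = (
    "embryonic",
    "early_fetal",
    "late_fetal",
    "infancy",
    "childhood",
    "adolescence",
    "young_adulthood",
    "adulthood",
)

#: Brain regions of the developmental expression set: 11 neocortical areas
#: plus hippocampus, amygdala, striatum, mediodorsal thalamus and cerebellar
#: cortex.
DEFAULT_REGIONS: tuple[str, ...] = (
    "OFC", "DFC", "VFC", "MFC", "M1C", "S1C", "IPC", "A1C",
    "STC", "ITC", "V1C", "HIP", "AMY", "STR", "MD", "CBC",
)


@dataclass
class ExpressionMatrix:
    """Genes x sample-sites expression values (the spatial profile of each gene).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per site id.
    normalized
        True once each row has been z-scored across sites (mean 0, SD 1).
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate site ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupImagingDataset:
    """Per-subject per-site values for one imaging index in a two-group cohort."""

    index_name: str
    values: pd.DataFrame          # subjects x sites
    group: pd.Series              # per-subject "case" / "control"

    def __post_init__(self) -> None:
        if self.index_name not in INDICES:
            raise ValueError(f"unknown imaging index {self.index_name!r}; expected one of {INDICES}")
        if not self.values.index.equals(self.group.index):
            raise ValueError("subject ids of values and group labels differ")
        counts = self.group.value_counts()
        for g in ("case", "control"):
            if counts.get(g, 0) < 2:
                raise ValueError(f"need >=2 subjects in group {g!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite imaging values")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (case, control) value arrays, subjects x sites."""
        v = self.values.to_numpy(float)
        mask = (self.group == "case").to_numpy()
        return v[mask], v[~mask]


@dataclass
class DifferenceMap:
    """Per-site case-control t contrast for one imaging index.

    Positive t means the index is higher in cases than controls.
    """

    index_name: str
    table: pd.DataFrame           # index: site_id; columns: t, p, p_adj, significant

    def __post_init__(self) -> None:
        required = {"t", "p", "p_adj", "significant"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"difference map missing columns {sorted(missing)}")
        p = self.table["p"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DevExpressionSet:
    """Developmental expression samples annotated by period, region and sex.

    ``samples`` is indexed by sample id with columns period / region / sex;
    ``expression`` is samples x genes and must be nonnegative (the specificity
    index is a cosine on nonnegative profiles).
    """

    samples: pd.DataFrame
    expression: pd.DataFrame
    periods: tuple[str, ...] = DEFAULT_PERIODS
    regions: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        for col in ("period", "region", "sex"):
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation missing column {col!r}")
        if not self.samples.index.equals(self.expression.index):
            raise ValueError("sample ids of annotations and expression differ")
        bad_period = set(self.samples["period"]) - set(self.periods)
        if bad_period:
            raise ValueError(f"unknown period labels: {sorted(bad_period)}")
        bad_region = set(self.samples["region"]) - set(self.regions)
        if bad_region:
            raise ValueError(f"unknown region labels: {sorted(bad_region)}")
        bad_sex = set(self.samples["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        if (self.expression.to_numpy(float) < 0).any():
            raise ValueError("developmental expression must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    def axis_labels(self, axis: str) -> tuple[str, ...]:
        if axis == "temporal":
            return self.periods
        if axis == "spatial":
            return self.regions
        raise ValueError(f"axis must be 'temporal' or 'spatial', got {axis!r}")

    def axis_column(self, axis: str) -> str:
        return "period" if axis == "temporal" else "region"
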