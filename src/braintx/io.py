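"""Readers and writers for the pipeline's tabular formats.

TSV dialect: tab-separated, UTF-8, header row, '.' decimal, "NA" for
missing values.  Gene sets use the GMT format (term, description, then one
gene id per field); reference gene lists are one id per line; ground truth
and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .types import DevExpressionSet, DifferenceMap, ExpressionMatrix, GroupImagingDataset

_TSV = dict(sep="\t", na_rep="NA")


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kw)
    except pd.errors.ParserError as exc:
        raise ValueError(f"corrupt TSV {path}: {exc}") from exc


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, **_TSV)


def read_expression_matrix(path: str | Path, normalized: bool = False) -> ExpressionMatrix:
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r} in matrix")
    return ExpressionMatrix(values=df.astype(float), normalized=normalized)


def write_imaging(data: GroupImagingDataset, path: str | Path) -> None:
    df = data.values.copy()
    df.insert(0, "group", data.group)
    df.index.name = "subject_id"
    df.to_csv(path, **_TSV)


def read_imaging(path: str | Path, index_name: str) -> GroupImagingDataset:
    df = _read_tsv(path, index_col=0)
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    group = df["group"].astype(str)
    values = df.drop(columns="group").astype(float)
    return GroupImagingDataset(index_name=index_name, values=values, group=group)


def write_difference_map(dmap: DifferenceMap, path: str | Path) -> None:
    dmap.table.to_csv(path, **_TSV)


def read_difference_map(path: str | Path, index_name: str) -> DifferenceMap:
    df = _read_tsv(path, index_col=0)
    df["significant"] = df["significant"].astype(bool)
    return DifferenceMap(index_name=index_name, table=df)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, index=False, **_TSV)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"protein_a", "protein_b", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gmt(terms: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = descriptions.get(term, "NA")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description and >=1 gene")
        terms[fields[0]] = set(fields[2:])
    return terms


def write_dev_set(dev: DevExpressionSet, path: str | Path) -> None:
    df = pd.concat([dev.samples, dev.expression], axis=1)
    df.index.name = "sample_id"
    df.to_csv(path, **_TSV)


def read_dev_set(
    path: str | Path,
    periods: tuple[str, ...] | None = None,
    regions: tuple[str, ...] | None = None,
) -> DevExpressionSet:
    df = _read_tsv(path, index_col=0)
    for col in ("period", "region", "sex"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing annotation column {col!r}")
    samples = df[["period", "region", "sex"]]
    expression = df.drop(columns=["period", "region", "sex"]).astype(float)
    kw = {}
    if periods is not None:
        kw["periods"] = tuple(periods)
    if regions is not None:
        kw["regions"] = tuple(regions)
    # fall back to the label sets present in the file when no vocabulary given
    if periods is None:
        kw["periods"] = tuple(pd.unique(samples["period"]))
    if regions is None:
        kw["regions"] = tuple(pd.unique(samples["region"]))
    return DevExpressionSet(samples=samples, expression=expression, **kw)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_grid(grid: pd.DataFrame, path: str | Path) -> None:
    g = grid.copy()
    g.index.name = "period"
    g.to_csv(path, **_TSV)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
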