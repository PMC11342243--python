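"""Probe-level to gene-level expression processing.

Mirrors the standard brain-wide microarray workflow on tabular inputs:
drop probes that fail background detection in more than half of the
samples, keep one representative probe per gene by peak mean intensity,
remove donor (batch) offsets, apply scaled robust sigmoid normalization
per gene, then z-score each gene across sites.  Probe-to-gene annotation
is an input (a supplied probe -> gene map inside the probe table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ProbeTable:
    """Probe-level intensities with background-detection flags.

    ``values`` and ``above_background`` are probes x sites with identical
    shape and indices; ``gene_id`` maps each probe to its gene.
    """

    gene_id: pd.Series                 # per-probe gene id
    values: pd.DataFrame               # probes x sites
    above_background: pd.DataFrame     # probes x sites, boolean

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if not self.values.index.equals(self.above_background.index):
            raise ValueError("values and flags disagree on probe ids")
        if not self.values.columns.equals(self.above_background.columns):
            raise ValueError("values and flags disagree on site ids")
        if not self.values.index.equals(self.gene_id.index):
            raise ValueError("gene map does not cover every probe")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)


def filter_probes(probes: ProbeTable) -> ProbeTable:
    """Keep probes detected above background in at least half the sites.

    The elimination rule targets probes failing in *more than* 50% of sites,
    so a probe above background in exactly half of them is retained.
    """
    if len(probes.values) == 0:
        raise ValueError("empty probe table")
    frac = probes.above_background.mean(axis=1)
    keep = frac >= 0.5
    return ProbeTable(
        gene_id=probes.gene_id[keep],
        values=probes.values[keep],
        above_background=probes.above_background[keep],
    )


def select_representative_probe(probes: ProbeTable) -> ExpressionMatrix:
    """One row per gene: the probe with the highest mean intensity across sites.

    Ties break to the lexicographically smallest probe id.  Genes whose
    probes were all filtered out are simply absent from the output.
    """
    means = probes.values.mean(axis=1)
    table = pd.DataFrame({"gene_id": probes.gene_id, "mean": means})
    table = table.sort_index()  # lexicographic probe order => first max wins ties
    winners = table.groupby("gene_id")["mean"].idxmax()
    values = probes.values.loc[winners.to_numpy()]
    values.index = winners.index
    n_lost = probes.gene_id.nunique() - len(winners)
    if n_lost:
        log.info("%d genes lost all probes during collapse", n_lost)
    return ExpressionMatrix(values=values.sort_index(), normalized=False)


def srs_normalize(row: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median)/(IQR/1.35)), min-max
    rescaled to [0, 1].  Order-preserving; degenerate rows (IQR 0) come back
    as all 0.5 with a warning."""
    row = np.asarray(row, float)
    if row.size < 2:
        raise ValueError("row must have length >= 2")
    med = np.median(row)
    q75, q25 = np.percentile(row, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        log.warning("zero IQR: scaled-robust-sigmoid output degenerate (0.5)")
        return np.full_like(row, 0.5)
    y = 1.0 / (1.0 + np.exp(-(row - med) / (iqr / 1.35)))
    return (y - y.min()) / (y.max() - y.min())


def normalize_matrix(m: ExpressionMatrix, donor_ids: pd.Series) -> ExpressionMatrix:
    """Donor-mean centering, then SRS per gene row, then row z-scoring.

    The per-gene per-donor centering removes additive between-donor offsets
    so the aggregated sites show no inter-individual disparities; donors
    contributing a single site are skipped (their offset is unidentifiable).
    """
    donor_ids = pd.Series(donor_ids)
    if list(donor_ids.index) != m.site_ids:
        donor_ids = pd.Series(np.asarray(donor_ids), index=m.site_ids)
    values = m.values.to_numpy(float).copy()
    donors = donor_ids.to_numpy()
    for donor in pd.unique(donors):
        mask = donors == donor
        if mask.sum() < 2:
            log.warning("donor %r has a single site; centering skipped", donor)
            continue
        values[:, mask] -= values[:, mask].mean(axis=1, keepdims=True)
    srs = np.apply_along_axis(srs_normalize, 1, values)
    z = (srs - srs.mean(axis=1, keepdims=True))
    sd = srs.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, z / sd, 0.0)
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, normalized=True)
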