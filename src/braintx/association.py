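"""Spearman association of gene expression with contrast maps, permutation
p-values, and directional classification of depression-related genes.

A gene is called depression-related when its spatial expression profile is
simultaneously correlated (permutation P below ``alpha``) with the
structural contrast (GMD) and with at least one functional contrast (ALFF,
fALFF or ReHo).  Selected genes are split by directional effect:

* Class 1 — negative correlation with the GMD contrast and positive with
  every significant functional contrast (negative effect on grey matter
  density, positive on function);
* Class 2 — the mirror image;
* genes with mixed significant functional signs stay "unclassified";
* non-selected genes are "control".

The permutation null shuffles the contrast map across sites (naive
exchangeability — no spatial-autocorrelation-preserving surrogate), and the
two-sided p-value carries an add-one correction so that with 10,000
permutations the attainable minimum is 1/10,001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import substream
from .types import (
    DifferenceMap,
    ExpressionMatrix,
    FUNCTIONAL_INDICES,
    INDICES,
    STRUCTURAL_INDEX,
)

CLASS1 = "Class1"
CLASS2 = "Class2"
UNCLASSIFIED = "unclassified"
CONTROL = "control"


@dataclass
class AssociationRecord:
    """Spearman rho and permutation p for one gene against one contrast map."""

    gene_id: str
    index_name: str
    rho: float
    p_perm: float
    n_perm: int

    def __post_init__(self) -> None:
        if not np.isnan(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| > 1")
        if self.p_perm < 1.0 / (self.n_perm + 1) - 1e-15:
            raise ValueError("p_perm below attainable minimum 1/(n_perm+1)")


def spearman_rho(expr: np.ndarray, contrast: np.ndarray) -> float:
    """Spearman's rho with average ranks for ties; NaN for constant input."""
    expr = np.asarray(expr, float)
    contrast = np.asarray(contrast, float)
    if expr.shape != contrast.shape or expr.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if expr.size < 3:
        raise ValueError("need >=3 sites")
    if np.ptp(expr) == 0 or np.ptp(contrast) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(expr, contrast)
    return float(rho)


def _rank_z(matrix: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, standardized to mean 0 / SD 1 (population).

    Rows with zero rank variance (constant input) come back as all-NaN so the
    resulting correlations are flagged missing.
    """
    r = stats.rankdata(matrix, axis=-1)
    r = r - r.mean(axis=-1, keepdims=True)
    sd = r.std(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, r / sd, np.nan)
    return z


def _permutation_pvalues(
    expr_values: np.ndarray,
    contrast: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    perm_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized permutation test for all genes against one contrast map.

    Spearman's rho is the Pearson correlation of average ranks, so one
    matrix product against the permuted standardized contrast ranks yields
    the whole null ensemble.

    Returns (rho, p, perm_indices).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = contrast.shape[0]
    if expr_values.shape[1] != n:
        raise ValueError("expression and contrast site counts differ")
    if n < 3:
        raise ValueError("need >=3 sites")
    ez = _rank_z(expr_values)            # genes x sites
    cz = _rank_z(contrast[None, :])[0]   # sites
    rho = ez @ cz / n
    if perm_indices is None:
        perm_indices = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = ez @ cz[perm_indices].T / n   # genes x n_perm
    exceed = (np.abs(null) >= np.abs(rho)[:, None] - 1e-12).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p, perm_indices


def permutation_pvalue(
    expr: np.ndarray,
    contrast: np.ndarray,
    n_perm: int,
    seed: int,
    gene_id: str = "gene",
    index_name: str = "ALFF",
) -> AssociationRecord:
    """Two-sided permutation p-value for one gene/contrast pair.

    The contrast map is shuffled across sites ``n_perm`` times;
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1).
    """
    expr = np.asarray(expr, float)
    contrast = np.asarray(contrast, float)
    rng = substream(seed, f"perm:{index_name}")
    rho, p, _ = _permutation_pvalues(expr[None, :], contrast, n_perm, rng)
    return AssociationRecord(
        gene_id=gene_id,
        index_name=index_name,
        rho=float(rho[0]),
        p_perm=float(p[0]),
        n_perm=n_perm,
    )


def associate_all(
    expr: ExpressionMatrix,
    maps: dict[str, DifferenceMap],
    n_perm: int = 10_000,
    seed: int = 0,
    shared_permutations: bool = True,
) -> pd.DataFrame:
    """Per-gene rho and permutation p for every imaging index.

    With ``shared_permutations`` (default) one seeded permutation set of the
    site labels is reused for every gene within an index, which keeps runs
    reproducible and lets the null ensemble be computed as a single matrix
    product.  Per-gene independent permutations are available by flag.
    """
    missing = set(INDICES) - set(maps)
    if missing:
        raise ValueError(f"missing difference maps for indices: {sorted(missing)}")
    sites = expr.site_ids
    for name, dmap in maps.items():
        if list(dmap.site_ids) != sites:
            offending = sorted(set(dmap.site_ids) ^ set(sites))
            raise ValueError(
                f"site mismatch between expression matrix and {name} map: {offending[:10]}"
            )
    values = expr.values.to_numpy(float)
    out: dict[str, np.ndarray] = {}
    for name in INDICES:
        contrast = maps[name].t.to_numpy(float)
        rng = substream(seed, f"perm:{name}")
        if shared_permutations:
            rho, p, _ = _permutation_pvalues(values, contrast, n_perm, rng)
        else:
            # independent permutation set per gene: permuting the gene's own
            # ranks against the fixed map ranks draws from the same null
            n = contrast.shape[0]
            ez = _rank_z(values)
            cz = _rank_z(contrast[None, :])[0]
            rho = ez @ cz / n
            p = np.empty(len(values))
            for i in range(len(values)):
                perms = np.argsort(rng.random((n_perm, n)), axis=1)
                null = ez[i][perms] @ cz / n
                exceed = (np.abs(null) >= abs(rho[i]) - 1e-12).sum()
                p[i] = (1.0 + exceed) / (n_perm + 1.0)
            p = np.where(np.isnan(rho), np.nan, p)
        out[f"rho_{name}"] = rho
        out[f"p_{name}"] = p
    records = pd.DataFrame(out, index=pd.Index(expr.gene_ids, name="gene_id"))
    records.attrs["n_perm"] = n_perm
    return records


def identify_depression_genes(
    expr: ExpressionMatrix,
    maps: dict[str, DifferenceMap],
    alpha: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
    shared_permutations: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Select genes correlated with GMD AND at least one functional index.

    Returns the full association record table and the selected gene ids.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    records = associate_all(
        expr, maps, n_perm=n_perm, seed=seed, shared_permutations=shared_permutations
    )
    sig_gmd = records[f"p_{STRUCTURAL_INDEX}"] < alpha
    sig_fun = np.zeros(len(records), dtype=bool)
    for name in FUNCTIONAL_INDICES:
        sig_fun |= (records[f"p_{name}"] < alpha).to_numpy()
    selected = records.index[sig_gmd.to_numpy() & sig_fun].tolist()
    return records, selected


def classify_directional(
    records: pd.DataFrame,
    selected: list[str],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Assign Class1 / Class2 / unclassified / control labels.

    Only *significant* functional correlations constrain the sign pattern;
    a selected gene whose significant functional rhos disagree in sign (or
    disagree with the required GMD sign) is left unclassified rather than
    forced into a class.
    """
    needed = [f"rho_{n}" for n in INDICES] + [f"p_{n}" for n in INDICES]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"association records missing columns: {missing}")
    unknown = set(selected) - set(records.index)
    if unknown:
        raise ValueError(f"selected genes without records: {sorted(unknown)[:5]}")

    labels = pd.Series(CONTROL, index=records.index, name="class")
    sel = records.loc[list(selected)]
    rho_gmd = sel[f"rho_{STRUCTURAL_INDEX}"].to_numpy()
    fun_rho = sel[[f"rho_{n}" for n in FUNCTIONAL_INDICES]].to_numpy()
    fun_sig = (sel[[f"p_{n}" for n in FUNCTIONAL_INDICES]].to_numpy() < alpha)

    sig_pos = ((fun_rho > 0) | ~fun_sig).all(axis=1) & fun_sig.any(axis=1)
    sig_neg = ((fun_rho < 0) | ~fun_sig).all(axis=1) & fun_sig.any(axis=1)
    cls = np.where(
        (rho_gmd < 0) & sig_pos,
        CLASS1,
        np.where((rho_gmd > 0) & sig_neg, CLASS2, UNCLASSIFIED),
    )
    labels.loc[sel.index] = cls
    out = records.copy()
    out["class"] = labels
    return out


def class_counts(classification: pd.DataFrame) -> dict[str, int]:
    """Counts per label plus the total number of depression-related genes
    (Class 1 + Class 2)."""
    counts = classification["class"].value_counts().to_dict()
    counts.setdefault(CLASS1, 0)
    counts.setdefault(CLASS2, 0)
    counts["depression_related"] = counts[CLASS1] + counts[CLASS2]
    return counts


def class_gene_sets(classification: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-id sets per class label."""
    return {
        label: set(classification.index[classification["class"] == label])
        for label in (CLASS1, CLASS2, UNCLASSIFIED, CONTROL)
    }
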