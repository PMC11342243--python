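"""Protein-interaction network construction and node topology.

Edges arrive as a scored list (STRING detailed-links dialect,
``combined_score`` on a 0-1000 scale); only high-confidence edges with
score strictly above the threshold (default 900) are kept.  Per node the
pipeline reports degree, unnormalized betweenness centrality (shortest-path
counts summed over unordered pairs) and the local clustering coefficient,
then compares gene classes metric by metric with two-sided t-tests.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import two_sample_t

METRICS = ("degree", "betweenness", "clustering")


def build_graph(edges: pd.DataFrame, threshold: int = 900) -> nx.Graph:
    """Thresholded, simple, undirected interaction graph.

    Duplicate edges (either orientation) collapse to one keeping the maximum
    score; self-loops are dropped; edges with score <= threshold are dropped.
    """
    required = {"protein_a", "protein_b", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns {sorted(missing)}")
    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    bad = scores.isna() | (scores < 0) | (scores > 1000)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based, after header
        raise ValueError(f"malformed combined_score at line {line}")
    g = nx.Graph()
    for a, b, s in zip(edges["protein_a"], edges["protein_b"], scores):
        if a == b or s <= threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], float(s))
        else:
            g.add_edge(a, b, combined_score=float(s))
    return g


def compute_topology(g: nx.Graph) -> pd.DataFrame:
    """Degree, unnormalized betweenness and clustering coefficient per node."""
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=list(METRICS)).rename_axis("gene_id")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g)
    out = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "clustering": pd.Series(clustering),
        }
    ).rename_axis("gene_id")
    return out.sort_index()


def compare_topology(
    records: pd.DataFrame,
    class_sets: dict[str, set[str]],
    include_missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided t-tests of each topology metric between classes.

    Genes absent from the thresholded graph are excluded by default (STRING
    coverage is partial; zero-filling would manufacture signal) but can be
    included as all-zero records by flag.
    """
    groups: dict[str, pd.DataFrame] = {}
    for label, genes in class_sets.items():
        present = sorted(set(genes) & set(records.index))
        sub = records.loc[present]
        if include_missing_as_zero:
            absent = sorted(set(genes) - set(records.index))
            zeros = pd.DataFrame(0.0, index=absent, columns=records.columns)
            sub = pd.concat([sub, zeros])
        if len(sub) < 2:
            raise ValueError(f"group {label!r} has <2 genes in the graph")
        groups[label] = sub
    labels = list(groups)
    rows = []
    for metric in METRICS:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                va = groups[a][metric].to_numpy(float)
                vb = groups[b][metric].to_numpy(float)
                t, p = two_sample_t(va[:, None], vb[:, None])
                rows.append(
                    {
                        "metric": metric,
                        "group_a": a,
                        "group_b": b,
                        "mean_a": va.mean(),
                        "mean_b": vb.mean(),
                        "t": float(t[0]),
                        "p": float(p[0]),
                    }
                )
    return pd.DataFrame(rows)
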