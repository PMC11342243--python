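"""Stage orchestration: run the whole analysis on disk-resident inputs.

Stages run in dependency order (simulate -> contrast -> associate/classify
-> genesets -> network -> specificity -> sexdiff); every stage reads and
writes the TSV/GMT/JSON formats of :mod:`braintx.io`, so each is also
independently runnable from the CLI.  A manifest records the configuration
and input checksums of each run.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import association, genesets, io, network, sexdiff, specificity
from .config import RunConfig
from .imaging import group_difference_map
from .simulate import (
    DE_TISSUES,
    default_effect_maps,
    gen_dev_expression,
    gen_expression_matrix,
    gen_imaging_cohort,
    gen_interaction_network,
    gen_reference_lists,
    gen_term_sets,
    make_ground_truth,
)
from .types import INDICES

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(config: RunConfig, outdir: str | Path) -> None:
    """Generate every pipeline input with known ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_ground_truth(
        n_genes=config.n_genes,
        n_class1=config.n_class1,
        n_class2=config.n_class2,
        hub_fraction=config.hub_fraction,
        seed=config.seed,
    )
    io.write_truth(truth, outdir / "truth.json")
    maps = default_effect_maps(config.n_sites, config.effect_amplitude, seed=config.seed)
    cohort = gen_imaging_cohort(
        config.n_sites, config.n_per_group, maps, noise_sd=config.noise_sd, seed=config.seed
    )
    for name, data in cohort.items():
        io.write_imaging(data, outdir / f"imaging_{name}.tsv")
    sites = list(cohort["ALFF"].values.columns)
    expr = gen_expression_matrix(
        config.n_genes, sites, truth, corr_strength=config.corr_strength, seed=config.seed
    )
    io.write_expression_matrix(expr, outdir / "expression.tsv")
    dev = gen_dev_expression(truth, n_per_cell=config.n_per_cell, seed=config.seed)
    io.write_dev_set(dev, outdir / "dev_expression.tsv")
    edges = gen_interaction_network(
        config.network_nodes, config.hub_fraction, truth, seed=config.seed
    )
    io.write_edges(edges, outdir / "edges.tsv")
    for name, genes in gen_reference_lists(truth, seed=config.seed).items():
        io.write_gene_list(genes, outdir / f"{name}.txt")
    io.write_gmt(gen_term_sets(truth, seed=config.seed), outdir / "terms.gmt")


def run_contrast(config: RunConfig, workdir: Path) -> dict:
    maps = {}
    for name in INDICES:
        data = io.read_imaging(workdir / f"imaging_{name}.tsv", index_name=name)
        dmap = group_difference_map(data, q=config.bh_q)
        io.write_difference_map(dmap, workdir / f"contrast_{name}.tsv")
        maps[name] = dmap
    return maps


def run_associate(config: RunConfig, workdir: Path) -> pd.DataFrame:
    expr = io.read_expression_matrix(workdir / "expression.tsv")
    maps = {
        name: io.read_difference_map(workdir / f"contrast_{name}.tsv", index_name=name)
        for name in INDICES
    }
    records, selected = association.identify_depression_genes(
        expr, maps, alpha=config.alpha_assoc, n_perm=config.n_perm, seed=config.seed
    )
    classification = association.classify_directional(records, selected, alpha=config.alpha_assoc)
    classification.to_csv(workdir / "classification.tsv", sep="\t", na_rep="NA")
    return classification


def _class_sets(workdir: Path) -> dict[str, set[str]]:
    cls = pd.read_csv(workdir / "classification.tsv", sep="\t", index_col=0)
    return {
        label: set(cls.index[cls["class"] == label])
        for label in (association.CLASS1, association.CLASS2, association.CONTROL)
    }


def run_genesets(config: RunConfig, workdir: Path) -> None:
    sets = _class_sets(workdir)
    rows = []
    for ref_name in ["risk"] + [f"de_down_{t}" for t in DE_TISSUES]:
        path = workdir / f"{ref_name}.txt"
        if not path.exists():
            continue
        reference = io.read_gene_list(path)
        table = genesets.overlap_table(sets, reference)
        table["reference"] = ref_name
        rows.append(table.reset_index())
    if rows:
        pd.concat(rows).to_csv(workdir / "overlap.tsv", sep="\t", index=False, na_rep="NA")
    gmt = workdir / "terms.gmt"
    if gmt.exists():
        terms = io.read_gmt(gmt)
        background = set().union(*sets.values())
        selected = sets[association.CLASS1] | sets[association.CLASS2]
        enr = genesets.hypergeometric_enrichment(
            selected, terms, background,
            alpha=config.enrich_alpha,
            min_count=config.enrich_min_count,
            min_factor=config.enrich_min_factor,
        )
        enr.to_csv(workdir / "enrichment.tsv", sep="\t", na_rep="NA")


def run_network(config: RunConfig, workdir: Path) -> None:
    edges = io.read_edges(workdir / "edges.tsv")
    g = network.build_graph(edges, threshold=config.string_threshold)
    records = network.compute_topology(g)
    records.to_csv(workdir / "topology.tsv", sep="\t", na_rep="NA")
    comparison = network.compare_topology(records, _class_sets(workdir))
    comparison.to_csv(workdir / "topology_comparison.tsv", sep="\t", index=False, na_rep="NA")


def run_specificity(config: RunConfig, workdir: Path) -> None:
    dev = io.read_dev_set(workdir / "dev_expression.tsv")
    sets = _class_sets(workdir)
    table, comparison = specificity.class_dpi_comparison(dev, sets)
    table.to_csv(workdir / "dpi.tsv", sep="\t", na_rep="NA")
    comparison.to_csv(workdir / "dpi_comparison.tsv", sep="\t", index=False, na_rep="NA")
    selected = sets[association.CLASS1] | sets[association.CLASS2]
    t_grid, p_grid = specificity.overexpression_grid(dev, selected, sets[association.CONTROL])
    io.write_grid(t_grid, workdir / "overexpression_t.tsv")
    io.write_grid(p_grid, workdir / "overexpression_p.tsv")


def run_sexdiff(config: RunConfig, workdir: Path) -> None:
    dev = io.read_dev_set(workdir / "dev_expression.tsv")
    sets = _class_sets(workdir)
    records = sexdiff.sex_de_genes(dev, alpha=config.sexdiff_alpha)
    records.to_csv(workdir / "sexdiff.tsv", sep="\t", na_rep="NA")
    pct = sexdiff.sex_bias_percentages(records, sets)
    pct.to_csv(workdir / "sexdiff_percentages.tsv", sep="\t", na_rep="NA")
    selected = sets[association.CLASS1] | sets[association.CLASS2]
    sexdiff_selected = set(records.index) & selected
    if sexdiff_selected:
        t_grid, p_grid = sexdiff.sex_overexpression_grid(
            dev, sexdiff_selected, sets[association.CONTROL]
        )
        io.write_grid(t_grid, workdir / "sex_overexpression_t.tsv")
        io.write_grid(p_grid, workdir / "sex_overexpression_p.tsv")


def write_manifest(config: RunConfig, workdir: Path) -> None:
    from . import __version__

    inputs = sorted(
        p for p in workdir.iterdir()
        if p.suffix in (".tsv", ".txt", ".gmt", ".json") and p.name != "manifest.json"
    )
    io.write_json(
        {
            "version": __version__,
            "config": config.to_dict(),
            "inputs": {p.name: _sha256(p) for p in inputs},
        },
        workdir / "manifest.json",
    )


def run_pipeline(config: RunConfig, workdir: str | Path, simulate: bool = False) -> None:
    """Execute all stages in dependency order; write a manifest at the end."""
    workdir = Path(workdir)
    if simulate:
        simulate_inputs(config, workdir)
    required = [f"imaging_{n}.tsv" for n in INDICES] + ["expression.tsv", "dev_expression.tsv", "edges.tsv"]
    missing = [f for f in required if not (workdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs in {workdir}: {missing}")
    run_contrast(config, workdir)
    run_associate(config, workdir)
    run_genesets(config, workdir)
    run_network(config, workdir)
    run_specificity(config, workdir)
    run_sexdiff(config, workdir)
    write_manifest(config, workdir)
    log.info("pipeline complete in %s", workdir)
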