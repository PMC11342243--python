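"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's real data
sources at desk scale: a two-group imaging cohort whose case-control effect
maps share one latent spatial pattern (functional indices shifted along the
pattern, grey matter density along its negative); an expression matrix whose
planted Class-1 / Class-2 genes mix a monotone transform of that pattern
into their site profiles with controlled Spearman strength; a developmental
expression set with region-specific, period-specific and sex-biased genes;
a scored interaction network whose planted depression genes sit on the
periphery; and reference gene lists (downregulated DE per tissue, GWAS risk
genes) with configured class overlap rates.

Defaults are a desk-scale configuration (200 sites, 2,000 genes, 150/200
planted class genes) echoing the proportions of the full-scale study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._stats import substream
from .types import (
    DEFAULT_PERIODS,
    DEFAULT_REGIONS,
    DevExpressionSet,
    ExpressionMatrix,
    FUNCTIONAL_INDICES,
    GroupImagingDataset,
    INDICES,
    STRUCTURAL_INDEX,
)

DE_TISSUES = ("hippocampus", "prefrontal_cortex", "striatum")


@dataclass
class GroundTruth:
    """Planted structure of one simulation, used to score recovery."""

    class1_genes: set[str] = field(default_factory=set)
    class2_genes: set[str] = field(default_factory=set)
    specific_genes: dict[str, tuple[str, str]] = field(default_factory=dict)  # gene -> (axis, level)
    sex_biased_genes: dict[str, str] = field(default_factory=dict)            # gene -> female|male
    hub_genes: set[str] = field(default_factory=set)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class1_genes & self.class2_genes:
            raise ValueError("Class 1 and Class 2 must be disjoint")
        if self.genes:
            universe = set(self.genes)
            planted = (
                self.class1_genes
                | self.class2_genes
                | set(self.specific_genes)
                | set(self.sex_biased_genes)
                | self.hub_genes
            )
            stray = planted - universe
            if stray:
                raise ValueError(f"planted genes outside the gene universe: {sorted(stray)[:5]}")

    @property
    def control_genes(self) -> set[str]:
        return set(self.genes) - self.class1_genes - self.class2_genes

    def to_json(self) -> str:
        d = asdict(self)
        d["class1_genes"] = sorted(self.class1_genes)
        d["class2_genes"] = sorted(self.class2_genes)
        d["hub_genes"] = sorted(self.hub_genes)
        d["specific_genes"] = {g: list(v) for g, v in self.specific_genes.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            class1_genes=set(d["class1_genes"]),
            class2_genes=set(d["class2_genes"]),
            specific_genes={g: (v[0], v[1]) for g, v in d["specific_genes"].items()},
            sex_biased_genes=dict(d["sex_biased_genes"]),
            hub_genes=set(d["hub_genes"]),
            effect_sizes=dict(d["effect_sizes"]),
            genes=list(d["genes"]),
        )


def make_ground_truth(
    n_genes: int = 2000,
    n_class1: int = 150,
    n_class2: int = 200,
    n_sex_class1: int = 8,
    n_sex_class2: int = 9,
    n_sex_control: int = 100,
    n_period_specific: int = 50,
    hub_fraction: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Gene universe plus planted class/specificity/sex/hub assignments.

    Class genes are region-specific by construction (the depression-related
    signature: expressed in few regions across many periods); a separate
    block of control genes is period-specific so temporal specificity is
    also exercised.  Class-1 sex-biased genes are female-high, Class-2 and
    control sex-biased genes alternate directions.
    """
    if n_class1 + n_class2 >= n_genes:
        raise ValueError("planted classes exceed the gene universe")
    rng = substream(seed, "truth")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    class1 = [genes[i] for i in order[:n_class1]]
    class2 = [genes[i] for i in order[n_class1:n_class1 + n_class2]]
    controls = [genes[i] for i in order[n_class1 + n_class2:]]

    specific: dict[str, tuple[str, str]] = {}
    for g in class1 + class2:
        specific[g] = ("region", DEFAULT_REGIONS[int(rng.integers(len(DEFAULT_REGIONS)))])
    for g in controls[:n_period_specific]:
        specific[g] = ("period", DEFAULT_PERIODS[int(rng.integers(len(DEFAULT_PERIODS)))])

    sex_biased: dict[str, str] = {}
    for g in class1[:n_sex_class1]:
        sex_biased[g] = "female"
    for i, g in enumerate(class2[:n_sex_class2]):
        sex_biased[g] = "female" if i % 2 == 0 else "male"
    for i, g in enumerate(controls[n_period_specific:n_period_specific + n_sex_control]):
        sex_biased[g] = "female" if i % 2 == 0 else "male"

    eligible_hubs = [g for g in controls if g not in sex_biased and g not in specific]
    n_hubs = max(1, int(round(hub_fraction * n_genes)))
    hubs = set(eligible_hubs[-n_hubs:])
    return GroundTruth(
        class1_genes=set(class1),
        class2_genes=set(class2),
        specific_genes=specific,
        sex_biased_genes=sex_biased,
        hub_genes=hubs,
        effect_sizes={},
        genes=genes,
    )


def latent_pattern(n_sites: int, seed: int) -> np.ndarray:
    """Latent per-site spatial pattern shared by all four effect maps."""
    rng = substream(seed, "latent")
    return rng.normal(size=n_sites)


def default_effect_maps(
    n_sites: int,
    amplitude: float = 0.5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-index case-minus-control mean shift vectors.

    Functional indices follow the latent pattern positively, GMD its
    negative (function up where grey-matter density is down), each with a
    small independent component so the functional maps are not identical.
    """
    b = latent_pattern(n_sites, seed)
    rng = substream(seed, "effect-maps")
    maps = {}
    for name in FUNCTIONAL_INDICES:
        maps[name] = amplitude * (b + 0.15 * rng.normal(size=n_sites))
    maps[STRUCTURAL_INDEX] = -amplitude * (b + 0.15 * rng.normal(size=n_sites))
    return maps


def gen_imaging_cohort(
    n_sites: int,
    n_per_group: int,
    effect_maps: dict[str, np.ndarray],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, GroupImagingDataset]:
    """Two-group cohort per index: cases shifted by the effect map, iid noise."""
    if n_sites < 2 or n_per_group < 2:
        raise ValueError("need >=2 sites and >=2 subjects per group")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    missing = set(INDICES) - set(effect_maps)
    if missing:
        raise ValueError(f"effect maps missing for indices: {sorted(missing)}")
    sites = [f"S{i:04d}" for i in range(n_sites)]
    subjects = [f"sub{i:04d}" for i in range(2 * n_per_group)]
    group = pd.Series(
        ["case"] * n_per_group + ["control"] * n_per_group,
        index=pd.Index(subjects, name="subject_id"),
        name="group",
    )
    out = {}
    for name in INDICES:
        shift = np.asarray(effect_maps[name], float)
        if shift.shape != (n_sites,):
            raise ValueError(f"effect map for {name} has wrong length")
        rng = substream(seed, f"imaging:{name}")
        values = rng.normal(scale=noise_sd, size=(2 * n_per_group, n_sites))
        values[:n_per_group] += shift
        out[name] = GroupImagingDataset(
            index_name=name,
            values=pd.DataFrame(values, index=group.index, columns=sites),
            group=group,
        )
    return out


def gen_expression_matrix(
    n_genes: int,
    sites: list[str],
    truth: GroundTruth,
    corr_strength: float = 0.8,
    seed: int = 0,
    coupling: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Site profiles with planted map correlations.

    Class-1 genes mix ``corr_strength`` of the (standardized) latent
    coupling pattern into their profile, Class-2 genes its negative, and
    all other genes are independent noise.  Spearman correlations with any
    map that is monotone in the pattern therefore carry the planted signs,
    with magnitude increasing in ``corr_strength``.
    """
    if not 0 < corr_strength < 1:
        raise ValueError("corr_strength must be strictly between 0 and 1")
    if len(sites) < 3:
        raise ValueError("need >=3 sites (correlation undefined otherwise)")
    if n_genes < len(truth.genes):
        raise ValueError("n_genes smaller than the ground-truth gene universe")
    genes = list(truth.genes) + [f"G{i:05d}" for i in range(len(truth.genes), n_genes)]
    n_sites = len(sites)
    if coupling is None:
        coupling = latent_pattern(n_sites, seed)
    coupling = np.asarray(coupling, float)
    if coupling.shape != (n_sites,):
        raise ValueError("coupling pattern length must equal the site count")
    zb = (coupling - coupling.mean()) / coupling.std()
    rng = substream(seed, "expression")
    noise = rng.normal(size=(len(genes), n_sites))
    sign = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in truth.class1_genes:
            sign[i] = 1.0
        elif g in truth.class2_genes:
            sign[i] = -1.0
    mix = np.sqrt(1.0 - corr_strength**2)
    values = np.where(
        sign[:, None] != 0,
        sign[:, None] * corr_strength * zb[None, :] + mix * noise,
        noise,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sites),
        normalized=False,
    )


def gen_dev_expression(
    truth: GroundTruth,
    periods: tuple[str, ...] = DEFAULT_PERIODS,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    n_per_cell: int = 4,
    baseline: float = 5.0,
    noise_sd: float = 1.0,
    specific_shift: float = 4.0,
    temporal_sd: float = 0.75,
    sex_shift: float = 1.0,
    seed: int = 0,
) -> DevExpressionSet:
    """Developmental expression with planted specificity and sex bias.

    Every non-planted gene carries a random period-to-period modulation
    (SD ``temporal_sd``) on top of the baseline — real genes are not flat
    in time — while region-specific planted genes are temporally flat and
    boosted by ``specific_shift`` in their target region across all
    periods.  Period-specific genes mirror this on the temporal axis.
    Sex-biased genes get a ``sex_shift`` mean increase in the labeled sex.
    Values are clamped at zero (specificity needs nonnegative profiles).
    """
    if len(periods) != 8:
        raise ValueError("expected 8 period labels")
    if len(regions) != 16:
        raise ValueError("expected 16 region labels")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = substream(seed, "dev-expression")
    genes = list(truth.genes)
    rows = []
    cell = 0
    for period in periods:
        for region in regions:
            for k in range(n_per_cell):
                # alternate within and across cells so both sexes appear in
                # every cell when n_per_cell >= 2 and overall even when not
                sex = "female" if (cell + k) % 2 == 0 else "male"
                rows.append((period, region, sex))
            cell += 1
    samples = pd.DataFrame(rows, columns=["period", "region", "sex"])
    samples.index = pd.Index([f"DS{i:04d}" for i in range(len(samples))], name="sample_id")

    planted = {g: truth.specific_genes.get(g) for g in genes}
    # per-gene per-period modulation; planted genes are flat in the axes
    # they are not planted on so their specificity is driven by the plant
    period_mod = rng.normal(scale=temporal_sd, size=(len(genes), len(periods)))
    for i, g in enumerate(genes):
        if planted[g] is not None:
            period_mod[i] = 0.0
    p_idx = {p: i for i, p in enumerate(periods)}
    r_idx = {r: i for i, r in enumerate(regions)}

    mean = np.full((len(samples), len(genes)), baseline)
    mean += period_mod[:, [p_idx[p] for p in samples["period"]]].T
    for i, g in enumerate(genes):
        plant = planted[g]
        if plant is not None:
            axis, level = plant
            col = "region" if axis == "region" else "period"
            mean[:, i] += np.where(samples[col] == level, specific_shift, 0.0)
        bias = truth.sex_biased_genes.get(g)
        if bias is not None:
            mean[:, i] += np.where(samples["sex"] == bias, sex_shift, 0.0)
    values = np.clip(mean + rng.normal(scale=noise_sd, size=mean.shape), 0.0, None)
    expression = pd.DataFrame(values, index=samples.index, columns=genes)
    return DevExpressionSet(
        samples=samples, expression=expression, periods=tuple(periods), regions=tuple(regions)
    )


def gen_interaction_network(
    n_nodes: int,
    hub_fraction: float = 0.05,
    truth: GroundTruth | None = None,
    seed: int = 0,
    mean_degree: float = 12.0,
) -> pd.DataFrame:
    """Scored edge list with hubs and peripheral planted Class-1 genes.

    Endpoints are drawn proportionally to per-node attachment weights
    (hubs 20, Class-1 genes 0.3, others 1), so Class-1 gene products
    interact with few other proteins.  ``combined_score`` is uniform on
    [700, 1000]; roughly a third of the edges survive the >900 filter.
    """
    if n_nodes < 2:
        raise ValueError("need >=2 nodes")
    if not 0 < hub_fraction < 1:
        raise ValueError("hub_fraction must be in (0, 1)")
    truth = truth or GroundTruth()
    rng = substream(seed, "network")
    if truth.genes:
        nodes = list(truth.genes)[:n_nodes]
    else:
        nodes = [f"G{i:05d}" for i in range(n_nodes)]
    weights = np.ones(len(nodes))
    n_hubs = max(1, int(round(hub_fraction * len(nodes))))
    hub_set = set(truth.hub_genes) & set(nodes)
    if not hub_set:
        hub_set = set(nodes[-n_hubs:]) - truth.class1_genes
    for i, g in enumerate(nodes):
        if g in hub_set:
            weights[i] = 20.0
        elif g in truth.class1_genes:
            weights[i] = 0.3
    prob = weights / weights.sum()
    n_edges = int(mean_degree * len(nodes) / 2)
    a = rng.choice(len(nodes), size=3 * n_edges, p=prob)
    b = rng.choice(len(nodes), size=3 * n_edges, p=prob)
    keep = a != b
    pairs = set()
    rows = []
    scores = rng.integers(700, 1001, size=keep.sum())
    for (i, j), s in zip(zip(a[keep], b[keep]), scores):
        key = (min(i, j), max(i, j))
        if key in pairs:
            continue
        pairs.add(key)
        rows.append((nodes[key[0]], nodes[key[1]], int(s)))
        if len(rows) >= n_edges:
            break
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])


def gen_reference_lists(
    truth: GroundTruth,
    overlap_rates: dict[str, float] | None = None,
    list_size: int = 260,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Risk-gene list and per-tissue downregulated DE lists.

    Each class gene enters a list independently with its class's overlap
    rate; the list is then padded with genes from outside the universe so
    its size does not betray the plant.  Keys: ``risk`` plus one
    ``de_down_<tissue>`` per post-mortem tissue.
    """
    rates = overlap_rates or {"class1": 0.2, "class2": 0.1, "control": 0.05}
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"overlap rate for {k!r} outside [0, 1]")
    rng = substream(seed, "reference-lists")
    pools = {
        "class1": sorted(truth.class1_genes),
        "class2": sorted(truth.class2_genes),
        "control": sorted(truth.control_genes),
    }
    out: dict[str, set[str]] = {}
    for li, name in enumerate(["risk"] + [f"de_down_{t}" for t in DE_TISSUES]):
        chosen: set[str] = set()
        for key, pool in pools.items():
            take = rng.random(len(pool)) < rates[key]
            chosen |= {g for g, t in zip(pool, take) if t}
        pad = max(0, list_size - len(chosen))
        chosen |= {f"X{li}_{i:05d}" for i in range(pad)}
        out[name] = chosen
    return out


def gen_term_sets(
    truth: GroundTruth,
    n_terms: int = 30,
    term_size: int = 40,
    enriched_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic annotation term -> gene sets (GMT content) for enrichment.

    Half the terms oversample Class-1 or Class-2 genes; the rest are drawn
    uniformly from the universe.
    """
    rng = substream(seed, "terms")
    genes = np.array(truth.genes)
    out: dict[str, set[str]] = {}
    class_pools = [sorted(truth.class1_genes), sorted(truth.class2_genes)]
    for i in range(n_terms):
        if i < int(enriched_fraction * n_terms) and class_pools[i % 2]:
            pool = class_pools[i % 2]
            n_from_class = min(len(pool), term_size // 2)
            part = list(rng.choice(pool, size=n_from_class, replace=False))
            rest = list(rng.choice(genes, size=term_size - n_from_class, replace=False))
            out[f"TERM{i:03d}"] = set(part) | set(rest)
        else:
            out[f"TERM{i:03d}"] = set(rng.choice(genes, size=term_size, replace=False))
    return out
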