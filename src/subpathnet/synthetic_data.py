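"""Synthetic pathway topologies and case/control expression datasets.

The generator emulates the study design the pipeline expects — one
cancer-like dataset compared against two AD-like datasets over a shared gene
universe — with known ground truth:

* random signed pathway graphs (configurable edge density and inhibition
  fraction) with *planted chains* embedded verbatim;
* per-sample log-normal expression for case and control arms; the per-gene
  fold-change is the ratio of geometric means, so samples-per-arm and noise
  act exactly as they would on real ratio tables;
* planted chain genes receive coherent directions that make their chains
  fully sign-consistent in the designated datasets;
* a configurable set of genes planted in *opposite* directions between the
  cancer-like and both AD-like datasets (the direction-opposed common genes
  the comparison stage looks for).

Everything is reproducible from ``SyntheticConfig.seed``; the truth record
lists the planted chains and opposite-direction genes so recovery can be
checked end to end.

Default planted chains span 6–8 genes: under the sign-based null a fully
consistent chain of ``e`` edges has P = 2^-e, so 5 edges (6 genes) is the
shortest chain that can fall below the 0.05 significance filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from xml.sax.saxutils import quoteattr

import numpy as np

from .errors import ConfigError
from .pathway_io import (
    ACTIVATION,
    INHIBITION,
    ExpressionDataset,
    SignedPathwayGraph,
    Subpathway,
)

CANCER_ID = "SIMCRC"
AD1_ID = "SIMAD1"
AD2_ID = "SIMAD2"
DATASET_IDS = (CANCER_ID, AD1_ID, AD2_ID)


@dataclass(frozen=True)
class PlantedChain:
    """A chain of ``length`` genes embedded in pathway ``pathway_index`` and
    made sign-consistent in each dataset of ``dataset_ids``."""

    pathway_index: int
    length: int
    dataset_ids: tuple[str, ...]


def _default_chains() -> list[PlantedChain]:
    return [
        PlantedChain(0, 6, (CANCER_ID,)),
        PlantedChain(1, 7, (CANCER_ID,)),
        PlantedChain(2, 8, (CANCER_ID,)),
        PlantedChain(0, 6, (AD1_ID, AD2_ID)),
        PlantedChain(1, 7, (AD1_ID, AD2_ID)),
        PlantedChain(3, 8, (AD1_ID, AD2_ID)),
    ]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic benchmark.

    ``effect_size`` is the mean |log2 fold-change| of planted genes;
    ``noise_sd`` the standard deviation of per-sample log2 expression noise.
    ``n_opposite_genes`` genes are split between up-in-cancer/down-in-AD and
    the mirror.
    """

    n_genes: int = 600
    n_pathways: int = 4
    pathway_size_range: tuple[int, int] = (25, 40)
    edge_density: float = 0.05
    inhibition_fraction: float = 0.25
    planted_chains: list[PlantedChain] = field(default_factory=_default_chains)
    effect_size: float = 1.0
    noise_sd: float = 0.25
    n_opposite_genes: int = 16
    samples_per_arm: int = 10
    seed: int = 4107

    def __post_init__(self):
        # Accept YAML-friendly planted-chain forms: dicts or [pathway, length, ids].
        coerced = []
        for chain in self.planted_chains:
            if isinstance(chain, PlantedChain):
                coerced.append(chain)
            elif isinstance(chain, dict):
                coerced.append(
                    PlantedChain(
                        int(chain["pathway_index"]), int(chain["length"]),
                        tuple(chain["dataset_ids"]),
                    )
                )
            else:
                pathway_index, length, dataset_ids = chain
                coerced.append(
                    PlantedChain(int(pathway_index), int(length), tuple(dataset_ids))
                )
        self.planted_chains = coerced
        self.pathway_size_range = tuple(self.pathway_size_range)
        if min(self.n_genes, self.n_pathways, self.samples_per_arm) < 1:
            raise ConfigError("n_genes, n_pathways and samples_per_arm must be >= 1")
        lo, hi = self.pathway_size_range
        if not 2 <= lo <= hi <= self.n_genes:
            raise ConfigError(
                f"pathway_size_range {self.pathway_size_range} must satisfy "
                f"2 <= lo <= hi <= n_genes"
            )
        for p in (self.edge_density, self.inhibition_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ConfigError("effect_size and noise_sd must be >= 0")
        if self.n_opposite_genes < 0:
            raise ConfigError("n_opposite_genes must be >= 0")
        for chain in self.planted_chains:
            if chain.length < 2:
                raise ConfigError("planted chain length must be >= 2")
            if not 0 <= chain.pathway_index < self.n_pathways:
                raise ConfigError(
                    f"planted chain pathway_index {chain.pathway_index} "
                    f"outside [0, {self.n_pathways})"
                )
            unknown = set(chain.dataset_ids) - set(DATASET_IDS)
            if unknown:
                raise ConfigError(f"unknown dataset id(s) {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated benchmark."""

    planted_chains: list[tuple[Subpathway, tuple[str, ...]]]
    opposite_up_in_cancer: frozenset[str]
    opposite_down_in_cancer: frozenset[str]
    #: dataset id -> gene -> planted direction (+1 up, -1 down)
    directions: dict[str, dict[str, int]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_chains": [
                    {
                        "pathway_id": sub.pathway_id,
                        "nodes": list(sub.nodes),
                        "signs": list(sub.signs),
                        "dataset_ids": list(ids),
                    }
                    for sub, ids in self.planted_chains
                ],
                "opposite_up_in_cancer": sorted(self.opposite_up_in_cancer),
                "opposite_down_in_cancer": sorted(self.opposite_down_in_cancer),
                "directions": {
                    ds: dict(sorted(d.items())) for ds, d in self.directions.items()
                },
            },
            indent=2,
        )


def _gene_universe(config: SyntheticConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


@dataclass
class _Layout:
    pathway_genes: list[list[str]]
    chains: list[tuple[Subpathway, tuple[str, ...]]]
    opposite_up: list[str]
    opposite_down: list[str]


def _layout(config: SyntheticConfig) -> _Layout:
    """Deterministic placement of pathway gene sets, planted chains and
    opposite-direction genes (shared by pathway and dataset generation)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    universe = _gene_universe(config)
    lo, hi = config.pathway_size_range
    pathway_genes: list[list[str]] = []
    for _ in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pathway_genes.append(sorted(rng.choice(universe, size, replace=False)))

    used: set[str] = set()
    chains: list[tuple[Subpathway, tuple[str, ...]]] = []
    for chain in config.planted_chains:
        pool = [g for g in pathway_genes[chain.pathway_index] if g not in used]
        if chain.length > len(pool):
            raise ConfigError(
                f"planted chain of {chain.length} genes does not fit pathway "
                f"{chain.pathway_index} ({len(pool)} unused genes)"
            )
        nodes = tuple(rng.choice(pool, chain.length, replace=False))
        used.update(nodes)
        signs = tuple(
            INHIBITION if rng.random() < config.inhibition_fraction else ACTIVATION
            for _ in range(chain.length - 1)
        )
        pathway_id = f"syn{chain.pathway_index + 1:05d}"
        chains.append((Subpathway(pathway_id, nodes, signs), chain.dataset_ids))

    free = [g for g in universe if g not in used]
    if config.n_opposite_genes > len(free):
        raise ConfigError(
            f"n_opposite_genes {config.n_opposite_genes} exceeds the "
            f"{len(free)} genes left outside planted chains"
        )
    opposite = list(rng.choice(free, config.n_opposite_genes, replace=False))
    half = config.n_opposite_genes // 2
    return _Layout(pathway_genes, chains, opposite[:half], opposite[half:])


def generate_pathways(config: SyntheticConfig) -> list[SignedPathwayGraph]:
    """Random signed digraphs with the planted chains embedded verbatim."""
    layout = _layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    graphs = []
    for i, genes in enumerate(layout.pathway_genes):
        pathway_id = f"syn{i + 1:05d}"
        pair_sign: dict[tuple[str, str], int] = {}
        n = len(genes)
        draw = rng.random((n, n))
        signs = rng.random((n, n))
        for a in range(n):
            for b in range(n):
                if a != b and draw[a, b] < config.edge_density:
                    sign = (
                        INHIBITION
                        if signs[a, b] < config.inhibition_fraction
                        else ACTIVATION
                    )
                    pair_sign[(genes[a], genes[b])] = sign
        for sub, _ in layout.chains:
            if sub.pathway_id != pathway_id:
                continue
            for u, v, s in sub.edges():
                pair_sign[(u, v)] = s  # planted edges override random ones
                pair_sign.pop((v, u), None)  # keep the chain cleanly recoverable
        edges = {(u, v, s) for (u, v), s in pair_sign.items()}
        graphs.append(
            SignedPathwayGraph(pathway_id, f"Synthetic pathway {i + 1}", set(genes), edges)
        )
    return graphs


def _planted_directions(config: SyntheticConfig, layout: _Layout, rng) -> dict[str, dict[str, int]]:
    directions: dict[str, dict[str, int]] = {ds: {} for ds in DATASET_IDS}
    for sub, dataset_ids in layout.chains:
        head = int(rng.choice((1, -1)))
        node_dirs = [head]
        for s in sub.signs:
            node_dirs.append(node_dirs[-1] * s)
        for ds in dataset_ids:
            for gene, d in zip(sub.nodes, node_dirs):
                directions[ds][gene] = d
    for gene in layout.opposite_up:
        directions[CANCER_ID][gene] = 1
        directions[AD1_ID][gene] = -1
        directions[AD2_ID][gene] = -1
    for gene in layout.opposite_down:
        directions[CANCER_ID][gene] = -1
        directions[AD1_ID][gene] = 1
        directions[AD2_ID][gene] = 1
    return directions


def generate_datasets(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset, SyntheticTruth]:
    """Generate the cancer-like dataset, the two AD-like datasets and the truth.

    Per gene and arm, ``samples_per_arm`` log2-expression samples are drawn
    from N(planted log2 effect, ``noise_sd``) (cases) and N(0, ``noise_sd``)
    (controls); the fold-change is the ratio of geometric means, i.e.
    ``2**(mean(case) - mean(control))``. Unplanted genes have median
    fold-change 1.
    """
    layout = _layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    directions = _planted_directions(config, layout, rng)
    universe = _gene_universe(config)
    labels = {CANCER_ID: "cancer-like", AD1_ID: "AD-like", AD2_ID: "AD-like"}
    datasets = []
    n = config.samples_per_arm
    for ds_id in DATASET_IDS:
        mu = np.array(
            [config.effect_size * directions[ds_id].get(g, 0) for g in universe]
        )
        case = rng.normal(0.0, 1.0, (len(universe), n)) * config.noise_sd + mu[:, None]
        control = rng.normal(0.0, 1.0, (len(universe), n)) * config.noise_sd
        log2fc = case.mean(axis=1) - control.mean(axis=1)
        fcs = {g: float(2.0 ** v) for g, v in zip(universe, log2fc)}
        datasets.append(ExpressionDataset(ds_id, labels[ds_id], fcs))
    truth = SyntheticTruth(
        planted_chains=layout.chains,
        opposite_up_in_cancer=frozenset(layout.opposite_up),
        opposite_down_in_cancer=frozenset(layout.opposite_down),
        directions=directions,
    )
    return datasets[0], datasets[1], datasets[2], truth


def generate_benchmark(config: SyntheticConfig):
    """Convenience bundle: ``(pathways, [cancer, ad1, ad2], truth)``."""
    pathways = generate_pathways(config)
    cancer, ad1, ad2, truth = generate_datasets(config)
    return pathways, [cancer, ad1, ad2], truth


def generate_annotation(
    config: SyntheticConfig, n_categories: int = 5, category_size: int = 20
) -> dict[str, set[str]]:
    """Category→gene sets over the synthetic universe, GMT-shaped.

    Each category mixes a few planted opposite-direction genes with random
    universe genes, so the category table and the over-representation stage
    have real signal to find. Categories may overlap (as real functional
    ontologies do).
    """
    layout = _layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    opposite = sorted(layout.opposite_up + layout.opposite_down)
    universe = _gene_universe(config)
    categories: dict[str, set[str]] = {}
    for i in range(n_categories):
        genes: set[str] = set()
        if opposite:
            n_opp = min(4, len(opposite))
            genes |= set(rng.choice(opposite, n_opp, replace=False))
        filler = max(category_size - len(genes), 0)
        genes |= set(rng.choice(universe, filler, replace=False))
        categories[f"Synthetic term {i + 1:02d}"] = genes
    return categories


def null_chain_type1_rate(
    n_chains: int = 1000,
    chain_nodes: int = 6,
    universe_size: int = 500,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 1297,
) -> float:
    """Empirical type-I error of the permutation test on null chains.

    Draws one universe of i.i.d. log-normal fold-changes, then ``n_chains``
    random chains (random genes, random edge signs) carrying no signal, and
    returns the fraction whose permutation P falls below ``alpha``.

    The consistency statistic is discrete: a fully consistent chain of ``e``
    edges has tail probability 2^-e, so chains need at least 5 edges
    (6 nodes) before rejection at 0.05 is possible at all; the default
    therefore exercises the shortest chain length with a non-trivial
    rejection region, where the attainable level is 2^-5 ≈ 0.031.
    """
    from .subpathway_stats import permutation_pvalue

    rng = np.random.default_rng(seed)
    seed_seq = np.random.SeedSequence(seed)
    width = max(4, len(str(universe_size)))
    fcs = {
        f"N{i:0{width}d}": float(np.exp(v))
        for i, v in enumerate(rng.normal(0.0, 1.0, universe_size))
    }
    data = ExpressionDataset("NULL", "other", fcs)
    genes = sorted(fcs)
    rejections = 0
    for _ in range(n_chains):
        nodes = tuple(rng.choice(genes, chain_nodes, replace=False))
        signs = tuple(
            int(s) for s in rng.choice((ACTIVATION, INHIBITION), chain_nodes - 1)
        )
        sub = Subpathway("null", nodes, signs)
        p = permutation_pvalue(sub, data, n_perm=n_perm, seed=seed_seq.spawn(1)[0])
        rejections += p < alpha
    return rejections / n_chains


def generate_kgml_fixture(graph: SignedPathwayGraph, path) -> None:
    """Serialize a graph as minimal KGML whose read round trip is exact."""
    gene_ids = {g: str(i + 1) for i, g in enumerate(sorted(graph.nodes))}
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<pathway name={quoteattr("path:" + graph.pathway_id)} '
        f'title={quoteattr(graph.pathway_name or graph.pathway_id)} org="syn">',
    ]
    for gene, eid in gene_ids.items():
        lines.append(
            f'  <entry id="{eid}" name={quoteattr("syn:" + gene)} type="gene">'
        )
        lines.append(f'    <graphics name={quoteattr(gene)} type="rectangle"/>')
        lines.append("  </entry>")
    for u, v, s in sorted(graph.edges):
        name, value = (
            ("activation", "--&gt;") if s == ACTIVATION else ("inhibition", "--|")
        )
        lines.append(
            f'  <relation entry1="{gene_ids[u]}" entry2="{gene_ids[v]}" type="PPrel">'
        )
        lines.append(f'    <subtype name="{name}" value="{value}"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
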