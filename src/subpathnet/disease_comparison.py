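"""Cross-disease comparison: direction-opposed common genes and their usage.

Two phenotypically opposite diseases (here: a cancer-like dataset versus
Alzheimer's-like datasets) are compared through the genes measured in every
dataset that move in *opposite* directions: up in the cancer-like dataset and
down in every AD-like dataset, or the mirror. Those genes are then laid out
two ways:

* against a category→gene-set annotation (e.g. inflammation-related
  functional terms) — which categories the opposed genes fall in;
* against the per-dataset disease networks — which pathways each opposed
  gene participates in within each network, alongside its direction in each
  dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .network_builder import DiseaseNetwork
from .pathway_io import ExpressionDataset
from .subpathway_stats import direction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectionalComparison:
    """The two disjoint opposite-direction common-gene sets.

    ``crc_up_ad_down``: up in the cancer-like dataset and down in every
    AD-like dataset. ``crc_down_ad_up``: the mirror. Every member is
    measured in all input datasets.
    """

    crc_up_ad_down: frozenset[str]
    crc_down_ad_up: frozenset[str]
    up_cutoff: float = 1.0
    down_cutoff: float = 1.0

    def __post_init__(self):
        if self.crc_up_ad_down & self.crc_down_ad_up:
            raise ValueError("the two opposite-direction sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.crc_up_ad_down | self.crc_down_ad_up


@dataclass(frozen=True)
class CategoryAnnotation:
    """Named gene-set categories (symbols upper-cased, sets non-empty)."""

    categories: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        folded = {}
        for name, genes in self.categories.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"category {name!r} has an empty gene set")
            folded[name] = genes
        object.__setattr__(self, "categories", folded)

    @classmethod
    def from_gmt(cls, mapping: dict) -> "CategoryAnnotation":
        return cls({name: frozenset(genes) for name, genes in mapping.items()})

    @property
    def all_genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for genes in self.categories.values():
            out |= genes
        return out


def classify_directions(
    data: ExpressionDataset, up_cutoff: float = 1.0, down_cutoff: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split a dataset's genes into up (> ``up_cutoff``) and down (< ``down_cutoff``).

    Defaults (both 1.0) count any deviation from no-change; genes at exactly
    1.0 — or between the cutoffs — stay unclassified.
    """
    if not down_cutoff <= 1.0 <= up_cutoff:
        raise ValueError(
            f"need down_cutoff <= 1 <= up_cutoff, got {down_cutoff} / {up_cutoff}"
        )
    up = {g for g, fc in data.fold_changes.items() if fc > up_cutoff}
    down = {g for g, fc in data.fold_changes.items() if fc < down_cutoff}
    return up, down


def opposite_common_genes(
    cancer: ExpressionDataset,
    ad_list: list[ExpressionDataset],
    up_cutoff: float = 1.0,
    down_cutoff: float = 1.0,
) -> DirectionalComparison:
    """Genes moving oppositely between the cancer-like and every AD-like dataset.

    A gene qualifies only if it is measured in *all* datasets, and its
    direction in the cancer-like dataset is opposed unanimously by every
    AD-like dataset.
    """
    if not ad_list:
        raise ValueError("need at least one AD-like dataset")
    cancer_up, cancer_down = classify_directions(cancer, up_cutoff, down_cutoff)
    common = set(cancer.genes)
    for ds in ad_list:
        common &= ds.genes
    up_ad_down = cancer_up & common
    down_ad_up = cancer_down & common
    for ds in ad_list:
        ad_up, ad_down = classify_directions(ds, up_cutoff, down_cutoff)
        up_ad_down &= ad_down
        down_ad_up &= ad_up
    logger.info(
        "%d genes up in %s & down in all AD-like; %d the mirror (of %d common)",
        len(up_ad_down), cancer.dataset_id, len(down_ad_up), len(common),
    )
    return DirectionalComparison(
        frozenset(up_ad_down), frozenset(down_ad_up), up_cutoff, down_cutoff
    )


def assign_categories(
    comparison: DirectionalComparison, annotation: CategoryAnnotation
) -> tuple[dict[str, tuple[tuple[str, ...], tuple[str, ...]]], int]:
    """Lay the opposed genes out by annotation category.

    Returns ``(table, distinct_gene_count)`` where ``table`` maps each
    category name to a pair of sorted gene tuples:
    (down-in-AD/up-in-cancer members, up-in-AD/down-in-cancer members).
    A gene may appear under several categories; ``distinct_gene_count``
    deduplicates across the whole table.
    """
    table: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    assigned: set[str] = set()
    for name in sorted(annotation.categories):
        genes = annotation.categories[name]
        up_crc = tuple(sorted(comparison.crc_up_ad_down & genes))
        down_crc = tuple(sorted(comparison.crc_down_ad_up & genes))
        if up_crc or down_crc:
            table[name] = (up_crc, down_crc)
            assigned.update(up_crc, down_crc)
    return table, len(assigned)


def gene_pathway_usage(
    genes: set[str],
    networks: list[DiseaseNetwork],
    datasets: list[ExpressionDataset],
) -> pd.DataFrame:
    """Cross-tabulate genes against network pathway membership and directions.

    One row per gene: for each network, the semicolon-joined sorted KEGG
    pathway ids of member subpathways containing the gene; for each dataset,
    the gene's direction (``Up``/``Down``/``Neutral``, or ``NA`` when
    unmeasured). Genes found in no network are kept, with empty pathway
    columns and a warning.
    """
    rows = []
    for gene in sorted(g.upper() for g in genes):
        row: dict[str, str] = {"gene": gene}
        hit_any = False
        for net in networks:
            ids = net.pathways_containing(gene)
            hit_any = hit_any or bool(ids)
            row[f"pathways_{net.dataset_id}"] = ";".join(sorted(ids))
        for ds in datasets:
            if gene in ds.fold_changes:
                row[f"direction_{ds.dataset_id}"] = direction(
                    ds.fold_changes[gene]
                ).capitalize()
            else:
                row[f"direction_{ds.dataset_id}"] = "NA"
        if not hit_any:
            logger.warning("gene %s appears in no network", gene)
        rows.append(row)
    columns = ["gene"]
    columns += [f"pathways_{n.dataset_id}" for n in networks]
    columns += [f"direction_{d.dataset_id}" for d in datasets]
    return pd.DataFrame(rows, columns=columns)
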