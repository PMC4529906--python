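"""Readers, writers and core containers for signed pathway analysis.

The module owns the three domain containers the rest of the package operates
on — :class:`SignedPathwayGraph`, :class:`Subpathway` and
:class:`ExpressionDataset` — together with the file dialects they travel in:

* KGML (KEGG Markup Language) pathway topologies, read into signed directed
  graphs where ``+1`` marks activation and ``-1`` inhibition;
* two-column TSV fold-change tables (gene symbol, case-over-control ratio);
* GMT category→gene-set annotation files;
* SIF / GraphML network exports;
* the linear-chain report notation ``"B (fc) <- A (fc)"`` (A activates B) and
  ``"B (fc) |- A (fc)"`` (A represses B), printed most-downstream gene first.

All readers accept gzip-compressed files (by ``.gz`` suffix). Gene symbols are
upper-cased on load everywhere, and matching between datasets, pathways and
annotations is by exact symbol.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from lxml import etree

from .errors import (
    EdgeConflictError,
    KgmlParseError,
    NotationParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ACTIVATION = 1
INHIBITION = -1

#: KGML relation subtypes carrying a sign usable by the consistency statistic.
KGML_SUBTYPE_SIGNS: Mapping[str, int] = {
    "activation": ACTIVATION,
    "expression": ACTIVATION,
    "inhibition": INHIBITION,
    "repression": INHIBITION,
}

_SIGN_WORD = {ACTIVATION: "activates", INHIBITION: "represses"}
_WORD_SIGN = {w: s for s, w in _SIGN_WORD.items()}


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding=None if "b" in mode else "utf-8")
    return open(path, mode, encoding=None if "b" in mode else "utf-8")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class SignedPathwayGraph:
    """A directed graph of gene symbols with signed (±1) edges.

    Parameters
    ----------
    pathway_id
        KEGG-style identifier, e.g. ``"hsa04310"``.
    pathway_name
        Free-text pathway title.
    nodes
        Gene symbols (upper case).
    edges
        ``(source, target, sign)`` triples with ``sign`` in ``{+1, -1}``.
        An ordered gene pair may carry at most one sign; self-loops are
        rejected.
    """

    pathway_id: str
    pathway_name: str = ""
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, int]] = field(default_factory=set)

    def __post_init__(self):
        self.nodes = {str(n).upper() for n in self.nodes}
        self.edges = {(str(u).upper(), str(v).upper(), int(s)) for u, v, s in self.edges}
        seen: dict[tuple[str, str], int] = {}
        for u, v, s in sorted(self.edges):
            if s not in (ACTIVATION, INHIBITION):
                raise ValidationError(f"edge ({u}, {v}) has sign {s}; expected +1 or -1")
            if u == v:
                raise ValidationError(f"self-loop on {u} is not allowed")
            if seen.setdefault((u, v), s) != s:
                raise EdgeConflictError(
                    f"conflicting signs on ordered gene pair ({u}, {v})"
                )
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"edge endpoint missing from nodes: ({u}, {v})")

    def to_networkx(self) -> nx.DiGraph:
        """Return the graph as a :class:`networkx.DiGraph` with ``sign`` edge data."""
        g = nx.DiGraph(pathway_id=self.pathway_id, pathway_name=self.pathway_name)
        g.add_nodes_from(sorted(self.nodes))
        for u, v, s in sorted(self.edges):
            g.add_edge(u, v, sign=s)
        return g


@dataclass(frozen=True)
class Subpathway:
    """An ordered, repeat-free chain of genes with an edge-sign sequence.

    ``nodes`` runs from the most-upstream gene to the most-downstream gene;
    ``signs[i]`` is the sign of the edge ``nodes[i] -> nodes[i+1]``.
    """

    pathway_id: str
    nodes: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(str(n).upper() for n in self.nodes))
        object.__setattr__(self, "signs", tuple(int(s) for s in self.signs))
        if len(self.nodes) < 2:
            raise ValidationError("a subpathway needs at least 2 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            dup = sorted({n for n in self.nodes if self.nodes.count(n) > 1})
            raise ValidationError(f"repeated gene(s) in chain: {', '.join(dup)}")
        if len(self.signs) != len(self.nodes) - 1:
            raise ValidationError(
                f"{len(self.nodes)} nodes require {len(self.nodes) - 1} signs, "
                f"got {len(self.signs)}"
            )
        if any(s not in (ACTIVATION, INHIBITION) for s in self.signs):
            raise ValidationError("edge signs must be +1 or -1")

    @property
    def n_edges(self) -> int:
        return len(self.signs)

    def edges(self) -> list[tuple[str, str, int]]:
        return [
            (self.nodes[i], self.nodes[i + 1], self.signs[i])
            for i in range(self.n_edges)
        ]


@dataclass
class ExpressionDataset:
    """A dataset's per-gene fold-changes (case over control, ratio scale).

    ``disease_label`` is one of ``"cancer-like"``, ``"AD-like"``, ``"other"``.
    Fold-changes must be strictly positive; symbols are upper-cased and must
    be unique after case-folding.
    """

    dataset_id: str
    disease_label: str = "other"
    fold_changes: dict[str, float] = field(default_factory=dict)

    _LABELS = ("cancer-like", "AD-like", "other")

    def __post_init__(self):
        if self.disease_label not in self._LABELS:
            raise ValidationError(
                f"disease_label must be one of {self._LABELS}, got {self.disease_label!r}"
            )
        folded: dict[str, float] = {}
        dups = []
        for gene, fc in self.fold_changes.items():
            sym = str(gene).upper()
            fc = float(fc)
            if fc <= 0:
                raise ValidationError(
                    f"fold-change for {sym} must be > 0, got {fc}"
                )
            if sym in folded:
                dups.append(sym)
            folded[sym] = fc
        if dups:
            raise ValidationError(
                f"duplicate gene symbol(s) in {self.dataset_id}: {', '.join(sorted(set(dups)))}"
            )
        self.fold_changes = folded

    @property
    def genes(self) -> set[str]:
        return set(self.fold_changes)

    def __len__(self) -> int:
        return len(self.fold_changes)


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------


def read_kgml(path) -> SignedPathwayGraph:
    """Read a KGML pathway file into a :class:`SignedPathwayGraph`.

    Only gene-type entries become nodes; an entry listing several gene symbols
    is split into one node per symbol, each inheriting all of the entry's
    relations. Relation subtypes ``activation``/``expression`` map to ``+1``
    and ``inhibition``/``repression`` to ``-1``; any other subtype (binding,
    indirect effect, ...) is dropped with a warning, as are map/compound
    entries and self-loops.

    Raises
    ------
    KgmlParseError
        If the XML is malformed (the message names the byte offset).
    EdgeConflictError
        If the same ordered gene pair ends up with both signs.
    """
    with _open_text(path, "rb") as fh:
        raw = fh.read()
    try:
        root = etree.fromstring(raw)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        offset = _byte_offset(raw, line, col)
        raise KgmlParseError(
            f"malformed KGML in {path}: {exc.msg} at byte offset {offset}"
        ) from exc

    pathway_id = (root.get("name") or "").replace("path:", "") or "unknown"
    pathway_name = root.get("title") or ""

    entry_genes: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        etype = entry.get("type", "")
        if etype != "gene":
            if etype not in ("gene", "group"):
                logger.debug("dropping %s-type entry %s", etype, entry.get("id"))
            continue
        genes = _entry_gene_symbols(entry)
        if genes:
            entry_genes[entry.get("id")] = genes

    nodes: set[str] = {g for genes in entry_genes.values() for g in genes}
    pair_sign: dict[tuple[str, str], int] = {}
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in entry_genes or e2 not in entry_genes:
            continue
        signs = set()
        for sub in rel.iter("subtype"):
            name = (sub.get("name") or "").lower()
            if name in KGML_SUBTYPE_SIGNS:
                signs.add(KGML_SUBTYPE_SIGNS[name])
            else:
                logger.warning(
                    "dropping relation subtype %r (%s -> %s) in %s",
                    name, e1, e2, pathway_id,
                )
        if len(signs) > 1:
            raise EdgeConflictError(
                f"relation {e1} -> {e2} in {pathway_id} carries both signs"
            )
        if not signs:
            continue
        sign = signs.pop()
        for u in entry_genes[e1]:
            for v in entry_genes[e2]:
                if u == v:
                    logger.warning("dropping self-loop on %s in %s", u, pathway_id)
                    continue
                if pair_sign.setdefault((u, v), sign) != sign:
                    raise EdgeConflictError(
                        f"conflicting signs on ordered gene pair ({u}, {v}) in {pathway_id}"
                    )
    edges = {(u, v, s) for (u, v), s in pair_sign.items()}
    return SignedPathwayGraph(pathway_id, pathway_name, nodes, edges)


def _byte_offset(raw: bytes, line: int, col: int) -> int:
    lines = raw.split(b"\n")
    return sum(len(l) + 1 for l in lines[: max(line - 1, 0)]) + max(col - 1, 0)


def _entry_gene_symbols(entry) -> list[str]:
    graphics = entry.find("graphics")
    text = ""
    if graphics is not None and graphics.get("name"):
        text = graphics.get("name")
    elif entry.get("name"):
        text = entry.get("name")
    text = text.replace("...", "")
    symbols = []
    for tok in re.split(r"[,\s]+", text):
        tok = tok.strip().upper()
        if not tok:
            continue
        # KEGG id tokens like "hsa:7473" carry no symbol; keep the tail only
        # when nothing better exists.
        if ":" in tok:
            tok = tok.split(":")[-1]
        symbols.append(tok)
    return list(dict.fromkeys(symbols))


# ---------------------------------------------------------------------------
# Chain report notation
# ---------------------------------------------------------------------------

# "B (fc) <- A (fc)": A activates B.  "B (fc) |- A (fc)": A represses B.
# The printed U+2223 DIVIDES glyph is accepted as a pipe.
_ARROW_SIGNS = {"<-": ACTIVATION, "|-": INHIBITION, "∣-": INHIBITION}
_TOKEN_RE = re.compile(r"\s*([A-Za-z0-9_.:@/-]+)\s*\(\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*\)")
_ARROW_RE = re.compile(r"\s*(<-|\|-|∣-)")


def parse_subpathway_notation(
    text: str,
    universe: set[str] | None = None,
    pathway_id: str = "",
) -> tuple[Subpathway, dict[str, float]]:
    """Parse a printed chain like ``"PTCH1 (1.863) <- GLI2 (2.878) |- CSNK1G1 (0.587)"``.

    The chain is printed most-downstream gene first; the returned
    :class:`Subpathway` runs upstream→downstream (the reverse of print
    order), with one sign per arrow. Returns the subpathway and the
    fold-changes keyed by gene.

    ``universe``, when given, restricts the accepted gene symbols.
    """
    genes: list[str] = []
    fcs: dict[str, float] = {}
    arrow_signs: list[int] = []
    pos = 0
    expect_gene = True
    while pos < len(text):
        if expect_gene:
            m = _TOKEN_RE.match(text, pos)
            if not m:
                if text[pos:].strip() == "" and genes:
                    break
                raise NotationParseError(
                    f"expected GENE (FC) in {text!r}", column=pos + 1
                )
            gene = m.group(1).upper()
            if universe is not None and gene not in universe:
                raise NotationParseError(
                    f"unknown gene symbol {gene!r}", column=m.start(1) + 1
                )
            if gene in fcs:
                raise ValidationError(f"repeated gene {gene} in chain {text!r}")
            genes.append(gene)
            fcs[gene] = float(m.group(2))
            pos = m.end()
            expect_gene = False
        else:
            if text[pos:].strip() == "":
                break
            m = _ARROW_RE.match(text, pos)
            if not m:
                raise NotationParseError(
                    f"expected arrow '<-' or '|-' in {text!r}", column=pos + 1
                )
            arrow_signs.append(_ARROW_SIGNS[m.group(1)])
            pos = m.end()
            expect_gene = True
    if expect_gene and genes:
        raise NotationParseError(f"dangling arrow at end of {text!r}", column=len(text))
    if len(genes) < 2:
        raise ValidationError(
            f"a subpathway needs at least 2 genes, got {len(genes)} in {text!r}"
        )
    nodes = tuple(reversed(genes))
    signs = tuple(reversed(arrow_signs))
    return Subpathway(pathway_id, nodes, signs), fcs


def _format_ratio(value: float) -> str:
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def format_subpathway_notation(sub: Subpathway, fcs: Mapping[str, float]) -> str:
    """Format a chain most-downstream-first in the report notation (ASCII ``|-``)."""
    missing = [n for n in sub.nodes if n not in fcs]
    if missing:
        raise KeyError(f"missing fold-change for gene(s): {', '.join(missing)}")
    parts = []
    for i, gene in enumerate(reversed(sub.nodes)):
        if i > 0:
            sign = sub.signs[len(sub.signs) - i]
            parts.append("<-" if sign == ACTIVATION else "|-")
        parts.append(f"{gene} ({_format_ratio(fcs[gene])})")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def read_fold_change_table(
    path,
    dataset_id: str | None = None,
    disease_label: str = "other",
) -> ExpressionDataset:
    """Read a two-column TSV (gene symbol, fold-change ratio).

    A first line whose second field is not numeric is treated as a header and
    skipped. Duplicate genes and non-positive ratios are validation errors;
    an empty file yields an empty dataset with a warning.
    """
    dataset_id = dataset_id or Path(path).name.split(".")[0]
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{ln}: expected 2 tab-separated columns"
                )
            rows.append((fields[0], fields[1]))
    if rows:
        try:
            float(rows[0][1])
        except ValueError:
            rows = rows[1:]
    if not rows:
        logger.warning("fold-change table %s is empty", path)
        return ExpressionDataset(dataset_id, disease_label, {})
    genes = [g.upper() for g, _ in rows]
    dup = sorted({g for g in genes if genes.count(g) > 1})
    if dup:
        raise ValidationError(f"duplicate gene(s) in {path}: {', '.join(dup)}")
    fcs = {}
    for gene, val in rows:
        try:
            ratio = float(val)
        except ValueError as exc:
            raise ValidationError(f"non-numeric ratio {val!r} for {gene} in {path}") from exc
        if ratio <= 0:
            raise ValidationError(f"non-positive ratio {ratio} for {gene} in {path}")
        fcs[gene.upper()] = ratio
    return ExpressionDataset(dataset_id, disease_label, fcs)


def write_fold_change_table(dataset: ExpressionDataset, path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(dataset.fold_changes):
            fh.write(f"{gene}\t{_format_ratio(dataset.fold_changes[gene])}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into ``{category name: gene set}`` (symbols upper-cased)."""
    categories: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{ln}: GMT line needs name, description and >= 1 gene"
                )
            name = fields[0]
            if name in categories:
                raise ValidationError(f"{path}:{ln}: duplicate category {name!r}")
            genes = {g.upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise ValidationError(f"{path}:{ln}: category {name!r} has no genes")
            categories[name] = genes
    return categories


def write_gmt(categories: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name in sorted(categories):
            genes = "\t".join(sorted({g.upper() for g in categories[name]}))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def _iter_signed_edges(network) -> list[tuple[str, str, int]]:
    if hasattr(network, "union_graph"):
        network = network.union_graph
    if isinstance(network, SignedPathwayGraph):
        return sorted(network.edges)
    if isinstance(network, (nx.DiGraph, nx.MultiDiGraph)):
        return sorted(
            (u, v, int(d["sign"])) for u, v, d in network.edges(data=True)
        )
    raise TypeError(f"cannot extract signed edges from {type(network).__name__}")


def write_network_sif(network, path) -> None:
    """Write edges as SIF lines ``source activates|represses target``."""
    with _open_text(path, "wt") as fh:
        for u, v, s in _iter_signed_edges(network):
            fh.write(f"{u}\t{_SIGN_WORD[s]}\t{v}\n")


def read_network_sif(path) -> SignedPathwayGraph:
    nodes: set[str] = set()
    edges: set[tuple[str, str, int]] = set()
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[1] not in _WORD_SIGN:
                raise ValidationError(f"{path}:{ln}: bad SIF line {line!r}")
            u, word, v = fields
            nodes |= {u.upper(), v.upper()}
            edges.add((u.upper(), v.upper(), _WORD_SIGN[word]))
    return SignedPathwayGraph(Path(path).name.split(".")[0], "", nodes, edges)


def write_network_graphml(network, path) -> None:
    g = nx.DiGraph()
    for u, v, s in _iter_signed_edges(network):
        g.add_edge(u, v, sign=s, interaction=_SIGN_WORD[s])
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Bundled reference tables (transcribed report inputs)
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("subpathnet.data").joinpath(name).read_text(encoding="utf-8")


def load_inflammation_terms() -> dict[str, set[str]]:
    """Bundled inflammation-related category→gene sets (GMT)."""
    text = _data_text("inflammation_terms.gmt")
    categories = {}
    for line in text.splitlines():
        if line.strip():
            fields = line.split("\t")
            categories[fields[0]] = {g.upper() for g in fields[2:] if g.strip()}
    return categories


def load_reported_gene_pathways() -> pd.DataFrame:
    """Bundled 16-gene pathway-usage table (gene, pathways, per-dataset direction)."""
    return pd.read_csv(
        io.StringIO(_data_text("reported_gene_pathways.tsv")), sep="\t"
    )


def load_reported_subpathways() -> pd.DataFrame:
    """Bundled reported subpathway chains (pathway id, dataset, chain, printed p)."""
    return pd.read_csv(
        io.StringIO(_data_text("reported_subpathways.tsv")), sep="\t"
    )
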