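"""Knowledge-graph data model and I/O.

The knowledge graph is an undirected gene/protein interaction graph. Each edge
carries the set of evidence channels supporting the interaction — 'E'
(experimental), 'D' (curated database), 'T' (literature text mining) — and a
combined confidence score in [0, 1]. Each node carries cellular-abundance
values, subcellular-localization annotations over a 41-term hierarchical
taxonomy, and GO-term annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from perturbgraph.taxonomy import Taxonomy, default_taxonomy

logger = logging.getLogger(__name__)

#: Evidence channels in precedence order: experimental > database > text mining.
EVIDENCE_CHANNELS = ("E", "D", "T")

_EDGE_COLUMNS = [
    "protein1",
    "protein2",
    "experimental",
    "database",
    "textmining",
    "combined_score",
]


def strongest_channel(channels) -> str:
    """The highest-precedence evidence channel present (E > D > T)."""
    for c in EVIDENCE_CHANNELS:
        if c in channels:
            return c
    raise ValueError(f"no valid evidence channel in {channels!r}")


@dataclass(frozen=True)
class GeneAttributes:
    """Node attributes for one gene/protein.

    Abundances are nonnegative when measured, ``None`` when missing.
    ``localizations`` is ancestor-closed under the taxonomy.
    """

    rna_cell_line: float | None = None
    rna_cell_type: float | None = None
    protein_cell_type: float | None = None
    localizations: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("rna_cell_line", "rna_cell_type", "protein_cell_type"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class Phenotype:
    """A named phenotype represented by surrogate target nodes in the graph."""

    name: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("a phenotype needs at least one target node")


class KnowledgeGraph:
    """Undirected attributed interaction graph.

    Thin wrapper over :class:`networkx.Graph`; edges carry ``channels``
    (frozenset over {'E','D','T'}) and ``score`` (combined confidence).
    Node order for matrix operations is the sorted gene-id list.
    """

    def __init__(self, graph: nx.Graph | None = None, taxonomy: Taxonomy | None = None):
        self.g = graph if graph is not None else nx.Graph()
        self.taxonomy = taxonomy if taxonomy is not None else default_taxonomy()

    # -- construction ------------------------------------------------------

    def add_gene(self, gene: str, attrs: GeneAttributes | None = None) -> None:
        self.g.add_node(gene, attrs=attrs or GeneAttributes())

    def add_interaction(self, gene_a: str, gene_b: str, channels, score: float) -> None:
        if gene_a == gene_b:
            raise ValueError(f"self-loop rejected: {gene_a!r}")
        channels = frozenset(channels)
        if not channels or not channels <= set(EVIDENCE_CHANNELS):
            raise ValueError(f"invalid evidence channels {set(channels)!r}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"combined score {score} outside [0, 1]")
        for gene in (gene_a, gene_b):
            if gene not in self.g:
                self.add_gene(gene)
        if self.g.has_edge(gene_a, gene_b):
            # duplicate unordered pair: union channels, keep max score
            data = self.g.edges[gene_a, gene_b]
            data["channels"] = data["channels"] | channels
            data["score"] = max(data["score"], score)
        else:
            self.g.add_edge(gene_a, gene_b, channels=channels, score=score)

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.g

    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def degree(self, gene: str) -> int:
        """Number of incident edges; raises ``KeyError`` for unknown genes."""
        if gene not in self.g:
            raise KeyError(gene)
        return self.g.degree[gene]

    def attrs(self, gene: str) -> GeneAttributes:
        return self.g.nodes[gene].get("attrs") or GeneAttributes()

    def set_attrs(self, gene: str, attrs: GeneAttributes) -> None:
        self.g.nodes[gene]["attrs"] = attrs

    def channels(self, gene_a: str, gene_b: str) -> frozenset[str]:
        return self.g.edges[gene_a, gene_b]["channels"]

    def score(self, gene_a: str, gene_b: str) -> float:
        return self.g.edges[gene_a, gene_b]["score"]

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted symmetric adjacency in sorted-node order."""
        return nx.to_scipy_sparse_array(self.g, nodelist=self.nodes, weight=None, format="csr")

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if set(self.g.nodes) != set(other.g.nodes):
            return False
        for u, v, d in self.g.edges(data=True):
            if not other.g.has_edge(u, v):
                return False
            od = other.g.edges[u, v]
            if d["channels"] != od["channels"] or d["score"] != od["score"]:
                return False
        return self.g.number_of_edges() == other.g.number_of_edges() and all(
            self.attrs(g) == other.attrs(g) for g in self.g.nodes
        )


# -- I/O -------------------------------------------------------------------


def read_edge_table(
    path, score_threshold: float = 0.0, taxonomy: Taxonomy | None = None
) -> KnowledgeGraph:
    """Load a STRING-physical-style edge TSV into a :class:`KnowledgeGraph`.

    Expected header: ``protein1 protein2 experimental database textmining
    combined_score``; a nonzero channel column marks that channel as present.
    Duplicate unordered pairs are merged (union of channels, max score) before
    edges with merged score below ``score_threshold`` are dropped.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold {score_threshold} outside [0, 1]")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein1": str, "protein2": str},
        float_precision="round_trip",
    )
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge table {path} missing columns {missing}")

    kg = KnowledgeGraph(taxonomy=taxonomy)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            channels = set()
            if float(row.experimental):
                channels.add("E")
            if float(row.database):
                channels.add("D")
            if float(row.textmining):
                channels.add("T")
            kg.add_interaction(row.protein1, row.protein2, channels, float(row.combined_score))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc

    if score_threshold > 0:
        drop = [(u, v) for u, v, s in kg.g.edges(data="score") if s < score_threshold]
        kg.g.remove_edges_from(drop)
    return kg


def write_edge_table(kg: KnowledgeGraph, path) -> None:
    rows = []
    for u, v in sorted(map(lambda e: tuple(sorted(e)), kg.g.edges())):
        ch = kg.channels(u, v)
        rows.append(
            {
                "protein1": u,
                "protein2": v,
                "experimental": int("E" in ch),
                "database": int("D" in ch),
                "textmining": int("T" in ch),
                # repr round-trips the float exactly
                "combined_score": repr(kg.score(u, v)),
            }
        )
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_attribute_tables(abundance, localization, go, graph: KnowledgeGraph) -> KnowledgeGraph:
    """Attach abundance / localization / GO annotation tables to graph nodes.

    Genes absent from a table keep missing abundances / empty annotation sets;
    table rows for genes not in the graph are skipped (one logged count per
    table). Localization terms are validated against the graph's taxonomy and
    ancestor-closed. Returns the (mutated) graph.
    """
    tax = graph.taxonomy

    ab = pd.read_csv(abundance, sep="\t", dtype={"gene": str})
    unknown = 0
    for row in ab.itertuples(index=False):
        if row.gene not in graph:
            unknown += 1
            continue
        graph.set_attrs(
            row.gene,
            replace(
                graph.attrs(row.gene),
                rna_cell_line=_opt_float(row.rna_cell_line),
                rna_cell_type=_opt_float(row.rna_cell_type),
                protein_cell_type=_opt_float(row.protein_cell_type),
            ),
        )
    if unknown:
        logger.warning("abundance table: %d rows for genes not in graph ignored", unknown)

    loc = pd.read_csv(localization, sep="\t", dtype=str)
    bad_terms = sorted(set(loc["compartment"]) - set(tax.terms))
    if bad_terms:
        raise ValueError(f"unknown compartment terms: {bad_terms}")
    unknown = 0
    for gene, grp in loc.groupby("gene"):
        if gene not in graph:
            unknown += len(grp)
            continue
        terms = tax.closure(set(grp["compartment"]))
        graph.set_attrs(gene, replace(graph.attrs(gene), localizations=terms))
    if unknown:
        logger.warning("localization table: %d rows for genes not in graph ignored", unknown)

    go_df = pd.read_csv(go, sep="\t", dtype=str)
    unknown = 0
    for gene, grp in go_df.groupby("gene"):
        if gene not in graph:
            unknown += len(grp)
            continue
        graph.set_attrs(gene, replace(graph.attrs(gene), go_terms=frozenset(grp["go_id"])))
    if unknown:
        logger.warning("GO table: %d rows for genes not in graph ignored", unknown)
    return graph


def read_phenotype(path) -> Phenotype:
    """Load a phenotype YAML: ``{name: ..., targets: [...]}``."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    return Phenotype(name=d["name"], targets=frozenset(d["targets"]))


def write_phenotype(phenotype: Phenotype, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"name": phenotype.name, "targets": sorted(phenotype.targets)}, fh)
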