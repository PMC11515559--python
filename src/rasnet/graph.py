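"""Metabolite-centric metabolic graphs.

Nodes are metabolites (KEGG compound/glycan identifiers); directed edges
are metabolic reactions carrying a gene-protein-reaction rule and the set
of pathways they belong to.  Graphs are built by merging KEGG KGML pathway
files or by loading a tabular edge list, and can be edited (reaction
removal) and summarized.

At most one edge exists per ordered node pair: when several KEGG reactions
connect the same (source, target) pair their GPRs are merged with OR
semantics and all reaction ids are retained in the edge metadata, so the
per-sample weighted adjacency matrix stays well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

from .gpr import GPRRule, parse_gpr

__all__ = [
    "MetaboliteNode",
    "ReactionEdge",
    "MetabolicGraph",
    "GraphStructureError",
    "DEFAULT_DEGRADATION_REACTIONS",
    "parse_kgml",
    "load_graph_table",
    "load_gene_pathways",
    "remove_reactions",
    "graph_summary",
    "write_graph_table",
    "write_graphml",
]

#: Degradation reactions (GM1 -> GM2 -> GM3) removed from the merged
#: glycosphingolipid graph by default: they are catabolic, not competing
#: biosynthetic steps.
DEFAULT_DEGRADATION_REACTIONS = frozenset({"R06010", "R06004"})

SERIES_TAGS = (
    "0-series",
    "a-series",
    "b-series",
    "c-series",
    "globo",
    "lacto/neolacto",
    "other",
)


class GraphStructureError(ValueError):
    """Raised for structurally invalid graph inputs."""


@dataclass(frozen=True)
class MetaboliteNode:
    """A metabolite: KEGG compound id, display label, optional series tag."""

    id: str
    label: str = ""
    series_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if self.series_tag is not None and self.series_tag not in SERIES_TAGS:
            raise ValueError(f"unknown series tag {self.series_tag!r}")


@dataclass(frozen=True)
class ReactionEdge:
    """A directed reaction edge with its GPR rule and pathway membership."""

    reaction_id: str
    source: str
    target: str
    gpr: GPRRule
    pathways: frozenset[str]
    all_reaction_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise GraphStructureError(
                f"self-loop on {self.source!r} (reaction {self.reaction_id})"
            )
        if not self.pathways:
            raise GraphStructureError(
                f"reaction {self.reaction_id} has no pathway annotation"
            )
        if not self.all_reaction_ids:
            object.__setattr__(self, "all_reaction_ids", (self.reaction_id,))


class MetabolicGraph:
    """Directed metabolite-centric graph G = (V, E) with GPR-annotated edges.

    Node order (sorted metabolite ids) fixes the row/column alignment of
    every adjacency and transition matrix; edge order (sorted by
    (source, target)) fixes the row order of reaction-by-sample matrices.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node: MetaboliteNode | str, label: str = "",
                 series_tag: str | None = None) -> None:
        if isinstance(node, str):
            node = MetaboliteNode(node, label or node, series_tag)
        if node.id in self._g:
            # keep the richer label
            if node.label and not self._g.nodes[node.id].get("label"):
                self._g.nodes[node.id]["label"] = node.label
            return
        self._g.add_node(node.id, label=node.label or node.id,
                         series_tag=node.series_tag)

    def add_reaction(
        self,
        reaction_id: str,
        source: str,
        target: str,
        gpr: GPRRule,
        pathways: Iterable[str],
        create_nodes: bool = True,
    ) -> None:
        """Add one directed reaction edge; merges on (source, target) clash."""
        pathways = frozenset(pathways)
        if source == target:
            raise GraphStructureError(
                f"self-loop on {source!r} (reaction {reaction_id})")
        if not pathways:
            raise GraphStructureError(
                f"reaction {reaction_id} has no pathway annotation")
        for nid in (source, target):
            if nid not in self._g:
                if not create_nodes:
                    raise GraphStructureError(
                        f"reaction {reaction_id} references unknown "
                        f"metabolite {nid!r}")
                self.add_node(nid)
        if self._g.has_edge(source, target):
            data = self._g.edges[source, target]
            ids = tuple(sorted(set(data["all_reaction_ids"]) | {reaction_id}))
            if gpr != data["gpr"]:
                gpr = GPRRule.any_of(data["gpr"], gpr)
            else:
                gpr = data["gpr"]
            self._g.add_edge(source, target, reaction_id=ids[0], gpr=gpr,
                             pathways=data["pathways"] | pathways,
                             all_reaction_ids=ids)
        else:
            self._g.add_edge(source, target, reaction_id=reaction_id, gpr=gpr,
                             pathways=pathways,
                             all_reaction_ids=(reaction_id,))

    # -- views --------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @property
    def node_order(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_order)}

    def nodes(self) -> list[MetaboliteNode]:
        return [
            MetaboliteNode(n, d.get("label", n), d.get("series_tag"))
            for n, d in sorted(self._g.nodes(data=True))
        ]

    def edges(self) -> list[ReactionEdge]:
        out = []
        for u, v in sorted(self._g.edges):
            d = self._g.edges[u, v]
            out.append(ReactionEdge(d["reaction_id"], u, v, d["gpr"],
                                    d["pathways"], d["all_reaction_ids"]))
        return out

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(e.reaction_id for e in self.edges())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_reactions(self) -> int:
        return self._g.number_of_edges()

    @property
    def gene_universe(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for _, _, d in self._g.edges(data=True):
            out |= d["gpr"].genes
        return out

    def edge_for(self, reaction_id: str) -> ReactionEdge:
        for e in self.edges():
            if e.reaction_id == reaction_id or reaction_id in e.all_reaction_ids:
                return e
        raise KeyError(reaction_id)

    def copy(self) -> "MetabolicGraph":
        new = MetabolicGraph()
        new._g = self._g.copy()
        return new

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MetabolicGraph(nodes={self.n_nodes}, "
                f"reactions={self.n_reactions})")


# ---------------------------------------------------------------------
# KGML ingestion
# ---------------------------------------------------------------------

def _strip_ns(token: str) -> str:
    """Drop a KEGG namespace prefix: 'cpd:C01290' -> 'C01290'."""
    return token.rsplit(":", 1)[-1]


def parse_kgml(
    files: Sequence[str | Path],
    gpr_table: Mapping[str, str] | pd.DataFrame | None = None,
) -> MetabolicGraph:
    """Merge KGML pathway files into a single metabolite-centric graph.

    Compound entries become nodes; each (substrate, product) pair of a
    reaction becomes a directed edge (both directions for reversible
    reactions).  KGML gene entries attached to a reaction default to an
    OR rule over the listed genes; an explicit ``gpr_table`` mapping
    reaction ids to GPR strings (e.g. rules derived from a genome-scale
    metabolic model) overrides the KGML gene lists.
    """
    if isinstance(gpr_table, pd.DataFrame):
        gpr_table = dict(zip(gpr_table["reaction_id"], gpr_table["gpr"]))
    graph = MetabolicGraph()
    for path in files:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise GraphStructureError(
                f"malformed KGML file {path.name}: {exc}") from exc
        root = tree.getroot()
        pathway_id = _strip_ns(root.get("name", path.stem))

        compounds: set[str] = set()
        for entry in root.findall("entry"):
            if entry.get("type") != "compound":
                continue
            for token in entry.get("name", "").split():
                cid = _strip_ns(token)
                label = cid
                graphics = entry.find("graphics")
                if graphics is not None and graphics.get("name"):
                    label = graphics.get("name").split(",")[0].strip()
                compounds.add(cid)
                graph.add_node(MetaboliteNode(cid, label))

        # gene entries reference reactions they catalyze
        reaction_genes: dict[str, set[str]] = {}
        for entry in root.findall("entry"):
            if entry.get("type") != "gene" or not entry.get("reaction"):
                continue
            genes = {_strip_ns(t) for t in entry.get("name", "").split()}
            for rn in entry.get("reaction").split():
                reaction_genes.setdefault(_strip_ns(rn), set()).update(genes)

        for reaction in root.findall("reaction"):
            reversible = reaction.get("type") == "reversible"
            subs = [_strip_ns(s.get("name")) for s in reaction.findall("substrate")]
            prods = [_strip_ns(p.get("name")) for p in reaction.findall("product")]
            for rid_tok in reaction.get("name", "").split():
                rid = _strip_ns(rid_tok)
                if gpr_table is not None and rid in gpr_table:
                    gpr = parse_gpr(gpr_table[rid])
                else:
                    genes = sorted(reaction_genes.get(rid, ()))
                    if not genes:
                        warnings.warn(
                            f"reaction {rid} in {path.name} has no gene "
                            f"association; skipped", stacklevel=2)
                        continue
                    gpr = GPRRule.any_of(*(GPRRule.leaf(g) for g in genes))
                for s in subs:
                    for p in prods:
                        for cid in (s, p):
                            if cid not in compounds:
                                raise GraphStructureError(
                                    f"reaction {rid} in {path.name} references "
                                    f"unknown compound {cid!r}")
                        graph.add_reaction(rid, s, p, gpr, {pathway_id},
                                           create_nodes=False)
                        if reversible:
                            graph.add_reaction(rid, p, s, gpr, {pathway_id},
                                               create_nodes=False)
    return graph


# ---------------------------------------------------------------------
# Tabular ingestion / export
# ---------------------------------------------------------------------

def load_graph_table(table: str | Path | pd.DataFrame) -> MetabolicGraph:
    """Build a graph from an edge table.

    Expected columns: ``reaction_id, source, target, gpr, pathways`` with
    pathways semicolon-separated and ``gpr`` a boolean expression over
    gene ids.  Row order is irrelevant; duplicate (source, target) rows
    are rejected.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", dtype=str)
    required = {"reaction_id", "source", "target", "gpr", "pathways"}
    missing = required - set(table.columns)
    if missing:
        raise GraphStructureError(f"graph table missing columns {sorted(missing)}")
    graph = MetabolicGraph()
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(table.itertuples(index=False)):
        key = (row.source, row.target)
        if key in seen:
            raise GraphStructureError(
                f"duplicate edge {key} at row {i}")
        seen.add(key)
        try:
            gpr = parse_gpr(row.gpr)
        except ValueError as exc:
            raise GraphStructureError(
                f"row {i}: cannot parse GPR {row.gpr!r}: {exc}") from exc
        pathways = {p for p in str(row.pathways).split(";") if p}
        graph.add_reaction(row.reaction_id, row.source, row.target, gpr,
                           pathways)
    return graph


def write_graph_table(graph: MetabolicGraph, path: str | Path) -> None:
    """Write the edge list as TSV in the dialect :func:`load_graph_table` reads."""
    rows = [
        {
            "reaction_id": e.reaction_id,
            "source": e.source,
            "target": e.target,
            "gpr": e.gpr.to_string(),
            "pathways": ";".join(sorted(e.pathways)),
            "all_reaction_ids": ";".join(e.all_reaction_ids),
        }
        for e in graph.edges()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(graph: MetabolicGraph, path: str | Path) -> None:
    """Export for external viewers; GPR and pathway sets become strings."""
    g = nx.DiGraph()
    for n in graph.nodes():
        g.add_node(n.id, label=n.label, series_tag=n.series_tag or "")
    for e in graph.edges():
        g.add_edge(e.source, e.target, reaction_id=e.reaction_id,
                   gpr=e.gpr.to_string(), pathways=";".join(sorted(e.pathways)),
                   all_reaction_ids=";".join(e.all_reaction_ids))
    nx.write_graphml(g, str(path))


def load_gene_pathways(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> pathway annotation TSV (columns gene, pathway)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, pw in zip(df["gene"], df["pathway"]):
        out.setdefault(gene, set()).add(pw)
    return out


# ---------------------------------------------------------------------
# Editing & summary
# ---------------------------------------------------------------------

def remove_reactions(
    graph: MetabolicGraph,
    ids: Iterable[str] = DEFAULT_DEGRADATION_REACTIONS,
) -> MetabolicGraph:
    """Return a copy of the graph without the listed reactions.

    Nodes are retained even if left isolated.  Absent ids only warn, so
    the default degradation set can be applied to arbitrary subgraphs.
    """
    ids = set(ids)
    new = graph.copy()
    found: set[str] = set()
    for e in graph.edges():
        hit = ids & set(e.all_reaction_ids)
        if hit:
            found |= hit
            new.graph.remove_edge(e.source, e.target)
    absent = ids - found
    if absent:
        warnings.warn(
            f"reactions not present in graph: {sorted(absent)}", stacklevel=2)
    return new


def graph_summary(
    graph: MetabolicGraph,
    gsl_pathways: Iterable[str] | None = None,
    gene_pathways: Mapping[str, set[str]] | None = None,
) -> dict:
    """Count reactions by GPR class and enzymes by pathway membership.

    ``gene_pathways`` maps each gene to the KEGG pathways it is annotated
    to; together with ``gsl_pathways`` it yields the number of enzymes
    that also act outside the pathway set of interest.
    """
    edges = graph.edges()
    by_class = {"AND": 0, "OR": 0, "single": 0, "nested": 0}
    for e in edges:
        by_class[e.gpr.classification] += 1
    summary = {
        "n_reactions": len(edges),
        "n_and": by_class["AND"],
        "n_or": by_class["OR"],
        "n_single": by_class["single"],
        "n_nested": by_class["nested"],
        "n_enzymes": len(graph.gene_universe),
    }
    if gene_pathways is not None and gsl_pathways is not None:
        gsl = set(gsl_pathways)
        summary["n_enzymes_non_gsl"] = sum(
            1 for g in graph.gene_universe
            if gene_pathways.get(g, set()) - gsl
        )
    return summary
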