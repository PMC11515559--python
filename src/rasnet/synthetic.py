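"""Synthetic graphs and grouped count matrices for testing the pipeline.

The generators reproduce the two structural features the method relies
on: metabolic graphs with parallel biosynthetic series whose step-wise
reactions share enzymes (so unadjusted RAS values are identical across
series), and grouped bulk RNA-seq-like counts (negative-binomial, with
optional multiplicative group effects on named genes).  Everything is
fully determined by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpr import GPRRule
from .graph import MetabolicGraph, write_graph_table

__all__ = [
    "FixtureSpec",
    "toy_shared_enzyme_graph",
    "parallel_chains",
    "random_dag",
    "simulate_counts",
    "write_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study.

    ``effects`` lists (gene, log2_effect, group): the negative-binomial
    mean of that gene is multiplied by 2**log2_effect in samples of that
    group only.  ``nb_mean`` is the typical per-gene count scale and
    ``dispersion`` the NB dispersion (variance = mu + dispersion * mu^2).
    """

    n_chains: int = 2
    chain_length: int = 3
    effects: tuple[tuple[str, float, str], ...] = ()
    nb_mean: float = 500.0
    dispersion: float = 0.1
    samples_per_group: int = 20
    groups: tuple[str, ...] = ("A", "B")
    n_background: int = 50
    seed: int = 0


def toy_shared_enzyme_graph() -> MetabolicGraph:
    """Branch node plus two parallel 3-step chains sharing enzymes.

    Node ``s`` branches to ``a`` and ``b`` via reactions with distinct
    genes (GA, GB); the chains a->c->e->g and b->d->f->h then share one
    gene per step (G1, G2, G3 on corresponding edges).  Unadjusted RAS
    values of corresponding chain edges are therefore identical for any
    expression, while the TP adjustments can tell the chains apart
    whenever the branch reactions differ.
    """
    g = MetabolicGraph()
    edges = [
        ("R01", "s", "a", "GA"),
        ("R02", "s", "b", "GB"),
        ("R03", "a", "c", "G1"),
        ("R04", "b", "d", "G1"),
        ("R05", "c", "e", "G2"),
        ("R06", "d", "f", "G2"),
        ("R07", "e", "g", "G3"),
        ("R08", "f", "h", "G3"),
    ]
    for rid, u, v, gene in edges:
        g.add_reaction(rid, u, v, GPRRule.leaf(gene), {"toy"})
    return g


def parallel_chains(n_chains: int = 2, chain_length: int = 3) -> MetabolicGraph:
    """Generalized fixture: one branch node feeding n parallel chains.

    Branch reactions carry distinct genes (GB1..GBn); step k of every
    chain shares the gene Gk, emulating shared-enzyme series of
    arbitrary width and depth.
    """
    if n_chains < 1 or chain_length < 1:
        raise ValueError("need at least one chain of length one")
    g = MetabolicGraph()
    rid = 0

    def next_rid() -> str:
        nonlocal rid
        rid += 1
        return f"R{rid:03d}"

    for c in range(n_chains):
        prev = "s"
        g.add_reaction(next_rid(), "s", f"n{c}_0",
                       GPRRule.leaf(f"GB{c + 1}"), {"chains"})
        prev = f"n{c}_0"
        for k in range(1, chain_length + 1):
            node = f"n{c}_{k}"
            g.add_reaction(next_rid(), prev, node,
                           GPRRule.leaf(f"G{k}"), {"chains"})
            prev = node
    return g


def random_dag(n_nodes: int, edge_prob: float, seed: int) -> MetabolicGraph:
    """Random topologically ordered DAG with single-gene GPRs.

    Each ordered pair (i, j), i < j, gets an edge with probability
    ``edge_prob``; each edge carries its own gene so edge weights can be
    set independently through expression.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    g = MetabolicGraph()
    names = [f"N{i:02d}" for i in range(n_nodes)]
    for name in names:
        g.add_node(name)
    rid = 0
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                rid += 1
                g.add_reaction(f"R{rid:03d}", names[i], names[j],
                               GPRRule.leaf(f"G{rid:03d}"), {"dag"})
    return g


def simulate_counts(
    graph: MetabolicGraph,
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for the graph's genes plus background genes.

    Returns (counts genes x samples, annotations with a ``group``
    column).  Per-gene baseline means are drawn once (log-uniform within
    a factor of 2 around ``nb_mean``) so genes differ in scale; group
    effects multiply the affected gene's mean by 2**log2_effect for the
    named group's samples only.
    """
    if spec.nb_mean <= 0 or spec.dispersion <= 0:
        raise ValueError("nb_mean and dispersion must be positive")
    rng = np.random.default_rng(spec.seed)
    genes = sorted(graph.gene_universe) + [
        f"BG{i:03d}" for i in range(spec.n_background)
    ]
    unknown = {g for g, _, _ in spec.effects} - set(genes)
    if unknown:
        raise ValueError(f"effect genes not in fixture: {sorted(unknown)}")
    samples = [f"{grp}{i + 1:03d}" for grp in spec.groups
               for i in range(spec.samples_per_group)]
    sample_group = [grp for grp in spec.groups
                    for _ in range(spec.samples_per_group)]
    base = spec.nb_mean * 2.0 ** rng.uniform(-1, 1, size=len(genes))
    mu = np.tile(base[:, None], (1, len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for gene, log2_effect, group in spec.effects:
        cols = [j for j, grp in enumerate(sample_group) if grp == group]
        mu[gene_idx[gene], cols] *= 2.0 ** log2_effect
    # NB(mean mu, variance mu + dispersion * mu^2): n = 1/dispersion
    n = 1.0 / spec.dispersion
    p = n / (n + mu)
    counts = rng.negative_binomial(n, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    annotations = pd.DataFrame({"group": sample_group}, index=samples)
    annotations.index.name = "sample"
    return counts_df, annotations


def write_fixture(
    graph: MetabolicGraph,
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write graph table, counts and annotations in the ingestion dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graph": outdir / "graph.tsv",
        "counts": outdir / "counts.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    write_graph_table(graph, paths["graph"])
    counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    annotations.to_csv(paths["annotations"], sep="\t")
    return paths
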