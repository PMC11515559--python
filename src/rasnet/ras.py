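"""Reaction Activity Scores (RAS).

A RAS summarizes, per sample and per reaction, the expression of the
genes whose products catalyze the reaction, by evaluating the reaction's
GPR rule over normalized expression: AND nodes (enzyme subunits) take
the minimum of their children, OR nodes (isoenzymes) take the sum, and a
leaf contributes the gene's expression value.  The RAS values of one
sample weight the graph's edges, giving a weighted directed graph per
sample; stacked over samples they form the reaction-by-sample matrix
that all downstream analyses consume.

Raw counts are normalized with the median-of-ratios method (per-sample
size factor = median across reference genes of count / gene-wise
geometric mean) followed by log10(x + 1); a pre-normalized matrix may be
supplied directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .gpr import GPRRule
from .graph import MetabolicGraph

__all__ = [
    "ExpressionMatrix",
    "normalize_counts",
    "median_of_ratios_size_factors",
    "evaluate_gpr",
    "compute_ras",
    "sample_adjacency",
]


@dataclass
class ExpressionMatrix:
    """Normalized, log-transformed gene-by-sample expression.

    ``values``: genes x samples DataFrame of non-negative reals.
    ``annotations``: optional per-sample table (index = sample ids)
    carrying group labels such as tumor entity or MYCN status.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if (v.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.annotations is not None:
            missing = set(v.columns) - set(self.annotations.index)
            if missing:
                raise ValueError(
                    f"samples missing from annotations: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    The reference for each gene is its geometric mean across samples;
    only genes expressed in every sample (strictly positive counts) are
    used.  The size factor of a sample is the median over reference
    genes of count / reference.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "every gene has a zero count in some sample; no reference genes "
            "for median-of-ratios — consider a pseudo-reference (e.g. add a "
            "pseudocount before normalization) or supply pre-normalized data")
    log_ref = np.log(x[positive]).mean(axis=1)
    ratios = np.exp(np.log(x[positive]) - log_ref[:, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(
    raw: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Median-of-ratios normalization followed by log10(x + 1).

    ``raw``: genes x samples matrix of non-negative integer counts.
    """
    sf = median_of_ratios_size_factors(raw)
    normalized = raw.astype(float).div(sf, axis=1)
    values = np.log10(normalized + 1.0)
    return ExpressionMatrix(values=values, annotations=annotations)


def evaluate_gpr(
    rule: GPRRule,
    expr: Mapping[str, float],
    missing: str = "zero",
) -> float:
    """Evaluate one GPR rule on a gene -> expression mapping.

    ALL -> min of children, ANY -> sum of children, leaf -> expression.
    A leaf gene absent from ``expr`` contributes 0 with a warning
    (``missing="zero"``, default) or raises (``missing="raise"``).
    """
    if missing not in ("zero", "raise"):
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    if rule.is_leaf:
        if rule.gene in expr:
            return float(expr[rule.gene])
        if missing == "raise":
            raise KeyError(rule.gene)
        warnings.warn(f"gene {rule.gene!r} absent from expression; treated "
                      f"as 0", stacklevel=2)
        return 0.0
    vals = [evaluate_gpr(c, expr, missing) for c in rule.children]
    return float(min(vals) if rule.op == "ALL" else sum(vals))


def _evaluate_gpr_frame(rule: GPRRule, values: pd.DataFrame) -> np.ndarray:
    """Vectorized GPR evaluation: one value per sample (column)."""
    if rule.is_leaf:
        if rule.gene in values.index:
            return values.loc[rule.gene].to_numpy(dtype=float)
        return np.zeros(values.shape[1])
    child = np.stack([_evaluate_gpr_frame(c, values) for c in rule.children])
    return child.min(axis=0) if rule.op == "ALL" else child.sum(axis=0)


def compute_ras(
    graph: MetabolicGraph,
    expr: ExpressionMatrix | pd.DataFrame,
    missing: str = "zero",
) -> pd.DataFrame:
    """Reaction-by-sample RAS matrix for every reaction of the graph.

    Reactions sharing an identical GPR receive identical rows by
    construction.  Genes of the graph absent from the expression matrix
    follow the missing-gene policy (default: contribute 0, warn once).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.empty:
        raise ValueError("expression matrix is empty")
    absent = sorted(graph.gene_universe - set(values.index))
    if absent:
        if missing == "raise":
            raise KeyError(f"genes absent from expression: {absent}")
        warnings.warn(
            f"{len(absent)} graph gene(s) absent from expression, treated "
            f"as 0: {absent[:10]}", stacklevel=2)
    rows = {}
    for e in graph.edges():
        rows[e.reaction_id] = _evaluate_gpr_frame(e.gpr, values)
    ras = pd.DataFrame.from_dict(rows, orient="index", columns=values.columns)
    return ras.loc[list(graph.reaction_ids)]


def sample_adjacency(
    graph: MetabolicGraph,
    ras: pd.DataFrame,
    sample: str,
) -> np.ndarray:
    """Weighted adjacency matrix W of one sample (RAS values on edges).

    Rows/columns follow ``graph.node_order``; W[i, j] is the RAS of the
    reaction i -> j, 0 where no edge exists.
    """
    if sample not in ras.columns:
        raise KeyError(f"unknown sample {sample!r}")
    idx = graph.node_index
    n = graph.n_nodes
    W = np.zeros((n, n))
    col = ras[sample]
    for e in graph.edges():
        W[idx[e.source], idx[e.target]] = col[e.reaction_id]
    return W
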