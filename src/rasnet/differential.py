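"""Differential reaction activity between two sample groups.

For each reaction, the log2 fold-change of the mean (adjusted) RAS is
computed between the groups, a two-sided two-sample Kolmogorov-Smirnov
test compares the per-group RAS distributions, and p-values are adjusted
for multiple testing over all reactions with the Benjamini-Hochberg
step-up procedure.  Pathway-level activity aggregates the matrix as the
sum over each pathway's member reactions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph import MetabolicGraph
from .transition import AdjustedRASMatrix

__all__ = ["differential_reactions", "bh_adjust", "pathway_activity"]


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_reactions(
    M: pd.DataFrame | AdjustedRASMatrix,
    groups: Mapping[str, str] | pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction two-group comparison (log2FC + KS test + BH).

    ``groups`` maps sample id to group label.  ``group_a``/``group_b``
    pick the two groups compared (default: the two labels present, in
    sorted order); positive log2FC means higher mean activity in group A.
    ``epsilon`` guards the fold-change against zero means and is echoed
    in the result's ``attrs``.
    """
    values = M.values if isinstance(M, AdjustedRASMatrix) else M
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = groups.reindex(values.columns).dropna()
    if group_a is None or group_b is None:
        uniq = sorted(labels.unique())
        if len(uniq) != 2:
            raise ValueError(
                f"expected exactly 2 group labels, found {uniq}; pass "
                f"group_a/group_b explicitly")
        group_a, group_b = uniq
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {len(cols_a)} {group_a!r}, "
            f"{len(cols_b)} {group_b!r})")

    A = values[cols_a].to_numpy(dtype=float)
    B = values[cols_b].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2fc = np.log2((mean_a + epsilon) / (mean_b + epsilon))
    ks = np.empty(values.shape[0])
    pval = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        res = stats.ks_2samp(A[i], B[i], alternative="two-sided", method="auto")
        ks[i], pval[i] = res.statistic, res.pvalue
    padj = bh_adjust(pval)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "ks_D": ks,
            "pvalue": pval,
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=values.index,
    )
    out.index.name = "reaction_id"
    out.attrs.update(group_a=group_a, group_b=group_b, alpha=alpha,
                     epsilon=epsilon)
    return out


def pathway_activity(
    M: pd.DataFrame | AdjustedRASMatrix,
    graph: MetabolicGraph,
) -> pd.DataFrame:
    """Pathway-by-sample activity: sum of member-reaction values.

    A reaction annotated to several pathways contributes its full value
    to each of them.
    """
    values = M.values if isinstance(M, AdjustedRASMatrix) else M
    members: dict[str, list[str]] = {}
    for e in graph.edges():
        if e.reaction_id not in values.index:
            continue
        for pw in e.pathways:
            members.setdefault(pw, []).append(e.reaction_id)
    rows = {
        pw: values.loc[rids].sum(axis=0)
        for pw, rids in sorted(members.items())
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pathway"
    return out
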