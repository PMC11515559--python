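"""Reading count matrices and sample annotations.

Counts come as TSV/CSV (genes x samples, first column = gene id) or as
MatrixMarket MTX with sidecar row (gene) and column (sample) files, one
id per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.io import mmread

__all__ = ["read_counts", "read_annotations", "read_matrix_tsv"]


def read_counts(
    path: str | Path,
    genes: str | Path | None = None,
    samples: str | Path | None = None,
) -> pd.DataFrame:
    """Load a genes x samples count matrix from TSV/CSV or MTX."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes is None or samples is None:
            raise ValueError("MTX input requires gene and sample id files")
        mat = mmread(str(path)).toarray()
        gene_ids = Path(genes).read_text().split()
        sample_ids = Path(samples).read_text().split()
        return pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    sep = "," if path.suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Load a reactions x samples matrix written by this package."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Load a sample annotation table (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
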