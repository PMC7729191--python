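"""Intercorrelation structure of the candidate measures and predictor choice.

The eight candidate measures typically fall into two blocks of moderate to
strong correlations — the displacement measures on one side and the
speed/acceleration measures on the other.  One representative is selected
from each block to avoid collinear predictors in the rating models; the
default picks the mean distance to the clip neutral face and the mean speed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import FEATURE_COLUMNS


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the measure columns.

    Requires at least 3 clips and nonzero variance in every measure; the
    diagonal is exactly 1.
    """
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not cols:
        cols = list(table.columns)
    data = table[cols].astype(float)
    if data.isna().to_numpy().any():
        raise ValueError("feature table contains missing values")
    if len(data) < 3:
        raise ValueError("need at least 3 clips for a correlation matrix")
    dead = [c for c in cols if data[c].nunique() == 1]
    if dead:
        raise ValueError(f"zero-variance measure(s): {dead}")
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_blocks(
    matrix: pd.DataFrame, threshold: float = 0.5
) -> list[tuple[str, ...]]:
    """Partition measures into blocks of mutually correlated variables.

    Blocks are the connected components of the graph whose edges join
    measures with |r| >= threshold.  Returned as tuples of measure names,
    each sorted, and the list ordered by first member.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    labels = list(matrix.columns)
    adj = (matrix.abs().to_numpy() >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    blocks = []
    for k in range(n_comp):
        members = tuple(sorted(labels[i] for i in range(len(labels)) if comp[i] == k))
        blocks.append(members)
    return sorted(blocks, key=lambda b: b[0])


def select_predictors(
    blocks: list[tuple[str, ...]], policy: str = "mean"
) -> tuple[str, str]:
    """Choose one displacement and one motion measure, one per block.

    The default ``mean`` policy returns the mean distance to the clip neutral
    face and the mean speed — mean-aggregated measures are more robust to
    single-frame outliers than the maximum.  ``max`` selects the
    max-aggregated counterparts.
    """
    if len(blocks) < 2:
        raise ValueError(
            "predictor selection needs at least two correlation blocks"
        )
    if policy not in ("mean", "max"):
        raise ValueError(f"unknown selection policy {policy!r}")
    wanted = (f"dist_neutral_{policy}", f"speed_{policy}")
    members = {m for b in blocks for m in b}
    missing = [w for w in wanted if w not in members]
    if missing:
        raise ValueError(f"measures {missing} not present in blocks")
    d_block = next(b for b in blocks if wanted[0] in b)
    s_block = next(b for b in blocks if wanted[1] in b)
    if d_block == s_block:
        raise ValueError(
            "distance and speed measures fall in the same correlation block; "
            "representatives would be collinear"
        )
    return wanted


def save_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional heatmap export of the correlation matrix (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            ax.text(
                j, i, f"{matrix.iloc[i, j]:.2f}",
                ha="center", va="center", fontsize=7,
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
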