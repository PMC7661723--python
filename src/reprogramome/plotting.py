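"""Heat-map rendering of log2-normalized counts for saved runs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def heatmap(
    log2: pd.DataFrame,
    path: str | Path,
    cluster_genes: bool = True,
    cluster_samples: bool = True,
    title: str = "",
) -> None:
    """Render a log2 expression matrix with average-linkage correlation
    clustering on either axis (the convention used for expression panels)."""
    mat = log2.to_numpy(dtype=float)

    def order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 3:
            return np.arange(m.shape[0])
        with np.errstate(invalid="ignore"):
            d = pdist(m, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)
        return hierarchy.leaves_list(hierarchy.linkage(d, method="average"))

    gi = order(mat) if cluster_genes else np.arange(mat.shape[0])
    si = order(mat.T) if cluster_samples else np.arange(mat.shape[1])
    mat = mat[np.ix_(gi, si)]

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * mat.shape[1]), max(4, 0.02 * mat.shape[0]))
    )
    im = ax.imshow(mat, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels([log2.columns[i] for i in si], rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2(normalized + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def state_heatmap(run_dir: Path, path: Path, categories: tuple[str, ...] = ()) -> None:
    """Heat map of a saved run's classified genes (reprogramome by default)."""
    log2 = pd.read_csv(run_dir / "log2_normalized.tsv", sep="\t", index_col=0)
    calls = pd.read_csv(run_dir / "state_calls.tsv", sep="\t").set_index("gene")
    if not categories:
        categories = (
            "activatome",
            "erasome",
            "upreprogramome_enriched",
            "downreprogramome_enriched",
        )
    genes = calls.index[calls["category"].isin(categories)]
    heatmap(log2.loc[genes], path, title=f"{len(genes)} classified TFs")
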