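"""All-pairs (and n-wise) combination screens with clustered matrix export.

For a drug panel, every unordered pair is analysed as a two-drug
combination and a chosen scalar metric — composite-ADR count, mode-1 or
mode-2 GO-node count, or CRM count — fills a symmetric drug × drug
matrix.  The diagonal is 0: composite concepts are undefined for a
single drug.  Rows can be reordered by agglomerative hierarchical
clustering (Euclidean distance, average linkage by default) to expose
blocks of drugs with similar combination risk profiles; the permutation
is part of the exported artefact so orderings are auditable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .combination import CombinationReport, report
from .graph import NodeKind, TripartiteNetwork

__all__ = [
    "METRICS",
    "PairwiseMatrix",
    "pairwise_metric",
    "cluster_order",
    "export_matrix",
    "screen_combinations",
]

#: metric name -> extractor from a CombinationReport
METRICS = {
    "cadr": lambda r: r.n_cadrs,
    "mode1": lambda r: r.n_mode1_go,
    "mode2": lambda r: r.n_mode2_go,
    "crm": lambda r: r.n_crms,
}


@dataclass
class PairwiseMatrix:
    """Symmetric drug × drug matrix of a combination metric."""

    drugs: tuple[str, ...]
    values: np.ndarray
    metric: str
    order: np.ndarray | None = None  # clustering-derived row permutation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.drugs)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match drug list")

    def to_frame(self, clustered: bool = True) -> pd.DataFrame:
        idx = (
            self.order
            if (clustered and self.order is not None)
            else np.arange(len(self.drugs))
        )
        labels = [self.drugs[i] for i in idx]
        return pd.DataFrame(
            self.values[np.ix_(idx, idx)], index=labels, columns=labels
        )


def pairwise_metric(
    net: TripartiteNetwork,
    drugs: Sequence[str],
    metric: str = "cadr",
) -> PairwiseMatrix:
    """Fill the symmetric pair matrix of a combination metric.

    Drugs missing from the network are skipped with a warning listing
    them.  Each unordered pair is analysed once.
    """
    if metric not in METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(METRICS)}"
        )
    drugs = [str(d) for d in drugs]
    missing = [
        d for d in drugs if d not in net or net.kind(d) is not NodeKind.DRUG
    ]
    if missing:
        warnings.warn(
            "skipping drugs not in the network: " + ", ".join(missing),
            stacklevel=2,
        )
    kept = tuple(d for d in drugs if d not in set(missing))
    n = len(kept)
    values = np.zeros((n, n), dtype=int)
    extract = METRICS[metric]
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = extract(report(net, (kept[i], kept[j])))
    return PairwiseMatrix(drugs=kept, values=values, metric=metric)


def cluster_order(
    matrix: "PairwiseMatrix | np.ndarray",
    method: str = "average",
    distance: str = "euclidean",
) -> np.ndarray:
    """Row permutation from agglomerative clustering of the matrix rows.

    Deterministic for a given input.  A degenerate matrix whose rows are
    all identical yields the identity permutation with a warning.
    """
    values = matrix.values if isinstance(matrix, PairwiseMatrix) else np.asarray(matrix)
    n = values.shape[0]
    if n < 2 or values.ndim != 2:
        raise ValueError("clustering needs a matrix of at least 2x2")
    dists = pdist(values.astype(float), metric=distance)
    if np.allclose(dists, 0):
        warnings.warn(
            "all rows identical: returning identity order", stacklevel=2
        )
        perm = np.arange(n)
    else:
        perm = np.asarray(leaves_list(linkage(dists, method=method)))
    if isinstance(matrix, PairwiseMatrix):
        matrix.order = perm
    return perm


def export_matrix(
    matrix: PairwiseMatrix,
    path: "str | Path",
    image: "str | Path | None" = None,
    clustered: bool = True,
) -> None:
    """Write the (optionally permuted) matrix as CSV, plus an optional heatmap.

    The CSV carries drug identifiers as row and column headers.  The
    heatmap rendering is a convenience view, not a contractual output.
    """
    frame = matrix.to_frame(clustered=clustered)
    frame.to_csv(path)
    if image is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, len(frame) * 0.25),) * 2, constrained_layout=True
        )
        im = ax.imshow(frame.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(frame)), frame.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(frame)), frame.index, fontsize=6)
        fig.colorbar(im, ax=ax, label=matrix.metric)
        fig.savefig(image, dpi=150)
        plt.close(fig)


def screen_combinations(
    net: TripartiteNetwork, drugs: Iterable[str], r: int = 2
) -> Iterator[CombinationReport]:
    """Lazily analyse every r-drug combination of a panel.

    An iterator rather than a materialised matrix, since the number of
    combinations grows combinatorially with r.
    """
    drugs = sorted(str(d) for d in drugs)
    for combo in itertools.combinations(drugs, r):
        yield report(net, combo)
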