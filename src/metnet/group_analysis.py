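"""Multi-organism analysis: similarity matrices, clustering, heatmaps.

All unordered organism pairs are compared once and the chosen global
index is assembled into a symmetric similarity matrix with unit
diagonal. Organisms are grouped by complete-linkage agglomerative
clustering on distances d = 1 - s (the minimal monotone transform
keeping d in [0, 1]); dendrograms serialize to Newick with branch
lengths derived from merge heights.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import matplotlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .network_model import TwoLevelNetwork
from .similarity import ComparisonMode, compare_pair

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "INDEX_NAMES",
    "SimilarityMatrix",
    "Dendrogram",
    "similarity_matrix",
    "cluster",
    "render_matrix",
]

INDEX_NAMES = ("psim", "psim_w", "ssim", "csim")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric organisms x organisms table of one global index."""

    organisms: tuple[str, ...]
    index_name: str
    values: np.ndarray

    def missing_pairs(self) -> list[tuple[str, str]]:
        """Organism pairs whose value is undefined (NaN PsimW)."""
        pairs = []
        for i in range(len(self.organisms)):
            for j in range(i + 1, len(self.organisms)):
                if math.isnan(self.values[i, j]):
                    pairs.append((self.organisms[i], self.organisms[j]))
        return pairs

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.organisms)]
        for i, org in enumerate(self.organisms):
            cells = "\t".join(format(v, ".10g") for v in self.values[i])
            lines.append(f"{org}\t{cells}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, index_name: str = "psim") -> "SimilarityMatrix":
        rows = [line.split("\t") for line in text.rstrip("\n").split("\n")]
        organisms = tuple(rows[0][1:])
        values = np.array([[float(c) for c in row[1:]] for row in rows[1:]])
        if values.shape != (len(organisms),) * 2:
            raise ValueError("similarity matrix TSV is not square")
        return cls(organisms=organisms, index_name=index_name, values=values)


def similarity_matrix(
    nets: list[TwoLevelNetwork],
    index_name: str = "psim",
    mode: ComparisonMode = ComparisonMode.SET,
) -> SimilarityMatrix:
    """All-pairs global-index matrix for a set of organisms.

    Each unordered pair is compared once and mirrored; the diagonal is
    1 by definition (an organism compared with itself) and is not
    recomputed.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 organisms")
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    universe = nets[0].universe
    for net in nets[1:]:
        if net.universe != universe:
            raise ValueError(
                f"universe mismatch: {net.org_code!r} differs from {nets[0].org_code!r}"
            )
    n = len(nets)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            cmp = compare_pair(nets[i], nets[j], mode)
            values[i, j] = values[j, i] = cmp.globals_dict()[index_name]
    return SimilarityMatrix(
        organisms=tuple(net.org_code for net in nets),
        index_name=index_name,
        values=values,
    )


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree over organisms, heights on the d = 1 - s scale."""

    organisms: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format over `organisms` order

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two organism groups separated by the root merge."""
        n = len(self.organisms)
        members: dict[int, frozenset[str]] = {
            i: frozenset({org}) for i, org in enumerate(self.organisms)
        }
        for step, (left, right, _, _) in enumerate(self.linkage_matrix):
            members[n + step] = members[int(left)] | members[int(right)]
        last = self.linkage_matrix[-1]
        return members[int(last[0])], members[int(last[1])]

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        n = len(self.organisms)
        heights = {i: 0.0 for i in range(n)}
        labels: dict[int, str] = dict(enumerate(self.organisms))
        for step, (left, right, height, _) in enumerate(self.linkage_matrix):
            node = n + step
            heights[node] = float(height)
            parts = []
            for child in (int(left), int(right)):
                length = heights[node] - heights[child]
                parts.append(f"{labels[child]}:{format(length, '.10g')}")
            labels[node] = "(" + ",".join(sorted(parts)) + ")"
        return labels[n + len(self.linkage_matrix) - 1] + ";\n"


def cluster(matrix: SimilarityMatrix) -> Dendrogram:
    """Complete-linkage hierarchical clustering of a similarity matrix.

    Distances are d = 1 - s. Missing entries (undefined PsimW) are
    rejected with the offending pairs named rather than imputed.
    Organisms are ordered lexicographically before agglomeration so
    equal-distance merges resolve the same way on every run.
    """
    missing = matrix.missing_pairs()
    if missing:
        raise ValueError(f"similarity matrix has missing values for pairs: {missing}")
    if len(matrix.organisms) < 2:
        raise ValueError("need at least 2 organisms to cluster")
    order = sorted(range(len(matrix.organisms)), key=lambda i: matrix.organisms[i])
    organisms = tuple(matrix.organisms[i] for i in order)
    values = matrix.values[np.ix_(order, order)]
    distances = 1.0 - values
    np.fill_diagonal(distances, 0.0)
    condensed = squareform(distances, checks=False)
    link = linkage(condensed, method="complete")
    return Dendrogram(organisms=organisms, linkage_matrix=link)


def render_matrix(
    matrix: SimilarityMatrix,
    out_path=None,
    size: tuple[float, float] = (6.0, 5.0),
    dpi: int = 100,
) -> bytes:
    """Render the similarity matrix as a colour-map heatmap (PNG bytes).

    The scale runs yellow (high similarity) to blue (low), so the main
    diagonal is always yellow. Output bytes are deterministic for fixed
    inputs and size.
    """
    fig, ax = plt.subplots(figsize=size, dpi=dpi)
    try:
        image = ax.imshow(matrix.values, cmap="viridis", vmin=0.0, vmax=1.0)
        ax.set_xticks(range(len(matrix.organisms)), matrix.organisms, rotation=90)
        ax.set_yticks(range(len(matrix.organisms)), matrix.organisms)
        ax.set_title(matrix.index_name)
        fig.colorbar(image, ax=ax)
        buffer = io.BytesIO()
        fig.savefig(buffer, format="png", metadata={"Software": "metnet"})
    finally:
        plt.close(fig)
    data = buffer.getvalue()
    if out_path is not None:
        with open(out_path, "wb") as handle:
            handle.write(data)
    return data
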