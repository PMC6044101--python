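"""Cluster-3.0-style hierarchical clustering and CDT/GTR/ATR output.

The clustering stage mirrors Gene Cluster 3.0's default workflow for
expression heat maps: log2 transform, per-gene median centering, centered
(Pearson) correlation as the similarity metric (distance = 1 - r, in
[0, 2]) and unweighted average linkage (UPGMA) over genes and samples.
The agglomerator is written here rather than delegated, because its merge
bookkeeping, deterministic tie-breaking and similarity-on-merge records are
what the tree files encode; scipy only serves as an independent
cross-check in the test suite.

Output files follow the CDT/GTR/ATR convention consumed by Java TreeView:
``GENE<i>X``/``ARRY<j>X`` ids refer to *original* row/column positions,
``NODE<k>X`` to the k-th merge, and each GTR/ATR line records a merge's two
children and its similarity (1 - average-linkage distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ParseError, UsageError

logger = logging.getLogger("exopattern")


def log2_median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and subtract each row's median (zero-median rows out).

    Requires strictly positive input — guaranteed downstream of the
    low-count replacement floor. Even-length rows use the mean of the two
    central values as the median.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise DomainError(
            "log2 median centering requires strictly positive values; "
            "run the low-count replacement first"
        )
    logged = np.log2(vals)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def centered_correlation_distance(x, y) -> float:
    """1 - Pearson correlation of two vectors; range [0, 2].

    A zero-variance vector has correlation defined as 0 by convention
    (distance 1), with a warning — constant rows carry no shape
    information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError(f"vectors must share one shape, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise UsageError("need length >= 2 to correlate")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    if nx == 0 or ny == 0:
        logger.warning("zero-variance vector in correlation; using r = 0")
        r = 0.0
    else:
        r = float((xc * yc).sum() / (nx * ny))
    return float(min(max(1.0 - r, 0.0), 2.0))


def pairwise_distance_matrix(matrix: pd.DataFrame, axis: str = "genes") -> np.ndarray:
    """Symmetric centered-correlation distance matrix over rows or columns.

    ``axis="genes"`` compares rows, ``axis="samples"`` columns. Zero
    diagonal; entries clipped to [0, 2]. Zero-variance items sit at
    distance 1 from everything.
    """
    if axis == "genes":
        X = matrix.to_numpy(dtype=float)
    elif axis == "samples":
        X = matrix.to_numpy(dtype=float).T
    else:
        raise UsageError(f"axis must be 'genes' or 'samples', got {axis!r}")
    n = X.shape[0]
    if n < 2:
        raise UsageError("need at least 2 items to compute pairwise distances")
    if X.shape[1] < 2:
        raise UsageError("need vectors of length >= 2")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    flat = norms == 0
    if flat.any():
        logger.warning("%d zero-variance rows in distance matrix; r = 0 for them",
                       int(flat.sum()))
    safe = np.where(flat, 1.0, norms)
    Xn = Xc / safe[:, None]
    D = Xn @ Xn.T
    np.negative(D, out=D)
    D += 1.0
    if flat.any():
        D[flat, :] = 1.0
        D[:, flat] = 1.0
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: child node ids and the merge distance."""

    left: int
    right: int
    distance: float

    @property
    def similarity(self) -> float:
        return 1.0 - self.distance


@dataclass
class DendrogramTree:
    """Agglomeration result: n - 1 merges over nodes 0..2n-2.

    Leaves are 0..n-1 (original item positions); the k-th merge creates
    node n + k. ``left < right`` in every merge record.
    """

    n_leaves: int
    merges: Tuple[Merge, ...]

    def validate(self) -> None:
        n = self.n_leaves
        if len(self.merges) != n - 1:
            raise DataError(f"expected {n - 1} merges, got {len(self.merges)}")
        used = set()
        for k, m in enumerate(self.merges):
            for child in (m.left, m.right):
                if child in used:
                    raise DataError(f"node {child} used as a child twice")
                if child >= n + k:
                    raise DataError(f"merge {k} references future node {child}")
                used.add(child)
        if len(used) != 2 * n - 2:
            raise DataError("not every node was used exactly once as a child")

    def leaf_order(self) -> list[int]:
        """Dendrogram leaf ordering: left subtree before right, as merged."""
        n = self.n_leaves
        if n == 1:
            return [0]
        order: list[int] = []
        stack = [2 * n - 2]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                m = self.merges[node - n]
                stack.append(m.right)
                stack.append(m.left)
        return order


def _validate_square(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataError(f"distance matrix must be square, got shape {D.shape}")
    n = D.shape[0]
    if not np.all(np.isfinite(D)):
        raise DataError("distance matrix contains non-finite values")
    if D.min() < 0:
        raise DataError("distance matrix contains negative entries")
    if n <= 1500:
        if not np.allclose(D, D.T, atol=1e-8):
            raise DataError("distance matrix is not symmetric")
    else:  # sampled symmetry check keeps the large-n path cheap
        rng = np.random.default_rng(0)
        ii = rng.integers(0, n, size=2000)
        jj = rng.integers(0, n, size=2000)
        if not np.allclose(D[ii, jj], D[jj, ii], atol=1e-8):
            raise DataError("distance matrix is not symmetric")
    if np.abs(np.diagonal(D)).max() > 1e-8:
        raise DataError("distance matrix has a nonzero diagonal")


def average_linkage(dist, *, overwrite: bool = False) -> DendrogramTree:
    """Unweighted average-linkage (UPGMA) agglomeration of a distance matrix.

    Repeatedly merges the cluster pair with the minimal average
    inter-cluster distance (unweighted mean over all cross pairs,
    maintained by the Lance-Williams update). Ties are broken by the
    lexicographically smallest (left, right) pair of node ids in the
    current numbering. With ``overwrite=True`` the input array is consumed
    in place, halving peak memory for large matrices.

    The nearest-neighbour cache makes the common case ~O(n^2); average
    linkage is reducible, so merge distances are non-decreasing.
    """
    D = np.array(dist, dtype=float, copy=not overwrite)
    _validate_square(D)
    n = D.shape[0]
    if n < 2:
        raise UsageError("need at least 2 items to cluster")
    d = D
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    node = np.arange(n)  # node id currently held by each slot
    active = np.ones(n, dtype=bool)
    rows = np.arange(n)
    nn = d.argmin(axis=1)
    nnd = d[rows, nn]
    merges: list[Merge] = []
    for k in range(n - 1):
        act = np.flatnonzero(active)
        gmin = nnd[act].min()
        # all pairs at the global minimum; tie-break on node ids
        best = None
        for i in act[nnd[act] == gmin]:
            for j in np.flatnonzero(d[i] == gmin):
                a, b = (node[i], node[j]) if node[i] < node[j] else (node[j], node[i])
                if best is None or (a, b) < best[0]:
                    best = ((a, b), i, j)
        (left, right), i, j = best
        si, sj = size[i], size[j]
        new = (si * d[i] + sj * d[j]) / (si + sj)
        new[i] = np.inf
        new[j] = np.inf
        d[i, :] = new
        d[:, i] = new
        d[j, :] = np.inf
        d[:, j] = np.inf
        active[j] = False
        size[i] = si + sj
        node[i] = n + k
        merges.append(Merge(int(left), int(right), float(gmin)))
        if k == n - 2:
            break
        # maintain the nearest-neighbour cache exactly
        nn_i = int(np.argmin(d[i]))
        nn[i], nnd[i] = nn_i, d[i, nn_i]
        act2 = np.flatnonzero(active)
        stale = act2[((nn[act2] == i) | (nn[act2] == j)) & (act2 != i)]
        for r in stale:
            m = int(np.argmin(d[r]))
            nn[r], nnd[r] = m, d[r, m]
        better = act2[(d[act2, i] < nnd[act2]) & (act2 != i)]
        nn[better] = i
        nnd[better] = d[better, i]
    tree = DendrogramTree(n, tuple(merges))
    tree.validate()
    return tree


# --------------------------------------------------------------- file I/O

def _gene_id(i: int) -> str:
    return f"GENE{i}X"


def _arry_id(j: int) -> str:
    return f"ARRY{j}X"


def _node_name(node: int, n: int, leaf_fmt) -> str:
    return leaf_fmt(node) if node < n else f"NODE{node - n + 1}X"


def _write_tree(path: Path, tree: DendrogramTree, leaf_fmt) -> None:
    n = tree.n_leaves
    with open(path, "w") as fh:
        for k, m in enumerate(tree.merges):
            fh.write(
                f"NODE{k + 1}X\t{_node_name(m.left, n, leaf_fmt)}\t"
                f"{_node_name(m.right, n, leaf_fmt)}\t{m.similarity!r}\n"
            )


def write_cdt_gtr(
    matrix: pd.DataFrame,
    gene_tree: DendrogramTree,
    sample_tree: Optional[DendrogramTree],
    out_prefix: str | Path,
) -> list[Path]:
    """Write <prefix>.cdt and <prefix>.gtr (and .atr when a sample tree is given).

    Rows appear in gene-tree leaf order, columns in sample-tree leaf order;
    GENE/ARRY ids always refer to original positions. Data cells use
    Python's shortest round-trip float representation so the CDT can be
    parsed back exactly.
    """
    ng, ns = matrix.shape
    if gene_tree.n_leaves != ng:
        raise UsageError(f"gene tree has {gene_tree.n_leaves} leaves, matrix {ng} rows")
    if sample_tree is not None and sample_tree.n_leaves != ns:
        raise UsageError(
            f"sample tree has {sample_tree.n_leaves} leaves, matrix {ns} columns"
        )
    prefix = Path(out_prefix)
    row_order = gene_tree.leaf_order()
    col_order = sample_tree.leaf_order() if sample_tree is not None else list(range(ns))
    written = []

    gtr = prefix.parent / (prefix.name + ".gtr")
    _write_tree(gtr, gene_tree, _gene_id)
    written.append(gtr)
    if sample_tree is not None:
        atr = prefix.parent / (prefix.name + ".atr")
        _write_tree(atr, sample_tree, _arry_id)
        written.append(atr)

    cdt = prefix.parent / (prefix.name + ".cdt")
    vals = matrix.to_numpy()
    ids = list(matrix.index.astype(str))
    cols = list(matrix.columns.astype(str))
    with open(cdt, "w") as fh:
        fh.write("\t".join(["GID", "UNIQID", "NAME", "GWEIGHT"]
                           + [cols[j] for j in col_order]) + "\n")
        if sample_tree is not None:
            fh.write("\t".join(["AID", "", "", ""]
                               + [_arry_id(j) for j in col_order]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] + ["1"] * ns) + "\n")
        for i in row_order:
            cells = [repr(float(vals[i, j])) for j in col_order]
            fh.write("\t".join([_gene_id(i), ids[i], ids[i], "1"] + cells) + "\n")
    written.append(cdt)
    return written


def read_cdt(path: str | Path) -> pd.DataFrame:
    """Parse a CDT back into a DataFrame (rows in file order)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["GID", "UNIQID", "NAME", "GWEIGHT"]:
            raise ParseError(f"{path}: not a CDT header: {header[:4]}")
        samples = header[4:]
        rows = []
        ids = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] in ("AID", "EWEIGHT"):
                continue
            ids.append(fields[1])
            rows.append([float(v) for v in fields[4:]])
    return pd.DataFrame(rows, index=ids, columns=samples)


def heatmap(centered: pd.DataFrame, path: str | Path, units: float = 3.0) -> None:
    """Optional heat-map export: one colour-bar unit per log2 unit.

    Green-black-red diverging scale saturating at +-``units`` log2 units,
    matching the Java TreeView convention. Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("gbr", ["#00ff00", "#000000", "#ff0000"])
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(centered.to_numpy(), aspect="auto", cmap=cmap,
                   vmin=-units, vmax=units, interpolation="nearest")
    ax.set_xticks(range(centered.shape[1]))
    ax.set_xticklabels(centered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    cbar = fig.colorbar(im, ax=ax, ticks=range(-int(units), int(units) + 1))
    cbar.set_label("log2 units from gene median")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
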