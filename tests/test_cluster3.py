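"""Centering, correlation distance, UPGMA agglomeration, CDT/GTR files."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exopattern import (
    DendrogramTree,
    Merge,
    average_linkage,
    centered_correlation_distance,
    log2_median_center,
    pairwise_distance_matrix,
    read_cdt,
    write_cdt_gtr,
)
from exopattern.errors import DataError, DomainError, UsageError


def naive_upgma(D):
    """O(n^3) reference: rescan all cluster pairs, averaging original distances."""
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    for _ in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            d = float(np.mean([D[x, y] for x in members[a] for y in members[b]]))
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        members[nxt] = members.pop(a) + members.pop(b)
        nxt += 1
    return merges


def random_distance(rng, n, m=6):
    X = rng.normal(size=(n, m))
    return pairwise_distance_matrix(pd.DataFrame(X), axis="genes")


# --------------------------------------------------------------- centering

def test_median_centering_examples():
    mat = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]])
    out = log2_median_center(mat)
    assert out.iloc[0].tolist() == [0.0, 0.0, 0.0]
    assert out.iloc[1].tolist() == [-1.0, 0.0, 1.0]


def test_median_centering_even_row_uses_central_mean():
    out = log2_median_center(pd.DataFrame([[1.0, 2.0, 4.0, 8.0]]))
    # log2 -> [0,1,2,3], median 1.5
    assert out.iloc[0].tolist() == [-1.5, -0.5, 0.5, 1.5]


def test_median_centering_rejects_nonpositive():
    with pytest.raises(DomainError):
        log2_median_center(pd.DataFrame([[1.0, 0.0]]))


# --------------------------------------------------------------- distances

def test_distance_closed_forms():
    x = np.array([1.0, 2.0, 3.0])
    assert centered_correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)
    assert centered_correlation_distance(x, -x) == pytest.approx(2.0, abs=1e-12)
    assert centered_correlation_distance(x, [1.0, 3.0, 2.0]) == pytest.approx(0.5, abs=1e-12)


def test_distance_zero_variance_convention():
    assert centered_correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 1.0


def test_distance_length_mismatch():
    with pytest.raises(UsageError):
        centered_correlation_distance([1.0, 2.0], [1.0, 2.0, 3.0])


def test_distance_affine_invariance():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 8))
    base = centered_correlation_distance(x, y)
    assert centered_correlation_distance(3.5 * x + 2.0, y) == pytest.approx(base, abs=1e-12)
    assert centered_correlation_distance(x, 0.25 * y - 7.0) == pytest.approx(base, abs=1e-12)


def test_pairwise_matches_scalar_and_axis_contract():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.normal(size=(10, 6)))
    D = pairwise_distance_matrix(mat, axis="genes")
    assert D.shape == (10, 10)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert D.min() >= 0.0 and D.max() <= 2.0
    for i in range(10):
        for j in range(i + 1, 10):
            expected = centered_correlation_distance(mat.iloc[i], mat.iloc[j])
            assert D[i, j] == pytest.approx(expected, abs=1e-12)
    Dt = pairwise_distance_matrix(mat.T, axis="samples")
    assert np.array_equal(D, Dt)


def test_pairwise_duplicate_rows_have_zero_distance():
    mat = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]])
    D = pairwise_distance_matrix(mat, axis="genes")
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)  # perfectly correlated


# --------------------------------------------------------------- linkage

def test_two_leaves_single_merge():
    D = np.array([[0.0, 0.7], [0.7, 0.0]])
    tree = average_linkage(D)
    assert tree.merges == (Merge(0, 1, 0.7),)
    assert tree.leaf_order() == [0, 1]


def test_hand_agglomeration_three_items():
    # d(A,B)=1, d(A,C)=4, d(B,C)=5: merge (A,B) at 1 then with C at (4+5)/2
    D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = average_linkage(D)
    assert tree.merges[0] == Merge(0, 1, 1.0)
    assert tree.merges[1].distance == pytest.approx(4.5, abs=1e-12)
    assert (tree.merges[1].left, tree.merges[1].right) == (2, 3)


def test_tie_break_prefers_smallest_node_ids():
    # d(0,1) == d(0,2) == 1: the (0,1) merge must win
    D = np.array([
        [0.0, 1.0, 1.0, 4.0],
        [1.0, 0.0, 2.0, 4.0],
        [1.0, 2.0, 0.0, 4.0],
        [4.0, 4.0, 4.0, 0.0],
    ])
    tree = average_linkage(D)
    assert (tree.merges[0].left, tree.merges[0].right) == (0, 1)
    assert (tree.merges[1].left, tree.merges[1].right) == (2, 4)


def test_linkage_matches_naive_oracle_and_scipy():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(77)
    for _ in range(50):
        n = int(rng.integers(2, 16))
        D = random_distance(rng, n)
        tree = average_linkage(D.copy())
        ref = naive_upgma(D)
        for merge, (a, b, d) in zip(tree.merges, ref):
            assert (merge.left, merge.right) == (a, b)
            assert merge.distance == pytest.approx(d, abs=1e-9)
        Z = linkage(squareform(D, checks=False), method="average")
        assert np.allclose(sorted(m.distance for m in tree.merges),
                           sorted(Z[:, 2]), atol=1e-9)


def test_merge_heights_monotone():
    rng = np.random.default_rng(78)
    D = random_distance(rng, 40)
    tree = average_linkage(D)
    heights = [m.distance for m in tree.merges]
    assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_block_structure_recovers_clades():
    # two groups of mutually perfectly correlated rows; cross-group merge last
    rng = np.random.default_rng(79)
    base1 = rng.normal(size=6)
    base2 = -base1 + rng.normal(scale=0.3, size=6)
    rows = [2.0 * base1 + 1, 0.5 * base1, base1 + 3] + [base2, 3.0 * base2 - 2]
    D = pairwise_distance_matrix(pd.DataFrame(rows), axis="genes")
    tree = average_linkage(D)
    order = tree.leaf_order()
    first = {0, 1, 2}
    pos = [order.index(i) for i in first]
    assert max(pos) - min(pos) == 2  # group 1 contiguous -> a clade
    last = tree.merges[-1]
    # the final merge joins the two blocks
    assert last.distance == max(m.distance for m in tree.merges)


def test_tree_invariant_under_rowwise_affine_maps():
    rng = np.random.default_rng(80)
    mat = pd.DataFrame(rng.normal(size=(12, 6)))
    scaled = mat.mul(rng.uniform(0.5, 4.0, size=12), axis=0).add(
        rng.uniform(-3, 3, size=12), axis=0)
    t1 = average_linkage(pairwise_distance_matrix(mat, axis="genes"))
    t2 = average_linkage(pairwise_distance_matrix(scaled, axis="genes"))
    assert [(m.left, m.right) for m in t1.merges] == [(m.left, m.right) for m in t2.merges]
    assert np.allclose([m.distance for m in t1.merges],
                       [m.distance for m in t2.merges], atol=1e-9)


def test_linkage_rejects_bad_matrices():
    with pytest.raises(DataError):
        average_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(DataError):
        average_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative


def test_tree_validate_catches_reuse():
    bad = DendrogramTree(3, (Merge(0, 1, 0.1), Merge(0, 3, 0.2)))
    with pytest.raises(DataError):
        bad.validate()


# --------------------------------------------------------------- files

@pytest.fixture
def clustered(tmp_path):
    rng = np.random.default_rng(90)
    mat = pd.DataFrame(
        rng.normal(size=(7, 4)),
        index=[f"g{i}" for i in range(7)],
        columns=[f"s{j}" for j in range(4)],
    )
    gene_tree = average_linkage(pairwise_distance_matrix(mat, axis="genes"))
    sample_tree = average_linkage(pairwise_distance_matrix(mat, axis="samples"))
    paths = write_cdt_gtr(mat, gene_tree, sample_tree, tmp_path / "out")
    return mat, gene_tree, sample_tree, {p.suffix: p for p in paths}


def test_gtr_has_n_minus_one_merges_with_similarity(clustered):
    _, gene_tree, _, paths = clustered
    lines = paths[".gtr"].read_text().splitlines()
    assert len(lines) == 6
    for line, merge in zip(lines, gene_tree.merges):
        fields = line.split("\t")
        assert fields[0].startswith("NODE") and fields[0].endswith("X")
        assert float(fields[3]) == 1.0 - merge.distance


def test_cdt_round_trip_recovers_leaf_ordered_matrix(clustered):
    mat, gene_tree, sample_tree, paths = clustered
    parsed = read_cdt(paths[".cdt"])
    expected = mat.iloc[gene_tree.leaf_order(), sample_tree.leaf_order()]
    assert list(parsed.index) == list(expected.index)
    assert list(parsed.columns) == list(expected.columns)
    assert np.array_equal(parsed.to_numpy(), expected.to_numpy())  # exact


def test_cdt_minimal_two_by_two(tmp_path):
    mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["x", "y"])
    tree = average_linkage(pairwise_distance_matrix(mat, axis="genes"))
    paths = write_cdt_gtr(mat, tree, None, tmp_path / "mini")
    by_suffix = {p.suffix: p for p in paths}
    assert ".atr" not in by_suffix
    assert len(by_suffix[".gtr"].read_text().splitlines()) == 1
    body = [l for l in by_suffix[".cdt"].read_text().splitlines()
            if l.startswith("GENE")]
    assert len(body) == 2


def test_cdt_dimension_mismatch_rejected(tmp_path):
    mat = pd.DataFrame(np.ones((3, 2)))
    tree = average_linkage(np.array([[0.0, 0.5], [0.5, 0.0]]))
    with pytest.raises(UsageError):
        write_cdt_gtr(mat, tree, None, tmp_path / "bad")
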