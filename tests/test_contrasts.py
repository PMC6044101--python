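"""Fold-change sign convention, splicing index, rescue-pattern classifier."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exopattern import (
    CHAINED,
    VS_CONTROL,
    CountMatrix,
    QuantifyParams,
    SimulationConfig,
    assign_pattern_truth,
    classify_pattern,
    classify_pattern_frame,
    contrast_table,
    generate_feature_table,
    group_value,
    pattern_gene_lists,
    quantify_counts,
    rescue_triple,
    signed_fold_change,
    simulate_counts,
    splice_index_table,
    splicing_index,
)
from exopattern.contrasts import RESCUE_COLUMNS
from exopattern.errors import DomainError
from exopattern.quantify import ExpressionMatrix


def _expr_from_group_rpkms(rpkms: dict[str, float], n_features: int = 1):
    """Single-tissue ExpressionMatrix with one sample per group."""
    samples = pd.DataFrame({
        "sample": [f"brain_{g}" for g in rpkms],
        "group": list(rpkms),
        "tissue": "brain",
        "library_size": 10**6,
    }).set_index("sample")
    ids = [f"f{i}" for i in range(n_features)]
    vals = pd.DataFrame(
        {f"brain_{g}": [v] * n_features for g, v in rpkms.items()},
        index=pd.Index(ids, name="feature_id"),
    )
    expr = ExpressionMatrix(
        values=vals, replaced=vals.astype(bool) & False,
        length_bp=pd.Series(100, index=vals.index),
        library_size=samples["library_size"],
    )
    return expr, samples


def test_group_value_is_mean_of_group_columns():
    expr, samples = _expr_from_group_rpkms({"C": 2.0, "T": 4.0})
    extra = expr.values.copy()
    extra["brain_C2"] = 4.0
    samples2 = pd.concat([samples, pd.DataFrame(
        {"group": ["C"], "tissue": ["brain"], "library_size": [10**6]},
        index=pd.Index(["brain_C2"], name="sample"))])
    expr2 = dataclasses.replace(expr, values=extra)
    assert group_value(expr2, samples2, "C").iloc[0] == 3.0  # mean(2, 4)
    assert group_value(expr2, samples2, "T").iloc[0] == 4.0  # single sample


@pytest.mark.parametrize("num,den,expected", [(2, 2, 1.0), (4, 2, 2.0), (2, 4, -2.0)])
def test_signed_fold_change_examples(num, den, expected):
    assert signed_fold_change(num, den) == expected


def test_signed_fold_change_rejects_nonpositive():
    with pytest.raises(DomainError):
        signed_fold_change(0.0, 1.0)
    with pytest.raises(DomainError):
        signed_fold_change(1.0, -2.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    a=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False),
    b=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False),
)
def test_signed_fold_change_contract(a, b):
    fc = signed_fold_change(a, b)
    assert abs(fc) >= 1.0
    if a == b:
        assert fc == 1.0
    else:
        assert signed_fold_change(b, a) == -fc  # exact, by branch-wise division


def test_contrast_table_chained_and_vs_control():
    expr, samples = _expr_from_group_rpkms({"C": 1.0, "T": 4.0, "TE": 1.0, "TEdM": 4.0})
    chained = contrast_table(expr, samples, CHAINED)
    assert chained.iloc[0].tolist() == [4.0, -4.0, 4.0]
    vs = contrast_table(expr, samples, VS_CONTROL)
    assert vs.iloc[0].tolist() == [4.0, 1.0, 4.0]


def test_contrast_table_flat_feature_is_all_ones():
    expr, samples = _expr_from_group_rpkms({"C": 3.0, "T": 3.0, "TE": 3.0, "TEdM": 3.0})
    table = contrast_table(expr, samples, CHAINED)
    assert table.iloc[0].tolist() == [1.0, 1.0, 1.0]


def test_rescue_triple_from_vs_control_matches_chained():
    expr, samples = _expr_from_group_rpkms({"C": 2.0, "T": 8.0, "TE": 2.0, "TEdM": 16.0})
    direct = rescue_triple(contrast_table(expr, samples, CHAINED), CHAINED)
    derived = rescue_triple(contrast_table(expr, samples, VS_CONTROL), VS_CONTROL)
    assert np.allclose(direct.to_numpy(), derived.to_numpy(), rtol=1e-12)


@pytest.mark.parametrize(
    "exon,gene,expected",
    [(5.0, 5.0, 1.0), (10.0, 5.0, 2.0), (0.0, 5.0, 0.0)],
)
def test_splicing_index_formula(exon, gene, expected):
    assert splicing_index(exon, gene) == expected


def test_splicing_index_zero_gene_is_nan_not_inf():
    assert np.isnan(splicing_index(3.0, 0.0))


@pytest.mark.parametrize(
    "triple,expected",
    [
        ((4.0, -4.0, 4.0), 1),
        ((-4.0, 4.0, -4.0), -1),
        ((4.0, -1.5, 4.0), 0),   # fails the twofold filter
        ((4.0, 4.0, 4.0), 0),    # wrong direction on the rescue contrast
        ((1.0, -4.0, 4.0), 0),   # exactly +-1 counts as no change
    ],
)
def test_classifier_rule(triple, expected):
    assert classify_pattern(*triple, min_fold=2.0) == expected


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.tuples(*[st.floats(1.0, 50.0) for _ in range(3)]),
       st.tuples(*[st.booleans() for _ in range(3)]))
def test_classifier_symmetry_under_direction_flip(mags, signs):
    f = [m if s else -m for m, s in zip(mags, signs)]
    flipped = [-x for x in f]
    a = classify_pattern(*f)
    b = classify_pattern(*flipped)
    assert a == -b


def test_label_implies_twofold_pass():
    frame = pd.DataFrame(
        np.column_stack([
            np.random.default_rng(3).uniform(-9, 9, size=(300, 3)),
        ]).reshape(300, 3),
        columns=list(RESCUE_COLUMNS),
    )
    # force |v| >= 1 like a real contrast table
    vals = frame.to_numpy()
    vals = np.where(np.abs(vals) < 1, np.sign(vals) + (vals == 0), vals)
    frame = pd.DataFrame(vals, columns=list(RESCUE_COLUMNS))
    calls = classify_pattern_frame(frame)
    assert (calls.loc[calls["label"] != 0, "passed_twofold"]).all()


def test_pattern_lists_empty_table():
    calls = pattern_gene_lists(pd.DataFrame(), CHAINED)
    assert len(calls) == 0


def test_pattern_lists_sorted_by_rescue_magnitude_then_id():
    table = pd.DataFrame(
        {
            "T_vs_C": [4.0, 4.0, 4.0],
            "TE_vs_T": [-8.0, -3.0, -8.0],
            "TEdM_vs_TE": [4.0, 4.0, 4.0],
        },
        index=["b", "a", "a0"],
    )
    calls = pattern_gene_lists(table, CHAINED)
    assert list(calls.index) == ["a0", "b", "a"]


def _noiseless_run(n=400, seed=29):
    cfg = SimulationConfig(n_features=n, tissues=("brain",), seed=seed, noise="none")
    features = generate_feature_table(cfg)
    truth = assign_pattern_truth(features, cfg)
    counts = simulate_counts(features, truth, cfg)
    top = CountMatrix(counts.counts.loc[features.top_level.index], counts.samples)
    expr = quantify_counts(top, features, QuantifyParams())
    table = contrast_table(expr, counts.samples, CHAINED)
    calls = pattern_gene_lists(table, CHAINED)
    return features, truth, counts, calls


def test_noiseless_recovery_matches_truth_exactly():
    features, truth, _, calls = _noiseless_run()
    top = features.top_level.index
    assert set(calls.index) == set(top)
    got = calls["label"].reindex(top)
    assert (got == truth.labels(top)).all()


def test_pattern_list_sizes_equal_bruteforce_enumeration():
    _, _, _, calls = _noiseless_run()
    f1, f2, f3 = (calls[c] for c in RESCUE_COLUMNS)
    up = ((f1 > 1) & (f2 < -1) & (f3 > 1) & (f2.abs() >= 2)).sum()
    down = ((f1 < -1) & (f2 > 1) & (f3 < -1) & (f2.abs() >= 2)).sum()
    assert (calls["label"] == 1).sum() == up
    assert (calls["label"] == -1).sum() == down


def test_splice_index_length_weighted_average_is_one(small_dataset, small_expression):
    # exon counts sum to the gene count, so the length-weighted mean of
    # exon splicing indices is exactly 1 wherever the gene has reads
    features, _, counts = small_dataset
    from exopattern import rpkm_matrix

    expr_all = rpkm_matrix(counts, features)
    si = splice_index_table(expr_all.values, features)
    exons = features.exons
    weights = exons["length_bp"] / exons.groupby("parent_gene_id")["length_bp"].transform("sum")
    sample = counts.samples.index[0]
    weighted = (si[sample] * weights).groupby(exons["parent_gene_id"]).sum()
    gene_has_reads = counts.counts.loc[weighted.index, sample] > 0
    assert np.allclose(weighted[gene_has_reads], 1.0, atol=1e-9)
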