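"""Recovery benchmarking of the rescue-pattern classifier on synthetic data."""

from __future__ import annotations

import numpy as np

from .config import CHAINED, QuantifyParams, SimulationConfig
from .contrasts import contrast_table, pattern_gene_lists
from .quantify import quantify_counts
from .synthcounts import (
    CountMatrix,
    assign_pattern_truth,
    generate_feature_table,
    simulate_counts,
)


def pattern_recovery(config: SimulationConfig,
                     params: QuantifyParams | None = None,
                     min_fold: float = 2.0) -> dict:
    """Simulate, quantify, classify and score calls against injected truth.

    Features dropped by the retention filter count as negatives (label 0).
    Sensitivity is the fraction of injected +-1 features called with the
    matching sign; specificity the fraction of null features not called.
    """
    params = params or QuantifyParams()
    features = generate_feature_table(config)
    truth = assign_pattern_truth(features, config)
    counts = simulate_counts(features, truth, config)
    top_index = features.top_level.index
    top = CountMatrix(counts.counts.loc[top_index], counts.samples)
    expr = quantify_counts(top, features, params)
    calls_by_tissue = {}
    for tissue in dict.fromkeys(counts.samples["tissue"]):
        samples = counts.samples[counts.samples["tissue"] == tissue]
        table = contrast_table(expr, samples, CHAINED)
        calls_by_tissue[tissue] = pattern_gene_lists(table, CHAINED, min_fold=min_fold)

    # score against truth, pooling tissues (the pattern is injected in both)
    true = truth.labels(top_index)
    tp = fn = fp = tn = 0
    n_up = n_down = 0
    rescue_mags = []
    for calls in calls_by_tissue.values():
        called = calls["label"].reindex(top_index).fillna(0).astype(int)
        pos = true != 0
        tp += int((called[pos] == true[pos]).sum())
        fn += int((called[pos] != true[pos]).sum())
        fp += int((called[~pos] != 0).sum())
        tn += int((called[~pos] == 0).sum())
        n_up += int((calls["label"] == 1).sum())
        n_down += int((calls["label"] == -1).sum())
        hit = calls.index[(calls["label"] != 0)
                          & (calls["label"] == true.reindex(calls.index))]
        rescue_mags.extend(np.abs(calls.loc[hit, "f_rescue"]).tolist())
    return {
        "n_features": int(len(top_index)),
        "n_injected": int((true != 0).sum()),
        "n_retained": int(expr.retained.sum()),
        "replacement_value": float(expr.replacement_value),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "n_up_calls": n_up,
        "n_down_calls": n_down,
        "mean_rescue_fold": float(np.mean(rescue_mags)) if rescue_mags else float("nan"),
    }
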