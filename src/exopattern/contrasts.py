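"""Signed fold changes, splicing index, and rescue-pattern classification.

Fold changes are expressed as the negative reciprocal: a ratio r >= 1 is
reported as +r, a ratio r < 1 as -1/r, so the magnitude is always >= 1 and
the sign encodes direction (+1.0 means no change). The rescue pattern of
interest is a feature that goes up with injury (T vs C), back down with
exosome treatment (TE vs T), and up again when the exosomes are depleted of
their lncRNA cargo (TEdM vs TE) — labeled +1 — or the mirrored pattern
(-1), with a minimum fold-change filter on the treatment-response contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ContrastScheme
from .errors import ConfigurationError, DataError, DomainError, UsageError
from .features import FeatureTable
from .quantify import ExpressionMatrix

logger = logging.getLogger("exopattern")

RESCUE_COLUMNS = ("f_injury", "f_rescue", "f_depleted")


def group_value(expr: ExpressionMatrix, samples: pd.DataFrame, group: str) -> pd.Series:
    """Per-feature expression for one group: the mean over the group's samples.

    With one pooled library per group (the default design) this is the
    identity on that column.
    """
    cols = samples.index[samples["group"] == group]
    if len(cols) == 0:
        raise ConfigurationError(f"group {group!r} has no samples")
    return expr.values[cols].mean(axis=1)


def signed_fold_change(numerator: float, denominator: float) -> float:
    """Negative-reciprocal signed fold change of two positive expression values.

    Computed branch-wise (num/den or -(den/num)) so that antisymmetry
    fc(a, b) == -fc(b, a) holds exactly in floating point.
    """
    if numerator <= 0 or denominator <= 0:
        raise DomainError(
            "fold change requires strictly positive values; run the "
            "low-count replacement first"
        )
    if numerator >= denominator:
        return numerator / denominator
    return -(denominator / numerator)


def _signed(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(num >= den, num / den, -(den / num))


def _signed_to_ratio(fc: np.ndarray) -> np.ndarray:
    """Invert the sign convention: signed fold change -> plain ratio."""
    return np.where(fc >= 0, fc, -1.0 / fc)


def contrast_table(
    expr: ExpressionMatrix, samples: pd.DataFrame, scheme: ContrastScheme
) -> pd.DataFrame:
    """Signed fold change per retained feature and contrast.

    Features dropped by the retention filter are absent from the result.
    Requires a post-replacement matrix (strictly positive group values).
    """
    values = expr.retained_values()
    out = {}
    gv = {}
    for c in scheme.contrasts:
        for g in (c.numerator, c.denominator):
            if g not in gv:
                gv[g] = group_value(expr, samples, g).loc[values.index]
    for c in scheme.contrasts:
        num, den = gv[c.numerator].to_numpy(), gv[c.denominator].to_numpy()
        bad = (num <= 0) | (den <= 0)
        if bad.any():
            fid = values.index[bad][0]
            raise DomainError(
                f"feature {fid!r}: nonpositive group value in contrast {c.name}; "
                "run the low-count replacement first"
            )
        out[c.name] = _signed(num, den)
    return pd.DataFrame(out, index=values.index)


def splicing_index(exon_rpkm: float, gene_rpkm: float) -> float:
    """Exon RPKM divided by its parent gene's RPKM.

    Undefined (NaN, with a warning) when the gene RPKM is zero — never
    infinity.
    """
    if exon_rpkm < 0 or gene_rpkm < 0:
        raise DomainError("RPKM values must be nonnegative")
    if gene_rpkm == 0:
        logger.warning("splicing index undefined: gene RPKM is 0")
        return float("nan")
    return exon_rpkm / gene_rpkm


def splice_index_table(rpkm_values: pd.DataFrame, features: FeatureTable) -> pd.DataFrame:
    """Splicing index for every (exon, sample) from a raw RPKM matrix.

    Entries where the parent gene's RPKM is zero are NaN (one warning is
    emitted for the whole table). Result is indexed by exon id with a
    ``parent_gene_id`` column followed by one column per sample.
    """
    exons = features.exons
    missing = exons.index.difference(rpkm_values.index)
    if len(missing):
        raise DataError(f"exon {missing[0]!r} missing from the RPKM matrix")
    gene_vals = rpkm_values.loc[exons["parent_gene_id"]].to_numpy()
    exon_vals = rpkm_values.loc[exons.index].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(gene_vals > 0, exon_vals / np.where(gene_vals > 0, gene_vals, 1.0), np.nan)
    if (gene_vals == 0).any():
        logger.warning("splicing index undefined for %d entries (gene RPKM = 0)",
                       int((gene_vals == 0).sum()))
    out = pd.DataFrame(si, index=exons.index, columns=rpkm_values.columns)
    out.insert(0, "parent_gene_id", exons["parent_gene_id"])
    return out


def rescue_triple(table: pd.DataFrame, scheme: ContrastScheme) -> pd.DataFrame:
    """Chained signed triple (T/C, TE/T, TEdM/TE) from a contrast table.

    For the ``chained`` scheme this is the table itself; for ``vs_control``
    the chained ratios are derived by dividing consecutive vs-control
    ratios.
    """
    cols = scheme.contrast_names
    if scheme.name == "chained":
        out = table[cols].copy()
    elif scheme.name == "vs_control":
        r = np.column_stack([_signed_to_ratio(table[c].to_numpy()) for c in cols])
        f1 = _signed(r[:, 0], np.ones(len(table)))
        f2 = _signed(r[:, 1], r[:, 0])
        f3 = _signed(r[:, 2], r[:, 1])
        out = pd.DataFrame(np.column_stack([f1, f2, f3]), index=table.index)
    else:
        raise ConfigurationError(f"no rescue-triple rule for scheme {scheme.name!r}")
    out.columns = list(RESCUE_COLUMNS)
    return out


def classify_pattern(f1: float, f2: float, f3: float, min_fold: float = 2.0,
                     twofold_scope: str = "rescue") -> int:
    """Label one feature +1, -1 or 0 from its chained signed fold changes.

    +1 requires up with injury (f1 > 1), down with treatment (f2 < -1) and
    up again on cargo depletion (f3 > 1); -1 the mirror. Values of exactly
    +-1 are "no change" and force 0. The minimum-fold filter applies to the
    treatment-response contrast f2 (scope "rescue", default) or to all
    three (scope "all").
    """
    arr = classify_pattern_frame(
        pd.DataFrame([[f1, f2, f3]], columns=list(RESCUE_COLUMNS)),
        min_fold=min_fold, twofold_scope=twofold_scope,
    )
    return int(arr["label"].iloc[0])


def classify_pattern_frame(triple: pd.DataFrame, min_fold: float = 2.0,
                           twofold_scope: str = "rescue") -> pd.DataFrame:
    """Vectorized classifier over a rescue-triple frame.

    Returns a frame with the three fold changes, ``passed_twofold`` and the
    ``label``; label != 0 implies passed_twofold.
    """
    if list(triple.columns) != list(RESCUE_COLUMNS):
        raise UsageError(f"expected columns {RESCUE_COLUMNS}, got {list(triple.columns)}")
    if min_fold < 1:
        raise UsageError(f"min_fold must be >= 1, got {min_fold}")
    f1 = triple["f_injury"].to_numpy()
    f2 = triple["f_rescue"].to_numpy()
    f3 = triple["f_depleted"].to_numpy()
    if twofold_scope == "rescue":
        passed = np.abs(f2) >= min_fold
    elif twofold_scope == "all":
        passed = (np.abs(f1) >= min_fold) & (np.abs(f2) >= min_fold) & (np.abs(f3) >= min_fold)
    else:
        raise UsageError(f"unknown twofold_scope {twofold_scope!r}")
    up = (f1 > 1) & (f2 < -1) & (f3 > 1) & passed
    down = (f1 < -1) & (f2 > 1) & (f3 < -1) & passed
    label = np.where(up, 1, np.where(down, -1, 0))
    out = triple.copy()
    out["passed_twofold"] = passed
    out["label"] = label
    return out


def pattern_gene_lists(table: pd.DataFrame, scheme: ContrastScheme,
                       min_fold: float = 2.0, twofold_scope: str = "rescue") -> pd.DataFrame:
    """One pattern call per feature of a contrast table.

    The result is sorted for export: |f_rescue| descending, ties broken by
    feature id, so the +1/-1 lists are deterministic.
    """
    if len(table) == 0:
        return pd.DataFrame(
            columns=list(RESCUE_COLUMNS) + ["passed_twofold", "label"]
        )
    triple = rescue_triple(table, scheme)
    calls = classify_pattern_frame(triple, min_fold=min_fold, twofold_scope=twofold_scope)
    order = pd.DataFrame({
        "mag": -calls["f_rescue"].abs(),
        "fid": calls.index,
    }, index=calls.index).sort_values(["mag", "fid"], kind="mergesort")
    return calls.loc[order.index]


@dataclass
class PatternCall:
    """Exported +1 / -1 feature lists for one tissue."""

    calls: pd.DataFrame

    @property
    def up(self) -> list[str]:
        return list(self.calls.index[self.calls["label"] == 1])

    @property
    def down(self) -> list[str]:
        return list(self.calls.index[self.calls["label"] == -1])

    def write_lists(self, up_path, down_path) -> None:
        for path, ids in ((up_path, self.up), (down_path, self.down)):
            with open(path, "w") as fh:
                fh.writelines(f"{fid}\n" for fid in ids)
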