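"""Synthetic annotation, ground-truth labels and negative-binomial counts.

Emulates the pooled four-group (C, T, TE, TEdM), two-tissue RNA-seq design:
one library per group and tissue, coding genes with exon structure plus
miRNA/snoRNA/lncRNA biotypes, and a configurable fraction of features that
carry the "rescue" expression pattern. A +1 feature is elevated in the
injured, unrescued groups (T, TEdM) and at baseline in C and TE; a -1
feature shows the mirrored pattern. Expected counts follow

    mu = expected_RPKM * length_kb * library_size / 1e6

and counts are drawn negative-binomially with variance mu + d * mu**2
(d = 0 degenerates to Poisson; ``noise="none"`` yields round(mu) exactly).
Gene counts are drawn at the gene level and split across exons
multinomially in proportion to exon length, so exon count totals equal the
gene count and the splicing index is exercisable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError, DataError, SimulationError
from .features import COLUMNS, FeatureTable

# rng substream tags: one per operation so each is deterministic in isolation
_RNG_FEATURES = 11
_RNG_TRUTH = 13
_RNG_BASELINE = 17
_RNG_COUNTS = 19
_RNG_EXONS = 23


@dataclass
class SyntheticTruth:
    """Per-feature injected pattern label (+1 / -1 / 0) and applied effect size.

    Exon rows inherit their parent gene's label (they physically carry the
    effect); label-count accounting is over top-level features.
    """

    df: pd.DataFrame  # index feature_id; columns: label, effect_size_applied

    def labels(self, top_level_index: pd.Index) -> pd.Series:
        return self.df.loc[top_level_index, "label"]


@dataclass
class CountMatrix:
    """Integer counts per feature x sample with the sample sidecar.

    ``samples`` carries group, tissue and library_size (total mapped reads,
    which may exceed the in-feature column sum: libraries contain reads
    outside the annotated feature set).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def validate(self, features: FeatureTable | None = None) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise DataError("counts columns and sample sidecar are misaligned")
        if (self.counts.values < 0).any():
            raise DataError("negative counts")
        if features is not None and not self.counts.index.equals(features.df.index):
            raise DataError("counts rows do not match the feature table")
        colsum = self.counts.sum(axis=0)
        lib = self.samples["library_size"]
        over = colsum > lib
        if over.any():
            bad = over.index[over][0]
            raise DataError(
                f"sample {bad!r}: in-feature reads {colsum[bad]} exceed "
                f"library_size {lib[bad]}"
            )

    def library_sizes(self) -> pd.Series:
        return self.samples["library_size"]


def generate_feature_table(config: SimulationConfig) -> FeatureTable:
    """Deterministically generate the synthetic annotation.

    Biotype counts are floor(fraction * n) with the rounding remainder
    assigned to 'gene'. Genes are laid out on one chromosome with
    non-overlapping exons separated by short introns, so a gene's union
    length equals the sum of its exon lengths.
    """
    rng = np.random.default_rng([config.seed, _RNG_FEATURES])
    n = config.n_features
    counts = {bt: int(np.floor(config.biotype_fractions[bt] * n)) for bt in
              ("gene", "miRNA", "snoRNA", "lncRNA")}
    counts["gene"] += n - sum(counts.values())

    rows: list[dict] = []
    cursor = 1
    elo, ehi = config.length_bp_range["exon"]
    klo, khi = config.exons_per_gene
    for i in range(counts["gene"]):
        gid = f"gene-{i:06d}"
        k = int(rng.integers(klo, khi + 1))
        exon_lens = rng.integers(elo, ehi + 1, size=k)
        introns = rng.integers(30, 301, size=k)  # introns[0] unused
        start = cursor
        pos = start
        exon_rows = []
        for j in range(k):
            if j > 0:
                pos += int(introns[j])
            e_start, e_end = pos, pos + int(exon_lens[j]) - 1
            exon_rows.append(
                {"feature_id": f"{gid}.e{j + 1}", "biotype": "exon", "chrom": "chr1",
                 "start": e_start, "end": e_end,
                 "length_bp": int(exon_lens[j]), "parent_gene_id": gid}
            )
            pos = e_end + 1
        gene_end = exon_rows[-1]["end"]
        rows.append(
            {"feature_id": gid, "biotype": "gene", "chrom": "chr1", "start": start,
             "end": gene_end, "length_bp": int(exon_lens.sum()),
             "parent_gene_id": None}
        )
        rows.extend(exon_rows)
        cursor = gene_end + 100
    for bt, prefix in (("miRNA", "mirna"), ("snoRNA", "snorna"), ("lncRNA", "lncrna")):
        lo, hi = config.length_bp_range[bt]
        lens = rng.integers(lo, hi + 1, size=counts[bt])
        for i in range(counts[bt]):
            length = int(lens[i])
            rows.append(
                {"feature_id": f"{prefix}-{i:06d}", "biotype": bt, "chrom": "chr1",
                 "start": cursor, "end": cursor + length - 1, "length_bp": length,
                 "parent_gene_id": None}
            )
            cursor += length + 100
    if not rows:
        df = pd.DataFrame(columns=COLUMNS, index=pd.Index([], name="feature_id"))
        return FeatureTable(df)
    df = pd.DataFrame(rows).set_index("feature_id")
    df["parent_gene_id"] = df["parent_gene_id"].astype(object)
    table = FeatureTable(df[COLUMNS])
    table.validate()
    return table


def assign_pattern_truth(features: FeatureTable, config: SimulationConfig) -> SyntheticTruth:
    """Label features +1 / -1 / 0 by a seeded shuffle of top-level features.

    Exactly floor(frac * n) features receive each nonzero label; the
    remainder stays 0 (conservative nulls). Exons inherit the parent label.
    """
    if config.frac_pattern_up + config.frac_pattern_down > 1:
        raise ConfigurationError("pattern fractions sum > 1")
    top = features.top_level
    n = len(top)
    n_up = int(np.floor(config.frac_pattern_up * n))
    n_down = int(np.floor(config.frac_pattern_down * n))
    rng = np.random.default_rng([config.seed, _RNG_TRUTH])
    perm = rng.permutation(n)
    labels = np.zeros(n, dtype=int)
    labels[perm[:n_up]] = 1
    labels[perm[n_up:n_up + n_down]] = -1
    lab = pd.Series(labels, index=top.index)
    full = pd.Series(0, index=features.df.index, dtype=int)
    full.loc[top.index] = lab
    exons = features.exons
    if len(exons):
        full.loc[exons.index] = lab.reindex(exons["parent_gene_id"]).fillna(0).astype(int).values
    eff = np.where(full.values != 0, float(config.effect_size), 1.0)
    df = pd.DataFrame({"label": full, "effect_size_applied": eff})
    return SyntheticTruth(df)


def _group_multipliers(labels: np.ndarray, groups: np.ndarray, effect: float) -> np.ndarray:
    """Expected-RPKM multiplier per (feature, sample).

    +1: effect in T/TEdM, 1 in C/TE; -1: 1/effect in T/TEdM, 1 in C/TE.
    """
    injured = np.isin(groups, ("T", "TEdM"))
    mult = np.ones((labels.size, groups.size))
    mult[np.ix_(labels == 1, injured)] = effect
    mult[np.ix_(labels == -1, injured)] = 1.0 / effect
    return mult


def _deterministic_split(total: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of integer totals across categories.

    Preserves the column sum exactly; ties go to the lower category index.
    """
    x = total[:, None] * probs[None, :]
    base = np.floor(x).astype(np.int64)
    rem = (total - base.sum(axis=1)).astype(np.int64)
    frac = x - base
    order = np.argsort(-frac, axis=1, kind="stable")
    for r in range(x.shape[0]):
        base[r, order[r, : rem[r]]] += 1
    return base


def simulate_counts(
    features: FeatureTable, truth: SyntheticTruth, config: SimulationConfig
) -> CountMatrix:
    """Draw the count matrix for all features (top-level and exon rows).

    Baseline RPKMs are log-uniform over ``baseline_rpkm_range``; the pattern
    multiplier model and the count law are described in the module
    docstring. Reproducible given ``config.seed``.
    """
    samples = config.samples_frame()
    top = features.top_level
    n_top = len(top)
    rng_base = np.random.default_rng([config.seed, _RNG_BASELINE])
    lo, hi = config.baseline_rpkm_range
    baseline = np.exp(rng_base.uniform(np.log(lo), np.log(hi), size=n_top))

    labels = truth.df.loc[top.index, "label"].to_numpy()
    groups = samples["group"].to_numpy()
    mult = _group_multipliers(labels, groups, config.effect_size)
    length_kb = top["length_bp"].to_numpy() / 1000.0
    lib = samples["library_size"].to_numpy().astype(float)
    mu = baseline[:, None] * mult * length_kb[:, None] * (lib[None, :] / 1e6)
    if not np.all(np.isfinite(mu)):
        raise SimulationError("non-finite expected count; check config magnitudes")

    rng_counts = np.random.default_rng([config.seed, _RNG_COUNTS])
    if config.noise == "none":
        counts_top = np.rint(mu).astype(np.int64)
    elif config.dispersion == 0:
        counts_top = rng_counts.poisson(mu).astype(np.int64)
    else:
        size = 1.0 / config.dispersion
        p = size / (size + mu)
        counts_top = rng_counts.negative_binomial(size, p).astype(np.int64)

    all_index = features.df.index
    mat = np.zeros((len(all_index), len(samples)), dtype=np.int64)
    row_pos = pd.Series(np.arange(len(all_index)), index=all_index)
    mat[row_pos[top.index].to_numpy()] = counts_top

    exons = features.exons
    if len(exons):
        rng_exons = np.random.default_rng([config.seed, _RNG_EXONS])
        top_pos = pd.Series(np.arange(n_top), index=top.index)
        for gid, sub in exons.groupby("parent_gene_id", sort=False):
            probs = sub["length_bp"].to_numpy().astype(float)
            probs /= probs.sum()
            gene_counts = counts_top[top_pos[gid]]  # one count per sample
            if config.noise == "none":
                alloc = _deterministic_split(gene_counts, probs)
            else:
                alloc = rng_exons.multinomial(gene_counts, probs)
            mat[row_pos[sub.index].to_numpy()] = alloc.T  # (exon, sample)
    counts = pd.DataFrame(mat, index=all_index, columns=samples.index)
    cm = CountMatrix(counts, samples)
    cm.validate(features)
    return cm


# ----------------------------------------------------------------- writers

def write_counts_tsv(cm: CountMatrix, counts_path, samples_path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    side = cm.samples.copy()
    side.index.name = "sample"
    side.to_csv(samples_path, sep="\t")


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    cm = CountMatrix(counts.astype(np.int64), samples)
    cm.validate()
    return cm


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    out = truth.df.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
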