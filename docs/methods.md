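# Methods

## Scope and data model

The package implements the downstream half of a bulk RNA-seq analysis: it
starts from a feature × sample matrix of integer read counts plus a GFF3
annotation (feature lengths, gene–exon parentage) and a sample sidecar
(group, tissue, total mapped reads), and ends at ±1/0 pattern calls,
splicing indices and clustered heat-map files. Alignment and read counting
are upstream of this package and out of scope.

Coordinates are GFF3 1-based inclusive throughout; no half-open formats are
accepted, to avoid silent off-by-one errors. A gene's length is the length
of the union of its exon intervals (overlapping exons are merged), which is
the length the RPKM denominator uses. Features dropped by the retention
filter are kept in every table with `retained = False` rather than deleted,
so matrices stay aligned and decisions are auditable.

## Quantification rules

RPKM = count · 10⁹ / (length_bp · library_size), with library_size the
*total* mapped reads of the library, not the in-feature sum.

**Retention (RQT).** A feature is retained when its RPKM reaches the
RPKM-equivalent of 50 mapped reads in ≥ 1 sample. The implementation
computes the threshold with the same floating-point expression as the RPKM
itself, so the RPKM-space decision coincides bit-for-bit with the integer
rule "count ≥ 50 in some sample". The boundary is inclusive (a feature at
exactly 50 reads is kept); a `strict_rqt` flag switches to a strict
inequality, because both readings of the rule are in circulation. The
decision is made on the raw, count-derived RPKM, which makes the filter
commute with the replacement step.

**Low-count replacement.** The floor is
V = meanₛ [10 · 10⁹ / (0.122 kb · 1000 · library_sizeₛ)], and every entry
whose *count* is ≤ 10 becomes V (flagged `replaced`). Keying on counts
rather than on RPKM makes the operation idempotent. The 0.122 kb median
length is the documented default for ncRNA tables; a per-run option uses
the data's own median feature length instead. The pipeline applies
retention and replacement to top-level features (genes and ncRNAs) only:
exon RPKMs stay raw, because flooring exon values at an ncRNA-derived
constant would bias the splicing index.

## Contrasts and classification

Group values are arithmetic means over a group's samples — the identity
under the pooled one-library-per-group design, and a plain mean when
replicates are simulated. Fold changes use the negative-reciprocal sign
convention and are computed branch-wise (a/b or −(b/a)) so that
antisymmetry holds exactly in floating point.

The default contrast scheme is the treatment chain T/C, TE/T, TEdM/TE; a
vs-control preset (T/C, TE/C, TEdM/C) is provided, and the classifier
derives the chained triple from it by dividing consecutive ratios. The
label rule is strict: values of exactly ±1 are "no change" and force label
0, so flat features are never classified. The minimum-fold filter (default
2) applies to the treatment-response contrast f₂ = TE/T only — that is the
"change compared with injury" the rescue signature hinges on — with a
`twofold_scope="all"` option to require it of all three contrasts. Exported
+1/−1 lists are sorted by |f₂| descending with ties broken by feature id,
so outputs are deterministic.

The splicing index is exon RPKM / parent-gene RPKM; where the gene RPKM is
zero the index is NaN (with a warning), never infinity.

## Clustering

Expression is log2-transformed and per-gene median-centered (even-length
rows use the mean of the two central values). "Centered correlation" is
read as the Pearson correlation, the meaning it has in the Cluster 3.0
lineage; distance = 1 − r ∈ [0, 2]. This is not a metric and no triangle
inequality is assumed. Zero-variance vectors get r = 0 (distance 1) by
convention, with a logged warning.

Agglomeration is unweighted average linkage (UPGMA): the pair of clusters
with the smallest unweighted mean of all cross-pair distances merges first,
maintained incrementally with the Lance–Williams update
d(i∪j, k) = (nᵢ d(i,k) + nⱼ d(j,k)) / (nᵢ + nⱼ). Ties are broken by the
lexicographically smallest (left, right) pair of node ids in the current
numbering — leaves 0..n−1, the k-th merge creating node n+k — so trees are
reproducible. Average linkage is reducible, hence merge heights are
non-decreasing; the test suite checks the full merge sequence against a
naive O(n³) re-scan reference and cross-checks heights against an
independent library implementation. A nearest-neighbour cache makes the
common case ~O(n²): ~19,000 genes cluster in well under a minute on one
core, with the distance matrix consumed in place to halve peak memory.

Leaf ordering is the standard dendrogram order (left subtree before right,
as merged); no optimal-leaf-ordering optimisation is applied. Output files
follow the CDT/GTR/ATR convention of Java TreeView, with GENE/ARRY ids
referring to original row/column positions and each tree line recording a
merge's similarity 1 − distance. CDT data cells are written with Python's
shortest round-trip float representation — unlike the 6-significant-digit
formatting used for every TSV table — so parsing a CDT reconstructs the
clustered matrix exactly; GWEIGHT/EWEIGHT are 1. The optional heat-map
export uses a green–black–red scale with one colour-bar unit per log2 unit.

Clustering runs per tissue by default (each tissue's groups form one
4-sample block), with a joint mode available; the tissues' gene trees are
independent objects either way.

## Synthetic data generator

The generator emulates the study shape rather than any real genome:

* **Design.** Groups C, T, TE, TEdM × tissues brain, spleen, one pooled
  library per group and tissue (`replicates_per_group = 1`; more replicates
  are supported for power exploration). Library size 4 × 10⁷ reads — a
  round number at the scale of the study's sequencing depth, exposed in
  config and claimed to match nothing.
* **Features.** Default 10,000 top-level features: 50% multi-exon genes
  (2–8 exons of 80–320 bp), 20% miRNA (70–120 bp), 20% snoRNA (100–300 bp),
  10% lncRNA (200–2000 bp). Biotype counts are floor(fraction · n) with the
  remainder assigned to genes. Short ncRNA lengths bracket the 0.122 kb
  median length the replacement rule assumes.
* **Truth.** floor(frac · n) features get label +1 and −1 respectively via
  a seeded shuffle (defaults 2% each); the remainder are null — rounding
  remainders become conservative nulls. Exon rows inherit the parent
  gene's label.
* **Count law.** Expected RPKM is the feature's baseline in C and TE and
  baseline × effect (label +1) or baseline / effect (label −1) in T and
  TEdM; effect defaults to 8. μ = RPKM · length_kb · library/10⁶; counts
  are negative-binomial with variance μ + d·μ² (d defaults to 0.05; d = 0
  degenerates continuously to Poisson). `noise="none"` instead returns
  round(μ) — the true noiseless limit, which Poisson at d = 0 is not; exact
  end-to-end recovery is asserted only in that mode. Gene counts are drawn
  at the gene level and allocated to exons multinomially in proportion to
  exon length (largest-remainder allocation in noiseless mode), so exon
  sums equal gene counts exactly and the length-weighted mean splicing
  index is identically 1 — the generator cannot create differential exon
  usage, it only makes the index computable.
* **Baselines.** Per-feature baseline RPKM is log-uniform on (18, 64).
  The range is deliberately the *reliably quantified* stratum, chosen so
  that two structural constraints hold simultaneously: (i) every feature,
  including the shortest miRNA, has an expected baseline count ≥ 50
  (18 × 0.070 kb × 40 = 50.4), so noiseless recovery of injected labels is
  exact rather than censored by the retention filter; and (ii) expected
  in-feature reads stay below the library size with ~9% headroom even in
  the injured-group columns (where +1 features carry an 8× multiplier) at
  the 19,058-feature scale, keeping total-mapped-reads semantics coherent.
  Real transcriptomes span far wider dynamic ranges; see limitations.
* **Determinism.** Every operation draws from its own seeded substream, so
  identical (config, seed) give bit-identical annotation, truth and counts,
  and the full pipeline yields byte-identical files (the manifest records
  SHA-256 checksums; all TSVs use fixed 6-significant-digit floats).

## What the defaults measure

At the default conditions (10,000 features, 400 injected, effect 8,
d = 0.05) the classifier reaches sensitivity ≈ 1.0 and specificity ≈ 0.97
— comfortably inside the ≥ 0.85 / ≥ 0.95 working bounds the test suite
asserts. The ~2–3% false-positive rate among nulls is intrinsic to
thresholding fold changes from single pooled libraries at this
overdispersion: the three sign conditions share samples and are therefore
positively correlated, which multiplies the naive independent-probability
estimate several-fold. This is a faithful property of the published design,
not an implementation artifact, and it is why the ±1 lists feed a
downstream enrichment tool rather than being reported as significant genes.

`scripts/acceptance.py` recomputes these quantities from scratch at the
conditions above; the full-scale smoke test runs the entire pipeline at
19,058 features × 8 samples (the detectable-gene scale of the motivating
study), which completes in ~2 minutes on one core.

## Numerical choices

* Fold changes: branch-wise division for exact antisymmetry; strict
  inequalities in the classifier.
* RQT boundary: inclusive ≥, switchable to strict.
* Distances clipped to [0, 2] after the matrix product; diagonal forced to
  zero; symmetry of user-supplied matrices validated exhaustively up to
  n = 1500 and by random sampling beyond.
* UPGMA tie-break: smallest (left, right) node-id pair; merges recorded
  left < right.
* Degenerate inputs: empty feature tables propagate as empty outputs;
  single-sample groups are identities; zero-variance rows warn and sit at
  distance 1; gene RPKM 0 yields NaN splicing indices.

## Known limitations

* The generator's expression distribution is narrow by construction (see
  above); it does not emulate the sub-threshold tail of real libraries, so
  passing recovery tests says nothing about features near or below the
  50-read threshold in real data — in real use those are exactly the
  features the RQT filter exists to exclude.
* No biological replicates, hence no variance estimation or significance
  testing anywhere — by design, matching the pooled single-library study.
* The exon-count model is a stand-in: real exon-level counting (and hence
  real splicing-index variation) depends on upstream tooling this package
  does not reimplement.
* Centered-correlation distance ignores scale and offset per gene
  (affine-invariant), which is intended for heat-map clustering but means
  the trees carry no amplitude information.
* TMM/DESeq-style normalisation, batch correction and pathway inference
  are deliberately absent; the pipeline stops at the ±1 lists and tree
  files.
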