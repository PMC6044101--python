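"""End-to-end orchestration: simulate/load -> quantify -> contrasts -> cluster.

Every stage writes plain-text artifacts into the output directory and the
run ends with a JSON manifest recording file checksums and per-stage
accounting (features in, retained after the reliable-quantification
filter, replaced entries, +1/-1 calls per tissue). A run is a pure
function of (config, seed): identical inputs give byte-identical outputs,
which the manifest checksums make easy to verify. All floating-point
tables are written with 6 significant digits; the CDT keeps full
precision so it round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cluster3, contrasts, quantify, synthcounts
from .config import ContrastScheme, PipelineConfig, QuantifyParams
from .errors import PipelineError
from .features import FeatureTable
from .quantify import ExpressionMatrix

logger = logging.getLogger("exopattern")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineResult:
    """Manifest (files, checksums, stage counts) of a finished run."""

    manifest: dict
    outdir: Path

    @property
    def counts(self) -> dict:
        return self.manifest["counts"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_name: str) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _top_level_counts(cm: synthcounts.CountMatrix, features: FeatureTable):
    top = features.top_level.index
    return synthcounts.CountMatrix(cm.counts.loc[top], cm.samples)


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.counts: dict = {}
        self.features: Optional[FeatureTable] = None
        self.cm: Optional[synthcounts.CountMatrix] = None
        self.expr: Optional[ExpressionMatrix] = None
        self.rpkm_all: Optional[pd.DataFrame] = None

    def record(self, *paths: Path) -> None:
        self.files.extend(paths)

    # -------------------------------------------------------------- stages

    def simulate(self) -> None:
        cfg = self.config.simulation
        features = synthcounts.generate_feature_table(cfg)
        truth = synthcounts.assign_pattern_truth(features, cfg)
        cm = synthcounts.simulate_counts(features, truth, cfg)
        gff = self.outdir / "features.gff3"
        features.to_gff3(gff)
        cpath, spath = self.outdir / "counts.tsv", self.outdir / "samples.tsv"
        synthcounts.write_counts_tsv(cm, cpath, spath)
        tpath = self.outdir / "truth.tsv"
        synthcounts.write_truth_tsv(truth, tpath)
        self.record(gff, cpath, spath, tpath)
        self.features, self.cm = features, cm
        self.counts["n_features"] = int(len(features.top_level))
        self.counts["n_exons"] = int(len(features.exons))
        self.counts["n_samples"] = int(len(cm.samples))
        logger.info("simulated %d top-level features x %d samples",
                    self.counts["n_features"], self.counts["n_samples"])

    def load(self) -> None:
        paths = self.config.inputs
        self.features = FeatureTable.from_gff3(paths["gff3"])
        self.cm = synthcounts.read_counts_tsv(paths["counts"], paths["samples"])
        self.cm.validate(self.features)
        self.counts["n_features"] = int(len(self.features.top_level))
        self.counts["n_exons"] = int(len(self.features.exons))
        self.counts["n_samples"] = int(len(self.cm.samples))

    def quantify(self) -> None:
        params = self.config.quantify
        if self.config.replacement_length == "data-median":
            median_kb = float(self.features.top_level["length_bp"].median()) / 1000.0
            params = QuantifyParams(params.rqt_reads, params.replace_max_reads,
                                    median_kb, params.strict_rqt)
        expr_all = quantify.rpkm_matrix(self.cm, self.features)
        self.rpkm_all = expr_all.values
        top_cm = _top_level_counts(self.cm, self.features)
        expr = quantify.rpkm_matrix(top_cm, self.features)
        expr = quantify.rqt_filter(expr, top_cm, params)
        expr = quantify.low_count_replacement(expr, top_cm, params)
        self.expr = expr

        rpath = self.outdir / "rpkm.tsv"
        _write_tsv(expr.values, rpath, "feature_id")
        ret = self.outdir / "retention.tsv"
        _write_tsv(expr.retained.astype(int).to_frame("retained"), ret, "feature_id")
        prov = self.outdir / "provenance.tsv"
        flags = expr.replaced.stack()
        prov_df = flags.map({True: "replaced", False: "raw"}).rename("flag").reset_index()
        prov_df.columns = ["feature_id", "sample", "flag"]
        prov_df.to_csv(prov, sep="\t", index=False)
        self.record(rpath, ret, prov)

        self.counts["n_retained"] = int(expr.retained.sum())
        self.counts["n_replaced_entries"] = int(expr.replaced.to_numpy().sum())
        self.counts["replacement_value"] = float(expr.replacement_value)
        logger.info("retained %d/%d features; replaced %d entries (floor %.6g)",
                    self.counts["n_retained"], self.counts["n_features"],
                    self.counts["n_replaced_entries"], expr.replacement_value)

    def _tissues(self) -> list[str]:
        return list(dict.fromkeys(self.cm.samples["tissue"]))

    def contrasts(self) -> None:
        scheme = ContrastScheme.preset(self.config.scheme)
        self._tables = {}
        for tissue in self._tissues():
            samples = self.cm.samples[self.cm.samples["tissue"] == tissue]
            table = contrasts.contrast_table(self.expr, samples, scheme)
            self._tables[tissue] = table
            path = self.outdir / f"contrasts_{tissue}.tsv"
            _write_tsv(table, path, "feature_id")
            self.record(path)
        if len(self.features.exons):
            si = contrasts.splice_index_table(self.rpkm_all, self.features)
            path = self.outdir / "splice_index.tsv"
            _write_tsv(si, path, "exon_id")
            self.record(path)

    def classify(self) -> None:
        scheme = ContrastScheme.preset(self.config.scheme)
        for tissue, table in self._tables.items():
            calls = contrasts.pattern_gene_lists(
                table, scheme, min_fold=self.config.min_fold,
                twofold_scope=self.config.twofold_scope,
            )
            path = self.outdir / f"patterns_{tissue}.tsv"
            _write_tsv(calls, path, "feature_id")
            pc = contrasts.PatternCall(calls)
            up = self.outdir / f"pattern_up_{tissue}.txt"
            down = self.outdir / f"pattern_down_{tissue}.txt"
            pc.write_lists(up, down)
            self.record(path, up, down)
            self.counts[f"n_up_{tissue}"] = len(pc.up)
            self.counts[f"n_down_{tissue}"] = len(pc.down)
            logger.info("%s: %d features labeled +1, %d labeled -1",
                        tissue, len(pc.up), len(pc.down))

    def cluster(self) -> None:
        groups: list[tuple[str, pd.DataFrame]] = []
        retained = self.expr.values[self.expr.retained]
        if self.config.cluster_per_tissue:
            for tissue in self._tissues():
                cols = self.cm.samples.index[self.cm.samples["tissue"] == tissue]
                groups.append((tissue, retained[cols]))
        else:
            groups.append(("joint", retained))
        for name, block in groups:
            centered = cluster3.log2_median_center(block)
            gene_tree = None
            sample_tree = None
            if "genes" in self.config.cluster_axes and len(centered) >= 2:
                D = cluster3.pairwise_distance_matrix(centered, axis="genes")
                gene_tree = cluster3.average_linkage(D, overwrite=True)
                del D
            if "samples" in self.config.cluster_axes and centered.shape[1] >= 2:
                Ds = cluster3.pairwise_distance_matrix(centered, axis="samples")
                sample_tree = cluster3.average_linkage(Ds, overwrite=True)
            if gene_tree is None:
                continue
            written = cluster3.write_cdt_gtr(
                centered, gene_tree, sample_tree, self.outdir / name
            )
            self.record(*written)
            logger.info("%s: clustered %d genes, %d samples",
                        name, centered.shape[0], centered.shape[1])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order and write the manifest.

    On a stage failure the manifest is still written (status "failed",
    listing only files that exist) and a :class:`PipelineError` naming the
    stage is raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    run = _Run(config)
    stage_fns = [
        ("simulate", run.simulate if config.simulation is not None else run.load),
        ("quantify", run.quantify),
        ("contrasts", run.contrasts),
        ("classify", run.classify),
        ("cluster", run.cluster),
    ]
    wanted = set(config.stages)
    status = "ok"
    failed_stage = None
    try:
        for name, fn in stage_fns:
            if name not in wanted:
                continue
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                status = "failed"
                failed_stage = name
                raise PipelineError(name, str(exc)) from exc
    finally:
        manifest = _build_manifest(run, status, failed_stage)
        with open(run.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(manifest, run.outdir)


def _build_manifest(run: _Run, status: str, failed_stage: Optional[str]) -> dict:
    files = {}
    for path in run.files:
        if path.exists():  # never claim files that do not exist
            files[path.name] = {"sha256": _sha256(path), "bytes": path.stat().st_size}
    manifest = {
        "status": status,
        "counts": _consistent_counts(run.counts),
        "files": files,
        "seed": run.config.simulation.seed if run.config.simulation else None,
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    return manifest


def _consistent_counts(counts: dict) -> dict:
    n = counts.get("n_features")
    kept = counts.get("n_retained")
    if n is not None and kept is not None and kept > n:
        raise PipelineError("manifest", f"retained {kept} > input {n}")
    if kept is not None:
        for key, val in counts.items():
            if key.startswith("n_up_") or key.startswith("n_down_"):
                if val > kept:
                    raise PipelineError("manifest", f"{key}={val} > retained {kept}")
    return {k: (float(v) if isinstance(v, float) else int(v)) for k, v in counts.items()}
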