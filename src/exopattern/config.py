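"""Configuration objects for simulation, quantification, contrasts and the pipeline.

All configuration is plain dataclasses with eager validation: a bad field
raises :class:`~exopattern.errors.ConfigurationError` naming the field, so
errors surface at construction time rather than mid-pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .errors import ConfigurationError

GROUPS = ("C", "T", "TE", "TEdM")
#: biotypes simulated for top-level features; exon rows are children of genes
BIOTYPES = ("gene", "miRNA", "snoRNA", "lncRNA")


def _check_range(name: str, rng: Tuple[float, float], positive: bool = True) -> None:
    lo, hi = rng
    if lo > hi:
        raise ConfigurationError(f"{name}: low {lo} > high {hi}")
    if positive and lo <= 0:
        raise ConfigurationError(f"{name}: bounds must be positive, got {rng}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pooled four-group, two-tissue experiment.

    Defaults describe the emulated study design: four treatment groups
    (sham control C, injury T, injury + exosomes TE, injury + lncRNA-depleted
    exosomes TEdM), one pooled sequencing library per group and tissue, and a
    mix of coding genes (with exon structure) and short noncoding biotypes.
    ``effect_size`` is the expression ratio applied to the injured/unrescued
    groups of a pattern feature; the negative-binomial ``dispersion`` follows
    the variance = mu + dispersion * mu**2 parameterization (0 -> Poisson).
    ``noise="none"`` replaces the stochastic draw with round(mu), the
    noiseless limit used for exact-recovery checks.
    """

    n_features: int = 10_000
    biotype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.5, "miRNA": 0.2, "snoRNA": 0.2, "lncRNA": 0.1}
    )
    exons_per_gene: Tuple[int, int] = (2, 8)
    length_bp_range: Mapping[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "miRNA": (70, 120),
            "snoRNA": (100, 300),
            "lncRNA": (200, 2000),
            "exon": (80, 320),
        }
    )
    groups: Sequence[str] = GROUPS
    tissues: Sequence[str] = ("brain", "spleen")
    replicates_per_group: int = 1
    library_size: int = 40_000_000
    library_sizes: Optional[Mapping[str, int]] = None
    frac_pattern_up: float = 0.02
    frac_pattern_down: float = 0.02
    effect_size: float = 8.0
    baseline_rpkm_range: Tuple[float, float] = (18.0, 64.0)
    dispersion: float = 0.05
    noise: str = "nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 0:
            raise ConfigurationError(f"n_features: must be >= 0, got {self.n_features}")
        missing = set(BIOTYPES) - set(self.biotype_fractions)
        if missing:
            raise ConfigurationError(f"biotype_fractions: missing biotypes {sorted(missing)}")
        total = sum(self.biotype_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"biotype_fractions: sum {total} != 1 within 1e-9")
        if any(v < 0 for v in self.biotype_fractions.values()):
            raise ConfigurationError("biotype_fractions: fractions must be >= 0")
        _check_range("exons_per_gene", self.exons_per_gene)
        for bt in ("miRNA", "snoRNA", "lncRNA", "exon"):
            if bt not in self.length_bp_range:
                raise ConfigurationError(f"length_bp_range: missing biotype '{bt}'")
            _check_range(f"length_bp_range[{bt}]", self.length_bp_range[bt])
        if self.replicates_per_group < 1:
            raise ConfigurationError("replicates_per_group: must be >= 1")
        if self.library_size <= 0:
            raise ConfigurationError("library_size: must be positive")
        if self.library_sizes is not None and any(v <= 0 for v in self.library_sizes.values()):
            raise ConfigurationError("library_sizes: all entries must be positive")
        if self.frac_pattern_up < 0 or self.frac_pattern_down < 0:
            raise ConfigurationError("frac_pattern_up/down: must be >= 0")
        if self.frac_pattern_up + self.frac_pattern_down > 1:
            raise ConfigurationError(
                "frac_pattern_up + frac_pattern_down: "
                f"{self.frac_pattern_up + self.frac_pattern_down} > 1"
            )
        if self.effect_size <= 1:
            raise ConfigurationError(f"effect_size: must be > 1, got {self.effect_size}")
        if self.dispersion < 0:
            raise ConfigurationError(f"dispersion: must be >= 0, got {self.dispersion}")
        _check_range("baseline_rpkm_range", self.baseline_rpkm_range)
        if self.noise not in ("nb", "none"):
            raise ConfigurationError(f"noise: must be 'nb' or 'none', got {self.noise!r}")
        if not self.groups:
            raise ConfigurationError("groups: must be nonempty")

    def sample_names(self) -> list[str]:
        names = []
        for tissue in self.tissues:
            for group in self.groups:
                if self.replicates_per_group == 1:
                    names.append(f"{tissue}_{group}")
                else:
                    names.extend(
                        f"{tissue}_{group}_r{k + 1}" for k in range(self.replicates_per_group)
                    )
        return names

    def samples_frame(self) -> pd.DataFrame:
        """Sample sidecar: group, tissue, library_size per sample (index = sample id)."""
        rows = []
        for tissue in self.tissues:
            for group in self.groups:
                for k in range(self.replicates_per_group):
                    name = (
                        f"{tissue}_{group}"
                        if self.replicates_per_group == 1
                        else f"{tissue}_{group}_r{k + 1}"
                    )
                    lib = self.library_size
                    if self.library_sizes is not None and name in self.library_sizes:
                        lib = self.library_sizes[name]
                    rows.append({"sample": name, "group": group, "tissue": tissue,
                                 "library_size": int(lib)})
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class QuantifyParams:
    """Retention and replacement thresholds for RPKM quantification.

    ``rqt_reads`` is the reliable-quantification threshold: a feature is kept
    when its RPKM corresponds to at least this many mapped reads in one or
    more samples. RPKMs arising from ``replace_max_reads`` or fewer reads are
    replaced by the cross-sample average RPKM-equivalent of
    ``replace_max_reads`` reads at ``median_length_kb``. ``strict_rqt``
    switches the retention boundary from >= to > (both readings of the rule
    appear in the field; >= is the default).
    """

    rqt_reads: int = 50
    replace_max_reads: int = 10
    median_length_kb: float = 0.122
    strict_rqt: bool = False

    def __post_init__(self) -> None:
        if self.rqt_reads <= 0:
            raise ConfigurationError("rqt_reads: must be positive")
        if self.replace_max_reads <= 0:
            raise ConfigurationError("replace_max_reads: must be positive")
        if self.replace_max_reads >= self.rqt_reads:
            raise ConfigurationError(
                f"replace_max_reads ({self.replace_max_reads}) must be < "
                f"rqt_reads ({self.rqt_reads})"
            )
        if self.median_length_kb <= 0:
            raise ConfigurationError("median_length_kb: must be positive")


@dataclass(frozen=True)
class Contrast:
    name: str
    numerator: str
    denominator: str


@dataclass(frozen=True)
class ContrastScheme:
    """Ordered fold-change contrasts between treatment groups.

    ``chained`` follows the treatment chain (T/C, TE/T, TEdM/TE);
    ``vs_control`` expresses every group against the sham control
    (T/C, TE/C, TEdM/C). The rescue-pattern classifier always reasons on the
    chained triple; vs-control tables are converted internally.
    """

    name: str
    contrasts: Tuple[Contrast, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contrasts]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"contrast names not unique: {names}")

    @property
    def contrast_names(self) -> list[str]:
        return [c.name for c in self.contrasts]

    @staticmethod
    def preset(name: str) -> "ContrastScheme":
        if name == "chained":
            return CHAINED
        if name == "vs_control":
            return VS_CONTROL
        raise ConfigurationError(f"unknown contrast scheme preset: {name!r}")


CHAINED = ContrastScheme(
    "chained",
    (
        Contrast("T_vs_C", "T", "C"),
        Contrast("TE_vs_T", "TE", "T"),
        Contrast("TEdM_vs_TE", "TEdM", "TE"),
    ),
)

VS_CONTROL = ContrastScheme(
    "vs_control",
    (
        Contrast("T_vs_C", "T", "C"),
        Contrast("TE_vs_C", "TE", "C"),
        Contrast("TEdM_vs_C", "TEdM", "C"),
    ),
)

ALL_STAGES = ("simulate", "quantify", "contrasts", "classify", "cluster")


@dataclass
class PipelineConfig:
    """Full pipeline run description.

    Exactly one of ``simulation`` (generate data) or ``inputs`` (paths to
    counts TSV, sample sidecar TSV and GFF3 annotation) must be provided.
    """

    outdir: Path
    simulation: Optional[SimulationConfig] = None
    inputs: Optional[Mapping[str, str]] = None
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    scheme: str = "chained"
    min_fold: float = 2.0
    twofold_scope: str = "rescue"
    replacement_length: str = "config"
    cluster_axes: Sequence[str] = ("genes", "samples")
    cluster_per_tissue: bool = True
    stages: Sequence[str] = ALL_STAGES
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulation' or 'inputs' must be provided"
            )
        if self.inputs is not None:
            missing = {"counts", "samples", "gff3"} - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs: missing paths {sorted(missing)}")
        ContrastScheme.preset(self.scheme)
        if self.min_fold < 1:
            raise ConfigurationError(f"min_fold: must be >= 1, got {self.min_fold}")
        if self.twofold_scope not in ("rescue", "all"):
            raise ConfigurationError("twofold_scope: must be 'rescue' or 'all'")
        if self.replacement_length not in ("config", "data-median"):
            raise ConfigurationError("replacement_length: must be 'config' or 'data-median'")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigurationError(f"stages: unknown stage(s) {sorted(bad)}")
        bad_axes = set(self.cluster_axes) - {"genes", "samples"}
        if bad_axes:
            raise ConfigurationError(f"cluster_axes: unknown axis {sorted(bad_axes)}")
        if self.seed is not None and self.simulation is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            for key in ("exons_per_gene", "baseline_rpkm_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "length_bp_range" in sim:
                sim["length_bp_range"] = {k: tuple(v) for k, v in sim["length_bp_range"].items()}
            raw["simulation"] = SimulationConfig(**sim)
        if "quantify" in raw and isinstance(raw["quantify"], dict):
            raw["quantify"] = QuantifyParams(**raw["quantify"])
        return PipelineConfig(**raw)
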