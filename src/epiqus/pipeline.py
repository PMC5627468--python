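"""End-to-end orchestration: QC -> LD pruning -> pairwise interaction scan.

A single :class:`PipelineConfig` — loaded from a YAML file or built in code —
names either four input files (genotypes, marker panel, covariates, phenotype)
or a simulation block, and fixes every threshold.  :func:`run_pipeline` runs
the stages in that order, writes the QC report, the pruning report, the ranked
scan table and a human-readable summary to the output directory, and echoes
the configuration for provenance.  Stages remain independently callable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .interaction import ScanResult, render_threshold, scan_all_pairs
from .io_panel import (
    ValidationError,
    align_cohort,
    load_reference_panel,
    read_covariates,
    read_genotypes,
    read_marker_panel,
    read_phenotype,
    write_scan_results,
)
from .ld_prune import prune_ld
from .qc import qc_filter
from .simulate import (
    InteractionEffect,
    MainEffect,
    SimulationConfig,
    generate_cohort,
)

__all__ = ["PipelineConfig", "PipelineSummary", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full run description; exactly one of ``inputs`` / ``simulate`` is set."""

    inputs: dict[str, str] | None = None      # genotypes, panel, covariates, phenotype
    simulate: SimulationConfig | None = None
    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_exclude_p: float | None = None
    prune_r2: float = 0.90
    coding: str = "carrier"
    alpha: float = 0.05
    out_dir: str = "epiqus_results"
    seed: int | None = None                   # overrides simulate.seed when given

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValidationError(
                "config must supply exactly one of an inputs block or a "
                "simulate block"
            )
        if self.inputs is not None:
            required = {"genotypes", "covariates", "phenotype"}
            missing = required - set(self.inputs)
            if missing:
                raise ValidationError(f"inputs block missing paths: {sorted(missing)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 <= self.prune_r2 <= 1.0:
            raise ValidationError("prune_r2 must lie in [0, 1]")
        if self.coding not in ("carrier", "additive"):
            raise ValidationError("coding must be 'carrier' or 'additive'")
        for name in ("maf_min", "missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    # -- YAML loading -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim = _sim_config_from_dict(raw["simulate"])
        qc_block = raw.get("qc", {}) or {}
        prune_block = raw.get("prune", {}) or {}
        scan_block = raw.get("scan", {}) or {}
        cfg = cls(
            inputs=raw.get("inputs"),
            simulate=sim,
            maf_min=float(qc_block.get("maf_min", 0.01)),
            missing_max=float(qc_block.get("missing_max", 0.05)),
            hwe_exclude_p=qc_block.get("hwe_exclude_p"),
            prune_r2=float(prune_block.get("threshold", 0.90)),
            coding=scan_block.get("coding", "carrier"),
            alpha=float(scan_block.get("alpha", 0.05)),
            out_dir=raw.get("out_dir", "epiqus_results"),
            seed=raw.get("seed"),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "inputs": self.inputs,
            "qc": {
                "maf_min": self.maf_min,
                "missing_max": self.missing_max,
                "hwe_exclude_p": self.hwe_exclude_p,
            },
            "prune": {"threshold": self.prune_r2},
            "scan": {"coding": self.coding, "alpha": self.alpha},
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["panel"] = None if self.simulate.panel is None else [
                m.rsid for m in self.simulate.panel
            ]
            d["simulate"] = sim
        return d


def _sim_config_from_dict(block: dict[str, Any]) -> SimulationConfig:
    kwargs = dict(block)
    if "ld_pairs" in kwargs and kwargs["ld_pairs"] is not None:
        kwargs["ld_pairs"] = [
            (str(a), str(b), float(r2)) for a, b, r2 in kwargs["ld_pairs"]
        ]
    if "snp_effects" in kwargs and kwargs["snp_effects"] is not None:
        kwargs["snp_effects"] = [MainEffect(**e) for e in kwargs["snp_effects"]]
    if "interaction_effects" in kwargs and kwargs["interaction_effects"] is not None:
        kwargs["interaction_effects"] = [
            InteractionEffect(**e) for e in kwargs["interaction_effects"]
        ]
    kwargs.pop("panel", None)  # panel overrides are code-level only
    return SimulationConfig(**kwargs)


@dataclass
class PipelineSummary:
    n_samples: int
    markers_in: int
    markers_after_qc: int
    markers_after_prune: int
    pairs_tested: int
    bonferroni_threshold: float
    n_estimable: int
    n_significant: int
    top_pair: str
    top_p: float
    coding: str

    def render(self) -> str:
        lines = [
            "epiqus pipeline summary",
            f"  samples analysed        : {self.n_samples}",
            f"  markers in              : {self.markers_in}",
            f"  markers after QC        : {self.markers_after_qc}",
            f"  markers after LD prune  : {self.markers_after_prune}",
            f"  pairs tested            : {self.pairs_tested}",
            f"  Bonferroni threshold    : {self.bonferroni_threshold:.6g}"
            f" (~{render_threshold(self.bonferroni_threshold)})",
            f"  estimable pairs         : {self.n_estimable}",
            f"  Bonferroni-significant  : {self.n_significant}",
            f"  coding                  : {self.coding}",
            f"  top pair                : {self.top_pair} (p={self.top_p:.3g})",
        ]
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    panel = (
        read_marker_panel(paths["panel"])
        if paths.get("panel")
        else load_reference_panel()
    )
    genotypes = read_genotypes(paths["genotypes"], panel)
    covariates = read_covariates(paths["covariates"])
    phenotype = read_phenotype(paths["phenotype"])
    return genotypes, covariates, phenotype


def run_pipeline(config: PipelineConfig) -> tuple[PipelineSummary, ScanResult]:
    """Run QC, pruning and the pairwise scan; write all reports to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        logger.info("simulating cohort (n=%d, seed=%s)", sim.n_samples, sim.seed)
        genotypes, covariates, phenotype = generate_cohort(sim)
    else:
        genotypes, covariates, phenotype = _load_inputs(config)

    genotypes, covariates, phenotype = align_cohort(genotypes, covariates, phenotype)
    markers_in = len(genotypes.markers)

    qc_report, retained = qc_filter(
        genotypes,
        maf_min=config.maf_min,
        missing_max=config.missing_max,
        hwe_exclude_p=config.hwe_exclude_p,
    )
    qc_report.write(out / "qc_report.tsv")
    logger.info("QC: %d of %d markers retained", len(retained), markers_in)
    genotypes = genotypes.subset(retained)

    prune_result = prune_ld(genotypes, threshold=config.prune_r2)
    prune_result.write(out / "prune_report.tsv")
    genotypes = genotypes.subset(prune_result.kept)

    scan = scan_all_pairs(
        genotypes, phenotype, covariates, coding=config.coding, alpha=config.alpha
    )
    write_scan_results(scan.results, out / "scan_results.tsv")

    estimable = [r for r in scan.results if r.estimable]
    top = estimable[0] if estimable else None
    summary = PipelineSummary(
        n_samples=len(genotypes.sample_ids),
        markers_in=markers_in,
        markers_after_qc=len(retained),
        markers_after_prune=len(prune_result.kept),
        pairs_tested=scan.n_pairs,
        bonferroni_threshold=scan.threshold,
        n_estimable=scan.n_estimable,
        n_significant=len(scan.significant),
        top_pair=f"{top.rsid1}-{top.rsid2}" if top else "none",
        top_p=top.p_value if top else float("nan"),
        coding=config.coding,
    )
    (out / "summary.txt").write_text(summary.render())
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return summary, scan
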