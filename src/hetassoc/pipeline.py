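"""End-to-end pipeline: (simulate | load) → QC → heterozygosity → association.

One :class:`RunConfig` drives the whole run; all outputs are deterministic
TSV/JSON files in the chosen output directory:

``qc_report.tsv``, ``removed_variants.txt``, ``removed_samples.txt``,
``het_profiles.tsv`` (all strata), ``association.tsv`` (the 12-cell grid),
``cohort_summary.tsv`` and ``run_manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import analysis_grid, cohort_summary
from .heterozygosity import HetOptions, compute_strata
from .qc import QCConfig, run_qc
from .simulate import SimulationConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``genotypes`` [+ ``samples``]) or ``simulation`` must be
    set.  ``strata`` are MAF thresholds, strictly increasing, each in
    [0, 0.5).
    """

    genotypes: str | None = None  # VCF or genotype TSV path
    samples: str | None = None  # sample TSV path
    simulation: SimulationConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    het: HetOptions = field(default_factory=HetOptions)
    strata: tuple[float, ...] = (0.01, 0.1)
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    outdir: str = "hetassoc_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = self.genotypes is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of input paths or a simulation config is required"
            )
        if has_files and self.samples is None:
            raise ValueError("genotype input requires a sample table")
        s = list(self.strata)
        if s != sorted(s) or len(set(s)) != len(s):
            raise ValueError("strata must be strictly increasing")
        if any(not (0 <= t < 0.5) for t in s):
            raise ValueError("each stratum must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "qc" in kwargs:
            kwargs["qc"] = QCConfig(**kwargs["qc"])
        if "het" in kwargs:
            kwargs["het"] = HetOptions(**kwargs["het"])
        for tup in ("strata", "covariates"):
            if tup in kwargs and kwargs[tup] is not None:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        g, samples, truth = generate_cohort(sim)
        return g, samples, truth
    path = Path(config.genotypes)
    if path.suffix in (".vcf", ".gz", ".bcf") or str(path).endswith(".vcf.gz"):
        g = io.read_vcf(path)
    else:
        g = io.read_genotype_tsv(path)
    samples = io.read_sample_table(config.samples)
    return g, samples, None


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        g, samples, truth = _load_inputs(config)
        if truth is not None:
            write_cohort(g, samples, truth, outdir / "cohort")

        stage = "qc"
        g_qc, samples_qc, report = run_qc(g, samples, config.qc)
        io.write_table(report.to_frame(), outdir / "qc_report.tsv", kind="qc_report")
        (outdir / "removed_variants.txt").write_text(
            "\n".join(report.removed_variant_ids) + ("\n" if report.removed_variant_ids else "")
        )
        (outdir / "removed_samples.txt").write_text(
            "\n".join(report.removed_sample_ids) + ("\n" if report.removed_sample_ids else "")
        )

        stage = "heterozygosity"
        profiles = compute_strata(g_qc, config.strata, config.het)
        io.write_table(profiles, outdir / "het_profiles.tsv", kind="het_profiles")

        stage = "association"
        grid = analysis_grid(profiles, samples_qc, list(config.covariates))
        io.write_table(grid, outdir / "association.tsv", kind="association")
        summary = cohort_summary(samples_qc)
        summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")

        stage = "manifest"
        manifest = {
            "config": _jsonable(config.to_dict()),
            "seed": config.seed,
            "versions": {
                "hetassoc": _safe_version("hetassoc"),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_samples_analyzed": int(g_qc.n_samples),
            "n_variants_analyzed": int(g_qc.n_variants),
        }
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        for f in outdir.glob("*.tsv"):
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise
    return outdir


def _safe_version(name: str) -> str:
    try:
        return _pkg_version(name)
    except Exception:
        return "unknown"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
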