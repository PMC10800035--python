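"""Simulation-based calibration and recovery checks.

These helpers run the full estimator (simulate → QC → heterozygosity →
logistic fit) over many seeded replicates to measure its operating
characteristics: the type-I error of the association test under a null
cohort, confidence-interval coverage at a known effect, and recovery of the
simulated per-SD effect and of the het_excess/F relationship.  The test
suite and the reproduction script both call these.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import stats

from .association import AssociationResult, association_test
from .heterozygosity import compute_het_profiles
from .qc import QCConfig, run_qc
from .simulate import SimulationConfig, generate_cohort


def _null_config(seed: int, n_samples: int, n_snps: int) -> SimulationConfig:
    """The null-calibration cohort: case status independent of inbreeding."""
    return SimulationConfig(
        n_samples=n_samples,
        case_fraction=0.5,
        n_snps=n_snps,
        n_x_snps=0,
        maf_dist=("uniform", 0.05, 0.5),
        f_dist=("normal_truncated", 0.01, 0.01),
        beta_het=0.0,
        beta_age=0.0,
        beta_bmi=0.0,
        beta_sex=0.0,
        beta_diabetes=0.0,
        cov_f_age=0.0,
        cov_f_bmi=0.0,
        missing_rate=0.0,
        seed=seed,
    )


def _fit_het_excess(cfg: SimulationConfig, qc: bool = True) -> AssociationResult:
    g, s, _ = generate_cohort(cfg)
    if qc:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g, s, _ = run_qc(g, s, QCConfig())
    prof = compute_het_profiles(g, 0.01)
    return association_test(prof, s, "het_excess", "all_oa", [])


def null_rejection_rate(
    n_replicates: int = 500,
    seed: int = 0,
    n_samples: int = 300,
    n_snps: int = 2000,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Empirical type-I error of the het_excess association test.

    Each replicate draws a null cohort (beta_het = 0), runs full QC, computes
    z-scored het_excess at MAF > 0.01, fits the logistic regression of status
    on the z-score, and tests at ``alpha``.  Returns (rejection fraction,
    number of replicates).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        res = _fit_het_excess(_null_config(rep_seed, n_samples, n_snps), qc=True)
        if res.p < alpha:
            rejections += 1
    return rejections / n_replicates, n_replicates


def _effect_config(seed: int, n_samples: int, n_snps: int,
                   or_per_sd: float) -> SimulationConfig:
    """A protective-effect cohort with enough F spread that the measured
    z(het_excess) tracks the true propensity closely (correlation > 0.95)."""
    return replace(
        _null_config(seed, n_samples, n_snps),
        f_dist=("normal_truncated", 0.05, 0.05),
        beta_het=float(np.log(or_per_sd)),
    )


def recovered_or(
    seed: int = 0,
    n_samples: int = 2000,
    n_snps: int = 20_000,
    true_or: float = 0.6,
) -> AssociationResult:
    """Fit one large protective-effect cohort; the OR per SD should recover
    the simulated effect up to sampling and attenuation error."""
    return _fit_het_excess(
        _effect_config(seed, n_samples, n_snps, true_or), qc=False
    )


def ci_coverage(
    n_replicates: int = 300,
    seed: int = 0,
    n_samples: int = 400,
    n_snps: int = 10_000,
    true_or: float = 0.6,
) -> tuple[float, int]:
    """Fraction of replicates whose 95% Wald CI contains the simulated OR."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        res = _fit_het_excess(
            _effect_config(rep_seed, n_samples, n_snps, true_or), qc=False
        )
        if res.ci_low <= true_or <= res.ci_high:
            hits += 1
    return hits / n_replicates, n_replicates


def het_excess_f_slope(
    seed: int = 0, n_samples: int = 400, n_snps: int = 20_000
) -> float:
    """Slope of het_excess on the true F (expected ≈ −1)."""
    cfg = _effect_config(seed, n_samples, n_snps, 1.0)
    g, s, truth = generate_cohort(cfg)
    prof = compute_het_profiles(g, 0.01)
    order = {sid: i for i, sid in enumerate(g.samples)}
    f = np.array([truth.f[order[sid]] for sid in prof.sample_id])
    return float(stats.linregress(f, prof.het_excess).slope)
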