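"""Seeded case-control cohort simulator.

The generative model mirrors what the analysis assumes: each individual
carries an inbreeding coefficient ``F`` that depresses their per-locus
heterozygote probability (``P(het) = 2p(1−p)(1−F)``); covariates can be given
a chosen Pearson correlation with ``−F``; and case status follows a logistic
model whose heterozygosity term is expressed per SD of the standardised
heterozygosity propensity ``s = z(−F)``, so the simulated ``beta_het`` reads
directly in the per-SD odds-ratio units the analysis reports.  QC violations
(missingness, heterozygote-deficit variants, exact duplicate samples, sex
swaps) can be injected and are recorded in a ground-truth registry for
recovery tests.

Variants are independent (no linkage disequilibrium): genome-wide per-sample
heterozygosity is a mean over loci, whose expectation LD does not change.

All randomness flows from one seed through named substreams, so changing
e.g. the number of injected duplicates does not shift genotype draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    GenotypeMatrix,
    MISSING,
    SampleTable,
    VARIANT_COLUMNS,
    write_genotype_tsv,
    write_sample_table,
)

_STREAMS = ("freqs", "f", "genotypes", "covariates", "outcome", "artifacts")


@dataclass
class SimulationConfig:
    """Cohort-generator parameters.

    Defaults encode the discovery-cohort design: 559 knee/hip OA cases and
    118 controls (172/559 hip), cohort-scale covariate distributions
    (age ≈ 62 ± 9 y, BMI ≈ 32 ± 6 kg/m², 56% female, 15% diabetes), weak
    age/BMI–heterozygosity correlations of magnitude ≈ 0.09, a protective
    per-SD heterozygosity effect of OR 0.6, and essentially complete
    genotyping (0.5% missingness) as after imputation.
    """

    n_samples: int = 677
    case_fraction: float = 559 / 677
    hip_fraction_of_cases: float = 172 / 559
    n_snps: int = 20_000
    n_x_snps: int = 200
    maf_dist: tuple = ("uniform", 0.05, 0.5)
    f_dist: tuple = ("normal_truncated", 0.01, 0.01)
    beta0: float | None = None  # None -> tuned to hit case_fraction
    beta_het: float = float(np.log(0.6))
    beta_age: float = 0.05
    beta_sex: float = 0.0
    beta_bmi: float = 0.05
    beta_diabetes: float = 0.0
    cov_f_age: float = -0.09
    cov_f_bmi: float = 0.09
    female_fraction: float = 0.56
    missing_rate: float = 0.005
    n_hwe_violations: int = 0
    n_duplicates: int = 0
    n_sex_swaps: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("case_fraction", "hip_fraction_of_cases", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_snps < 1 or self.n_samples < 2:
            raise ValueError("need n_snps >= 1 and n_samples >= 2")
        for name in ("cov_f_age", "cov_f_bmi"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be in (-1, 1)")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a generated cohort."""

    f: np.ndarray
    s: np.ndarray  # z-scored −F, the heterozygosity propensity
    beta_het: float
    beta0: float
    hwe_violation_ids: list[str] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    sex_swapped_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = {
            "f": np.asarray(self.f).tolist(),
            "s": np.asarray(self.s).tolist(),
            "beta_het": self.beta_het,
            "beta0": self.beta0,
            "hwe_violation_ids": self.hwe_violation_ids,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "sex_swapped_ids": self.sex_swapped_ids,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS.index(stream)])
    )


def draw_allele_freqs(n_snps: int, maf_dist: tuple, seed: int) -> np.ndarray:
    """Draw per-variant alt-allele frequencies in (0, 0.5] (alt = minor)."""
    rng = _rng(seed, "freqs")
    law, *params = maf_dist
    if law == "uniform":
        lo, hi = params
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"uniform MAF bounds must be within (0, 0.5], got {params}")
        return rng.uniform(lo, hi, size=n_snps)
    if law == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be > 0")
        p = rng.beta(a, b, size=n_snps)
        # fold onto (0, 0.5] and keep away from 0
        p = np.minimum(p, 1.0 - p)
        return np.clip(p, 1e-4, 0.5)
    raise ValueError(f"unknown MAF law {law!r}")


def draw_f(n: int, f_dist: tuple, seed: int) -> np.ndarray:
    """Per-sample inbreeding coefficients under the configured law."""
    rng = _rng(seed, "f")
    law, *params = f_dist
    if law == "point":
        return np.full(n, float(params[0]))
    if law == "normal_truncated":
        mean, sd = params
        f = rng.normal(mean, sd, size=n)
        return np.clip(f, -0.05, 0.5)
    if law == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be > 0")
        return rng.beta(a, b, size=n)
    raise ValueError(f"unknown F law {law!r}")


def _genotype_probs(p: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative genotype thresholds (hom_ref, hom_ref+het) per sample×variant.

    F is clamped per variant to the largest negative value that keeps all
    three genotype probabilities non-negative.
    """
    p = p[None, :]
    fcol = f[:, None]
    f_min = -np.minimum(p / (1 - p), (1 - p) / p)
    f_eff = np.maximum(fcol, f_min)
    pq = p * (1 - p)
    p_hom_ref = (1 - p) ** 2 + f_eff * pq
    p_het = 2 * pq * (1 - f_eff)
    return p_hom_ref, p_hom_ref + p_het


def simulate_genotypes(
    p: np.ndarray, f: np.ndarray, seed: int, chunk: int = 256
) -> GenotypeMatrix:
    """Draw genotypes with per-sample inbreeding.

    Per sample×variant: P(het) = 2p(1−p)(1−F), P(hom_alt) = p² + F·p(1−p),
    P(hom_ref) = (1−p)² + F·p(1−p).  Autosomal chromosome labels 1..22 are
    assigned round-robin.
    """
    p = np.asarray(p, float)
    f = np.asarray(f, float)
    if p.size == 0 or f.size == 0:
        raise ValueError("empty frequency or F vector")
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("allele frequencies must be in (0, 1)")
    rng = _rng(seed, "genotypes")
    n, m = f.size, p.size
    calls = np.empty((n, m), dtype=np.int8)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        c1, c2 = _genotype_probs(p, f[start:stop])
        u = rng.random((stop - start, m))
        calls[start:stop] = (u >= c1).astype(np.int8) + (u >= c2).astype(np.int8)
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1}" for j in range(m)],
            "chrom": [str(j % 22 + 1) for j in range(m)],
            "pos": [j // 22 + 1 for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )[VARIANT_COLUMNS]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, variants, calls)


def simulate_covariates(
    n: int,
    cov_f_age: float,
    cov_f_bmi: float,
    f: np.ndarray,
    seed: int,
    female_fraction: float = 0.56,
) -> pd.DataFrame:
    """Draw age, sex, BMI, diabetes; age/BMI get the requested Pearson
    correlation with −F via a bivariate-normal construction."""
    for rho in (cov_f_age, cov_f_bmi):
        if not abs(rho) < 1:
            raise ValueError("correlations must be in (-1, 1)")
    rng = _rng(seed, "covariates")
    neg_f = -np.asarray(f, float)
    sd = neg_f.std()
    z = (neg_f - neg_f.mean()) / sd if sd > 0 else np.zeros(n)

    def corr_normal(rho: float, mean: float, scale: float) -> np.ndarray:
        e = rng.standard_normal(n)
        return mean + scale * (rho * z + np.sqrt(1 - rho**2) * e)

    age = np.clip(corr_normal(cov_f_age, 62.0, 9.0), 18.0, None)
    bmi = np.clip(corr_normal(cov_f_bmi, 32.0, 6.0), 12.0, None)
    sex = np.where(rng.random(n) < female_fraction, "female", "male")
    diabetes = np.where(rng.random(n) < 0.15, "yes", "no")
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "diabetes": diabetes})


def simulate_outcome(
    f: np.ndarray, covariates: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """Draw case/control status and affected joint from the logistic model.

    The heterozygosity propensity is ``s = z(−F)``.  Unless ``config.beta0``
    is set, the intercept is tuned by bisection (against a fixed uniform
    draw, so the map from intercept to case count is a monotone step
    function) until the realised case fraction is within ±0.01 of target.
    Returns (status/joint frame, beta0 used, s).
    """
    cfg = config
    neg_f = -np.asarray(f, float)
    n = neg_f.size
    sd = neg_f.std(ddof=1)
    s = (neg_f - neg_f.mean()) / sd if sd > 0 else np.zeros(n)
    age_c = covariates["age"].to_numpy(float) - covariates["age"].mean()
    bmi_c = covariates["bmi"].to_numpy(float) - covariates["bmi"].mean()
    sex01 = (covariates["sex"] == "male").to_numpy(float)
    dia01 = (covariates["diabetes"] == "yes").to_numpy(float)
    lin = (
        cfg.beta_het * s
        + cfg.beta_age * age_c
        + cfg.beta_sex * sex01
        + cfg.beta_bmi * bmi_c
        + cfg.beta_diabetes * dia01
    )
    rng = _rng(cfg.seed, "outcome")
    u = rng.random(n)

    if cfg.beta0 is not None:
        beta0 = float(cfg.beta0)
        status = u < expit(beta0 + lin)
    else:
        target = int(round(cfg.case_fraction * n))
        lo, hi = -40.0, 40.0
        if (u < expit(lo + lin)).sum() > target or (u < expit(hi + lin)).sum() < target:
            raise ValueError("unattainable case fraction")
        for _ in range(200):
            beta0 = 0.5 * (lo + hi)
            k = int((u < expit(beta0 + lin)).sum())
            if k < target:
                lo = beta0
            elif k > target:
                hi = beta0
            else:
                break
        status = u < expit(beta0 + lin)
        if abs(status.mean() - cfg.case_fraction) > 0.01:
            raise ValueError("unattainable case fraction")

    joint = np.where(
        status, np.where(rng.random(n) < cfg.hip_fraction_of_cases, "hip", "knee"),
        "none",
    )
    out = pd.DataFrame(
        {"status": np.where(status, "case", "control"), "joint": joint}
    )
    return out, float(beta0), s


def inject_artifacts(
    g: GenotypeMatrix,
    samples: SampleTable,
    config: SimulationConfig,
    truth: SimulationTruth,
) -> tuple[GenotypeMatrix, SampleTable, SimulationTruth]:
    """Inject QC violations and the sex-aware X-chromosome block.

    Order: X block appended (males hemizygous → coded as homozygotes, no
    hets; females under HWE) → random missingness → heterozygote-deficit
    variants (all samples redrawn at F = 0.8) → exact duplicate samples
    appended under new ids → recorded-sex swaps.  Everything is registered
    in the truth object.
    """
    cfg = config
    rng = _rng(cfg.seed, "artifacts")
    calls = g.calls.copy()
    variants = g.variants.copy()

    # sex-aware X block
    if cfg.n_x_snps > 0:
        px = rng.uniform(0.05, 0.5, size=cfg.n_x_snps)
        male = (samples.df["sex"] == "male").to_numpy()
        u = rng.random((g.n_samples, cfg.n_x_snps))
        female_calls = (u >= (1 - px) ** 2).astype(np.int8) + (
            u >= (1 - px) ** 2 + 2 * px * (1 - px)
        ).astype(np.int8)
        male_calls = np.where(u < px, 2, 0).astype(np.int8)
        xblock = np.where(male[:, None], male_calls, female_calls)
        xvars = pd.DataFrame(
            {
                "variant_id": [f"xsnp{j + 1}" for j in range(cfg.n_x_snps)],
                "chrom": "X",
                "pos": np.arange(1, cfg.n_x_snps + 1),
                "ref": "A",
                "alt": "G",
            }
        )[VARIANT_COLUMNS]
        calls = np.hstack([calls, xblock])
        variants = pd.concat([variants, xvars], ignore_index=True)

    # random missingness
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    # heterozygote-deficit variants (strong HWE violation, F = 0.8)
    auto_idx = np.flatnonzero(
        variants["chrom"].isin([str(i) for i in range(1, 23)]).to_numpy()
    )
    if cfg.n_hwe_violations > 0:
        if cfg.n_hwe_violations > auto_idx.size:
            raise ValueError("more HWE violations requested than autosomal variants")
        chosen = rng.choice(auto_idx, size=cfg.n_hwe_violations, replace=False)
        pv = rng.uniform(0.2, 0.5, size=chosen.size)
        fdef = np.full(calls.shape[0], 0.8)
        for k, j in enumerate(chosen):
            c1, c2 = _genotype_probs(np.array([pv[k]]), fdef)
            u = rng.random((calls.shape[0], 1))
            calls[:, [j]] = (u >= c1).astype(np.int8) + (u >= c2).astype(np.int8)
        truth.hwe_violation_ids = sorted(variants["variant_id"].iloc[chosen])

    sdf = samples.df.copy()
    sample_ids = list(g.samples)

    # exact duplicates under new ids
    if cfg.n_duplicates > 0:
        if cfg.n_duplicates > len(sample_ids):
            raise ValueError("more duplicates requested than samples")
        src = rng.choice(len(sample_ids), size=cfg.n_duplicates, replace=False)
        dup_rows, pairs = [], []
        for i in src:
            new_id = f"{sample_ids[i]}dup"
            pairs.append((sample_ids[i], new_id))
            row = sdf.iloc[i].copy()
            row["sample_id"] = new_id
            dup_rows.append(row)
            calls = np.vstack([calls, calls[i][None, :]])
            sample_ids.append(new_id)
        sdf = pd.concat([sdf, pd.DataFrame(dup_rows)], ignore_index=True)
        truth.duplicate_pairs = pairs

    # sex swaps
    if cfg.n_sex_swaps > 0:
        has_sex = sdf["sex"].notna().to_numpy()
        pool = np.flatnonzero(has_sex[: g.n_samples])
        if cfg.n_sex_swaps > pool.size:
            raise ValueError("more sex swaps requested than samples with sex")
        swap = rng.choice(pool, size=cfg.n_sex_swaps, replace=False)
        flip = {"female": "male", "male": "female"}
        sdf.loc[swap, "sex"] = sdf.loc[swap, "sex"].map(flip)
        truth.sex_swapped_ids = sorted(sdf.loc[swap, "sample_id"])

    g_out = GenotypeMatrix(sample_ids, variants, calls)
    return g_out, SampleTable(sdf), truth


def generate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleTable, SimulationTruth]:
    """End-to-end cohort generation, fully reproducible from the config."""
    cfg = config
    cfg.validate()
    p = draw_allele_freqs(cfg.n_snps, cfg.maf_dist, cfg.seed)
    f = draw_f(cfg.n_samples, cfg.f_dist, cfg.seed)
    g = simulate_genotypes(p, f, cfg.seed)
    cov = simulate_covariates(
        cfg.n_samples, cfg.cov_f_age, cfg.cov_f_bmi, f, cfg.seed,
        cfg.female_fraction,
    )
    outcome, beta0, s = simulate_outcome(f, cov, cfg)
    sdf = pd.concat(
        [pd.DataFrame({"sample_id": g.samples}), outcome, cov], axis=1
    )[["sample_id", "status", "joint", "age", "sex", "bmi", "diabetes"]]
    samples = SampleTable(sdf)
    truth = SimulationTruth(f=f, s=s, beta_het=cfg.beta_het, beta0=beta0,
                            seed=cfg.seed)
    return inject_artifacts(g, samples, cfg, truth)


def write_cohort(
    g: GenotypeMatrix, samples: SampleTable, truth: SimulationTruth, outdir: str | Path
) -> None:
    """Write a generated cohort as genotype TSV + sidecar + sample TSV + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_tsv(g, outdir / "genotypes.tsv")
    write_sample_table(samples, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")


# study-design presets ------------------------------------------------------

def preset(name: str, **overrides) -> SimulationConfig:
    """Named study-design presets.

    ``nl``: 559 cases / 118 controls with covariate effects (discovery
    design).  ``replication``: 2,019 cases / 2,029 controls, all female, no
    covariate effects (replication design, where age and BMI are unused).
    """
    if name == "nl":
        cfg = SimulationConfig()
    elif name == "replication":
        cfg = SimulationConfig(
            n_samples=4048,
            case_fraction=2019 / 4048,
            hip_fraction_of_cases=0.5,
            beta_age=0.0,
            beta_bmi=0.0,
            cov_f_age=0.0,
            cov_f_bmi=0.0,
            female_fraction=1.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg
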