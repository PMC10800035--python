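"""Per-individual heterozygosity statistics.

Two per-sample metrics drive the analysis:

* ``het_rate`` — the count of heterozygous genotypes divided by the count of
  homozygous-alternative genotypes (an ``hom_all`` denominator option divides
  by all homozygotes instead, the convention of standard per-sample
  heterozygosity tooling).
* ``het_excess`` — ``(H_obs − H_exp) / H_exp``, the individual's relative
  excess of observed over expected heterozygosity.  Algebraically this equals
  ``−F̂`` where ``F̂ = 1 − H_obs/H_exp`` is the method-of-moments inbreeding
  coefficient, so a more inbred individual has a more negative ``het_excess``.

Both are computed over autosomal variants above a MAF threshold (two strata
by default: MAF > 0.01 and MAF > 0.1) and z-standardised across the analysis
set before any regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HET_PROFILE_COLUMNS, MISSING, GenotypeMatrix
from .qc import allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class HetOptions:
    """Options for :func:`compute_het_profiles`.

    denominator : 'hom_alt' (heterozygotes over homozygous-alt genotypes) or
        'hom_all' (over all homozygotes).
    small_sample_correction : multiply per-variant 2p(1−p) by 2N/(2N−1),
        matching standard per-sample expected-homozygosity tooling.
    """

    denominator: str = "hom_alt"
    small_sample_correction: bool = True

    def __post_init__(self) -> None:
        if self.denominator not in ("hom_alt", "hom_all"):
            raise ValueError(f"unknown denominator mode {self.denominator!r}")


def stratum_label(maf_threshold: float) -> str:
    if abs(maf_threshold - 0.01) < 1e-12:
        return "maf_gt_001"
    if abs(maf_threshold - 0.1) < 1e-12:
        return "maf_gt_01"
    return f"maf_gt_{maf_threshold:g}"


def genotype_counts(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample genotype counts over autosomal variants.

    Returns a frame with n_het, n_hom_ref, n_hom_alt, n_missing per sample.
    Samples with zero non-missing calls are flagged (``degenerate`` column)
    and excluded downstream.
    """
    auto = g.autosomal_mask()
    c = g.calls[:, auto]
    df = pd.DataFrame(
        {
            "sample_id": g.samples,
            "n_het": (c == 1).sum(axis=1),
            "n_hom_ref": (c == 0).sum(axis=1),
            "n_hom_alt": (c == 2).sum(axis=1),
            "n_missing": (c == MISSING).sum(axis=1),
        }
    )
    df["degenerate"] = (df.n_het + df.n_hom_ref + df.n_hom_alt) == 0
    for sid in df.loc[df.degenerate, "sample_id"]:
        logger.warning("sample %s has no non-missing autosomal calls", sid)
    return df


def het_rate(
    n_het: int, n_hom_alt: int, n_hom_ref: int = 0, denominator: str = "hom_alt"
) -> float:
    """Heterozygote count over the chosen homozygote count.

    Returns NaN when the denominator is zero (the caller excludes such
    samples with a warning).
    """
    denom = n_hom_alt if denominator == "hom_alt" else n_hom_alt + n_hom_ref
    if denom == 0:
        return float("nan")
    return n_het / denom


def het_excess(h_obs: float, h_exp: float) -> float:
    """Relative excess of observed over expected heterozygosity."""
    if h_exp == 0:
        return float("nan")
    return (h_obs - h_exp) / h_exp


def expected_het(
    g: GenotypeMatrix,
    freqs: pd.DataFrame | None = None,
    small_sample_correction: bool = True,
) -> np.ndarray:
    """Per-sample expected heterozygosity rate.

    For sample *i*: the mean over its non-missing autosomal variants *j* of
    ``u_j = 2 p_j (1 − p_j)``, optionally multiplied by ``2N_j/(2N_j − 1)``
    (``N_j`` = samples called at *j*).  Monomorphic variants contribute 0.
    Samples with no non-missing calls get NaN.
    """
    auto = g.autosomal_mask()
    ga = g.subset_variants(auto) if not auto.all() else g
    if freqs is None:
        freqs = allele_frequencies(ga)
    p = freqs["p_alt"].to_numpy(dtype=float)
    n_called = freqs["n_called"].to_numpy(dtype=float)
    u = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(n_called > 0, u * 2 * n_called / (2 * n_called - 1), 0.0)
    u = np.nan_to_num(u, nan=0.0)
    nonmissing = ga.calls != MISSING
    denom = nonmissing.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_exp = np.where(denom > 0, nonmissing @ u / denom, np.nan)
    return h_exp


def zscore(values: np.ndarray | list[float]) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = x.std(ddof=1)
    # relative guard: rounding noise on a constant vector is not spread
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("cannot standardize constant vector")
    return (x - x.mean()) / sd


def compute_het_profiles(
    g: GenotypeMatrix,
    maf_threshold: float = 0.01,
    options: HetOptions | None = None,
) -> pd.DataFrame:
    """Heterozygosity profile per sample for one MAF stratum.

    Restricts to autosomal variants with MAF strictly above the threshold,
    computes genotype counts, H_obs, H_exp, het_rate and het_excess, then
    z-scores both metrics across all retained samples (cases and controls
    together).  Samples with an undefined statistic (zero denominator or no
    calls) are dropped from the table entirely so both metrics share one
    analysis set.
    """
    options = options or HetOptions()
    auto = g.autosomal_mask()
    ga = g.subset_variants(auto)
    if ga.n_variants == 0:
        raise ValueError("no autosomal variants")
    freqs = allele_frequencies(ga)
    keep = freqs["maf"].to_numpy() > maf_threshold
    gs = ga.subset_variants(keep)
    if gs.n_variants == 0:
        raise ValueError(f"no variants above MAF {maf_threshold}")
    freqs_s = freqs.loc[keep].reset_index(drop=True)

    counts = genotype_counts(gs)
    n_nm = (counts.n_het + counts.n_hom_ref + counts.n_hom_alt).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_obs = np.where(n_nm > 0, counts.n_het / n_nm, np.nan)
    h_exp = expected_het(gs, freqs_s, options.small_sample_correction)

    hr = np.array(
        [
            het_rate(h, a, r, options.denominator)
            for h, a, r in zip(counts.n_het, counts.n_hom_alt, counts.n_hom_ref)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = np.where(h_exp > 0, (h_obs - h_exp) / h_exp, np.nan)

    df = counts.drop(columns="degenerate").copy()
    df["stratum"] = stratum_label(maf_threshold)
    df["h_obs"], df["h_exp"] = h_obs, h_exp
    df["het_rate"], df["het_excess"] = hr, hx

    ok = np.isfinite(hr) & np.isfinite(hx)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "dropping %d sample(s) with undefined heterozygosity statistics: %s",
            n_dropped, list(df.loc[~ok, "sample_id"]),
        )
    df = df.loc[ok].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("fewer than 2 samples with defined statistics")
    df["z_het_rate"] = zscore(df["het_rate"])
    df["z_het_excess"] = zscore(df["het_excess"])
    return df[HET_PROFILE_COLUMNS]


def compute_strata(
    g: GenotypeMatrix,
    maf_thresholds: tuple[float, ...] = (0.01, 0.1),
    options: HetOptions | None = None,
) -> pd.DataFrame:
    """Profiles for several MAF strata, concatenated (one row per sample per
    stratum)."""
    frames = [compute_het_profiles(g, t, options) for t in maf_thresholds]
    return pd.concat(frames, ignore_index=True)
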