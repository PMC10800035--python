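"""Variant- and sample-level genotype quality control.

Sample filters (exact-duplicate removal by identity-by-state, sex-discordance
by X-chromosome heterozygosity) run first; variant filters then run in the
order missingness → Hardy–Weinberg → minor allele frequency, with allele
frequencies recomputed after sample removal.  Every removal is attributed to
exactly one filter in the :class:`QCReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for :func:`run_qc`.  Defaults follow standard GWAS practice:
    keep MAF > 0.01, drop missingness > 5%, exact-test HWE at alpha 1e-6 over
    all samples, duplicates at IBS >= 0.95."""

    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_alpha: float = 1e-6
    hwe_scope: str = "all"  # "all" or "controls"
    ibs_min: float = 0.95
    x_het_female_min: float = 0.05
    x_het_male_max: float = 0.10
    # hook for user-supplied exclusions (e.g. population-structure outliers)
    exclude_samples: tuple[str, ...] = ()


@dataclass
class QCReport:
    n_variants_in: int
    n_variants_out: int
    n_samples_in: int
    n_samples_out: int
    removed_by_maf: int
    removed_by_missingness: int
    removed_by_hwe: int
    removed_duplicate_samples: int
    removed_sex_discordant: int
    thresholds: QCConfig
    removed_variant_ids: list[str] = field(default_factory=list)
    removed_sample_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_variants_out == (
            self.n_variants_in - self.removed_by_maf
            - self.removed_by_missingness - self.removed_by_hwe
        )
        assert self.n_samples_out == (
            self.n_samples_in - self.removed_duplicate_samples
            - self.removed_sex_discordant - getattr(self, "removed_excluded", 0)
        )

    def to_frame(self) -> pd.DataFrame:
        t = self.thresholds
        return pd.DataFrame(
            [
                ("duplicates", t.ibs_min, self.removed_duplicate_samples),
                ("sex_discordance", "-", self.removed_sex_discordant),
                ("missingness", t.miss_max, self.removed_by_missingness),
                ("hwe", t.hwe_alpha, self.removed_by_hwe),
                ("maf", t.maf_min, self.removed_by_maf),
            ],
            columns=["filter", "threshold", "n_removed"],
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def genotype_count_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant genotype counts (n_hom_ref, n_het, n_hom_alt, n_missing)."""
    c = g.calls
    return pd.DataFrame(
        {
            "variant_id": g.variant_ids.to_numpy(),
            "n_hom_ref": (c == 0).sum(axis=0),
            "n_het": (c == 1).sum(axis=0),
            "n_hom_alt": (c == 2).sum(axis=0),
            "n_missing": (c == MISSING).sum(axis=0),
        }
    )


def allele_frequencies(g: GenotypeMatrix) -> pd.DataFrame:
    """Alt-allele frequency and MAF per variant, missing calls excluded.

    Variants with no non-missing call get ``p_alt = NaN`` (they fail every
    frequency-based filter downstream rather than raising).
    """
    c = g.calls
    called = c != MISSING
    n_called = called.sum(axis=0)
    alt_sum = np.where(called, c, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame(
        {
            "variant_id": g.variant_ids.to_numpy(),
            "p_alt": p_alt,
            "maf": maf,
            "n_called": n_called,
        }
    )


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

def filter_maf(
    g: GenotypeMatrix, freqs: pd.DataFrame, maf_min: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep variants with MAF strictly greater than ``maf_min``."""
    if not (0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    maf = freqs["maf"].to_numpy()
    keep = maf > maf_min  # NaN compares False -> degenerate variants removed
    removed = list(g.variant_ids[~keep])
    return g.subset_variants(keep), removed


def filter_missingness(
    g: GenotypeMatrix, miss_max: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove variants whose missing-call fraction exceeds ``miss_max``."""
    if not (0 <= miss_max <= 1):
        raise ValueError(f"miss_max must be in [0, 1], got {miss_max}")
    rate = (g.calls == MISSING).mean(axis=0)
    keep = rate <= miss_max  # strict ">" removal
    removed = list(g.variant_ids[~keep])
    return g.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _het_distribution(n_minor: int, n_total: int) -> np.ndarray:
    """Conditional distribution of the heterozygote count given allele counts.

    P(n_het | n_minor minor alleles among 2*n_total) over the attainable
    heterozygote counts ``n_minor, n_minor-2, ...`` (same parity as n_minor),
    computed with log-gamma for stability and normalised to sum to 1.
    """
    from scipy.special import gammaln

    n_major = 2 * n_total - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (n_major - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n_total + 1)
        - gammaln(hom_minor + 1) - gammaln(hets + 1) - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every attainable heterozygote count whose conditional probability does
    not exceed that of the observed count.  Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    probs = _het_distribution(n_minor, n)
    idx = (n_het - (n_minor % 2)) // 2
    p_obs = probs[idx]
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


def filter_hwe(
    g: GenotypeMatrix,
    hwe_alpha: float,
    scope: str = "all",
    samples: SampleTable | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove autosomal variants failing the HWE exact test at ``hwe_alpha``.

    ``scope='controls'`` computes the test over control samples only (a
    SampleTable is then required); the default tests all samples.
    Non-autosomal variants are always retained: male hemizygosity makes the
    diploid HWE law inapplicable on X/Y.
    """
    if not (0 < hwe_alpha < 1):
        raise ValueError(f"hwe_alpha must be in (0, 1), got {hwe_alpha}")
    if scope not in ("all", "controls"):
        raise ValueError(f"unknown HWE scope {scope!r}")
    gt = g
    if scope == "controls":
        if samples is None:
            raise ValueError("scope='controls' requires a SampleTable")
        ctrl = samples.df.loc[samples.df["status"] == "control", "sample_id"]
        gt = g.subset_samples([s for s in g.samples if s in set(ctrl)])
    counts = genotype_count_table(gt)
    autosomal = g.autosomal_mask()
    keep = np.ones(g.n_variants, dtype=bool)
    for j, (a, b, c) in enumerate(
        counts[["n_hom_ref", "n_het", "n_hom_alt"]].itertuples(index=False)
    ):
        if not autosomal[j]:
            continue
        if a + b + c == 0:
            keep[j] = False
            continue
        keep[j] = hwe_exact_test(a, b, c) >= hwe_alpha
    removed = list(g.variant_ids[~keep])
    return g.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# sample filters
# ---------------------------------------------------------------------------

def find_duplicates(
    g: GenotypeMatrix, ibs_min: float = 0.95, min_overlap: int = 50
) -> list[tuple[str, str, float]]:
    """Find sample pairs with identity-by-state >= ``ibs_min``.

    IBS is the fraction of identical genotype codes over mutually non-missing
    variants.  Pairs with fewer than ``min_overlap`` overlapping variants are
    skipped with a warning (their IBS is unreliable).
    """
    if g.n_samples < 2:
        return []
    c = g.calls
    called = (c != MISSING).astype(np.float64)
    overlap = called @ called.T
    matches = np.zeros_like(overlap)
    for code in (0, 1, 2):
        ind = (c == code).astype(np.float64)
        matches += ind @ ind.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ibs = np.where(overlap > 0, matches / overlap, np.nan)
    out: list[tuple[str, str, float]] = []
    n = g.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            if overlap[i, j] < min_overlap:
                warnings.warn(
                    f"pair ({g.samples[i]}, {g.samples[j]}): only "
                    f"{int(overlap[i, j])} overlapping variants; IBS skipped"
                )
                continue
            if ibs[i, j] >= ibs_min:
                out.append((g.samples[i], g.samples[j], float(ibs[i, j])))
    return out


def check_sex(
    g: GenotypeMatrix,
    samples: SampleTable,
    x_het_female_min: float = 0.05,
    x_het_male_max: float = 0.10,
) -> list[str]:
    """Flag samples whose X-heterozygosity contradicts their recorded sex.

    Males are hemizygous on X, so a genuine male shows essentially no X
    heterozygotes; a recorded male above ``x_het_male_max`` or a recorded
    female below ``x_het_female_min`` is flagged.
    """
    xmask = g.x_mask()
    if not xmask.any():
        warnings.warn("check_sex: no X-chromosome variants; skipping")
        return []
    x = g.calls[:, xmask]
    called = (x != MISSING).sum(axis=1)
    het = (x == 1).sum(axis=1)
    sex = samples.df.set_index("sample_id")["sex"]
    flagged: list[str] = []
    for i, sid in enumerate(g.samples):
        rec = sex.get(sid)
        if pd.isna(rec) or called[i] == 0:
            warnings.warn(f"check_sex: sample {sid} skipped (no sex or no X calls)")
            continue
        rate = het[i] / called[i]
        if (rec == "female" and rate < x_het_female_min) or (
            rec == "male" and rate > x_het_male_max
        ):
            flagged.append(sid)
    return flagged


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_qc(
    g: GenotypeMatrix, samples: SampleTable, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, SampleTable, QCReport]:
    """Full QC: duplicates → sex discordance → missingness → HWE → MAF.

    Within a duplicate pair the member with fewer missing calls is kept
    (ties: lexicographically smaller sample_id).  Frequencies for the variant
    filters are recomputed on the post-sample-QC matrix.
    """
    config = config or QCConfig()
    n_variants_in, n_samples_in = g.n_variants, g.n_samples

    drop: set[str] = set()
    if config.exclude_samples:
        drop |= set(config.exclude_samples) & set(g.samples)
    n_excluded = len(drop)

    miss_per_sample = dict(zip(g.samples, (g.calls == MISSING).sum(axis=1)))
    dup_drop: set[str] = set()
    for s1, s2, _ in find_duplicates(g, config.ibs_min):
        if s1 in dup_drop or s2 in dup_drop:
            continue
        key = lambda s: (miss_per_sample[s], s)
        dup_drop.add(max((s1, s2), key=key))
    dup_drop -= drop
    drop |= dup_drop

    sex_drop = set(
        check_sex(g, samples, config.x_het_female_min, config.x_het_male_max)
    ) - drop
    drop |= sex_drop

    keep_ids = [s for s in g.samples if s not in drop]
    if not keep_ids:
        raise RuntimeError("QC removed everything: no samples left")
    g2 = g.subset_samples(keep_ids)
    samples2 = samples.subset(keep_ids)

    g3, rm_miss = filter_missingness(g2, config.miss_max)
    g4, rm_hwe = filter_hwe(
        g3, config.hwe_alpha, config.hwe_scope,
        samples2 if config.hwe_scope == "controls" else None,
    )
    freqs = allele_frequencies(g4)
    g5, rm_maf = filter_maf(g4, freqs, config.maf_min)
    if g5.n_variants == 0:
        raise RuntimeError("QC removed everything: no variants left")

    report = QCReport(
        n_variants_in=n_variants_in,
        n_variants_out=g5.n_variants,
        n_samples_in=n_samples_in,
        n_samples_out=g5.n_samples,
        removed_by_maf=len(rm_maf),
        removed_by_missingness=len(rm_miss),
        removed_by_hwe=len(rm_hwe),
        removed_duplicate_samples=len(dup_drop),
        removed_sex_discordant=len(sex_drop),
        thresholds=config,
        removed_variant_ids=rm_miss + rm_hwe + rm_maf,
        removed_sample_ids=sorted(drop),
    )
    report.removed_excluded = n_excluded  # type: ignore[attr-defined]
    logger.info(
        "QC: %d->%d samples, %d->%d variants (miss %d, hwe %d, maf %d)",
        n_samples_in, g5.n_samples, n_variants_in, g5.n_variants,
        len(rm_miss), len(rm_hwe), len(rm_maf),
    )
    return g5, samples2, report
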