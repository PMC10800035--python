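"""Genotype, sample-metadata and result-table I/O.

Genotypes are carried as a dense samples × variants matrix of alt-allele
counts (0/1/2) with a dedicated missing sentinel, the substrate for all
heterozygosity computation.  Supported on-disk formats are VCF (GT field,
biallelic SNVs) and a plain genotype TSV dialect with a ``*.variants.tsv``
sidecar holding variant coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never enters arithmetic.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

HET_PROFILE_COLUMNS = [
    "sample_id", "stratum", "n_het", "n_hom_ref", "n_hom_alt", "n_missing",
    "h_obs", "h_exp", "het_rate", "het_excess", "z_het_rate", "z_het_excess",
]

ASSOCIATION_COLUMNS = [
    "stratum", "metric", "subgroup", "n_case", "n_control",
    "beta", "se", "or_per_sd", "ci_low", "ci_high", "p", "covariates",
]


class FormatError(ValueError):
    """Malformed input file (names the offending line/cell where possible)."""


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GenotypeMatrix:
    """Samples × variants alt-allele count matrix.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, in matrix row order; unique.
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos, ref, alt``;
        ``variant_id`` unique, ``pos`` 1-based.
    calls : numpy.ndarray of int8
        Shape ``(len(samples), len(variants))``; entries in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample_id in GenotypeMatrix")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            raise ValueError("duplicate variant_id in GenotypeMatrix")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[i, j]} at "
                f"sample {self.samples[i]}, variant {vid.iloc[j]}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Series:
        return self.variants["variant_id"]

    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over variants on chromosomes 1..22."""
        return self.variants["chrom"].map(_norm_chrom).isin(AUTOSOMES).to_numpy()

    def x_mask(self) -> np.ndarray:
        norm = self.variants["chrom"].map(_norm_chrom)
        return norm.isin({"X", "23"}).to_numpy()

    # -- subsetting -----------------------------------------------------
    def subset_variants(self, which: np.ndarray) -> "GenotypeMatrix":
        """Subset (boolean mask) or reorder (integer index array) variants."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.flatnonzero(which)
        else:
            idx = which
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def subset_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in keep_ids]
        return GenotypeMatrix(
            samples=list(keep_ids),
            variants=self.variants.copy(),
            calls=self.calls[rows, :].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SampleTable:
    """Per-sample phenotype and covariates.

    Wraps a DataFrame with columns ``sample_id, status, joint, age, sex,
    bmi, diabetes``; optional fields may be NaN/None.  Invariants:
    ``joint == 'none'`` exactly for controls; positive age and BMI.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = ["sample_id", "status", "joint", "age", "sex", "bmi", "diabetes"]
        for col in required:
            if col not in df.columns:
                df[col] = np.nan
        df = df[required]
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        for i, row in df.iterrows():
            _validate_sample_row(row, i)
        self.df = df

    @property
    def sample_ids(self) -> pd.Series:
        return self.df["sample_id"]

    def subset(self, keep_ids: list[str]) -> "SampleTable":
        sub = self.df.set_index("sample_id").loc[list(keep_ids)].reset_index()
        return SampleTable(sub)

    def equals(self, other: "SampleTable") -> bool:
        a, b = self.df, other.df
        if list(a["sample_id"]) != list(b["sample_id"]):
            return False
        for col in ("status", "joint", "sex", "diabetes"):
            if not a[col].fillna("").equals(b[col].fillna("")):
                return False
        for col in ("age", "bmi"):
            av, bv = a[col].to_numpy(float), b[col].to_numpy(float)
            ok = np.isclose(av, bv, rtol=1e-5, equal_nan=True)
            if not ok.all():
                return False
        return True


def _validate_sample_row(row: pd.Series, i: int) -> None:
    sid = row["sample_id"]
    if row["status"] not in ("case", "control"):
        raise FormatError(f"row {i} ({sid}): unknown status {row['status']!r}")
    if row["joint"] not in ("hip", "knee", "none"):
        raise FormatError(f"row {i} ({sid}): unknown joint {row['joint']!r}")
    if (row["status"] == "control") != (row["joint"] == "none"):
        raise FormatError(
            f"row {i} ({sid}): joint {row['joint']!r} inconsistent with "
            f"status {row['status']!r}"
        )
    sex = row["sex"]
    if not (pd.isna(sex) or sex in ("female", "male")):
        raise FormatError(f"row {i} ({sid}): unknown sex {sex!r}")
    dia = row["diabetes"]
    if not (pd.isna(dia) or dia in ("yes", "no")):
        raise FormatError(f"row {i} ({sid}): unknown diabetes flag {dia!r}")
    for col in ("age", "bmi"):
        v = row[col]
        if not pd.isna(v) and float(v) <= 0:
            raise FormatError(f"row {i} ({sid}): {col} must be positive, got {v}")


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF (plain or bgzipped) into a matrix.

    Only the GT subfield is used; phase is ignored, half calls and ``./.``
    become missing.  Multiallelic and non-SNV records are skipped (a count
    is logged).  Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")

    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        calls = np.empty(len(samples), dtype=np.int8)
        for k, g in enumerate(gts):
            a = g[:-1]
            if len(a) < 2 or min(a) < 0:
                calls[k] = MISSING
            else:
                calls[k] = int(a[0] > 0) + int(a[1] > 0)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        meta.append((vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        rows.append(calls)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNV records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic SNV records")
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(samples, variants, np.column_stack(rows))


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    base = str(path)
    if base.endswith(".tsv"):
        base = base[: -len(".tsv")]
    return Path(base + ".variants.tsv")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype TSV dialect (main matrix + ``*.variants.tsv`` sidecar).

    Main file: header ``sample_id<TAB>variant ids...``, one row per sample,
    cells in {0,1,2,NA}.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    for p in (path, sidecar):
        if not p.exists():
            raise FormatError(f"no such file: {p}")
    variants = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
    if list(variants.columns) != VARIANT_COLUMNS:
        raise FormatError(f"{sidecar}: expected columns {VARIANT_COLUMNS}")

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample_id":
            raise FormatError(f"{path}: first header field must be 'sample_id'")
        variant_ids = header[1:]
        if variant_ids != list(variants["variant_id"]):
            raise FormatError(f"{path}: variant ids disagree with sidecar {sidecar}")
        samples: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(variant_ids) + 1:
                raise FormatError(
                    f"{path}: row {lineno} has {len(fields)} fields, "
                    f"expected {len(variant_ids) + 1}"
                )
            samples.append(fields[0])
            row = np.empty(len(variant_ids), dtype=np.int8)
            for j, cell in enumerate(fields[1:]):
                if cell == "NA":
                    row[j] = MISSING
                elif cell in ("0", "1", "2"):
                    row[j] = int(cell)
                else:
                    raise FormatError(
                        f"{path}: invalid cell {cell!r} at row {lineno}, "
                        f"column {j + 2}"
                    )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    return GenotypeMatrix(samples, variants, np.vstack(rows))


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix in the TSV dialect (matrix + variants sidecar)."""
    path = Path(path)
    g.variants[VARIANT_COLUMNS].to_csv(_sidecar_path(path), sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", *g.variant_ids]) + "\n")
        lookup = np.array(["0", "1", "2"] + [""] * 252 + ["NA"], dtype=object)
        for i, sid in enumerate(g.samples):
            cells = lookup[g.calls[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    """Read the sample TSV (sample_id,status,joint,age,sex,bmi,diabetes)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str},
        keep_default_na=True, na_values=[""],
    )
    expected = ["sample_id", "status", "joint", "age", "sex", "bmi", "diabetes"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    # an empty joint cell on a control reads as 'none'
    ctrl = df["status"] == "control"
    df.loc[ctrl & df["joint"].isna(), "joint"] = "none"
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    df = samples.df.copy()
    df.loc[df["joint"] == "none", "joint"] = np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a result table (het profiles, association grid, QC report) as TSV.

    Column order is fixed per table kind, floats are written at 6 significant
    digits, and rows are sorted deterministically (by sample then stratum, or
    by stratum/metric/subgroup).  ``kind`` is inferred from the columns when
    not given.
    """
    if not isinstance(rows, pd.DataFrame) or rows.empty:
        raise ValueError("write_table: empty input")
    df = rows.copy()
    cols = set(df.columns)
    if kind is None:
        if {"sample_id", "het_rate"} <= cols:
            kind = "het_profiles"
        elif {"or_per_sd", "subgroup"} <= cols:
            kind = "association"
        elif {"filter", "n_removed"} <= cols:
            kind = "qc_report"
        else:
            raise ValueError(f"write_table: cannot infer table kind from {sorted(cols)}")
    if kind == "het_profiles":
        df = df[HET_PROFILE_COLUMNS].sort_values(["sample_id", "stratum"])
    elif kind == "association":
        df = df[ASSOCIATION_COLUMNS]
        df = df.sort_values(["stratum", "metric", "subgroup"], kind="stable")
    elif kind == "qc_report":
        df = df[["filter", "threshold", "n_removed"]]
    else:
        raise ValueError(f"write_table: unknown kind {kind!r}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
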