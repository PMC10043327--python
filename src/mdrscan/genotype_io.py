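"""Genotype matrix I/O and per-SNP quality control.

Genotypes are stored as minor-allele dosage (0/1/2) for biallelic autosomal
SNPs in an n_samples x n_snps integer matrix.  A reserved sentinel marks
missing calls; the default QC gate (0% missingness) guarantees downstream
modules see complete data, so they treat the sentinel as a contract
violation rather than a condition to handle.

Supported on-disk dialects are PLINK text ped/map (whitespace-delimited
allele-letter pairs, ``0 0`` = missing) and a simple TSV with a
``sample_id`` header column followed by one 0/1/2/NA column per SNP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reserved dosage code for a missing genotype call.
MISSING: int = -1

SAMPLE_COLUMNS = ["sample_id", "status5y", "stage", "location", "chemo", "radio"]
OPTIONAL_SAMPLE_COLUMNS = ["time", "event"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under the named dialect."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: identity, position and the observed allele pair.

    ``allele_minor`` is determined from the data (lower observed frequency,
    ties broken to the alphabetically later allele) and is the allele the
    dosage column counts.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_major: str
    allele_minor: str
    gene_hint: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor allele identical")

    @property
    def label(self) -> str:
        """Report-style name ``rsID_minorAllele``."""
        return f"{self.snp_id}_{self.allele_minor}"


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with per-SNP metadata."""

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # int8, values in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in variant list")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,MISSING}")
        self._index = {v.snp_id: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self._index[snp_id]]

    def column_index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, row_idx: Sequence[int]) -> "GenotypeMatrix":
        row_idx = list(row_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in row_idx],
            variants=list(self.variants),
            dosage=self.dosage[row_idx, :].copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _minor_major(counts: dict[str, int]) -> tuple[str, str]:
    """(minor, major) from allele counts; tie -> alphabetically later minor."""
    alleles = sorted(counts)  # alphabetical
    if len(alleles) == 1:
        # monomorphic: call the observed allele major and invent no minor;
        # handled by caller
        raise ValueError("monomorphic")
    a, b = alleles
    if counts[a] < counts[b]:
        return a, b
    if counts[b] < counts[a]:
        return b, a
    return b, a  # tie: alphabetically later allele is minor


def read_genotypes(path: str | Path, format: str = "ped_map") -> GenotypeMatrix:
    """Read a genotype matrix from ``ped_map`` or ``tsv`` dialect.

    Dosage is coded against the minor allele determined from the data;
    column order follows the map/header order (deterministic).
    """
    path = Path(path)
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_ped_map(ped_path: Path) -> GenotypeMatrix:
    ped_path = Path(ped_path)
    if ped_path.suffix == ".ped":
        map_path = ped_path.with_suffix(".map")
    else:
        map_path = Path(str(ped_path) + ".map")
        ped_path = Path(str(ped_path) + ".ped")
    sites: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeParseError(f"{map_path}:{lineno}: expected 4 columns")
        chrom, snp_id, _cm, pos = parts[:4]
        try:
            sites.append((snp_id, chrom, int(pos)))
        except ValueError as exc:
            raise GenotypeParseError(f"{map_path}:{lineno}: bad position {pos!r}") from exc

    m = len(sites)
    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        samples.append(parts[1])
        pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        allele_rows.append(pairs)

    n = len(samples)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (snp_id, chrom, pos) in enumerate(sites):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise GenotypeParseError(
                f"{snp_id}: non-biallelic site with alleles {sorted(counts)}"
            )
        if len(counts) == 0:
            raise GenotypeParseError(f"{snp_id}: all calls missing")
        if len(counts) == 1:
            only = next(iter(counts))
            # monomorphic: minor allele unobserved; use a placeholder partner
            minor = "N" if only != "N" else "X"
            major = only
        else:
            minor, major = _minor_major(counts)
        variants.append(VariantRecord(snp_id, chrom, pos, major, minor))
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(samples, variants, dosage)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise GenotypeParseError(f"{path}: first column must be 'sample_id'")
    samples = df["sample_id"].tolist()
    snp_ids = list(df.columns[1:])
    dosage = np.full((len(samples), len(snp_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(snp_ids):
        col = df[sid]
        called = col.notna()
        vals = col[called].astype(int)
        if not vals.isin([0, 1, 2]).all():
            raise GenotypeParseError(f"{path}: SNP {sid} has dosage outside 0/1/2")
        dosage[called.to_numpy(), j] = vals.to_numpy()
    # TSV carries no allele letters or coordinates; synthesize placeholders
    variants = [
        VariantRecord(sid, chrom="0", pos=j + 1, allele_major="A", allele_minor="B")
        for j, sid in enumerate(snp_ids)
    ]
    return GenotypeMatrix(samples, variants, dosage)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str = "ped_map") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            matrix.dosage.astype(float), columns=matrix.snp_ids, index=matrix.samples
        )
        df[matrix.dosage == MISSING] = np.nan
        df.index.name = "sample_id"
        out = df.reset_index()
        for c in matrix.snp_ids:
            out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False)
        return
    if format != "ped_map":
        raise ValueError(f"unknown genotype format {format!r}")
    base = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
    with open(str(base) + ".map", "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos}\n")
    with open(str(base) + ".ped", "w") as fh:
        for i, sid in enumerate(matrix.samples):
            fields = [sid, sid, "0", "0", "0", "0"]
            for j, v in enumerate(matrix.variants):
                d = matrix.dosage[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [v.allele_major, v.allele_major]
                elif d == 1:
                    fields += [v.allele_major, v.allele_minor]
                else:
                    fields += [v.allele_minor, v.allele_minor]
            fh.write(" ".join(fields) + "\n")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample table (TSV) and validate its columns.

    Required columns: sample_id, status5y, stage (I/II/III), location
    (colon/rectum), chemo (0/1), radio (0/1).  Optional: time (months),
    event (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns {missing}")
    return validate_samples(df)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if not df["stage"].isin(["I", "II", "III"]).all():
        raise ValueError("stage must be one of I/II/III")
    if not df["location"].isin(["colon", "rectum"]).all():
        raise ValueError("location must be colon or rectum")
    for c in ("status5y", "chemo", "radio"):
        # status5y may be NA for samples censored before 5y (excluded from MDR)
        vals = df[c].dropna() if c == "status5y" else df[c]
        if not vals.isin([0, 1]).all():
            raise ValueError(f"{c} must be binary 0/1")
    if "time" in df.columns and (df["time"].dropna() < 0).any():
        raise ValueError("time must be non-negative")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def compute_maf(column: np.ndarray) -> float:
    """Folded minor-allele frequency of a dosage column, MISSING excluded."""
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        raise ValueError("all calls missing: MAF undefined")
    f = called.sum() / (2.0 * called.size)
    return float(min(f, 1.0 - f))


def missingness_rate(column: np.ndarray) -> float:
    col = np.asarray(column)
    if col.size == 0:
        raise ValueError("empty column")
    return float(np.mean(col == MISSING))


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Levene-Haldane).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (plain, not mid-, p-value).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(n_het | n, n_rare) up to a constant:
    #   C(n, nhom_r, nhet, nhom_c) * 2^nhet  over the allele-count hypergeometric
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_r + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def ld_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns (composite r^2)."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns differ in length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance column: r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_min_p: float = 1e-4,
    max_missing: float = 0.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs by MAF, exact-HWE p-value and missingness.

    Retained SNPs satisfy MAF >= maf_min AND hwe_p > hwe_min_p AND
    missingness <= max_missing.  The first failed gate (checked in the order
    missingness, maf, hwe) is recorded as the failure reason.  With the
    default ``max_missing=0`` the retained matrix is guaranteed complete.
    """
    if matrix.n_snps == 0:
        raise ValueError("empty genotype matrix")
    rows = []
    keep: list[str] = []
    for v in matrix.variants:
        col = matrix.column(v.snp_id)
        miss = missingness_rate(col)
        called = col[col != MISSING]
        if called.size == 0:
            rows.append((v.snp_id, np.nan, np.nan, miss, False, "missingness"))
            continue
        maf = compute_maf(col)
        n_aa = int(np.sum(called == 2))
        n_het = int(np.sum(called == 1))
        n_AA = int(np.sum(called == 0))
        hwe_p = hwe_exact_pvalue(n_AA, n_het, n_aa)
        if miss > max_missing:
            reason = "missingness"
        elif maf < maf_min:
            reason = "maf"
        elif hwe_p <= hwe_min_p:
            reason = "hwe"
        else:
            reason = ""
        ok = reason == ""
        rows.append((v.snp_id, maf, hwe_p, miss, ok, reason))
        if ok:
            keep.append(v.snp_id)
    report = pd.DataFrame(
        rows, columns=["snp_id", "maf", "hwe_p", "missing_fraction", "passed", "reason"]
    )
    if not keep:
        warnings.warn("QC removed every SNP; returning empty matrix")
        return (
            GenotypeMatrix(list(matrix.samples), [], matrix.dosage[:, :0]),
            report,
        )
    return matrix.subset_snps(keep), report


def ld_prune(
    matrix: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 5,
    r2_max: float = 0.8,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning.

    Within each window (per chromosome, sorted by position) the pair with the
    highest r^2 above ``r2_max`` loses its lower-MAF member (MAF tie: the
    later-position member is dropped) until no retained within-window pair
    exceeds the threshold; the window then advances by ``step`` SNPs.
    Output keeps the input column order.
    """
    order = sorted(
        range(matrix.n_snps),
        key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos),
    )
    if order != list(range(matrix.n_snps)):
        raise ValueError("variants must be sorted by (chrom, pos) before pruning")
    mafs = np.array([compute_maf(matrix.dosage[:, j]) for j in range(matrix.n_snps)])
    removed: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(matrix.variants):
        by_chrom.setdefault(v.chrom, []).append(j)

    for chrom_idx in by_chrom.values():
        start = 0
        while start < len(chrom_idx):
            window = [j for j in chrom_idx[start : start + window_snps] if j not in removed]
            while True:
                worst: tuple[float, int, int] | None = None
                for ai in range(len(window)):
                    for bi in range(ai + 1, len(window)):
                        a, b = window[ai], window[bi]
                        ca, cb = matrix.dosage[:, a], matrix.dosage[:, b]
                        if ca.std() == 0 or cb.std() == 0:
                            continue
                        r2 = ld_r2(ca, cb)
                        if r2 > r2_max and (worst is None or r2 > worst[0]):
                            worst = (r2, a, b)
                if worst is None:
                    break
                _, a, b = worst
                if mafs[a] < mafs[b]:
                    drop = a
                elif mafs[b] < mafs[a]:
                    drop = b
                else:
                    drop = max(a, b)  # MAF tie: later position
                removed.add(drop)
                window.remove(drop)
            start += step
    keep_ids = [v.snp_id for j, v in enumerate(matrix.variants) if j not in removed]
    return matrix.subset_snps(keep_ids)
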