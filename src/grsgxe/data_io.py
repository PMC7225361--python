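"""Genotype / phenotype input, quality control, and gene-region extraction.

Genotypes are handled as minor-allele dosage matrices (0/1/2 under the
additive model, NaN for missing calls) with per-variant metadata.  The PLINK 1
binary trio (.bed/.bim/.fam) is read and written directly: the .bed payload is
SNP-major, two bits per genotype, with the standard code mapping
(00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2).

Quality control follows the usual candidate-gene pipeline for common
variants: call rate >= 95%, Hardy-Weinberg exact-test p >= 5.7e-7, and
MAF >= 1%, applied sequentially in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypePanel",
    "CohortTable",
    "QCReport",
    "PlinkFormatError",
    "EmptyRegionError",
    "NoVariantsRetainedError",
    "read_plink",
    "write_plink",
    "read_cohort_table",
    "hwe_exact_p",
    "qc_filter",
    "extract_gene_region",
]


class PlinkFormatError(ValueError):
    """Raised when a PLINK trio is missing, truncated, or inconsistent."""


class EmptyRegionError(ValueError):
    """Raised when a requested gene region contains no variants."""


class NoVariantsRetainedError(ValueError):
    """Raised when quality control removes every variant."""


@dataclass
class VariantRecord:
    """Per-SNP metadata, including the quantities used by QC filtering."""

    id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str
    maf: float
    call_rate: float
    hwe_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"call_rate must lie in [0, 1], got {self.call_rate}")
        if not (0.0 <= self.hwe_p <= 1.0):
            raise ValueError(f"hwe_p must lie in [0, 1], got {self.hwe_p}")


@dataclass
class GenotypePanel:
    """An n x L minor-allele dosage matrix plus variant and sample metadata.

    ``dosages`` entries are 0.0/1.0/2.0 or NaN (missing).  Dosage always
    counts the minor allele in the analyzed sample.
    """

    dosages: np.ndarray
    variants: list[VariantRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata length must match dosage columns")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match dosage rows")
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing calls mean-imputed per SNP (float copy)."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            col_means = np.nanmean(out, axis=0)
            idx = np.where(np.isnan(out))
            out[idx] = col_means[idx[1]]
        return out

    def subset_variants(self, indices: np.ndarray) -> "GenotypePanel":
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            dosages=self.dosages[:, indices],
            variants=[self.variants[i] for i in indices],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class CohortTable:
    """Phenotype, exposure, and covariates for the analyzed samples.

    ``family`` is ``"gaussian"`` (continuous trait, identity link) or
    ``"binomial"`` (0/1 trait, logit link).  ``covariates`` may have zero
    columns; an intercept is never stored here.
    """

    y: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray
    family: str = "gaussian"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.exposure = np.asarray(self.exposure, dtype=float).ravel()
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] == 0 or self.covariates.size == 0:
            self.covariates = np.zeros((self.y.shape[0], 0))
        if self.covariates.shape[0] != self.y.shape[0]:
            raise ValueError("covariate rows must match phenotype length")
        if self.exposure.shape[0] != self.y.shape[0]:
            raise ValueError("exposure length must match phenotype length")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binomial phenotype must be 0/1")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class QCReport:
    """Counts of variants removed by each sequential QC filter."""

    n_input: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (self.n_removed_callrate, self.n_removed_hwe,
                  self.n_removed_maf, self.n_retained)
        if any(c < 0 for c in counts):
            raise ValueError("QC counts must be non-negative")
        if sum(counts) != self.n_input:
            raise ValueError("QC counts must sum to the input variant count")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


# ---------------------------------------------------------------------------
# PLINK 1 binary trio
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # third byte: SNP-major layout
# two-bit code -> dosage of allele A1 (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _variant_stats(col: np.ndarray) -> tuple[float, float, float]:
    """(maf, call_rate, hwe_p) from one dosage column (may contain NaN)."""
    obs = col[~np.isnan(col)]
    call_rate = obs.size / col.size if col.size else 0.0
    if obs.size == 0:
        return 0.0, 0.0, 1.0
    freq = obs.mean() / 2.0
    maf = min(freq, 1.0 - freq)
    n2 = int((obs == 2.0).sum())
    n1 = int((obs == 1.0).sum())
    n0 = int((obs == 0.0).sum())
    return maf, call_rate, hwe_exact_p(n2, n1, n0)


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 ``.bed``/``.bim``/``.fam`` trio into a `GenotypePanel`.

    Dosages are re-oriented so that the value counts the minor allele in this
    sample (columns whose A1 allele is actually major are flipped, and the
    allele labels swapped).  Missing genotypes are preserved as NaN.
    """
    prefix = Path(prefix)
    paths = {ext: Path(f"{prefix}.{ext}") for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise PlinkFormatError(f"missing PLINK file: {p}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise PlinkFormatError(f"{paths['bim']}: expected 6 columns")
    n, L = len(fam), len(bim)

    raw = paths["bed"].read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{paths['bed']}: bad magic bytes (not SNP-major PLINK 1 .bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + L * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{paths['bed']}: size {len(raw)} != expected {expected} "
            f"for {n} samples x {L} variants")

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(L, bytes_per_snp)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (payload[:, :, None] >> shifts) & 0x03
    dosages = _CODE_TO_DOSAGE[codes.reshape(L, -1)[:, :n]].T.copy()  # n x L

    variants: list[VariantRecord] = []
    for j in range(L):
        a1, a2 = str(bim.iat[j, 4]), str(bim.iat[j, 5])
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            dosages[:, j] = 2.0 - col  # flip so dosage counts the minor allele
            a1, a2 = a2, a1
        maf, call_rate, hwe_p = _variant_stats(dosages[:, j])
        variants.append(VariantRecord(
            id=str(bim.iat[j, 1]), chromosome=str(bim.iat[j, 0]),
            position=int(bim.iat[j, 3]), allele_minor=a1, allele_major=a2,
            maf=maf, call_rate=call_rate, hwe_p=hwe_p))

    sample_ids = fam.iloc[:, 1].tolist()
    return GenotypePanel(dosages=dosages, variants=variants, sample_ids=sample_ids)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1 trio (dosage 2 stored as homozygous A1)."""
    prefix = Path(prefix)
    n, L = panel.n_samples, panel.n_variants
    with open(f"{prefix}.fam", "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chromosome} {v.id} 0 {v.position} "
                     f"{v.allele_minor} {v.allele_major}\n")
    # dosage -> two-bit code: 2 -> 00, NaN -> 01, 1 -> 10, 0 -> 11
    codes = np.full((L, (n + 3) // 4 * 4), 0b01, dtype=np.uint8)
    d = panel.dosages.T
    code_col = np.where(np.isnan(d), 1, np.where(d == 2.0, 0, np.where(d == 1.0, 2, 3)))
    codes[:, :n] = code_col.astype(np.uint8)
    codes = codes.reshape(L, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_cohort_table(path: str | Path, pheno_col: str, env_col: str,
                      covar_cols: list[str] | None = None,
                      family: str = "gaussian",
                      sep: str | None = None) -> tuple[CohortTable, list[str]]:
    """Read a delimited phenotype/exposure/covariate table.

    The delimiter is sniffed (tab or comma) unless given.  Returns the cohort
    and the sample-id column values (first column) for alignment against a
    genotype panel.
    """
    path = Path(path)
    if sep is None:
        head = path.open().readline()
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    covar_cols = covar_cols or []
    for col in [pheno_col, env_col, *covar_cols]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    cohort = CohortTable(
        y=df[pheno_col].to_numpy(float),
        exposure=df[env_col].to_numpy(float),
        covariates=df[covar_cols].to_numpy(float) if covar_cols
        else np.zeros((len(df), 0)),
        family=family)
    return cohort, df.iloc[:, 0].astype(str).tolist()


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more likely than the observed one (plain exact test, no mid-p).
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one subject is required")

    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probability of each het count (hypergeometric-type pmf)
    from scipy.special import gammaln
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logprob = (hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1)
               - gammaln(hom_c + 1))
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = np.searchsorted(hets, n_Aa)
    if obs >= hets.size or hets[obs] != n_Aa:  # parity mismatch cannot occur
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(1.0, prob[prob <= prob[obs] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filtering and region extraction
# ---------------------------------------------------------------------------

def qc_filter(panel: GenotypePanel, min_call_rate: float = 0.95,
              hwe_threshold: float = 5.7e-7,
              min_maf: float = 0.01) -> tuple[GenotypePanel, QCReport]:
    """Sequentially remove SNPs failing call-rate, HWE, then MAF thresholds.

    Each filter is counted against the survivors of the previous one, so the
    three removal counts plus the retained count sum to the input L.
    """
    for name, t in (("min_call_rate", min_call_rate),
                    ("hwe_threshold", hwe_threshold), ("min_maf", min_maf)):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")

    call = np.array([v.call_rate for v in panel.variants])
    hwe = np.array([v.hwe_p for v in panel.variants])
    maf = np.array([v.maf for v in panel.variants])

    pass_call = call >= min_call_rate
    pass_hwe = pass_call & (hwe >= hwe_threshold)
    pass_maf = pass_hwe & (maf >= min_maf)

    report = QCReport(
        n_input=panel.n_variants,
        n_removed_callrate=int((~pass_call).sum()),
        n_removed_hwe=int((pass_call & ~pass_hwe).sum()),
        n_removed_maf=int((pass_hwe & ~pass_maf).sum()),
        n_retained=int(pass_maf.sum()))
    if report.n_retained == 0:
        raise NoVariantsRetainedError("no variants retained after QC filtering")
    return panel.subset_variants(np.where(pass_maf)[0]), report


def extract_gene_region(panel: GenotypePanel, chromosome: str, start: int,
                        end: int, flank: int = 50_000) -> GenotypePanel:
    """Keep SNPs on ``chromosome`` within ``[start - flank, end + flank]``.

    Positions are 1-based and the flanked window is inclusive at both ends,
    mirroring the convention of padding a gene with 50 kb of potential
    regulatory sequence on each side.
    """
    if start > end:
        raise ValueError("start must not exceed end")
    lo, hi = start - flank, end + flank
    keep = [j for j, v in enumerate(panel.variants)
            if v.chromosome == str(chromosome) and lo <= v.position <= hi]
    if not keep:
        raise EmptyRegionError(
            f"no variants on chromosome {chromosome} in [{lo}, {hi}]")
    return panel.subset_variants(np.array(keep))
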