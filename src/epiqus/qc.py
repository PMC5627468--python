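"""Per-SNP quality control: MAF, call rate and Hardy-Weinberg equilibrium.

Inclusion filters follow candidate-panel convention: a marker fails on minor
allele frequency below 1% or on per-marker missingness above 5%.  HWE is
assessed with Pearson's goodness-of-fit chi-square on the three genotype
classes (1 df, no continuity correction) and is report-only by default; an
optional exclusion alpha is available for reuse in stricter pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_panel import GenotypeMatrix

__all__ = [
    "HweResult",
    "QcReport",
    "compute_maf",
    "compute_call_rate",
    "genotype_counts",
    "hwe_chi_square",
    "qc_filter",
]


class AllMissingError(ValueError):
    """Raised when a statistic is undefined because every call is missing."""


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    monomorphic: bool = False

    def __iter__(self):  # allow `chi2, p = hwe_chi_square(...)`
        return iter((self.chi2, self.p))


@dataclass
class QcReport:
    """Per-marker QC table plus the thresholds that produced the pass flags.

    Columns: rsid, maf, call_rate, hwe_chi2, hwe_p, monomorphic, maf_pass,
    missingness_pass, hwe_note, retained.
    """

    table: pd.DataFrame
    maf_min: float
    missing_max: float
    hwe_alert_p: float

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one dosage column, folded to [0, 0.5].

    Missing (NaN) entries are excluded from both numerator and denominator.
    The coded-allele frequency f = sum(dosage) / (2 * n_called) is folded to
    min(f, 1 - f), so a column whose coded allele is actually the common one
    still reports a valid MAF.
    """
    d = np.asarray(dosages, dtype=float)
    called = d[~np.isnan(d)]
    if called.size == 0:
        raise AllMissingError("MAF undefined: all genotype calls missing")
    f = called.sum() / (2.0 * called.size)
    return float(min(f, 1.0 - f))


def compute_call_rate(dosages: np.ndarray) -> float:
    """Fraction of non-missing calls in the column."""
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty genotype column")
    return float(1.0 - np.isnan(d).mean())


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n major homozygote, n heterozygote, n minor homozygote), missing excluded."""
    d = np.asarray(dosages, dtype=float)
    return (
        int(np.nansum(d == 0)),
        int(np.nansum(d == 1)),
        int(np.nansum(d == 2)),
    )


def hwe_chi_square(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Pearson goodness-of-fit chi-square test of Hardy-Weinberg proportions.

    Expected counts are n*p^2, 2n*p*q, n*q^2 at the observed allele frequency;
    the statistic is referred to the upper tail of chi-square with 1 degree of
    freedom.  A monomorphic sample (allele frequency 0 or 1) is reported as
    (chi2=0, p=1) with the ``monomorphic`` flag set rather than an error, so
    batch QC never aborts.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("genotype counts must be nonnegative integers")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    q = (counts[1] + 2.0 * counts[2]) / (2.0 * n)  # minor-coded allele freq
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, p=1.0, monomorphic=True)
    expected = n * np.array([p * p, 2.0 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_max: float = 0.05,
    hwe_alert_p: float = 0.05,
    hwe_exclude_p: float | None = None,
) -> tuple[QcReport, list[str]]:
    """Run per-marker QC and return the report plus the retained rsID list.

    A marker is retained iff observed MAF >= ``maf_min`` (so exactly 1% passes)
    and missingness <= ``missing_max`` (so exactly 5% passes).  HWE is computed
    for every marker; by default it only raises the ``hwe_note`` flag below
    ``hwe_alert_p`` and never excludes, unless ``hwe_exclude_p`` is set.
    """
    if genotypes.dosages.size == 0:
        raise ValueError("empty genotype matrix")
    rows = []
    retained: list[str] = []
    for j, marker in enumerate(genotypes.markers):
        col = genotypes.dosages[:, j]
        call_rate = compute_call_rate(col)
        if call_rate == 0.0:
            maf, hwe = 0.0, HweResult(0.0, 1.0, monomorphic=True)
        else:
            maf = compute_maf(col)
            hwe = hwe_chi_square(*genotype_counts(col))
        maf_pass = maf >= maf_min
        missing_pass = (1.0 - call_rate) <= missing_max
        hwe_note = hwe.p < hwe_alert_p
        keep = maf_pass and missing_pass
        if hwe_exclude_p is not None and hwe.p < hwe_exclude_p:
            keep = False
        if keep:
            retained.append(marker.rsid)
        rows.append(
            {
                "rsid": marker.rsid,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p,
                "monomorphic": hwe.monomorphic,
                "maf_pass": maf_pass,
                "missingness_pass": missing_pass,
                "hwe_note": hwe_note,
                "retained": keep,
            }
        )
    report = QcReport(
        table=pd.DataFrame(rows),
        maf_min=maf_min,
        missing_max=missing_max,
        hwe_alert_p=hwe_alert_p,
    )
    return report, retained
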