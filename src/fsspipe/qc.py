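"""Per-SNP quality control: call rate, designated-allele frequency, and the
Hardy-Weinberg goodness-of-fit test, plus the study inclusion filters.

A SNP is kept iff (i) the minor-allele frequency in controls is at least 5%,
(ii) the combined call rate is at least 95%, and (iii) the control genotype
distribution does not depart from Hardy-Weinberg proportions at p < 0.05
(1-df Pearson chi-square).  HWE is evaluated in controls only; the case-side
statistic is reported but never filters.  The MAF threshold applies to
min(f, 1-f) of the designated allele, since an externally designated allele
may be the commoner one in this cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError
from .genotypes import GroupedGenotypeCounts, SnpMeta


@dataclass(frozen=True)
class QcThresholds:
    min_maf: float = 0.05
    min_call_rate: float = 0.95
    min_hwe_p: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")


@dataclass(frozen=True)
class QcResult:
    snp: SnpMeta
    call_rate_cases: float
    call_rate_controls: float
    call_rate_total: float
    maf_controls: float
    hwe_chi2: float
    hwe_p: float
    hwe_chi2_cases: float | None = None
    hwe_p_cases: float | None = None

    def failures(self, thresholds: QcThresholds) -> list[str]:
        reasons = []
        folded = min(self.maf_controls, 1.0 - self.maf_controls)
        if folded < thresholds.min_maf:
            reasons.append("maf")
        if self.call_rate_total < thresholds.min_call_rate:
            reasons.append("call_rate")
        if self.hwe_p < thresholds.min_hwe_p:
            reasons.append("hwe")
        return reasons

    def passed(self, thresholds: QcThresholds) -> bool:
        return not self.failures(thresholds)


def call_rate(
    counts: GroupedGenotypeCounts, n_total_cases: int, n_total_controls: int
) -> tuple[float, float, float]:
    """(case, control, combined) genotyping call rates."""
    gc, gt = counts.n_cases, counts.n_controls
    if gc > n_total_cases or gt > n_total_controls:
        raise ValidationError(
            f"{counts.snp.rsid}: genotyped counts exceed cohort totals"
        )
    rc = gc / n_total_cases if n_total_cases else 0.0
    rt = gt / n_total_controls if n_total_controls else 0.0
    denom = n_total_cases + n_total_controls
    return rc, rt, (gc + gt) / denom if denom else 0.0


def designated_allele_frequency(counts_triple: Sequence[int]) -> float:
    """Frequency of the designated (minor) allele from a (major-hom, het,
    minor-hom) triple; may exceed 0.5 under external designation."""
    n = sum(counts_triple)
    if n <= 0:
        raise ComputationError("allele frequency undefined for an empty triple")
    _, het, minhom = counts_triple
    return (het + 2 * minhom) / (2 * n)


def hwe_chisq_test(counts_triple: Sequence[int]) -> tuple[float, float]:
    """1-df Pearson goodness-of-fit test against Hardy-Weinberg proportions.

    Expected counts use the observed allele frequency; no continuity
    correction.  Monomorphic input returns (0, 1).
    """
    n = sum(counts_triple)
    if n <= 0:
        raise ComputationError("HWE test undefined for an empty triple")
    q = designated_allele_frequency(counts_triple)
    if q <= 0.0 or q >= 1.0:
        return 0.0, 1.0
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.asarray(counts_triple, float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compute_qc(
    counts_list: Iterable[GroupedGenotypeCounts],
    n_total_cases: int,
    n_total_controls: int,
) -> list[QcResult]:
    """Full QC metrics for every SNP."""
    out = []
    for counts in counts_list:
        rc, rt, rall = call_rate(counts, n_total_cases, n_total_controls)
        maf = (
            designated_allele_frequency(counts.control_counts)
            if counts.n_controls
            else float("nan")
        )
        chi2, p = hwe_chisq_test(counts.control_counts) if counts.n_controls else (0.0, 1.0)
        chi2_ca, p_ca = (
            hwe_chisq_test(counts.case_counts) if counts.n_cases else (0.0, 1.0)
        )
        out.append(
            QcResult(
                snp=counts.snp,
                call_rate_cases=rc,
                call_rate_controls=rt,
                call_rate_total=rall,
                maf_controls=maf,
                hwe_chi2=chi2,
                hwe_p=p,
                hwe_chi2_cases=chi2_ca,
                hwe_p_cases=p_ca,
            )
        )
    return out


def apply_qc_filters(
    results: Iterable[QcResult], thresholds: QcThresholds | None = None
) -> tuple[list[SnpMeta], pd.DataFrame]:
    """Apply the inclusion filters; returns (passed SNPs, per-SNP report).

    Every failure reason is recorded (not just the first one hit).
    """
    thresholds = thresholds or QcThresholds()
    passed: list[SnpMeta] = []
    rows = []
    for res in results:
        reasons = res.failures(thresholds)
        if not reasons:
            passed.append(res.snp)
        rows.append(
            {
                "rsid": res.snp.rsid,
                "gene": res.snp.gene_label or ".",
                "chr": res.snp.chromosome,
                "pos": res.snp.position,
                "allele": res.snp.minor_allele,
                "maf_controls_pct": round(100.0 * res.maf_controls, 1),
                "call_rate_pct": round(100.0 * res.call_rate_total, 1),
                "hwe_p_controls": res.hwe_p,
                "passed": not reasons,
                "fail_reasons": ",".join(reasons) if reasons else ".",
            }
        )
    return passed, pd.DataFrame(rows)


def write_qc_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


__all__ = [
    "QcThresholds",
    "QcResult",
    "call_rate",
    "designated_allele_frequency",
    "hwe_chisq_test",
    "compute_qc",
    "apply_qc_filters",
    "write_qc_report",
]
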