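"""Weighted genetic risk score (wGRS), quartile analysis and trend test.

The per-individual score sums risk-allele dosages (0/1/2) over the panel,
each weighted by the SNP's natural-log odds ratio.  Two scale conventions
are provided: ``raw_logOR`` (the plain weighted sum, range 0..2*sum(w)) and
``rescaled_to_allele_count`` (raw * K / sum(w), range 0..2K for K SNPs, so a
score of K corresponds to carrying one average-weight risk allele per SNP).
The rescaled convention is the default.  Scores are cut at quartiles of the
pooled case+control distribution into Q1..Q4 with left-open, right-closed
intervals; each upper quartile is compared with Q1 by logistic regression
(equal to the closed-form 2x2 cross-product ratio for this saturated
design), and the dose-response across quartiles is summarized by the
Cochran-Armitage trend test with integer category scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z_975, fit_grouped_binomial
from .errors import ComputationError, ValidationError
from .genotypes import GenotypeMatrix

RAW = "raw_logOR"
RESCALED = "rescaled_to_allele_count"

#: Fraction of missing weighted SNPs above which a sample's score is
#: flagged unreliable.
_UNRELIABLE_MISSING_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskWeight:
    rsid: str
    risk_allele: str
    log_or: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_or):
            raise ValidationError(f"{self.rsid}: weight must be finite")


@dataclass(frozen=True)
class RiskWeightTable:
    weights: tuple[RiskWeight, ...]

    def __post_init__(self) -> None:
        rsids = [w.rsid for w in self.weights]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsid in weight table")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(sum(w.log_or for w in self.weights))

    def as_dict(self) -> dict[str, RiskWeight]:
        return {w.rsid: w for w in self.weights}

    @classmethod
    def from_association_table(cls, table: pd.DataFrame) -> "RiskWeightTable":
        """Weights = ln(OR) from an association report DataFrame."""
        return cls(
            tuple(
                RiskWeight(rsid=r["rsid"], risk_allele=r["risk_allele"], log_or=float(r["beta"]))
                for _, r in table.iterrows()
            )
        )

    @classmethod
    def from_odds_ratios(
        cls, entries: Iterable[tuple[str, str, float]]
    ) -> "RiskWeightTable":
        """Entries of (rsid, risk_allele, OR); weights are natural logs."""
        return cls(
            tuple(RiskWeight(rsid=r, risk_allele=a, log_or=float(np.log(o)))
                  for r, a, o in entries)
        )


def read_weights_tsv(path: str | Path) -> RiskWeightTable:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "risk_allele": str})
    need = {"rsid", "risk_allele", "log_or"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: weight table needs columns {sorted(need)}")
    return RiskWeightTable(
        tuple(
            RiskWeight(rsid=r["rsid"], risk_allele=r["risk_allele"], log_or=float(r["log_or"]))
            for _, r in df.iterrows()
        )
    )


def write_weights_tsv(table: RiskWeightTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"rsid": w.rsid, "risk_allele": w.risk_allele, "log_or": w.log_or}
         for w in table.weights]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Score construction
# ---------------------------------------------------------------------------

@dataclass
class GrsVector:
    raw: np.ndarray
    rescaled: np.ndarray
    convention: str
    n_missing: np.ndarray
    unreliable: np.ndarray  # bool mask: > 50% of weighted SNPs missing

    @property
    def scores(self) -> np.ndarray:
        return self.raw if self.convention == RAW else self.rescaled


def weighted_grs(
    matrix: GenotypeMatrix,
    weights: RiskWeightTable,
    convention: str = RESCALED,
    missing_policy: str = "impute",
) -> GrsVector:
    """Per-sample weighted risk score over the SNPs in ``weights``.

    Missing dosages: ``impute`` (default) substitutes the expected
    risk-allele dosage in controls (2 x control risk-allele frequency);
    ``complete`` yields NaN for any sample missing a weighted SNP.  Samples
    missing more than half of the weighted SNPs are flagged unreliable.
    """
    if convention not in (RAW, RESCALED):
        raise ValidationError(f"unknown convention {convention!r}")
    if missing_policy not in ("impute", "complete"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    if len(weights) == 0:
        raise ValidationError("empty weight table")

    panel = {s.rsid: j for j, s in enumerate(matrix.snps)}
    absent = [w.rsid for w in weights.weights if w.rsid not in panel]
    if absent:
        raise ValidationError(f"weights reference SNPs absent from the panel: {absent}")

    K = len(weights)
    w_vec = np.empty(K)
    risk_dosage = np.empty((matrix.n_samples, K))
    is_control = ~matrix.is_case
    for k, w in enumerate(weights.weights):
        j = panel[w.rsid]
        snp = matrix.snps[j]
        if w.risk_allele == snp.minor_allele:
            x = matrix.dosage[:, j]
        elif w.risk_allele == snp.major_allele:
            x = 2.0 - matrix.dosage[:, j]
        else:
            raise ValidationError(
                f"{w.rsid}: weight risk allele {w.risk_allele!r} matches neither panel allele"
            )
        w_vec[k] = w.log_or
        risk_dosage[:, k] = x

    missing = np.isnan(risk_dosage)
    n_missing = missing.sum(axis=1)
    if missing_policy == "impute":
        for k in range(K):
            obs = risk_dosage[is_control, k]
            obs = obs[~np.isnan(obs)]
            if obs.size == 0:
                raise ComputationError(
                    f"{weights.weights[k].rsid}: no control calls to impute from"
                )
            risk_dosage[missing[:, k], k] = obs.mean()
        raw = risk_dosage @ w_vec
    else:
        raw = np.where(n_missing > 0, np.nan, np.nansum(risk_dosage * w_vec, axis=1))

    total_w = w_vec.sum()
    if total_w == 0:
        raise ComputationError("weights sum to zero; rescaled convention undefined")
    rescaled = raw * K / total_w
    return GrsVector(
        raw=raw,
        rescaled=rescaled,
        convention=convention,
        n_missing=n_missing,
        unreliable=n_missing > _UNRELIABLE_MISSING_FRACTION * K,
    )


# ---------------------------------------------------------------------------
# Quartiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuartilePartition:
    cutpoints: tuple[float, float, float]
    labels: np.ndarray  # 1..4 per sample (0 = unassignable score)
    case_counts: tuple[int, int, int, int]
    control_counts: tuple[int, int, int, int]

    def table(self) -> np.ndarray:
        return np.array([self.case_counts, self.control_counts], dtype=float)


def assign_quartiles(
    scores: GrsVector | np.ndarray,
    is_case: np.ndarray,
    cutpoints: Sequence[float] | None = None,
) -> QuartilePartition:
    """Assign each sample to a score quartile.

    Cut-points default to the empirical quartiles of the pooled
    case+control distribution; membership uses left-open, right-closed
    intervals (a score exactly at a cut-point falls in the lower quartile).
    """
    vals = scores.scores if isinstance(scores, GrsVector) else np.asarray(scores, float)
    is_case = np.asarray(is_case, bool)
    if vals.shape != is_case.shape:
        raise ValidationError("scores and phenotype must align")
    finite = np.isfinite(vals)
    if not finite.any():
        raise ComputationError("no finite scores")
    if cutpoints is None:
        pool = vals[finite]
        if np.ptp(pool) == 0:
            raise ComputationError("constant scores: quartile partition degenerate")
        cutpoints = tuple(np.quantile(pool, [0.25, 0.5, 0.75]))
    c1, c2, c3 = cutpoints
    if not c1 <= c2 <= c3:
        raise ValidationError("cut-points must be non-decreasing")

    labels = np.zeros(vals.shape, dtype=int)
    labels[finite] = 1 + (
        (vals[finite] > c1).astype(int)
        + (vals[finite] > c2).astype(int)
        + (vals[finite] > c3).astype(int)
    )
    case_counts = tuple(int(((labels == q) & is_case).sum()) for q in (1, 2, 3, 4))
    ctrl_counts = tuple(int(((labels == q) & ~is_case).sum()) for q in (1, 2, 3, 4))
    return QuartilePartition(
        cutpoints=(float(c1), float(c2), float(c3)),
        labels=labels,
        case_counts=case_counts,
        control_counts=ctrl_counts,
    )


def quartile_association(partition: QuartilePartition) -> pd.DataFrame:
    """Per-quartile ORs vs Q1 by logistic regression on quartile indicators.

    For this saturated categorical design the ML estimate equals the 2x2
    cross-product ratio; Wald CI and p are reported.  Quartiles with an
    empty phenotype cell are flagged and their OR omitted.
    """
    ca = np.asarray(partition.case_counts, float)
    co = np.asarray(partition.control_counts, float)
    if ca[0] == 0 or co[0] == 0:
        raise ComputationError("reference quartile Q1 lacks cases or controls")
    X = np.column_stack([np.ones(4), np.eye(4)[:, 1:]])
    rows = [{"quartile": "Q1", "cases": int(ca[0]), "controls": int(co[0]),
             "or": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
             "reference": True, "degenerate": False}]
    degenerate = (ca == 0) | (co == 0)
    if degenerate[1:].any():
        # drop degenerate quartiles from the fit, flag them in the report
        keep = ~degenerate
        fit = fit_grouped_binomial(X[keep][:, [0] + [q for q in range(1, 4) if keep[q]]],
                                   ca[keep], co[keep])
        coefs = iter(range(1, int(keep[1:].sum()) + 1))
        for q in (1, 2, 3):
            if degenerate[q]:
                rows.append({"quartile": f"Q{q + 1}", "cases": int(ca[q]),
                             "controls": int(co[q]), "or": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan, "reference": False,
                             "degenerate": True})
            else:
                k = next(coefs)
                b, se = fit.beta[k], np.sqrt(fit.cov[k, k])
                z = b / se
                rows.append({"quartile": f"Q{q + 1}", "cases": int(ca[q]),
                             "controls": int(co[q]), "or": float(np.exp(b)),
                             "ci_low": float(np.exp(b - Z_975 * se)),
                             "ci_high": float(np.exp(b + Z_975 * se)),
                             "p": float(2 * stats.norm.sf(abs(z))),
                             "reference": False, "degenerate": False})
        return pd.DataFrame(rows)

    fit = fit_grouped_binomial(X, ca, co)
    for q in (1, 2, 3):
        b, se = fit.beta[q], np.sqrt(fit.cov[q, q])
        z = b / se
        rows.append({"quartile": f"Q{q + 1}", "cases": int(ca[q]), "controls": int(co[q]),
                     "or": float(np.exp(b)),
                     "ci_low": float(np.exp(b - Z_975 * se)),
                     "ci_high": float(np.exp(b + Z_975 * se)),
                     "p": float(2 * stats.norm.sf(abs(z))),
                     "reference": False, "degenerate": False})
    return pd.DataFrame(rows)


def cochran_armitage_trend(
    table: np.ndarray, scores: Sequence[float] | None = None
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in case proportion across ordered
    categories.

    ``table`` is 2 x k: first row case counts, second row control counts.
    Default category scores 1..k.  Returns (Z, two-sided normal p).
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValidationError("need a 2 x k table with k >= 2")
    if table.sum() <= 0:
        raise ComputationError("all-zero table")
    k = table.shape[1]
    s = np.asarray(scores if scores is not None else np.arange(1, k + 1), float)
    cases, controls = table
    N = cases + controls
    T = N.sum()
    R = cases.sum()
    if R == 0 or R == T:
        raise ComputationError("trend undefined with a single phenotype")
    num = (cases * s).sum() - R * (N * s).sum() / T
    var = R * (T - R) / T * ((N * s * s).sum() - (N * s).sum() ** 2 / T) / T
    if var <= 0:
        raise ComputationError("zero trend variance (all weight in one category)")
    z = float(num / np.sqrt(var))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def grs_report(
    grs: GrsVector, is_case: np.ndarray, cutpoints: Sequence[float] | None = None
) -> tuple[QuartilePartition, pd.DataFrame, tuple[float, float]]:
    """Quartile partition, per-quartile OR table and trend test in one call."""
    part = assign_quartiles(grs, is_case, cutpoints)
    table = quartile_association(part)
    trend = cochran_armitage_trend(part.table())
    return part, table, trend


def write_grs_tsv(
    matrix: GenotypeMatrix, grs: GrsVector, partition: QuartilePartition, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "phenotype": matrix.phenotype,
            "grs_raw": grs.raw,
            "grs_rescaled": grs.rescaled,
            "quartile": partition.labels,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


__all__ = [
    "RAW",
    "RESCALED",
    "RiskWeight",
    "RiskWeightTable",
    "read_weights_tsv",
    "write_weights_tsv",
    "GrsVector",
    "weighted_grs",
    "QuartilePartition",
    "assign_quartiles",
    "quartile_association",
    "cochran_armitage_trend",
    "grs_report",
    "write_grs_tsv",
]
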