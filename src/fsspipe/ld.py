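"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by expectation-maximization
on the 3x3 genotype cross-table: only double heterozygotes are phase
ambiguous, and their two resolutions are weighted by the current haplotype
frequencies each E-step.  From the fitted frequencies the module computes
the raw disequilibrium D, Lewontin's D' (|D| normalised by its maximum
given the allele frequencies) and the squared allelic correlation r².
Percentile bootstrap intervals for D' (resampling individuals) feed a
Gabriel-style haplotype-block rule and a greedy D'-threshold pruner that
reduces a panel to approximately independent markers.

Haplotype labels: allele 1 is the major allele at each locus, so p11 is the
major-major haplotype frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .genotypes import GenotypeMatrix, SnpMeta

_EM_TOL = 1e-10
_EM_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# Genotype cross-tables
# ---------------------------------------------------------------------------

def genotype_cross_table(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """3x3 table of joint minor-allele dosages; missing-at-either excluded."""
    a = np.asarray(dos_a, float)
    b = np.asarray(dos_b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep].astype(int), b[keep].astype(int)
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (a, b), 1.0)
    return table


def _pair_table(pair: object) -> np.ndarray:
    """Coerce a two-SNP matrix, a (dosA, dosB) pair, or a 3x3 table."""
    if isinstance(pair, GenotypeMatrix):
        if pair.n_snps != 2:
            raise ValidationError("expected a matrix restricted to exactly 2 SNPs")
        return genotype_cross_table(pair.dosage[:, 0], pair.dosage[:, 1])
    if isinstance(pair, np.ndarray) and pair.shape == (3, 3):
        return np.asarray(pair, float)
    if isinstance(pair, (tuple, list)) and len(pair) == 2:
        return genotype_cross_table(pair[0], pair[1])
    raise ValidationError("cannot interpret pair genotypes")


# ---------------------------------------------------------------------------
# EM over batches of 3x3 tables
# ---------------------------------------------------------------------------

def _table_loglik(tables: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Observed-data multinomial log-likelihood, batched.

    ``tables``: (B,3,3); ``freqs``: (B,4) as (p11,p12,p21,p22).
    """
    p11, p12, p21, p22 = freqs.T
    probs = np.stack(
        [
            p11**2, 2 * p11 * p12, p12**2,
            2 * p11 * p21, 2 * (p11 * p22 + p12 * p21), 2 * p12 * p22,
            p21**2, 2 * p21 * p22, p22**2,
        ],
        axis=1,
    ).reshape(-1, 3, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tables * np.log(probs)
    terms = np.where(tables > 0, terms, 0.0)
    return terms.sum(axis=(1, 2))


def _em_run(tables: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One EM solve per table from the given (B,4) start frequencies."""
    B = tables.shape[0]
    n = tables.sum(axis=(1, 2))
    dh = tables[:, 1, 1]
    # phase-unambiguous haplotype contributions (constant across iterations)
    base11 = 2 * tables[:, 0, 0] + tables[:, 0, 1] + tables[:, 1, 0]
    base12 = 2 * tables[:, 0, 2] + tables[:, 0, 1] + tables[:, 1, 2]
    base21 = 2 * tables[:, 2, 0] + tables[:, 1, 0] + tables[:, 2, 1]
    base22 = 2 * tables[:, 2, 2] + tables[:, 2, 1] + tables[:, 1, 2]

    iters = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    for _ in range(_EM_MAX_ITER):
        if not active.any():
            break
        p11, p12, p21, p22 = freqs.T
        num = p11 * p22
        den = num + p12 * p21
        w = np.where(den > 0, np.divide(num, den, out=np.full(B, 0.5), where=den > 0), 0.5)
        new = np.stack(
            [
                base11 + w * dh,
                base12 + (1 - w) * dh,
                base21 + (1 - w) * dh,
                base22 + w * dh,
            ],
            axis=1,
        ) / (2 * n)[:, None]
        delta = np.abs(new - freqs).max(axis=1)
        freqs = np.where(active[:, None], new, freqs)
        iters += active
        active = active & (delta >= _EM_TOL)
    return freqs, iters


def _em_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EM haplotype frequencies for a batch of 3x3 genotype tables.

    Returns (freqs (B,4), n_iterations (B,)).  The linkage-equilibrium
    start is an EM fixed point for some symmetric samples (e.g. all double
    heterozygotes), so EM also runs from one coupling- and one
    repulsion-perturbed start and the solution with the highest
    observed-data likelihood is returned.
    """
    tables = np.asarray(tables, float)
    if tables.ndim == 2:
        tables = tables[None]
    n = tables.sum(axis=(1, 2))
    if (n <= 0).any():
        raise ComputationError("empty genotype table")
    # minor-allele frequencies at each locus
    qa = (tables.sum(axis=2) @ np.arange(3.0)) / (2 * n)
    qb = (tables.sum(axis=1) @ np.arange(3.0)) / (2 * n)
    if ((qa <= 0) | (qa >= 1) | (qb <= 0) | (qb >= 1)).any():
        raise ComputationError("monomorphic locus: LD undefined")
    pa, pb = 1 - qa, 1 - qb

    def start_from_p11(p11: np.ndarray) -> np.ndarray:
        return np.stack([p11, pa - p11, pb - p11, 1 - pa - pb + p11], axis=1)

    le = pa * pb
    hi = np.minimum(pa, pb)
    lo = np.maximum(0.0, pa + pb - 1.0)
    starts = [
        start_from_p11(le),
        start_from_p11(le + 0.5 * (hi - le)),
        start_from_p11(le - 0.5 * (le - lo)),
    ]
    best_freqs = best_iters = best_ll = None
    for s in starts:
        freqs, iters = _em_run(tables, s)
        ll = _table_loglik(tables, freqs)
        if best_ll is None:
            best_freqs, best_iters, best_ll = freqs, iters, ll
        else:
            better = ll > best_ll + 1e-12
            best_freqs = np.where(better[:, None], freqs, best_freqs)
            best_iters = np.where(better, iters, best_iters)
            best_ll = np.maximum(ll, best_ll)
    return best_freqs, best_iters


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Two-locus haplotype frequencies; allele 1 = major at each locus."""

    p11: float
    p12: float
    p21: float
    p22: float
    n_iterations: int = 0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if (arr < -1e-9).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError("haplotype frequencies must be >=0 and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p21, self.p22])


def em_haplotype_freqs(pair_genotypes: object) -> HaplotypeFrequencies:
    """EM haplotype-frequency estimate for one SNP pair.

    Accepts a two-SNP GenotypeMatrix, a (dosage_a, dosage_b) pair, or a
    3x3 genotype cross-table.
    """
    table = _pair_table(pair_genotypes)
    freqs, iters = _em_batch(table)
    f = np.clip(freqs[0], 0.0, 1.0)
    f = f / f.sum()
    return HaplotypeFrequencies(*map(float, f), n_iterations=int(iters[0]))


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdStatistics:
    D: float
    d_prime: float
    r2: float
    ci: tuple[float, float] | None = None
    n_iterations: int = 0


def _ld_from_freq_array(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched (D, D', r2) from (B,4) haplotype frequencies."""
    p11, p12, p21, _ = freqs.T
    p1 = p11 + p12  # major at locus A
    p2 = p11 + p21  # major at locus B
    q1, q2 = 1 - p1, 1 - p2
    if ((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)).any():
        raise ComputationError("marginal allele frequency 0 or 1: LD undefined")
    D = p11 - p1 * p2
    dmax = np.where(D > 0, np.minimum(p1 * q2, q1 * p2), np.minimum(p1 * p2, q1 * q2))
    with np.errstate(invalid="ignore"):
        dprime = np.where(D == 0, 0.0, np.abs(D) / dmax)
    r2 = D**2 / (p1 * q1 * p2 * q2)
    return D, np.clip(dprime, 0.0, 1.0), np.clip(r2, 0.0, 1.0)


def ld_statistics(haps: HaplotypeFrequencies) -> LdStatistics:
    """Lewontin D' and r² from haplotype frequencies."""
    D, dprime, r2 = _ld_from_freq_array(haps.as_array()[None])
    return LdStatistics(D=float(D[0]), d_prime=float(dprime[0]), r2=float(r2[0]),
                        n_iterations=haps.n_iterations)


def pair_ld(pair_genotypes: object) -> LdStatistics:
    """EM + D'/r² for one pair of SNPs."""
    return ld_statistics(em_haplotype_freqs(pair_genotypes))


# ---------------------------------------------------------------------------
# Bootstrap confidence interval for D'
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DprimeCI:
    low: float
    high: float
    n_boot: int
    n_redrawn: int
    level: float


def bootstrap_dprime_ci(
    pair_genotypes: object,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> DprimeCI:
    """Percentile bootstrap interval for D', resampling individuals.

    Resampling the 3x3 genotype table multinomially is equivalent to
    resampling complete-case individuals with replacement.  Degenerate
    (monomorphic) resamples are redrawn and counted.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0,1)")
    table = _pair_table(pair_genotypes)
    n = int(table.sum())
    if n == 0:
        raise ComputationError("no complete-case individuals")
    probs = (table / n).ravel()
    rng = np.random.default_rng(seed)

    def degenerate(tabs: np.ndarray) -> np.ndarray:
        qa = (tabs.sum(axis=2) @ np.arange(3.0)) / (2 * tabs.sum(axis=(1, 2)))
        qb = (tabs.sum(axis=1) @ np.arange(3.0)) / (2 * tabs.sum(axis=(1, 2)))
        return (qa <= 0) | (qa >= 1) | (qb <= 0) | (qb >= 1)

    tabs = rng.multinomial(n, probs, size=n_boot).reshape(n_boot, 3, 3).astype(float)
    n_redrawn = 0
    for _ in range(1000):
        bad = degenerate(tabs)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        tabs[bad] = (
            rng.multinomial(n, probs, size=int(bad.sum())).reshape(-1, 3, 3).astype(float)
        )
    else:
        raise ComputationError("could not draw non-degenerate bootstrap resamples")

    freqs, _ = _em_batch(tabs)
    _, dprime, _ = _ld_from_freq_array(freqs)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(dprime, [alpha, 1.0 - alpha])
    return DprimeCI(low=float(lo), high=float(hi), n_boot=n_boot,
                    n_redrawn=n_redrawn, level=level)


# ---------------------------------------------------------------------------
# Panel-wide pairwise LD
# ---------------------------------------------------------------------------

def _group_rows(matrix: GenotypeMatrix, group: str) -> np.ndarray:
    if group == "pooled":
        return np.ones(matrix.n_samples, dtype=bool)
    if group == "cases":
        return matrix.is_case
    if group == "controls":
        return ~matrix.is_case
    raise ValidationError(f"unknown group {group!r} (pooled/cases/controls)")


def pairwise_ld(
    matrix: GenotypeMatrix,
    group: str = "pooled",
    with_ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format LD table for all within-chromosome SNP pairs."""
    rows_mask = _group_rows(matrix, group)
    dos = matrix.dosage[rows_mask]
    records = []
    for i in range(matrix.n_snps):
        for j in range(i + 1, matrix.n_snps):
            a, b = matrix.snps[i], matrix.snps[j]
            if a.chromosome != b.chromosome:
                continue
            pair = (dos[:, i], dos[:, j])
            n_pair = int(genotype_cross_table(*pair).sum())
            try:
                st = pair_ld(pair)
            except ComputationError:
                records.append({"rsid_a": a.rsid, "rsid_b": b.rsid, "D": np.nan,
                                "d_prime": np.nan, "r2": np.nan, "ci_low": np.nan,
                                "ci_high": np.nan, "n": n_pair})
                continue
            ci = (np.nan, np.nan)
            if with_ci:
                boot = bootstrap_dprime_ci(pair, n_boot=n_boot, seed=seed + i * 1000 + j)
                ci = (boot.low, boot.high)
            records.append({"rsid_a": a.rsid, "rsid_b": b.rsid, "D": st.D,
                            "d_prime": st.d_prime, "r2": st.r2,
                            "ci_low": ci[0], "ci_high": ci[1], "n": n_pair})
    return pd.DataFrame(
        records,
        columns=["rsid_a", "rsid_b", "D", "d_prime", "r2", "ci_low", "ci_high", "n"],
    )


def dprime_matrix(matrix: GenotypeMatrix, group: str = "pooled") -> np.ndarray:
    """Symmetric K x K D' matrix; cross-chromosome pairs are defined as 0
    (physical linkage only), undefined pairs as NaN."""
    rows_mask = _group_rows(matrix, group)
    dos = matrix.dosage[rows_mask]
    K = matrix.n_snps
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            if matrix.snps[i].chromosome != matrix.snps[j].chromosome:
                continue
            try:
                st = pair_ld((dos[:, i], dos[:, j]))
                out[i, j] = out[j, i] = st.d_prime
            except ComputationError:
                out[i, j] = out[j, i] = np.nan
    return out


# ---------------------------------------------------------------------------
# Haplotype blocks (Gabriel-style, CI-based)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockRuleParams:
    """Confidence-interval classification thresholds for block building."""

    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    min_strong_fraction: float = 0.95


@dataclass(frozen=True)
class Block:
    chromosome: str
    start_index: int  # inclusive, panel index
    end_index: int  # inclusive
    start_pos: int
    end_pos: int
    rsids: tuple[str, ...]


@dataclass(frozen=True)
class BlockPartition:
    blocks: tuple[Block, ...]
    #: (i, j) -> "strong" | "recomb" | "uninformative"
    pair_class: dict[tuple[int, int], str]


def classify_pair(ci_low: float, ci_high: float, params: BlockRuleParams) -> str:
    if np.isnan(ci_low) or np.isnan(ci_high):
        return "uninformative"
    if ci_low >= params.strong_ci_low and ci_high >= params.strong_ci_high:
        return "strong"
    if ci_high < params.recomb_ci_high:
        return "recomb"
    return "uninformative"


def build_blocks(
    snps: Sequence[SnpMeta],
    pair_cis: dict[tuple[int, int], tuple[float, float]],
    params: BlockRuleParams | None = None,
) -> BlockPartition:
    """Partition position-sorted SNPs into haplotype blocks.

    ``pair_cis`` maps within-chromosome index pairs (i < j) to bootstrap
    (ci_low, ci_high) for D'.  An interval qualifies when its outermost pair
    is strong LD and at least ``min_strong_fraction`` of its informative
    pairs are strong; qualifying intervals are accepted longest-first,
    non-overlapping.
    """
    params = params or BlockRuleParams()
    for k in range(1, len(snps)):
        a, b = snps[k - 1], snps[k]
        if a.chromosome == b.chromosome and a.position < b.position:
            continue
        if a.chromosome != b.chromosome:
            continue
        raise ValidationError("SNPs must be position-sorted within chromosome")

    pair_class = {
        (i, j): classify_pair(lo, hi, params) for (i, j), (lo, hi) in pair_cis.items()
    }

    candidates = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if snps[i].chromosome != snps[j].chromosome:
                continue
            if pair_class.get((i, j)) != "strong":
                continue
            strong = recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    c = pair_class.get((a, b), "uninformative")
                    strong += c == "strong"
                    recomb += c == "recomb"
            informative = strong + recomb
            if informative and strong / informative >= params.min_strong_fraction:
                span = snps[j].position - snps[i].position
                candidates.append((j - i, span, i, j))

    candidates.sort(reverse=True)
    taken = np.zeros(len(snps), dtype=bool)
    blocks = []
    for _, _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            Block(
                chromosome=snps[i].chromosome,
                start_index=i,
                end_index=j,
                start_pos=snps[i].position,
                end_pos=snps[j].position,
                rsids=tuple(s.rsid for s in snps[i : j + 1]),
            )
        )
    blocks.sort(key=lambda b: (b.chromosome, b.start_index))
    return BlockPartition(blocks=tuple(blocks), pair_class=pair_class)


def write_blocks_bed(partition: BlockPartition, path: str | Path) -> None:
    rows = [
        {
            "chrom": b.chromosome,
            "start_pos": b.start_pos,
            "end_pos": b.end_pos,
            "n_snps": len(b.rsids),
            "rsids": ",".join(b.rsids),
        }
        for b in partition.blocks
    ]
    pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos", "n_snps", "rsids"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# D'-threshold pruning
# ---------------------------------------------------------------------------

def prune_by_dprime(
    dprime: np.ndarray,
    threshold: float = 0.8,
    priority: Sequence[int] | None = None,
) -> list[int]:
    """Greedy LD pruning: visit SNPs in priority order, retain a SNP iff its
    D' with every already-retained SNP is <= threshold.

    ``priority`` is an ordering of panel indices (default: panel order);
    the result is deterministic given the ordering.  Undefined (NaN) pairs
    never exclude a SNP.
    """
    dprime = np.asarray(dprime, float)
    K = dprime.shape[0]
    if dprime.shape != (K, K):
        raise ValidationError("dprime must be square")
    order = list(priority) if priority is not None else list(range(K))
    if sorted(order) != list(range(K)):
        raise ValidationError("priority must be a permutation of panel indices")
    retained: list[int] = []
    for idx in order:
        vals = dprime[idx, retained]
        if retained and np.any(vals[~np.isnan(vals)] > threshold):
            continue
        retained.append(idx)
    return sorted(retained)


__all__ = [
    "genotype_cross_table",
    "HaplotypeFrequencies",
    "em_haplotype_freqs",
    "LdStatistics",
    "ld_statistics",
    "pair_ld",
    "DprimeCI",
    "bootstrap_dprime_ci",
    "pairwise_ld",
    "dprime_matrix",
    "BlockRuleParams",
    "Block",
    "BlockPartition",
    "classify_pair",
    "build_blocks",
    "write_blocks_bed",
    "prune_by_dprime",
]
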