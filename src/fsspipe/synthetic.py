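"""Synthetic case-control cohorts and packaged reference tables.

The generator draws control genotypes from Hardy-Weinberg proportions at a
specified control risk-allele frequency and case genotypes from the
exponential-tilt family P_case(g) proportional to P_control(g) * OR**g.
Under that sampling model the additive-model logistic odds ratio on the
resulting grouped data equals the specified OR in expectation, which gives
every downstream estimator an analytic recovery target.  Optional LD blocks
are specified at the haplotype level: all SNPs of a block are drawn as two
haplotypes per individual from a shared pool, with the case tilt applied to
the dosage of the block's causal SNP.

Also packaged here: the published 13-SNP genotype count tables, risk-score
quartile table and per-SNP QC summaries for a familial short stature
case-control study (978 cases / 1,129 controls of Han Chinese ancestry),
used as desk-scale fixtures throughout the test-suite and reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotypes import CASE, CONTROL, GenotypeMatrix, GroupedGenotypeCounts, SnpMeta

_PROB_TOL = 1e-12


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSimSpec:
    """One simulated SNP: either (control risk-allele frequency, OR) under
    HWE, or explicit case/control genotype-probability triples ordered by
    risk-allele dosage (0, 1, 2).

    The simulated risk allele is identified with the designated minor
    allele, so dosages in the emitted matrix are risk-allele dosages.
    """

    rsid: str
    control_freq: float | None = None
    or_: float | None = None
    case_probs: tuple[float, float, float] | None = None
    control_probs: tuple[float, float, float] | None = None
    chromosome: str = "1"
    position: int = 1
    minor_allele: str = "A"
    major_allele: str = "G"

    def __post_init__(self) -> None:
        explicit = self.case_probs is not None and self.control_probs is not None
        hwe = self.control_freq is not None
        if explicit == hwe:
            raise ValidationError(
                f"{self.rsid}: specify either (control_freq, or_) or explicit "
                "case/control genotype probabilities"
            )
        if hwe:
            if not (0.0 < self.control_freq < 1.0):
                raise ValidationError(
                    f"{self.rsid}: control_freq must be in (0,1) under the OR "
                    "parameterization"
                )
            if self.or_ is None or self.or_ <= 0:
                raise ValidationError(f"{self.rsid}: OR must be positive")
        else:
            for name, tri in (("case", self.case_probs), ("control", self.control_probs)):
                if len(tri) != 3 or any(p < 0 for p in tri):
                    raise ValidationError(f"{self.rsid}: bad {name} probability triple")
                if abs(sum(tri) - 1.0) > _PROB_TOL:
                    raise ValidationError(f"{self.rsid}: {name} probabilities must sum to 1")

    def genotype_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(control, case) genotype probability triples over dosage 0/1/2."""
        if self.control_probs is not None:
            return np.asarray(self.control_probs, float), np.asarray(self.case_probs, float)
        f = self.control_freq
        ctrl = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        case = ctrl * self.or_ ** np.arange(3)
        return ctrl, case / case.sum()


@dataclass(frozen=True)
class LdBlockSpec:
    """SNP indices sharing a haplotype pool.

    ``hap_freqs`` has one entry per haplotype in binary order over the block
    SNPs (bit value 1 = carries the risk/minor allele; the last index is the
    fastest-varying bit).  ``or_`` tilts case haplotype-pair probabilities by
    OR**dosage at the block SNP ``causal`` (position within the block).
    """

    indices: tuple[int, ...]
    hap_freqs: tuple[float, ...]
    or_: float = 1.0
    causal: int = 0

    def __post_init__(self) -> None:
        m = len(self.indices)
        if m < 2 or m > 8:
            raise ValidationError("LD blocks must span 2..8 SNPs")
        if len(self.hap_freqs) != 2**m:
            raise ValidationError(f"block of {m} SNPs needs {2 ** m} haplotype frequencies")
        if any(f < 0 for f in self.hap_freqs) or abs(sum(self.hap_freqs) - 1.0) > _PROB_TOL:
            raise ValidationError("haplotype frequencies must be non-negative and sum to 1")
        if not 0 <= self.causal < m:
            raise ValidationError("causal index outside block")
        if self.or_ <= 0:
            raise ValidationError("block OR must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic case-control cohort."""

    n_cases: int
    n_controls: int
    snp_specs: tuple[SnpSimSpec, ...]
    ld_blocks: tuple[LdBlockSpec, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0,1]")
        covered: set[int] = set()
        for blk in self.ld_blocks:
            if max(blk.indices) >= len(self.snp_specs):
                raise ValidationError("LD block index out of range")
            if covered & set(blk.indices):
                raise ValidationError("LD blocks overlap")
            covered |= set(blk.indices)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-column substream; adding SNPs never perturbs
    earlier columns."""
    return np.random.default_rng([seed, *key])


def _snp_meta(spec: SnpSimSpec) -> SnpMeta:
    return SnpMeta(
        rsid=spec.rsid,
        chromosome=spec.chromosome,
        position=spec.position,
        minor_allele=spec.minor_allele,
        major_allele=spec.major_allele,
        risk_allele=spec.minor_allele,
    )


def generate_cohort(spec: CohortSpec) -> GenotypeMatrix:
    """Draw a cohort according to ``spec``; bit-reproducible given its seed."""
    n = spec.n_cases + spec.n_controls
    k = len(spec.snp_specs)
    dosage = np.empty((n, k))
    case_rows = slice(0, spec.n_cases)
    ctrl_rows = slice(spec.n_cases, n)

    in_block = {i for blk in spec.ld_blocks for i in blk.indices}
    for j, snp in enumerate(spec.snp_specs):
        if j in in_block:
            continue
        ctrl_p, case_p = snp.genotype_probs()
        rng = _rng(spec.seed, 1, j)
        dosage[case_rows, j] = rng.choice(3, size=spec.n_cases, p=case_p)
        dosage[ctrl_rows, j] = rng.choice(3, size=spec.n_controls, p=ctrl_p)

    for b, blk in enumerate(spec.ld_blocks):
        m = len(blk.indices)
        haps = np.array(list(itertools.product((0, 1), repeat=m)))  # (2^m, m)
        f = np.asarray(blk.hap_freqs, float)
        pair_p = np.outer(f, f)  # ordered haplotype pairs
        causal_dosage = haps[:, blk.causal][:, None] + haps[None, :, blk.causal]
        tilted = pair_p * blk.or_**causal_dosage
        tilted /= tilted.sum()
        rng = _rng(spec.seed, 2, b)
        flat_case = rng.choice(pair_p.size, size=spec.n_cases, p=tilted.ravel())
        flat_ctrl = rng.choice(pair_p.size, size=spec.n_controls, p=(pair_p / pair_p.sum()).ravel())
        for rows, flat in ((case_rows, flat_case), (ctrl_rows, flat_ctrl)):
            h1, h2 = np.unravel_index(flat, pair_p.shape)
            geno = haps[h1] + haps[h2]  # (n_group, m)
            for c, j in enumerate(blk.indices):
                dosage[rows, j] = geno[:, c]

    if spec.missing_rate > 0:
        for j in range(k):
            rng = _rng(spec.seed, 3, j)
            mask = rng.random(n) < spec.missing_rate
            dosage[mask, j] = np.nan

    phenotype = np.array([CASE] * spec.n_cases + [CONTROL] * spec.n_controls, dtype=object)
    sample_ids = [f"case{i + 1}" for i in range(spec.n_cases)] + [
        f"ctrl{i + 1}" for i in range(spec.n_controls)
    ]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        phenotype=phenotype,
        snps=[_snp_meta(s) for s in spec.snp_specs],
        dosage=dosage,
    )


def generate_ld_pair(
    haplotype_freqs: tuple[float, float, float, float], n: int, seed: int
) -> GenotypeMatrix:
    """Draw ``n`` individuals as two iid haplotypes at two loci.

    ``haplotype_freqs`` = (p11, p12, p21, p22) where allele 1 is the major
    allele at each locus (the convention of the LD module).  Returns an
    unphased two-SNP matrix of control-labelled individuals.
    """
    f = np.asarray(haplotype_freqs, float)
    if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > _PROB_TOL:
        raise ValidationError("haplotype frequencies must be 4 non-negatives summing to 1")
    # haplotype index -> (minor-allele dosage at locus A, at locus B)
    hap_minor = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    rng = np.random.default_rng(seed)
    h = rng.choice(4, size=(n, 2), p=f)
    geno = hap_minor[h[:, 0]] + hap_minor[h[:, 1]]
    snps = [
        SnpMeta(rsid="snpA", chromosome="1", position=1000, minor_allele="A", major_allele="G"),
        SnpMeta(rsid="snpB", chromosome="1", position=2000, minor_allele="A", major_allele="G"),
    ]
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        phenotype=np.array([CONTROL] * n, dtype=object),
        snps=snps,
        dosage=geno.astype(float),
    )


# ---------------------------------------------------------------------------
# Published reference tables (desk-scale fixtures)
# ---------------------------------------------------------------------------

#: Per-SNP QC summary of all 34 candidate SNPs as published: designated
#: (reference-panel minor) allele, its frequency in the reference Han
#: Chinese panel and in the study controls, call rate, and the control
#: Hardy-Weinberg goodness-of-fit p-value.  Percentages as printed.
_QC_TABLE = """\
rs1926872 COLGALT2 1 184049341 G 47.1 51.5 100.0 0.34
rs1046934 TSEN15 1 184054395 C 47.1 51.8 100.0 0.35
rs3791679 EFEMP1 2 55869757 T 20.7 24.9 99.8 0.08
rs3791675 EFEMP1 2 55884174 G 22.2 25.3 100.0 0.26
rs3771381 ZNF638 2 71333535 T 42.7 39.7 100.0 0.52
rs10935120 CEP63 3 134514250 A 18.9 15.0 99.8 0.85
rs6440003 ZBTB38 3 141375367 A 35.6 34.8 100.0 0.21
rs7632381 ZBTB38 3 141387221 C 34.4 35.6 100.0 0.24
rs1344672 ZBTB38 3 141406863 C 33.3 35.5 100.0 0.29
rs9825379 ZBTB38 3 141418193 A 17.1 19.9 99.9 0.40
rs7678436 DCAF16 4 17796343 A 34.1 32.4 99.6 0.69
rs16895802 NCAPG 4 17814266 G 12.2 12.0 100.0 0.60
rs6842303 LCORL 4 17852432 T 45.0 47.4 100.0 0.86
rs13131350 LCORL 4 17875864 G 22.2 24.6 100.0 0.69
rs16896276 LCORL 4 18013533 A 46.7 47.4 100.0 0.51
rs2011603 LCORL 4 18023861 G 45.1 47.9 100.0 0.57
rs17720281 NA 4 144622624 T 20.0 24.9 100.0 0.64
rs6845999 HHIP 4 144644674 T 26.8 24.7 99.9 0.66
rs4240326 ANAPC10 4 144918112 A 36.7 30.0 100.0 0.55
rs6823268 ANAPC10 4 145061411 G 17.1 17.3 100.0 0.31
rs4733724 GSDMC 8 129711482 A 30.5 28.2 100.0 0.10
rs6470764 GSDMC 8 129713419 C 33.0 28.2 100.0 0.10
rs10858250 QSOX2 9 136227369 G 24.7 23.4 100.0 0.90
rs12338076 QSOX2 9 136229894 C 32.4 31.4 99.9 0.44
rs2401171 ADAMTSL3 15 83888924 T 29.1 23.5 100.0 0.09
rs10906982 ADAMTSL3 15 83899406 T 28.9 23.7 99.8 0.07
rs7183263 ADAMTSL3 15 83904289 T 29.1 23.4 100.0 0.10
rs11259936 ADAMTSL3 15 83911830 A 29.1 23.4 100.0 0.10
rs4842838 ADAMTSL3 15 83913372 G 28.9 23.3 99.8 0.08
rs258324 CDK10 16 89687847 A 34.4 32.5 100.0 0.50
rs4800452 CABLES1 18 23147647 C 17.6 16.9 100.0 0.50
rs4369779 CABLES1 18 23155444 T 15.8 14.4 99.9 0.53
rs4308051 CABLES1 18 23155497 T 15.8 14.4 100.0 0.50
rs8094261 CABLES1 18 23166764 G 13.4 14.8 100.0 0.44
"""


def qc_summary_table() -> pd.DataFrame:
    """The published 34-SNP QC summary as a DataFrame."""
    rows = [ln.split() for ln in _QC_TABLE.strip().splitlines()]
    df = pd.DataFrame(
        rows,
        columns=["rsid", "gene", "chromosome", "position", "allele",
                 "maf_chb_pct", "maf_controls_pct", "call_rate_pct", "hwe_p_controls"],
    )
    for c in ("maf_chb_pct", "maf_controls_pct", "call_rate_pct", "hwe_p_controls"):
        df[c] = df[c].astype(float)
    df["position"] = df["position"].astype(int)
    return df


#: The 13 LD-pruned SNPs with published genotype counts and additive-model
#: results.  Counts are (major-hom, het, minor-hom) in the designated-allele
#: orientation.  The second allele is not printed for SNPs whose risk allele
#: is the designated one; a placeholder letter is used there (it never
#: enters any statistic).  For rs3771381 the published risk-allele letter
#: ("A") contradicts the published counts and OR; the count-consistent
#: orientation (risk = designated T) is stored and flagged.
_ASSOC_ROWS = [
    # rsid, gene, chr, pos, minor, major, risk, case counts, control counts,
    # printed OR, printed CI, printed p, note
    ("rs1046934", "TSEN15", "1", 184054395, "C", "A", "A",
     (287, 500, 189), (270, 548, 311), 1.32, (1.16, 1.49), 1.06e-5, None),
    ("rs3791679", "EFEMP1", "2", 55869757, "T", "C", "C",
     (629, 311, 34), (625, 443, 59), 1.39, (1.19, 1.61), 1.96e-5, None),
    ("rs3771381", "ZNF638", "2", 71333535, "T", "A", "T",
     (278, 495, 205), (416, 530, 183), 1.31, (1.16, 1.48), 1.83e-5,
     "published risk-allele letter 'A' is inconsistent with the published "
     "counts/OR; count-consistent risk allele T stored"),
    ("rs10935120", "CEP63", "3", 134514250, "A", "G", "A",
     (623, 317, 38), (816, 285, 26), 1.43, (1.22, 1.68), 1.27e-5,
     "major-allele letter not published; placeholder"),
    ("rs7632381", "ZBTB38", "3", 141387221, "C", "T", "T",
     (479, 424, 75), (459, 536, 134), 1.35, (1.18, 1.54), 1.17e-5, None),
    ("rs13131350", "LCORL", "4", 17875864, "G", "A", "G",
     (432, 433, 112), (639, 424, 66), 1.55, (1.36, 1.78), 2.06e-10,
     "major-allele letter not published; placeholder"),
    ("rs6845999", "HHIP", "4", 144644674, "T", "C", "C",
     (639, 306, 32), (637, 425, 66), 1.41, (1.22, 1.64), 6.86e-6, None),
    ("rs4240326", "ANAPC10", "4", 144918112, "A", "G", "G",
     (571, 350, 57), (557, 466, 106), 1.37, (1.19, 1.59), 5.95e-6, None),
    ("rs6470764", "GSDMC", "8", 129713419, "C", "T", "T",
     (590, 336, 51), (593, 435, 101), 1.35, (1.18, 1.54), 2.57e-5, None),
    ("rs12338076", "QSOX2", "9", 136229894, "C", "A", "A",
     (564, 330, 83), (536, 475, 117), 1.33, (1.16, 1.52), 2.92e-5, None),
    ("rs4842838", "ADAMTSL3", "15", 83913372, "G", "A", "G",
     (484, 400, 94), (652, 424, 51), 1.42, (1.23, 1.63), 8.51e-7,
     "major-allele letter not published; placeholder"),
    ("rs258324", "CDK10", "16", 89687847, "A", "C", "C",
     (528, 388, 62), (510, 505, 114), 1.37, (1.19, 1.56), 7.32e-6, None),
    ("rs4308051", "CABLES1", "18", 23155497, "T", "C", "T",
     (636, 304, 38), (831, 272, 26), 1.43, (1.22, 1.69), 1.39e-5,
     "major-allele letter not published; placeholder"),
]


@dataclass(frozen=True)
class AssocFixtureRow:
    counts: GroupedGenotypeCounts
    printed_or: float
    printed_ci: tuple[float, float]
    printed_p: float
    note: str | None = None

    @property
    def snp(self) -> SnpMeta:
        return self.counts.snp


@dataclass(frozen=True)
class Table2Fixture:
    """Published desk-scale inputs: 13 grouped genotype tables with risk
    alleles and printed ORs, plus the risk-score quartile table."""

    rows: tuple[AssocFixtureRow, ...]
    n_cases: int
    n_controls: int
    quartile_case_counts: tuple[int, int, int, int]
    quartile_control_counts: tuple[int, int, int, int]
    quartile_printed_ors: tuple[float, float, float]  # Q2..Q4 vs Q1
    quartile_printed_cis: tuple[tuple[float, float], ...]
    quartile_cutpoints: tuple[float, float, float]

    def counts(self) -> list[GroupedGenotypeCounts]:
        return [r.counts for r in self.rows]

    def row(self, rsid: str) -> AssocFixtureRow:
        for r in self.rows:
            if r.snp.rsid == rsid:
                return r
        raise KeyError(rsid)


def table2_fixture() -> Table2Fixture:
    """Published genotype-count and quartile tables as a fixture object."""
    rows = []
    for (rsid, gene, chrom, pos, minor, major, risk,
         case_tri, ctrl_tri, por, pci, pp, note) in _ASSOC_ROWS:
        snp = SnpMeta(rsid=rsid, chromosome=chrom, position=pos,
                      minor_allele=minor, major_allele=major,
                      risk_allele=risk, gene_label=gene)
        rows.append(
            AssocFixtureRow(
                counts=GroupedGenotypeCounts(snp=snp, case_counts=case_tri,
                                             control_counts=ctrl_tri),
                printed_or=por, printed_ci=pci, printed_p=pp, note=note,
            )
        )
    return Table2Fixture(
        rows=tuple(rows),
        n_cases=978,
        n_controls=1129,
        quartile_case_counts=(144, 199, 254, 381),
        quartile_control_counts=(412, 282, 278, 157),
        quartile_printed_ors=(2.02, 2.61, 6.94),
        quartile_printed_cis=((1.55, 2.63), (2.03, 3.37), (5.32, 9.06)),
        quartile_cutpoints=(11.88, 13.50, 15.05),
    )


__all__ = [
    "SnpSimSpec",
    "LdBlockSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_ld_pair",
    "qc_summary_table",
    "AssocFixtureRow",
    "Table2Fixture",
    "table2_fixture",
]
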