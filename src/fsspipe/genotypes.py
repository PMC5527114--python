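"""Data model and I/O for biallelic case-control genotype data.

Genotypes are stored as minor-allele dosages (0/1/2, NaN = missing) in a
samples x SNPs matrix together with per-SNP metadata.  "Minor" means the
externally designated allele (the reference-panel minor allele), which may
exceed 50% frequency in a particular cohort; the designation, not the
in-cohort frequency, fixes the dosage orientation.  Grouped per-SNP count
tables (major-homozygote, heterozygote, minor-homozygote) x (case, control)
are the unit most statistics downstream operate on.

Supported text formats: a simple genotype TSV (allele pairs or dosages),
PLINK-style .ped/.map, and optionally VCF (GT field, biallelic records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

NUCLEOTIDES = frozenset("ACGT")

#: Tokens accepted as a missing genotype in the TSV dialect.
MISSING_CODES = frozenset({"NA", "--", "00", ".", "./.", "NN"})

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata: identity, 1-based position and allele designations."""

    rsid: str
    chromosome: str
    position: int
    minor_allele: str
    major_allele: str
    risk_allele: str | None = None
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValidationError(f"{self.rsid}: position must be positive")
        for name in ("minor_allele", "major_allele"):
            a = getattr(self, name)
            if a not in NUCLEOTIDES:
                raise ValidationError(f"{self.rsid}: {name} {a!r} not in A/C/G/T")
        if self.minor_allele == self.major_allele:
            raise ValidationError(f"{self.rsid}: minor and major allele identical")
        if self.risk_allele is not None and self.risk_allele not in (
            self.minor_allele,
            self.major_allele,
        ):
            raise ValidationError(
                f"{self.rsid}: risk allele {self.risk_allele!r} is neither "
                f"{self.minor_allele!r} nor {self.major_allele!r}"
            )

    @property
    def risk_is_minor(self) -> bool:
        if self.risk_allele is None:
            raise ValidationError(f"{self.rsid}: risk allele not set")
        return self.risk_allele == self.minor_allele


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes for a case-control cohort.

    ``dosage[i, j]`` counts copies of ``snps[j].minor_allele`` carried by
    sample ``i``; NaN marks a missing call.
    """

    sample_ids: list[str]
    phenotype: np.ndarray  # dtype object/str: "case" | "control"
    snps: list[SnpMeta]
    dosage: np.ndarray  # float, shape (n_samples, n_snps), NaN = missing

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.sample_ids)}, {len(self.snps)})"
            )
        if self.phenotype.shape != (len(self.sample_ids),):
            raise ValidationError("phenotype length != number of samples")
        bad = set(self.phenotype) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown phenotype labels: {sorted(bad)}")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValidationError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            snps=[self.snps[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def snp_index(self, rsid: str) -> int:
        for i, s in enumerate(self.snps):
            if s.rsid == rsid:
                return i
        raise KeyError(rsid)


@dataclass(frozen=True)
class GroupedGenotypeCounts:
    """Per-SNP 2x3 genotype count table.

    Category order is fixed as (major-homozygote, heterozygote,
    minor-homozygote) where "minor" is the designated allele.
    """

    snp: SnpMeta
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for tri in (self.case_counts, self.control_counts):
            if len(tri) != 3 or any(c < 0 for c in tri):
                raise ValidationError(f"{self.snp.rsid}: counts must be 3 non-negatives")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    @property
    def pooled_counts(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.case_counts, self.control_counts))


def dosage_for_risk_allele(
    counts: GroupedGenotypeCounts,
) -> list[tuple[int, int, int]]:
    """Re-key a count table by risk-allele dosage.

    Returns ``[(dosage, case_count, control_count)]`` for dosages 0, 1, 2.
    If the risk allele is the designated minor allele the category order
    (major-hom, het, minor-hom) already is dosage (0, 1, 2); if it is the
    major allele the order reverses.
    """
    if counts.snp.risk_allele is None:
        raise ValidationError(f"{counts.snp.rsid}: risk allele not set")
    order = (0, 1, 2) if counts.snp.risk_is_minor else (2, 1, 0)
    return [
        (d, counts.case_counts[i], counts.control_counts[i])
        for i, d in sorted(enumerate(order), key=lambda t: t[1])
    ]


def collapse_to_counts(matrix: GenotypeMatrix) -> list[GroupedGenotypeCounts]:
    """Collapse an individual-level matrix to per-SNP grouped count tables.

    Missing dosages are excluded per SNP (complete case per marker).
    """
    out = []
    is_case = matrix.is_case
    for j, snp in enumerate(matrix.snps):
        col = matrix.dosage[:, j]
        tri = {}
        for grp, mask in ((CASE, is_case), (CONTROL, ~is_case)):
            vals = col[mask]
            vals = vals[~np.isnan(vals)]
            tri[grp] = tuple(int((vals == d).sum()) for d in (0.0, 1.0, 2.0))
        out.append(
            GroupedGenotypeCounts(snp=snp, case_counts=tri[CASE], control_counts=tri[CONTROL])
        )
    return out


# ---------------------------------------------------------------------------
# SNP metadata I/O
# ---------------------------------------------------------------------------

META_COLUMNS = ["rsid", "chromosome", "position", "minor_allele", "major_allele", "risk_allele", "gene"]


def read_snp_metadata_tsv(path: str | Path) -> dict[str, SnpMeta]:
    """Read a SNP metadata TSV into a mapping rsid -> SnpMeta."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(META_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    out: dict[str, SnpMeta] = {}
    for _, row in df.iterrows():
        risk = row.get("risk_allele")
        gene = row.get("gene")
        out[row["rsid"]] = SnpMeta(
            rsid=row["rsid"],
            chromosome=str(row["chromosome"]),
            position=int(row["position"]),
            minor_allele=row["minor_allele"],
            major_allele=row["major_allele"],
            risk_allele=None if pd.isna(risk) or risk in ("", ".") else risk,
            gene_label=None if pd.isna(gene) or gene in ("", ".") else gene,
        )
    return out


def write_snp_metadata_tsv(snps: Iterable[SnpMeta], path: str | Path) -> None:
    rows = [
        {
            "rsid": s.rsid,
            "chromosome": s.chromosome,
            "position": s.position,
            "minor_allele": s.minor_allele,
            "major_allele": s.major_allele,
            "risk_allele": s.risk_allele or ".",
            "gene": s.gene_label or ".",
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------

def _parse_cell(token: str, snp: SnpMeta, line_no: int, path: str) -> float:
    """One genotype cell -> minor-allele dosage (NaN for missing)."""
    tok = token.strip().upper()
    if tok in MISSING_CODES or tok == "":
        return np.nan
    if tok in ("0", "1", "2"):
        return float(tok)
    if len(tok) == 2:
        # allele pair, e.g. "AC"; any non-nucleotide character -> missing call
        if not set(tok) <= NUCLEOTIDES:
            if set(tok) <= NUCLEOTIDES | {"-", "0", "N", "."}:
                return np.nan
            raise ParseError(f"{path}, line {line_no}: allele not in A/C/G/T: {token!r}")
        alleles = {snp.minor_allele, snp.major_allele}
        if not set(tok) <= alleles:
            raise ParseError(
                f"{path}, line {line_no}: genotype {token!r} inconsistent with "
                f"{snp.rsid} alleles {sorted(alleles)}"
            )
        return float(sum(a == snp.minor_allele for a in tok))
    raise ParseError(f"{path}, line {line_no}: cannot parse genotype {token!r}")


def _infer_orientation(
    rsid: str, column: list[str], line_offset: int, path: str
) -> tuple[str, str]:
    """Infer (minor, major) alleles of a TSV column from pooled frequency.

    Ties broken alphabetically (minor = lexicographically smaller allele).
    """
    tally: dict[str, int] = {}
    for tok in column:
        tok = tok.strip().upper()
        if tok in MISSING_CODES or tok == "" or tok in ("0", "1", "2"):
            continue
        for a in tok:
            if a in NUCLEOTIDES:
                tally[a] = tally.get(a, 0) + 1
    if not tally:
        raise ParseError(f"{path}: column {rsid}: no allele calls, cannot infer orientation")
    if len(tally) == 1:
        (only,) = tally
        other = "A" if only != "A" else "G"
        return only, other  # monomorphic: arbitrary but valid orientation
    if len(tally) > 2:
        raise ParseError(f"{path}: column {rsid}: more than two alleles {sorted(tally)}")
    (a1, n1), (a2, n2) = sorted(tally.items())
    if n1 < n2:
        return a1, a2
    if n2 < n1:
        return a2, a1
    return a1, a2


def read_genotype_tsv(
    path: str | Path,
    metadata: dict[str, SnpMeta] | str | Path | None = None,
) -> GenotypeMatrix:
    """Read the genotype TSV dialect.

    Header: ``sample_id<TAB>phenotype<TAB><rsid1><TAB>...``; cells are
    two-character allele pairs (``AC``) or single-digit dosages; missing is
    ``NA``, ``--`` or ``00``.  Minor/major orientation comes from
    ``metadata`` when given, otherwise it is inferred from the pooled allele
    frequency (dosage cells then require metadata).
    """
    path = str(path)
    if metadata is not None and not isinstance(metadata, dict):
        metadata = read_snp_metadata_tsv(metadata)

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
        raise ParseError(f"{path}: header must start 'sample_id\\tphenotype\\t<rsid>...'")
    rsids = header[2:]

    sample_ids: list[str] = []
    phenos: list[str] = []
    cells: list[list[str]] = []
    for line_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}, line {line_no}: expected {len(header)} fields, got {len(parts)}"
            )
        pheno = parts[1].strip().lower()
        if pheno not in (CASE, CONTROL):
            raise ValidationError(
                f"{path}, line {line_no}: phenotype must be 'case' or 'control', got {parts[1]!r}"
            )
        sample_ids.append(parts[0])
        phenos.append(pheno)
        cells.append(parts[2:])

    snps: list[SnpMeta] = []
    for j, rsid in enumerate(rsids):
        if metadata and rsid in metadata:
            snps.append(metadata[rsid])
        else:
            minor, major = _infer_orientation(rsid, [row[j] for row in cells], 2, path)
            snps.append(
                SnpMeta(rsid=rsid, chromosome="0", position=j + 1,
                        minor_allele=minor, major_allele=major)
            )

    dosage = np.full((len(sample_ids), len(rsids)), np.nan)
    for i, row in enumerate(cells):
        for j, tok in enumerate(row):
            dosage[i, j] = _parse_cell(tok, snps[j], i + 2, path)
    return GenotypeMatrix(sample_ids=sample_ids, phenotype=np.array(phenos, dtype=object),
                          snps=snps, dosage=dosage)


def write_genotype_tsv(
    matrix: GenotypeMatrix, path: str | Path, style: str = "alleles"
) -> None:
    """Write a matrix in the genotype TSV dialect (``style``: alleles|dosage)."""
    if style not in ("alleles", "dosage"):
        raise ValidationError(f"unknown style {style!r}")
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(s.rsid for s in matrix.snps) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            toks = []
            for j, snp in enumerate(matrix.snps):
                d = matrix.dosage[i, j]
                if np.isnan(d):
                    toks.append("NA")
                elif style == "dosage":
                    toks.append(str(int(d)))
                else:
                    k = int(d)
                    toks.append(snp.major_allele * (2 - k) + snp.minor_allele * k)
            fh.write(f"{sid}\t{matrix.phenotype[i]}\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# PLINK .ped/.map text
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    metadata: dict[str, SnpMeta] | None = None,
) -> GenotypeMatrix:
    """Read a PLINK-style text .ped/.map pair.

    Phenotype codes: 1 = control, 2 = case; 0 or -9 (missing) drops the
    sample with a warning.  Allele pair "0 0" is a missing genotype.
    """
    map_rows = []
    with open(map_path) as fh:
        for line_no, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}, line {line_no}: expected 4 columns")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    phenos: list[str] = []
    pairs: list[list[tuple[str, str]]] = []
    n_dropped = 0
    with open(ped_path) as fh:
        for line_no, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValidationError(
                    f"{ped_path}, line {line_no}: expected {6 + 2 * n_snps} fields "
                    f"({n_snps} SNPs from {map_path}), got {len(parts)}"
                )
            code = parts[5]
            if code == "1":
                pheno = CONTROL
            elif code == "2":
                pheno = CASE
            else:
                n_dropped += 1
                continue
            sample_ids.append(parts[1])
            phenos.append(pheno)
            geno = parts[6:]
            pairs.append([(geno[2 * j].upper(), geno[2 * j + 1].upper()) for j in range(n_snps)])
    if n_dropped:
        warnings.warn(
            f"{ped_path}: dropped {n_dropped} sample(s) with missing phenotype code",
            stacklevel=2,
        )

    snps: list[SnpMeta] = []
    for j, (chrom, rsid, pos) in enumerate(map_rows):
        if metadata and rsid in metadata:
            snps.append(metadata[rsid])
        else:
            column = ["".join(p[j]) if "0" not in p[j] else "00" for p in pairs]
            minor, major = _infer_orientation(rsid, column, 1, str(ped_path))
            snps.append(SnpMeta(rsid=rsid, chromosome=chrom, position=max(pos, 1),
                                minor_allele=minor, major_allele=major))

    dosage = np.full((len(sample_ids), n_snps), np.nan)
    for i, row in enumerate(pairs):
        for j, (a1, a2) in enumerate(row):
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if a not in NUCLEOTIDES:
                    raise ParseError(f"{ped_path}: sample {sample_ids[i]}: bad allele {a!r}")
            dosage[i, j] = (a1 == snps[j].minor_allele) + (a2 == snps[j].minor_allele)
    return GenotypeMatrix(sample_ids=sample_ids, phenotype=np.array(phenos, dtype=object),
                          snps=snps, dosage=dosage)


# ---------------------------------------------------------------------------
# Optional VCF reading (GT field, biallelic SNVs only)
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    phenotypes: dict[str, str],
    metadata: dict[str, SnpMeta] | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNV records from a VCF (v4.x) via cyvcf2.

    ``phenotypes`` maps sample id -> "case"/"control"; samples absent from
    the mapping are dropped.  REF is taken as the major and ALT as the minor
    allele unless ``metadata`` overrides a record's rsid.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF support requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    keep = [i for i, s in enumerate(vcf.samples) if s in phenotypes]
    if not keep:
        raise ValidationError(f"{path}: no VCF sample matches the phenotype mapping")
    sample_ids = [vcf.samples[i] for i in keep]
    phenos = [phenotypes[s] for s in sample_ids]
    bad = set(phenos) - {CASE, CONTROL}
    if bad:
        raise ValidationError(f"phenotype labels must be case/control, got {sorted(bad)}")

    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            continue
        rsid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if metadata and rsid in metadata:
            meta = metadata[rsid]
        else:
            meta = SnpMeta(rsid=rsid, chromosome=str(rec.CHROM), position=rec.POS,
                           minor_allele=alt, major_allele=ref)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types[keep]
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        if meta.minor_allele == ref and meta.major_allele == alt:
            col = 2.0 - col
        snps.append(meta)
        columns.append(col)
    dosage = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, phenotype=np.array(phenos, dtype=object),
                          snps=snps, dosage=dosage)


__all__ = [
    "CASE",
    "CONTROL",
    "SnpMeta",
    "GenotypeMatrix",
    "GroupedGenotypeCounts",
    "collapse_to_counts",
    "dosage_for_risk_allele",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_snp_metadata_tsv",
    "write_snp_metadata_tsv",
    "read_plink_text",
    "read_vcf",
]
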