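"""End-to-end orchestration: QC -> association -> LD pruning -> wGRS.

Stage order follows the study design: markers passing per-SNP QC are tested
under the additive model; markers significant at the Bonferroni screen
threshold are pruned to an approximately independent subset (D' <= 0.8,
keeping the most significant marker of each LD cluster — the re-selection
rule is a package choice and is echoed in the log); the pruned set defines
the weighted genetic risk score, its quartile odds ratios and the trend
test.  Every run writes TSV reports per stage plus a JSON run report; given
a seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from configparser import ConfigParser
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import SignificancePolicy, association_table, bonferroni_threshold, write_association_table
from .errors import ComputationError, FsspipeError, ValidationError
from .genotypes import (
    GenotypeMatrix,
    collapse_to_counts,
    read_genotype_tsv,
    read_plink_text,
    read_snp_metadata_tsv,
)
from .grs import (
    RESCALED,
    RiskWeightTable,
    assign_quartiles,
    cochran_armitage_trend,
    quartile_association,
    weighted_grs,
    write_grs_tsv,
    write_weights_tsv,
)
from .ld import BlockRuleParams, dprime_matrix, pairwise_ld, prune_by_dprime
from .qc import QcThresholds, apply_qc_filters, compute_qc, write_qc_report
from .synthetic import table2_fixture

logger = logging.getLogger("fsspipe")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; defaults are the study thresholds."""

    genotype_path: str | None = None
    metadata_path: str | None = None
    ped_path: str | None = None
    map_path: str | None = None
    out_dir: str = "fsspipe_out"
    seed: int = 0
    qc: QcThresholds = field(default_factory=QcThresholds)
    significance: SignificancePolicy = field(default_factory=SignificancePolicy)
    dprime_threshold: float = 0.8
    ld_group: str = "pooled"
    n_boot: int = 1000
    block_rule: BlockRuleParams = field(default_factory=BlockRuleParams)
    grs_convention: str = RESCALED
    grs_missing_policy: str = "impute"
    grs_cutpoints: tuple[float, float, float] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dprime_threshold <= 1.0:
            raise ValidationError("dprime_threshold must be in [0,1]")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key-value config file (one section per stage)."""
    cp = ConfigParser()
    read = cp.read(path)
    if not read:
        raise ValidationError(f"config file not found: {path}")

    def get(section: str, key: str, default, cast):
        if cp.has_option(section, key):
            return cast(cp.get(section, key))
        return default

    cut = get("grs", "cutpoints", None, str)
    cutpoints = tuple(float(x) for x in cut.split(",")) if cut else None
    if cutpoints is not None and len(cutpoints) != 3:
        raise ValidationError("grs cutpoints must be three comma-separated numbers")
    return PipelineConfig(
        genotype_path=get("input", "genotypes", None, str),
        metadata_path=get("input", "metadata", None, str),
        ped_path=get("input", "ped", None, str),
        map_path=get("input", "map", None, str),
        out_dir=get("output", "out_dir", "fsspipe_out", str),
        seed=get("output", "seed", 0, int),
        log_level=get("output", "log_level", "INFO", str),
        qc=QcThresholds(
            min_maf=get("qc", "min_maf", 0.05, float),
            min_call_rate=get("qc", "min_call_rate", 0.95, float),
            min_hwe_p=get("qc", "min_hwe_p", 0.05, float),
        ),
        significance=SignificancePolicy(
            alpha=get("significance", "alpha", 0.05, float),
            n_tests_additive=get("significance", "n_tests_additive", 1033, int),
            n_tests_domdev=get("significance", "n_tests_domdev", 34, int),
        ),
        dprime_threshold=get("ld", "dprime_threshold", 0.8, float),
        ld_group=get("ld", "group", "pooled", str),
        n_boot=get("ld", "n_boot", 1000, int),
        block_rule=BlockRuleParams(
            strong_ci_low=get("ld", "strong_ci_low", 0.70, float),
            strong_ci_high=get("ld", "strong_ci_high", 0.98, float),
            recomb_ci_high=get("ld", "recomb_ci_high", 0.90, float),
            min_strong_fraction=get("ld", "min_strong_fraction", 0.95, float),
        ),
        grs_convention=get("grs", "convention", RESCALED, str),
        grs_missing_policy=get("grs", "missing_policy", "impute", str),
        grs_cutpoints=cutpoints,
    )


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    return fh


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    n_input: int
    n_qc_passed: int
    n_significant: int
    n_pruned: int
    files: dict[str, str]
    seed: int
    thresholds: dict
    trend: tuple[float, float] | None = None
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_matrix(config: PipelineConfig) -> GenotypeMatrix:
    meta = read_snp_metadata_tsv(config.metadata_path) if config.metadata_path else None
    if config.genotype_path:
        return read_genotype_tsv(config.genotype_path, meta)
    if config.ped_path and config.map_path:
        return read_plink_text(config.ped_path, config.map_path, meta)
    raise ValidationError("config must name either genotypes or a ped/map pair")


def run_pipeline(
    config: PipelineConfig, matrix: GenotypeMatrix | None = None
) -> RunReport:
    """Execute the full pipeline; returns the run report.

    On any stage error the partial outputs are removed and the error is
    re-raised with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = _setup_logging(out_dir, config.log_level)
    written: list[Path] = [out_dir / "run.log"]
    files: dict[str, str] = {}

    def emit(tag: str, name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)
        files[tag] = str(path)

    stage = "input"
    try:
        logger.info(
            "thresholds: maf>=%g call_rate>=%g hwe_p>=%g additive_p<%g "
            "domdev_p<%g dprime<=%g; seed=%d; pruning priority: ascending additive p",
            config.qc.min_maf, config.qc.min_call_rate, config.qc.min_hwe_p,
            bonferroni_threshold(config.significance, "additive"),
            bonferroni_threshold(config.significance, "domdev"),
            config.dprime_threshold, config.seed,
        )
        if matrix is None:
            matrix = _load_matrix(config)
        logger.info("input: %d samples (%d cases, %d controls), %d SNPs",
                    matrix.n_samples, matrix.n_cases, matrix.n_controls, matrix.n_snps)

        stage = "qc"
        counts = collapse_to_counts(matrix)
        qc_results = compute_qc(counts, matrix.n_cases, matrix.n_controls)
        passed_snps, qc_report = apply_qc_filters(qc_results, config.qc)
        emit("qc_report", "qc_report.tsv", lambda p: write_qc_report(qc_report, p))
        passed_rsids = {s.rsid for s in passed_snps}
        logger.info("qc: %d / %d SNPs pass", len(passed_snps), matrix.n_snps)

        stage = "association"
        kept_counts = [c for c in counts if c.snp.rsid in passed_rsids]
        assoc = association_table(kept_counts, config.significance)
        emit("association", "association.tsv", lambda p: write_association_table(assoc, p))
        sig = assoc[assoc["significant"]] if not assoc.empty else assoc
        logger.info("association: %d / %d SNPs significant at %.3g",
                    len(sig), len(assoc),
                    bonferroni_threshold(config.significance, "additive"))

        stage = "ld"
        sig_rsids = list(sig["rsid"]) if not sig.empty else []
        retained_rsids: list[str] = []
        if sig_rsids:
            sig_idx = [matrix.snp_index(r) for r in sig_rsids]
            sub = matrix.subset_snps(sig_idx)
            dmat = dprime_matrix(sub, group=config.ld_group)
            priority = list(np.argsort(sig["p_additive"].to_numpy(), kind="mergesort"))
            retained_local = prune_by_dprime(dmat, config.dprime_threshold, priority)
            retained_rsids = [sub.snps[i].rsid for i in retained_local]
            ld_long = pairwise_ld(sub, group=config.ld_group)
            emit("ld_matrix", "ld_pairs.tsv",
                 lambda p: ld_long.to_csv(p, sep="\t", index=False, float_format="%.6g"))
        logger.info("ld pruning (D' > %g excluded): %d -> %d SNPs",
                    config.dprime_threshold, len(sig_rsids), len(retained_rsids))

        stage = "grs"
        trend = None
        if retained_rsids:
            pruned_assoc = assoc[assoc["rsid"].isin(retained_rsids)]
            weights = RiskWeightTable.from_association_table(pruned_assoc)
            emit("weights", "grs_weights.tsv", lambda p: write_weights_tsv(weights, p))
            grs_vec = weighted_grs(
                matrix, weights,
                convention=config.grs_convention,
                missing_policy=config.grs_missing_policy,
            )
            partition = assign_quartiles(grs_vec, matrix.is_case, config.grs_cutpoints)
            quart = quartile_association(partition)
            trend = cochran_armitage_trend(partition.table())
            quart = quart.assign(trend_z=trend[0], trend_p=trend[1])
            emit("grs", "grs_scores.tsv",
                 lambda p: write_grs_tsv(matrix, grs_vec, partition, p))
            emit("quartiles", "quartile_report.tsv",
                 lambda p: quart.to_csv(p, sep="\t", index=False, float_format="%.6g"))
            logger.info("grs: cut-points %s, trend Z=%.3f p=%.3g",
                        np.round(partition.cutpoints, 4).tolist(), trend[0], trend[1])

        report = RunReport(
            n_input=matrix.n_snps,
            n_qc_passed=len(passed_snps),
            n_significant=len(sig_rsids),
            n_pruned=len(retained_rsids),
            files=files,
            seed=config.seed,
            thresholds={
                "min_maf": config.qc.min_maf,
                "min_call_rate": config.qc.min_call_rate,
                "min_hwe_p": config.qc.min_hwe_p,
                "additive_p": bonferroni_threshold(config.significance, "additive"),
                "domdev_p": bonferroni_threshold(config.significance, "domdev"),
                "dprime_threshold": config.dprime_threshold,
            },
            trend=trend,
        )
        (out_dir / "run_report.json").write_text(report.to_json() + "\n")
        files["run_report"] = str(out_dir / "run_report.json")
        return report
    except FsspipeError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(fh)
        fh.close()


# ---------------------------------------------------------------------------
# Fixture mode: recompute the published desk-scale tables
# ---------------------------------------------------------------------------

def run_fixture_mode(out_dir: str | Path | None = None) -> dict:
    """Recompute OR/CI/p and quartile/trend columns from the packaged
    published count tables and compare with the printed values.

    Returns a dict with the comparison tables and flags any recomputed OR
    differing from print by more than 0.01.
    """
    fx = table2_fixture()
    policy = SignificancePolicy()
    assoc = association_table(fx.counts(), policy)

    printed = {r.snp.rsid: r for r in fx.rows}
    rows = []
    for _, r in assoc.iterrows():
        p = printed[r["rsid"]]
        rows.append(
            {
                "rsid": r["rsid"],
                "or_recomputed": round(float(r["or"]), 2),
                "or_printed": p.printed_or,
                "or_abs_diff": abs(float(r["or"]) - p.printed_or),
                "p_recomputed": float(r["p_additive"]),
                "p_printed": p.printed_p,
                "significant": bool(r["significant"]),
                "flag": abs(float(r["or"]) - p.printed_or) > 0.01,
            }
        )
    assoc_cmp = pd.DataFrame(rows)

    table3 = np.array([fx.quartile_case_counts, fx.quartile_control_counts], float)
    part = _partition_from_counts(fx)
    quart = quartile_association(part)
    trend = cochran_armitage_trend(table3)
    qrows = []
    for q, por in zip((2, 3, 4), fx.quartile_printed_ors):
        rec = float(quart.loc[quart["quartile"] == f"Q{q}", "or"].iloc[0])
        qrows.append(
            {"quartile": f"Q{q}", "or_recomputed": round(rec, 2), "or_printed": por,
             "or_abs_diff": abs(rec - por), "flag": abs(rec - por) > 0.01}
        )
    quart_cmp = pd.DataFrame(qrows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        assoc_cmp.to_csv(out / "fixture_association_check.tsv", sep="\t", index=False)
        quart_cmp.to_csv(out / "fixture_quartile_check.tsv", sep="\t", index=False)

    return {
        "association": assoc_cmp,
        "quartiles": quart_cmp,
        "trend_z": trend[0],
        "trend_p": trend[1],
        "n_flagged": int(assoc_cmp["flag"].sum() + quart_cmp["flag"].sum()),
    }


def _partition_from_counts(fx) -> "QuartilePartition":
    from .grs import QuartilePartition

    return QuartilePartition(
        cutpoints=fx.quartile_cutpoints,
        labels=np.array([]),
        case_counts=fx.quartile_case_counts,
        control_counts=fx.quartile_control_counts,
    )


__all__ = [
    "PipelineConfig",
    "load_config",
    "RunReport",
    "run_pipeline",
    "run_fixture_mode",
]
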