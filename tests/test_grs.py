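"""Weighted genetic risk score, quartile ORs and the trend test."""

import numpy as np
import pytest

from fsspipe import (
    CohortSpec,
    GenotypeMatrix,
    QuartilePartition,
    RiskWeightTable,
    SnpMeta,
    assign_quartiles,
    cochran_armitage_trend,
    generate_cohort,
    qc_summary_table,
    quartile_association,
    weighted_grs,
)
from fsspipe.errors import ComputationError
from fsspipe.genotypes import CASE, CONTROL
from fsspipe.grs import RAW, RESCALED
from fsspipe.synthetic import SnpSimSpec


def matrix_with_dosages(dosage, phenos, risk_is_minor=True):
    """Small matrix whose SNP risk alleles equal the minor ('C') allele."""
    dosage = np.asarray(dosage, float)
    n, k = dosage.shape
    snps = [
        SnpMeta(rsid=f"rs{j}", chromosome="1", position=j + 1, minor_allele="C",
                major_allele="A", risk_allele="C" if risk_is_minor else "A")
        for j in range(k)
    ]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        phenotype=np.array(phenos, dtype=object),
        snps=snps,
        dosage=dosage,
    )


def fixture_weights(fx):
    return RiskWeightTable.from_odds_ratios(
        [(r.snp.rsid, r.snp.risk_allele, r.printed_or) for r in fx.rows]
    )


class TestWeightedGrs:
    def test_zero_dosages_give_zero_under_both_conventions(self):
        m = matrix_with_dosages(np.zeros((4, 3)), [CASE, CASE, CONTROL, CONTROL])
        w = RiskWeightTable.from_odds_ratios(
            [(f"rs{j}", "C", 1.4) for j in range(3)]
        )
        for conv in (RAW, RESCALED):
            assert weighted_grs(m, w, convention=conv).scores.tolist() == [0.0] * 4

    def test_single_risk_allele_everywhere_sums_the_log_ors(self, fx):
        # one risk allele at each of the 13 published SNPs
        k = 13
        m = matrix_with_dosages(np.ones((2, k)), [CASE, CONTROL])
        w = RiskWeightTable.from_odds_ratios(
            [(f"rs{j}", "C", r.printed_or) for j, r in enumerate(fx.rows)]
        )
        vec = weighted_grs(m, w)
        expected_raw = sum(np.log(r.printed_or) for r in fx.rows)
        assert expected_raw == pytest.approx(4.24, abs=0.01)
        assert vec.raw[0] == pytest.approx(expected_raw)
        # rescaled score is exactly K when every dosage is 1
        assert vec.rescaled[0] == pytest.approx(13.0)

    def test_weight_scale_equivariance(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(20, 5)).astype(float)
        m = matrix_with_dosages(dos, [CASE] * 10 + [CONTROL] * 10)
        w1 = RiskWeightTable.from_odds_ratios([(f"rs{j}", "C", 1.3) for j in range(5)])
        w2 = RiskWeightTable.from_odds_ratios([(f"rs{j}", "C", 1.3**2) for j in range(5)])
        v1, v2 = weighted_grs(m, w1), weighted_grs(m, w2)
        np.testing.assert_allclose(v2.raw, 2 * v1.raw, atol=1e-12)
        np.testing.assert_allclose(v2.rescaled, v1.rescaled, atol=1e-12)

    def test_major_risk_allele_counts_complementary_dosage(self):
        m = matrix_with_dosages([[0.0], [2.0]], [CASE, CONTROL], risk_is_minor=False)
        w = RiskWeightTable.from_odds_ratios([("rs0", "A", np.e)])  # weight 1
        vec = weighted_grs(m, w, convention=RAW)
        assert vec.raw.tolist() == [2.0, 0.0]

    def test_missing_imputed_with_control_expectation(self):
        dos = np.array([[np.nan], [2.0], [0.0], [1.0]])
        m = matrix_with_dosages(dos, [CASE, CONTROL, CONTROL, CONTROL])
        w = RiskWeightTable.from_odds_ratios([("rs0", "C", np.e)])
        vec = weighted_grs(m, w, convention=RAW)
        assert vec.raw[0] == pytest.approx(1.0)  # control mean dosage
        assert vec.n_missing[0] == 1

    def test_complete_case_policy_yields_nan(self):
        dos = np.array([[np.nan], [2.0]])
        m = matrix_with_dosages(dos, [CASE, CONTROL])
        w = RiskWeightTable.from_odds_ratios([("rs0", "C", np.e)])
        vec = weighted_grs(m, w, convention=RAW, missing_policy="complete")
        assert np.isnan(vec.raw[0]) and vec.raw[1] == pytest.approx(2.0)

    def test_unreliable_flag_above_half_missing(self):
        dos = np.array([[np.nan, np.nan, 1.0], [1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        m = matrix_with_dosages(dos, [CASE, CONTROL, CONTROL])
        w = RiskWeightTable.from_odds_ratios([(f"rs{j}", "C", 1.5) for j in range(3)])
        vec = weighted_grs(m, w)
        assert vec.unreliable.tolist() == [True, False, False]


class TestQuartiles:
    def test_score_on_cutpoint_falls_in_lower_quartile(self, fx):
        scores = np.array([5.0, 13.50, 14.0, 16.0])
        part = assign_quartiles(scores, np.array([True, False, True, False]),
                                cutpoints=fx.quartile_cutpoints)
        assert part.labels.tolist() == [1, 2, 3, 4]  # 13.50 -> Q2 (right-closed)

    def test_empirical_quartiles_balance_distinct_scores(self):
        scores = np.arange(8.0)
        part = assign_quartiles(scores, np.array([True] * 4 + [False] * 4))
        counts = np.asarray(part.case_counts) + np.asarray(part.control_counts)
        assert counts.tolist() == [2, 2, 2, 2]

    def test_partition_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        is_case = rng.random(40) < 0.5
        part = assign_quartiles(scores, is_case)
        perm = rng.permutation(40)
        part_p = assign_quartiles(scores[perm], is_case[perm])
        assert part.case_counts == part_p.case_counts
        assert part.cutpoints == part_p.cutpoints

    def test_constant_scores_rejected(self):
        with pytest.raises(ComputationError, match="degenerate"):
            assign_quartiles(np.ones(10), np.array([True] * 5 + [False] * 5))


class TestQuartileAssociation:
    def partition(self, fx):
        return QuartilePartition(
            cutpoints=fx.quartile_cutpoints,
            labels=np.array([]),
            case_counts=fx.quartile_case_counts,
            control_counts=fx.quartile_control_counts,
        )

    def test_published_quartile_odds_ratios(self, fx):
        table = quartile_association(self.partition(fx))
        ors = [round(v, 2) for v in table["or"].iloc[1:]]
        assert ors == [2.02, 2.61, 6.94]

    def test_published_quartile_confidence_intervals(self, fx):
        table = quartile_association(self.partition(fx))
        for q, (lo, hi) in zip((1, 2, 3), fx.quartile_printed_cis):
            assert round(table["ci_low"].iloc[q], 2) == pytest.approx(lo, abs=0.011)
            assert round(table["ci_high"].iloc[q], 2) == pytest.approx(hi, abs=0.011)

    def test_logistic_equals_closed_form_cross_product(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ca = rng.integers(5, 400, size=4)
            co = rng.integers(5, 400, size=4)
            part = QuartilePartition(cutpoints=(1, 2, 3), labels=np.array([]),
                                     case_counts=tuple(ca), control_counts=tuple(co))
            table = quartile_association(part)
            for q in (1, 2, 3):
                closed = (ca[q] * co[0]) / (co[q] * ca[0])
                assert table["or"].iloc[q] == pytest.approx(closed, abs=1e-9)

    def test_uniform_case_fraction_gives_unit_ors(self):
        part = QuartilePartition(cutpoints=(1, 2, 3), labels=np.array([]),
                                 case_counts=(50, 100, 150, 200),
                                 control_counts=(100, 200, 300, 400))
        table = quartile_association(part)
        np.testing.assert_allclose(table["or"].iloc[1:], 1.0, atol=1e-9)

    def test_empty_cell_flagged_and_omitted(self):
        part = QuartilePartition(cutpoints=(1, 2, 3), labels=np.array([]),
                                 case_counts=(50, 0, 60, 70),
                                 control_counts=(100, 80, 90, 100))
        table = quartile_association(part)
        assert table.loc[table["quartile"] == "Q2", "degenerate"].item()
        assert np.isnan(table.loc[table["quartile"] == "Q2", "or"].item())
        assert np.isfinite(table.loc[table["quartile"] == "Q4", "or"].item())


class TestTrend:
    def test_published_table_trend_significant(self, fx):
        table = np.array([fx.quartile_case_counts, fx.quartile_control_counts])
        z, p = cochran_armitage_trend(table)
        assert p < 0.001
        assert z > 0  # risk increases with quartile

    def test_identical_distributions_give_null(self):
        table = np.array([[10, 20, 30, 40], [10, 20, 30, 40]], float)
        z, p = cochran_armitage_trend(table)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_antisymmetric_under_category_reversal(self):
        table = np.array([[10, 25, 30, 55], [50, 30, 25, 15]], float)
        z_f, p_f = cochran_armitage_trend(table)
        z_r, p_r = cochran_armitage_trend(table[:, ::-1])
        assert z_r == pytest.approx(-z_f)
        assert p_r == pytest.approx(p_f)

    def test_matches_permutation_oracle_on_small_table(self):
        """Asymptotic p agrees with the conditional permutation null."""
        table = np.array([[10, 15, 20, 25], [20, 18, 15, 10]], float)
        z_obs, p_asym = cochran_armitage_trend(table)
        rng = np.random.default_rng(123)
        col_totals = table.sum(axis=0).astype(int)
        n_cases = int(table[0].sum())
        n_perm = 100_000
        # permutation null conditions on both margins: distribute the cases
        # over categories by multivariate hypergeometric sampling
        draws = rng.multivariate_hypergeometric(col_totals, n_cases, size=n_perm)
        # vectorized trend statistic over the permuted tables
        s = np.arange(1, 5, dtype=float)
        N = col_totals.astype(float)
        T = N.sum()
        R = float(n_cases)
        num = draws @ s - R * (N @ s) / T
        var = R * (T - R) / T * ((N @ (s * s)) - (N @ s) ** 2 / T) / T
        zs = num / np.sqrt(var)
        p_perm = (np.abs(zs) >= abs(z_obs) - 1e-12).mean()
        assert abs(p_asym - p_perm) < 0.02

    def test_all_zero_table_rejected(self):
        with pytest.raises(ComputationError):
            cochran_armitage_trend(np.zeros((2, 4)))


class TestEndToEndMonotonicity:
    def test_quartile_ors_monotone_on_study_scale_cohorts(self, fx):
        """Cohorts drawn at the published ORs and frequencies yield
        monotone quartile ORs in >= 95% of seeded replicates."""
        qc = {r.rsid: r for r in qc_summary_table().itertuples()}
        specs = []
        for j, r in enumerate(fx.rows):
            maf = qc[r.snp.rsid].maf_controls_pct / 100.0
            risk_freq = maf if r.snp.risk_is_minor else 1.0 - maf
            specs.append(SnpSimSpec(rsid=r.snp.rsid, control_freq=risk_freq,
                                    or_=r.printed_or, position=j + 1))
        weights = RiskWeightTable.from_odds_ratios(
            [(r.snp.rsid, "A", r.printed_or) for r in fx.rows]
        )
        n_monotone = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = CohortSpec(n_cases=978, n_controls=1129, snp_specs=tuple(specs),
                              seed=50_000 + rep)
            m = generate_cohort(spec)
            vec = weighted_grs(m, weights)
            part = assign_quartiles(vec, m.is_case)
            table = quartile_association(part)
            ors = table["or"].to_numpy()
            n_monotone += bool(np.all(np.diff(ors) > 0))
        assert n_monotone / n_rep >= 0.95
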