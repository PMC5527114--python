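"""Two-locus EM, D'/r2, bootstrap CIs, blocks and pruning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsspipe import (
    HaplotypeFrequencies,
    SnpMeta,
    bootstrap_dprime_ci,
    build_blocks,
    em_haplotype_freqs,
    generate_ld_pair,
    ld_statistics,
    pair_ld,
    prune_by_dprime,
)
from fsspipe.errors import ComputationError
from fsspipe.ld import BlockRuleParams, _table_loglik, genotype_cross_table


def grid_search_loglik(table, resolution=1e-4):
    """Brute-force maximizer of the observed-data likelihood.

    At the MLE the haplotype marginals equal the observed allele
    frequencies, leaving one free parameter p11 on a closed interval.
    """
    table = np.asarray(table, float)
    n = table.sum()
    qa = (table.sum(axis=1) @ np.arange(3)) / (2 * n)
    qb = (table.sum(axis=0) @ np.arange(3)) / (2 * n)
    p1, p2 = 1 - qa, 1 - qb
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    best = -np.inf
    best_p11 = lo
    for p11 in np.arange(lo, hi + resolution, resolution):
        p11 = min(p11, hi)
        freqs = np.array([[p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11]])
        if (freqs < -1e-12).any():
            continue
        ll = _table_loglik(np.asarray([table]), np.clip(freqs, 0, 1))[0]
        if ll > best:
            best, best_p11 = ll, p11
    return best, best_p11


class TestEm:
    def test_equals_direct_counting_without_double_heterozygotes(self):
        # phase is unambiguous for every individual here
        dos_a = np.array([0, 0, 1, 2, 2, 1, 0], float)
        dos_b = np.array([0, 1, 0, 2, 1, 2, 0], float)
        est = em_haplotype_freqs((dos_a, dos_b))
        # direct haplotype tally: each individual contributes 2 haplotypes
        n11 = n12 = n21 = n22 = 0
        for ga, gb in zip(dos_a, dos_b):
            a_hap = [0] * int(2 - ga) + [1] * int(ga)  # 1 = minor
            b_hap = [0] * int(2 - gb) + [1] * int(gb)
            if ga == 1 and gb == 1:
                raise AssertionError("construction must avoid double hets")
            for x, y in zip(sorted(a_hap), sorted(b_hap)):
                n11 += (x, y) == (0, 0)
                n12 += (x, y) == (0, 1)
                n21 += (x, y) == (1, 0)
                n22 += (x, y) == (1, 1)
        direct = np.array([n11, n12, n21, n22]) / (2 * len(dos_a))
        np.testing.assert_allclose(est.as_array(), direct, atol=1e-9)

    def test_all_double_heterozygotes_reach_global_boundary_optimum(self):
        table = np.zeros((3, 3))
        table[1, 1] = 100
        est = em_haplotype_freqs(table)
        ll_em = _table_loglik(np.asarray([table]), est.as_array()[None])[0]
        ll_grid, _ = grid_search_loglik(table)
        assert ll_em >= ll_grid - 1e-6
        # the optimum sits on the coupling/repulsion boundary set
        f = est.as_array()
        assert (f[0] + f[3] == pytest.approx(1.0, abs=1e-6)) or (
            f[1] + f[2] == pytest.approx(1.0, abs=1e-6)
        )

    def test_em_matches_grid_search_on_random_small_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            f = rng.dirichlet(np.ones(4))
            if min(f[0] + f[1], f[0] + f[2]) < 0.05 or max(f[0] + f[1], f[0] + f[2]) > 0.95:
                continue
            m = generate_ld_pair(tuple(f), n=30, seed=int(rng.integers(2**31)))
            table = genotype_cross_table(m.dosage[:, 0], m.dosage[:, 1])
            try:
                est = em_haplotype_freqs(table)
            except ComputationError:
                continue  # monomorphic draw at n=30
            ll_em = _table_loglik(np.asarray([table]), est.as_array()[None])[0]
            ll_grid, _ = grid_search_loglik(table)
            assert ll_em >= ll_grid - 1e-6

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(11)
        m = generate_ld_pair((0.35, 0.15, 0.25, 0.25), n=200, seed=3)
        table = genotype_cross_table(m.dosage[:, 0], m.dosage[:, 1])
        n = table.sum()
        qa = (table.sum(axis=1) @ np.arange(3)) / (2 * n)
        qb = (table.sum(axis=0) @ np.arange(3)) / (2 * n)
        f = np.array([(1 - qa) * (1 - qb), (1 - qa) * qb, qa * (1 - qb), qa * qb])
        dh = table[1, 1]
        base = np.array([
            2 * table[0, 0] + table[0, 1] + table[1, 0],
            2 * table[0, 2] + table[0, 1] + table[1, 2],
            2 * table[2, 0] + table[1, 0] + table[2, 1],
            2 * table[2, 2] + table[2, 1] + table[1, 2],
        ])
        ll_prev = _table_loglik(np.asarray([table]), f[None])[0]
        for _ in range(200):
            w = f[0] * f[3] / (f[0] * f[3] + f[1] * f[2])
            f = (base + dh * np.array([w, 1 - w, 1 - w, w])) / (2 * n)
            ll = _table_loglik(np.asarray([table]), f[None])[0]
            assert ll >= ll_prev - 1e-9
            ll_prev = ll
        np.testing.assert_allclose(f, em_haplotype_freqs(table).as_array(), atol=1e-6)

    def test_monomorphic_locus_rejected(self):
        dos_a = np.zeros(50)
        dos_b = np.array([0, 1, 2] * 16 + [0, 1])
        with pytest.raises(ComputationError, match="monomorphic"):
            em_haplotype_freqs((dos_a, dos_b))


class TestLdStatistics:
    def test_closed_form_worked_example(self):
        st_ = ld_statistics(HaplotypeFrequencies(0.4, 0.1, 0.2, 0.3))
        assert st_.D == pytest.approx(0.1)
        assert st_.d_prime == pytest.approx(0.5)
        assert st_.r2 == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_perfect_coupling(self):
        st_ = ld_statistics(HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5))
        assert st_.d_prime == pytest.approx(1.0)
        assert st_.r2 == pytest.approx(1.0)

    def test_linkage_equilibrium(self):
        p1, p2 = 0.6, 0.3
        st_ = ld_statistics(HaplotypeFrequencies(
            p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)))
        assert st_.D == pytest.approx(0.0, abs=1e-12)
        assert st_.d_prime == 0.0 and st_.r2 == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabeling_flips_d_sign_only(self):
        a = ld_statistics(HaplotypeFrequencies(0.4, 0.1, 0.2, 0.3))
        b = ld_statistics(HaplotypeFrequencies(0.1, 0.4, 0.3, 0.2))  # relabel locus B
        assert b.D == pytest.approx(-a.D)
        assert b.d_prime == pytest.approx(a.d_prime)
        assert b.r2 == pytest.approx(a.r2)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_r2_bounded_by_dprime(self, raw):
        f = np.asarray(raw) / np.sum(raw)
        marg = (f[0] + f[1], f[0] + f[2])
        if not all(0.001 < m < 0.999 for m in marg):
            return
        st_ = ld_statistics(HaplotypeFrequencies(*f))
        assert 0.0 <= st_.r2 <= st_.d_prime + 1e-9 <= 1.0 + 1e-9

    def test_marginal_zero_rejected(self):
        with pytest.raises(ComputationError):
            ld_statistics(HaplotypeFrequencies(0.0, 0.0, 0.5, 0.5))


class TestBootstrapCi:
    def test_perfect_ld_gives_degenerate_interval(self):
        m = generate_ld_pair((0.6, 0.0, 0.0, 0.4), n=300, seed=2)
        ci = bootstrap_dprime_ci(m, n_boot=200, seed=1)
        assert ci.low == pytest.approx(1.0) and ci.high == pytest.approx(1.0)

    def test_interval_width_shrinks_with_sample_size(self):
        freqs = (0.4, 0.1, 0.2, 0.3)
        small = generate_ld_pair(freqs, n=250, seed=6)
        large = generate_ld_pair(freqs, n=4000, seed=6)
        ci_s = bootstrap_dprime_ci(small, n_boot=300, seed=9)
        ci_l = bootstrap_dprime_ci(large, n_boot=300, seed=9)
        assert ci_l.high - ci_l.low < ci_s.high - ci_s.low

    def test_coverage_of_true_dprime(self):
        """95% percentile interval covers the true D' at close to 95%."""
        true = ld_statistics(HaplotypeFrequencies(0.4, 0.1, 0.2, 0.3)).d_prime
        covered = 0
        n_sim = 500
        for k in range(n_sim):
            m = generate_ld_pair((0.4, 0.1, 0.2, 0.3), n=400, seed=10_000 + k)
            ci = bootstrap_dprime_ci(m, n_boot=200, seed=k)
            covered += ci.low <= true <= ci.high
        assert 0.92 <= covered / n_sim <= 0.98


def _meta(rsid, chrom, pos):
    return SnpMeta(rsid=rsid, chromosome=chrom, position=pos,
                   minor_allele="A", major_allele="G")


class TestBlocks:
    def test_perfect_ld_triplet_forms_single_block(self):
        snps = [_meta(f"rs{i}", "1", 100 * (i + 1)) for i in range(5)]
        cis = {}
        core = {1, 2, 3}
        for i, j in itertools.combinations(range(5), 2):
            if i in core and j in core:
                cis[(i, j)] = (1.0, 1.0)  # strong
            else:
                cis[(i, j)] = (0.0, 0.2)  # strong recombination
        part = build_blocks(snps, cis)
        assert len(part.blocks) == 1
        assert part.blocks[0].rsids == ("rs1", "rs2", "rs3")

    def test_independent_panel_has_no_blocks(self):
        snps = [_meta(f"rs{i}", "1", 100 * (i + 1)) for i in range(4)]
        cis = {(i, j): (0.0, 0.3) for i, j in itertools.combinations(range(4), 2)}
        assert build_blocks(snps, cis).blocks == ()

    def test_blocks_never_interleave_or_span_chromosomes(self):
        snps = [_meta(f"rs{i}", "1", 100 * (i + 1)) for i in range(4)] + [
            _meta(f"rs{i}", "2", 100 * (i + 1)) for i in range(4, 8)
        ]
        cis = {
            (i, j): (1.0, 1.0)
            for i, j in itertools.combinations(range(8), 2)
            if snps[i].chromosome == snps[j].chromosome
        }
        part = build_blocks(snps, cis)
        spans = []
        for b in part.blocks:
            assert len({snps[i].chromosome for i in range(b.start_index, b.end_index + 1)}) == 1
            spans.append((b.start_index, b.end_index))
        for (s1, e1), (s2, e2) in itertools.combinations(spans, 2):
            assert e1 < s2 or e2 < s1


class TestPruning:
    @staticmethod
    def clustered_dprime(n_clusters=13, sizes=None):
        sizes = sizes or [4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2]  # 34 SNPs
        assert len(sizes) == n_clusters
        K = sum(sizes)
        rng = np.random.default_rng(0)
        d = rng.uniform(0.0, 0.2, size=(K, K))
        d = (d + d.T) / 2
        labels = np.repeat(np.arange(n_clusters), sizes)
        for i in range(K):
            for j in range(K):
                if i != j and labels[i] == labels[j]:
                    d[i, j] = 0.97
        np.fill_diagonal(d, 1.0)
        return d, labels

    def test_13_clusters_prune_to_13_representatives(self):
        d, labels = self.clustered_dprime()
        kept = prune_by_dprime(d, threshold=0.8)
        assert len(kept) == 13
        assert sorted(labels[kept]) == list(range(13))

    def test_priority_orders_the_representative(self):
        d, labels = self.clustered_dprime()
        # prefer the last SNP of each cluster by visiting indices backwards
        kept = prune_by_dprime(d, threshold=0.8, priority=list(range(33, -1, -1)))
        for cluster in range(13):
            members = np.where(labels == cluster)[0]
            assert members.max() in kept

    def test_independent_panel_fully_retained(self):
        d = np.zeros((6, 6))
        assert prune_by_dprime(d, threshold=0.8) == list(range(6))

    def test_threshold_one_retains_all_without_perfect_ld(self):
        d, _ = self.clustered_dprime()
        d[d == 0.97] = 0.99
        np.fill_diagonal(d, 1.0)
        assert len(prune_by_dprime(d, threshold=1.0)) == 34


class TestPairLd:
    def test_em_statistics_from_sampled_pair(self):
        m = generate_ld_pair((0.4, 0.1, 0.2, 0.3), n=50_000, seed=21)
        st_ = pair_ld(m)
        assert st_.d_prime == pytest.approx(0.5, abs=0.03)
        assert st_.r2 == pytest.approx(1 / 6, abs=0.03)
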