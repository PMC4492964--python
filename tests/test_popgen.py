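import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop.genotype import GenotypeMatrix, LocusDef, SampleRecord
from msatpop.popgen import (
    allele_freqs,
    expected_het,
    f_is,
    fdr_adjust,
    hwe_test,
    ld_test,
    observed_het,
    shared_allele_count,
    summarize_locus,
)

from conftest import build_matrix, random_matrix


def single_locus_matrix(genotypes, locus="L1"):
    rows = {f"s{i}": [g] for i, g in enumerate(genotypes)}
    return build_matrix(rows, locus_ids=[locus])


class TestAlleleFreqs:
    def test_simple_tally(self):
        m = single_locus_matrix([(100, 100), (100, 104)])
        assert allele_freqs(m, "L1") == {100: 0.75, 104: 0.25}

    def test_monomorphic(self):
        m = single_locus_matrix([(100, 100)] * 4)
        assert allele_freqs(m, "L1") == {100: 1.0}

    def test_all_missing_errors(self):
        m = single_locus_matrix([(0, 0), (0, 0)])
        with pytest.raises(ValueError):
            allele_freqs(m, "L1")

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_counting_oracle(self, seed):
        m = random_matrix(seed, n_samples=10, n_loci=1, p_missing=0.2)
        try:
            freqs = allele_freqs(m, "L1")
        except ValueError:
            return
        tally = {}
        for s in m.samples:
            g = s.genotypes["L1"]
            if g[0] == 0:
                continue
            for a in g:
                tally[a] = tally.get(a, 0) + 1
        total = sum(tally.values())
        assert freqs == {a: c / total for a, c in sorted(tally.items())}
        assert math.isclose(sum(freqs.values()), 1.0)


class TestHeterozygosityAndFis:
    @pytest.mark.parametrize(
        "h_e,h_o,expected",
        [
            (0.905, 0.700, 0.227),
            (0.785, 0.800, -0.019),
            (0.815, 0.300, 0.632),
            (0.875, 0.500, 0.429),
            (0.890, 1.000, -0.124),
            (0.820, 0.800, 0.024),
        ],
    )
    def test_deviation_index_printed_rows(self, h_e, h_o, expected):
        assert round(f_is(h_e, h_o), 3) == expected

    def test_fis_zero_when_equal(self):
        assert f_is(0.5, 0.5) == 0.0

    def test_fis_undefined_at_he_zero(self):
        with pytest.raises(ValueError):
            f_is(0.0, 0.0)

    def test_summarize_monomorphic_fis_none(self):
        m = single_locus_matrix([(100, 100)] * 6)
        st_ = summarize_locus(m, "L1")
        assert st_.f_is is None and st_.n_a == 1 and st_.h_e == 0.0

    def test_he_invariant_under_relabeling(self):
        assert expected_het({1: 0.3, 2: 0.7}) == expected_het({9: 0.7, 4: 0.3})

    def test_he_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for k in range(2, 7):
            uniform = expected_het(np.full(k, 1.0 / k))
            for _ in range(200):
                p = rng.dirichlet(np.ones(k))
                assert expected_het(p) <= uniform + 1e-12

    def test_summary_consistency(self):
        m = single_locus_matrix([(100, 104), (100, 104), (100, 100), (104, 104)])
        st_ = summarize_locus(m, "L1")
        assert st_.h_e == pytest.approx(0.5)
        assert st_.h_o == pytest.approx(0.5)
        assert st_.f_is == pytest.approx(0.0)

    def test_fis_recovers_planted_inbreeding(self):
        # genotypes drawn with P(autozygous) = 0.3
        rng = np.random.default_rng(42)
        f_in, n, n_loci, k = 0.3, 100, 25, 8
        rows = {f"s{i}": [] for i in range(n)}
        for _ in range(n_loci):
            p = rng.dirichlet(np.ones(k))
            sizes = 100 + 3 * np.arange(k)
            for i in range(n):
                a = rng.choice(sizes, p=p)
                b = a if rng.random() < f_in else rng.choice(sizes, p=p)
                rows[f"s{i}"].append((int(min(a, b)), int(max(a, b))))
        m = build_matrix(rows)
        vals = [summarize_locus(m, lid).f_is for lid in m.locus_ids]
        assert abs(np.mean(vals) - f_in) < 0.05


class TestHWE:
    def test_perfect_proportions_p_one(self):
        m = single_locus_matrix(
            [(100, 100)] * 4 + [(100, 104)] * 8 + [(104, 104)] * 4
        )
        res = hwe_test(m, "L1")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_all_homozygote_rejected(self):
        m = single_locus_matrix([(100, 100)] * 10 + [(104, 104)] * 10)
        res = hwe_test(m, "L1")
        # brute-force chi-square: E = (5, 10, 5) vs O = (10, 0, 10)
        expect = (10 - 5) ** 2 / 5 + (0 - 10) ** 2 / 10 + (10 - 5) ** 2 / 5
        assert res.statistic == pytest.approx(expect)
        assert res.p_value < 0.05

    def test_monomorphic_rejected(self):
        m = single_locus_matrix([(100, 100)] * 10)
        with pytest.raises(ValueError):
            hwe_test(m, "L1")

    def test_low_expected_flagged(self):
        m = single_locus_matrix(
            [(100, 104)] * 5 + [(100, 100)] * 2 + [(108, 108)] * 2
        )
        assert hwe_test(m, "L1").low_expected


class TestLD:
    def test_exact_copy_floor_p(self):
        rng = np.random.default_rng(1)
        genos = [
            tuple(sorted(rng.choice([100, 103, 106], size=2))) for _ in range(30)
        ]
        rows = {f"s{i}": [g, g] for i, g in enumerate(genos)}
        m = build_matrix(rows)
        res = ld_test(m, "L1", "L2", n_perm=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_g_statistic_hand_computed_2x2(self):
        # 10 samples: genotype categories perfectly associated, table [[5,0],[0,5]]
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = [(100, 100), (200, 200)]
            rows[f"b{i}"] = [(103, 103), (203, 203)]
        m = build_matrix(rows)
        res = ld_test(m, "L1", "L2", n_perm=50, seed=0)
        # G = 2 * sum O ln(O/E) with E = 2.5 on the diagonal cells
        expect = 2 * (5 * math.log(5 / 2.5) + 5 * math.log(5 / 2.5))
        assert res.g_statistic == pytest.approx(expect)

    def test_insufficient_overlap_errors(self):
        rows = {
            "s1": [(100, 100), (0, 0)],
            "s2": [(100, 103), (0, 0)],
            "s3": [(0, 0), (200, 200)],
            "s4": [(100, 100), (200, 203)],
            "s5": [(103, 103), (200, 200)],
        }
        m = build_matrix(rows)
        with pytest.raises(ValueError, match="typed lineages"):
            ld_test(m, "L1", "L2")


class TestFDR:
    def test_all_ones_no_flags(self):
        assert not fdr_adjust([1.0, 1.0, 1.0]).any()

    def test_step_up_oracle(self):
        # m=4, q=0.05: thresholds .0125 .025 .0375 .05 -> first three pass
        flags = fdr_adjust([0.001, 0.02, 0.03, 0.9], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_single_p_raw_threshold(self):
        assert fdr_adjust([0.04]).tolist() == [True]
        assert fdr_adjust([0.06]).tolist() == [False]

    def test_empty(self):
        assert fdr_adjust([]).size == 0

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(8)
        flags = fdr_adjust(p)
        i = int(rng.integers(8))
        p2 = p.copy()
        p2[i] = p2[i] * rng.random()  # lower one p-value
        flags2 = fdr_adjust(p2)
        others = np.arange(8) != i
        assert np.all(flags2[others] >= flags[others])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestSharedAlleles:
    def _matrix(self, genos_a, genos_b):
        rows = {}
        mito = {}
        for i, g in enumerate(genos_a):
            rows[f"a{i}"] = g
            mito[f"a{i}"] = "mt-L"
        for i, g in enumerate(genos_b):
            rows[f"b{i}"] = g
            mito[f"b{i}"] = "mt-S"
        return build_matrix(rows, mito_types=mito)

    def test_disjoint(self):
        m = self._matrix([[(100, 103)]], [[(106, 109)]])
        assert shared_allele_count(m, "mt-L", "mt-S") == (0, 4)

    def test_identical_sets(self):
        m = self._matrix(
            [[(100, 103)], [(106, 109)]], [[(100, 109)], [(103, 106)]]
        )
        assert shared_allele_count(m, "mt-L", "mt-S") == (4, 4)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_set_oracle(self, seed):
        m = random_matrix(seed, n_samples=8, n_loci=3, p_missing=0.15)
        try:
            got = shared_allele_count(m, "mt-L", "mt-S")
        except ValueError:
            return
        shared = total = 0
        for lid in m.locus_ids:
            sa, sb = set(), set()
            for s in m.samples:
                g = s.genotypes[lid]
                if g[0] == 0:
                    continue
                (sa if s.mito_type == "mt-L" else sb).update(g)
            shared += len(sa & sb)
            total += len(sa | sb)
        assert got == (shared, total)
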