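"""Exact HWE testing, FDR, the deficit scan and its clustering."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lethscan as ls
from lethscan.errors import DegenerateVariantError
from lethscan.hwe import (
    GenotypeCounts,
    ScanConfig,
    _het_distribution,
    summarize_genotype_counts,
)
from lethscan.io import GenotypeMatrix, VariantDef
from lethscan.sim import LethalSimConfig, simulate_lethal_population


def exact_hwe_oracle(n_AA: int, n_AB: int, n_BB: int, mode: str = "two_sided") -> Fraction:
    """Independent exact-rational enumeration of the conditional HWE test."""
    n = n_AA + n_AB + n_BB
    n_minor = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    if n_minor == 0 or n_minor == 2 * n:
        return Fraction(1)
    weights = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        na = (n_minor - h) // 2
        nb = n - h - na
        weights[h] = (
            2**h
            * math.factorial(n)
            // (math.factorial(na) * math.factorial(h) * math.factorial(nb))
        )
    w_obs = weights[n_AB]
    total = sum(weights.values())
    if mode == "deficit":
        return Fraction(sum(w for h, w in weights.items() if h >= n_AB), total)
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)


class TestGenotypeCounts:
    def test_direct_count(self, tiny_matrix):
        c = ls.genotype_counts(tiny_matrix, 0)
        assert (c.n_AA, c.n_AB, c.n_BB, c.n_missing) == (1, 2, 1, 0)

    def test_missing_reported(self, tiny_matrix):
        c = ls.genotype_counts(tiny_matrix, 2)
        assert c.n_missing == 1 and c.n == 3

    def test_subset(self, tiny_matrix):
        c = ls.genotype_counts(tiny_matrix, 0, subset={"s1", "s2"})
        assert (c.n_AA, c.n_AB, c.n_BB) == (1, 1, 0)

    def test_all_missing_is_degenerate(self):
        m = GenotypeMatrix(
            variants=[VariantDef("1", 1, "v", "A", "G")],
            samples=["s1", "s2"],
            calls=np.array([[-1], [-1]], dtype=np.int8),
        )
        with pytest.raises(DegenerateVariantError):
            ls.genotype_counts(m, 0)


class TestExpectedMinorHomozygotes:
    # published genotype counts (minor hom, het, major hom) -> rounded E
    @pytest.mark.parametrize(
        "minor_hom,het,major_hom,expected",
        [
            (0, 66, 90, 7),  # Australian Thoroughbreds, n=156
            (22, 226, 393, 28),  # Coldblooded Trotter second SNP
            (0, 97, 40, 17),  # Quarter Horse, n=137
        ],
    )
    def test_published_counts(self, minor_hom, het, major_hom, expected):
        c = GenotypeCounts(n_AA=major_hom, n_AB=het, n_BB=minor_hom)
        real, rounded = ls.expected_minor_homozygotes(c)
        assert rounded == expected
        assert real == pytest.approx(c.n * c.q**2)

    def test_monomorphic_is_zero(self):
        real, rounded = ls.expected_minor_homozygotes(GenotypeCounts(100, 0, 0))
        assert real == 0.0 and rounded == 0

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    @settings(derandomize=True, max_examples=200)
    def test_zero_iff_monomorphic(self, a, h, b):
        if a + h + b == 0:
            return
        c = GenotypeCounts(a, h, b)
        real, _ = ls.expected_minor_homozygotes(c)
        assert (real == 0.0) == (c.q == 0.0)


class TestHweExactTest:
    def test_monomorphic_convention(self):
        assert ls.hwe_exact_test(GenotypeCounts(0, 0, 100)) == 1.0

    def test_modal_table_gives_p_one(self):
        # h = 50 is the modal heterozygote count for 25/50/25, so every
        # table satisfies P <= P_obs and the two-sided p is 1
        assert ls.hwe_exact_test(GenotypeCounts(25, 50, 25)) == 1.0

    def test_published_significance(self):
        assert ls.hwe_exact_test(GenotypeCounts(90, 66, 0)) < 0.05

    def test_matches_oracle_on_small_tables(self):
        for n in range(1, 16):
            for a in range(n + 1):
                for h in range(n - a + 1):
                    b = n - a - h
                    for mode in ("two_sided", "deficit"):
                        p = ls.hwe_exact_test(GenotypeCounts(a, h, b), mode)
                        assert p == pytest.approx(
                            float(exact_hwe_oracle(a, h, b, mode)), abs=1e-12
                        )

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(derandomize=True, max_examples=300)
    def test_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        assert ls.hwe_exact_test(GenotypeCounts(a, h, b)) == pytest.approx(
            ls.hwe_exact_test(GenotypeCounts(b, h, a)), rel=1e-12
        )

    @given(st.integers(1, 50), st.integers(0, 100))
    @settings(derandomize=True, max_examples=300)
    def test_enumeration_sums_to_one(self, n, n_minor):
        n_minor = min(n_minor, n)  # keep the minor side minor
        if n_minor == 0:
            return
        _, probs = _het_distribution(n, n_minor)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deficit_tail_is_heterozygote_excess(self):
        # zero minor homozygotes with many hets: deficit tail p is the
        # probability of at least as many hets, small under HWE
        p_def = ls.hwe_exact_test(GenotypeCounts(90, 66, 0), "deficit")
        p_two = ls.hwe_exact_test(GenotypeCounts(90, 66, 0), "two_sided")
        assert 0 < p_def <= p_two


class TestFdrAdjust:
    def test_no_signal_identity(self):
        assert ls.fdr_adjust([1.0, 1.0, 1.0], "bh").tolist() == [1.0, 1.0, 1.0]

    def test_single_p_identity_bh(self):
        assert ls.fdr_adjust([0.03], "bh")[0] == pytest.approx(0.03)

    def test_bh_hand_computed(self):
        q = ls.fdr_adjust([0.01, 0.02, 0.04, 0.8], "bh")
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_bh_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = ls.fdr_adjust(p, "bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_le_bh_when_pi0_below_one(self):
        # spiked p-value mix: many tiny p-values drag pi0 below 1
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.random(400), rng.random(100) * 1e-4])
        q_bh = ls.fdr_adjust(p, "bh")
        q_st = ls.fdr_adjust(p, "storey")
        assert (q_st <= q_bh + 1e-12).all()
        assert (q_st < q_bh - 1e-9).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.fdr_adjust([0.5, 1.5])

    def test_order_preserved(self):
        p = [0.9, 0.001, 0.5]
        q = ls.fdr_adjust(p, "bh")
        assert np.argmin(q) == 1


def _matrix_from_columns(columns, chrom="1"):
    n = len(columns[0])
    variants = [
        VariantDef(chrom, (j + 1) * 1000, f"v{j}", "A", "G")
        for j in range(len(columns))
    ]
    calls = np.array(columns, dtype=np.int8).T
    return GenotypeMatrix(variants=variants, samples=[f"s{i}" for i in range(n)], calls=calls)


class TestScanDeficit:
    def test_neutral_hwe_raw_rate_conservative(self):
        cfg = LethalSimConfig(n_samples=500, q_pre=0.0, n_neutral=2000, seed=12)
        m, _ = simulate_lethal_population(cfg)
        res = ls.scan_deficit(m)
        tested = [r for r in res if r.tested]
        frac = np.mean([r.p_hwe < 0.05 for r in tested])
        assert frac <= 0.05  # the exact test is conservative

    def test_planted_pair_flagged(self):
        cfg = LethalSimConfig(n_samples=500, q_pre=0.21, n_neutral=1000, seed=5)
        m, truth = simulate_lethal_population(cfg)
        res = ls.scan_deficit(m)
        for idx in truth.lethal_variant_indices:
            assert res[idx].flagged and res[idx].zero_minor_hom

    def test_monomorphic_never_flagged(self):
        m = _matrix_from_columns([[0, 0, 0, 0]] * 3)
        res = ls.scan_deficit(m)
        assert all(not r.flagged and r.p_hwe == 1.0 for r in res)

    def test_every_variant_reported_once(self, tiny_matrix):
        res = ls.scan_deficit(tiny_matrix)
        assert [r.index for r in res] == [0, 1, 2]


class TestClusterAdjacent:
    def _results(self, flags, chroms=None):
        n = len(flags)
        chroms = chroms or ["1"] * n
        m = _matrix_from_columns([[0, 1, 1, 2]] * n)
        res = ls.scan_deficit(m)
        for r, f, c in zip(res, flags, chroms):
            r.flagged = f
            r.variant = VariantDef(c, r.variant.pos, r.variant.id, "A", "G")
        return res

    def test_pair_forms_block(self):
        res = self._results([False] * 5 + [True, True] + [False])
        blocks = ls.cluster_adjacent(res)
        assert len(blocks) == 1 and blocks[0].size == 2

    def test_singleton_discarded(self):
        res = self._results([False, True, False])
        assert ls.cluster_adjacent(res) == []

    def test_run_of_three_is_one_block(self):
        res = self._results([False] * 5 + [True, True, True])
        blocks = ls.cluster_adjacent(res)
        assert len(blocks) == 1 and blocks[0].size == 3

    def test_chromosome_break_splits_runs(self):
        res = self._results([True, True, True, True], chroms=["1", "1", "2", "2"])
        blocks = ls.cluster_adjacent(res)
        assert [b.chrom for b in blocks] == ["1", "2"]

    def test_min_block_size_respected(self):
        res = self._results([True, True, False])
        cfg = ScanConfig(min_block_size=3)
        assert ls.cluster_adjacent(res, cfg) == []


class TestPopulationSummary:
    def test_published_het_percentages(self):
        # Quarter Horse 71%; pooled Thoroughbreds 35%
        qh = summarize_genotype_counts(GenotypeCounts(40, 97, 0))
        assert qh["het_percent"] == 71 and qh["significant"]
        tb = summarize_genotype_counts(GenotypeCounts(90 + 253, 66 + 117, 0))
        assert tb["n"] == 526 and tb["het_percent"] == 35

    def test_groups_and_unassigned(self, tiny_matrix):
        labels = {"s1": "popA", "s2": "popA"}  # s3, s4 unlabelled
        table = ls.population_summary(tiny_matrix, [0], by=labels)
        assert set(table["population"]) == {"popA", "unassigned"}

    def test_all_missing_population_row(self):
        m = GenotypeMatrix(
            variants=[VariantDef("1", 1, "v", "A", "G")],
            samples=["s1", "s2"],
            calls=np.array([[0], [-1]], dtype=np.int8),
            population={"s1": "A", "s2": "B"},
        )
        table = ls.population_summary(m, [0])
        row_b = table[table["population"] == "B"].iloc[0]
        assert row_b["n"] == 0 and not row_b["significant"]


class TestZeroHomozygoteNullProb:
    def test_closed_form_values(self):
        assert ls.zero_homozygote_null_prob(10, 0.0) == 1.0
        assert ls.zero_homozygote_null_prob(1, 0.5) == 0.75
        assert ls.zero_homozygote_null_prob(156, 0.2115) == pytest.approx(
            (1 - 0.2115**2) ** 156
        )

    def test_monte_carlo_agreement(self):
        n, q = 156, 0.2115
        rng = np.random.default_rng(0)
        draws = rng.binomial(n, q * q, size=1_000_000)
        mc = (draws == 0).mean()
        p = ls.zero_homozygote_null_prob(n, q)
        se = math.sqrt(p * (1 - p) / 1_000_000)
        assert abs(mc - p) < 4 * se + 1e-6
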