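"""Filter-cascade stages: worked examples, oracle agreement, invariants."""

import pytest

from conftest import (
    V,
    matrix_of,
    oracle_hom_diallelic,
    oracle_prune,
    oracle_seg_ratio,
    single_snp_matrix,
)

from snp2mab.filters import (
    filter_distinguishable,
    filter_homozygous_diallelic,
    filter_segregation_ratio,
    prune_flanking,
    report_to_table,
    run_cascade,
)
from snp2mab.model import FilterParams, FilterStepResult, GenotypeMatrix
from snp2mab.simulate import SimulationConfig, simulate_genotype_matrix

SCALED_SIZES = tuple(round(x * 0.01, 6) for x in
                     (25.86, 41.50, 28.95, 46.08, 45.34, 53.29, 26.68, 29.11, 37.64))


def small_config(seed, n_snps=400, **kw):
    return SimulationConfig(
        seed=seed, chrom_sizes_mb=SCALED_SIZES, n_snps=n_snps, n_genes=10, **kw
    )


class TestHomozygousDiallelic:
    def test_two_hom_classes_retained(self):
        m = single_snp_matrix([("A", "A")] * 6 + [("G", "G")] * 4)
        out, step = filter_homozygous_diallelic(m)
        assert len(out) == 1 and step.n_removed == 0

    def test_one_het_call_removes_snp(self):
        m = single_snp_matrix([("A", "A")] * 5 + [("A", "G")] + [("G", "G")] * 4)
        out, step = filter_homozygous_diallelic(m)
        assert len(out) == 0 and step.n_removed == 1

    def test_monomorphic_removed(self):
        m = single_snp_matrix([("A", "A")] * 10)
        out, _ = filter_homozygous_diallelic(m)
        assert len(out) == 0

    def test_triallelic_removed(self):
        m = single_snp_matrix(
            [("A", "A")] * 4 + [("G", "G")] * 3 + [("T", "T")] * 3, alts=("G", "T")
        )
        out, _ = filter_homozygous_diallelic(m)
        assert len(out) == 0


class TestDistinguishable:
    def test_14_callable_of_33_removed_at_k15(self):
        calls = [("A", "A")] * 7 + [("G", "G")] * 7 + [None] * 19
        m = single_snp_matrix(calls)
        out, _ = filter_distinguishable(m, FilterParams())
        assert len(out) == 0

    def test_15_callable_boundary_retained(self):
        calls = [("A", "A")] * 8 + [("G", "G")] * 7 + [None] * 18
        m = single_snp_matrix(calls)
        out, _ = filter_distinguishable(m, FilterParams())
        assert len(out) == 1

    def test_minor_class_mode_20_13_retained_at_k13(self):
        calls = [("A", "A")] * 20 + [("G", "G")] * 13
        m = single_snp_matrix(calls)
        params = FilterParams(min_distinguishable=13, distinguish_mode="minor_class")
        out, _ = filter_distinguishable(m, params)
        assert len(out) == 1
        params = FilterParams(min_distinguishable=14, distinguish_mode="minor_class")
        out, _ = filter_distinguishable(m, params)
        assert len(out) == 0

    def test_threshold_beyond_panel_size_errors(self):
        m = single_snp_matrix([("A", "A")] * 10)
        with pytest.raises(ValueError, match="exceeds"):
            filter_distinguishable(m, FilterParams(min_distinguishable=11))


class TestSegregationRatio:
    def test_16_17_split_retained(self):
        calls = [("A", "A")] * 16 + [("G", "G")] * 17
        out, _ = filter_segregation_ratio(single_snp_matrix(calls), FilterParams())
        assert len(out) == 1

    def test_30_3_split_removed(self):
        calls = [("A", "A")] * 30 + [("G", "G")] * 3
        out, _ = filter_segregation_ratio(single_snp_matrix(calls), FilterParams())
        assert len(out) == 0

    def test_bounds_inclusive(self):
        calls = [("A", "A")] * 7 + [("G", "G")] * 3  # minor = 0.3 exactly
        out, _ = filter_segregation_ratio(single_snp_matrix(calls), FilterParams())
        assert len(out) == 1

    def test_all_missing_removed_not_error(self):
        out, step = filter_segregation_ratio(
            single_snp_matrix([None] * 5), FilterParams()
        )
        assert len(out) == 0 and step.n_removed == 1


class TestPruneFlanking:
    def plain(self, positions):
        vs = [V("Chr1", p, "A", ("G",), [("A", "A"), ("G", "G")]) for p in positions]
        return matrix_of(vs, 2, {"Chr1": 10**6})

    def test_close_pair_removed_symmetrically(self):
        out, _ = prune_flanking(self.plain([100, 150, 300]), FilterParams())
        assert [v.pos for v in out.variants] == [300]

    def test_boundary_61_bp_apart_both_retained(self):
        out, _ = prune_flanking(self.plain([100, 161]), FilterParams())
        assert [v.pos for v in out.variants] == [100, 161]

    def test_exactly_60_bp_apart_both_removed(self):
        out, _ = prune_flanking(self.plain([100, 160]), FilterParams())
        assert len(out) == 0

    def test_keep_first_mode_is_greedy(self):
        params = FilterParams(prune_mode="keep_first")
        out, _ = prune_flanking(self.plain([100, 150, 300]), params)
        assert [v.pos for v in out.variants] == [100, 300]

    def test_clustered_positions_match_quadratic_oracle(self):
        cfg = small_config(11, n_snps=1000, cluster_frac=0.3)
        m, _ = simulate_genotype_matrix(cfg)
        params = FilterParams()
        out, _ = prune_flanking(m, params)
        assert {(v.chrom, v.pos) for v in out.variants} == oracle_prune(
            m.variants, params.flank_window
        )


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_stage_predicates_match_oracles(seed):
    m, _ = simulate_genotype_matrix(small_config(seed))
    params = FilterParams()
    out1, _ = filter_homozygous_diallelic(m)
    assert {(v.chrom, v.pos) for v in out1.variants} == {
        (v.chrom, v.pos) for v in m.variants if oracle_hom_diallelic(v)
    }
    out3, _ = filter_segregation_ratio(m, params)
    assert {(v.chrom, v.pos) for v in out3.variants} == {
        (v.chrom, v.pos) for v in m.variants if oracle_seg_ratio(v, 0.3, 0.7)
    }


@pytest.mark.parametrize("seed", [4, 5])
def test_callable_mode_is_a_pure_count(seed):
    m, _ = simulate_genotype_matrix(small_config(seed))
    out, _ = filter_distinguishable(m, FilterParams())
    expected = sum(1 for v in m.variants if v.n_called() >= 15)
    assert len(out) == expected


@pytest.mark.parametrize(
    "stage",
    [
        lambda m: filter_homozygous_diallelic(m),
        lambda m: filter_distinguishable(m, FilterParams()),
        lambda m: filter_segregation_ratio(m, FilterParams()),
    ],
)
def test_stage_idempotence(stage):
    m, _ = simulate_genotype_matrix(small_config(9))
    once, _ = stage(m)
    twice, step = stage(once)
    assert step.n_removed == 0
    assert len(twice) == len(once)


def test_prune_output_spacing_always_clean():
    for seed in (1, 6):
        m, _ = simulate_genotype_matrix(small_config(seed, cluster_frac=0.4))
        out, _ = prune_flanking(m, FilterParams())
        prev = {}
        for v in out.variants:
            if v.chrom in prev:
                assert v.pos - prev[v.chrom] > 60
            prev[v.chrom] = v.pos


class TestCascade:
    def test_empty_matrix_reports_zeros(self):
        m = GenotypeMatrix([], ["K1"], {"Chr1": 1000})
        panel, report = run_cascade(m)
        assert len(panel) == 0
        for row in report_to_table(report):
            assert row[1:] == (0, 0, 0.0)

    def test_chaining_and_monotonicity(self):
        m, _ = simulate_genotype_matrix(small_config(7, n_snps=800))
        _, report = run_cascade(m)
        retained = [s.n_retained for s in report.steps]
        assert retained == sorted(retained, reverse=True)
        for prev, cur in zip(report.steps, report.steps[1:]):
            assert cur.n_input == prev.n_retained
            assert cur.n_input == cur.n_retained + cur.n_removed

    def test_conservation_violation_rejected(self):
        with pytest.raises(ValueError):
            FilterStepResult("x", 10, 5, 4)

    def test_truth_table_agreement(self):
        m, truth = simulate_genotype_matrix(small_config(8, n_snps=800))
        _, report = run_cascade(m)
        cum = truth.pass_hom_diallelic
        expected = [cum.sum()]
        cum = cum & truth.pass_distinguishability
        expected.append(cum.sum())
        cum = cum & truth.pass_segregation
        expected.append(cum.sum())
        expected.append(truth.pass_flanking.sum())
        got = [s.n_retained for s in report.steps[:4]]
        for e, g in zip(expected, got):
            assert abs(e - g) <= 0.01 * len(truth)


def test_report_percentage_arithmetic():
    step = FilterStepResult("distinguishability", 901522, 802404, 99118)
    assert step.pct_removed == 11.0
    step = FilterStepResult("segregation_ratio", 802404, 67568, 734836)
    assert step.pct_removed == 91.6
    step = FilterStepResult("mab_select", 4951, 298, 4653)
    assert step.pct_removed == 94.0
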