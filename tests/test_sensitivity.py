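"""Detection-sensitivity math: calling rule, binomial power, all-WT bound,
replicate combination and prior-weighted gene classification."""

import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ngsadequacy.sensitivity import (
    CallingParams,
    CoverageRecord,
    PriorWeights,
    TumorContext,
    all_wt_sensitivity,
    base_sensitivity,
    binomial_power_sensitivity,
    call_threshold,
    expected_mutation_frequency,
    gene_sensitivity,
    panel_gene_sensitivity,
    read_coverage,
    sensitivity_report,
    write_report,
)


def exact_binomial_tail(n: int, k0: int, m: float) -> float:
    """Independent oracle: exact-rational term-by-term binomial upper tail."""
    if k0 > n:
        return 0.0
    mf = Fraction(m).limit_denominator(10**12)
    total = Fraction(0)
    for k in range(k0, n + 1):
        total += math.comb(n, k) * mf**k * (1 - mf) ** (n - k)
    return float(total)


class TestCallingRule:
    @pytest.mark.parametrize(
        "n,c,r,expected",
        [
            (100, 5, 0.02, 5),  # ceil(2) = 2 < c
            (0, 5, 0.02, 5),  # no coverage: still needs c reads (call impossible)
            (1000, 5, 0.02, 20),  # ceil(20) = 20 > c; float noise must not give 21
            (1, 1, 1.0, 1),
            (99, 3, 0.05, 5),  # ceil(4.95) = 5
        ],
    )
    def test_threshold(self, n, c, r, expected):
        assert call_threshold(n, CallingParams(c=c, r=r)) == expected

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            call_threshold(-1, CallingParams())

    @pytest.mark.parametrize("c,r,thr", [(0, 0.02, 0.99), (5, 0.0, 0.99), (5, 0.02, 1.0)])
    def test_invalid_params_rejected(self, c, r, thr):
        with pytest.raises(ValueError):
            CallingParams(c=c, r=r, sensitivity_threshold=thr)


class TestBinomialPower:
    def test_single_read_threshold_closed_form(self):
        # n=10, c=1, r=0.05 -> threshold 1; P(X>=1), X~Bin(10, 1/2) = 1 - 2^-10
        got = binomial_power_sensitivity(10, CallingParams(c=1, r=0.05), 0.5)
        assert got == pytest.approx(1.0 - 2.0**-10, abs=1e-15)

    def test_zero_frequency_gives_zero(self):
        for n in (0, 1, 50, 10_000):
            assert binomial_power_sensitivity(n, CallingParams(c=1, r=0.01), 0.0) == 0.0

    def test_matches_exact_rational_tail(self):
        params = CallingParams(c=5, r=0.02)
        expected = exact_binomial_tail(200, call_threshold(200, params), 0.025)
        got = binomial_power_sensitivity(200, params, 0.025)
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n", [1, 7, 23, 60])
    @pytest.mark.parametrize("c,r", [(1, 0.05), (3, 0.02), (5, 0.1)])
    def test_exact_oracle_small_grid(self, n, c, r):
        params = CallingParams(c=c, r=r)
        for m in (0.01, 0.1, 0.5, 0.9):
            expected = exact_binomial_tail(n, call_threshold(n, params), m)
            assert binomial_power_sensitivity(n, params, m) == pytest.approx(expected, abs=1e-12)

    def test_large_n_is_finite_and_fast(self):
        got = binomial_power_sensitivity(1_000_000, CallingParams(c=5, r=0.02), 0.025)
        assert 0.0 <= got <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_power_sensitivity(-1, CallingParams(), 0.1)
        with pytest.raises(ValueError):
            binomial_power_sensitivity(10, CallingParams(), 1.5)

    @given(m=st.floats(0.001, 0.999), n=st.integers(1, 300))
    def test_monotone_in_m(self, m, n):
        params = CallingParams(c=3, r=0.02)
        lower = binomial_power_sensitivity(n, params, m * 0.5)
        assert binomial_power_sensitivity(n, params, m) >= lower - 1e-12

    @given(n=st.integers(1, 400), m=st.floats(0.01, 0.5))
    def test_monotone_in_c_and_r(self, n, m):
        base = binomial_power_sensitivity(n, CallingParams(c=2, r=0.01), m)
        assert binomial_power_sensitivity(n, CallingParams(c=4, r=0.01), m) <= base + 1e-12
        assert binomial_power_sensitivity(n, CallingParams(c=2, r=0.05), m) <= base + 1e-12

    @given(n=st.integers(1, 200), m=st.floats(0.01, 0.6))
    def test_monotone_in_n_while_threshold_constant(self, n, m):
        # within a constant call-threshold segment more coverage can only help
        params = CallingParams(c=5, r=0.02)
        if call_threshold(n, params) == call_threshold(n + 1, params):
            assert binomial_power_sensitivity(n + 1, params, m) >= (
                binomial_power_sensitivity(n, params, m) - 1e-12
            )


class TestAllWtBound:
    @pytest.mark.parametrize(
        "n,r,expected",
        [(1, 0.5, 0.5), (0, 0.3, 0.0), (300, 0.01, 1.0 - 0.99**300), (2, 1.0, 1.0)],
    )
    def test_examples(self, n, r, expected):
        assert all_wt_sensitivity(n, r) == pytest.approx(expected, abs=1e-12)

    def test_log_space_survives_huge_n(self):
        assert all_wt_sensitivity(10**7, 0.01) == pytest.approx(1.0)

    def test_misuse_with_observed_mutants_rejected(self):
        with pytest.raises(ValueError, match="all-WT"):
            all_wt_sensitivity(100, 0.02, observed_mutant_reads=3)

    @given(n=st.integers(0, 10_000), r=st.floats(0.001, 0.999))
    def test_monotone_in_n_and_bounded(self, n, r):
        s0, s1 = all_wt_sensitivity(n, r), all_wt_sensitivity(n + 1, r)
        assert 0.0 <= s0 <= s1 <= 1.0

    @given(n=st.integers(1, 500))
    def test_dominates_standard_power_on_all_wt_base(self, n):
        # extra information (every read WT) can only sharpen the bound
        for c, r in ((1, 0.02), (3, 0.05), (5, 0.01)):
            params = CallingParams(c=c, r=r)
            assert all_wt_sensitivity(n, r) >= binomial_power_sensitivity(n, params, r) - 1e-12


class TestBaseSensitivity:
    def test_two_all_wt_replicates_combine_by_product(self, rng):
        params = CallingParams(c=1, r=0.5)
        records = [
            CoverageRecord("G", 1, 1, 1, 0),
            CoverageRecord("G", 1, 2, 1, 0),
        ]
        bs = base_sensitivity(records, params, m=0.5)
        assert bs.per_replicate == (0.5, 0.5)
        assert bs.combined == pytest.approx(0.25)
        assert bs.method == "all_wt"
        # Monte-Carlo oracle: two independent Binomial(1, 0.5) libraries must
        # both reach the call threshold max(c, ceil(r*n)) = 1
        draws = rng.binomial(1, 0.5, size=(200_000, 2))
        assert (draws >= 1).all(axis=1).mean() == pytest.approx(0.25, abs=0.005)

    def test_certainty_composes(self):
        params = CallingParams(c=1, r=0.01)
        records = [CoverageRecord("G", 1, i, 100_000, 0) for i in (1, 2)]
        bs = base_sensitivity(records, params, m=0.5)
        assert bs.combined == pytest.approx(1.0)

    def test_zero_coverage_single_replicate(self):
        bs = base_sensitivity([CoverageRecord("G", 1, 1, 0, 0)], CallingParams(), m=0.25)
        assert bs.per_replicate == (0.0,)
        assert bs.combined == 0.0
        assert bs.single_replicate

    def test_mixed_paths_selected_per_replicate(self):
        params = CallingParams(c=5, r=0.02)
        records = [
            CoverageRecord("G", 7, 1, 1000, 0),  # all WT -> sharper bound
            CoverageRecord("G", 7, 2, 1000, 12),  # mutants observed -> power calc
        ]
        bs = base_sensitivity(records, params, m=0.04)
        assert bs.per_replicate[0] == pytest.approx(all_wt_sensitivity(1000, 0.02))
        assert bs.per_replicate[1] == pytest.approx(
            binomial_power_sensitivity(1000, params, 0.04)
        )
        assert bs.method == "binomial_power"
        assert bs.combined == pytest.approx(bs.per_replicate[0] * bs.per_replicate[1])
        assert bs.combined <= max(bs.per_replicate) + 1e-15

    def test_either_policy_is_complement_product(self):
        params = CallingParams(c=1, r=0.5)
        records = [CoverageRecord("G", 1, i, 1, 0) for i in (1, 2)]
        bs = base_sensitivity(records, params, m=0.5, policy="either")
        assert bs.combined == pytest.approx(0.75)

    def test_mismatched_positions_and_duplicate_replicates_rejected(self):
        params = CallingParams()
        with pytest.raises(ValueError):
            base_sensitivity(
                [CoverageRecord("G", 1, 1, 10, 0), CoverageRecord("G", 2, 2, 10, 0)],
                params,
                0.1,
            )
        with pytest.raises(ValueError):
            base_sensitivity(
                [CoverageRecord("G", 1, 1, 10, 0), CoverageRecord("G", 1, 1, 10, 0)],
                params,
                0.1,
            )


def _bs(gene, pos, combined):
    from ngsadequacy.sensitivity import BaseSensitivity

    return BaseSensitivity(gene, pos, (combined,), combined, "binomial_power")


class TestGeneSensitivity:
    def test_uniform_weights_constant_sensitivity(self):
        bases = [_bs("G", i, 0.95) for i in range(1, 5)]
        weights = PriorWeights({("G", i): 1.0 for i in range(1, 5)})
        gs = gene_sensitivity(bases, weights, CallingParams())
        assert gs.weighted_sensitivity == pytest.approx(0.95)
        assert gs.low_coverage

    def test_weighted_mean_forced_arithmetic(self):
        bases = [_bs("G", 1, 0.90), _bs("G", 2, 1.00)]
        weights = PriorWeights({("G", 1): 0.25, ("G", 2): 0.75})
        gs = gene_sensitivity(bases, weights, CallingParams())
        assert gs.weighted_sensitivity == pytest.approx(0.975)
        assert gs.low_coverage  # 0.975 < 0.99

    def test_reporting_threshold_is_strictly_less_than(self):
        bases = [_bs("G", i, 0.995) for i in (1, 2)]
        weights = PriorWeights({("G", 1): 1.0, ("G", 2): 3.0})
        gs = gene_sensitivity(bases, weights, CallingParams())
        assert gs.weighted_sensitivity == pytest.approx(0.995)
        assert not gs.low_coverage

    def test_zero_weight_bases_excluded_not_zeroing(self):
        bases = [_bs("G", 1, 0.10), _bs("G", 2, 1.00)]
        weights = PriorWeights({("G", 1): 0.0, ("G", 2): 2.0})
        gs = gene_sensitivity(bases, weights, CallingParams())
        assert gs.weighted_sensitivity == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self):
        bases = [_bs("G", 1, 0.5)]
        with pytest.raises(ValueError, match="zero"):
            gene_sensitivity(bases, PriorWeights({("G", 1): 0.0}), CallingParams())

    @given(
        sens=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
        scale=st.floats(0.01, 100.0),
        data=st.data(),
    )
    def test_bounded_and_rescale_invariant(self, sens, scale, data):
        ws = data.draw(
            st.lists(st.floats(0.1, 10.0), min_size=len(sens), max_size=len(sens))
        )
        bases = [_bs("G", i + 1, s) for i, s in enumerate(sens)]
        w1 = PriorWeights({("G", i + 1): w for i, w in enumerate(ws)})
        w2 = PriorWeights({("G", i + 1): w * scale for i, w in enumerate(ws)})
        g1 = gene_sensitivity(bases, w1, CallingParams())
        g2 = gene_sensitivity(bases, w2, CallingParams())
        assert min(sens) - 1e-12 <= g1.weighted_sensitivity <= max(sens) + 1e-12
        assert g1.weighted_sensitivity == pytest.approx(g2.weighted_sensitivity, abs=1e-12)


class TestExpectedFrequency:
    @pytest.mark.parametrize("purity,m", [(0.50, 0.25), (0.03, 0.015), (1.0, 0.5)])
    def test_half_purity(self, purity, m):
        assert expected_mutation_frequency(purity) == pytest.approx(m)

    @pytest.mark.parametrize("purity", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, purity):
        with pytest.raises(ValueError):
            expected_mutation_frequency(purity)

    def test_tumor_context_default_and_override(self):
        assert TumorContext(0.5).m == pytest.approx(0.25)
        assert TumorContext(0.5, m=0.4).m == pytest.approx(0.4)
        with pytest.raises(ValueError):
            TumorContext(0.0)


class TestPanelVectorization:
    def test_panel_matches_scalar_path(self, rng):
        """The vectorized cohort path must reproduce the per-base scalar path."""
        params = CallingParams(c=5, r=0.02)
        G, B, R = 3, 4, 2
        n = rng.integers(0, 2000, size=(G, B, R))
        mut = rng.binomial(n, 0.01)
        w = rng.uniform(0.1, 2.0, size=(G, B))
        m = 0.05
        fast = panel_gene_sensitivity(n, mut, w, params, m)
        for g in range(G):
            bases = []
            for b in range(B):
                records = [
                    CoverageRecord(f"G{g}", b + 1, rep + 1, int(n[g, b, rep]), int(mut[g, b, rep]))
                    for rep in range(R)
                ]
                bases.append(base_sensitivity(records, params, m))
            weights = PriorWeights({(f"G{g}", b + 1): w[g, b] for b in range(B)})
            slow = gene_sensitivity(bases, weights, params)
            assert fast[g] == pytest.approx(slow.weighted_sensitivity, abs=1e-12)


class TestTabularRoundTrip:
    def test_coverage_report_io(self, tmp_path):
        cov = pd.DataFrame(
            {
                "gene": ["BRAF"] * 4 + ["KRAS"] * 4,
                "position": [1, 1, 2, 2] * 2,
                "replicate": [1, 2, 1, 2] * 2,
                "n": [5000, 5200, 4800, 5100, 300, 280, 290, 310],
                "mutant_reads": [0, 0, 3, 4, 0, 0, 0, 1],
            }
        )
        cov_path = tmp_path / "coverage.tsv"
        cov.to_csv(cov_path, sep="\t", index=False)
        weights = PriorWeights(
            {("BRAF", 1): 3.0, ("BRAF", 2): 1.0, ("KRAS", 1): 1.0, ("KRAS", 2): 1.0}
        )
        report = sensitivity_report(
            read_coverage(cov_path), weights, CallingParams(), m=0.05
        )
        assert list(report["gene"]) == ["BRAF", "KRAS"]
        assert ((0 <= report["weighted_sensitivity"]) & (report["weighted_sensitivity"] <= 1)).all()
        write_report(report, tmp_path / "report.tsv", tmp_path / "report.json")
        back = pd.read_csv(tmp_path / "report.tsv", sep="\t")
        assert back["weighted_sensitivity"].tolist() == pytest.approx(
            report["weighted_sensitivity"].tolist()
        )
        import json

        summary = json.loads((tmp_path / "report.json").read_text())
        assert set(summary) == {"BRAF", "KRAS"}

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene": ["G"], "position": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_coverage(path)
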