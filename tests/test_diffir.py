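import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irquant import diffir, simgen
from irquant.diffir import DiffResult, SampleSet
from irquant.quantify import IRRecord


def rec(ratio, depth=100, warnings=()):
    a_i = ratio * depth
    n_s = int(round(depth - a_i))
    return IRRecord(
        "c", 0, 100, "+", "g/t", a_i, depth - a_i, n_s, n_s, n_s, tuple(warnings)
    )


def sample_sets(seed=0, n_introns=200, delta=None, n_planted=0, depth=100,
                base_ir=0.15, n_per_group=3):
    _gtf, truth = simgen.simulate_model(
        n_genes=(n_introns + 2) // 3, introns_per_gene=3, seed=17,
        ir_values=[base_ir],
    )
    keys = sorted(truth.introns)[:n_introns]
    truth.introns = {k: truth.introns[k] for k in keys}
    planted = set(keys[:n_planted])
    dmap = {k: delta for k in planted} if delta else None
    groups = simgen.simulate_groups(truth, n_per_group, dmap, seed=seed, depth=depth)
    conds = list(groups)
    return (
        SampleSet(conds[0], groups[conds[0]]),
        SampleSet(conds[1], groups[conds[1]]),
        planted,
    )


class TestFilterIntrons:
    def _sets(self, rows):
        # rows: list of (ratios per 3 samples, warnings flag per sample)
        samples_a = [dict() for _ in range(2)]
        samples_b = [dict() for _ in range(1)]
        for i, (ratios, warns) in enumerate(rows):
            key = f"i{i}"
            allsamp = samples_a + samples_b
            for s, r, w in zip(allsamp, ratios, warns):
                s[key] = rec(r, warnings=("LowCover",) if w else ())
        return [SampleSet("a", samples_a), SampleSet("b", samples_b)]

    def test_one_sample_above_min_ratio_keeps_intron(self):
        sets = self._sets([([0.06, 0.01, 0.0], [0, 0, 0])])
        assert diffir.filter_introns(sets) == ["i0"]

    def test_all_below_min_ratio_drops_intron(self):
        sets = self._sets([([0.04, 0.01, 0.0], [0, 0, 0])])
        assert diffir.filter_introns(sets) == []

    def test_single_lowcover_sample_drops_intron(self):
        sets = self._sets([([0.3, 0.3, 0.3], [0, 1, 0])])
        assert diffir.filter_introns(sets) == []
        assert diffir.filter_introns(sets, drop_lowcover=False) == ["i0"]

    def test_matches_refilter_oracle_on_simulated_sets(self):
        a, b, _ = sample_sets(seed=3, n_introns=120, depth=30)
        kept = set(diffir.filter_introns([a, b]))
        for key in a.samples[0]:
            recs = [s[key] for ss in (a, b) for s in ss.samples]
            expect = (
                max(r.irratio for r in recs) >= 0.05
                and not any("LowCover" in r.warnings for r in recs)
            )
            assert (key in kept) == expect


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        got = diffir.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diffir.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_one(self):
        assert np.allclose(diffir.bh_adjust([1.0] * 5), 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_dominates_raw_p(self, ps):
        got = diffir.bh_adjust(ps)
        # independent step-up oracle
        p = np.asarray(ps)
        n = p.size
        order = np.argsort(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, oracle)
        assert (got >= p - 1e-12).all()


class TestGlmDiff:
    def test_planted_events_recovered(self):
        a, b, planted = sample_sets(seed=12, n_introns=300, delta=0.3,
                                    n_planted=40)
        res = diffir.glm_diff(a, b)
        called = {r.intron for r in diffir.default_calls(res)}
        assert len(called & planted) >= 0.8 * len(planted)

    def test_null_simulation_controls_false_calls(self):
        a, b, _ = sample_sets(seed=13, n_introns=300)
        res = diffir.glm_diff(a, b)
        tested = [r for r in res if not r.untestable]
        frac_sig = np.mean([r.padj < 0.05 for r in tested])
        assert frac_sig <= 0.10

    def test_identical_groups_give_null_results(self):
        a, b, _ = sample_sets(seed=14, n_introns=30)
        twin = SampleSet("b", a.samples)
        for r in diffir.glm_diff(a, twin):
            assert r.untestable or r.pvalue > 0.99

    def test_all_zero_counts_flagged_untestable_and_excluded_from_bh(self):
        samples = [{"i0": rec(0.5), "i1": rec(0.0, depth=0)} for _ in range(2)]
        # i1 has zero counts everywhere; keep it past the ratio filter via i0
        a = SampleSet("a", [dict(s) for s in samples])
        b = SampleSet("b", [dict(s) for s in samples])
        res = diffir.glm_diff(a, b, min_ratio=0.0, drop_lowcover=False)
        by_key = {r.intron: r for r in res}
        assert by_key["i1"].untestable
        assert np.isnan(by_key["i1"].padj)

    def test_fewer_than_two_samples_rejected(self):
        a = SampleSet("a", [{"i0": rec(0.2)}])
        with pytest.raises(ValueError):
            diffir.glm_diff(a, a)

    def test_label_swap_negates_effect(self):
        a, b, _ = sample_sets(seed=15, n_introns=60, delta=0.25, n_planted=20)
        fwd = {r.intron: r for r in diffir.glm_diff(a, b)}
        rev = {r.intron: r for r in diffir.glm_diff(b, a)}
        for key, rf in fwd.items():
            rr = rev[key]
            if rf.untestable or rr.untestable:
                continue
            assert rf.effect == pytest.approx(-rr.effect, abs=1e-6)
            assert rf.pvalue == pytest.approx(rr.pvalue, abs=1e-6)


class TestRatioDiff:
    def test_identical_groups_give_zero_delta(self):
        a, b, _ = sample_sets(seed=16, n_introns=40)
        twin = SampleSet("b", a.samples)
        for r in diffir.ratio_diff(a, twin):
            assert r.effect == 0.0
            assert r.pvalue == 1.0

    def test_planted_delta_estimated_accurately(self):
        a, b, planted = sample_sets(seed=18, n_introns=300, delta=0.3,
                                    n_planted=40)
        res = {r.intron: r for r in diffir.ratio_diff(a, b)}
        errs = [abs(res[k].effect - 0.3) for k in planted if k in res]
        assert np.mean(errs) < 0.07

    def test_label_swap_negates_delta_exactly(self):
        a, b, _ = sample_sets(seed=19, n_introns=60, delta=0.25, n_planted=20)
        fwd = {r.intron: r for r in diffir.ratio_diff(a, b)}
        rev = {r.intron: r for r in diffir.ratio_diff(b, a)}
        for key, rf in fwd.items():
            assert rf.effect == -rev[key].effect
            assert rf.pvalue == rev[key].pvalue

    def test_calls_fewer_low_coverage_events_than_glm(self):
        a, b, _ = sample_sets(seed=22, n_introns=300, delta=0.3, n_planted=60,
                              depth=10)
        n_glm = len(diffir.default_calls(diffir.glm_diff(a, b, drop_lowcover=False)))
        n_ratio = len(
            diffir.default_calls(diffir.ratio_diff(a, b, drop_lowcover=False))
        )
        assert n_ratio < n_glm

    def test_null_simulation_controls_false_calls(self):
        a, b, _ = sample_sets(seed=23, n_introns=300)
        res = diffir.ratio_diff(a, b)
        frac_sig = np.mean([r.padj < 0.05 for r in res])
        assert frac_sig <= 0.10


class TestPairwise:
    def _three_sets(self):
        a, b, _ = sample_sets(seed=30, n_introns=30)
        c = SampleSet("third", b.samples)
        return [a, b, c]

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 6)])
    def test_pair_count_combinatorics(self, n, expected):
        sets = self._three_sets()
        while len(sets) < n:
            sets.append(SampleSet(f"extra{len(sets)}", sets[0].samples))
        out = diffir.pairwise_compare(sets[:n], method="ratio")
        assert len(out) == expected

    def test_no_result_for_filtered_intron(self):
        a, b, _ = sample_sets(seed=31, n_introns=50, depth=30)
        kept = set(diffir.filter_introns([a, b]))
        for res in diffir.pairwise_compare([a, b], method="glm").values():
            assert {r.intron for r in res} <= kept

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            diffir.pairwise_compare(self._three_sets(), method="wilcoxon")
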