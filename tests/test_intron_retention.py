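import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proxisplice.intron_retention import (
    IntronRetentionModel,
    RiParams,
    _vectorized_t,
    call_ri_events,
    compute_idratio,
    impute_log2,
    prefilter,
    ri_test,
    ri_verdicts,
    tally_events,
)
from proxisplice.simulate import gen_depth_experiment, gen_gene_models


class TestComputeIdratio:
    def test_internal_intron_ten_percent(self):
        """Intron depth 10 between exons at depth 100 -> 10% retention."""
        assert compute_idratio(10, 100, 100, "internal") == pytest.approx(0.10)

    def test_first_intron_uses_only_three_prime_exon(self):
        assert compute_idratio(5, 0, 50, "first") == pytest.approx(0.10)

    def test_last_intron_uses_only_five_prime_exon(self):
        assert compute_idratio(5, 50, 0, "last") == pytest.approx(0.10)

    def test_zero_denominator_is_undefined(self):
        assert math.isnan(compute_idratio(7, 0, 0, "internal"))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_idratio(-1, 10, 10, "internal")

    @given(
        st.floats(0.1, 1e4),
        st.floats(0.1, 1e4),
        st.floats(0.1, 1e4),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, intron, up, down, c):
        base = compute_idratio(intron, up, down, "internal")
        scaled = compute_idratio(intron * c, up * c, down * c, "internal")
        assert scaled == pytest.approx(base, rel=1e-9)

    @given(st.floats(0.1, 1e3), st.floats(0.1, 1e3), st.floats(1.01, 10.0))
    def test_monotone_in_intron_depth(self, intron, exon, factor):
        low = compute_idratio(intron, exon, exon, "internal")
        high = compute_idratio(intron * factor, exon, exon, "internal")
        assert high > low


class TestImputation:
    def test_all_finite_is_identity(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        out, flags = impute_log2(x, seed=0)
        np.testing.assert_array_equal(out, x)
        assert not flags.any()

    def test_seeded_reproducibility(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, -np.inf])
        a, _ = impute_log2(x, seed=7)
        b, _ = impute_log2(x, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_flags_mark_exactly_the_nonfinite(self):
        x = np.array([0.5, np.nan, 1.5, -np.inf, 2.5])
        out, flags = impute_log2(x, seed=1)
        np.testing.assert_array_equal(flags, [False, True, False, True, False])
        assert np.isfinite(out).all()

    def test_too_few_finite_values_is_error(self):
        x = np.array([1.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="prefilter"):
            impute_log2(x, seed=0)

    def test_downshifted_moments(self):
        """Imputed draws follow Normal(m - 1.8 s, (0.3 s)^2)."""
        rng = np.random.default_rng(5)
        finite = rng.normal(0.0, 1.0, size=2000)
        col = np.concatenate([finite, np.full(20000, np.nan)])
        out, flags = impute_log2(col, seed=5)
        m, s = finite.mean(), finite.std(ddof=1)
        drawn = out[flags]
        assert drawn.mean() == pytest.approx(m - 1.8 * s, abs=0.02)
        assert drawn.std(ddof=1) == pytest.approx(0.3 * s, abs=0.02)


class TestRiTest:
    def test_identical_groups(self):
        p, fc = ri_test([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0])
        assert fc == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fold_change_from_mean_difference(self):
        lg3 = math.log2(3.0)
        p, fc = ri_test([0.0] * 4, [lg3] * 4)
        assert fc == pytest.approx(3.0)
        assert p == 0.0  # zero variance both groups, unequal means

    def test_matches_textbook_pooled_t(self):
        """p equals the hand-computed pooled-variance t for a fixed example."""
        ref = np.array([1.0, 1.2, 0.9, 1.1])
        test = np.array([2.0, 2.1, 1.9, 2.2])
        # independent arithmetic: pooled variance, t, survival function
        sp2 = (ref.var(ddof=1) * 3 + test.var(ddof=1) * 3) / 6
        t = (test.mean() - ref.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        expected_p = 2 * stats.t.sf(abs(t), 6)
        p, fc = ri_test(ref, test)
        assert p == pytest.approx(expected_p, rel=1e-12)
        assert fc == pytest.approx(2 ** (test.mean() - ref.mean()))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=(50, 4))
        g2 = rng.normal(size=(50, 4))
        pv, fcv = _vectorized_t(g2, g1)
        for i in range(50):
            p, fc = ri_test(g1[i], g2[i])
            assert pv[i] == pytest.approx(p, rel=1e-10)
            assert fcv[i] == pytest.approx(fc, rel=1e-10)


class TestPrefilter:
    params = RiParams()

    def _rec(self, ref, test):
        return pd.DataFrame({"mean_idr_ref": [ref], "mean_idr_test": [test]})

    def test_both_below_threshold_dropped(self):
        assert len(prefilter(self._rec(0.05, 0.05), self.params)) == 0

    def test_one_group_above_kept(self):
        assert len(prefilter(self._rec(0.05, 0.20), self.params)) == 1

    def test_boundary_at_least_fifteen_percent_kept(self):
        assert len(prefilter(self._rec(0.15, 0.01), self.params)) == 1


class TestFilterCascade:
    def _record(self, **over):
        base = dict(
            feature_id="G1:intron:2", gene_id="G1", ordinal=2,
            position_class="internal", p_value=0.01, fold_change=2.0,
            gene_rpkm=5.0, mean_depth_ref=30.0, mean_depth_test=30.0,
            mean_idr_ref=0.2, mean_idr_test=0.4,
        )
        base.update(over)
        return pd.DataFrame([base])

    def test_all_criteria_pass(self):
        called = call_ri_events(self._record(), RiParams(), "increased")
        assert len(called) == 1

    @pytest.mark.parametrize(
        "override,criterion",
        [
            ({"p_value": 0.06}, 1),
            ({"fold_change": 1.4}, 2),
            ({"gene_rpkm": 1.0}, 3),  # strict > 1
            ({"mean_depth_test": 4.9}, 4),
            ({"position_class": "only"}, 5),
            ({"mean_idr_test": 0.15}, 6),  # strict > 0.15
        ],
    )
    def test_first_failing_criterion_recorded(self, override, criterion):
        out = ri_verdicts(self._record(**override), RiParams(), "increased")
        assert out["excluded_by"].iloc[0] == criterion

    def test_boundary_semantics_inclusive_where_stated(self):
        rec = self._record(p_value=0.05, fold_change=1.5, mean_depth_test=5.0)
        assert len(call_ri_events(rec, RiParams(), "increased")) == 1

    def test_decreased_direction_uses_reference_group(self):
        rec = self._record(
            fold_change=0.5, mean_depth_test=1.0, mean_idr_test=0.01,
            mean_depth_ref=30.0, mean_idr_ref=0.4,
        )
        assert len(call_ri_events(rec, RiParams(), "decreased")) == 1
        # same record fails when reference-side depth is too low
        rec2 = self._record(fold_change=0.5, mean_depth_ref=4.0)
        out = ri_verdicts(rec2, RiParams(), "decreased")
        assert out["excluded_by"].iloc[0] == 4


class TestTally:
    def test_empty_input_gives_zeros(self):
        out = tally_events({"RI": pd.DataFrame(), "ES": pd.DataFrame()})
        assert (out[["up", "down", "total"]].to_numpy() == 0).all()

    def test_grand_total_is_sum_of_classes(self):
        rng = np.random.default_rng(0)
        per_class = {}
        for cls in ("RI", "ES", "AD"):
            n = int(rng.integers(1, 30))
            per_class[cls] = pd.DataFrame(
                {
                    "gene_id": [f"g{i % 7}" for i in range(n)],
                    "direction": rng.choice(["increased", "decreased"], n),
                }
            )
        out = tally_events(per_class).set_index("event_class")
        assert out.loc["total", "total"] == sum(
            len(v) for v in per_class.values()
        )
        for cls, ev in per_class.items():
            assert out.loc[cls, "total"] == out.loc[cls, "up"] + out.loc[cls, "down"]
            assert out.loc[cls, "genes"] == ev["gene_id"].nunique()


class TestModelFit:
    def test_fit_on_tiny_experiment(self, tiny_depth_experiment):
        res = IntronRetentionModel(
            tiny_depth_experiment, RiParams(seed=1)
        ).fit()
        rec = res.tested.set_index("feature_id")
        # G1 intron 1: wt ratios 20/100, 22/100 (first intron -> 3' exon)
        assert rec.loc["G1:intron:1", "idr_wt_1"] == pytest.approx(20 / 100)
        assert rec.loc["G1:intron:1", "fold_change"] > 2.5
        # G2's only intron is classed 'only'
        assert rec.loc["G2:intron:1", "position_class"] == "only"
        assert "increased retention events" in res.summary()

    def test_pipeline_deterministic_under_seed(self):
        models = gen_gene_models(30, seed=9)
        exp, _ = gen_depth_experiment(models, zero_exon_fraction=0.05, seed=9)
        r1 = IntronRetentionModel(exp, RiParams(seed=4)).fit()
        r2 = IntronRetentionModel(exp, RiParams(seed=4)).fit()
        pd.testing.assert_frame_equal(r1.tested, r2.tested)

    def test_type_one_error_controlled_on_null_data(self):
        """On spike-free data the t-test calls ~5% of introns at alpha=0.05."""
        models = gen_gene_models(500, exon_count_range=(4, 7), seed=13)
        exp, _ = gen_depth_experiment(models, seed=13)
        res = IntronRetentionModel(exp, RiParams(seed=13)).fit()
        frac = (res.tested["p_value"] <= 0.05).mean()
        n = len(res.tested)
        assert frac == pytest.approx(0.05, abs=4 * math.sqrt(0.05 * 0.95 / n))

    def test_spiked_introns_recovered(self):
        """FC=3 spikes at deep coverage are all called; no null is called."""
        models = gen_gene_models(60, seed=7)
        n_introns = sum(m.n_introns for m in models)
        exp, truth = gen_depth_experiment(
            models,
            baseline_log_mean=5.5,
            dispersion=100.0,
            retention_range=(0.15, 0.3),
            ri_spike_count=8,
            ri_spike_fold_changes=(3.0,),
            seed=7,
        )
        res = IntronRetentionModel(exp, RiParams(seed=7)).fit()
        called = set(res.call_events("increased")["feature_id"])
        spiked = set(truth.table[truth.table["spiked"]]["feature_id"])
        assert called == spiked
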