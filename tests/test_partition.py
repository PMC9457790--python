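"""Mass-balance estimator: worked-example reproduction, replicate handling,
clipping behaviour, N2O consistency and bootstrap uncertainty."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrfopart.demo import worked_example, worked_example_inputs
from nrfopart.kinetics import TimeCourse
from nrfopart.partition import (
    bootstrap_uncertainty,
    consumed,
    n2o_consistency,
    partition_fe,
    round_percent,
)


def make_course(setup_id, series, strain="test", times=(0.0, 240.0)):
    """series: {analyte: [per-replicate (start, end) tuples]}"""
    rows = []
    for analyte, reps in series.items():
        for i, (v0, v1) in enumerate(reps, start=1):
            rows.append((i, times[0], analyte, v0, "mM"))
            rows.append((i, times[1], analyte, v1, "mM"))
    data = pd.DataFrame(rows, columns=["replicate", "time_h", "analyte", "value", "unit"])
    return TimeCourse(setup_id=setup_id, strain=strain, data=data)


class TestConsumed:
    def test_identical_triplicates(self):
        tc = make_course("a", {"NO3": [(10.0, 8.92)] * 3})
        s = consumed(tc, "NO3", 0, 240)
        assert s.mean_consumed == pytest.approx(1.08)
        assert s.sd_consumed == 0.0
        assert s.n_replicates == 3

    def test_constant_series_zero_consumption(self):
        tc = make_course("a", {"NO3": [(5.0, 5.0)] * 2})
        assert consumed(tc, "NO3", 0, 240).mean_consumed == 0.0

    def test_mean_and_sample_sd_across_replicates(self):
        tc = make_course("a", {"NO3": [(10.0, 9.0), (10.0, 8.9), (10.0, 8.8)]})
        s = consumed(tc, "NO3", 0, 240)
        assert s.mean_consumed == pytest.approx(1.1)
        assert s.sd_consumed == pytest.approx(0.1)

    def test_negative_consumption_kept_but_warned(self):
        tc = make_course("a", {"NO3": [(10.0, 10.2), (10.0, 9.0)]})
        s = consumed(tc, "NO3", 0, 240)
        assert s.mean_consumed == pytest.approx(0.4)
        assert any("negative" in w for w in s.warnings)

    def test_missing_analyte_and_bad_window_rejected(self):
        tc = make_course("a", {"NO3": [(10.0, 9.0)]})
        with pytest.raises(KeyError, match="Fe2"):
            consumed(tc, "Fe2", 0, 240)
        with pytest.raises(ValueError, match="exceed"):
            consumed(tc, "NO3", 240, 0)

    def test_nearest_sample_matching_within_one_hour(self):
        tc = make_course("a", {"NO3": [(10.0, 9.0)]}, times=(0.0, 239.5))
        assert consumed(tc, "NO3", 0, 240).mean_consumed == pytest.approx(1.0)
        with pytest.raises(KeyError, match="no sample within"):
            consumed(tc, "NO3", 0, 230)


class TestWorkedExample:
    """The published end-point partition, reproduced through the estimator."""

    def test_low_endpoint(self):
        est = worked_example()["low"]
        assert est.delta_no3 == pytest.approx(0.41)
        assert est.enzymatic_fe == pytest.approx(0.82)
        assert est.abiotic_fe == pytest.approx(2.98)
        assert est.frac_enzymatic_pct == 22
        assert est.frac_abiotic_pct == 78
        assert est.frac_no3_fe_driven_pct == 38
        assert est.frac_enzymatic == pytest.approx(0.82 / 3.80)

    def test_high_endpoint(self):
        est = worked_example()["high"]
        assert est.delta_no3 == pytest.approx(0.55)
        assert est.enzymatic_fe == pytest.approx(1.10)
        assert est.abiotic_fe == pytest.approx(2.70)
        assert est.frac_enzymatic_pct == 29
        assert est.frac_abiotic_pct == 71
        assert est.frac_no3_fe_driven_pct == 34
        assert est.n2o_predicted_chem == pytest.approx(2.70 / 4)

    def test_predicted_chem_n2o_from_abiotic_fe(self):
        assert worked_example()["low"].n2o_predicted_chem == pytest.approx(0.745)


class TestPartitionFe:
    def test_identical_consumption_gives_zero_enzymatic(self):
        with_fe = make_course("w", {"NO3": [(10.0, 9.0)] * 3, "Fe2": [(4.5, 1.5)] * 3})
        without = make_course("o", {"NO3": [(10.0, 9.0)] * 3})
        est = partition_fe(with_fe, without)
        assert est.delta_no3 == 0.0
        assert est.frac_enzymatic == 0.0
        assert est.frac_abiotic == 1.0

    def test_negative_delta_clipped_with_warning(self):
        with_fe = make_course("w", {"NO3": [(10.0, 9.5)] * 2, "Fe2": [(4.5, 3.5)] * 2})
        without = make_course("o", {"NO3": [(10.0, 9.0)] * 2})
        est = partition_fe(with_fe, without)
        assert est.delta_no3 == 0.0
        assert any("clipped" in w for w in est.warnings)

    def test_enzymatic_exceeding_total_clips_abiotic_with_warning(self):
        with_fe = make_course("w", {"NO3": [(10.0, 8.0)] * 2, "Fe2": [(4.5, 3.5)] * 2})
        without = make_course("o", {"NO3": [(10.0, 10.0)] * 2})
        est = partition_fe(with_fe, without)
        assert est.abiotic_fe == 0.0
        assert est.frac_enzymatic == 1.0
        assert any("abiotic" in w for w in est.warnings)

    def test_no_fe_oxidation_is_an_error(self):
        with_fe = make_course("w", {"NO3": [(10.0, 9.0)] * 2, "Fe2": [(4.5, 4.5)] * 2})
        without = make_course("o", {"NO3": [(10.0, 9.5)] * 2})
        with pytest.raises(ValueError, match="no Fe"):
            partition_fe(with_fe, without)

    def test_strain_mismatch_rejected(self):
        with_fe = make_course("w", {"NO3": [(10, 9)], "Fe2": [(4, 1)]}, strain="A")
        without = make_course("o", {"NO3": [(10, 9.5)]}, strain="B")
        with pytest.raises(ValueError, match="strain mismatch"):
            partition_fe(with_fe, without)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           no3_w=st.floats(min_value=0.5, max_value=3.0),
           gap=st.floats(min_value=0.0, max_value=0.4),
           fe=st.floats(min_value=2.0, max_value=5.0))
    def test_scale_equivariance(self, scale, no3_w, gap, fe):
        """Multiplying all concentrations by c > 0 scales the mM quantities
        by c and leaves every fraction unchanged."""
        def build(s):
            w = make_course("w", {"NO3": [(10 * s, (10 - no3_w) * s)] * 2,
                                  "Fe2": [(5 * s, (5 - fe / 2) * s)] * 2})
            o = make_course("o", {"NO3": [(10 * s, (10 - no3_w + gap) * s)] * 2})
            return partition_fe(w, o)

        base, scaled = build(1.0), build(scale)
        assert scaled.delta_no3 == pytest.approx(base.delta_no3 * scale, rel=1e-9, abs=1e-12)
        assert scaled.enzymatic_fe == pytest.approx(base.enzymatic_fe * scale, rel=1e-9, abs=1e-12)
        assert scaled.total_fe_ox == pytest.approx(base.total_fe_ox * scale, rel=1e-9)
        assert scaled.abiotic_fe == pytest.approx(base.abiotic_fe * scale, rel=1e-9, abs=1e-12)
        assert scaled.frac_enzymatic == pytest.approx(base.frac_enzymatic, rel=1e-9, abs=1e-12)
        assert scaled.frac_abiotic == pytest.approx(base.frac_abiotic, rel=1e-9, abs=1e-12)
        assert 0.0 <= scaled.frac_enzymatic <= 1.0

    def test_rounding_half_up_to_whole_percent(self):
        assert round_percent(0.215) == 22
        assert round_percent(0.2149) == 21
        assert round_percent(0.289) == 29


class TestN2OConsistency:
    def test_observed_equal_to_predicted_is_consistent(self):
        with_fe = make_course("w", {"NO3": [(10.0, 8.92)] * 2, "Fe2": [(4.5, 0.7)] * 2,
                                    "N2O": [(0.0, 1.045)] * 2})
        without = make_course("o", {"NO3": [(10.0, 9.33)] * 2, "N2O": [(0.0, 0.3)] * 2})
        est = partition_fe(with_fe, without)
        rec = n2o_consistency(est, with_fe, without)
        assert rec.available
        assert rec.predicted == pytest.approx(est.abiotic_fe / 4)
        assert rec.ratio == pytest.approx(1.0)
        assert rec.consistent

    def test_absent_n2o_marked_unavailable(self):
        with_fe = make_course("w", {"NO3": [(10.0, 9.0)] * 2, "Fe2": [(4.5, 1.5)] * 2})
        without = make_course("o", {"NO3": [(10.0, 9.3)] * 2})
        est = partition_fe(with_fe, without)
        rec = n2o_consistency(est, with_fe, without)
        assert not rec.available
        assert rec.consistent is None

    def test_simulator_output_consistent_end_to_end(self, noise_free_pair):
        """On noise-free simulator output the observed N2O excess matches the
        chemodenitrification prediction (both setups reduce the same nitrite
        amount microbially, so the excess is purely chemical)."""
        tc_fe, tc_ctrl = noise_free_pair
        est = partition_fe(tc_fe, tc_ctrl)
        rec = n2o_consistency(est, tc_fe, tc_ctrl)
        assert rec.available
        assert rec.ratio == pytest.approx(1.0, abs=0.15)
        assert rec.consistent


class TestBootstrap:
    def test_zero_noise_gives_zero_width(self):
        w, o = worked_example_inputs("low")
        lo, hi = bootstrap_uncertainty(w, o, B=200, seed=5)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(0.82 / 3.80)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        w = make_course("w", {"NO3": [(10, 10 - c) for c in rng.normal(1.1, 0.1, 3)],
                              "Fe2": [(4.5, 4.5 - c) for c in rng.normal(3.0, 0.2, 3)]})
        o = make_course("o", {"NO3": [(10, 10 - c) for c in rng.normal(0.8, 0.1, 3)]})
        assert bootstrap_uncertainty(w, o, B=500, seed=1) == \
            bootstrap_uncertainty(w, o, B=500, seed=1)

    def test_single_replicate_rejected(self):
        w = make_course("w", {"NO3": [(10, 9)], "Fe2": [(4.5, 1.5)]})
        o = make_course("o", {"NO3": [(10, 9.5)]})
        with pytest.raises(ValueError, match="noise-free"):
            bootstrap_uncertainty(w, o)

    def test_exhaustive_two_replicate_enumeration_matches_brute_force(self):
        """With 2 replicates per setup the 16 equally likely joint resamples
        can be enumerated by hand; the exhaustive bootstrap must match an
        independently coded enumeration exactly."""
        no3_w = [1.0, 1.2]
        fe_w = [3.0, 3.4]
        no3_o = [0.6, 0.8]
        w = make_course("w", {"NO3": [(10, 10 - c) for c in no3_w],
                              "Fe2": [(4.5, 4.5 - c) for c in fe_w]})
        o = make_course("o", {"NO3": [(10, 10 - c) for c in no3_o]})

        fracs = []
        for iw in itertools.product(range(2), repeat=2):
            for io in itertools.product(range(2), repeat=2):
                nw = np.mean([no3_w[i] for i in iw])
                fw = np.mean([fe_w[i] for i in iw])
                no = np.mean([no3_o[i] for i in io])
                fracs.append(min(max(2 * (nw - no), 0.0) / fw, 1.0))
        expect_lo, expect_hi = np.percentile(fracs, [2.5, 97.5])

        lo, hi = bootstrap_uncertainty(w, o, B="exhaustive")
        assert lo == pytest.approx(expect_lo, abs=1e-12)
        assert hi == pytest.approx(expect_hi, abs=1e-12)
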