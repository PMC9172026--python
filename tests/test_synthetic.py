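"""Synthetic study generator: ground truth, determinism, noise model."""

import numpy as np
import pandas as pd
import pytest

from photophase.rhythm_stats import averaged_level_test
from photophase.synthetic_data import (
    GeneSimSpec,
    InvalidSpecError,
    StudySimSpec,
    default_schemes,
    default_study,
    mean_curve,
    simulate_ct,
    simulate_series,
    simulate_study,
    true_acrophase,
)
from photophase.quantification import NormalizationSpec, relative_expression
from photophase.timeframes import (
    ClockTime,
    PeakRecord,
    circular_diff,
    classify_mode,
    to_midnight_frame,
    to_sunset_frame,
)


class TestTrueAcrophase:
    def test_anchor_examples(self, schemes):
        mm = GeneSimSpec("g", "Midnight/Midday", anchor_offset=-1.0)
        assert true_acrophase(mm, schemes["LD"]) == pytest.approx(18.0)
        ss = GeneSimSpec("g", "Sunset", anchor_offset=0.0)
        assert true_acrophase(ss, schemes["SD"]) == pytest.approx(10.0)

    def test_sunrise_gene_has_zero_zt_shift(self, schemes):
        spec = GeneSimSpec("g", "Sunrise", anchor_offset=5.6)
        t_ld = true_acrophase(spec, schemes["LD"])
        t_sd = true_acrophase(spec, schemes["SD"])
        assert t_ld == t_sd == pytest.approx(5.6)
        comp = classify_mode(
            PeakRecord("g", "LD", ClockTime(t_ld)),
            PeakRecord("g", "SD", ClockTime(t_sd)),
            schemes["LD"], schemes["SD"],
        )
        assert comp.mode == "Sunrise"
        assert comp.delta_zt == 0.0
        assert comp.delta_mnft > 0 and comp.delta_ssft > 0

    @pytest.mark.parametrize("mode", ["Sunrise", "Midnight/Midday", "Sunset"])
    def test_zero_shift_only_in_own_frame(self, schemes, mode):
        """The defining signature the classifier must detect: LD and SD
        acrophases coincide in the mode's own frame and nowhere else."""
        spec = GeneSimSpec("g", mode, anchor_offset=1.3)
        a = ClockTime(true_acrophase(spec, schemes["LD"]))
        b = ClockTime(true_acrophase(spec, schemes["SD"]))
        deltas = {
            "Sunrise": circular_diff(a.hours, b.hours),
            "Midnight/Midday": circular_diff(
                to_midnight_frame(a, schemes["LD"]).hours,
                to_midnight_frame(b, schemes["SD"]).hours,
            ),
            "Sunset": circular_diff(
                to_sunset_frame(a, schemes["LD"]).hours,
                to_sunset_frame(b, schemes["SD"]).hours,
            ),
        }
        assert deltas.pop(mode) == pytest.approx(0.0)
        assert all(d > 0 for d in deltas.values())


class TestSimulateSeries:
    def test_zero_noise_equals_mean_curve(self, schemes):
        spec = GeneSimSpec("g", "Sunset", noise_cv=0.0, n_harmonics=2)
        design = StudySimSpec(genes=(spec,), schemes=(schemes["LD"],), seed=1)
        s = simulate_series(spec, schemes["LD"], design)
        expected = np.repeat(
            mean_curve(spec, schemes["LD"], np.asarray(design.timepoints)),
            design.replicates,
        )
        assert np.array_equal(s.level, expected)

    def test_light_boost_only_in_light_and_not_projected(self, schemes):
        spec = GeneSimSpec("g", "Sunrise", amplitude=0.0, light_boost=1.5,
                           noise_cv=0.0)
        t = np.arange(1.0, 24.0, 2.0)
        ld = mean_curve(spec, schemes["LD"], t)
        dd = mean_curve(spec, schemes["LD-DD"], t)
        assert np.allclose(ld[t < 14], 1.5)
        assert np.allclose(ld[t >= 14], 1.0)
        assert np.allclose(dd, 1.0)

    def test_light_boost_detected_as_level_difference(self, schemes):
        """A light-driven gene shows significantly higher averaged levels
        under entrainment than in constant darkness."""
        spec = GeneSimSpec("boosted", "Sunrise", anchor_offset=2.0,
                           amplitude=0.3, light_boost=1.5)
        hits = 0
        for seed in range(20):
            design = StudySimSpec(genes=(spec,),
                                  schemes=default_schemes(), seed=seed)
            ld = simulate_series(spec, schemes["LD"], design)
            dd = simulate_series(spec, schemes["LD-DD"], design)
            res = averaged_level_test(ld, dd)
            hits += res.significant and res.direction == "LD"
        assert hits >= 18

    def test_invalid_spec_rejected(self, schemes):
        with pytest.raises(ValueError):
            GeneSimSpec("g", "Sunrise", amplitude=1.5, mesor=1.0)
        bad = GeneSimSpec("g", "Sunrise", second_peak=(12.0, -2.0),
                          noise_cv=0.0)
        with pytest.raises(InvalidSpecError):
            mean_curve(bad, schemes["LD"], np.arange(0.0, 24.0, 0.5))

    def test_second_peak_adds_local_maximum(self, schemes):
        spec = GeneSimSpec("g", "Sunrise", anchor_offset=5.0,
                           second_peak=(15.0, 0.5), noise_cv=0.0)
        t = np.arange(0.0, 24.0, 0.01)
        v = mean_curve(spec, schemes["LD"], t)
        is_max = (v > np.roll(v, 1)) & (v >= np.roll(v, -1))
        assert is_max.sum() == 2


class TestStudy:
    def test_seed_determinism(self):
        e1, t1 = simulate_study(default_study(11))
        e2, t2 = simulate_study(default_study(11))
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_distinct_seeds_share_ground_truth(self):
        e1, t1 = simulate_study(default_study(1))
        e2, t2 = simulate_study(default_study(2))
        pd.testing.assert_frame_equal(t1, t2)
        assert not np.allclose(e1.level, e2.level)

    def test_default_study_shape(self):
        study = default_study(0)
        expr, truth = simulate_study(study)
        assert truth.gene.nunique() == 12
        assert truth.groupby("gene").true_mode.first().value_counts().tolist() == [4, 4, 4]
        # 12 genes x 4 conditions x 12 timepoints x 4 replicates
        assert len(expr) == 12 * 4 * 12 * 4


class TestSimulateCt:
    def test_noise_free_ct_values(self, schemes):
        from photophase.cosinor import ExpressionSeries

        s = ExpressionSeries("g", "LD", [1.0, 3.0], [0, 0], [1.0, 4.0])
        ct = simulate_ct(s, base_ct=25.0)
        tgt = ct[ct.gene == "g"].set_index("zt").ct
        assert tgt[1.0] == pytest.approx(25.0)
        assert tgt[3.0] == pytest.approx(23.0)  # log2(4) cycles earlier

    def test_round_trip_to_fold_changes(self):
        expr, _ = simulate_study(default_study(5))
        sub = expr[(expr.condition == "LD")
                   & expr.gene.isin(["sunrise1", "sunset2"])]
        ct = simulate_ct(sub, noise_sd=0.0)
        spec = NormalizationSpec(("refA", "refB"), calibrator=("LD", 1.0, 0))
        out = relative_expression(ct, spec)
        merged = sub.merge(out, on=["gene", "condition", "zt", "replicate"],
                           suffixes=("_true", "_rec"))
        cal = sub[(sub.zt == 1.0) & (sub.replicate == 0)].set_index("gene").level
        fold_true = merged.level_true / merged.gene.map(cal)
        assert np.max(np.abs(merged.level_rec - fold_true)) < 1e-9

    def test_noisy_ct_correlates_with_truth(self):
        expr, _ = simulate_study(default_study(6))
        sub = expr[(expr.condition == "LD") & (expr.gene == "midnight1")]
        ct = simulate_ct(sub, noise_sd=0.1, seed=6)
        spec = NormalizationSpec(("refA", "refB"))
        out = relative_expression(ct, spec)
        merged = sub.merge(out, on=["gene", "condition", "zt", "replicate"],
                           suffixes=("_true", "_rec"))
        r = np.corrcoef(merged.level_true, merged.level_rec)[0, 1]
        assert r > 0.95

    def test_nonpositive_level_rejected(self):
        from photophase.cosinor import ExpressionSeries

        s = ExpressionSeries("g", "LD", [1.0], [0], [0.0])
        with pytest.raises(InvalidSpecError):
            simulate_ct(s)
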