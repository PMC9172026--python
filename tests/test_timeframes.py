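"""Circular frame conversions, shift widths and mode classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from photophase.timeframes import (
    ClockTime,
    IncompletePairError,
    InvalidFrameError,
    InvalidPairError,
    PeakRecord,
    PhotoperiodScheme,
    build_phase_table,
    circular_diff,
    classify_mode,
    to_midnight_frame,
    to_sunset_frame,
    to_zeitgeber,
)
from photophase import published

hours = st.floats(min_value=0.0, max_value=23.999, allow_nan=False)


class TestFrameConversion:
    @pytest.mark.parametrize(
        "zt, light_hours, expected_mnft, expected_ssft",
        [
            (5.60, 14.0, 10.60, 15.60),   # zebrafish Cry1aa under long days
            (9.17, 10.0, 16.17, 23.17),   # medaka Cry1ba under short days
            (19.00, 14.0, 0.00, 5.00),    # the midnight anchor maps to zero
            (14.00, 14.0, 19.00, 0.00),   # sunset maps to zero
        ],
    )
    def test_published_and_anchor_conversions(
        self, zt, light_hours, expected_mnft, expected_ssft
    ):
        scheme = PhotoperiodScheme("X", light_hours)
        t = ClockTime(zt)
        assert to_midnight_frame(t, scheme).hours == pytest.approx(expected_mnft)
        assert to_sunset_frame(t, scheme).hours == pytest.approx(expected_ssft)

    def test_projected_flag_propagates(self, schemes):
        t = ClockTime(2.67, "pZT")
        out = to_sunset_frame(t, schemes["LD-DD"])
        assert out.frame == "pSSFT"
        assert out.hours == pytest.approx(12.67)

    def test_frame_mismatch_rejected(self, schemes):
        with pytest.raises(InvalidFrameError):
            to_midnight_frame(ClockTime(5.0, "MNFT"), schemes["LD"])
        with pytest.raises(InvalidFrameError):
            to_sunset_frame(ClockTime(5.0, "pZT"), schemes["LD"])

    def test_round_trip_recovers_zt(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.uniform(0, 24)
            scheme = PhotoperiodScheme("X", rng.uniform(0.5, 23.5))
            ct = ClockTime(t)
            for convert in (to_midnight_frame, to_sunset_frame):
                back = to_zeitgeber(convert(ct, scheme), scheme)
                assert back.hours == pytest.approx(t % 24, abs=1e-9)


class TestCircularDiff:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(5.60, 20.31, 9.29), (23.31, 0.46, 1.15), (3.0, 3.0, 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert circular_diff(a, b) == pytest.approx(expected)

    @given(hours, hours, st.integers(min_value=-3, max_value=3))
    def test_metric_properties(self, a, b, k):
        d = circular_diff(a, b)
        assert 0.0 <= d <= 12.0
        assert d == pytest.approx(circular_diff(b, a))
        assert d == pytest.approx(circular_diff(a + 24 * k, b), abs=1e-6)

    @given(hours, hours, hours)
    def test_triangle_inequality(self, a, b, c):
        assert circular_diff(a, c) <= (
            circular_diff(a, b) + circular_diff(b, c) + 1e-9
        )


class TestClassifyMode:
    def _peak(self, gene, cond, zt, label="primary", frame="ZT"):
        return PeakRecord(gene, cond, ClockTime(zt, frame), label)

    def test_sunrise_synchronized_gene(self, schemes):
        comp = classify_mode(
            self._peak("zCry1aa", "LD", 5.60),
            self._peak("zCry1aa", "SD", 5.19),
            schemes["LD"], schemes["SD"],
        )
        assert comp.delta_zt == pytest.approx(0.41)
        assert comp.delta_mnft == pytest.approx(1.59)
        assert comp.delta_ssft == pytest.approx(3.59)
        assert comp.mode == "Sunrise" and not comp.tie

    def test_midnight_synchronized_gene(self, schemes):
        comp = classify_mode(
            self._peak("gCry1ba", "LD", 13.06),
            self._peak("gCry1ba", "SD", 11.05),
            schemes["LD"], schemes["SD"],
        )
        deltas = (comp.delta_zt, comp.delta_mnft, comp.delta_ssft)
        assert deltas == pytest.approx((2.01, 0.01, 1.99))
        assert comp.mode == "Midnight/Midday"

    def test_degenerate_identical_peaks_tie(self, schemes):
        comp = classify_mode(
            self._peak("g", "LD", 7.0), self._peak("g", "LD", 7.0),
            schemes["LD"], schemes["LD"],
        )
        assert (comp.delta_zt, comp.delta_mnft, comp.delta_ssft) == (0, 0, 0)
        assert comp.tie and comp.mode == "Sunrise"

    def test_swap_invariance(self, schemes):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = self._peak("g", "LD", rng.uniform(0, 24))
            b = self._peak("g", "SD", rng.uniform(0, 24))
            fwd = classify_mode(a, b, schemes["LD"], schemes["SD"])
            rev = classify_mode(b, a, schemes["SD"], schemes["LD"])
            assert fwd.mode == rev.mode
            assert fwd.delta_zt == pytest.approx(rev.delta_zt)
            assert fwd.delta_mnft == pytest.approx(rev.delta_mnft)
            assert fwd.delta_ssft == pytest.approx(rev.delta_ssft)

    def test_gene_mismatch_rejected(self, schemes):
        with pytest.raises(InvalidPairError):
            classify_mode(
                self._peak("a", "LD", 5.0), self._peak("b", "SD", 5.0),
                schemes["LD"], schemes["SD"],
            )


class TestPhaseTable:
    def test_zebrafish_modes(self, schemes):
        peaks = [
            p for p in published.peak_records("LD_SD") if p.gene.startswith("z")
        ]
        table = build_phase_table(peaks, schemes, [("LD", "SD")])
        modes = dict(zip(zip(table.gene, table.peak_label), table["mode"]))
        assert modes == {
            ("zCry1aa", "primary"): "Sunrise",
            ("zCry1aa", "second"): "Sunset",
            ("zCry1ab", "M"): "Midnight/Midday",
            ("zCry1ab", "E"): "Sunset",
            ("zCry1ba", "primary"): "Midnight/Midday",
            ("zCry1bb", "primary"): "Midnight/Midday",
            ("zCry2", "primary"): "Sunset",
            ("zCry4", "primary"): "Sunrise",
        }

    def test_fallback_reuses_primary_peak_flagged(self, schemes):
        peaks = [
            PeakRecord("g", "LD", ClockTime(5.60), "primary"),
            PeakRecord("g", "SD", ClockTime(5.19), "primary"),
            PeakRecord("g", "SD", ClockTime(20.31), "second"),
        ]
        table = build_phase_table(peaks, schemes, [("LD", "SD")])
        second = table[table.peak_label == "second"].iloc[0]
        assert second.partner_reused
        assert second.zt_a == pytest.approx(5.60)
        assert second.delta_zt == pytest.approx(9.29)

    def test_missing_primary_partner_names_gene(self, schemes):
        peaks = [PeakRecord("lonely", "LD", ClockTime(5.0), "primary")]
        with pytest.raises(IncompletePairError, match="lonely"):
            build_phase_table(peaks, schemes, [("LD", "SD")],
                              fallback_to_primary=False)

    def test_single_gene_single_pair_one_row(self, schemes):
        peaks = [
            PeakRecord("g", "LD", ClockTime(5.0)),
            PeakRecord("g", "SD", ClockTime(5.5)),
        ]
        assert len(build_phase_table(peaks, schemes, [("LD", "SD")])) == 1

    def test_six_genes_midnight_in_both_pairs(self, schemes):
        """Cross-table check: six genes stay midnight/midday-synchronized
        under entrained and free-running conditions alike."""
        modes = {}
        for which, pair in (("LD_SD", ("LD", "SD")), ("DD", ("LD-DD", "SD-DD"))):
            table = build_phase_table(
                published.peak_records(which), schemes, [pair]
            )
            for row in table.itertuples():
                modes.setdefault((row.gene, row.peak_label), []).append(row.mode)
        both_midnight = [
            gene
            for (gene, label), ms in modes.items()
            if len(ms) == 2 and set(ms) == {"Midnight/Midday"}
        ]
        assert sorted(both_midnight) == sorted(
            ["zCry1ba", "zCry1bb", "gCry1ab", "gCry1ba", "gCry2", "OlCry2"]
        )

    def test_report_rounding_half_away(self, schemes):
        peaks = [
            PeakRecord("g", "LD", ClockTime(5.125)),
            PeakRecord("g", "SD", ClockTime(5.0)),
        ]
        table = build_phase_table(peaks, schemes, [("LD", "SD")], decimals=2)
        assert table.iloc[0].zt_a == 5.13  # ties away from zero
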