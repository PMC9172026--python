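"""Published eye *Cry* acrophases for zebrafish, goldfish and medaka.

Reported cosinor peak times of cryptochrome (*Cry*) gene expression in the
eyes of three teleosts under long-day (LD, 14 h light : 10 h dark) and
short-day (SD, 10 h light : 14 h dark) photoperiods, and on the first day of
constant darkness after each entrainment (LD-DD, SD-DD). The ZT/pZT
acrophases are the *inputs* to the phase analysis; the frame-converted times
(MNFT/SSFT and projected variants), circular shift widths and
synchronization modes reported alongside them serve as a golden oracle for
:func:`photophase.pipeline.validate_against_golden` and the test suite.

For ``zCry1aa`` a second peak exists only under SD; its LD comparison
partner is the LD primary peak (``ld_reused`` below), mirroring the
parenthesized reuse in the source tables.
"""

from __future__ import annotations

import pandas as pd

from .timeframes import ClockTime, PeakRecord, PhotoperiodScheme

__all__ = [
    "schemes",
    "golden_frame",
    "peak_records",
    "peak_frame",
    "TABLE_LD_SD",
    "TABLE_DD",
]

# gene, peak_label, species, zt_a, zt_b, mnft_a, mnft_b, ssft_a, ssft_b,
# delta_zt, delta_mnft, delta_ssft, mode, ld_reused
# (a = LD or LD-DD, b = SD or SD-DD)
TABLE_LD_SD = [
    ("zCry1aa", "primary", "zebrafish", 5.60, 5.19, 10.60, 12.19, 15.60, 19.19, 0.41, 1.59, 3.59, "Sunrise", False),
    ("zCry1aa", "second", "zebrafish", 5.60, 20.31, 10.60, 3.31, 15.60, 10.31, 9.29, 7.29, 5.29, "Sunset", True),
    ("zCry1ab", "M", "zebrafish", 23.66, 21.51, 4.66, 4.51, 9.66, 11.51, 2.15, 0.15, 1.85, "Midnight/Midday", False),
    ("zCry1ab", "E", "zebrafish", 13.00, 9.03, 18.00, 16.03, 23.00, 23.03, 3.97, 1.97, 0.03, "Sunset", False),
    ("zCry1ba", "primary", "zebrafish", 13.31, 10.46, 18.31, 17.46, 23.31, 0.46, 2.85, 0.85, 1.15, "Midnight/Midday", False),
    ("zCry1bb", "primary", "zebrafish", 11.12, 9.98, 16.12, 16.98, 21.12, 23.98, 1.14, 0.86, 2.86, "Midnight/Midday", False),
    ("zCry2", "primary", "zebrafish", 22.97, 18.49, 3.97, 1.49, 8.97, 8.49, 4.48, 2.48, 0.48, "Sunset", False),
    ("zCry4", "primary", "zebrafish", 10.38, 10.23, 15.38, 17.23, 20.38, 0.23, 0.15, 1.85, 3.85, "Sunrise", False),
    ("gCry1aa", "primary", "goldfish", 5.04, 4.06, 10.04, 11.06, 15.04, 18.06, 0.98, 1.02, 3.02, "Sunrise", False),
    ("gCry1ab", "primary", "goldfish", 12.61, 10.14, 17.61, 17.14, 22.61, 0.14, 2.47, 0.47, 1.53, "Midnight/Midday", False),
    ("gCry1ba", "primary", "goldfish", 13.06, 11.05, 18.06, 18.05, 23.06, 1.05, 2.01, 0.01, 1.99, "Midnight/Midday", False),
    ("gCry1bb", "primary", "goldfish", 10.81, 9.44, 15.81, 16.44, 20.81, 23.44, 1.37, 0.63, 2.63, "Midnight/Midday", False),
    ("gCry2", "primary", "goldfish", 22.02, 19.59, 3.02, 2.59, 8.02, 9.59, 2.43, 0.43, 1.57, "Midnight/Midday", False),
    ("gCry4", "primary", "goldfish", 13.18, 12.47, 18.18, 19.47, 23.18, 2.47, 0.71, 1.29, 3.29, "Sunrise", False),
    ("OlCry1aa", "primary", "medaka", 3.85, 4.77, 8.85, 11.77, 13.85, 18.77, 0.92, 2.92, 4.92, "Sunrise", False),
    ("OlCry1ab", "primary", "medaka", 2.68, 1.37, 7.68, 8.37, 12.68, 15.37, 1.31, 0.69, 2.69, "Midnight/Midday", False),
    ("OlCry1ba", "primary", "medaka", 15.42, 9.17, 20.42, 16.17, 1.42, 23.17, 6.25, 4.25, 2.25, "Sunset", False),
    ("OlCry2", "primary", "medaka", 4.08, 1.94, 9.08, 8.94, 14.08, 15.94, 2.14, 0.14, 1.86, "Midnight/Midday", False),
]

TABLE_DD = [
    ("zCry1aa", "primary", "zebrafish", 2.67, 21.24, 7.67, 4.24, 12.67, 11.24, 5.43, 3.43, 1.43, "Sunset", False),
    ("zCry1ab", "M", "zebrafish", 1.80, 22.12, 6.80, 5.12, 11.80, 12.12, 3.68, 1.68, 0.32, "Sunset", False),
    ("zCry1ab", "E", "zebrafish", 11.86, 8.58, 16.86, 15.58, 21.86, 22.58, 3.28, 1.28, 0.72, "Sunset", False),
    ("zCry1ba", "primary", "zebrafish", 12.61, 9.74, 17.61, 16.74, 22.61, 23.74, 2.87, 0.87, 1.13, "Midnight/Midday", False),
    ("zCry1bb", "primary", "zebrafish", 11.29, 8.76, 16.29, 15.76, 21.29, 22.76, 2.53, 0.53, 1.47, "Midnight/Midday", False),
    ("zCry2", "primary", "zebrafish", 21.31, 18.28, 2.31, 1.28, 7.31, 8.28, 3.03, 1.03, 0.97, "Sunset", False),
    ("zCry4", "primary", "zebrafish", 10.12, 8.49, 15.12, 15.49, 20.12, 22.49, 1.63, 0.37, 2.37, "Midnight/Midday", False),
    ("gCry1aa", "primary", "goldfish", 2.67, 22.74, 7.67, 5.74, 12.67, 12.74, 3.93, 1.93, 0.07, "Sunset", False),
    ("gCry1ab", "primary", "goldfish", 13.47, 10.58, 18.47, 17.58, 23.47, 0.58, 2.89, 0.89, 1.11, "Midnight/Midday", False),
    ("gCry1ba", "primary", "goldfish", 12.59, 10.08, 17.59, 17.08, 22.59, 0.08, 2.51, 0.51, 1.49, "Midnight/Midday", False),
    ("gCry1bb", "primary", "goldfish", 12.42, 9.16, 17.42, 16.16, 22.42, 23.16, 3.26, 1.26, 0.74, "Sunset", False),
    ("gCry2", "primary", "goldfish", 23.08, 21.00, 4.08, 4.00, 9.08, 11.00, 2.08, 0.08, 1.92, "Midnight/Midday", False),
    ("gCry4", "primary", "goldfish", 14.69, 11.95, 19.69, 18.95, 0.69, 1.95, 2.74, 0.74, 1.26, "Midnight/Midday", False),
    ("OlCry1aa", "primary", "medaka", 23.49, 22.27, 4.49, 5.27, 9.49, 12.27, 1.22, 0.78, 2.78, "Midnight/Midday", False),
    ("OlCry1ab", "primary", "medaka", 1.74, 1.00, 6.74, 8.00, 11.74, 15.00, 0.74, 1.26, 3.26, "Sunrise", False),
    ("OlCry1ba", "primary", "medaka", 11.68, 10.99, 16.68, 17.99, 21.68, 0.99, 0.69, 1.31, 3.31, "Sunrise", False),
    ("OlCry2", "primary", "medaka", 23.12, 20.47, 4.12, 3.47, 9.12, 10.47, 2.65, 0.65, 1.35, "Midnight/Midday", False),
]

_COLUMNS = [
    "gene", "peak_label", "species",
    "zt_a", "zt_b", "mnft_a", "mnft_b", "ssft_a", "ssft_b",
    "delta_zt", "delta_mnft", "delta_ssft", "mode", "ld_reused",
]

_PAIRS = {"LD_SD": ("LD", "SD"), "DD": ("LD-DD", "SD-DD")}
_TABLES = {"LD_SD": TABLE_LD_SD, "DD": TABLE_DD}


def schemes() -> dict[str, PhotoperiodScheme]:
    """The four photoperiod schemes of the study, keyed by label."""
    return {
        "LD": PhotoperiodScheme("LD", 14.0),
        "SD": PhotoperiodScheme("SD", 10.0),
        "LD-DD": PhotoperiodScheme("LD-DD", 14.0, projected=True, entrainment_label="LD"),
        "SD-DD": PhotoperiodScheme("SD-DD", 10.0, projected=True, entrainment_label="SD"),
    }


def golden_frame(which: str = "LD_SD") -> pd.DataFrame:
    """Published phase table (``"LD_SD"`` or ``"DD"``) as a DataFrame."""
    cond_a, cond_b = _PAIRS[which]
    df = pd.DataFrame(_TABLES[which], columns=_COLUMNS)
    df.insert(3, "condition_a", cond_a)
    df.insert(4, "condition_b", cond_b)
    return df


def peak_records(which: str = "LD_SD") -> list[PeakRecord]:
    """The ZT/pZT acrophases as input peak records.

    Reused entries (the LD partner of ``zCry1aa``'s SD-only second peak) are
    omitted: the phase tabulator recreates them via its explicit
    primary-peak fallback.
    """
    cond_a, cond_b = _PAIRS[which]
    frame = "pZT" if which == "DD" else "ZT"
    records: list[PeakRecord] = []
    for row in _TABLES[which]:
        gene, label, _species, zt_a, zt_b = row[:5]
        ld_reused = row[-1]
        if not ld_reused:
            records.append(
                PeakRecord(gene, cond_a, ClockTime(zt_a, frame), label)
            )
        records.append(PeakRecord(gene, cond_b, ClockTime(zt_b, frame), label))
    return records


def peak_frame() -> pd.DataFrame:
    """All input acrophases as a long peak-record table (both pairs)."""
    rows = []
    for which in ("LD_SD", "DD"):
        for rec in peak_records(which):
            rows.append(
                {
                    "gene": rec.gene,
                    "condition": rec.condition,
                    "peak_label": rec.peak_label,
                    "peak_time_zt": rec.peak_time.hours,
                }
            )
    return pd.DataFrame(rows)
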