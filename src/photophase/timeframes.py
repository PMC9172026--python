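"""Circular time arithmetic on the 24 h day for photoperiodic phase analysis.

A gene-expression peak measured under two photoperiods (e.g. long day, 14 h
light : 10 h dark, versus short day, 10 h light : 14 h dark) can be expressed
in three reference frames:

* **ZT** (Zeitgeber time) — hours since lights-on (sunrise anchor, ZT 0);
* **MNFT** (midnight-fitting time) — hours since the midpoint of the dark
  period (anchor ``12 + L/2`` for an ``L`` h light period);
* **SSFT** (sunset-fitting time) — hours since lights-off (anchor ``L``).

Projected variants (pZT, pMNFT, pSSFT) carry the same arithmetic into
constant darkness, using the anchors of the preceding entrainment cycle.

The frame in which a peak shifts *least* between two photoperiods identifies
the synchronization mode of the underlying oscillator: ``Sunrise``,
``Midnight/Midday`` or ``Sunset``. This module provides the frame
conversions, the circular shift widths, and the minimum-shift classifier,
plus a tabulator producing one row per gene × peak × condition pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MODE_ORDER",
    "PhotoperiodScheme",
    "ClockTime",
    "PeakRecord",
    "PhaseComparison",
    "InvalidFrameError",
    "InvalidPairError",
    "IncompletePairError",
    "to_midnight_frame",
    "to_sunset_frame",
    "to_zeitgeber",
    "circular_diff",
    "classify_mode",
    "compare_peaks",
    "build_phase_table",
    "round_half_away",
]

#: Synchronization modes in canonical (sunrise-first) order; doubles as the
#: tie-break order when two frames give the same shift width.
MODE_ORDER: tuple[str, str, str] = ("Sunrise", "Midnight/Midday", "Sunset")

_BASE_FRAMES = ("ZT", "MNFT", "SSFT")
_FRAMES = _BASE_FRAMES + tuple("p" + f for f in _BASE_FRAMES)


class InvalidFrameError(ValueError):
    """A time was supplied in a frame the operation does not accept."""


class InvalidPairError(ValueError):
    """Two peaks cannot be compared (gene or peak-label mismatch)."""


class IncompletePairError(KeyError):
    """A requested condition pair lacks a partner peak for some gene."""


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (report convention)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class PhotoperiodScheme:
    """A named light:dark regimen on a 24 h cycle.

    Parameters
    ----------
    label:
        Condition name, e.g. ``"LD"``, ``"SD"``, ``"LD-DD"``.
    light_hours:
        Length ``L`` of the light period in hours, ``0 < L < 24``. For a
        projected (constant-dark) scheme this is the light length of the
        entrainment cycle.
    projected:
        True for constant-dark conditions; all anchors are then "projected"
        from the preceding entrainment cycle and times are reported in the
        projected frames (pZT/pMNFT/pSSFT).
    entrainment_label:
        For projected schemes, the label of the entrainment condition.
    """

    label: str
    light_hours: float
    projected: bool = False
    entrainment_label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.light_hours < 24.0:
            raise ValueError(
                f"light_hours must lie in (0, 24), got {self.light_hours!r}"
            )

    @property
    def sunrise(self) -> float:
        """Lights-on anchor (ZT 0)."""
        return 0.0

    @property
    def sunset(self) -> float:
        """Lights-off anchor (ZT L)."""
        return self.light_hours

    @property
    def midnight(self) -> float:
        """Midpoint of the dark period, ZT ``12 + L/2``."""
        return 12.0 + self.light_hours / 2.0

    def frame(self, base: str) -> str:
        """Frame name for this scheme: ``base`` or its projected variant."""
        if base not in _BASE_FRAMES:
            raise InvalidFrameError(f"unknown base frame {base!r}")
        return ("p" + base) if self.projected else base


@dataclass(frozen=True)
class ClockTime:
    """A time of day in hours, tagged with its reference frame.

    ``hours`` is reduced modulo 24 on construction.
    """

    hours: float
    frame: str = "ZT"

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise InvalidFrameError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "hours", float(self.hours) % 24.0)

    @property
    def projected(self) -> bool:
        return self.frame.startswith("p")


def _require_zeitgeber(t: ClockTime, scheme: PhotoperiodScheme) -> None:
    if t.frame not in ("ZT", "pZT"):
        raise InvalidFrameError(
            f"expected a ZT/pZT time, got frame {t.frame!r}"
        )
    if t.projected != scheme.projected:
        raise InvalidFrameError(
            f"frame {t.frame!r} does not match projected={scheme.projected} "
            f"of scheme {scheme.label!r}"
        )


def to_midnight_frame(t: ClockTime, scheme: PhotoperiodScheme) -> ClockTime:
    """Re-express a ZT/pZT time as hours since (projected) midnight.

    MNFT = (t − (12 + L/2)) mod 24; the midnight anchor is ZT 19 for a
    14 h light period and ZT 17 for 10 h.
    """
    _require_zeitgeber(t, scheme)
    return ClockTime((t.hours - scheme.midnight) % 24.0, scheme.frame("MNFT"))


def to_sunset_frame(t: ClockTime, scheme: PhotoperiodScheme) -> ClockTime:
    """Re-express a ZT/pZT time as hours since (projected) lights-off.

    SSFT = (t − L) mod 24.
    """
    _require_zeitgeber(t, scheme)
    return ClockTime((t.hours - scheme.sunset) % 24.0, scheme.frame("SSFT"))


def to_zeitgeber(t: ClockTime, scheme: PhotoperiodScheme) -> ClockTime:
    """Invert a MNFT/SSFT (or projected) time back to ZT/pZT."""
    if t.projected != scheme.projected:
        raise InvalidFrameError(
            f"frame {t.frame!r} does not match projected={scheme.projected}"
        )
    base = t.frame.lstrip("p") if t.projected else t.frame
    if base == "ZT":
        return t
    if base == "MNFT":
        anchor = scheme.midnight
    elif base == "SSFT":
        anchor = scheme.sunset
    else:  # pragma: no cover - _FRAMES guards this
        raise InvalidFrameError(f"unknown frame {t.frame!r}")
    return ClockTime((t.hours + anchor) % 24.0, scheme.frame("ZT"))


def circular_diff(a: float, b: float) -> float:
    """Shorter-arc distance between two clock times on the 24 h circle.

    Always in [0, 12]; e.g. |5.60 − 20.31| = 14.71 h wraps to 9.29 h.
    """
    d = abs(float(a) - float(b)) % 24.0
    return min(d, 24.0 - d)


@dataclass(frozen=True)
class PeakRecord:
    """One labeled expression peak (acrophase) for a gene × condition.

    ``peak_label`` distinguishes multiple peaks of one gene: ``primary`` for
    a single peak, ``M``/``E`` for morning/evening peaks of a bimodal
    profile, ``second`` for an extra peak whose partner condition is
    unimodal.
    """

    gene: str
    condition: str
    peak_time: ClockTime
    peak_label: str = "primary"


@dataclass(frozen=True)
class PhaseComparison:
    """Shift widths of one peak between two photoperiod conditions.

    ``delta_zt``/``delta_mnft``/``delta_ssft`` are circular distances (≤ 12 h)
    between the two conditions' peak times in each frame; ``mode`` names the
    frame achieving the minimum, interpreted as the synchronization mode.
    """

    gene: str
    peak_label: str
    condition_a: str
    condition_b: str
    zt_a: float
    zt_b: float
    mnft_a: float
    mnft_b: float
    ssft_a: float
    ssft_b: float
    delta_zt: float
    delta_mnft: float
    delta_ssft: float
    mode: str
    tie: bool = False
    projected: bool = False
    partner_reused: bool = False

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "peak_label": self.peak_label,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "zt_a": self.zt_a,
            "zt_b": self.zt_b,
            "mnft_a": self.mnft_a,
            "mnft_b": self.mnft_b,
            "ssft_a": self.ssft_a,
            "ssft_b": self.ssft_b,
            "delta_zt": self.delta_zt,
            "delta_mnft": self.delta_mnft,
            "delta_ssft": self.delta_ssft,
            "mode": self.mode,
            "tie": self.tie,
            "projected": self.projected,
            "partner_reused": self.partner_reused,
        }


def classify_mode(
    peak_a: PeakRecord,
    peak_b: PeakRecord,
    scheme_a: PhotoperiodScheme,
    scheme_b: PhotoperiodScheme,
    *,
    partner_reused: bool = False,
) -> PhaseComparison:
    """Classify one peak's photoperiodic response by the minimum-shift rule.

    The peak is expressed in the sunrise (ZT), midnight (MNFT) and sunset
    (SSFT) frames under both schemes; the circular shift width between the
    conditions is computed in each frame, and the frame with the smallest
    shift gives the synchronization mode. Ties at full floating-point
    precision are broken in favour of the first frame in :data:`MODE_ORDER`
    and flagged with ``tie=True``.
    """
    if peak_a.gene != peak_b.gene or peak_a.peak_label != peak_b.peak_label:
        raise InvalidPairError(
            f"cannot compare {peak_a.gene}/{peak_a.peak_label} with "
            f"{peak_b.gene}/{peak_b.peak_label}"
        )
    for peak, scheme in ((peak_a, scheme_a), (peak_b, scheme_b)):
        if peak.condition != scheme.label:
            raise InvalidPairError(
                f"peak condition {peak.condition!r} does not match scheme "
                f"{scheme.label!r}"
            )

    ta, tb = peak_a.peak_time, peak_b.peak_time
    mn_a, mn_b = to_midnight_frame(ta, scheme_a), to_midnight_frame(tb, scheme_b)
    ss_a, ss_b = to_sunset_frame(ta, scheme_a), to_sunset_frame(tb, scheme_b)

    deltas = (
        circular_diff(ta.hours, tb.hours),
        circular_diff(mn_a.hours, mn_b.hours),
        circular_diff(ss_a.hours, ss_b.hours),
    )
    lo = min(deltas)
    winners = [i for i, d in enumerate(deltas) if abs(d - lo) < 1e-9]
    mode = MODE_ORDER[winners[0]]
    return PhaseComparison(
        gene=peak_a.gene,
        peak_label=peak_a.peak_label,
        condition_a=peak_a.condition,
        condition_b=peak_b.condition,
        zt_a=ta.hours,
        zt_b=tb.hours,
        mnft_a=mn_a.hours,
        mnft_b=mn_b.hours,
        ssft_a=ss_a.hours,
        ssft_b=ss_b.hours,
        delta_zt=deltas[0],
        delta_mnft=deltas[1],
        delta_ssft=deltas[2],
        mode=mode,
        tie=len(winners) > 1,
        projected=scheme_a.projected and scheme_b.projected,
        partner_reused=partner_reused,
    )


def compare_peaks(
    peaks: Iterable[PeakRecord],
    schemes: Mapping[str, PhotoperiodScheme],
    pairs: Sequence[tuple[str, str]],
    *,
    fallback_to_primary: bool = True,
) -> list[PhaseComparison]:
    """Pair up peaks across conditions and classify each one.

    For every requested condition pair and every gene × peak-label present in
    either condition, the partner peak is looked up in the other condition.
    A missing partner for a non-primary label falls back to that condition's
    primary peak when ``fallback_to_primary`` is set (the comparison row is
    then flagged ``partner_reused``); a missing primary partner raises
    :class:`IncompletePairError`.
    """
    index: dict[tuple[str, str, str], PeakRecord] = {}
    order: list[tuple[str, str]] = []
    for p in peaks:
        key = (p.gene, p.peak_label, p.condition)
        if key in index:
            raise ValueError(f"duplicate peak record for {key}")
        index[key] = p
        if (p.gene, p.peak_label) not in order:
            order.append((p.gene, p.peak_label))

    def lookup(gene: str, label: str, cond: str) -> tuple[PeakRecord, bool]:
        rec = index.get((gene, label, cond))
        if rec is not None:
            return rec, False
        if fallback_to_primary and label != "primary":
            primary = index.get((gene, "primary", cond))
            if primary is not None:
                return replace(primary, peak_label=label), True
        raise IncompletePairError(
            f"gene {gene!r}: no {label!r} peak under condition {cond!r}"
        )

    out: list[PhaseComparison] = []
    for cond_a, cond_b in pairs:
        for scheme_label in (cond_a, cond_b):
            if scheme_label not in schemes:
                raise KeyError(f"no scheme defined for condition {scheme_label!r}")
        for gene, label in order:
            in_a = (gene, label, cond_a) in index
            in_b = (gene, label, cond_b) in index
            if not (in_a or in_b):
                continue
            rec_a, reused_a = lookup(gene, label, cond_a)
            rec_b, reused_b = lookup(gene, label, cond_b)
            out.append(
                classify_mode(
                    rec_a,
                    rec_b,
                    schemes[cond_a],
                    schemes[cond_b],
                    partner_reused=reused_a or reused_b,
                )
            )
    return out


def build_phase_table(
    peaks: Iterable[PeakRecord],
    schemes: Mapping[str, PhotoperiodScheme],
    pairs: Sequence[tuple[str, str]],
    *,
    fallback_to_primary: bool = True,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Tabulate phase comparisons: one row per gene × peak label × pair.

    Columns give both conditions' peak times in all three frames, the three
    circular shift widths, and the synchronization mode. With ``decimals``
    set, times and deltas are rounded half-away-from-zero for reporting;
    otherwise full precision is retained.
    """
    comps = compare_peaks(
        peaks, schemes, pairs, fallback_to_primary=fallback_to_primary
    )
    columns = list(PhaseComparison.__dataclass_fields__)
    df = pd.DataFrame([c.as_dict() for c in comps], columns=columns)
    if decimals is not None and not df.empty:
        value_cols = [
            "zt_a", "zt_b", "mnft_a", "mnft_b", "ssft_a", "ssft_b",
            "delta_zt", "delta_mnft", "delta_ssft",
        ]
        for col in value_cols:
            df[col] = df[col].map(lambda x: round_half_away(x, decimals))
    return df
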