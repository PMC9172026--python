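"""Synthetic qPCR-like expression time courses with known ground truth.

Generates replicate relative-expression series (and optionally raw Ct
tables) that emulate eye clock-gene profiles: 24 h-periodic mean curves
anchored to sunrise, midnight or sunset, sampled every 2 h (ZT1–ZT23) with a
few replicates per point, multiplicative lognormal noise whose spread grows
with the mean, an optional light-driven expression boost that disappears in
constant darkness, and optional secondary peaks. Because each gene's peak is
tied to its mode's anchor, the long-day and short-day acrophases have zero
circular difference in that mode's own frame and nonzero differences in the
others — the defining signature the minimum-shift classifier must recover.

All randomness flows through :class:`numpy.random.Generator` seeded from the
study seed plus stable per-series keys, so identical seeds give identical
datasets regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cosinor import ExpressionSeries
from .timeframes import PhotoperiodScheme

__all__ = [
    "MODES",
    "GeneSimSpec",
    "StudySimSpec",
    "InvalidSpecError",
    "mode_anchor",
    "true_acrophase",
    "mean_curve",
    "simulate_series",
    "simulate_study",
    "simulate_ct",
    "default_schemes",
    "default_study",
]

MODES = ("Sunrise", "Midnight/Midday", "Sunset")

_PERIOD = 24.0
#: Width parameter of the secondary-peak bump (concentration of the
#: von-Mises-shaped term); 6 gives a ~3 h half-width at 2 h sampling.
_BUMP_KAPPA = 6.0
#: Geometric decay of higher-harmonic weights in multi-harmonic genes.
_HARMONIC_DECAY = 0.5


class InvalidSpecError(ValueError):
    """A simulation spec yields non-positive expression levels."""


@dataclass(frozen=True)
class GeneSimSpec:
    """Ground-truth description of one simulated gene.

    The peak sits at ``anchor(mode) + anchor_offset`` in every condition, so
    the gene is, by construction, synchronized to its mode's reference
    event. ``light_boost`` multiplies the mean curve during the light period
    of non-projected schemes only, emulating light-driven genes whose
    daytime peak collapses in constant darkness. ``second_peak`` is an
    optional ``(offset_hours_from_primary, amplitude)`` bump. ``noise_cv``
    is the coefficient of variation of the multiplicative lognormal noise.
    """

    gene: str
    mode: str
    anchor_offset: float = 0.0
    amplitude: float = 0.7
    mesor: float = 1.0
    n_harmonics: int = 1
    second_peak: tuple[float, float] | None = None
    light_boost: float = 1.0
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mesor <= 0:
            raise ValueError("mesor must be positive")
        if not 0 <= self.amplitude < self.mesor:
            raise ValueError("amplitude must lie in [0, mesor) to keep levels positive")
        if not 1 <= self.n_harmonics <= 3:
            raise ValueError("n_harmonics must be 1..3")
        if self.light_boost < 1:
            raise ValueError("light_boost must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class StudySimSpec:
    """Design of a full simulated study (genes × conditions × grid)."""

    genes: tuple[GeneSimSpec, ...]
    schemes: tuple[PhotoperiodScheme, ...]
    timepoints: tuple[float, ...] = tuple(float(z) for z in range(1, 24, 2))
    replicates: int = 4
    seed: int = 0


def default_schemes() -> tuple[PhotoperiodScheme, ...]:
    """LD (14L10D), SD (10L14D) and their projected DD counterparts."""
    return (
        PhotoperiodScheme("LD", 14.0),
        PhotoperiodScheme("SD", 10.0),
        PhotoperiodScheme("LD-DD", 14.0, projected=True, entrainment_label="LD"),
        PhotoperiodScheme("SD-DD", 10.0, projected=True, entrainment_label="SD"),
    )


def default_study(seed: int = 0) -> StudySimSpec:
    """The default study: 12 genes, four per synchronization mode.

    Sampling design mirrors the study conditions: 12 time points (ZT1–ZT23,
    every 2 h), 4 replicates per point, 4 conditions, noise CV 0.2.
    """
    offsets = (-2.0, 0.0, 2.5, 5.0)
    genes = tuple(
        GeneSimSpec(
            gene=f"{prefix}{i + 1}",
            mode=mode,
            anchor_offset=off,
        )
        for mode, prefix in zip(MODES, ("sunrise", "midnight", "sunset"))
        for i, off in enumerate(offsets)
    )
    return StudySimSpec(genes=genes, schemes=default_schemes(), seed=seed)


def mode_anchor(mode: str, scheme: PhotoperiodScheme) -> float:
    """Anchor time (ZT hours) of a synchronization mode under a scheme."""
    if mode == "Sunrise":
        return scheme.sunrise
    if mode == "Midnight/Midday":
        return scheme.midnight
    if mode == "Sunset":
        return scheme.sunset
    raise ValueError(f"unknown mode {mode!r}")


def true_acrophase(spec: GeneSimSpec, scheme: PhotoperiodScheme) -> float:
    """Ground-truth peak time in ZT hours: anchor(mode) + offset, mod 24."""
    return (mode_anchor(spec.mode, scheme) + spec.anchor_offset) % _PERIOD


def mean_curve(
    spec: GeneSimSpec, scheme: PhotoperiodScheme, t: np.ndarray
) -> np.ndarray:
    """Noise-free mean expression at times ``t`` (ZT hours)."""
    t = np.asarray(t, dtype=float) % _PERIOD
    phi = true_acrophase(spec, scheme)
    weights = np.array([_HARMONIC_DECAY**j for j in range(spec.n_harmonics)])
    theta = 2.0 * np.pi * (t[:, None] - phi) / _PERIOD
    shape = (np.cos(theta * np.arange(1, spec.n_harmonics + 1)) @ weights) / weights.sum()
    level = spec.mesor + spec.amplitude * shape
    if spec.second_peak is not None:
        off, amp2 = spec.second_peak
        t2 = (phi + off) % _PERIOD
        level = level + amp2 * np.exp(
            _BUMP_KAPPA * (np.cos(2.0 * np.pi * (t - t2) / _PERIOD) - 1.0)
        )
    if not scheme.projected and spec.light_boost != 1.0:
        level = np.where(t < scheme.light_hours, level * spec.light_boost, level)
    if np.any(level <= 0):
        raise InvalidSpecError(
            f"{spec.gene}/{scheme.label}: mean curve is non-positive"
        )
    return level


def _series_rng(seed: int, *keys: str) -> np.random.Generator:
    tags = [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tags]))


def simulate_series(
    spec: GeneSimSpec,
    scheme: PhotoperiodScheme,
    design: StudySimSpec,
    rng: np.random.Generator | None = None,
) -> ExpressionSeries:
    """Simulate one gene × condition replicate time course.

    Replicate values are the mean curve multiplied by lognormal noise with
    unit mean and coefficient of variation ``spec.noise_cv``; with
    ``noise_cv = 0`` the replicates equal the mean curve exactly.
    """
    if rng is None:
        rng = _series_rng(design.seed, spec.gene, scheme.label)
    times = np.repeat(np.asarray(design.timepoints, dtype=float), design.replicates)
    reps = np.tile(np.arange(design.replicates), len(design.timepoints))
    mean = np.repeat(mean_curve(spec, scheme, np.asarray(design.timepoints)),
                     design.replicates)
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(mean))
    else:
        noise = np.ones_like(mean)
    return ExpressionSeries(
        gene=spec.gene,
        condition=scheme.label,
        time=times,
        replicate=reps,
        level=mean * noise,
    )


def simulate_study(design: StudySimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every gene × condition of a study.

    Returns ``(expression, truth)``: the long-format expression table
    (gene, condition, zt, replicate, level) and the ground-truth table
    (gene, condition, true_acrophase [ZT hours], true_mode).
    """
    frames, truth_rows = [], []
    for spec in design.genes:
        for scheme in design.schemes:
            frames.append(simulate_series(spec, scheme, design).to_frame())
            truth_rows.append(
                {
                    "gene": spec.gene,
                    "condition": scheme.label,
                    "true_acrophase": true_acrophase(spec, scheme),
                    "true_mode": spec.mode,
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


def simulate_ct(
    series: ExpressionSeries | Iterable[ExpressionSeries] | pd.DataFrame,
    reference_specs: Mapping[str, float] | None = None,
    base_ct: float = 25.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Back-convert expression levels into a raw Ct table.

    Target Ct = ``base_ct - log2(level)`` plus Gaussian technical noise of
    standard deviation ``noise_sd`` cycles; each reference gene in
    ``reference_specs`` (name → base Ct, default two flat references) is
    generated flat across all samples with the same technical noise. With
    ``noise_sd = 0`` the table round-trips through
    :func:`photophase.quantification.relative_expression` to the input
    fold-changes exactly.
    """
    if reference_specs is None:
        reference_specs = {"refA": 20.0, "refB": 22.0}
    if isinstance(series, ExpressionSeries):
        df = series.to_frame()
    elif isinstance(series, pd.DataFrame):
        df = series.copy()
    else:
        df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    if np.any(df["level"] <= 0):
        raise InvalidSpecError("expression levels must be positive to derive Ct")

    rng = _series_rng(seed, "ct")
    targets = df.copy()
    targets["ct"] = (
        base_ct
        - np.log2(targets["level"].to_numpy())
        + (rng.normal(0.0, noise_sd, len(targets)) if noise_sd > 0 else 0.0)
    )
    targets = targets.drop(columns=["level"])

    samples = df[["condition", "zt", "replicate"]].drop_duplicates()
    ref_frames = []
    for ref_gene, ref_base in reference_specs.items():
        ref = samples.copy()
        ref.insert(0, "gene", ref_gene)
        ref["ct"] = ref_base + (
            rng.normal(0.0, noise_sd, len(ref)) if noise_sd > 0 else 0.0
        )
        ref_frames.append(ref)
    return pd.concat([targets] + ref_frames, ignore_index=True)
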