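"""End-to-end orchestration: quantification → cosinor → phase classification → stats.

The pipeline accepts any of the three input schemas (raw Ct, relative
expression, or pre-extracted peaks) and runs the remaining stages, emitting
per-gene fit summaries, a labeled peak table, the phase/mode table for the
configured condition pairs, and the nonparametric statistics. Per-gene
failures are isolated and logged so a batch completes; every discretionary
decision taken for a gene (tie-broken mode, reused primary peak as a
comparison partner) is logged at info level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .cosinor import (
    ExpressionSeries,
    NoAcrophaseError,
    extract_acrophases,
    fit_cosinor,
    label_peaks,
)
from .io import detect_schema, peaks_from_frame, read_schemes, read_table
from .quantification import NormalizationSpec, relative_expression
from .rhythm_stats import (
    InsufficientDataError,
    averaged_level_test,
    timepoint_test,
)
from .synthetic_data import default_schemes
from .timeframes import (
    PeakRecord,
    PhotoperiodScheme,
    build_phase_table,
    round_half_away,
)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "Discrepancy",
    "run_pipeline",
    "validate_against_golden",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the input table.

    ``pairs`` are the condition pairs classified for synchronization mode;
    ``level_pairs`` the pairs compared for averaged expression level
    (entrained vs free-running by default).
    """

    schemes: dict[str, PhotoperiodScheme] = field(
        default_factory=lambda: {s.label: s for s in default_schemes()}
    )
    pairs: tuple[tuple[str, str], ...] = (("LD", "SD"), ("LD-DD", "SD-DD"))
    level_pairs: tuple[tuple[str, str], ...] = (("LD", "LD-DD"), ("SD", "SD-DD"))
    normalization: NormalizationSpec | None = None
    alpha: float = 0.05
    max_harmonics: int = 3
    min_prominence: float = 0.1
    grid_step: float = 0.01
    decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for pair_set in (self.pairs, self.level_pairs):
            for a, b in pair_set:
                for label in (a, b):
                    if label not in self.schemes:
                        raise ValueError(
                            f"condition {label!r} has no scheme definition"
                        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "schemes" in data:
            schemes = {}
            for entry in data["schemes"]:
                scheme = PhotoperiodScheme(
                    label=str(entry["label"]),
                    light_hours=float(entry["light_hours"]),
                    projected=bool(entry.get("projected", False)),
                    entrainment_label=entry.get("entrainment_label"),
                )
                schemes[scheme.label] = scheme
            kwargs["schemes"] = schemes
        for key in ("alpha", "max_harmonics", "min_prominence", "grid_step",
                    "decimals", "seed"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("pairs", "level_pairs"):
            if key in data:
                kwargs[key] = tuple(tuple(p) for p in data[key])
        if "normalization" in data:
            norm = data["normalization"]
            kwargs["normalization"] = NormalizationSpec(
                reference_genes=tuple(norm["reference_genes"]),
                aggregate=norm.get("aggregate", "mean_ct"),
                calibrator=tuple(norm["calibrator"]) if norm.get("calibrator") else None,
                efficiency_correction=bool(norm.get("efficiency_correction", False)),
            )
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "schemes": {
                k: [v.light_hours, v.projected, v.entrainment_label]
                for k, v in sorted(self.schemes.items())
            },
            "pairs": self.pairs,
            "level_pairs": self.level_pairs,
            "normalization": None
            if self.normalization is None
            else asdict(self.normalization),
            "alpha": self.alpha,
            "max_harmonics": self.max_harmonics,
            "min_prominence": self.min_prominence,
            "grid_step": self.grid_step,
            "decimals": self.decimals,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus provenance.

    Regenerating with the same config and inputs reproduces identical
    tables; timestamps live only in ``provenance``.
    """

    fits: pd.DataFrame
    peaks: pd.DataFrame
    phase_table: pd.DataFrame
    timepoint_stats: pd.DataFrame
    level_stats: pd.DataFrame
    errors: list[str]
    provenance: dict

    @property
    def empty(self) -> bool:
        return self.phase_table.empty and self.fits.empty

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        decimals = self.provenance.get("decimals", 2)
        tables = {
            "fits": self.fits,
            "peaks": self.peaks,
            "phase_table": _rounded(self.phase_table, decimals),
            "timepoint_stats": self.timepoint_stats,
            "level_stats": self.level_stats,
        }
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        report = {name: df.to_dict("records") for name, df in tables.items()}
        report["errors"] = self.errors
        report["provenance"] = self.provenance
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )


def _rounded(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    if df.empty:
        return df
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(
                lambda x: round_half_away(x, decimals) if pd.notna(x) else x
            )
    return df


def _fit_stage(
    expr: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, list[PeakRecord], pd.DataFrame, list[str]]:
    """Fit every gene × condition, extract and label acrophases."""
    fits_rows, errors = [], []
    acros: dict[tuple[str, str], "object"] = {}
    for (gene, condition), group in expr.groupby(["gene", "condition"], sort=False):
        try:
            series = ExpressionSeries.from_frame(group, gene, condition)
            fit = fit_cosinor(series, config.max_harmonics, config.alpha)
            row = {
                "gene": gene,
                "condition": condition,
                "n_sines": fit.n_harmonics,
                "p_value": fit.p_value,
                "r_squared": fit.r_squared,
                "mesor": fit.mesor,
            }
            try:
                acro = extract_acrophases(fit, config.grid_step, config.min_prominence)
                acros[(gene, condition)] = acro
                row["acrophases"] = ";".join(f"{t:.2f}" for t in acro.times)
            except NoAcrophaseError:
                row["acrophases"] = ""
                logger.info("%s/%s: flat fit, no acrophase", gene, condition)
            fits_rows.append(row)
        except Exception as exc:  # keep the batch going
            errors.append(f"fit {gene}/{condition}: {exc}")
            logger.warning("fit failed for %s/%s: %s", gene, condition, exc)

    # label peaks, resolving bimodal-vs-unimodal against the paired condition
    partners: dict[str, set[str]] = {}
    for a, b in config.pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    peak_records: list[PeakRecord] = []
    for (gene, condition), acro in acros.items():
        n_here = len(acro.times)
        partner_unimodal = any(
            len(acros[(gene, other)].times) < n_here
            for other in partners.get(condition, ())
            if (gene, other) in acros
        )
        if partner_unimodal:
            logger.info(
                "%s/%s: partner condition unimodal; labeling extra peak 'second'",
                gene, condition,
            )
        records = label_peaks(
            acro, config.schemes[condition], gene,
            partner_unimodal=partner_unimodal,
        )
        peak_records.extend(records)

    peaks_df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "condition": r.condition,
                "peak_label": r.peak_label,
                "peak_time_zt": r.peak_time.hours,
                "frame": r.peak_time.frame,
            }
            for r in peak_records
        ],
        columns=["gene", "condition", "peak_label", "peak_time_zt", "frame"],
    )
    fits_df = pd.DataFrame(
        fits_rows,
        columns=["gene", "condition", "n_sines", "p_value", "r_squared",
                 "mesor", "acrophases"],
    )
    return fits_df, peak_records, peaks_df, errors


def _stats_stage(
    expr: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    tp_rows, lvl_rows, errors = [], [], []
    by_key = {
        key: ExpressionSeries.from_frame(group, *key)
        for key, group in expr.groupby(["gene", "condition"], sort=False)
    }
    for (gene, condition), series in by_key.items():
        try:
            res = timepoint_test(series)
            tp_rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "kw_statistic": res.kw_statistic,
                    "kw_p": res.kw_p,
                    "n_significant_pairs": int(
                        (res.posthoc.to_numpy()[np.triu_indices(len(res.posthoc), 1)]
                         < config.alpha).sum()
                    ),
                    "degenerate": res.degenerate,
                }
            )
        except InsufficientDataError as exc:
            errors.append(f"timepoint_test {gene}/{condition}: {exc}")
    genes = expr["gene"].unique()
    for gene in genes:
        for cond_a, cond_b in config.level_pairs:
            sa, sb = by_key.get((gene, cond_a)), by_key.get((gene, cond_b))
            if sa is None or sb is None:
                continue
            try:
                res = averaged_level_test(sa, sb, alpha=config.alpha)
            except InsufficientDataError as exc:
                errors.append(f"averaged_level_test {gene}: {exc}")
                continue
            lvl_rows.append(
                {
                    "gene": gene,
                    "condition_a": cond_a,
                    "condition_b": cond_b,
                    "shapiro_p_a": res.shapiro_p[0],
                    "shapiro_p_b": res.shapiro_p[1],
                    "mw_u": res.mw_u,
                    "mw_p": res.mw_p,
                    "significant": res.significant,
                    "direction": res.direction,
                }
            )
    tp_cols = ["gene", "condition", "kw_statistic", "kw_p",
               "n_significant_pairs", "degenerate"]
    lvl_cols = ["gene", "condition_a", "condition_b", "shapiro_p_a",
                "shapiro_p_b", "mw_u", "mw_p", "significant", "direction"]
    return (pd.DataFrame(tp_rows, columns=tp_cols),
            pd.DataFrame(lvl_rows, columns=lvl_cols), errors)


def run_pipeline(
    config: PipelineConfig,
    data: pd.DataFrame | str | Path,
) -> RunReport:
    """Run every applicable stage on an input table (path or DataFrame).

    The stages executed depend on the detected schema: a Ct table is
    quantified first; an expression table starts at the cosinor stage; a
    peak table skips straight to classification (fits and stats are then
    empty).
    """
    if isinstance(data, (str, Path)):
        df, schema = read_table(data)
    else:
        df = data
        schema = detect_schema(df) if len(df.columns) else "expression"

    empty = RunReport(
        fits=pd.DataFrame(), peaks=pd.DataFrame(), phase_table=pd.DataFrame(),
        timepoint_stats=pd.DataFrame(), level_stats=pd.DataFrame(),
        errors=[], provenance=_provenance(config, schema, 0),
    )
    if df.empty:
        logger.warning("input table is empty; producing an empty report")
        return empty

    errors: list[str] = []
    if schema == "ct":
        if config.normalization is None:
            raise ValueError("Ct input requires a normalization spec in the config")
        df = relative_expression(df, config.normalization)
        schema_after = "expression"
    else:
        schema_after = schema

    if schema_after == "expression":
        fits_df, peak_records, peaks_df, fit_errors = _fit_stage(df, config)
        errors.extend(fit_errors)
        tp_stats, lvl_stats, stat_errors = _stats_stage(df, config)
        errors.extend(stat_errors)
    else:  # peaks input
        fits_df = pd.DataFrame()
        peak_records = peaks_from_frame(df, config.schemes)
        peaks_df = df.copy()
        tp_stats = lvl_stats = pd.DataFrame()

    present = {r.condition for r in peak_records}
    usable_pairs = [p for p in config.pairs if set(p) <= present]
    phase_df = build_phase_table(peak_records, config.schemes, usable_pairs)
    for row in phase_df.itertuples(index=False):
        if row.tie:
            logger.info("%s/%s: mode tie broken to %s", row.gene,
                        row.peak_label, row.mode)
        if row.partner_reused:
            logger.info("%s/%s: primary peak reused as comparison partner",
                        row.gene, row.peak_label)

    return RunReport(
        fits=fits_df,
        peaks=peaks_df,
        phase_table=phase_df,
        timepoint_stats=tp_stats,
        level_stats=lvl_stats,
        errors=errors,
        provenance=_provenance(config, schema, len(df)),
    )


def _provenance(config: PipelineConfig, schema: str, n_rows: int) -> dict:
    import datetime

    return {
        "photophase_version": _version,
        "config_digest": config.digest(),
        "input_schema": schema,
        "input_rows": n_rows,
        "decimals": config.decimals,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


@dataclass(frozen=True)
class Discrepancy:
    gene: str
    peak_label: str
    column: str
    expected: object
    actual: object


_GOLDEN_VALUE_COLS = (
    "zt_a", "zt_b", "mnft_a", "mnft_b", "ssft_a", "ssft_b",
    "delta_zt", "delta_mnft", "delta_ssft",
)


def validate_against_golden(
    phase_table: pd.DataFrame,
    golden: pd.DataFrame | str | Path,
    tolerance: float = 0.01,
) -> list[Discrepancy]:
    """Cell-by-cell comparison of a computed phase table against a golden one.

    Times and shift widths are compared at ``±tolerance`` (after report
    rounding of the computed values); modes exactly. Golden rows with no
    computed counterpart are reported as ``missing`` discrepancies rather
    than raising. An empty list means the tables agree.
    """
    if not isinstance(golden, pd.DataFrame):
        golden = pd.read_csv(golden)
    computed = {
        (row.gene, row.peak_label, row.condition_a, row.condition_b): row
        for row in phase_table.itertuples(index=False)
    }
    out: list[Discrepancy] = []
    for g in golden.itertuples(index=False):
        key = (g.gene, g.peak_label, g.condition_a, g.condition_b)
        row = computed.get(key)
        if row is None:
            out.append(Discrepancy(g.gene, g.peak_label, "row", "present", "missing"))
            continue
        for col in _GOLDEN_VALUE_COLS:
            if not hasattr(g, col):
                continue
            expected = float(getattr(g, col))
            actual = round_half_away(float(getattr(row, col)), 2)
            if abs(actual - expected) > tolerance + 1e-12:
                out.append(Discrepancy(g.gene, g.peak_label, col, expected, actual))
        if hasattr(g, "mode") and g.mode != row.mode:
            out.append(Discrepancy(g.gene, g.peak_label, "mode", g.mode, row.mode))
    return out
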