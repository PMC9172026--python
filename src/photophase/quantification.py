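"""Relative expression from raw qPCR Ct values (ddCt method).

Each sample's target Ct is normalized against an aggregate of one or more
reference genes, then calibrated:

    dCt  = Ct_target - Ct_ref_aggregate
    ddCt = dCt - dCt_calibrator
    level = base ** (-ddCt)

``base`` is 2 (ideal doubling per cycle) unless per-gene amplification
efficiencies E (%) are supplied, in which case ``base = 1 + E/100``. The
default reference aggregate is the arithmetic mean of the reference-gene Ct
values, i.e. the geometric mean of reference abundances — the usual
multi-reference normalization; averaging reference *quantities* instead is
available as an option. The default calibrator is the per-gene mean dCt
across all samples, so levels are in arbitrary relative units and only the
profile shape is meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationSpec",
    "IncompleteSampleError",
    "relative_expression",
]

_SAMPLE_KEY = ["condition", "zt", "replicate"]


class IncompleteSampleError(ValueError):
    """A sample lacks a Ct value for the target or a reference gene."""


@dataclass(frozen=True)
class NormalizationSpec:
    """How to normalize target Ct values.

    ``aggregate`` is ``"mean_ct"`` (arithmetic mean of reference Cts;
    geometric mean of abundances) or ``"mean_quantity"`` (arithmetic mean of
    reference abundances, re-expressed as an equivalent Ct). ``calibrator``
    is ``None`` for the per-gene mean dCt, or a ``(condition, zt)`` /
    ``(condition, zt, replicate)`` sample key whose dCt becomes the zero
    point. ``efficiency_correction`` switches the exponent base from 2 to
    ``1 + E/100`` where an ``efficiency`` column is present.
    """

    reference_genes: tuple[str, ...]
    aggregate: str = "mean_ct"
    calibrator: tuple | None = None
    efficiency_correction: bool = False

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        if self.aggregate not in ("mean_ct", "mean_quantity"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")


def _reference_aggregate(ref: pd.DataFrame, spec: NormalizationSpec) -> pd.Series:
    """Aggregate reference-gene Cts per sample, erroring on missing genes."""
    wide = ref.pivot_table(index=_SAMPLE_KEY, columns="gene", values="ct")
    missing_cols = set(spec.reference_genes) - set(wide.columns)
    if missing_cols:
        raise IncompleteSampleError(
            f"reference genes never measured: {sorted(missing_cols)}"
        )
    wide = wide[list(spec.reference_genes)]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise IncompleteSampleError(
            f"samples missing a reference Ct: {bad[:5]}"
        )
    if spec.aggregate == "mean_ct":
        return wide.mean(axis=1)
    # mean of reference quantities 2^-Ct, re-expressed as a Ct
    return -np.log2(np.exp2(-wide).mean(axis=1))


def relative_expression(
    records: pd.DataFrame,
    spec: NormalizationSpec,
) -> pd.DataFrame:
    """Compute ddCt relative expression for every non-reference gene.

    ``records`` is a long table with columns ``gene, condition, zt,
    replicate, ct`` (optionally ``efficiency``, percent). Returns the same
    long layout with ``level`` replacing ``ct``, reference genes dropped.
    Raises :class:`IncompleteSampleError` when a sample lacks the target or
    a reference Ct.
    """
    required = {"gene", "ct", *_SAMPLE_KEY}
    if not required.issubset(records.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ct = records["ct"]
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("Ct values must be finite and positive")
    if "efficiency" in records.columns:
        eff = records["efficiency"].dropna()
        if len(eff) and not ((eff > 50) & (eff < 150)).all():
            raise ValueError("amplification efficiencies must lie in (50, 150)%")

    is_ref = records["gene"].isin(spec.reference_genes)
    ref_ct = _reference_aggregate(records[is_ref], spec)
    targets = records[~is_ref].copy()
    if targets.empty:
        return targets.assign(level=[])

    sample_index = pd.MultiIndex.from_frame(targets[_SAMPLE_KEY])
    aligned = ref_ct.reindex(sample_index)
    if aligned.isna().any():
        bad = sample_index[aligned.isna()].tolist()
        raise IncompleteSampleError(f"samples with no reference Ct: {bad[:5]}")
    targets["dct"] = targets["ct"].to_numpy() - aligned.to_numpy()

    def base_for(group: pd.DataFrame) -> float:
        if spec.efficiency_correction and "efficiency" in group.columns:
            eff = group["efficiency"].dropna()
            if len(eff):
                return 1.0 + float(eff.iloc[0]) / 100.0
        return 2.0

    out = []
    for gene, group in targets.groupby("gene", sort=False):
        if spec.calibrator is None:
            dct_cal = group["dct"].mean()
        else:
            key = tuple(spec.calibrator)
            mask = np.ones(len(group), dtype=bool)
            for col, val in zip(_SAMPLE_KEY, key):
                mask &= group[col].to_numpy() == val
            if not mask.any():
                raise IncompleteSampleError(
                    f"gene {gene!r}: calibrator sample {key} not found"
                )
            dct_cal = group.loc[mask, "dct"].mean()
        group = group.copy()
        group["level"] = base_for(group) ** -(group["dct"] - dct_cal)
        out.append(group)
    result = pd.concat(out, ignore_index=True)
    return result.drop(columns=["ct", "dct"])
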