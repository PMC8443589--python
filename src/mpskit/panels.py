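"""Soluble-biomarker panel analytics.

Detectability filtering with an auditable exclusion report, one-way ANOVA
with Sidak-corrected pairwise comparisons against a reference group, and
Oil-Red-O absorbance normalisation to total protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mpskit.errors import InputError


@dataclass
class PanelMatrix:
    """Analyte x sample concentrations with per-cell detection flags.

    ``values`` and ``detected`` are aligned DataFrames (analytes as rows,
    samples as columns); ``sample_map`` maps each sample to its condition key
    (day, when relevant, is folded into the condition string, e.g.
    ``"nash_d14"``).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    sample_map: dict[str, str]

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise InputError("values and detected must be aligned")
        missing = [s for s in self.values.columns if s not in self.sample_map]
        if missing:
            raise InputError(f"sample_map missing samples: {missing}")
        vals = self.values.to_numpy(dtype=float)
        det = self.detected.to_numpy(dtype=bool)
        if np.any(vals[det] < 0):
            raise InputError("detected concentrations must be >= 0")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.sample_map[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_map[s] == condition]


@dataclass
class Exclusion:
    analyte: str
    reason: str      # "undetected" | "no_group_difference"


@dataclass
class PairwiseComparison:
    group: str
    p_raw: float
    p_sidak: float


@dataclass
class GroupStats:
    analyte: str
    f_statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass
class OroMeasurement:
    absorbance: float
    protein_mg: float
    normalized: float
    wavelength_nm: float = 515.0


def filter_detected(
    panel: PanelMatrix,
    min_detected_frac: float = 0.5,
    require_group_signal: bool = False,
    alpha: float = 0.05,
) -> tuple[PanelMatrix, list[Exclusion]]:
    """Drop analytes without a detectable or differential signal.

    An analyte is retained when it is detected in at least
    ``min_detected_frac`` of the samples of at least one condition.  With
    ``require_group_signal`` an additional one-way ANOVA across conditions is
    applied and analytes with p >= alpha are dropped as well.  Every dropped
    analyte carries exactly one primary reason ("undetected" dominates).
    """
    keep: list[str] = []
    exclusions: list[Exclusion] = []
    conditions = panel.conditions
    for analyte in panel.values.index:
        fracs = []
        for cond in conditions:
            samples = panel.samples_of(cond)
            flags = panel.detected.loc[analyte, samples].to_numpy(dtype=bool)
            fracs.append(flags.mean() if flags.size else 0.0)
        if max(fracs, default=0.0) < min_detected_frac:
            exclusions.append(Exclusion(analyte, "undetected"))
            continue
        if require_group_signal:
            groups = []
            for cond in conditions:
                samples = panel.samples_of(cond)
                flags = panel.detected.loc[analyte, samples].to_numpy(dtype=bool)
                vals = panel.values.loc[analyte, samples].to_numpy(dtype=float)[flags]
                if vals.size >= 2:
                    groups.append(vals)
            p = 1.0
            if len(groups) >= 2:
                with np.errstate(invalid="ignore"):
                    _, p = stats.f_oneway(*groups)
                if np.isnan(p):   # zero variance everywhere
                    p = 1.0
            if p >= alpha:
                exclusions.append(Exclusion(analyte, "no_group_difference"))
                continue
        keep.append(analyte)

    subset = PanelMatrix(
        values=panel.values.loc[keep].copy(),
        detected=panel.detected.loc[keep].copy(),
        sample_map=dict(panel.sample_map),
    )
    return subset, exclusions


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment for m comparisons: 1 - (1 - p)^m."""
    if not 0 <= p <= 1:
        raise InputError("p must lie in [0, 1]")
    if m < 1:
        raise InputError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def anova_sidak(
    values_by_group: dict[str, np.ndarray],
    reference: str,
    analyte: str = "",
) -> GroupStats:
    """One-way ANOVA plus two-tailed pairwise t-tests vs the reference group,
    Sidak-adjusted over the number of pairwise comparisons."""
    if reference not in values_by_group:
        raise InputError(f"reference group {reference!r} not present")
    if len(values_by_group) < 2:
        raise InputError("at least two groups are required")
    arrays = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise InputError(f"group {name!r} has fewer than 2 values")
        arrays[name] = arr

    f_stat, p = stats.f_oneway(*arrays.values())

    others = [g for g in arrays if g != reference]
    m = len(others)
    pairwise = []
    for g in others:
        _, p_raw = stats.ttest_ind(arrays[g], arrays[reference])
        pairwise.append(
            PairwiseComparison(group=g, p_raw=float(p_raw), p_sidak=sidak_adjust(float(p_raw), m))
        )
    return GroupStats(
        analyte=analyte, f_statistic=float(f_stat), p_value=float(p), pairwise=pairwise
    )


def oro_normalize(
    absorbance: float, protein_mg: float, wavelength_nm: float = 515.0
) -> OroMeasurement:
    """Oil-Red-O absorbance normalised to total protein (A.U. per mg)."""
    if protein_mg <= 0:
        raise InputError("protein_mg must be > 0")
    if absorbance < 0:
        raise InputError("absorbance must be >= 0")
    return OroMeasurement(
        absorbance=absorbance,
        protein_mg=protein_mg,
        normalized=absorbance / protein_mg,
        wavelength_nm=wavelength_nm,
    )
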