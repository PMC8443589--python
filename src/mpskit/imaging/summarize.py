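"""Aggregation of microtissue records to FOV and scaffold level, and
condition comparisons of scaffold summaries."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from mpskit.errors import InputError
from mpskit.imaging.types import (
    ConditionComparison,
    FOVSummary,
    MicrotissueRecord,
    ScaffoldSummary,
)

log = logging.getLogger(__name__)


def summarize(
    records: list[MicrotissueRecord],
    fov_to_scaffold: dict[str, str],
    scaffold_to_condition: dict[str, str],
) -> tuple[list[FOVSummary], list[ScaffoldSummary]]:
    """Per-FOV means over microtissues, then unweighted per-scaffold means
    over FOV means.

    FOVs with zero microtissues simply contribute nothing and are logged by
    omission; every record must map to a scaffold and condition.
    """
    for rec in records:
        if rec.fov_id not in fov_to_scaffold:
            raise InputError(f"record FOV {rec.fov_id!r} has no scaffold mapping")
    for fov, scaffold in fov_to_scaffold.items():
        if scaffold not in scaffold_to_condition:
            raise InputError(f"scaffold {scaffold!r} has no condition mapping")

    channels = sorted({ch for rec in records for ch in rec.total_intensity})

    by_fov: dict[str, list[MicrotissueRecord]] = {}
    for rec in records:
        by_fov.setdefault(rec.fov_id, []).append(rec)

    empty = [f for f in fov_to_scaffold if f not in by_fov]
    if empty:
        log.info("excluding %d FOVs with zero microtissues: %s", len(empty), empty)

    fov_summaries = [
        FOVSummary(
            fov_id=fov,
            scaffold_id=fov_to_scaffold[fov],
            mean_intensity={
                ch: float(np.mean([r.total_intensity[ch] for r in recs])) for ch in channels
            },
            n_microtissues=len(recs),
        )
        for fov, recs in sorted(by_fov.items())
    ]

    by_scaffold: dict[str, list[FOVSummary]] = {}
    for fs in fov_summaries:
        by_scaffold.setdefault(fs.scaffold_id, []).append(fs)

    scaffold_summaries = [
        ScaffoldSummary(
            scaffold_id=sid,
            condition=scaffold_to_condition[sid],
            mean_intensity={
                ch: float(np.mean([fs.mean_intensity[ch] for fs in fsums])) for ch in channels
            },
            n_fovs=len(fsums),
            n_microtissues=sum(fs.n_microtissues for fs in fsums),
        )
        for sid, fsums in sorted(by_scaffold.items())
    ]
    return fov_summaries, scaffold_summaries


def compare_conditions(
    summaries: list[ScaffoldSummary],
    reference_condition: str,
) -> list[ConditionComparison]:
    """Fold and percent change of each condition vs the reference.

    fold = mean(condition scaffold means) / mean(reference scaffold means);
    percent_change = 100 * (1 - condition/reference).  A zero reference mean
    flags the fold as undefined rather than producing a number.  A two-tailed
    t-test p-value is attached when both conditions have >= 2 scaffolds.
    """
    conditions = sorted({s.condition for s in summaries})
    if reference_condition not in conditions:
        raise InputError(f"reference condition {reference_condition!r} absent")
    channels = sorted({ch for s in summaries for ch in s.mean_intensity})

    def values(cond: str, ch: str) -> np.ndarray:
        return np.array(
            [s.mean_intensity[ch] for s in summaries if s.condition == cond], dtype=float
        )

    out: list[ConditionComparison] = []
    for cond in conditions:
        if cond == reference_condition:
            continue
        for ch in channels:
            ref_vals = values(reference_condition, ch)
            cond_vals = values(cond, ch)
            ref_mean = float(ref_vals.mean())
            cond_mean = float(cond_vals.mean())
            p = None
            if ref_vals.size >= 2 and cond_vals.size >= 2:
                p = float(sps.ttest_ind(cond_vals, ref_vals).pvalue)
            if ref_mean == 0:
                out.append(
                    ConditionComparison(
                        channel=ch,
                        condition=cond,
                        reference=reference_condition,
                        fold_change=None,
                        percent_change=None,
                        p_value=p,
                        undefined_fold=True,
                    )
                )
                continue
            out.append(
                ConditionComparison(
                    channel=ch,
                    condition=cond,
                    reference=reference_condition,
                    fold_change=cond_mean / ref_mean,
                    percent_change=100.0 * (1.0 - cond_mean / ref_mean),
                    p_value=p,
                )
            )
    return out
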