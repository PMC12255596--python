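"""Cohort-level simulation of per-subject ROI mean susceptibilities.

This emulates a clinical epilepsy-style study at the summary-statistic
level: each subject contributes a mean susceptibility per ROI drawn from a
group-level normal model with a shared per-subject offset (the across-brain
susceptibility shift referencing is designed to remove), an age trend, and
optional pathology in the reference regions themselves.

Default group sizes are 27 healthy controls (HC), 19 left and 17 right
temporal-lobe-epilepsy patients (LTLE / RTLE), ages uniform on 16-67 years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import DEFAULT_CHI_PPM, TEST_ROI_NAMES
from .types import CohortDesign, SubjectRecord

__all__ = [
    "STRATEGY_NAMES",
    "DEFAULT_GROUP_SIZES",
    "default_cohort_design",
    "simulate_cohort",
    "cohort_to_frame",
]

#: Referencing strategies carried on every cohort table, as ``ref_<name>``
#: columns.  ``none`` is identically 0; ``wholebrain`` is the near-zero
#: residual mean of a demeaned map; ``csf``/``cc``/``ic`` equal the subject's
#: simulated reference-ROI mean; ``r2s`` tracks CSF (fluid threshold) and
#: ``relvar`` tracks low-variance white matter, each with a small selection
#: jitter.
STRATEGY_NAMES = ("none", "wholebrain", "csf", "cc", "ic", "relvar", "r2s")

DEFAULT_GROUP_SIZES = {"HC": 27, "LTLE": 19, "RTLE": 17}

_REFERENCE_ROIS = ("CSF", "corpus_callosum", "internal_capsule")


def default_cohort_design(
    effects: dict[tuple[str, str], float] | None = None,
    ref_pathology_shift: dict[str, float] | None = None,
    roi_sd: float = 0.01,
    subject_offset_sd: float = 0.005,
    age_slope: float = 0.0005,
    seed: int = 0,
    group_sizes: dict[str, int] | None = None,
) -> CohortDesign:
    """Epilepsy-style three-group design over the nine standard ROIs.

    ``effects`` adds group-specific shifts (ppm) on top of the shared ROI
    means, e.g. ``{("LTLE", "hippocampus"): 0.01}``; with no effects the
    design is a global null.  ``ref_pathology_shift`` shifts the reference
    ROIs (CSF/CC/IC) per group, modelling disease in a reference region.
    """

    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    effects = effects or {}
    means: dict[tuple[str, str], float] = {}
    for g in sizes:
        for roi in TEST_ROI_NAMES:
            means[(g, roi)] = DEFAULT_CHI_PPM[roi] + effects.get((g, roi), 0.0)
    return CohortDesign(
        group_sizes=sizes,
        roi_means=means,
        roi_sd={roi: roi_sd for roi in TEST_ROI_NAMES},
        subject_offset_sd=subject_offset_sd,
        reference_rois=_REFERENCE_ROIS,
        ref_pathology_shift=ref_pathology_shift or {},
        age_slope=age_slope,
        seed=seed,
    )


def simulate_cohort(design: CohortDesign, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a cohort of subject records from the design's sampling model.

    Deterministic given ``(design, seed)``; ``seed`` defaults to
    ``design.seed``.  Reference-strategy values are generated alongside the
    ROI means so their covariance structure (shared subject offset) is
    explicit.
    """

    rng = np.random.default_rng(design.seed if seed is None else seed)
    rois = design.rois
    lo, hi = design.age_range
    age_center = 0.5 * (lo + hi)
    records: list[SubjectRecord] = []
    sid = 0
    for group, n in design.group_sizes.items():
        for _ in range(n):
            sid += 1
            age = float(rng.uniform(lo, hi))
            b = float(rng.normal(0.0, design.subject_offset_sd))
            trend = design.age_slope * (age - age_center)
            roi_mean: dict[str, float] = {}
            for roi in rois:
                mu = design.roi_means[(group, roi)]
                if roi in design.reference_rois:
                    mu += design.ref_pathology_shift.get(group, 0.0)
                roi_mean[roi] = mu + b + trend + float(rng.normal(0.0, design.roi_sd[roi]))
            refs = {
                "none": 0.0,
                "wholebrain": float(rng.normal(0.0, design.whole_brain_ref_sd)),
                "csf": roi_mean.get("CSF", 0.0),
                "cc": roi_mean.get("corpus_callosum", 0.0),
                "ic": roi_mean.get("internal_capsule", 0.0),
                "r2s": roi_mean.get("CSF", 0.0) + float(rng.normal(0.0, design.r2s_ref_jitter_sd)),
                "relvar": roi_mean.get("corpus_callosum", 0.0)
                + float(rng.normal(0.0, design.relvar_ref_jitter_sd)),
            }
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{sid:03d}",
                    group=group,
                    age=age,
                    roi_mean=roi_mean,
                    roi_sd={roi: design.within_roi_sd for roi in rois},
                    roi_n={roi: design.roi_voxel_count for roi in rois},
                    reference_values=refs,
                )
            )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the standard cohort table.

    Columns: ``subject_id, group, age``, then ``<roi>_mean``, ``<roi>_sd``,
    ``<roi>_n`` per ROI, then ``ref_<strategy>`` per strategy.
    """

    if not records:
        return pd.DataFrame(columns=["subject_id", "group", "age"])
    rois = list(records[0].roi_mean)
    rows = []
    for rec in records:
        row: dict[str, object] = {"subject_id": rec.subject_id, "group": rec.group, "age": rec.age}
        for roi in rois:
            row[f"{roi}_mean"] = rec.roi_mean[roi]
            row[f"{roi}_sd"] = rec.roi_sd[roi]
            row[f"{roi}_n"] = rec.roi_n[roi]
        for strat, val in rec.reference_values.items():
            row[f"ref_{strat}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
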