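"""Group statistics under referencing.

The two-sample test of the across-subject ROI means is the Welch t

    t_d = (x̄_n - ȳ_m) / S_d,     S_d² = S_X²/n + S_Y²/m,

with unbiased (n-1) sample variances throughout.  Referencing replaces each
subject's ROI mean X by X - R (R the subject's reference value), so the
sample mean becomes the difference of sample means and the sample variance
changes by Bienaymé's identity

    Var(X - R) = Var(X) + Var(R) - 2 Cov(X, R):

an uncorrelated reference inflates the variance (weakening the test) while
a positively correlated one deflates it.  The cohort workflow is
reference -> age-correct -> one-way ANOVA per ROI -> post-hoc Tukey-Kramer
restricted to ROIs with a significant ANOVA; the accuracy workflow compares
reconstruction ROI voxels against ground truth voxels with the same Welch
test, calling an ROI "accurate" when the difference is not significant.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import strategy_mask, strategy_reference_value, whole_brain_reference
from .types import (
    AccuracyTable,
    GroupStatReport,
    LabelMap,
    R2sMap,
    ReferenceStrategy,
    SusceptibilityVolume,
    WelchResult,
)

__all__ = [
    "welch_t",
    "anova_oneway",
    "tukey_kramer",
    "age_correct",
    "variance_change",
    "bienayme_decomposition",
    "accuracy_test",
    "accuracy_table",
    "run_group_pipeline",
]


def welch_t(x, y) -> WelchResult:
    """Welch two-sample t test (unequal variances, two-sided).

    Degrees of freedom by Welch-Satterthwaite.  If both sample variances
    are zero: t = 0 and p = 1 when the means agree, |t| = inf and p = 0
    otherwise.
    """

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("both samples need at least 2 values")
    s2x = float(np.var(x, ddof=1))
    s2y = float(np.var(y, ddof=1))
    s2d = s2x / n + s2y / m
    diff = float(np.mean(x) - np.mean(y))
    if s2d == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, float(n + m - 2), 1.0, s2x, s2y, s2d, n, m)
        return WelchResult(float(np.sign(diff)) * np.inf, float(n + m - 2), 0.0, s2x, s2y, s2d, n, m)
    t = diff / np.sqrt(s2d)
    df = s2d**2 / ((s2x / n) ** 2 / (n - 1) + (s2y / m) ** 2 / (m - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p, s2x, s2y, s2d, n, m)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA across two or more groups."""

    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:  # all values identical: no variance to partition
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def tukey_kramer(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparison (studentized range, unequal sizes).

    For groups i, j with means m_i, m_j and the pooled within-group mean
    square MSW on N - k degrees of freedom,

        q_ij = |m_i - m_j| / sqrt( (MSW/2) (1/n_i + 1/n_j) ),

    with p from the studentized-range distribution with k groups and N - k
    df.  Returns one row per unordered pair.
    """

    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_w = int(ns.sum() - k)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    msw = ssw / df_w
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt((msw / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        if q == 0.0:
            p = 1.0
        rows.append({"group1": labels[i], "group2": labels[j], "diff": float(diff), "q": float(q), "p": p})
    return pd.DataFrame(rows)


def age_correct(values, ages, groups=None) -> np.ndarray:
    """Remove a linear age trend from (referenced) ROI means.

    Pooled simple linear regression of the values on age across all
    subjects; returns residuals plus the grand mean, so the output is
    age-decorrelated but keeps the original overall level.  With ``groups``
    given, the regression is fit within each group separately.
    """

    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size != ages.size:
        raise ValueError("values and ages must have equal length")
    if values.size < 3:
        raise ValueError("need at least 3 subjects for age correction")
    if np.ptp(ages) == 0.0:
        raise ValueError("ages are constant; age correction is undefined")
    if groups is None:
        slope, intercept = np.polyfit(ages, values, 1)
        resid = values - (slope * ages + intercept)
        return resid + values.mean()
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        sel = groups == g
        out[sel] = age_correct(values[sel], ages[sel])
    return out


def variance_change(roi_means, ref_values) -> float:
    """Percentage change in across-subject ROI variance due to referencing.

    ``100 * [Var(roi - ref) - Var(roi)] / Var(roi)`` with unbiased sample
    variances.  Negative values mean referencing sharpened the test
    (smaller variance); positive values mean it inflated it.
    """

    x = np.asarray(roi_means, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if x.size != r.size or x.size < 2:
        raise ValueError("need equal-length vectors of at least 2 subjects")
    var_x = float(np.var(x, ddof=1))
    if var_x == 0.0:
        raise ValueError("ROI variance is zero; relative change undefined")
    var_d = float(np.var(x - r, ddof=1))
    return 100.0 * (var_d - var_x) / var_x


def bienayme_decomposition(x, r) -> tuple[float, float, float, float]:
    """Sample-moment variance decomposition of referencing.

    Returns ``(VarX, VarR, Cov, VarDiff)`` with matching (n-1)
    normalization; the identity ``VarDiff = VarX + VarR - 2 Cov`` holds to
    floating-point rounding because all four are computed from the same
    sample moments.
    """

    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.size != r.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    var_x = float(np.var(x, ddof=1))
    var_r = float(np.var(r, ddof=1))
    cov = float(np.cov(x, r, ddof=1)[0, 1])
    var_diff = float(np.var(x - r, ddof=1))
    return var_x, var_r, cov, var_diff


def accuracy_test(
    recon_voxels,
    gt_voxels,
    recon_ref: float = 0.0,
    gt_ref: float = 0.0,
    alpha: float = 0.05,
) -> tuple[bool, WelchResult]:
    """Is an ROI reconstructed accurately after referencing?

    Welch test between the referenced reconstruction voxels and referenced
    ground-truth voxels, treating voxels as independent samples from an
    ROI-specific distribution.  Accurate means not significantly different
    (p >= alpha).  Since referencing only shifts means, the statistic is
    computed from the shifted means and the unshifted sample variances;
    referencing an ROI to its own mean therefore gives t = 0 exactly and
    the ROI is always accurate.
    """

    rv = np.asarray(recon_voxels, dtype=float)
    gv = np.asarray(gt_voxels, dtype=float)
    n, m = rv.size, gv.size
    if n < 2 or m < 2:
        raise ValueError("both voxel sets need at least 2 voxels")
    if not (np.isfinite(recon_ref) and np.isfinite(gt_ref)):
        raise ValueError("reference values must be finite")
    s2x = float(np.var(rv, ddof=1))
    s2y = float(np.var(gv, ddof=1))
    s2d = s2x / n + s2y / m
    diff = (float(np.mean(rv)) - recon_ref) - (float(np.mean(gv)) - gt_ref)
    if s2d == 0.0:
        res = WelchResult(
            0.0 if diff == 0.0 else float(np.sign(diff)) * np.inf,
            float(n + m - 2), 1.0 if diff == 0.0 else 0.0, s2x, s2y, s2d, n, m,
        )
    else:
        t = diff / np.sqrt(s2d)
        df = s2d**2 / ((s2x / n) ** 2 / (n - 1) + (s2y / m) ** 2 / (m - 1))
        res = WelchResult(float(t), float(df), 2.0 * float(sps.t.sf(abs(t), df)), s2x, s2y, s2d, n, m)
    return bool(res.p >= alpha), res


def accuracy_table(
    recons: dict[str, SusceptibilityVolume],
    gt: SusceptibilityVolume,
    label_map: LabelMap,
    strategies: dict[str, ReferenceStrategy],
    alpha: float = 0.05,
    r2s: R2sMap | None = None,
) -> AccuracyTable:
    """Accuracy booleans per (reconstruction, ROI, strategy) and column sums.

    Data-driven strategy masks (relative variance across the reconstruction
    set; R2* threshold) are computed once and shared; anatomical masks come
    from the label map; every strategy's reference value is then evaluated
    per volume over its mask.
    """

    recon_names = list(recons)
    roi_ids = sorted(label_map.legend)
    roi_names = [label_map.legend[i] for i in roi_ids]
    strat_names = list(strategies)
    volumes = list(recons.values())

    masks: dict[str, np.ndarray | None] = {}
    for sname, strat in strategies.items():
        masks[sname] = strategy_mask(
            strat, gt.brain_mask, label_map=label_map, volumes=volumes, r2s=r2s
        )

    def ref_of(strat: ReferenceStrategy, mask, vol: SusceptibilityVolume) -> float:
        if strat.kind == "none":
            return 0.0
        if strat.kind == "whole_brain":
            return whole_brain_reference(vol)
        return strategy_reference_value(strat, vol, mask=mask)

    acc = np.zeros((len(recon_names), len(roi_names), len(strat_names)), dtype=bool)
    tvals = np.zeros_like(acc, dtype=float)
    roi_masks = [label_map.mask(i) for i in roi_ids]
    for si, sname in enumerate(strat_names):
        strat = strategies[sname]
        gt_ref = ref_of(strat, masks[sname], gt)
        for ri, rname in enumerate(recon_names):
            vol = recons[rname]
            rec_ref = ref_of(strat, masks[sname], vol)
            for oi, roi_mask in enumerate(roi_masks):
                if not roi_mask.any():
                    raise ValueError(f"ROI {roi_names[oi]!r} has no voxels in the label map")
                ok, res = accuracy_test(vol.values[roi_mask], gt.values[roi_mask], rec_ref, gt_ref, alpha)
                acc[ri, oi, si] = ok
                tvals[ri, oi, si] = res.t
    return AccuracyTable(acc, tvals, recon_names, roi_names, strat_names)


def run_group_pipeline(
    cohort: pd.DataFrame,
    strategy: str,
    alpha: float = 0.05,
    rois: list[str] | None = None,
    correct_age: bool = True,
) -> GroupStatReport:
    """Cohort statistics for one referencing strategy.

    Steps, in order: subtract the per-subject ``ref_<strategy>`` value from
    every ROI mean (referencing on the raw maps), regress out the pooled
    age trend, run a one-way ANOVA per ROI across groups, and run post-hoc
    Tukey-Kramer pairs only for ROIs whose ANOVA p fell below alpha.  The
    variance-change percentage per ROI compares referenced to raw ROI
    means, before age correction.
    """

    ref_col = f"ref_{strategy}"
    if ref_col not in cohort.columns:
        raise ValueError(f"cohort table has no column {ref_col!r}")
    if rois is None:
        rois = [c[: -len("_mean")] for c in cohort.columns if c.endswith("_mean")]
    groups = cohort["group"].to_numpy()
    group_names = list(pd.unique(groups))
    ages = cohort["age"].to_numpy(dtype=float)
    refs = cohort[ref_col].to_numpy(dtype=float)

    anova_rows = []
    tukey_frames = []
    for roi in rois:
        raw = cohort[f"{roi}_mean"].to_numpy(dtype=float)
        referenced = raw - refs
        values = age_correct(referenced, ages) if correct_age else referenced
        per_group = [values[groups == g] for g in group_names]
        f, p = anova_oneway(per_group)
        vc = variance_change(raw, refs)
        anova_rows.append(
            {"roi": roi, "F": f, "p": p, "significant": bool(p < alpha), "var_change_pct": vc}
        )
        if p < alpha:
            tk = tukey_kramer(per_group, labels=group_names)
            tk.insert(0, "roi", roi)
            tk["significant"] = tk["p"] < alpha
            tukey_frames.append(tk)

    anova = pd.DataFrame(anova_rows, columns=["roi", "F", "p", "significant", "var_change_pct"])
    tukey_cols = ["roi", "group1", "group2", "diff", "q", "p", "significant"]
    tukey = (
        pd.concat(tukey_frames, ignore_index=True)[tukey_cols]
        if tukey_frames
        else pd.DataFrame(columns=tukey_cols)
    )
    return GroupStatReport(strategy=strategy, alpha=alpha, anova=anova, tukey=tukey)
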