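"""Reference-region extraction and the referencing operation.

Five strategies are supported:

1. ``anatomical`` — mean (or median) susceptibility of a labelled ROI
   (typically CSF or a white-matter structure such as the corpus callosum
   or internal capsule);
2. ``whole_brain`` — mean over the brain mask;
3. ``relative_variance`` — voxels in the lowest percentile (default 3) of
   |across-volume variance / across-volume mean|;
4. ``r2s_threshold`` — voxels whose R2* falls below a threshold (default
   4 Hz), i.e. fluid-like tissue, independent of anatomical segmentation;
5. ``none`` — no referencing (reference value 0).

Referencing subtracts a single scalar from every value, so it shifts means
but never changes the variance or shape of any fixed voxel set.
"""

from __future__ import annotations

import numpy as np

from .types import EchoSeries, LabelMap, R2sMap, ReferenceStrategy, RVMap, SusceptibilityVolume

__all__ = [
    "region_reference_value",
    "whole_brain_reference",
    "relative_variance_map",
    "low_percentile_mask",
    "fit_r2s",
    "fit_r2s_loglinear",
    "r2s_reference_mask",
    "apply_reference",
    "strategy_mask",
    "strategy_reference_value",
]


def region_reference_value(chi: SusceptibilityVolume, mask: np.ndarray, stat: str = "mean") -> float:
    """Mean or median susceptibility (ppm) over a voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    vals = chi.values[mask]
    if vals.size == 0:
        raise ValueError("reference mask is empty")
    if stat == "mean":
        return float(np.mean(vals))
    if stat == "median":
        return float(np.median(vals))
    raise ValueError("stat must be 'mean' or 'median'")


def whole_brain_reference(chi: SusceptibilityVolume) -> float:
    """Mean susceptibility over the brain mask (ppm)."""
    if not chi.brain_mask.any():
        raise ValueError("brain mask is empty")
    return float(np.mean(chi.values[chi.brain_mask]))


def relative_variance_map(chis: list[SusceptibilityVolume]) -> RVMap:
    """Voxelwise (sample variance across volumes) / (mean across volumes).

    Uses the unbiased (n-1) variance.  Where the across-volume mean is zero
    the ratio is set to +inf so such voxels can never enter the
    low-percentile reference region (their ratio is meaningless).
    """

    if len(chis) < 2:
        raise ValueError("relative variance needs at least 2 volumes")
    shape = chis[0].shape
    for c in chis[1:]:
        if c.shape != shape:
            raise ValueError("all volumes must share one lattice")
    stack = np.stack([c.values for c in chis], axis=0)
    var = np.var(stack, axis=0, ddof=1)
    mean = np.mean(stack, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = var / mean
    ratio = np.where(mean == 0.0, np.inf, ratio)
    return RVMap(ratio, n_inputs=len(chis))


def low_percentile_mask(values: np.ndarray, brain_mask: np.ndarray, percentile: float = 3.0) -> np.ndarray:
    """In-brain voxels whose |value| lies at or below the given percentile.

    Ranking is on the absolute value, so near-zero-mean voxels with huge
    relative-variance magnitude never make the cut and negative ratios do
    not spuriously dominate the low tail.  The percentile is computed with
    linear interpolation between order statistics (numpy default).
    """

    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    mag = np.abs(np.asarray(values, dtype=float))
    in_brain = mag[brain_mask]
    finite = in_brain[np.isfinite(in_brain)]
    if finite.size == 0:
        raise ValueError("no finite values inside brain mask")
    thr = np.percentile(finite, percentile)
    return brain_mask & (mag <= thr)


def _arlo_t2star(y: np.ndarray, dte: float) -> np.ndarray:
    """Closed-form T2* (same unit as dte) via autoregression on linear operations.

    For each consecutive echo triplet, the Simpson-rule integral of the
    signal over the triplet equals T2* times the difference of the outer
    echoes for an exact mono-exponential; the triplets are combined by the
    autoregressive least-squares estimator.
    """

    s = (dte / 3.0) * (y[..., :-2] + 4.0 * y[..., 1:-1] + y[..., 2:])
    d = y[..., :-2] - y[..., 2:]
    ss = np.sum(s * s, axis=-1)
    sd = np.sum(s * d, axis=-1)
    dd = np.sum(d * d, axis=-1)
    num = ss + (dte / 3.0) * sd
    den = sd + (dte / 3.0) * dd
    with np.errstate(divide="ignore", invalid="ignore"):
        t2s = num / den
    return np.where(den == 0.0, np.inf, t2s)


def fit_r2s(echoes: EchoSeries) -> R2sMap:
    """Per-voxel R2* (Hz) from equally spaced multi-echo magnitudes.

    Uses the fast autoregressive (ARLO-style) estimator; negative or
    undefined estimates are clipped to 0 Hz.  The estimate is invariant to
    a positive rescaling of all magnitudes.
    """

    t2s_ms = _arlo_t2star(echoes.magnitudes, echoes.echo_spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2s_hz = 1000.0 / t2s_ms  # ms^-1 -> Hz
    r2s_hz = np.where(np.isfinite(r2s_hz), r2s_hz, 0.0)
    return R2sMap(np.clip(r2s_hz, 0.0, None))


def fit_r2s_loglinear(echoes: EchoSeries, floor: float = 1e-12) -> R2sMap:
    """Log-linear least-squares R2* fit — independent fallback estimator.

    Fits ``log(magnitude)`` against echo time voxelwise.  Magnitudes are
    floored at a tiny positive value before the log.  Agrees with the
    autoregressive estimator on noiseless mono-exponential data.
    """

    te = echoes.echo_times / 1000.0  # s
    y = np.log(np.clip(echoes.magnitudes, floor, None))
    te_c = te - te.mean()
    slope = np.sum(y * te_c, axis=-1) / np.sum(te_c * te_c)
    r2s = np.clip(-slope, 0.0, None)
    return R2sMap(r2s)


def r2s_reference_mask(r2s: R2sMap, brain_mask: np.ndarray, threshold_hz: float = 4.0) -> np.ndarray:
    """In-brain voxels with R2* strictly below the threshold (default 4 Hz).

    Low R2* marks fluid-like, weakly susceptibility-sourced tissue (CSF).
    An empty result raises with a hint to raise the threshold.
    """

    if threshold_hz <= 0:
        raise ValueError("R2* threshold must be positive (Hz)")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    mask = brain_mask & (r2s.values < threshold_hz)
    if not mask.any():
        raise ValueError(
            f"no in-brain voxels with R2* below {threshold_hz} Hz; "
            "increase the threshold to obtain a non-empty reference region"
        )
    return mask


def apply_reference(values, ref_value: float):
    """Subtract a scalar reference from a volume or an array of ROI means.

    A scalar shift: the within-ROI voxel distribution shape and every
    sample variance are unchanged.  Accepts a ``SusceptibilityVolume`` (a
    new volume is returned) or any array-like.
    """

    if not np.isfinite(ref_value):
        raise ValueError("reference value must be finite")
    if isinstance(values, SusceptibilityVolume):
        return SusceptibilityVolume(values.values - ref_value, values.voxel_size, values.brain_mask)
    return np.asarray(values, dtype=float) - float(ref_value)


def strategy_mask(
    strategy: ReferenceStrategy,
    brain_mask: np.ndarray,
    label_map: LabelMap | None = None,
    volumes: list[SusceptibilityVolume] | None = None,
    r2s: R2sMap | None = None,
) -> np.ndarray | None:
    """Voxel mask a strategy reads its reference value from, or None.

    ``none`` and ``whole_brain`` return None (value is 0 / the brain mean).
    ``relative_variance`` needs the full set of volumes; ``r2s_threshold``
    needs an R2* map; ``anatomical`` needs a label map.
    """

    if strategy.kind in ("none", "whole_brain"):
        return None
    if strategy.kind == "anatomical":
        if label_map is None:
            raise ValueError("anatomical strategy requires a label map")
        return label_map.mask(strategy.params["roi"]) & np.asarray(brain_mask, dtype=bool)
    if strategy.kind == "relative_variance":
        if volumes is None:
            raise ValueError("relative-variance strategy requires the volume set")
        rv = relative_variance_map(volumes)
        return low_percentile_mask(rv.values, brain_mask, strategy.params.get("percentile", 3.0))
    if strategy.kind == "r2s_threshold":
        if r2s is None:
            raise ValueError("R2* strategy requires an R2* map")
        return r2s_reference_mask(r2s, brain_mask, strategy.params.get("threshold_hz", 4.0))
    raise ValueError(f"unknown strategy kind {strategy.kind!r}")


def strategy_reference_value(
    strategy: ReferenceStrategy,
    chi: SusceptibilityVolume,
    mask: np.ndarray | None = None,
    **mask_kwargs,
) -> float:
    """Scalar reference value of a strategy for one volume.

    If ``mask`` is given it is used directly (so a mask computed once — e.g.
    from the relative-variance map across all volumes — can be reused for
    every volume); otherwise it is derived via :func:`strategy_mask`.
    """

    if strategy.kind == "none":
        return 0.0
    if strategy.kind == "whole_brain":
        return whole_brain_reference(chi)
    if mask is None:
        mask = strategy_mask(strategy, chi.brain_mask, **mask_kwargs)
    return region_reference_value(chi, mask, strategy.params.get("stat", "mean"))
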