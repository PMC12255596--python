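"""Core containers for susceptibility volumes, label maps, echo series and cohorts.

All susceptibility values are in ppm, relaxation rates in Hz, echo times in
ms, ages in years.  Volumes live on a single voxel lattice (no resampling or
registration is performed anywhere in the package); masks are inclusive
boolean voxel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SusceptibilityVolume",
    "FieldVolume",
    "DipoleKernel",
    "LabelMap",
    "EchoSeries",
    "RVMap",
    "R2sMap",
    "ReferenceStrategy",
    "CohortDesign",
    "SubjectRecord",
    "RoiSummary",
    "WelchResult",
    "GroupStatReport",
    "AccuracyTable",
    "TheoryScanResult",
]


@dataclass
class SusceptibilityVolume:
    """A 3-D susceptibility map (ppm) with voxel size (mm) and a brain mask."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"susceptibility volume must be 3-D, got {self.values.ndim}-D")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.values.shape, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.values.shape:
            raise ValueError("brain mask shape does not match volume shape")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if not np.all(np.isfinite(self.values[self.brain_mask])):
            raise ValueError("non-finite susceptibility values inside brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class FieldVolume:
    """Field perturbation relative to B0 (ppm) produced by the dipole forward model."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("field volume must be 3-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class DipoleKernel:
    """Unit dipole kernel on the discrete spatial-frequency lattice.

    The kernel is ``1/3 - k_b0^2 / |k|^2`` with the zero-frequency value set
    to exactly 0 (the DC component of the field is undefined, which is the
    root of the referencing ambiguity).  Values are confined to [-2/3, 1/3].
    """

    values: np.ndarray
    b0_axis: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dipole kernel must be 3-D")
        flat0 = self.values[(0,) * 3]
        if flat0 != 0.0:
            raise ValueError("dipole kernel must vanish at zero frequency")
        if self.values.min() < -2.0 / 3.0 - 1e-12 or self.values.max() > 1.0 / 3.0 + 1e-12:
            raise ValueError("dipole kernel values outside [-2/3, 1/3]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class LabelMap:
    """Integer ROI labels on the voxel lattice with an id -> name legend.

    Label 0 is reserved for background and never appears in the legend.
    """

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-D")
        self.legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        if 0 in self.legend:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels missing from legend: {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return [self.legend[k] for k in sorted(self.legend)]

    def id_of(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"no ROI named {name!r} in legend")

    def mask(self, roi: int | str) -> np.ndarray:
        """Boolean mask of an ROI given by id or name."""
        if isinstance(roi, str):
            roi = self.id_of(roi)
        return self.labels == int(roi)


@dataclass
class EchoSeries:
    """Multi-echo gradient-echo magnitude data: 4-D array, last axis = echoes.

    Echo times are in ms and must be equally spaced (required by the
    autoregressive R2* estimator); at least three echoes are needed.
    """

    magnitudes: np.ndarray
    echo_times: np.ndarray

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.magnitudes.ndim != 4:
            raise ValueError("echo series must be 4-D (x, y, z, echo)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.magnitudes.shape[-1]:
            raise ValueError("echo_times length must match the last magnitude axis")
        if self.echo_times.size < 3:
            raise ValueError("at least 3 echoes are required")
        dte = np.diff(self.echo_times)
        if np.any(dte <= 0):
            raise ValueError("echo times must be strictly increasing")
        if not np.allclose(dte, dte[0], rtol=1e-6, atol=1e-9):
            raise ValueError("echo times must be equally spaced")
        if self.magnitudes.min() < 0:
            raise ValueError("magnitudes must be nonnegative")

    @property
    def echo_spacing(self) -> float:
        """Echo spacing in ms."""
        return float(self.echo_times[1] - self.echo_times[0])


@dataclass
class RVMap:
    """Voxelwise relative variance: across-volume sample variance / mean."""

    values: np.ndarray
    n_inputs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_inputs < 2:
            raise ValueError("relative variance needs at least 2 input volumes")


@dataclass
class R2sMap:
    """Effective transverse relaxation rate map in Hz, clipped at 0."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("R2* map must be 3-D")
        if np.nanmin(self.values) < 0:
            raise ValueError("R2* values must be nonnegative (clip before constructing)")


@dataclass
class ReferenceStrategy:
    """A referencing strategy specification.

    kind:
        ``none`` | ``anatomical`` | ``whole_brain`` | ``relative_variance`` |
        ``r2s_threshold``
    params:
        anatomical: ``roi`` (label id or name), optional ``stat`` (mean|median);
        relative_variance: ``percentile`` (default 3);
        r2s_threshold: ``threshold_hz`` (default 4).
    """

    kind: str
    params: dict = field(default_factory=dict)

    VALID_KINDS = ("none", "anatomical", "whole_brain", "relative_variance", "r2s_threshold")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        p = self.params.get("percentile")
        if p is not None and not (0 < float(p) < 100):
            raise ValueError("percentile must be in (0, 100)")
        t = self.params.get("threshold_hz")
        if t is not None and float(t) <= 0:
            raise ValueError("R2* threshold must be positive (Hz)")
        stat = self.params.get("stat", "mean")
        if stat not in ("mean", "median"):
            raise ValueError("stat must be 'mean' or 'median'")


@dataclass
class CohortDesign:
    """Sampling model for a multi-group cohort of per-subject ROI means.

    Each subject s in group g draws, for every ROI,

        mean(s, roi) = mu[g, roi] + b_s + age_slope * (age_s - midrange age)
                       + eps(s, roi)

    with a shared subject offset b_s ~ N(0, subject_offset_sd^2) — the
    common across-brain susceptibility shift that referencing is meant to
    remove — and independent eps ~ N(0, roi_sd[roi]^2).  ROIs listed in
    ``reference_rois`` additionally receive ``ref_pathology_shift[g]``,
    modelling disease-related change in a would-be reference region.
    """

    group_sizes: dict[str, int]
    roi_means: dict[tuple[str, str], float]
    roi_sd: dict[str, float]
    subject_offset_sd: float = 0.005
    reference_rois: tuple[str, ...] = ()
    ref_pathology_shift: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (16.0, 67.0)
    age_slope: float = 0.0
    whole_brain_ref_sd: float = 0.0005
    r2s_ref_jitter_sd: float = 0.002
    relvar_ref_jitter_sd: float = 0.003
    within_roi_sd: float = 0.01
    roi_voxel_count: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if any(sd < 0 for sd in self.roi_sd.values()):
            raise ValueError("ROI standard deviations must be nonnegative")
        if self.subject_offset_sd < 0:
            raise ValueError("subject offset sd must be nonnegative")
        for g in self.ref_pathology_shift:
            if g not in self.group_sizes:
                raise ValueError(f"pathology shift given for unknown group {g!r}")
        groups = set(self.group_sizes)
        rois = self.rois
        for (g, roi) in self.roi_means:
            if g not in groups:
                raise ValueError(f"roi_means contains unknown group {g!r}")
        for roi in rois:
            if roi not in self.roi_sd:
                raise ValueError(f"missing roi_sd for {roi!r}")

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)

    @property
    def rois(self) -> list[str]:
        seen: list[str] = []
        for (_, roi) in self.roi_means:
            if roi not in seen:
                seen.append(roi)
        return seen


@dataclass
class SubjectRecord:
    """One simulated subject: ROI summaries plus per-strategy reference values."""

    subject_id: str
    group: str
    age: float
    roi_mean: dict[str, float]
    roi_sd: dict[str, float]
    roi_n: dict[str, int]
    reference_values: dict[str, float]

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.roi_n.values()):
            raise ValueError("reported ROI voxel counts must be positive")


@dataclass
class RoiSummary:
    """Mean/sd of an ROI after erosion and percentile trimming."""

    name: str
    mean: float
    sd: float
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValueError("voxel count cannot grow during preprocessing")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class WelchResult:
    """Two-sample t test with unequal variances.

    ``s2_d`` is the unbiased estimate of Var(x̄ - ȳ):
    ``s2_x / n + s2_y / m`` — the identity holds exactly by construction.
    """

    t: float
    df: float
    p: float
    s2_x: float
    s2_y: float
    s2_d: float
    n: int
    m: int


@dataclass
class GroupStatReport:
    """Per-ROI ANOVA, gated post-hoc Tukey-Kramer pairs, and variance change.

    ``tukey`` only contains rows for ROIs whose ANOVA p-value fell below
    alpha (post-hoc gating).
    """

    strategy: str
    alpha: float
    anova: "pd.DataFrame"  # roi, F, p, significant, var_change_pct
    tukey: "pd.DataFrame"  # roi, group1, group2, diff, q, p, significant


@dataclass
class AccuracyTable:
    """Accuracy booleans per (reconstruction, ROI, strategy) plus column sums."""

    accurate: np.ndarray  # bool, shape (n_recon, n_roi, n_strategy)
    t_values: np.ndarray
    recon_names: list[str]
    roi_names: list[str]
    strategy_names: list[str]

    def counts(self) -> np.ndarray:
        """Accurate-ROI count per strategy (summed over reconstructions and ROIs)."""
        return self.accurate.sum(axis=(0, 1))

    def to_frame(self):
        """ROI x strategy table of accurate-reconstruction counts with a Sum row."""
        import pandas as pd

        counts = self.accurate.sum(axis=0)  # (n_roi, n_strategy)
        df = pd.DataFrame(counts, index=self.roi_names, columns=self.strategy_names)
        df.loc["Sum"] = df.sum(axis=0)
        df.index.name = "roi"
        return df


@dataclass
class TheoryScanResult:
    """Monte-Carlo scan of referenced variance against correlation."""

    table: "pd.DataFrame"  # rho, ratio_analytic, ratio_mc, n
    n_per_point: int
    seed: int
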