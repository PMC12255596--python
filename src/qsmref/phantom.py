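"""Synthetic phantom generation and the dipole forward/inverse model.

The phantom is parametric (spheres / ellipsoids / boxes inside a spherical
"brain") rather than anatomical, so every ROI mean is exact by construction.
The forward model is the standard susceptibility-to-field convolution

    field = F^-1[ D(k) . F[chi] ],   D(k) = 1/3 - k_b0^2 / |k|^2,  D(0) = 0,

and the reconstruction emulators are the two classical direct dipole
inversions: thresholded k-space division (TKD) and direct Tikhonov.
Because D(0) = 0, every forward field and every reconstruction has zero
lattice mean — the DC offset of a susceptibility map is fundamentally
undetermined, which is what makes referencing necessary in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import DipoleKernel, EchoSeries, FieldVolume, LabelMap, SusceptibilityVolume

__all__ = [
    "RoiGeometry",
    "TEST_ROI_NAMES",
    "DEFAULT_CHI_PPM",
    "DEFAULT_R2S_HZ",
    "default_roi_geometry",
    "build_phantom",
    "r2s_phantom",
    "dipole_kernel",
    "forward_field",
    "reconstruct",
    "simulate_echoes",
    "reconstruction_suite",
]

#: The nine test ROIs used throughout: three typical reference regions
#: (CSF, corpus callosum, internal capsule) and six deep grey-matter nuclei.
TEST_ROI_NAMES = (
    "CSF",
    "corpus_callosum",
    "internal_capsule",
    "amygdala",
    "caudate",
    "pallidum",
    "putamen",
    "thalamus",
    "hippocampus",
)

#: Piecewise-constant susceptibility per ROI (ppm), typical literature values
#: relative to surrounding tissue: CSF near water, myelinated white matter
#: diamagnetic, iron-rich nuclei paramagnetic.
DEFAULT_CHI_PPM = {
    "CSF": 0.0,
    "corpus_callosum": -0.03,
    "internal_capsule": -0.05,
    "amygdala": 0.02,
    "caudate": 0.05,
    "pallidum": 0.13,
    "putamen": 0.09,
    "thalamus": 0.01,
    "hippocampus": 0.03,
}

#: R2* per ROI (Hz).  CSF is fluid-like (~1 Hz); everything else is
#: parenchyma-like (>= 20 Hz) so a low-Hz threshold isolates CSF exactly.
DEFAULT_R2S_HZ = {
    "CSF": 1.0,
    "corpus_callosum": 20.0,
    "internal_capsule": 21.0,
    "amygdala": 25.0,
    "caudate": 26.0,
    "pallidum": 45.0,
    "putamen": 30.0,
    "thalamus": 22.0,
    "hippocampus": 24.0,
}


@dataclass
class RoiGeometry:
    """One parametric ROI: a sphere, axis-aligned ellipsoid, or box.

    ``size`` is a radius (sphere), three semi-axes (ellipsoid) or three
    half-widths (box), all in voxels; ``center`` is in 0-based voxel
    coordinates.
    """

    name: str
    kind: str
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]

    def voxel_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij", sparse=True)
        c = self.center
        if self.kind == "sphere":
            r = float(self.size)
            d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
            return d2 <= r * r
        if self.kind == "ellipsoid":
            ax = np.asarray(self.size, dtype=float)
            d2 = sum(((g - ci) / a) ** 2 for g, ci, a in zip(grids, c, ax))
            return d2 <= 1.0
        if self.kind == "box":
            hw = np.asarray(self.size, dtype=float)
            inside = np.ones(shape, dtype=bool)
            for g, ci, h in zip(grids, c, hw):
                inside &= np.abs(g - ci) <= h
            return inside
        raise ValueError(f"unknown geometry kind {self.kind!r}")


def default_roi_geometry(shape: tuple[int, int, int] = (48, 48, 48)) -> tuple[RoiGeometry, list[RoiGeometry]]:
    """Default brain sphere plus nine disjoint spherical test ROIs.

    Positions and radii scale with the lattice so the layout is valid for
    any cubic shape >= 32.  Returns ``(brain, rois)``.
    """

    n = min(shape)
    if n < 32:
        raise ValueError("default geometry requires a lattice of at least 32 voxels per axis")
    c = tuple(s / 2.0 for s in shape)
    scale = n / 48.0
    r = 4.0 * scale
    brain = RoiGeometry("brain", "sphere", c, 21.0 * scale)
    off = 9.0 * scale
    cx, cy, cz = c
    centers = {
        "CSF": (cx, cy, cz + off),
        "corpus_callosum": (cx, cy, cz - off),
        "internal_capsule": (cx - off, cy, cz),
        "amygdala": (cx + off, cy, cz),
        "caudate": (cx, cy - off, cz),
        "pallidum": (cx, cy + off, cz),
        "putamen": (cx - off, cy - off, cz),
        "thalamus": (cx + off, cy + off, cz),
        "hippocampus": (cx + off, cy - off, cz),
    }
    rois = [RoiGeometry(name, "sphere", centers[name], r) for name in TEST_ROI_NAMES]
    return brain, rois


def build_phantom(
    lattice_shape: tuple[int, int, int] = (48, 48, 48),
    roi_geometry: list[RoiGeometry] | None = None,
    chi_per_roi: dict[str, float] | None = None,
    brain: RoiGeometry | None = None,
    background_chi: float = 0.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[SusceptibilityVolume, LabelMap]:
    """Build a piecewise-constant susceptibility phantom and its label map.

    ROI geometries must be pairwise disjoint and lie inside the lattice;
    overlapping or out-of-lattice geometries raise ``ValueError``.  Each
    ROI's voxel set matches its geometry exactly, so its mean susceptibility
    is exactly the assigned value.
    """

    if roi_geometry is None or brain is None:
        default_brain, default_rois = default_roi_geometry(lattice_shape)
        brain = brain or default_brain
        roi_geometry = roi_geometry if roi_geometry is not None else default_rois
    chi_per_roi = dict(DEFAULT_CHI_PPM if chi_per_roi is None else chi_per_roi)

    shape = tuple(int(s) for s in lattice_shape)
    values = np.full(shape, float(background_chi))
    labels = np.zeros(shape, dtype=np.int32)
    legend: dict[int, str] = {}
    brain_mask = brain.voxel_mask(shape)

    claimed = np.zeros(shape, dtype=bool)
    for i, geom in enumerate(roi_geometry, start=1):
        mask = geom.voxel_mask(shape)
        if not mask.any():
            raise ValueError(f"ROI {geom.name!r} has no voxels inside the lattice")
        # geometry must fit: its continuous extent may not touch the lattice edge
        lo = np.array(geom.center) - np.max(np.atleast_1d(np.asarray(geom.size, dtype=float)))
        hi = np.array(geom.center) + np.max(np.atleast_1d(np.asarray(geom.size, dtype=float)))
        if np.any(lo < 0) or np.any(hi > np.array(shape) - 1):
            raise ValueError(f"ROI {geom.name!r} extends outside the lattice")
        if (mask & claimed).any():
            raise ValueError(f"ROI {geom.name!r} overlaps a previously placed ROI")
        claimed |= mask
        if geom.name not in chi_per_roi:
            raise ValueError(f"no susceptibility value given for ROI {geom.name!r}")
        values[mask] = float(chi_per_roi[geom.name])
        labels[mask] = i
        legend[i] = geom.name

    brain_mask |= claimed  # every ROI voxel counts as brain
    vol = SusceptibilityVolume(values, voxel_size=voxel_size, brain_mask=brain_mask)
    return vol, LabelMap(labels, legend)


def r2s_phantom(
    label_map: LabelMap,
    r2s_per_roi: dict[str, float] | None = None,
    background_hz: float = 20.0,
    brain_mask: np.ndarray | None = None,
    outside_hz: float = 0.0,
) -> np.ndarray:
    """Piecewise-constant R2* map (Hz) matching a label map."""

    r2s_per_roi = dict(DEFAULT_R2S_HZ if r2s_per_roi is None else r2s_per_roi)
    out = np.full(label_map.labels.shape, float(background_hz))
    for lid, name in label_map.legend.items():
        out[label_map.labels == lid] = float(r2s_per_roi.get(name, background_hz))
    if brain_mask is not None:
        out[~brain_mask] = float(outside_hz)
    return out


def dipole_kernel(
    lattice_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    b0_axis: int = 2,
) -> DipoleKernel:
    """Unit dipole kernel D(k) = 1/3 - k_b0^2/|k|^2 on the unshifted FFT lattice.

    The zero-frequency value is set to exactly 0: the mean field offset
    carries no information about the mean susceptibility.
    """

    shape = tuple(int(s) for s in lattice_shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("lattice shape must be three positive integers")
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel size must be positive")
    b0_axis = int(b0_axis)
    if b0_axis not in (0, 1, 2):
        raise ValueError("b0_axis must be 0, 1 or 2")
    if shape[b0_axis] == 1:
        raise ValueError("degenerate (size-1) axis along B0")

    ks = [np.fft.fftfreq(n, d=dv) for n, dv in zip(shape, voxel_size)]
    kg = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = sum(k**2 for k in kg)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (kg[b0_axis] ** 2) / k2
    d = np.asarray(d)
    d[(0, 0, 0)] = 0.0
    return DipoleKernel(d, b0_axis=b0_axis)


def forward_field(chi: SusceptibilityVolume, kernel: DipoleKernel) -> FieldVolume:
    """Field perturbation (ppm) from a susceptibility distribution.

    Spectral multiplication with the dipole kernel; the output has zero
    lattice mean because the kernel annihilates the DC component.
    """

    if chi.shape != kernel.shape:
        raise ValueError("susceptibility volume and kernel shapes differ")
    spec = np.fft.fftn(chi.values)
    field = np.fft.ifftn(spec * kernel.values).real
    return FieldVolume(field, voxel_size=chi.voxel_size)


def reconstruct(
    field: FieldVolume,
    method: str = "tkd",
    delta: float = 0.2,
    lam: float = 0.05,
    b0_axis: int = 2,
) -> SusceptibilityVolume:
    """Direct dipole inversion of a field map.

    ``tkd``: divide the field spectrum by D, replacing |D| < delta by
    sign(D)*delta (sign 0 treated as +) — thresholded k-space division.
    ``tikhonov``: multiply by D/(D^2 + lam).  Both leave the undefined DC
    term at zero, so the output lattice mean is ~0.
    """

    kernel = dipole_kernel(field.shape, field.voxel_size, b0_axis=b0_axis)
    d = kernel.values
    spec = np.fft.fftn(field.values)
    if method == "tkd":
        if delta <= 0:
            raise ValueError("TKD threshold delta must be positive")
        sign = np.where(d < 0, -1.0, 1.0)  # sign(0) -> +
        d_trunc = np.where(np.abs(d) < delta, sign * delta, d)
        chi_spec = spec / d_trunc
    elif method == "tikhonov":
        if lam <= 0:
            raise ValueError("Tikhonov lambda must be positive (0 gives an undefined inverse)")
        chi_spec = spec * d / (d**2 + lam)
    else:
        raise ValueError(f"unknown reconstruction method {method!r}")
    chi_spec[(0, 0, 0)] = 0.0
    chi = np.fft.ifftn(chi_spec).real
    return SusceptibilityVolume(chi, voxel_size=field.voxel_size)


def simulate_echoes(
    m0: np.ndarray,
    r2s_map: np.ndarray,
    echo_times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EchoSeries:
    """Mono-exponential multi-echo magnitude decay with Gaussian noise.

    ``magnitude = m0 * exp(-R2* * TE)`` (TE in ms, R2* in Hz) plus seeded
    Gaussian noise, clipped at zero.  Noise is Gaussian on the magnitude,
    not Rician — adequate at the simulated SNRs.
    """

    m0 = np.asarray(m0, dtype=float)
    r2s_map = np.asarray(r2s_map, dtype=float)
    if np.any(r2s_map < 0):
        raise ValueError("R2* map must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    te = np.asarray(echo_times, dtype=float)
    decay = np.exp(-r2s_map[..., None] * te / 1000.0)  # ms * Hz -> dimensionless
    mags = m0[..., None] * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mags = mags + rng.normal(0.0, noise_sd, size=mags.shape)
    return EchoSeries(np.clip(mags, 0.0, None), te)


def reconstruction_suite(
    gt: SusceptibilityVolume,
    smooth_sigma: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    methods: dict[str, dict] | None = None,
    b0_axis: int = 2,
) -> tuple[SusceptibilityVolume, dict[str, SusceptibilityVolume]]:
    """Emulate a set of imperfect reconstructions of one ground-truth phantom.

    The ground truth is lightly smoothed (partial-volume-like), passed
    through the dipole forward model (with optional field noise), and
    inverted with a spread of TKD thresholds and Tikhonov weights.  Returns
    the smoothed ground truth and a name -> volume mapping of
    reconstructions, all sharing the ground truth's brain mask.
    """

    if methods is None:
        methods = {
            "tkd_d10": {"method": "tkd", "delta": 0.10},
            "tkd_d20": {"method": "tkd", "delta": 0.20},
            "tkd_d30": {"method": "tkd", "delta": 0.30},
            "tik_l01": {"method": "tikhonov", "lam": 0.01},
            "tik_l05": {"method": "tikhonov", "lam": 0.05},
            "tik_l15": {"method": "tikhonov", "lam": 0.15},
        }
    values = gt.values
    if smooth_sigma > 0:
        values = gaussian_filter(values, smooth_sigma)
    gt_smooth = SusceptibilityVolume(values, gt.voxel_size, gt.brain_mask)
    kernel = dipole_kernel(gt.shape, gt.voxel_size, b0_axis=b0_axis)
    field = forward_field(gt_smooth, kernel)
    rng = np.random.default_rng(seed)
    recons: dict[str, SusceptibilityVolume] = {}
    for name, params in methods.items():
        fvals = field.values
        if noise_sd > 0:
            fvals = fvals + rng.normal(0.0, noise_sd, size=fvals.shape)
        noisy = FieldVolume(fvals, field.voxel_size)
        rec = reconstruct(noisy, b0_axis=b0_axis, **params)
        recons[name] = SusceptibilityVolume(rec.values, gt.voxel_size, gt.brain_mask)
    return gt_smooth, recons
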