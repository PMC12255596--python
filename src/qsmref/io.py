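"""NIfTI / CSV / JSON / YAML I/O.

Volumes, label maps and masks travel as NIfTI-1; echo times and ROI
legends as JSON sidecars (``<stem>.json``); cohort tables and reports as
comma-separated UTF-8 CSV with a mandatory header and ``.`` decimal.
Report writing is deterministic: fixed column order and fixed float
precision, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .types import (
    AccuracyTable,
    EchoSeries,
    GroupStatReport,
    LabelMap,
    SusceptibilityVolume,
    TheoryScanResult,
)

__all__ = [
    "sidecar_path",
    "write_volume",
    "write_labels",
    "write_mask",
    "write_echoes",
    "read_volume",
    "write_report",
    "load_config",
    "dump_config",
]

FLOAT_FORMAT = "%.10g"


def sidecar_path(path) -> Path:
    """JSON sidecar next to a NIfTI file (``x.nii`` / ``x.nii.gz`` -> ``x.json``)."""
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


def write_volume(vol: SusceptibilityVolume, path) -> Path:
    """Write a susceptibility volume (float64, voxel size in the affine)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.voxel_size))
    nib.save(img, path)
    return path


def write_mask(mask: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a boolean mask as 0/1 uint8 NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, path)
    return path


def write_labels(label_map: LabelMap, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a label map plus its legend sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(label_map.labels.astype(np.int32), _affine(voxel_size))
    nib.save(img, path)
    sidecar_path(path).write_text(
        json.dumps({"legend": {str(k): v for k, v in sorted(label_map.legend.items())}}, indent=1)
    )
    return path


def write_echoes(echoes: EchoSeries, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a 4-D echo series plus an echo-time (ms) sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(echoes.magnitudes.astype(np.float64), _affine(voxel_size))
    nib.save(img, path)
    sidecar_path(path).write_text(json.dumps({"EchoTimes_ms": list(map(float, echoes.echo_times))}))
    return path


def read_volume(path, mask: np.ndarray | None = None):
    """Read a NIfTI file, dispatching on dimensionality and dtype.

    3-D float -> :class:`SusceptibilityVolume` (mask defaults to all-true);
    3-D integer -> :class:`LabelMap` (legend from the JSON sidecar, or
    ``roi_<id>`` placeholders); 4-D -> :class:`EchoSeries` (requires the
    echo-time sidecar).  Anything else raises ``ValueError``.
    """

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if data.ndim == 4:
        sc = sidecar_path(path)
        if not sc.exists():
            raise ValueError(f"4-D series {path} requires an echo-time sidecar {sc}")
        meta = json.loads(sc.read_text())
        if "EchoTimes_ms" not in meta:
            raise ValueError(f"sidecar {sc} has no 'EchoTimes_ms' entry")
        return EchoSeries(data.astype(float), np.asarray(meta["EchoTimes_ms"], dtype=float))
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D or 4-D NIfTI payload, got {data.ndim}-D in {path}")
    if np.issubdtype(data.dtype, np.integer):
        sc = sidecar_path(path)
        if sc.exists():
            legend = {int(k): v for k, v in json.loads(sc.read_text())["legend"].items()}
        else:
            legend = {int(i): f"roi_{int(i)}" for i in np.unique(data) if i != 0}
        return LabelMap(data, legend)
    return SusceptibilityVolume(data.astype(float), voxel_size=voxel_size, brain_mask=mask)


def read_mask(path) -> np.ndarray:
    """Read a 0/1 NIfTI mask as boolean."""
    img = nib.load(Path(path))
    return np.asanyarray(img.dataobj) > 0


def write_report(report, path) -> Path:
    """Write a report object as deterministic CSV.

    ``GroupStatReport`` writes the ANOVA table to ``path`` and the gated
    Tukey pairs to ``<stem>_tukey.csv``; ``AccuracyTable`` writes the
    ROI x strategy count matrix with a Sum row; ``TheoryScanResult`` and
    plain DataFrames write as-is.
    """

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(report, GroupStatReport):
        report.anova.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        tukey_path = path.with_name(path.stem + "_tukey" + path.suffix)
        report.tukey.to_csv(tukey_path, index=False, float_format=FLOAT_FORMAT)
        return path
    if isinstance(report, AccuracyTable):
        report.to_frame().to_csv(path, float_format=FLOAT_FORMAT)
        return path
    if isinstance(report, TheoryScanResult):
        report.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        return path
    # plain DataFrame fallback
    report.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_config(path) -> dict:
    """Load a YAML run configuration; always returns a dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = yaml.safe_load(path.read_text())
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    """Write the resolved configuration next to a run's outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
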