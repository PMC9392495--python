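"""Readers/writers: NIfTI velocity volumes, HDF5 masks/k-space, YAML
configuration, JSON/CSV reports and run manifests.

Velocity NIfTI convention: one scalar 4D file per component with suffixes
``_vx``/``_vy``/``_vz`` plus ``_mag``, RAS+ affine with the isotropic voxel
size on the diagonal, values in cm/s.  The venc and provenance travel in a
JSON sidecar (``_meta.json``); if absent, the venc must be supplied
explicitly on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .experiment import ExperimentConfig, ExperimentReport
from .recon import VelocityVolume
from .sampling import AccelerationReport, KtMask, SamplingGeometry

__all__ = [
    "write_velocity_nifti", "read_velocity_nifti",
    "write_masks_h5", "read_masks_h5",
    "write_report", "report_rows",
    "load_experiment_config", "write_manifest",
]

_COMPONENT_SUFFIXES = ("vx", "vy", "vz")

REPORT_CSV_COLUMNS = [
    "r", "z", "r_total", "r_zf", "time_savings_vs_z0", "tpr_pct",
    "n_ref_aliased", "noise_lv_pct", "noise_hv_pct", "noise_dv_pct",
    "bias_mean", "bias_peak", "loa_mean_lower_pct", "loa_mean_upper_pct",
    "loa_peak_lower_pct", "loa_peak_upper_pct",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_velocity_nifti(vol: VelocityVolume, prefix: str | Path) -> list[Path]:
    """Write one 4D NIfTI per velocity component plus magnitude + sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol.voxel_size_mm)
    paths = []
    for d, suf in enumerate(_COMPONENT_SUFFIXES):
        p = prefix.parent / f"{prefix.name}_{suf}.nii.gz"
        nib.save(nib.Nifti1Image(vol.velocity[d].astype(np.float32), aff), p)
        paths.append(p)
    p = prefix.parent / f"{prefix.name}_mag.nii.gz"
    nib.save(nib.Nifti1Image(vol.magnitude.astype(np.float32), aff), p)
    paths.append(p)
    meta = {"venc": vol.venc, "role": vol.role,
            "voxel_size_mm": vol.voxel_size_mm, "provenance": vol.provenance}
    mp = prefix.parent / f"{prefix.name}_meta.json"
    mp.write_text(json.dumps(meta, indent=2))
    paths.append(mp)
    return paths


def read_velocity_nifti(prefix: str | Path, venc: float | None = None,
                        role: str | None = None) -> VelocityVolume:
    """Read a velocity volume written by :func:`write_velocity_nifti`.

    Header scaling (scl_slope/scl_inter) is applied by nibabel; shapes and
    affines of the component files must agree.
    """
    prefix = Path(prefix)
    imgs = [nib.load(prefix.parent / f"{prefix.name}_{suf}.nii.gz")
            for suf in _COMPONENT_SUFFIXES]
    mag_img = nib.load(prefix.parent / f"{prefix.name}_mag.nii.gz")
    shapes = {im.shape for im in imgs} | {mag_img.shape}
    if len(shapes) != 1:
        raise ValueError(f"component shapes disagree: {sorted(shapes)}")
    affines = [im.affine for im in imgs] + [mag_img.affine]
    if any(not np.allclose(a, affines[0]) for a in affines[1:]):
        raise ValueError("component affines disagree")

    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if venc is None:
        venc = meta.get("venc")
    if venc is None:
        raise ValueError("venc metadata missing; pass venc explicitly")

    vel = np.stack([im.get_fdata(dtype=np.float32) for im in imgs], axis=0)
    return VelocityVolume(
        velocity=vel,
        magnitude=mag_img.get_fdata(dtype=np.float32),
        venc=float(venc),
        role=role or meta.get("role", "LV"),
        voxel_size_mm=float(meta.get("voxel_size_mm", abs(affines[0][0, 0]))),
        provenance=meta.get("provenance", {}),
    )


def _geometry_attrs(geom: SamplingGeometry) -> dict:
    return {f.name: getattr(geom, f.name) for f in dataclasses.fields(geom)}


def write_masks_h5(path: str | Path, lv_mask: KtMask, hv_mask: KtMask) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("lv_mask", data=lv_mask.acquired, compression="gzip")
        f.create_dataset("hv_mask", data=hv_mask.acquired, compression="gzip")
        for k, v in _geometry_attrs(lv_mask.geometry).items():
            f.attrs[k] = v
    return path


def read_masks_h5(path: str | Path) -> tuple[KtMask, KtMask]:
    with h5py.File(path, "r") as f:
        geom = SamplingGeometry(**{k: (v.item() if hasattr(v, "item") else v)
                                   for k, v in f.attrs.items()})
        lv = KtMask(np.asarray(f["lv_mask"], dtype=bool), geom, "LV")
        hv = KtMask(np.asarray(f["hv_mask"], dtype=bool), geom, "HV")
    return lv, hv


def write_acceleration_json(report: AccelerationReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.as_dict(), indent=2))
    return path


def report_rows(report: ExperimentReport) -> list[dict]:
    """JSON-safe per-cell rows of an experiment report, fixed key order."""
    frame = report.to_frame()
    return [{k: row[k] for k in REPORT_CSV_COLUMNS}
            for row in frame.to_dict(orient="records")]


_REQUIRED_REPORT_KEYS = {"noise_sd", "seed", "cells"}


def write_report(report: ExperimentReport, path: str | Path,
                 format: str = "json") -> Path:
    """Write an experiment report; JSON carries the full structure, CSV the
    per-cell rows in a fixed, documented column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        doc = {"noise_sd": report.noise_sd, "seed": report.seed,
               "cells": report_rows(report),
               "summary": {
                   "min_tpr_pct": report.min_tpr(),
                   "max_loa_halfwidth_pct_ref": report.max_loa_halfwidth_pct_ref(),
               }}
        missing = _REQUIRED_REPORT_KEYS - doc.keys()
        if missing:  # schema guard for future edits
            raise ValueError(f"report missing keys: {missing}")
        path.write_text(json.dumps(doc, indent=2))
    elif format == "csv":
        report.to_frame()[REPORT_CSV_COLUMNS].to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return path


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file of scalar overrides."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {f.name for f in dataclasses.fields(ExperimentConfig)} - {"phantom"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("r_values", "z_values"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return ExperimentConfig(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: ExperimentConfig,
                   extra: dict | None = None) -> Path:
    """Manifest with tool version, config hash, seed and file checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    cfg_doc = {f.name: getattr(config, f.name)
               for f in dataclasses.fields(config) if f.name != "phantom"}
    cfg_yaml = yaml.safe_dump(cfg_doc, sort_keys=True)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "tool": "vsrdv", "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "config": cfg_doc,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
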