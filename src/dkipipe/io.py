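"""File I/O: NIfTI volumes, FSL-dialect gradient tables, cohort CSVs and
streamline point lists."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme
from .tractography import Streamline

__all__ = [
    "save_nifti", "load_nifti", "save_dwi", "load_dwi",
    "write_bval_bvec", "read_bval_bvec", "scheme_from_tables",
    "save_metric_maps", "write_streamlines_text", "read_streamlines_text",
]

#: conversion from internal mm^2/s diffusivities to the conventional
#: 10^-3 mm^2/s printing used in maps and tables
DIFFUSIVITY_SCALE = 1.0e3
DIFFUSIVITY_METRICS = ("md", "d_axial", "d_radial")


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None,
               dtype=np.float32) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """FSL dialect: bvals as one space-separated row; bvecs as three rows of
    x / y / z components, one column per volume."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError("bval/bvec volume counts disagree")
    return bvals, bvecs


def scheme_from_tables(bvals: np.ndarray, bvecs: np.ndarray) -> AcquisitionScheme:
    """Reconstruct a scheme from per-volume tables.

    Expects the layout written by :func:`write_bval_bvec`: b0 volumes first,
    then one block of identical directions per shell.
    """
    bvals = np.asarray(bvals, dtype=float)
    b0 = bvals == 0
    n_b0 = int(b0.sum())
    shells = sorted(set(bvals[~b0]))
    n_dir = int((~b0).sum() / len(shells)) if shells else 0
    dirs = np.asarray(bvecs, dtype=float)[~b0][:n_dir]
    return AcquisitionScheme(directions=dirs, shells=tuple(shells), n_b0=n_b0)


def save_dwi(path_prefix, dwi: np.ndarray, scheme: AcquisitionScheme,
             affine: np.ndarray | None = None) -> None:
    """Write <prefix>.nii.gz plus <prefix>.bval / <prefix>.bvec."""
    prefix = Path(path_prefix)
    save_nifti(prefix.with_suffix(".nii.gz"), dwi, affine)
    write_bval_bvec(scheme, prefix.with_suffix(".bval"), prefix.with_suffix(".bvec"))


def load_dwi(path_prefix):
    prefix = Path(path_prefix)
    data, affine = load_nifti(prefix.with_suffix(".nii.gz"))
    bvals, bvecs = read_bval_bvec(prefix.with_suffix(".bval"),
                                  prefix.with_suffix(".bvec"))
    return data, affine, scheme_from_tables(bvals, bvecs)


def save_metric_maps(out_dir, maps: dict[str, np.ndarray],
                     affine: np.ndarray | None = None) -> None:
    """Write the seven scalar maps as float32 NIfTI, diffusivities scaled to
    10^-3 mm^2/s."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, data in maps.items():
        scale = DIFFUSIVITY_SCALE if name in DIFFUSIVITY_METRICS else 1.0
        save_nifti(out / f"{name}.nii.gz", np.asarray(data) * scale, affine)


def write_streamlines_text(path, streamlines: list[Streamline]) -> None:
    """Plain whitespace-delimited point lists: one streamline per block,
    blocks separated by a blank line, columns x y z in mm."""
    with open(path, "w") as fh:
        for sl in streamlines:
            for x, y, z in sl.points:
                fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
            fh.write("\n")


def read_streamlines_text(path) -> list[np.ndarray]:
    blocks: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if current:
                    blocks.append(np.array(current))
                    current = []
                continue
            current.append([float(v) for v in line.split()])
    if current:
        blocks.append(np.array(current))
    return blocks
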