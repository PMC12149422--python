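"""Thin NIfTI helpers around nibabel.

Volumes are stored with a diagonal affine built from the voxel spacing.
Gzipped output is produced with ``mtime=0`` so that repeated writes of
identical data are byte-identical (plain ``nibabel`` embeds the wall clock
in the gzip header, which breaks manifest checksums).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(array: np.ndarray, spacing, path) -> None:
    """Write ``array`` with the given voxel spacing (mm) to ``path``.

    ``.nii.gz`` paths are compressed deterministically.
    """
    path = Path(path)
    affine = np.diag([float(spacing[0]), float(spacing[1]), float(spacing[2]), 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    if path.name.endswith(".nii.gz"):
        path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
    else:
        img.to_filename(str(path))


def load_nifti(path):
    """Read a volume; returns ``(array, spacing)`` with spacing in mm."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing
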