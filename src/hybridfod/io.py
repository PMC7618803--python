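"""Readers and writers for the on-disk formats the pipeline touches.

* FOD images: 4D NIfTI with one volume per SH coefficient, even degrees
  l = 0..8 ordered l ascending then m ascending (-l..l), real orthonormal
  basis (see :mod:`hybridfod.sh`).  Provenance is stored in a sidecar
  NIfTI when requested.
* Tractograms: TCK (primary, world mm) and TRK via nibabel.streamlines.
* Ball-and-Stick fields: bedpostX-style per-population volumes
  (merged_th<k>samples / merged_ph<k>samples / mean_f<k>samples) or a
  single-file NPZ container.
* Microscopy maps: 32-bit float TIFF (angles, retardance, transmittance)
  and 8-bit masks.
* Connectivity matrices: CSV with a header row of target labels and an
  index column of seed labels.
* Affines: NIfTI headers or 4x4 plain-text (FLIRT-style) matrices.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .evaluate import ConnectivityMatrix
from .fod import FodImage
from .match import BasField
from .tracking import Tractogram

__all__ = [
    "save_fod_nifti", "load_fod_nifti",
    "save_tractogram", "load_tractogram",
    "save_bedpostx", "load_bedpostx",
    "save_bas_npz", "load_bas_npz",
    "save_angle_tiff", "load_angle_tiff",
    "save_connectivity_csv", "load_connectivity_csv",
    "load_affine_text", "save_affine_text",
]


# ---------------------------------------------------------------------------
# FOD NIfTI

def save_fod_nifti(fod: FodImage, path: str, with_provenance: bool = False) -> None:
    img = nib.Nifti1Image(fod.coeffs.astype(np.float32), fod.affine)
    img.header.set_intent("estimate")
    nib.save(img, path)
    if with_provenance:
        nib.save(
            nib.Nifti1Image(fod.provenance.astype(np.uint8), fod.affine),
            _provenance_path(path),
        )


def load_fod_nifti(path: str) -> FodImage:
    img = nib.load(path)
    coeffs = np.asarray(img.dataobj, dtype=np.float32).astype(float)
    if coeffs.ndim != 4:
        raise ValueError(f"{path}: expected a 4D coefficient volume, got {coeffs.ndim}D")
    prov_path = _provenance_path(path)
    provenance = None
    if os.path.exists(prov_path):
        provenance = np.asarray(nib.load(prov_path).dataobj, dtype=np.uint8)
    lmax = _lmax_for(coeffs.shape[-1])
    return FodImage(coeffs, img.affine, provenance, lmax)


def _provenance_path(path: str) -> str:
    base = path
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            return base + "_provenance" + ext
    return base + "_provenance.nii"


def _lmax_for(k: int) -> int:
    lmax = int(np.round((-3 + np.sqrt(1 + 8 * k)) / 2))
    if (lmax + 1) * (lmax + 2) // 2 != k:
        raise ValueError(f"{k} volumes is not an even-order SH coefficient count")
    return lmax


# ---------------------------------------------------------------------------
# tractograms

def save_tractogram(tractogram: Tractogram, path: str) -> None:
    tg = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".tck"):
        nib.streamlines.save(nib.streamlines.tck.TckFile(tg), path)
    elif path.endswith(".trk"):
        nib.streamlines.save(nib.streamlines.trk.TrkFile(tg), path)
    else:
        raise ValueError("tractogram path must end in .tck or .trk")


def load_tractogram(path: str) -> Tractogram:
    tf = nib.streamlines.load(path)
    streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return Tractogram(streamlines)


# ---------------------------------------------------------------------------
# Ball-and-Stick fields

def save_bedpostx(bas: BasField, directory: str) -> None:
    """Write bedpostX-style volumes: per population k (1-based),
    merged_th<k>samples.nii / merged_ph<k>samples.nii (X,Y,Z,S polar/azimuth
    in radians) and mean_f<k>samples.nii."""
    os.makedirs(directory, exist_ok=True)
    s = bas.samples
    theta = np.arccos(np.clip(s[..., 2], -1, 1))
    phi = np.arctan2(s[..., 1], s[..., 0])
    for k in range(bas.n_populations):
        nib.save(
            nib.Nifti1Image(theta[:, :, :, k].astype(np.float32), bas.affine),
            os.path.join(directory, f"merged_th{k + 1}samples.nii"),
        )
        nib.save(
            nib.Nifti1Image(phi[:, :, :, k].astype(np.float32), bas.affine),
            os.path.join(directory, f"merged_ph{k + 1}samples.nii"),
        )
        nib.save(
            nib.Nifti1Image(bas.fractions[:, :, :, k].astype(np.float32), bas.affine),
            os.path.join(directory, f"mean_f{k + 1}samples.nii"),
        )


def load_bedpostx(directory: str) -> BasField:
    ths, phs, fs = [], [], []
    k = 1
    while True:
        th_path = _existing(directory, f"merged_th{k}samples")
        if th_path is None:
            break
        ths.append(np.asarray(nib.load(th_path).dataobj, dtype=float))
        phs.append(np.asarray(nib.load(_existing(directory, f"merged_ph{k}samples")).dataobj, dtype=float))
        fs.append(np.asarray(nib.load(_existing(directory, f"mean_f{k}samples")).dataobj, dtype=float))
        affine = nib.load(th_path).affine
        k += 1
    if not ths:
        raise ValueError(f"no merged_th<k>samples volumes found in {directory}")
    theta = np.stack(ths, axis=3)  # (X, Y, Z, P, S)
    phi = np.stack(phs, axis=3)
    fractions = np.stack(fs, axis=3)
    samples = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=-1,
    )
    # zero-fraction populations may hold garbage angles; zero them for hygiene
    samples[fractions == 0] = 0.0
    return BasField(affine, fractions, samples)


def _existing(directory: str, stem: str) -> str | None:
    for ext in (".nii", ".nii.gz"):
        p = os.path.join(directory, stem + ext)
        if os.path.exists(p):
            return p
    return None


def save_bas_npz(bas: BasField, path: str) -> None:
    """Single-file container: affine, fractions, samples, min_fraction."""
    np.savez_compressed(
        path,
        affine=bas.affine,
        fractions=bas.fractions,
        samples=bas.samples,
        min_fraction=bas.min_fraction,
    )


def load_bas_npz(path: str) -> BasField:
    with np.load(path) as z:
        return BasField(
            z["affine"], z["fractions"], z["samples"], float(z["min_fraction"])
        )


# ---------------------------------------------------------------------------
# microscopy maps

def save_angle_tiff(array: np.ndarray, path: str) -> None:
    a = np.asarray(array)
    if a.dtype == bool:
        tifffile.imwrite(path, a.astype(np.uint8) * 255)
    else:
        tifffile.imwrite(path, a.astype(np.float32))


def load_angle_tiff(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


# ---------------------------------------------------------------------------
# matrices and affines

def save_connectivity_csv(matrix: ConnectivityMatrix, path: str) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.seed_labels, columns=matrix.target_labels)
    df.to_csv(path, index_label="seed")


def load_connectivity_csv(path: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    cols = [_maybe_int(c) for c in df.columns]
    rows = [_maybe_int(r) for r in df.index]
    return ConnectivityMatrix(df.to_numpy(dtype=float), rows, cols)


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


def save_affine_text(affine: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(affine, dtype=float), fmt="%.10g")


def load_affine_text(path: str) -> np.ndarray:
    A = np.loadtxt(path)
    if A.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {A.shape}")
    return A
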