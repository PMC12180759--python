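"""NIfTI / bval / bvec input-output and run plumbing.

Volumes are processed exactly as stored: no reorientation, no resampling, and
the input affine is carried to every output bit-exact. Voxel indices are
0-based and window extents are in voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .pca_core import DenoiseResult

__all__ = ["DwiDataset", "read_dwi", "write_outputs", "parse_window",
           "save_nifti", "load_nifti", "write_protocol", "parse_index_spec"]


@dataclass
class DwiDataset:
    """A diffusion-weighted dataset: 4D data, protocol vectors, and affine."""

    data: np.ndarray      # (x, y, z, N)
    bvals: np.ndarray     # length N
    bvecs: np.ndarray     # N x 3, renormalized where nonzero
    affine: np.ndarray    # 4 x 4


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_dwi(dwi_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path) -> DwiDataset:
    """Load a NIfTI volume with FSL-style bval/bvec text files.

    bvals is one whitespace-separated row of N values; bvecs is three rows
    (x, y, z) of N values. Vector norms are renormalized to 1 where nonzero.
    """
    data, affine = load_nifti(dwi_path)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.ndim == 1:
        bvecs = bvecs[None, :]
    n = data.shape[-1]
    if len(bvals) != n or bvecs.shape != (n, 3):
        raise ValueError(
            f"protocol length mismatch: {n} volumes, {len(bvals)} bvals, "
            f"bvecs shape {bvecs.shape}")
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs = bvecs.copy()
    bvecs[nz] /= norms[nz, None]
    return DwiDataset(data=data, bvals=bvals, bvecs=bvecs, affine=affine)


def write_protocol(prefix: str | Path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write FSL-style ``<prefix>.bval`` / ``<prefix>.bvec`` files."""
    prefix = str(prefix)
    np.savetxt(prefix + ".bval", np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(prefix + ".bvec", np.asarray(bvecs).T, fmt="%.8f")


def write_outputs(result: DenoiseResult, affine: np.ndarray, out_path: str | Path,
                  ncomp_path: Optional[str | Path] = None,
                  residuals_path: Optional[str | Path] = None,
                  sigma2_path: Optional[str | Path] = None,
                  metadata: Optional[dict] = None) -> None:
    """Write denoiser outputs as NIfTI with the input affine, plus a JSON sidecar.

    The sidecar (``<out>.json``) records the run metadata verbatim.
    """
    save_nifti(out_path, result.denoised, affine)
    if ncomp_path is not None:
        save_nifti(ncomp_path, result.ncomp_map.astype(np.int32), affine)
    if residuals_path is not None:
        save_nifti(residuals_path, result.residuals, affine)
    if sigma2_path is not None and result.sigma2_map_used is not None:
        save_nifti(sigma2_path, result.sigma2_map_used, affine)
    if metadata is not None:
        sidecar = Path(str(out_path)).with_suffix("").with_suffix("")  # strip .nii.gz
        Path(str(sidecar) + ".json").write_text(json.dumps(metadata, indent=2))


def parse_window(spec: str) -> tuple[int, ...]:
    """Parse a window spec like ``11x11`` or ``9x9x3`` into odd positive ints."""
    try:
        dims = tuple(int(p) for p in spec.lower().split("x"))
    except ValueError as exc:
        raise ValueError(f"malformed window spec '{spec}'") from exc
    if len(dims) not in (2, 3):
        raise ValueError(f"window must be 2D or 3D, got '{spec}'")
    for d in dims:
        if d <= 0 or d % 2 == 0:
            raise ValueError(f"window dims must be positive odd integers, got {d} in '{spec}'")
    return dims


def parse_index_spec(spec: str, n: int) -> list[int]:
    """Parse volume indices like ``0:5`` (half-open) or ``0,3,7``."""
    if ":" in spec:
        lo, hi = (int(p) if p else None for p in spec.split(":"))
        return list(range(lo or 0, hi if hi is not None else n))
    return [int(p) for p in spec.split(",")]
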