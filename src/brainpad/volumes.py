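"""Volume plumbing: NIfTI I/O, smoothing, masking, vectorization, tissue volumes.

All cohort volumes are assumed to live on a shared voxel grid in a common
(already normalized) space; no registration is performed here. Voxel indices
are 0-based and vectorization uses C order over the mask, so feature vectors
are deterministic across runs and platforms.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class VolumeFormatError(ValueError):
    """Raised for unreadable or wrongly-shaped volume files."""


class DimensionError(ValueError):
    """Raised when volume grids or feature lengths do not match."""


@dataclass
class Volume3D:
    """A 3D scalar field with voxel edge lengths in mm.

    Carrier of tissue-probability maps (GM/WM/CSF) and binary masks.
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_label: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(
                f"Volume3D requires a 3D array, got ndim={self.data.ndim}"
            )
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)  # type: ignore[assignment]
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_mm, other.voxel_mm)
            and self.space_label == other.space_label
        )


@dataclass
class FeatureVector:
    """Concatenated masked GM then WM voxel intensities for one subject."""

    values: np.ndarray
    mask_id: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 volume from ``path``.

    Raises :class:`VolumeFormatError` for unreadable files and
    :class:`DimensionError` for non-3D images. Voxel dimensions come from the
    header zooms; the space label is taken from the header ``descrip`` field
    when present.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeFormatError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    descrip = img.header.get("descrip", b"")
    label = bytes(descrip).split(b"\x00", 1)[0].decode("ascii", "ignore") or "native"
    return Volume3D(np.asarray(data, dtype=np.float64), tuple(zooms), label)


def write_volume(vol: Volume3D, path) -> None:
    """Write ``vol`` as NIfTI-1 (float32 data, zooms = voxel_mm)."""
    affine = np.diag([*vol.voxel_mm, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_mm)
    img.header["descrip"] = vol.space_label.encode("ascii", "ignore")[:79]
    nib.save(img, str(path))


def gaussian_smooth(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with the given FWHM in mm.

    sigma per axis is ``fwhm_mm / (2*sqrt(2 ln 2)) / voxel_mm_axis``;
    ``fwhm_mm = 0`` is the identity. Boundary handling is nearest-edge
    replication, which conserves the volume integral away from edges.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return Volume3D(vol.data.copy(), vol.voxel_mm, vol.space_label)
    sigma_vox = [fwhm_mm / FWHM_PER_SIGMA / v for v in vol.voxel_mm]
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox, mode="nearest")
    return Volume3D(out, vol.voxel_mm, vol.space_label)


def mask_id_of(mask: Volume3D) -> str:
    """Stable identifier of a binary mask (shape + voxel membership hash)."""
    m = mask.data > 0.5
    h = hashlib.sha1()
    h.update(np.asarray(m.shape, dtype=np.int64).tobytes())
    h.update(np.packbits(m.ravel(order="C")).tobytes())
    return h.hexdigest()[:16]


def cohort_mask(
    gm_vols: Sequence[Volume3D],
    wm_vols: Sequence[Volume3D],
    threshold: float = 0.05,
) -> Volume3D:
    """Binary mask of voxels whose cohort-mean GM+WM exceeds ``threshold``."""
    if len(gm_vols) == 0 or len(gm_vols) != len(wm_vols):
        raise ValueError("need equal, nonzero numbers of GM and WM volumes")
    ref = gm_vols[0]
    acc = np.zeros(ref.shape, dtype=float)
    for g, w in zip(gm_vols, wm_vols):
        if not (g.same_grid(ref) and w.same_grid(ref)):
            raise DimensionError("all volumes entering one mask must share the grid")
        acc += g.data + w.data
    mean = acc / len(gm_vols)
    return Volume3D((mean > threshold).astype(np.float64), ref.voxel_mm, ref.space_label)


def vectorize_concat(gm: Volume3D, wm: Volume3D, mask: Volume3D) -> FeatureVector:
    """Masked GM voxels followed by masked WM voxels, C order over the grid.

    The ordering is fixed (C order over mask indices) so the same mask always
    yields byte-identical vectors; the dot-product kernel is insensitive to
    the particular order but determinism across runs is required.
    """
    if not (gm.same_grid(wm) and gm.shape == mask.shape):
        raise DimensionError(
            f"grid mismatch: gm {gm.shape}, wm {wm.shape}, mask {mask.shape}"
        )
    m = mask.data > 0.5
    n = int(m.sum())
    if n == 0:
        warnings.warn("all-zero mask: producing a length-0 feature vector")
        logger.warning("vectorize_concat called with an empty mask")
    values = np.concatenate([gm.data[m].ravel(order="C"), wm.data[m].ravel(order="C")])
    return FeatureVector(values=values, mask_id=mask_id_of(mask))


def tissue_volume(vol: Volume3D, tol: float = 1e-6) -> float:
    """Tissue volume in millilitres: sum of probabilities x voxel volume.

    Values must be tissue probabilities in [0, 1] (within ``tol``).
    """
    lo, hi = float(vol.data.min(initial=0.0)), float(vol.data.max(initial=0.0))
    if lo < -tol or hi > 1.0 + tol:
        raise ValueError(
            f"tissue probabilities outside [0,1]: range [{lo:.4g}, {hi:.4g}]"
        )
    return float(vol.data.sum() * vol.voxel_volume_mm3 / 1000.0)


def icv(gm: Volume3D, wm: Volume3D, csf: Volume3D) -> float:
    """Intracranial volume (ml) as the sum of GM, WM and CSF volumes."""
    return tissue_volume(gm) + tissue_volume(wm) + tissue_volume(csf)
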