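"""Volume data model, NIfTI I/O, isotropic resampling and segmentation.

Axis convention used throughout the package: axis 0 is the transverse slice
axis (superior–inferior, index increasing proximally, i.e. towards the knee),
axis 1 is anterior–posterior (increasing anteriorly) and axis 2 is
medial–lateral (increasing laterally).  All physical coordinates are in mm,
``x_mm = index * spacing + origin``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger("limbcast")

#: Default isotropic voxel edge after resampling, mm.
DEFAULT_SPACING_MM = 0.6

SLICE_AXIS = 0  # superior-inferior, proximal = increasing index
AP_AXIS = 1  # anterior-posterior, anterior = increasing index
ML_AXIS = 2  # medial-lateral, lateral = increasing index


class VolumeFormatError(ValueError):
    """Raised for inputs that are not 3-D scalar volumes."""


class SegmentationError(RuntimeError):
    """Raised when thresholding produces an empty foreground."""


def _as_spacing(spacing) -> np.ndarray:
    s = np.atleast_1d(np.asarray(spacing, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    if s.shape != (3,) or np.any(s <= 0):
        raise ValueError(f"spacing must be a positive scalar or 3-vector, got {spacing!r}")
    return s


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with isotropic (or recorded anisotropic) spacing."""

    data: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.full(3, DEFAULT_SPACING_MM))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    subject_id: str | None = None
    method: str | None = None  # "hands_on" | "hands_off"
    repetition: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D scalar volume, got ndim={self.data.ndim}")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing_mm, self.spacing_mm[0], rtol=0, atol=1e-6))

    @property
    def spacing(self) -> float:
        """Scalar isotropic spacing; raises if the volume is anisotropic."""
        if not self.is_isotropic:
            raise ValueError(f"volume is anisotropic: spacing={self.spacing_mm}")
        return float(self.spacing_mm[0])

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def meta(self) -> dict:
        return dict(subject_id=self.subject_id, method=self.method, repetition=self.repetition)

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


@dataclass
class BinaryMask(VoxelVolume):
    """Foreground/background volume (limb or tibia); data in {0, 1}."""

    label: str = "limb"  # "limb" | "tibia"

    def __post_init__(self):
        super().__post_init__()
        self.data = np.ascontiguousarray(self.data != 0).astype(np.uint8)

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing_mm))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affine(vol: VoxelVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing_mm)
    aff[:3, 3] = vol.origin_mm
    return aff


def read_volume(path, as_mask: bool = False, label: str = "limb") -> VoxelVolume:
    """Read a 3-D NIfTI-1 volume.

    Anisotropic headers load fine; the per-axis spacings are recorded and the
    volume is flagged non-isotropic (``vol.is_isotropic``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D scalar data, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    if not np.allclose(spacing, spacing[0], atol=1e-6):
        logger.warning("%s: anisotropic spacing %s recorded; resample before analysis", path, spacing)
    cls = BinaryMask if as_mask else VoxelVolume
    kw = {"label": label} if as_mask else {}
    return cls(data=data.astype(np.uint8 if as_mask else np.float32),
               spacing_mm=spacing, origin_mm=origin, **kw)


def write_volume(vol: VoxelVolume, path) -> Path:
    """Write as NIfTI-1 (.nii or .nii.gz); round-trips data bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol))
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(vol: VoxelVolume, target_mm: float = DEFAULT_SPACING_MM,
                       interpolation: str | None = None) -> VoxelVolume:
    """Resample onto an isotropic grid of edge ``target_mm``.

    Physical extent is preserved to within one voxel.  Masks default to
    nearest-neighbour (stay binary), greyscale to linear.  A volume already at
    the target spacing is returned unchanged (identity path).
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if np.allclose(vol.spacing_mm, target_mm, rtol=0, atol=1e-9):
        return vol
    is_mask = isinstance(vol, BinaryMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    order = {"nearest": 0, "linear": 1}[interpolation]

    src = vol.spacing_mm
    out_shape = tuple(int(max(1, round(n * s / target_mm))) for n, s in zip(vol.shape, src))
    # output index j -> input index j * target / spacing
    matrix = np.diag(target_mm / src)
    data = vol.data.astype(np.float32 if not is_mask else np.uint8)
    out = ndimage.affine_transform(data, matrix, output_shape=out_shape, order=order,
                                   mode="constant", cval=0.0)
    new = replace(vol, data=out, spacing_mm=np.full(3, float(target_mm)))
    return new


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 6-connected foreground component of a boolean array."""
    labels, n = ndimage.label(binary, structure=_SIX_CONN)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _clean(binary: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(largest_component(binary))


def segment_limb(vol: VoxelVolume, intensity_model: dict[str, float]) -> tuple[BinaryMask, BinaryMask]:
    """Threshold a phantom-style volume into (limb, tibia) masks.

    ``intensity_model`` maps tissue role (background, soft_tissue, bone and
    optionally gap, cast) to its mean grey value.  The limb (soft tissue plus
    bone) is thresholded at the midpoint between the soft-tissue mean and the
    brightest sub-soft-tissue class (the stockinet gap when present), the
    tibia at the soft-tissue/bone midpoint — with partial-volume boundary
    voxels these midpoints put the surface at the half-filled level.  Each
    mask is reduced to its largest 6-connected component with interior holes
    filled (3-D), so a low-intensity marrow cavity cannot perforate the bone
    mask used as the registration anchor.
    """
    import hashlib

    digest = hashlib.sha1(np.ascontiguousarray(vol.data)).hexdigest()[:12]
    logger.debug("segment_limb input %s sha1=%s", vol.meta(), digest)
    soft_mean = intensity_model["soft_tissue"]
    bone_mean = intensity_model["bone"]
    # the class adjacent to the skin is the stockinet gap when present (the
    # cast is separated from the limb by it), otherwise background
    floor = intensity_model.get("gap", intensity_model.get("background", 0.0))
    data = vol.data.astype(float)
    limb_raw = data >= (soft_mean + floor) / 2.0
    bone = data >= (soft_mean + bone_mean) / 2.0
    if not limb_raw.any():
        raise SegmentationError("empty foreground after thresholding (no soft tissue or bone voxels)")
    limb = _clean(limb_raw)
    tibia = _clean(bone) if bone.any() else np.zeros_like(limb_raw)
    mk = lambda arr, lab: BinaryMask(data=arr.astype(np.uint8), spacing_mm=vol.spacing_mm,
                                     origin_mm=vol.origin_mm, subject_id=vol.subject_id,
                                     method=vol.method, repetition=vol.repetition, label=lab)
    return mk(limb, "limb"), mk(tibia, "tibia")


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap of two binary masks on the same grid."""
    pa = a.data if isinstance(a, VoxelVolume) else np.asarray(a)
    pb = b.data if isinstance(b, VoxelVolume) else np.asarray(b)
    pa = pa != 0
    pb = pb != 0
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(pa, pb).sum()) / float(denom)
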