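"""Tibia-anchored anatomical frame: plateau alignment, length
standardisation and regional cutting planes.

The analysis frame is anchored on the tibia: transverse slices are made
parallel to the proximal bone surface (the tibial plateau), the residual limb
is cropped a fixed 30 slices proximal to the plateau so repeat scans share an
anatomical length, and the limb is partitioned into four quadrants
(anterolateral AL, anteromedial AM, posterolateral PL, posteromedial PM) by a
sagittal plane through the intercondylar tubercles and a coronal plane
through the plateau midpoint, plus three longitudinal bands (distal, middle,
proximal) cut at one- and two-thirds of the averaged limb length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .registration import RigidTransform
from .volume import BinaryMask

logger = logging.getLogger("limbcast")

#: Number of retained slices proximal to the tibial plateau.
SLICES_ABOVE_PLATEAU = 30

QUADRANT_NAMES = {1: "AL", 2: "AM", 3: "PL", 4: "PM"}
BAND_NAMES = {1: "distal", 2: "middle", 3: "proximal"}
REGION_NAMES = list(QUADRANT_NAMES.values()) + list(BAND_NAMES.values())


class InsufficientSurfaceError(RuntimeError):
    """Too few proximal bone-surface voxels to fit the plateau plane."""


class DegeneratePlanesError(ValueError):
    """Cutting planes are parallel or undefined (coincident tubercles)."""


_EZ = np.array([1.0, 0.0, 0.0])  # slice axis in (slice, AP, ML) component order


@dataclass
class AnatomicalFrame:
    """Plateau slice, tubercle landmarks and derived cutting planes."""

    plateau_slice: int
    tubercles_mm: np.ndarray  # (2, 3) points, (slice, AP, ML) mm
    plateau_mid_mm: np.ndarray  # (3,) midpoint of the tibial plateau, mm
    spacing_mm: float
    slices_above: int = SLICES_ABOVE_PLATEAU

    def __post_init__(self):
        self.tubercles_mm = np.asarray(self.tubercles_mm, dtype=float).reshape(2, 3)
        self.plateau_mid_mm = np.asarray(self.plateau_mid_mm, dtype=float).reshape(3)

    @property
    def crop_slice(self) -> int:
        return int(self.plateau_slice) + int(self.slices_above)

    @property
    def sagittal_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, unit normal): plane through both tubercles and the slice axis."""
        u = self.tubercles_mm[1] - self.tubercles_mm[0]
        n = np.cross(_EZ, u)
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise DegeneratePlanesError("tubercles coincide along the slice axis; "
                                        "sagittal plane undefined")
        n = n / nn
        if n[2] < 0:  # orient normal towards lateral (+ML)
            n = -n
        return self.tubercles_mm.mean(axis=0), n

    @property
    def coronal_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, unit normal): through the plateau midpoint, orthogonal to sagittal."""
        _, n_sag = self.sagittal_plane
        n = np.cross(_EZ, n_sag)
        n = n / np.linalg.norm(n)
        if n[1] < 0:  # orient normal towards anterior (+AP)
            n = -n
        return self.plateau_mid_mm, n


# ---------------------------------------------------------------------------
# Plateau alignment
# ---------------------------------------------------------------------------

def _column_top(data: np.ndarray) -> np.ndarray:
    """Per-(AP,ML)-column topmost (most proximal) bone slice index, -1 if empty."""
    nz = data.shape[0]
    zidx = np.where(data != 0, np.arange(nz)[:, None, None], -1)
    return zidx.max(axis=0)


def align_to_plateau(tibia: BinaryMask, top_band_mm: float = 2.5,
                     min_voxels: int = 50) -> RigidTransform:
    """Rotation making the proximal tibia surface normal to the slice axis.

    The proximal face is isolated in two steps: the bone's long axis is
    estimated by PCA of all bone voxels, and the upper-envelope voxels
    (per-column topmost) whose height *along that axis* lies within
    ``top_band_mm`` of the proximal end are taken as face candidates —
    measuring along the axis keeps the down-sloping crest of a tilted shaft
    out of the selection.  A least-squares plane is then fitted to the
    candidates with a shrinking residual trim that discards the intercondylar
    tubercle bumps, so the flat plateau dominates.  Returns the pure rotation
    (translation 0) about the surface centroid.
    """
    if not tibia.data.any():
        raise InsufficientSurfaceError("empty tibia mask")
    s = tibia.spacing
    top = _column_top(tibia.data)
    sel = top >= 0
    yy, xx = np.nonzero(sel)
    zz = top[sel]
    pts = np.column_stack([zz, yy, xx]).astype(float) * s + tibia.origin_mm

    all_pts = np.argwhere(tibia.data != 0).astype(float) * s + tibia.origin_mm
    axis = np.linalg.svd(all_pts - all_pts.mean(axis=0), full_matrices=False)[2][0]
    if axis[0] < 0:  # orient proximally (+slice)
        axis = -axis
    h = pts @ axis
    face = h >= h.max() - top_band_mm
    pts = pts[face]
    if len(pts) < min_voxels:
        raise InsufficientSurfaceError(
            f"only {len(pts)} proximal surface voxels (need >= {min_voxels})")

    # robust plane fit z = a*y + b*x + c with a shrinking trim schedule:
    # successive refits discard points ever further from the current plane
    # (the tubercle bumps first), until only the flat plateau sheet remains
    A = np.column_stack([pts[:, 1], pts[:, 2], np.ones(len(pts))])
    z = pts[:, 0]
    keep = np.ones(len(pts), dtype=bool)
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    for thr in (2.5 * s, 1.5 * s, 1.0 * s, 0.8 * s, 0.8 * s):
        resid = z - A @ coef
        med = np.median(resid[keep])
        new_keep = np.abs(resid - med) <= thr
        if new_keep.sum() < min_voxels:
            break
        keep = new_keep
        coef, *_ = np.linalg.lstsq(A[keep], z[keep], rcond=None)

    n = np.array([1.0, -coef[0], -coef[1]])
    n /= np.linalg.norm(n)
    rot, _ = Rotation.align_vectors(_EZ[None, :], n[None, :])
    centre = pts[keep].mean(axis=0)
    return RigidTransform(angles_deg=rot.as_euler("xyz", degrees=True),
                          translation_mm=np.zeros(3), centre_mm=centre)


def find_plateau_slice(tibia: BinaryMask, k: int = 5) -> int:
    """Most proximal slice index with at least ``k`` tibia voxels.

    ``k`` guards against stray voxels above the plateau; the tibia is assumed
    already aligned (plateau parallel to the slices).
    """
    counts = tibia.data.reshape(tibia.shape[0], -1).sum(axis=1)
    ok = np.nonzero(counts >= k)[0]
    if len(ok) == 0:
        raise InsufficientSurfaceError("empty tibia mask (no slice reaches the voxel guard)")
    return int(ok[-1])


def standardise(limb: BinaryMask, frame: AnatomicalFrame) -> BinaryMask:
    """Zero all slices strictly above plateau_slice + 30 (idempotent).

    Retains the 30 proximal slices inclusive, giving every repeat scan of a
    subject the same anatomical length.
    """
    crop = frame.crop_slice
    data = limb.data.copy()
    if crop >= limb.shape[0] - 1:
        warnings.warn(f"crop slice {crop} at/beyond grid top {limb.shape[0] - 1}; "
                      "standardise is a no-op")
        return replace(limb, data=data)
    data[crop + 1:] = 0
    return replace(limb, data=data)


# ---------------------------------------------------------------------------
# Regional partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Voxel -> quadrant {AL, AM, PL, PM} and band {distal, middle, proximal}.

    Quadrants come from the signed distances to the sagittal and coronal
    planes; bands from two transverse cuts at one- and two-thirds of the
    averaged limb length above the distal tip.  The strict tie rule assigns a
    voxel exactly on a plane to the lateral / anterior / proximal side
    (signed distance >= 0).
    """

    sagittal: tuple  # (point, normal)
    coronal: tuple
    cut_z_mm: tuple  # (distal/middle, middle/proximal) z levels
    spacing_mm: float

    def _coords_mm(self, mask: BinaryMask):
        idx = np.indices(mask.shape, dtype=float)
        return idx * np.asarray(mask.spacing_mm).reshape(3, 1, 1, 1) + \
            mask.origin_mm.reshape(3, 1, 1, 1)

    def quadrant_labels(self, mask: BinaryMask) -> np.ndarray:
        co = self._coords_mm(mask)
        p_s, n_s = self.sagittal
        p_c, n_c = self.coronal
        d_lat = sum((co[i] - p_s[i]) * n_s[i] for i in range(3))
        d_ant = sum((co[i] - p_c[i]) * n_c[i] for i in range(3))
        lat = d_lat >= 0
        ant = d_ant >= 0
        lab = np.where(ant, np.where(lat, 1, 2), np.where(lat, 3, 4)).astype(np.uint8)
        lab[mask.data == 0] = 0
        return lab

    def band_labels(self, mask: BinaryMask) -> np.ndarray:
        z = np.arange(mask.shape[0], dtype=float) * mask.spacing_mm[0] + mask.origin_mm[0]
        band = np.where(z >= self.cut_z_mm[1], 3, np.where(z >= self.cut_z_mm[0], 2, 1))
        lab = np.broadcast_to(band[:, None, None].astype(np.uint8), mask.shape).copy()
        lab[mask.data == 0] = 0
        return lab

    def region_masks(self, mask: BinaryMask) -> dict[str, np.ndarray]:
        q = self.quadrant_labels(mask)
        b = self.band_labels(mask)
        out = {name: q == code for code, name in QUADRANT_NAMES.items()}
        out.update({name: b == code for code, name in BAND_NAMES.items()})
        return out

    def region_volumes(self, mask: BinaryMask) -> dict[str, float]:
        vox = float(np.prod(mask.spacing_mm))
        return {name: float(m.sum()) * vox for name, m in self.region_masks(mask).items()}

    def legend(self) -> dict:
        return {"quadrants": QUADRANT_NAMES, "bands": BAND_NAMES}

    def export_labels(self, mask: BinaryMask, path) -> dict:
        """Write quadrant and band label volumes as uint8 NIfTI files plus a
        JSON legend; returns the paths."""
        import json
        from pathlib import Path

        from .volume import VoxelVolume, write_volume

        path = Path(path)
        stem = path.name.split(".")[0]
        out = {}
        for name, lab in (("quadrants", self.quadrant_labels(mask)),
                          ("bands", self.band_labels(mask))):
            vol = VoxelVolume(data=lab, spacing_mm=mask.spacing_mm,
                              origin_mm=mask.origin_mm)
            out[name] = write_volume(vol, path.with_name(f"{stem}_{name}.nii.gz"))
        legend_path = path.with_name(f"{stem}_legend.json")
        with open(legend_path, "w") as fh:
            json.dump(self.legend(), fh, indent=1)
        out["legend"] = legend_path
        return out


def build_regions(frame: AnatomicalFrame, avg_length_mm: float,
                  tip_z_mm: float | None = None) -> RegionPartition:
    """Construct the 4-quadrant / 3-band partition for one subject.

    ``avg_length_mm`` is the mean standardised limb length over the subject's
    four scans; the transverse cuts sit at one- and two-thirds of it above
    the distal tip (``tip_z_mm``, by default inferred as crop plane minus the
    averaged length).
    """
    if avg_length_mm <= 0:
        raise ValueError("avg_length_mm must be positive")
    p_s, n_s = frame.sagittal_plane
    p_c, n_c = frame.coronal_plane
    if abs(float(np.dot(n_s, n_c))) > 1e-6:
        raise DegeneratePlanesError("sagittal and coronal normals are not orthogonal")
    if tip_z_mm is None:
        tip_z_mm = frame.crop_slice * frame.spacing_mm - avg_length_mm
    cuts = (tip_z_mm + avg_length_mm / 3.0, tip_z_mm + 2.0 * avg_length_mm / 3.0)
    return RegionPartition(sagittal=(p_s, n_s), coronal=(p_c, n_c),
                           cut_z_mm=cuts, spacing_mm=frame.spacing_mm)


def distal_tip_z_mm(mask: BinaryMask) -> float:
    """z (mm) of the most distal slice containing foreground."""
    counts = mask.data.reshape(mask.shape[0], -1).sum(axis=1)
    nz = np.nonzero(counts)[0]
    if len(nz) == 0:
        raise ValueError("empty mask has no distal tip")
    return float(nz[0]) * mask.spacing_mm[0] + mask.origin_mm[0]
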