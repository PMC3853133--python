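"""Rigid registration by normalised mutual information (NMI).

Every repeat scan of a subject is aligned to a reference scan whose tibia has
been brought into the plateau-axial frame.  Because the anchor is rigid bone,
the transform model is rigid (6 DOF); the similarity is the normalised mutual
information NMI = (H(A)+H(B)) / H(A,B) estimated from a joint intensity
histogram, maximised by a derivative-free Powell search over a 3-level
multi-resolution pyramid.  When a tibia mask is supplied the similarity is
evaluated only over a dilated bone neighbourhood, so soft-tissue differences
between casts do not drive the fit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .volume import BinaryMask, VoxelVolume

logger = logging.getLogger("limbcast")


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """6-DOF rotation + translation mapping moving -> fixed physical coords.

    ``angles_deg[i]`` is an extrinsic rotation about grid axis *i*
    (slice, anterior-posterior, medial-lateral), applied in that order about
    ``centre_mm``:  x' = R (x - c) + c + t.
    """

    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    centre_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.centre_mm = np.asarray(self.centre_mm, dtype=float).reshape(3)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.angles_deg, degrees=True)

    @property
    def matrix(self) -> np.ndarray:
        """Rotation matrix (determinant +1)."""
        return self.rotation.as_matrix()

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        out = (self.matrix @ (pts - self.centre_mm).T).T + self.centre_mm + self.translation_mm
        return out.reshape(np.shape(pts_mm))

    def homogeneous(self) -> np.ndarray:
        m = np.eye(4)
        R = self.matrix
        m[:3, :3] = R
        m[:3, 3] = self.centre_mm + self.translation_mm - R @ self.centre_mm
        return m

    @classmethod
    def from_homogeneous(cls, m: np.ndarray, centre_mm=np.zeros(3)) -> "RigidTransform":
        R = np.asarray(m)[:3, :3]
        b = np.asarray(m)[:3, 3]
        c = np.asarray(centre_mm, dtype=float).reshape(3)
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = R @ c + b - c
        return cls(angles_deg=angles, translation_mm=t, centre_mm=c)

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        return RigidTransform(
            angles_deg=Rotation.from_matrix(R.T).as_euler("xyz", degrees=True),
            translation_mm=-R.T @ self.translation_mm,
            centre_mm=self.centre_mm,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (``other`` applied first); centre taken from self."""
        return RigidTransform.from_homogeneous(self.homogeneous() @ other.homogeneous(),
                                               centre_mm=self.centre_mm)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.angles_deg) < atol) and
                    np.all(np.abs(self.translation_mm) < atol))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"angles_deg": self.angles_deg.tolist(),
                "translation_mm": self.translation_mm.tolist(),
                "centre_mm": self.centre_mm.tolist()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["angles_deg"]), np.asarray(d["translation_mm"]),
                   np.asarray(d.get("centre_mm", np.zeros(3))))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def grid_centre_mm(vol: VoxelVolume) -> np.ndarray:
    """Physical centre of the voxel grid (the default rotation centre)."""
    return vol.origin_mm + (np.array(vol.shape) - 1) / 2.0 * vol.spacing_mm


# ---------------------------------------------------------------------------
# Normalised mutual information
# ---------------------------------------------------------------------------

def _entropies(a: np.ndarray, b: np.ndarray, bins: int) -> tuple[float, float, float]:
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def H(x):
        x = x[x > 0]
        return float(-(x * np.log(x)).sum())

    return H(pa), H(pb), H(p.ravel())


def _nmi_samples(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    if a.size == 0:
        raise ValueError("empty overlap: no voxels to estimate NMI from")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant image in NMI: zero marginal entropy, returning lower bound 1.0")
        return 1.0
    ha, hb, hab = _entropies(a, b, bins)
    if hab <= 0:
        return 1.0
    return (ha + hb) / hab


def nmi(fixed: VoxelVolume, moving: VoxelVolume, bins: int = 64,
        mask: BinaryMask | None = None, exclude_zero: bool = True) -> float:
    """NMI = (H(A)+H(B)) / H(A,B) over in-mask overlapping voxels; range (1, 2].

    Identical images give exactly 2.  Background voxels that are zero in both
    images are excluded by default (air dominates the field of view and would
    flatten the measure).
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    if fixed.shape != moving.shape:
        raise ValueError(f"grid mismatch: {fixed.shape} vs {moving.shape}")
    a = np.asarray(fixed.data, dtype=float).ravel()
    b = np.asarray(moving.data, dtype=float).ravel()
    if mask is not None:
        keep = mask.data.ravel() != 0
        a, b = a[keep], b[keep]
    elif exclude_zero:
        # intersection, not union: conditioning on "either non-zero" would
        # manufacture dependence between otherwise independent images
        keep = (a != 0) & (b != 0)
        a, b = a[keep], b[keep]
    return _nmi_samples(a, b, bins)


# ---------------------------------------------------------------------------
# Resampling under a rigid transform
# ---------------------------------------------------------------------------

def apply_transform(vol: VoxelVolume, t: RigidTransform,
                    interpolation: str | None = None) -> VoxelVolume:
    """Resample ``vol`` moved by ``t`` onto its own (fixed) grid.

    The output satisfies out(x) = vol(t⁻¹ x).  Greyscale volumes use linear
    interpolation.  Masks default to linear interpolation of the binary
    indicator re-thresholded at 0.5 — output stays binary while the effective
    surface displacement error is well below a voxel; pass
    ``interpolation="nearest"`` for classical NN resampling.
    """
    if t.is_identity():
        return replace(vol, data=vol.data.copy())
    is_mask = isinstance(vol, BinaryMask)
    if interpolation is None:
        interpolation = "linear"
    s = vol.spacing  # isotropic required
    R = t.matrix
    c = (t.centre_mm - vol.origin_mm) / s
    tv = t.translation_mm / s
    # input index = R^T (j - c - tv) + c
    matrix = R.T
    offset = c - R.T @ (c + tv)
    if is_mask and interpolation == "nearest":
        out = ndimage.affine_transform(vol.data, matrix, offset=offset, order=0,
                                       mode="constant", cval=0)
    elif is_mask:
        f = ndimage.affine_transform(vol.data.astype(np.float32), matrix, offset=offset,
                                     order=1, mode="constant", cval=0.0)
        out = (f >= 0.5).astype(np.uint8)
    else:
        order = 0 if interpolation == "nearest" else 1
        out = ndimage.affine_transform(vol.data.astype(np.float32), matrix, offset=offset,
                                       order=order, mode="constant", cval=0.0)
    return replace(vol, data=out)


# ---------------------------------------------------------------------------
# Rigid NMI registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    bins: int = 32  # joint-histogram bins during optimisation; with plain
    # binning of interpolated samples, 32 keeps the joint histogram densely
    # populated and the NMI surface smooth under acquisition noise
    pyramid: tuple = (4, 2, 1)  # downsampling factors, coarse to fine
    max_iter: int = 200  # Powell iterations per level
    tol: float = 1e-5  # convergence tolerance on NMI
    mask_dilation_mm: float = 6.0  # bone neighbourhood when a tibia mask is given
    max_samples: int = 120_000  # per-level cap on histogram samples


@dataclass
class RegistrationResult:
    transform: RigidTransform
    nmi: float
    converged: bool = True
    message: str = ""


def _sample_points(shape, mask: np.ndarray | None, stride: int, max_samples: int) -> np.ndarray:
    """Strided lattice of voxel indices (N,3), optionally inside a mask."""
    if mask is not None:
        idx = np.argwhere(mask)
        if stride > 1 or len(idx) > max_samples:
            step = max(stride ** 3 // 2, int(np.ceil(len(idx) / max_samples)), 1)
            idx = idx[::step]
        return idx
    sl = tuple(slice(0, n, stride) for n in shape)
    grid = np.mgrid[sl].reshape(3, -1).T
    if len(grid) > max_samples:
        grid = grid[:: int(np.ceil(len(grid) / max_samples))]
    return grid


def register_rigid(fixed: VoxelVolume, moving: VoxelVolume,
                   init: RigidTransform | None = None,
                   tibia_mask: BinaryMask | None = None,
                   config: RegistrationConfig | None = None) -> RegistrationResult:
    """Recover the rigid transform maximising NMI(fixed, moving ∘ T).

    Multi-resolution (Gaussian-smoothed, strided sampling at factors 4/2/1)
    Powell search over 3 angles (deg) + 3 translations (mm) about the fixed
    grid centre.  ``apply_transform(moving, result.transform)`` aligns the
    moving volume onto the fixed grid.  If the optimiser cannot improve on the
    starting point the initial transform is returned with ``converged=False``.
    """
    cfg = config or RegistrationConfig()
    if fixed.spacing != moving.spacing:
        raise ValueError("fixed and moving must share isotropic spacing")
    s = fixed.spacing
    centre = grid_centre_mm(fixed)
    if init is not None:
        x0 = np.concatenate([init.angles_deg, init.translation_mm])
    else:
        # moments initialisation: start from the foreground-centroid offset so
        # translations up to the limb size stay inside the capture range
        ffg = np.argwhere(fixed.data > 0)
        mfg = np.argwhere(moving.data > 0)
        x0 = np.zeros(6)
        if len(ffg) and len(mfg):
            x0[3:] = (ffg.mean(axis=0) - mfg.mean(axis=0)) * s

    fdata = np.asarray(fixed.data, dtype=np.float32)
    mdata = np.asarray(moving.data, dtype=np.float32)

    mask = None
    if tibia_mask is not None:
        it = max(1, int(round(cfg.mask_dilation_mm / s)))
        mask = ndimage.binary_dilation(tibia_mask.data != 0, iterations=it)
    else:
        # restrict to non-background neighbourhood of the fixed image
        mask = ndimage.binary_dilation(fdata != 0, iterations=2)
    if mask.sum() < 100:
        logger.warning("registration: fewer than 100 usable voxels; returning init")
        return RegistrationResult(init or RigidTransform(centre_mm=centre), 1.0,
                                  converged=False, message="degenerate input")

    def make_objective(f_sm, m_sm, pts_vox):
        B = cfg.bins
        pts_mm = pts_vox * s + fixed.origin_mm
        fvals = f_sm[tuple(pts_vox.T)].astype(np.float64)
        flo, fhi = fvals.min(), fvals.max()
        if fhi <= flo:
            fhi = flo + 1.0
        fidx = np.minimum((fvals - flo) * (B / (fhi - flo)), B - 1).astype(np.intp)
        mlo = float(m_sm.min())
        mhi = float(m_sm.max())
        if mhi <= mlo:
            mhi = mlo + 1.0
        mscale = B / (mhi - mlo)

        def neg_nmi(x):
            t = RigidTransform(x[:3], x[3:], centre)
            src_mm = t.inverse().apply_points(pts_mm)
            src_vox = ((src_mm - moving.origin_mm) / s).T
            mvals = ndimage.map_coordinates(m_sm, src_vox, order=1, mode="constant",
                                            cval=np.nan, prefilter=False)
            ok = ~np.isnan(mvals)
            if ok.sum() < 100:
                return 0.0  # no usable overlap
            midx = np.minimum((mvals[ok] - mlo) * mscale, B - 1).astype(np.intp)
            joint = np.bincount(fidx[ok] * B + midx, minlength=B * B)
            p = joint / joint.sum()
            pm = p.reshape(B, B)
            pa, pb = pm.sum(axis=1), pm.sum(axis=0)

            def H(q):
                q = q[q > 0]
                return -(q * np.log(q)).sum()

            hab = H(p)
            if hab <= 0 or H(pa) == 0 or H(pb) == 0:
                return -1.0
            return -(H(pa) + H(pb)) / hab

        return neg_nmi

    x = x0.copy()
    best_val = None
    for factor in cfg.pyramid:
        sigma = 0.0 if factor == 1 else factor / 2.0
        f_sm = ndimage.gaussian_filter(fdata, sigma) if sigma else fdata
        m_sm = ndimage.gaussian_filter(mdata, sigma) if sigma else mdata
        pts = _sample_points(fixed.shape, mask, factor, cfg.max_samples)
        obj = make_objective(f_sm, m_sm, pts)
        res = optimize.minimize(
            obj, x, method="Powell",
            options={"maxiter": cfg.max_iter, "xtol": 3e-3 * factor,
                     "ftol": cfg.tol, "disp": False})
        if best_val is None or res.fun < best_val or factor != cfg.pyramid[0]:
            x = res.x
            best_val = res.fun

    final = RigidTransform(x[:3], x[3:], centre)
    pts = _sample_points(fixed.shape, mask, 1, cfg.max_samples)
    obj = make_objective(fdata, mdata, pts)
    final_nmi = -obj(np.concatenate([final.angles_deg, final.translation_mm]))
    init_nmi = -obj(x0)
    if final_nmi < init_nmi - 1e-12:
        logger.warning("registration did not improve on the initial transform "
                       "(NMI %.5f -> %.5f); returning init", init_nmi, final_nmi)
        t0 = init or RigidTransform(centre_mm=centre)
        return RegistrationResult(t0, init_nmi, converged=False,
                                  message="optimiser non-improvement from degenerate start")
    return RegistrationResult(final, final_nmi, converged=True)
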