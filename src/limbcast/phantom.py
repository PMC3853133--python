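"""Synthetic residual-limb phantom and repeat-scan study generator.

The phantom emulates a below-knee residual limb as imaged for casting
studies: a rigid tibia-like bone (cylinder with a flat proximal plateau and
two small intercondylar tubercle bumps) embedded in a tapered soft-tissue
envelope with a superellipse cross-section, optionally wrapped by a
low-intensity stockinet gap (~3 mm) and a cast shell.  Repeat "scans" of a
subject share one bone/envelope geometry but differ by a rigid pose, smooth
local surface deformations (casting variability) and additive Gaussian
noise, so every downstream consistency statistic has a known ground truth.

All masks are produced by evaluating the analytic geometry at (inverse-posed)
voxel centres — the posed masks are exact, not resampled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from math import gamma
from pathlib import Path

import numpy as np

from .anatomy import AnatomicalFrame
from .registration import RigidTransform, grid_centre_mm
from .volume import BinaryMask, VoxelVolume, write_volume

logger = logging.getLogger("limbcast")

#: Grey-level means per tissue role (arbitrary units, well separated so that
#: nearest-mean thresholding is well posed).
DEFAULT_INTENSITIES = {"background": 0.0, "gap": 30.0, "cast": 65.0,
                       "soft_tissue": 110.0, "bone": 185.0}


class PhantomSizingError(ValueError):
    """The limb (plus gap shell) does not fit in the requested grid."""


@dataclass
class SurfaceBump:
    """Radial Gaussian perturbation of the soft-tissue surface.

    Positive amplitude bulges outward, negative dents inward; ``width_mm`` is
    the Gaussian sigma of the 3-D falloff around ``centre_mm``.
    """

    centre_mm: tuple
    amplitude_mm: float
    width_mm: float


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic scan.

    Defaults describe a scaled-down residuum (~50 mm long) that fits a 96³
    grid at 0.6 mm isotropic spacing.
    """

    grid_shape: tuple = (96, 96, 96)
    spacing_mm: float = 0.6
    limb_length_mm: float = 46.0
    proximal_radius_mm: float = 18.0
    distal_radius_mm: float = 10.0
    superellipse_exponent: float = 2.5  # cross-section |y/a|^p + |x/b|^p = 1
    ml_aspect: float = 0.52  # ML radius = aspect * AP radius (non-circular sections)
    tibia_length_mm: float = 20.0
    tibia_radius_mm: float = 7.5  # AP semi-axis at the plateau (flared metaphysis)
    tibia_distal_radius_mm: float = 4.0  # AP semi-axis at the distal bone end
    tibia_ml_aspect: float = 0.75  # bone section is elliptical (AP-elongated), as
    # anatomically; a circular shaft would leave axial rotation unobservable to
    # the bone-anchored registration
    tubercle_offset_mm: float = 2.0  # landmark offset from plateau centre, AP axis
    tubercle_radius_mm: float = 1.0  # small relative to the plateau, as anatomically
    tubercle_height_mm: float = 1.8
    gap_thickness_mm: float = 3.0  # stockinet gap between skin and cast
    cast_thickness_mm: float = 4.0
    with_cast: bool = True
    cap_height_mm: float | None = None  # distal-cap height; None -> distal radius
    tip_margin_mm: float = 3.0  # distal clearance from the grid bottom
    plateau_offset_mm: float = 24.0  # plateau height above the distal tip
    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    partial_volume: bool = True  # render boundary voxels with fractional fill
    # (as MR does); False gives piecewise-constant classes
    noise_sd: float = 0.0
    deformation: list = field(default_factory=list)  # list[SurfaceBump]
    pose: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0

    # -- derived geometry --------------------------------------------------
    @property
    def z_tip(self) -> float:
        return self.tip_margin_mm

    @property
    def z_top(self) -> float:
        return self.z_tip + self.limb_length_mm

    @property
    def z_plateau(self) -> float:
        return self.z_tip + self.plateau_offset_mm

    def axis_centre(self) -> np.ndarray:
        # centred on the voxel lattice midpoint (between voxel centres for
        # even grids) so the cutting planes do not coincide with voxel centres
        half = (np.array(self.grid_shape, dtype=float) - 1) / 2.0 * self.spacing_mm
        return np.array([0.0, half[1], half[2]])

    @property
    def cap_height(self) -> float:
        h = self.cap_height_mm
        return float(self.distal_radius_mm if h is None else h)

    def taper_radius(self, z):
        """AP semi-axis a(z): linear taper with an ellipsoidal distal cap of
        height ``cap_height`` (a hemisphere scaled to the distal radius by
        default)."""
        z = np.asarray(z, dtype=float)
        rd, rp = self.distal_radius_mm, self.proximal_radius_mm
        h = self.cap_height
        cap_top = self.z_tip + h
        lin = rd + (rp - rd) * np.clip(
            (z - cap_top) / max(self.limb_length_mm - h, 1e-9), 0.0, 1.0)
        frac = np.clip((cap_top - z) / h, 0.0, 1.0)
        return lin * np.sqrt(np.clip(1.0 - frac ** 2, 0.0, 1.0))

    def validate(self) -> None:
        s = self.spacing_mm
        if s <= 0:
            raise ValueError("spacing_mm must be positive")
        if not self.distal_radius_mm < self.proximal_radius_mm:
            raise ValueError("limb must taper distally (distal_radius < proximal_radius)")
        ext = np.array(self.grid_shape, dtype=float) * s
        pad = self.gap_thickness_mm if self.with_cast else 0.0
        if self.z_top + 2 * s > ext[0]:
            raise PhantomSizingError(
                f"limb length {self.limb_length_mm} mm + margins exceeds grid extent {ext[0]:.1f} mm")
        if self.proximal_radius_mm + pad + 2 * s > ext[1] / 2 or \
                self.ml_aspect * self.proximal_radius_mm + pad + 2 * s > ext[2] / 2:
            raise PhantomSizingError("limb radius (plus gap) exceeds the grid half-extent")
        # tibia strictly inside the envelope over its full extent
        z_bot = self.z_plateau - self.tibia_length_mm
        zz = np.linspace(z_bot, self.z_plateau + self.tubercle_height_mm, 128)
        rd = self.tibia_distal_radius_mm
        rt = rd + (self.tibia_radius_mm - rd) * np.clip(
            (zz - z_bot - rd) / max(self.tibia_length_mm - rd, 1e-9), 0.0, 1.0)
        rt = rt * np.sqrt(np.clip(1.0 - np.clip((z_bot + rd - zz) / rd, 0.0, 1.0) ** 2,
                                  0.0, 1.0))  # rounded distal bone end
        env = self.taper_radius(zz)
        if np.any(env * self.ml_aspect <= rt * self.tibia_ml_aspect + s) or \
                np.any(env <= rt + s):
            raise ValueError("tibia does not fit inside the soft-tissue envelope")
        if self.tibia_radius_mm <= self.tubercle_offset_mm + self.tubercle_radius_mm:
            raise ValueError("tubercles must sit on the tibial plateau")
        lv = sorted(self.intensity_levels.values())
        min_gap = min(b - a for a, b in zip(lv, lv[1:]))
        if self.noise_sd > 0 and min_gap < 5.0 * self.noise_sd:
            raise ValueError(f"intensity class gap {min_gap:.1f} < 5 x noise_sd; "
                             "threshold segmentation would be ill-posed")

    def superellipse_area_coeff(self) -> float:
        """Area of |y/a|^p+|x/b|^p<=1 equals coeff * a * b."""
        p = self.superellipse_exponent
        return 4.0 * gamma(1 + 1 / p) ** 2 / gamma(1 + 2 / p)


# ---------------------------------------------------------------------------
# Voxelisation
# ---------------------------------------------------------------------------

def _canonical_coords(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    """(z, y, x) mm coordinate arrays of all voxel centres, inverse-posed."""
    idx = np.indices(spec.grid_shape, dtype=np.float32)
    co = idx * spec.spacing_mm
    if not spec.pose.is_identity():
        pts = co.reshape(3, -1).T
        pts = spec.pose.inverse().apply_points(pts)
        co = pts.T.reshape((3,) + tuple(spec.grid_shape)).astype(np.float32)
    return co[0], co[1], co[2]


def _limb_distance(spec: PhantomSpec, z, y, x):
    """Signed distance (mm, approx; negative inside) to the deformed
    soft-tissue surface, radially, combined with the end planes."""
    c = spec.axis_centre()
    dy = y - c[1]
    dx = x - c[2]
    a = spec.taper_radius(z)  # AP semi-axis
    b = spec.ml_aspect * a  # ML semi-axis
    p = spec.superellipse_exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (np.abs(dy / np.maximum(a, 1e-9)) ** p +
               np.abs(dx / np.maximum(b, 1e-9)) ** p) ** (1.0 / p)
    r = np.hypot(dy, dx)
    # distance outside the undeformed surface along the ray from the axis
    r_excess = np.where(rho > 1e-6, r - r / np.maximum(rho, 1e-6),
                        -np.minimum(a, b))
    r_excess = np.where(a > 0, r_excess.astype(np.float32), np.float32(np.inf))

    delta = np.zeros_like(r_excess, dtype=np.float32)
    for bump in spec.deformation:
        bc = np.asarray(bump.centre_mm, dtype=float)
        d2 = (z - bc[0]) ** 2 + (y - bc[1]) ** 2 + (x - bc[2]) ** 2
        w = float(bump.width_mm)
        g = np.exp(-d2 / (2.0 * w ** 2)).astype(np.float32)
        g[d2 > (3.0 * w) ** 2] = 0.0  # compact support: strictly local bumps
        delta += np.float32(bump.amplitude_mm) * g
    d_rad = r_excess - delta
    return np.maximum(d_rad, np.maximum(spec.z_tip - z, z - spec.z_top))


def _tibia_distance(spec: PhantomSpec, z, y, x):
    """Signed distance (mm, approx) to the bone surface (shaft + tubercles)."""
    c = spec.axis_centre()
    dy = y - c[1]
    dx = x - c[2]
    z_bot = spec.z_plateau - spec.tibia_length_mm
    asp = spec.tibia_ml_aspect
    rd = spec.tibia_distal_radius_mm
    # shaft tapers from the flared plateau down to the distal end
    rt = rd + (spec.tibia_radius_mm - rd) * np.clip(
        (z - z_bot - rd) / max(spec.tibia_length_mm - rd, 1e-9), 0.0, 1.0)
    r_ell = np.hypot(dy, dx / asp)  # elliptical section, AP-elongated
    # rounded distal end of the bone
    scale = np.sqrt(np.clip(1.0 - np.clip((z_bot + rd - z) / rd, 0.0, 1.0) ** 2, 0.0, 1.0))
    # radial distance normalised back to ~mm using the minor-axis factor
    d_rad = (r_ell - rt * scale) * asp
    d_shaft = np.maximum(d_rad, np.maximum(z_bot - z, z - spec.z_plateau))
    # intercondylar tubercle bumps: half-ellipsoids on the plateau, +-AP offset
    h, rr = spec.tubercle_height_mm, spec.tubercle_radius_mm
    d_tub = np.full_like(d_shaft, np.float32(np.inf))
    for sgn in (+1, -1):
        dzn = (z - spec.z_plateau) / h
        d2n = ((dy - sgn * spec.tubercle_offset_mm) ** 2 + dx ** 2) / rr ** 2
        d_e = (np.sqrt(np.maximum(dzn ** 2 + d2n, 0.0)) - 1.0) * min(h, rr)
        d_e = np.maximum(d_e, spec.z_plateau - z)  # half-ellipsoid: above plateau
        d_tub = np.minimum(d_tub, d_e)
    return np.minimum(d_shaft, d_tub.astype(np.float32))


def _coverage(dist: np.ndarray, spacing: float) -> np.ndarray:
    """Approximate partial-volume fill fraction of a voxel from the signed
    distance at its centre (1 deep inside, 0 outside, linear ramp across the
    surface) — gives the greyscale the sub-voxel boundary information real
    scans carry."""
    return np.clip(0.5 - dist / spacing, 0.0, 1.0).astype(np.float32)


def _ground_truth_frame(spec: PhantomSpec, k: int = 5) -> AnatomicalFrame:
    """Frame of the canonical (unposed) geometry, voxelised on the same grid."""
    unposed = replace(spec, pose=RigidTransform())
    idx = np.indices(spec.grid_shape, dtype=np.float32)
    z, y, x = idx * spec.spacing_mm
    tibia = _tibia_distance(unposed, z, y, x) <= 0
    counts = tibia.reshape(tibia.shape[0], -1).sum(axis=1)
    ok = np.nonzero(counts >= k)[0]
    plateau_slice = int(ok[-1])
    c = spec.axis_centre()
    z_land = spec.z_plateau + spec.tubercle_height_mm
    tubercles = np.array([[z_land, c[1] + spec.tubercle_offset_mm, c[2]],
                          [z_land, c[1] - spec.tubercle_offset_mm, c[2]]])
    mid = np.array([spec.z_plateau, c[1], c[2]])
    return AnatomicalFrame(plateau_slice=plateau_slice, tubercles_mm=tubercles,
                           plateau_mid_mm=mid, spacing_mm=spec.spacing_mm)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, dict]:
    """Voxelise one scan; returns (greyscale volume, ground truth).

    Ground truth holds the exact ``limb_mask`` and ``tibia_mask`` on the same
    grid, the ``frame`` of the canonical (unposed) geometry, and the applied
    ``pose`` (canonical -> scanner).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    z, y, x = _canonical_coords(spec)
    s = spec.spacing_mm
    d_limb = _limb_distance(spec, z, y, x)
    d_tib = _tibia_distance(spec, z, y, x)
    limb = d_limb <= 0
    tibia = (d_tib <= 0) & limb  # bone strictly inside the envelope

    lv = spec.intensity_levels

    def cov(d):
        if spec.partial_volume:
            return _coverage(d, s)
        return (d <= 0).astype(np.float32)

    c_limb = cov(d_limb)
    c_tib = cov(d_tib)
    data = np.full(spec.grid_shape, lv["background"], dtype=np.float32)
    if spec.with_cast:
        c_lg = cov(d_limb - spec.gap_thickness_mm)
        c_lgc = cov(d_limb - spec.gap_thickness_mm - spec.cast_thickness_mm)
        data += (lv["gap"] - lv["background"]) * (c_lg - c_limb)
        data += (lv["cast"] - lv["background"]) * (c_lgc - c_lg)
    data += (lv["soft_tissue"] - lv["background"]) * c_limb
    data += (lv["bone"] - lv["soft_tissue"]) * c_tib
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    vol = VoxelVolume(data=data, spacing_mm=spec.spacing_mm)
    truth = {
        "limb_mask": BinaryMask(data=limb.astype(np.uint8), spacing_mm=spec.spacing_mm,
                                label="limb"),
        "tibia_mask": BinaryMask(data=tibia.astype(np.uint8), spacing_mm=spec.spacing_mm,
                                 label="tibia"),
        "frame": _ground_truth_frame(spec),
        "pose": spec.pose,
    }
    return vol, truth


# ---------------------------------------------------------------------------
# Repeat-scan study generation
# ---------------------------------------------------------------------------

@dataclass
class MethodEffects:
    """Casting-method shape model: within-method variability and mean offset.

    ``bump_amplitude_mm`` is the mean absolute radial surface deviation drawn
    per bump (sign random: bulge or dent); ``radial_offset_mm`` shifts the
    whole envelope radius, producing a between-method mean size difference.
    Pose jitter emulates repositioning in the scanner (uniform per axis).
    """

    bump_amplitude_mm: float = 1.2
    bump_amplitude_sd_mm: float = 0.5
    n_bumps: int = 3
    bump_width_mm: float = 5.0
    radial_offset_mm: float = 0.0
    pose_rot_deg: float = 2.0
    pose_trans_mm: float = 3.0


#: Hands-on casting is manual and less repeatable (larger, more variable
#: surface deviations, slightly larger overall cast); Hands-off uses a
#: uniform-pressure bladder (smaller deviations).
DEFAULT_METHOD_EFFECTS = {
    "hands_off": MethodEffects(bump_amplitude_mm=1.0, bump_amplitude_sd_mm=0.4),
    "hands_on": MethodEffects(bump_amplitude_mm=2.0, bump_amplitude_sd_mm=0.8,
                              radial_offset_mm=0.15),
}


@dataclass
class ScanRecord:
    volume: VoxelVolume
    truth: dict
    subject_id: str
    method: str
    repetition: int


def _surface_point(spec: PhantomSpec, z: float, theta: float) -> np.ndarray:
    """Point on the undeformed soft-tissue surface at height z, angle theta."""
    c = spec.axis_centre()
    a = float(spec.taper_radius(z))
    b = spec.ml_aspect * a
    p = spec.superellipse_exponent
    cy, sx = np.cos(theta), np.sin(theta)
    dy = a * np.sign(cy) * np.abs(cy) ** (2.0 / p)
    dx = b * np.sign(sx) * np.abs(sx) ** (2.0 / p)
    return np.array([z, c[1] + dy, c[2] + dx])


def _draw_bumps(spec: PhantomSpec, eff: MethodEffects, rng: np.random.Generator) -> list:
    bumps = []
    for _ in range(eff.n_bumps):
        zf = rng.uniform(0.3, 0.85)
        zb = spec.z_tip + zf * spec.limb_length_mm
        theta = rng.uniform(0.0, 2.0 * np.pi)
        amp = abs(rng.normal(eff.bump_amplitude_mm, eff.bump_amplitude_sd_mm))
        amp *= rng.choice([-1.0, 1.0])
        bumps.append(SurfaceBump(tuple(_surface_point(spec, zb, theta)),
                                 float(amp), eff.bump_width_mm))
    return bumps


def generate_study(spec: PhantomSpec, n_subjects: int, reps_per_method: int = 2,
                   method_effects: dict[str, MethodEffects] | None = None,
                   seed: int = 0, subject_size_sd: float = 0.12,
                   subject_length_sd: float = 0.05) -> list[list[ScanRecord]]:
    """Simulate a repeat-casting study: per subject, two casting methods with
    ``reps_per_method`` scans each, sharing one tibia/envelope geometry.

    Between-subject geometry varies (radius and length scale factors), giving
    the between-subject variance that drives ICC; within-method bump and pose
    draws give the known within-method variability.  Deterministic given
    ``seed``.  Returns a list of subjects, each a list of ScanRecord.
    """
    if n_subjects < 1 or reps_per_method < 1:
        raise ValueError("need n_subjects >= 1 and reps_per_method >= 1")
    effects = dict(DEFAULT_METHOD_EFFECTS) if method_effects is None else method_effects
    rng = np.random.default_rng(seed)
    study = []
    for si in range(n_subjects):
        size = float(np.clip(rng.normal(1.0, subject_size_sd), 0.82, 1.18))
        length = float(np.clip(rng.normal(1.0, subject_length_sd), 0.90, 1.10))
        base = replace(
            spec,
            proximal_radius_mm=spec.proximal_radius_mm * size,
            distal_radius_mm=spec.distal_radius_mm * size,
            tibia_radius_mm=spec.tibia_radius_mm * size,
            tibia_distal_radius_mm=spec.tibia_distal_radius_mm * size,
            limb_length_mm=spec.limb_length_mm * length,
            plateau_offset_mm=spec.plateau_offset_mm * length,
            tibia_length_mm=spec.tibia_length_mm * length,
        )
        subject = []
        for method, eff in effects.items():
            for rep in range(1, reps_per_method + 1):
                sp = replace(
                    base,
                    proximal_radius_mm=base.proximal_radius_mm + eff.radial_offset_mm,
                    distal_radius_mm=base.distal_radius_mm + eff.radial_offset_mm,
                    deformation=_draw_bumps(base, eff, rng),
                    pose=RigidTransform(
                        angles_deg=rng.uniform(-eff.pose_rot_deg, eff.pose_rot_deg, 3),
                        translation_mm=rng.uniform(-eff.pose_trans_mm, eff.pose_trans_mm, 3),
                        centre_mm=np.array(base.grid_shape) * base.spacing_mm / 2.0),
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                vol, truth = generate_phantom(sp)
                vol.subject_id = f"S{si + 1:02d}"
                vol.method = method
                vol.repetition = rep
                subject.append(ScanRecord(vol, truth, vol.subject_id, method, rep))
        study.append(subject)
    return study


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def save_scan(record: ScanRecord, out_dir) -> dict:
    """Write volume + masks as NIfTI and the ground truth as a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{record.subject_id}_{record.method}_rep{record.repetition}"
    paths = {
        "volume": write_volume(record.volume, out_dir / f"{stem}.nii.gz"),
        "limb_mask": write_volume(record.truth["limb_mask"], out_dir / f"{stem}_limb.nii.gz"),
        "tibia_mask": write_volume(record.truth["tibia_mask"], out_dir / f"{stem}_tibia.nii.gz"),
    }
    frame = record.truth["frame"]
    sidecar = {
        "pose": record.truth["pose"].to_dict(),
        "plateau_slice": int(frame.plateau_slice),
        "tubercles": frame.tubercles_mm.tolist(),
        "plateau_mid": frame.plateau_mid_mm.tolist(),
    }
    sc = out_dir / f"{stem}.json"
    with open(sc, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    paths["sidecar"] = sc
    return paths
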