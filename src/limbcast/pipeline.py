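"""End-to-end study runner: phantom -> segment -> register -> standardise ->
metrics -> consistency statistics.

Mirrors the study protocol: per subject, one of the four scans is selected
at random as the reference, its tibia is aligned so transverse slices are
parallel to the plateau, the remaining scans are rigidly registered to it by
tibia-anchored NMI, all limb masks are cropped 30 slices above the plateau,
and the shape/volume/length/CSSA/circularity metrics feed the intra- and
inter-cast consistency statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy, metrics, stats
from .anatomy import AnatomicalFrame
from .phantom import MethodEffects, PhantomSpec, ScanRecord, generate_study
from .registration import RegistrationConfig, RigidTransform, apply_transform, register_rigid
from .stats import ConsistencyReport
from .volume import segment_limb

logger = logging.getLogger("limbcast")

METHODS = ("hands_off", "hands_on")


@dataclass
class StudyConfig:
    """Everything one reproducible study run needs."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_subjects: int = 3
    reps_per_method: int = 2
    method_effects: dict | None = None  # {method: MethodEffects}
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    sock_pct: float = stats.DEFAULT_SOCK_PCT
    per_region_slices: int = 3
    seed: int = 0
    output_dir: str | None = None


@dataclass
class SubjectResult:
    subject_id: str
    frame: AnatomicalFrame
    reference: tuple  # (method, repetition)
    transforms: dict  # (method, rep) -> RigidTransform
    lengths_mm: dict  # (method, rep) -> float
    volumes_mm3: dict  # (method, rep) -> float
    regional_mm3: dict  # (method, rep) -> {region: mm3}
    slice_table: pd.DataFrame
    intra_shape: dict  # method -> ShapeDiffResult
    selected_slices: dict  # band -> [slice indices]


@dataclass
class StudyResult:
    config: StudyConfig
    subjects: list
    scan_metrics: pd.DataFrame
    slice_metrics: pd.DataFrame
    shape_metrics: pd.DataFrame
    report: pd.DataFrame
    clinical: dict
    failures: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-subject processing
# ---------------------------------------------------------------------------

def process_subject(scans: list[ScanRecord], cfg: StudyConfig,
                    rng: np.random.Generator) -> SubjectResult:
    intens = cfg.phantom.intensity_levels
    ref_i = int(rng.integers(len(scans)))
    ref = scans[ref_i]
    _, ref_tibia_native = segment_limb(ref.volume, intens)
    t_align = anatomy.align_to_plateau(ref_tibia_native)
    ref_grey = apply_transform(ref.volume, t_align)
    ref_limb, ref_tibia = segment_limb(ref_grey, intens)

    # masks are segmented from the transformed greyscale (not resampled
    # binaries): the partial-volume ramp carries the surface sub-voxel
    aligned = {}
    transforms = {}
    for i, rec in enumerate(scans):
        key = (rec.method, rec.repetition)
        if i == ref_i:
            aligned[key] = ref_limb
            transforms[key] = t_align
            continue
        res = register_rigid(ref_grey, rec.volume,
                             tibia_mask=ref_tibia, config=cfg.registration)
        if not res.converged:
            logger.warning("subject %s scan %s: registration flagged non-improving",
                           rec.subject_id, key)
        moved = apply_transform(rec.volume, res.transform)
        limb_i, _ = segment_limb(moved, intens)
        aligned[key] = limb_i
        transforms[key] = res.transform

    plateau = anatomy.find_plateau_slice(ref_tibia)
    truth_frame = ref.truth["frame"]
    pose = ref.truth["pose"]
    to_aligned = lambda pts: t_align.apply_points(pose.apply_points(pts))
    frame = AnatomicalFrame(
        plateau_slice=plateau,
        tubercles_mm=to_aligned(truth_frame.tubercles_mm),
        plateau_mid_mm=to_aligned(truth_frame.plateau_mid_mm),
        spacing_mm=ref.volume.spacing,
    )

    std = {k: anatomy.standardise(m, frame) for k, m in aligned.items()}
    lengths = {k: metrics.limb_length_mm(m) for k, m in std.items()}
    avg_length = float(np.mean(list(lengths.values())))
    ref_key = (scans[ref_i].method, scans[ref_i].repetition)
    tip = anatomy.distal_tip_z_mm(std[ref_key])
    partition = anatomy.build_regions(frame, avg_length, tip_z_mm=tip)

    volumes = {k: metrics.volume_mm3(m) for k, m in std.items()}
    regional = {k: partition.region_volumes(m) for k, m in std.items()}

    common = None
    for m in std.values():
        ne = m.data.reshape(m.shape[0], -1).any(axis=1)
        common = ne if common is None else (common & ne)
    selected = metrics.sample_slices(std[ref_key], partition,
                                     per_region=cfg.per_region_slices, seed=rng,
                                     restrict_to=np.nonzero(common)[0])
    slice_rows = []
    flat = [i for band in selected.values() for i in band]
    for k, m in std.items():
        for band, idxs in selected.items():
            for i in idxs:
                slice_rows.append({
                    "subject": scans[0].subject_id, "method": k[0], "repetition": k[1],
                    "band": band, "slice": i,
                    "cssa_mm2": metrics.cssa_mm2(m, i),
                    "circularity": metrics.circularity(m, i)})
    slice_table = pd.DataFrame(slice_rows)

    intra_shape = {}
    for method in METHODS:
        reps = sorted(r for (mth, r) in std if mth == method)
        if len(reps) >= 2:
            intra_shape[method] = metrics.shape_difference(
                std[(method, reps[0])], std[(method, reps[1])],
                partition=partition, keep_labels=False)

    return SubjectResult(
        subject_id=scans[0].subject_id, frame=frame, reference=ref_key,
        transforms=transforms, lengths_mm=lengths, volumes_mm3=volumes,
        regional_mm3=regional, slice_table=slice_table,
        intra_shape=intra_shape, selected_slices=selected)


# ---------------------------------------------------------------------------
# Study-level aggregation
# ---------------------------------------------------------------------------

def _subject_frame(subjects: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for (method, rep), vol in s.volumes_mm3.items():
            row = {"subject": s.subject_id, "method": method, "repetition": rep,
                   "volume_mm3": vol, "length_mm": s.lengths_mm[(method, rep)]}
            row.update({f"vol_{r}_mm3": v for r, v in s.regional_mm3[(method, rep)].items()})
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["subject", "method", "repetition"],
                                          ignore_index=True)


def _shape_frame(subjects: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for method, sd in s.intra_shape.items():
            row = {"subject": s.subject_id, "method": method,
                   "shape_diff_mm3": sd.total_mm3}
            row.update({f"shape_{r}_mm3": v for r, v in sd.per_region.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def _paired_rows(report: ConsistencyReport, scan_df: pd.DataFrame, metric_col: str,
                 metric_name: str) -> None:
    for method in METHODS:
        sub = scan_df[scan_df.method == method].pivot_table(
            index="subject", columns="repetition", values=metric_col)
        if sub.shape[1] < 2 or len(sub) < 3:
            continue
        x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
        pc = stats.paired_compare(x, y)
        ba = stats.bland_altman(x, y)
        report.add(metric_name, "overall", f"intra_{method}",
                   mean_diff=pc.mean_diff, sd_diff=pc.sd_diff,
                   icc=stats.icc(sub.to_numpy()), normality_p=pc.normality_p,
                   test_used=pc.test_used, p_value=pc.p_value,
                   ba_bias=ba["bias"], ba_loa_low=ba["loa_low"], ba_loa_high=ba["loa_high"])
    # inter-cast: method-averaged values
    avg = scan_df.pivot_table(index="subject", columns="method", values=metric_col)
    if set(METHODS) <= set(avg.columns) and len(avg) >= 3:
        x, y = avg["hands_off"].to_numpy(), avg["hands_on"].to_numpy()
        pc = stats.paired_compare(x, y)
        ba = stats.bland_altman(x, y)
        report.add(metric_name, "overall", "inter",
                   mean_diff=pc.mean_diff, sd_diff=pc.sd_diff, icc=float("nan"),
                   normality_p=pc.normality_p, test_used=pc.test_used,
                   p_value=pc.p_value, ba_bias=ba["bias"],
                   ba_loa_low=ba["loa_low"], ba_loa_high=ba["loa_high"])


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full consistency study; fully reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    study = generate_study(cfg.phantom, cfg.n_subjects, cfg.reps_per_method,
                           method_effects=cfg.method_effects,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
    subjects: list[SubjectResult] = []
    failures = []
    for scans in study:
        sid = scans[0].subject_id
        try:
            subjects.append(process_subject(scans, cfg, rng))
        except Exception as exc:  # a failed subject aborts the subject, not the study
            logger.exception("subject %s failed: %s", sid, exc)
            failures.append({"subject": sid, "error": str(exc)})
    if not subjects:
        raise RuntimeError("no subject completed the pipeline")

    scan_df = _subject_frame(subjects)
    shape_df = _shape_frame(subjects)
    slice_df = pd.concat([s.slice_table for s in subjects], ignore_index=True)

    report = ConsistencyReport()
    _paired_rows(report, scan_df, "volume_mm3", "volume")
    _paired_rows(report, scan_df, "length_mm", "length")
    for region in anatomy.REGION_NAMES:
        _paired_rows(report, scan_df, f"vol_{region}_mm3", f"volume_{region}")

    # shape-difference CoV per method, overall and regional
    def _cov(v):
        return stats.cov_pct(v) if float(np.mean(v)) != 0 else float("nan")

    for method in METHODS:
        sub = shape_df[shape_df.method == method]
        if len(sub) >= 2:
            report.add("shape_diff", "overall", f"intra_{method}",
                       mean_diff=float(sub.shape_diff_mm3.mean()),
                       sd_diff=float(sub.shape_diff_mm3.std(ddof=1)),
                       cov_pct=_cov(sub.shape_diff_mm3))
            for region in anatomy.REGION_NAMES:
                col = f"shape_{region}_mm3"
                if col in sub:
                    report.add("shape_diff", region, f"intra_{method}",
                               mean_diff=float(sub[col].mean()),
                               sd_diff=float(sub[col].std(ddof=1)),
                               cov_pct=_cov(sub[col]))

    # one-sock clinical significance
    clinical = {}
    vol_piv = {m: scan_df[scan_df.method == m].pivot_table(
        index="subject", columns="repetition", values="volume_mm3") for m in METHODS}
    mean4 = scan_df.pivot_table(index="subject", values="volume_mm3", aggfunc="mean")
    for method in METHODS:
        piv = vol_piv[method]
        sub_shape = shape_df[shape_df.method == method].set_index("subject")
        if piv.shape[1] >= 2 and len(piv) >= 3:
            shape_series = sub_shape.loc[piv.index, "shape_diff_mm3"].to_numpy() \
                if len(sub_shape) else None
            clinical[method] = stats.clinical_significance(
                piv.iloc[:, 0].to_numpy(), piv.iloc[:, 1].to_numpy(),
                sock_pct=cfg.sock_pct, shape_diffs=shape_series,
                mean_volumes=mean4.loc[piv.index, "volume_mm3"].to_numpy())
    avg = scan_df.pivot_table(index="subject", columns="method", values="volume_mm3")
    if set(METHODS) <= set(avg.columns) and len(avg) >= 3:
        clinical["inter"] = stats.clinical_significance(
            avg["hands_off"].to_numpy(), avg["hands_on"].to_numpy(),
            sock_pct=cfg.sock_pct)

    result = StudyResult(config=cfg, subjects=subjects, scan_metrics=scan_df,
                         slice_metrics=slice_df, shape_metrics=shape_df,
                         report=report.to_frame(), clinical=clinical,
                         failures=failures)
    if cfg.output_dir:
        write_outputs(result, cfg.output_dir)
    return result


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def summary_dict(result: StudyResult) -> dict:
    """Compact machine-readable summary of a study run."""
    rep = result.report
    out = {"n_subjects": len(result.subjects), "failures": result.failures,
           "clinical": {}}
    for key, tests in result.clinical.items():
        out["clinical"][key] = {
            name: {"mean_diff": t.mean_diff, "sd_diff": t.sd_diff,
                   "p_value": t.p_value, "verdict": t.verdict}
            for name, t in tests.items()}
    for _, row in rep.iterrows():
        k = f"{row['metric']}|{row['region']}|{row['comparison']}"
        out[k] = {c: _jsonable(row[c]) for c in rep.columns
                  if c not in ("metric", "region", "comparison") and pd.notna(row[c])}
    return out


def write_outputs(result: StudyResult, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out_dir / "report.csv", index=False)
    result.scan_metrics.to_csv(out_dir / "scan_metrics.csv", index=False)
    result.slice_metrics.to_csv(out_dir / "slice_metrics.csv", index=False)
    result.shape_metrics.to_csv(out_dir / "shape_metrics.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(summary_dict(result), fh, indent=1, sort_keys=True)
    manifest = {"config": _jsonable(result.config)}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    # Bland-Altman point data for the volume metric
    for method in METHODS:
        piv = result.scan_metrics[result.scan_metrics.method == method].pivot_table(
            index="subject", columns="repetition", values="volume_mm3")
        if piv.shape[1] >= 2:
            ba = stats.bland_altman(piv.iloc[:, 0].to_numpy(), piv.iloc[:, 1].to_numpy())
            pd.DataFrame({"subject": piv.index, "mean": ba["mean"],
                          "diff": ba["diff"]}).to_csv(
                out_dir / f"ba_volume_{method}.csv", index=False)
    return {"out_dir": out_dir}
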