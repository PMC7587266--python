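"""End-to-end orchestration: configuration, container I/O, the per-subject
pipeline, and the repeatability and comparative experiments on synthetic
cohorts.

Pipeline order per subject: polarization extraction -> anterior-segment
compensation -> frame ranking / registration / Stokes averaging ->
segmentation -> birefringence quantification -> subject summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import averaging, birefringence, cohort_stats, polarization, segmentation
from .averaging import AveragedScan
from .birefringence import BirefringenceProfile
from .cohort_stats import SubjectSummary
from .segmentation import LayerSegmentation
from .synthetic_data import (ComplexBScanPair, GroundTruth, NoiseParams,
                             Phantom, PRESETS, ScanGeometry, make_phantom,
                             render_circular_sequence)

logger = logging.getLogger("psoct_rnfl")

__all__ = [
    "PipelineConfig",
    "save_sequence",
    "load_sequence",
    "run_subject",
    "run_repeatability_experiment",
    "run_comparative_experiment",
]


@dataclass
class PipelineConfig:
    """All protocol constants of the per-subject pipeline."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_select: int = 50
    reference_policy: str | int = "medoid"
    compensation: bool = True
    dopu_window: tuple[int, int] = (4, 8)
    ilm_threshold_db: float = 15.0
    dopu_threshold: float = 0.70
    shadow_threshold: float = 0.6
    thickness_threshold_um: float = 100.0
    thickness_thresholds_um: tuple[float, ...] = (75.0, 100.0, 125.0)
    bin_width_deg: float = 0.25
    method: str = "both"  # quotient | regression | both

    def __post_init__(self) -> None:
        if self.method not in ("quotient", "regression", "both"):
            raise ValueError(f"invalid method {self.method!r}")
        for t in (self.thickness_threshold_um, *self.thickness_thresholds_um):
            if t <= 0:
                raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "geometry" in d:
            g = d["geometry"]
            if isinstance(g.get("raster_extent_deg"), list):
                g["raster_extent_deg"] = tuple(g["raster_extent_deg"])
            d["geometry"] = ScanGeometry(**g)
        if "noise" in d:
            d["noise"] = NoiseParams(**d["noise"])
        if "dopu_window" in d:
            d["dopu_window"] = tuple(d["dopu_window"])
        if "thickness_thresholds_um" in d:
            d["thickness_thresholds_um"] = tuple(d["thickness_thresholds_um"])
        return cls(**d)


# ---------------------------------------------------------------------------
# container I/O

def save_sequence(path: str | Path, pairs: list[ComplexBScanPair],
                  gt: GroundTruth | None = None,
                  geometry: ScanGeometry | None = None) -> None:
    """Write a rendered sequence (and its ground truth) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        H = np.stack([p.H for p in pairs])
        V = np.stack([p.V for p in pairs])
        f.create_dataset("bscans/H", data=H, compression="gzip", compression_opts=1)
        f.create_dataset("bscans/V", data=V, compression="gzip", compression_opts=1)
        if geometry is not None:
            f["bscans"].attrs["geometry"] = json.dumps(
                dataclasses.asdict(geometry))
        if gt is not None:
            g = f.create_group("groundtruth")
            for k, v in dataclasses.asdict(gt).items():
                g.create_dataset(k, data=np.asarray(v))


def load_sequence(path: str | Path
                  ) -> tuple[list[ComplexBScanPair], ScanGeometry | None]:
    with h5py.File(path, "r") as f:
        if "bscans" not in f:
            raise KeyError(f"container {path} is missing the /bscans group")
        H = f["bscans/H"][...]
        V = f["bscans/V"][...]
        geometry = None
        if "geometry" in f["bscans"].attrs:
            d = json.loads(f["bscans"].attrs["geometry"])
            d["raster_extent_deg"] = tuple(d["raster_extent_deg"])
            geometry = ScanGeometry(**d)
    pairs = [ComplexBScanPair(H[i], V[i]) for i in range(H.shape[0])]
    return pairs, geometry


def _write_results(path: str | Path, avg: AveragedScan,
                   seg: LayerSegmentation,
                   profile: BirefringenceProfile) -> None:
    with h5py.File(path, "a") as f:
        for name in ("averaged", "segmentation", "profile"):
            if name in f:
                del f[name]
        a = f.create_group("averaged")
        a.create_dataset("reflectivity", data=avg.mean_reflectivity_db)
        a.create_dataset("retardation", data=avg.mean_retardation_deg)
        a.create_dataset("dopu", data=avg.dopu)
        meta = a.create_group("meta")
        meta.create_dataset("selected_indices", data=avg.selected_indices)
        meta.create_dataset("correlation_scores", data=avg.correlation_scores)
        meta.create_dataset("shifts", data=avg.shifts)
        s = f.create_group("segmentation")
        for k in ("ilm_idx", "rnfl_lower_idx", "rpe_top_idx",
                  "rpe_bottom_idx", "vessel_mask", "valid"):
            s.create_dataset(k.replace("_idx", ""), data=getattr(seg, k))
        s.create_dataset("thickness_um", data=seg.thickness_um)
        p = f.create_group("profile")
        for k in ("angle_deg", "thickness_um", "delta_pr_deg",
                  "biref_quotient", "biref_regression",
                  "regression_npoints", "valid_mask", "vessel_mask"):
            p.create_dataset(k, data=getattr(profile, k))


def profile_to_frame(profile: BirefringenceProfile,
                     eye: str = "OD") -> pd.DataFrame:
    """Per-A-scan table (angle, thickness, delta_PR, both estimates,
    validity, quadrant) in TSNIT order."""
    quad = cohort_stats.quadrant_labels(profile.n_ascans, eye)
    return pd.DataFrame({
        "angle_deg": profile.angle_deg,
        "thickness_um": profile.thickness_um,
        "delta_pr_deg": profile.delta_pr_deg,
        "biref_quotient": profile.biref_quotient,
        "biref_regression": profile.biref_regression,
        "valid": profile.valid_mask,
        "vessel": profile.vessel_mask,
        "quadrant": quad,
    })


# ---------------------------------------------------------------------------
# per-subject pipeline

def _quick_surface(pol_frames: list[polarization.PolarizationBScan],
                   threshold_db: float) -> np.ndarray:
    """Rough per-A-scan retinal surface from a median of probe frames
    (for anterior-segment compensation, before registration)."""
    probes = np.unique(np.linspace(0, len(pol_frames) - 1,
                                   min(5, len(pol_frames))).astype(int))
    db = np.median(np.stack([pol_frames[int(i)].reflectivity_db
                             for i in probes]), axis=0)
    floor = segmentation.estimate_noise_floor_db(db)
    above = db > floor + threshold_db
    has = above.any(axis=0)
    idx = np.where(has, above.argmax(axis=0), -1)
    return idx


def run_subject(
    pairs: list[ComplexBScanPair],
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
    container: str | Path | None = None,
) -> tuple[AveragedScan, LayerSegmentation, BirefringenceProfile, SubjectSummary]:
    """Execute the full per-subject pipeline on a rendered sequence.

    Deterministic for fixed config and input.  If ``container`` is given,
    every stage's outputs are written back to it.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()

    pol_frames = [polarization.extract_polarization(p) for p in pairs]
    stokes_frames = [polarization.to_stokes(p) for p in pairs]
    logger.info("stage=extract frames=%d dt=%.2fs",
                len(pairs), time.perf_counter() - t0)

    if config.compensation:
        surface = _quick_surface(pol_frames, config.ilm_threshold_db)
        stokes_frames, rot = polarization.compensate_anterior_segment(
            stokes_frames, surface)
        logger.info("stage=compensate rotation_trace=%.4f", np.trace(rot))

    ref_idx, scores = averaging.rank_by_correlation(
        pol_frames, config.reference_policy)
    selected = averaging.select_frames(scores, config.n_select)
    shifts = np.array([averaging.estimate_shift(pol_frames[i],
                                                pol_frames[ref_idx])
                       for i in selected])
    avg = averaging.average_scan(stokes_frames, selected, shifts,
                                 geometry=config.geometry, scores=scores,
                                 dopu_window=config.dopu_window,
                                 reference_index=ref_idx)
    logger.info("stage=average ref=%d n_selected=%d", ref_idx, len(selected))

    seg = segmentation.segment_scan(
        avg, ilm_threshold_db=config.ilm_threshold_db,
        dopu_threshold=config.dopu_threshold,
        shadow_threshold=config.shadow_threshold)
    logger.info("stage=segment invalid_ascans=%d", int((~seg.valid).sum()))

    profile = birefringence.quantify_scan(
        avg, seg, thickness_threshold_um=config.thickness_threshold_um,
        bin_width_deg=config.bin_width_deg)
    summary = cohort_stats.subject_summary(profile, subject_id)
    logger.info("stage=quantify n_valid=%d dt_total=%.2fs",
                summary.n_valid, time.perf_counter() - t0)

    if container is not None:
        _write_results(container, avg, seg, profile)
    return avg, seg, profile, summary


def run_subject_container(container: str | Path,
                          config: PipelineConfig | None = None,
                          subject_id: str = "subject"):
    """``run_subject`` reading the rendered sequence from an HDF5 container."""
    pairs, geometry = load_sequence(container)
    if geometry is not None:
        config = config or PipelineConfig()
        config = dataclasses.replace(config, geometry=geometry)
    return run_subject(pairs, config, subject_id, container=container)


def summarize_at_threshold(profile: BirefringenceProfile,
                           threshold_um: float,
                           subject_id: str = "subject") -> SubjectSummary:
    """Re-summarize an existing profile under a different RNFL thickness
    threshold (the threshold-sensitivity analysis)."""
    with np.errstate(invalid="ignore"):
        mask = (profile.thickness_um > threshold_um) & \
            ~profile.vessel_mask & profile.seg_valid
    relabeled = dataclasses.replace(profile, valid_mask=mask)
    return cohort_stats.subject_summary(relabeled, subject_id)


# ---------------------------------------------------------------------------
# experiments

def run_repeatability_experiment(
    config: PipelineConfig,
    phantom: Phantom,
    n_repeats: int = 5,
    seed: int = 0,
    subject_id: str = "S1",
) -> dict:
    """Repeated independent acquisitions of one subject.

    Each repeat re-renders the phantom with fresh noise, jitter and frame
    corruption (emulating repositioning + reacquisition), runs the full
    pipeline, and the per-quantity sample SDs over repeats are reported.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2 ** 31)
    summaries = []
    for r in range(n_repeats):
        pairs, _ = render_circular_sequence(phantom, config.geometry,
                                            seed=int(seeds[r]))
        _, _, _, summary = run_subject(pairs, config, f"{subject_id}-rep{r}")
        summaries.append(summary)
    sds = cohort_stats.repeatability(summaries)
    return {"subject_id": subject_id, "summaries": summaries, "sd": sds,
            "config_hash": config.config_hash(),
            "seeds": [int(s) for s in seeds]}


def simulate_subject_phantom(preset: str, rng: np.random.Generator,
                             noise: NoiseParams | None = None,
                             n_phi: int = 2048) -> Phantom:
    """Draw one subject of a simulated cohort.

    Between-subject variability is a normal draw of the subject's
    superior/inferior birefringence level around the group preset mean
    with the group's between-subject SD; anterior-segment birefringence
    is drawn uniformly per subject.
    """
    p = PRESETS[preset]
    level = float(rng.normal(p["biref_level"], p["biref_sd"]))
    level = max(level, 0.02)
    noise = noise or NoiseParams()
    noise = dataclasses.replace(
        noise,
        corneal_retardation_deg=float(rng.uniform(0.0, 25.0)),
        corneal_axis_deg=float(rng.uniform(-90.0, 90.0)))
    seed = int(rng.integers(0, 2 ** 31 - 1))
    return make_phantom(preset, {"biref_level": level, "noise": noise},
                        seed=seed, n_phi=n_phi)


def run_comparative_experiment(
    config: PipelineConfig,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    control: str = "healthy",
) -> dict:
    """Simulated cohort comparison (group means, SDs, Welch p-values).

    Renders per-group phantoms with between-subject birefringence
    variation, runs the full pipeline on each subject, and reports the
    group comparison for thickness, retardation and birefringence plus
    the birefringence table at all configured thickness thresholds.
    """
    n_per_group = n_per_group or {"healthy": 7, "diabetic": 7, "glaucoma": 6}
    rng = np.random.default_rng(seed)
    n_phi = config.geometry.n_ascans_per_bscan

    per_threshold: dict[float, dict[str, list[SubjectSummary]]] = {
        t: {g: [] for g in n_per_group} for t in config.thickness_thresholds_um}
    groups: dict[str, list[SubjectSummary]] = {g: [] for g in n_per_group}
    subject_rows = []
    for label, n in n_per_group.items():
        for i in range(n):
            phantom = simulate_subject_phantom(label, rng, config.noise, n_phi)
            pairs, _ = render_circular_sequence(
                phantom, config.geometry, seed=int(rng.integers(0, 2 ** 31 - 1)))
            sid = f"{label}-{i + 1}"
            _, _, profile, summary = run_subject(pairs, config, sid)
            groups[label].append(summary)
            subject_rows.append({
                "subject": sid, "group": label,
                "true_level": float(np.interp(
                    90.0, phantom.phi_deg, phantom.biref_deg_per_um)),
                "thickness_um": summary.mean_thickness_um,
                "retardation_deg": summary.mean_retardation_deg,
                "biref_quotient": summary.mean_biref_quotient,
                "biref_regression": summary.mean_biref_regression,
                "n_valid": summary.n_valid})
            for t in config.thickness_thresholds_um:
                per_threshold[t][label].append(
                    summarize_at_threshold(profile, t, sid))

    quantities = ("thickness_um", "retardation_deg", "biref_regression")
    if config.method in ("quotient", "both"):
        quantities = quantities + ("biref_quotient",)
    comparisons = {
        q: _compare_or_undefined(groups, control, q) for q in quantities}
    threshold_tables = {
        t: _compare_or_undefined(per_threshold[t], control,
                                 "biref_regression")
        for t in config.thickness_thresholds_um}
    return {
        "subjects": pd.DataFrame(subject_rows),
        "groups": groups,
        "comparisons": comparisons,
        "threshold_tables": threshold_tables,
        "config_hash": config.config_hash(),
        "seed": seed,
        "metadata": {"ttest": "welch, two-tailed, from summary statistics",
                     "multiple_testing": "none (raw p-values)"},
    }


def _compare_or_undefined(groups, control, quantity):
    """group_compare, with p reported as undefined (NaN) for n < 2 groups."""
    if min(len(m) for m in groups.values()) >= 2:
        return cohort_stats.group_compare(groups, control, quantity)
    attr = {"thickness_um": "mean_thickness_um",
            "retardation_deg": "mean_retardation_deg",
            "biref_quotient": "mean_biref_quotient",
            "biref_regression": "mean_biref_regression"}[quantity]
    results = []
    for label, members in groups.items():
        vals = np.array([getattr(s, attr) for s in members], dtype=float)
        res = cohort_stats.GroupResult(
            label=label, n=len(vals), mean=float(vals.mean()),
            sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan)
        if label != control:
            res.comparisons.append((control, np.nan, np.nan, np.nan))
        results.append(res)
    return results


def run_enface(pairs: list[ComplexBScanPair], geometry: ScanGeometry,
               config: PipelineConfig | None = None,
               thickness_threshold_um: float = 75.0) -> dict[str, np.ndarray]:
    """Build en-face maps from a raster volume (demonstration-grade).

    Each B-scan is processed individually (no repeats to average in a
    raster acquisition): polarization extraction, single-frame Stokes
    'average', segmentation, and both birefringence estimators.
    Birefringence is masked below the visualization thickness threshold.
    """
    config = config or PipelineConfig()
    ny = len(pairs)
    nx = pairs[0].shape[1]
    thick = np.full((ny, nx), np.nan)
    retard = np.full((ny, nx), np.nan)
    biref = np.full((ny, nx), np.nan)
    for j, pair in enumerate(pairs):
        stokes = polarization.to_stokes(pair)
        avg = averaging.average_scan(
            [stokes], np.array([0]), np.array([[0, 0]]),
            geometry=geometry, dopu_window=config.dopu_window)
        try:
            seg = segmentation.segment_scan(
                avg, ilm_threshold_db=config.ilm_threshold_db,
                dopu_threshold=config.dopu_threshold,
                shadow_threshold=config.shadow_threshold)
        except ValueError:
            continue  # B-scan without a segmentable retina (e.g. ONH rows)
        thick[j] = seg.thickness_um
        delta, _ = birefringence.pr_retardation(
            avg, seg.rpe_top_idx, bin_width_deg=config.bin_width_deg)
        retard[j] = delta
        slope, _ = birefringence.regression_method(
            avg, seg.ilm_idx, seg.rnfl_lower_idx, seg.axial_pitch_um)
        biref[j] = slope
    return birefringence.enface_maps(thick, retard, biref,
                                     thickness_threshold_um)


def comparison_table(comparisons: dict) -> pd.DataFrame:
    """Flatten group_compare output into a tidy table."""
    rows = []
    for quantity, results in comparisons.items():
        for r in results:
            row = {"quantity": quantity, "group": r.label, "n": r.n,
                   "mean": r.mean, "sd": r.sd, "p_vs_control": np.nan}
            if r.comparisons:
                row["p_vs_control"] = r.comparisons[0][3]
            rows.append(row)
    return pd.DataFrame(rows)
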