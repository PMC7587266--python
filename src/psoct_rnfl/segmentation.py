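"""Layer segmentation on the averaged circular tomogram.

Boundaries found, in TSNIT-ordered lateral (A-scan) coordinates:

* ILM — first pixel from the top whose reflectivity exceeds the noise
  floor by a configurable margin (intensity thresholding);
* RPE — the contiguous low-DOPU run of maximal summed intensity per
  A-scan (the RPE is the depolarizing layer);
* RNFL lower boundary — a smooth bright-to-dark gradient path found by
  dynamic programming over a dense trellis (equivalent to a shortest
  path for this topology), periodic across the circular scan seam.

Vessel shadows are detected as A-scans of low RPE-band intensity.  All
lateral filtering treats the scan as periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .averaging import AveragedScan

__all__ = [
    "LayerSegmentation",
    "segment_ilm",
    "segment_rpe",
    "segment_rnfl_lower",
    "detect_vessels",
    "apply_overrides",
    "segment_scan",
]

INVALID = -1  # sentinel depth index for undefined boundaries


@dataclass
class LayerSegmentation:
    """Per-A-scan boundary indices (0-based; a boundary index is the first
    pixel inside the layer; the RNFL occupies [ilm_idx, rnfl_lower_idx))."""

    ilm_idx: np.ndarray
    rnfl_lower_idx: np.ndarray
    rpe_top_idx: np.ndarray
    rpe_bottom_idx: np.ndarray
    vessel_mask: np.ndarray
    valid: np.ndarray
    axial_pitch_um: float = 2.0
    overrides_applied: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check_order()

    def check_order(self) -> None:
        v = self.valid
        ok = ((self.ilm_idx[v] <= self.rnfl_lower_idx[v])
              & (self.rnfl_lower_idx[v] <= self.rpe_top_idx[v])
              & (self.rpe_top_idx[v] <= self.rpe_bottom_idx[v]))
        if not np.all(ok):
            bad = np.nonzero(v)[0][~ok]
            raise ValueError(
                f"boundary ordering violated at A-scans {bad[:10].tolist()}")

    @property
    def thickness_um(self) -> np.ndarray:
        t = (self.rnfl_lower_idx - self.ilm_idx) * self.axial_pitch_um
        return np.where(self.valid, t, np.nan)


def _circular_median(values: np.ndarray, width: int) -> np.ndarray:
    pad = width // 2
    ext = np.concatenate([values[-pad:], values, values[:pad]])
    return ndimage.median_filter(ext, size=width, mode="nearest")[pad:pad + len(values)]


def _smooth_boundary(idx: np.ndarray, valid: np.ndarray,
                     width: int = 15, snap_px: int = 10) -> np.ndarray:
    """Median filter (circular) then snap outliers back to the local median."""
    out = idx.astype(float)
    if valid.sum() < 3:
        return np.round(out).astype(int)
    # fill invalid gaps by circular nearest-valid interpolation for filtering
    n = len(idx)
    x = np.arange(n)
    filled = out.copy()
    if (~valid).any():
        xv = x[valid]
        filled[~valid] = np.interp(x[~valid], xv, out[valid], period=n)
    med = _circular_median(filled, width)
    snapped = np.where(np.abs(filled - med) > snap_px, med, filled)
    return np.round(snapped).astype(int)


def estimate_noise_floor_db(reflectivity_db: np.ndarray,
                            percentile: float = 25.0) -> float:
    """Noise floor estimated as a low percentile of the whole image.

    In a circumpapillary tomogram well under half the depth range carries
    tissue signal, so a low percentile lands in the vitreous / sub-RPE
    noise; it is also robust to zero-filled rows left by registration.
    """
    return float(np.percentile(reflectivity_db, percentile))


def segment_ilm(avg: AveragedScan, threshold_db: float = 15.0,
                median_width: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """ILM as the first pixel from the top above (noise floor + margin).

    Returns (ilm_idx, valid); A-scans with no pixel above threshold are
    flagged invalid.
    """
    db = avg.mean_reflectivity_db
    floor = estimate_noise_floor_db(db)
    above = db > floor + threshold_db
    has = above.any(axis=0)
    idx = np.where(has, above.argmax(axis=0), INVALID)
    idx = np.where(has, _smooth_boundary(idx, has, median_width), INVALID)
    return idx, has


def segment_rpe(avg: AveragedScan, dopu_threshold: float = 0.70,
                median_width: int = 15) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RPE band from its depolarizing property.

    Per A-scan, among contiguous runs of pixels with DOPU below threshold,
    the run with maximal summed linear intensity is taken as the RPE band.
    Returns (rpe_top_idx, rpe_bottom_idx, valid); bottom is one past the
    last band pixel.
    """
    if avg.dopu is None:
        raise ValueError("AveragedScan carries no DOPU data")
    if not (0.0 < dopu_threshold <= 1.0):
        # threshold 0 admits no pixel: everything invalid
        nx = avg.shape[1]
        inval = np.zeros(nx, dtype=bool)
        return (np.full(nx, INVALID), np.full(nx, INVALID), inval)
    low = avg.dopu < dopu_threshold
    intensity = avg.linear_intensity()
    nz, nx = low.shape
    top = np.full(nx, INVALID)
    bot = np.full(nx, INVALID)
    valid = np.zeros(nx, dtype=bool)
    for x in range(nx):
        col = low[:, x]
        if not col.any():
            continue
        # contiguous runs of sub-threshold DOPU
        edges = np.diff(col.astype(int))
        starts = np.nonzero(edges == 1)[0] + 1
        ends = np.nonzero(edges == -1)[0] + 1
        if col[0]:
            starts = np.r_[0, starts]
        if col[-1]:
            ends = np.r_[ends, nz]
        sums = [intensity[s:e, x].sum() for s, e in zip(starts, ends)]
        k = int(np.argmax(sums))
        top[x], bot[x] = starts[k], ends[k]
        valid[x] = True
    if valid.any():
        top = np.where(valid, _smooth_boundary(top, valid, median_width), INVALID)
        bot = np.where(valid, _smooth_boundary(bot, valid, median_width), INVALID)
    return top, bot, valid


def segment_rnfl_lower(
    avg: AveragedScan,
    ilm_idx: np.ndarray,
    rpe_top_idx: np.ndarray,
    max_step: int = 4,
    smoothness: float = 0.1,
    gradient_scale: float = 6.0,
    rpe_margin_px: int = 40,
    gradient_cap_db: float = 20.0,
    lateral_sigma: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lower RNFL boundary by dynamic programming over (A-scan, depth).

    Node cost is exp(-scale * g) with g the bright-to-dark axial gradient
    of the laterally smoothed log-intensity image, capped at
    ``gradient_cap_db`` and normalized; the log-domain gradient makes the
    edge contrast invariant to vessel-shadow attenuation, and the lateral
    smoothing (Gaussian, periodic across the scan seam) suppresses
    residual speckle gradients, which the laterally coherent boundary
    survives.  Transitions between adjacent A-scans pay a smoothness
    penalty proportional to |ddepth| and are limited to ``max_step``
    pixels, including across the circular seam (closed by a second,
    anchored pass).  Ties break toward the shallower boundary.

    ``rpe_margin_px`` keeps the search band above the photoreceptor
    complex (~30 px above the RPE), whose edges are stronger than the
    RNFL base and would otherwise capture the path.
    """
    ilm_idx = np.asarray(ilm_idx)
    rpe_top_idx = np.asarray(rpe_top_idx)
    col_ok = (ilm_idx >= 0) & (rpe_top_idx >= 0) & \
             (ilm_idx + 2 < rpe_top_idx - rpe_margin_px)
    if col_ok.mean() < 0.5:
        raise ValueError("ILM and RPE must be defined on >= 50% of A-scans")

    db = avg.mean_reflectivity_db
    nz, nx = db.shape
    if lateral_sigma > 0 and nx > 8:
        db = ndimage.gaussian_filter1d(db, lateral_sigma, axis=1,
                                       mode="wrap")
    # bright-to-dark gradient: positive where intensity drops with depth;
    # backward difference so a step edge peaks at the first dark pixel
    # (the boundary convention: first pixel below the RNFL)
    g = np.zeros_like(db)
    g[1:, :] = db[:-1, :] - db[1:, :]
    g = np.clip(g, 0.0, gradient_cap_db) / gradient_cap_db
    node = np.exp(-gradient_scale * g)

    lo = np.where(col_ok, ilm_idx + 2, 0)
    hi = np.where(col_ok, rpe_top_idx - rpe_margin_px, nz)  # exclusive
    cost = node.copy()
    for x in range(nx):
        if col_ok[x]:
            cost[:lo[x], x] = np.inf
            cost[hi[x]:, x] = np.inf
        # invalid columns stay neutral so the path can bridge them

    def _dp(start_col_cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dp = np.empty((nz, nx))
        back = np.zeros((nz, nx), dtype=np.int16)
        dp[:, 0] = start_col_cost
        steps = np.arange(-max_step, max_step + 1)
        penalties = smoothness * np.abs(steps)
        for x in range(1, nx):
            prev = dp[:, x - 1]
            best = np.full(nz, np.inf)
            arg = np.zeros(nz, dtype=np.int16)
            for s, pen in zip(steps, penalties):
                # candidate from depth z - s in the previous column
                cand = np.full(nz, np.inf)
                if s >= 0:
                    cand[s:] = prev[:nz - s] + pen if s else prev + pen
                else:
                    cand[:s] = prev[-s:] + pen
                upd = cand < best
                best[upd] = cand[upd]
                arg[upd] = s
            dp[:, x] = best + cost[:, x]
            back[:, x] = arg
        return dp, back

    def _backtrack(dp: np.ndarray, back: np.ndarray, z_end: int) -> np.ndarray:
        path = np.empty(nx, dtype=int)
        path[-1] = z_end
        for x in range(nx - 1, 0, -1):
            path[x - 1] = path[x] - back[path[x], x]
        return path

    # free pass to locate the path, anchored pass to close the seam
    dp, back = _dp(cost[:, 0])
    path = _backtrack(dp, back, int(np.argmin(dp[:, -1])))
    z0 = path[0]
    if nx > 1:
        start = np.full(nz, np.inf)
        start[z0] = cost[z0, 0]
        dp, back = _dp(start)
        final = dp[:, -1].copy()
        steps = np.arange(nz) - z0
        final += smoothness * np.abs(steps)
        final[np.abs(steps) > max_step] = np.inf
        path = _backtrack(dp, back, int(np.argmin(final)))

    return path, col_ok


def detect_vessels(avg: AveragedScan, rpe_top_idx: np.ndarray,
                   rpe_bottom_idx: np.ndarray,
                   shadow_threshold: float = 0.6,
                   dilate_px: int = 2) -> np.ndarray:
    """Vessel shadows as A-scans of low RPE-band intensity.

    Mask is true where the mean linear intensity inside the RPE band falls
    below ``shadow_threshold`` times the median over all A-scans, then
    dilated by ``dilate_px`` A-scans on each side (circularly).
    """
    intensity = avg.linear_intensity()
    nx = intensity.shape[1]
    band_mean = np.full(nx, np.nan)
    for x in range(nx):
        t, b = rpe_top_idx[x], rpe_bottom_idx[x]
        if t >= 0 and b > t:
            band_mean[x] = intensity[t:b, x].mean()
    med = np.nanmedian(band_mean)
    with np.errstate(invalid="ignore"):
        mask = band_mean < shadow_threshold * med
    mask = np.nan_to_num(mask, nan=0.0).astype(bool)
    if dilate_px > 0 and mask.any():
        structure = np.ones(2 * dilate_px + 1, dtype=bool)
        ext = np.r_[mask[-dilate_px:], mask, mask[:dilate_px]]
        ext = ndimage.binary_dilation(ext, structure=structure)
        mask = ext[dilate_px:dilate_px + nx]
    return mask


def apply_overrides(seg: LayerSegmentation,
                    corrections: list[tuple]) -> LayerSegmentation:
    """Apply programmatic boundary corrections (the counterpart of manual
    segmentation adjustment).

    Each correction is ``(start, stop, boundary_name, indices)`` replacing
    the boundary verbatim on the half-open A-scan range [start, stop).
    The boundary-ordering invariant is re-checked; provenance is recorded.
    """
    names = {"ilm": "ilm_idx", "rnfl_lower": "rnfl_lower_idx",
             "rpe_top": "rpe_top_idx", "rpe_bottom": "rpe_bottom_idx"}
    new = LayerSegmentation(
        ilm_idx=seg.ilm_idx.copy(), rnfl_lower_idx=seg.rnfl_lower_idx.copy(),
        rpe_top_idx=seg.rpe_top_idx.copy(),
        rpe_bottom_idx=seg.rpe_bottom_idx.copy(),
        vessel_mask=seg.vessel_mask.copy(), valid=seg.valid.copy(),
        axial_pitch_um=seg.axial_pitch_um,
        overrides_applied=list(seg.overrides_applied))
    for start, stop, name, indices in corrections:
        if name not in names:
            raise ValueError(f"unknown boundary {name!r}")
        arr = getattr(new, names[name])
        indices = np.asarray(indices, dtype=int)
        if not (0 <= start < stop <= len(arr)):
            raise ValueError(f"correction range [{start}, {stop}) out of bounds")
        if indices.size != stop - start:
            raise ValueError("correction length mismatch")
        arr[start:stop] = indices
        new.overrides_applied.append((int(start), int(stop), name, "override"))
        try:
            new.check_order()
        except ValueError as exc:
            raise ValueError(
                f"correction on [{start}, {stop}) violates boundary order: {exc}"
            ) from exc
    return new


def segment_scan(avg: AveragedScan, ilm_threshold_db: float = 15.0,
                 dopu_threshold: float = 0.70,
                 shadow_threshold: float = 0.6) -> LayerSegmentation:
    """Run the full segmentation chain on an averaged circular scan."""
    pitch = avg.geometry.axial_pitch_um if avg.geometry is not None else 2.0
    ilm, ilm_ok = segment_ilm(avg, ilm_threshold_db)
    rpe_top, rpe_bot, rpe_ok = segment_rpe(avg, dopu_threshold)
    lower, band_ok = segment_rnfl_lower(avg, ilm, rpe_top)
    vessels = detect_vessels(avg, rpe_top, rpe_bot, shadow_threshold)
    valid = ilm_ok & rpe_ok & band_ok
    # clip any residual crossings produced by independent per-layer smoothing
    lower = np.where(valid, np.clip(lower, ilm, rpe_top), lower)
    return LayerSegmentation(
        ilm_idx=np.where(ilm_ok, ilm, INVALID),
        rnfl_lower_idx=np.where(valid, lower, INVALID),
        rpe_top_idx=np.where(rpe_ok, rpe_top, INVALID),
        rpe_bottom_idx=np.where(rpe_ok, rpe_bot, INVALID),
        vessel_mask=vessels, valid=valid, axial_pitch_um=pitch)
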