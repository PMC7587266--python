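"""Frame selection, registration and Stokes-vector averaging.

Of the repeated circular B-scans of one acquisition, the 50 best correlated
to a reference frame are selected, registered by integer shifts (lateral
shifts wrap around the closed scan circle) and averaged component-wise in
the Stokes representation.  Retardation is extracted *after* averaging,
which is what reduces speckle noise in the polarization data.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import fft as sp_fft

from .polarization import (PolarizationBScan, StokesBScan, compute_dopu,
                           polarization_from_stokes, _to_db)
from .synthetic_data import ScanGeometry

__all__ = [
    "AveragedScan",
    "rank_by_correlation",
    "estimate_shift",
    "select_frames",
    "average_scan",
]

MAX_AXIAL_SHIFT = 50  # px; larger axial motion is treated as corruption


@dataclass
class AveragedScan:
    """Registered, Stokes-averaged circular tomogram with provenance."""

    mean_reflectivity_db: np.ndarray
    mean_retardation_deg: np.ndarray
    dopu: np.ndarray
    stokes: StokesBScan
    selected_indices: np.ndarray
    correlation_scores: np.ndarray
    shifts: np.ndarray                       # per selected frame (axial, lateral)
    geometry: ScanGeometry | None = None
    reference_index: int = -1                # frame everything was aligned to

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_reflectivity_db.shape

    def linear_intensity(self) -> np.ndarray:
        return 10.0 ** (self.mean_reflectivity_db / 10.0)


def _central_band(intensity: np.ndarray, frac: float = 0.8) -> np.ndarray:
    nz = intensity.shape[0]
    lo = int(round(nz * (1 - frac) / 2))
    return intensity[lo:nz - lo, :]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def estimate_shift(frame: PolarizationBScan,
                   reference: PolarizationBScan,
                   max_axial: int = MAX_AXIAL_SHIFT) -> tuple[int, int]:
    """Integer (axial, lateral) shift aligning ``frame`` to ``reference``.

    Maximizes the cross-correlation of linear intensity; the lateral axis
    is circular (closed scan circle), the axial shift is clamped to
    ``max_axial``.  Returned with the convention that rolling ``frame`` by
    the result aligns it to the reference.
    """
    a = frame.linear_intensity()
    b = reference.linear_intensity()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    a = a - a.mean()
    b = b - b.mean()
    xc = sp_fft.irfft2(np.conj(sp_fft.rfft2(a)) * sp_fft.rfft2(b),
                       s=a.shape)
    nz = a.shape[0]
    ax_shifts = np.fft.fftfreq(nz, 1.0 / nz).astype(int)
    xc[np.abs(ax_shifts) > max_axial, :] = -np.inf
    iz, ix = np.unravel_index(np.argmax(xc), xc.shape)
    ax = int(ax_shifts[iz])
    lat = int(np.fft.fftfreq(a.shape[1], 1.0 / a.shape[1])[ix])
    return ax, lat


def rank_by_correlation(
    frames: list[PolarizationBScan],
    reference_policy: str | int = "medoid",
) -> tuple[int, np.ndarray]:
    """Score every frame by its correlation to a reference frame.

    Scores are Pearson correlations of linear intensity (central 80% of
    depth, to avoid noise-floor dominance) after coarse registration of
    each frame to the reference.  ``reference_policy``: ``"medoid"`` picks
    the frame maximizing the median correlation to 10 evenly spaced probe
    frames, ``"first"`` uses frame 0, an integer selects that frame.
    """
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames to rank")

    if isinstance(reference_policy, (int, np.integer)):
        ref_idx = int(reference_policy)
        if not 0 <= ref_idx < n:
            raise ValueError("reference index out of range")
    elif reference_policy == "first":
        ref_idx = 0
    elif reference_policy == "medoid":
        probes = np.unique(np.linspace(0, n - 1, min(10, n)).astype(int))
        medians = np.empty(n)
        for i in range(n):
            cs = [_correlate_registered(frames[i], frames[int(p)])
                  for p in probes if int(p) != i]
            medians[i] = np.median(cs) if cs else 1.0
        ref_idx = int(np.argmax(medians))
    else:
        raise ValueError(f"unknown reference policy {reference_policy!r}")

    ref = frames[ref_idx]
    scores = np.array([_correlate_registered(f, ref) for f in frames])
    return ref_idx, scores


def _correlate_registered(frame: PolarizationBScan,
                          ref: PolarizationBScan) -> float:
    sh = estimate_shift(frame, ref)
    a = _roll_image(frame.linear_intensity(), sh)
    return _pearson(_central_band(a), _central_band(ref.linear_intensity()))


def _roll_image(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    ax, lat = shift
    out = np.roll(img, lat, axis=1)
    out = np.roll(out, ax, axis=0)
    if ax > 0:
        out[:ax, :] = 0
    elif ax < 0:
        out[ax:, :] = 0
    return out


def select_frames(scores: np.ndarray, n_select: int = 50) -> np.ndarray:
    """Indices of the ``n_select`` best-scoring frames (all if fewer)."""
    n = len(scores)
    if n < n_select:
        warnings.warn(f"only {n} frames available, selecting all "
                      f"(requested {n_select})")
        n_select = n
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:n_select])


def average_scan(
    stokes_frames: list[StokesBScan],
    selected: np.ndarray,
    shifts: np.ndarray,
    geometry: ScanGeometry | None = None,
    scores: np.ndarray | None = None,
    dopu_window: tuple[int, int] = (4, 8),
    reference_index: int = -1,
) -> AveragedScan:
    """Register the selected frames and average their Stokes components.

    Stokes vectors are averaged unnormalized (intensity-weighted), then the
    mean retardation image is extracted from the averaged components and
    DOPU is computed on the averaged data.  Mean reflectivity is the dB of
    the mean linear intensity.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("empty frame selection")
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (selected.size, 2):
        raise ValueError("one (axial, lateral) shift per selected frame required")

    acc = None
    for k, idx in enumerate(selected):
        sb = stokes_frames[idx]
        comps = np.stack([sb.I, sb.Q, sb.U, sb.V])
        rolled = np.stack([_roll_image(c, tuple(shifts[k])) for c in comps])
        acc = rolled if acc is None else acc + rolled
    acc /= selected.size
    mean_stokes = StokesBScan(I=acc[0], Q=acc[1], U=acc[2], V=acc[3])

    pol = polarization_from_stokes(mean_stokes)
    dopu = compute_dopu(mean_stokes, dopu_window)
    mean_stokes.dopu = dopu
    if scores is None:
        scores = np.full(len(stokes_frames), np.nan)
    return AveragedScan(
        mean_reflectivity_db=_to_db(mean_stokes.I),
        mean_retardation_deg=pol.retardation_deg,
        dopu=dopu,
        stokes=mean_stokes,
        selected_indices=selected,
        correlation_scores=np.asarray(scores, dtype=float),
        shifts=shifts,
        geometry=geometry,
        reference_index=reference_index,
    )
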