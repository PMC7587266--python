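"""Polarization parameter extraction from two-channel complex B-scans.

Under circular illumination and two-channel polarization-sensitive
detection, the standard per-pixel extraction from the detected complex
amplitudes (A_H, A_V) is

    reflectivity  R  ~ |A_H|^2 + |A_V|^2
    retardation   d  = arctan(|A_V| / |A_H|)          in [0, 90] deg
    axis          t  = (180 deg - dPhi) / 2,  dPhi = arg(A_V) - arg(A_H)

The Stokes representation (I, Q, U, V) of the same state supports
speckle-reducing averaging across registered frames and the degree of
polarization uniformity (DOPU) used to find the depolarizing RPE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic_data import ComplexBScanPair

__all__ = [
    "PolarizationBScan",
    "StokesBScan",
    "extract_polarization",
    "to_stokes",
    "polarization_from_stokes",
    "apply_retarder",
    "compensate_anterior_segment",
    "compute_dopu",
    "REFLECTIVITY_FLOOR_DB",
]

REFLECTIVITY_FLOOR_DB = -100.0


@dataclass
class PolarizationBScan:
    """Per-pixel reflectivity (dB, relative to image max), retardation
    (deg, in [0, 90]) and axis orientation (deg, in [-90, 90))."""

    reflectivity_db: np.ndarray
    retardation_deg: np.ndarray
    axis_deg: np.ndarray
    degenerate: np.ndarray | None = None  # pixels with undefined polarization

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectivity_db.shape

    def linear_intensity(self) -> np.ndarray:
        return 10.0 ** (self.reflectivity_db / 10.0)


@dataclass
class StokesBScan:
    """Per-pixel Stokes components; ``dopu`` is filled on demand."""

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    V: np.ndarray
    dopu: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.I.shape


def _wrap_axis(theta_deg: np.ndarray) -> np.ndarray:
    return np.mod(theta_deg + 90.0, 180.0) - 90.0


def _to_db(intensity: np.ndarray) -> np.ndarray:
    peak = float(intensity.max())
    if peak <= 0:
        return np.full(intensity.shape, REFLECTIVITY_FLOOR_DB)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(intensity / peak)
    return np.maximum(db, REFLECTIVITY_FLOOR_DB)


def extract_polarization(pair: ComplexBScanPair) -> PolarizationBScan:
    """Per-pixel reflectivity / retardation / axis from the channel pair.

    Pixels with no light in either channel get retardation 0, axis 0, and
    the reflectivity floor.
    """
    H, V = np.asarray(pair.H), np.asarray(pair.V)
    if H.shape != V.shape:
        raise ValueError("channel shape mismatch")
    if H.size == 0:
        raise ValueError("empty B-scan")
    aH, aV = np.abs(H), np.abs(V)
    intensity = aH ** 2 + aV ** 2
    dark = intensity == 0
    ret = np.degrees(np.arctan2(aV, aH))
    ret[dark] = 0.0
    dphi = np.angle(V) - np.angle(H)
    theta = _wrap_axis((180.0 - np.degrees(dphi)) / 2.0)
    theta[dark] = 0.0
    return PolarizationBScan(_to_db(intensity), ret, theta, degenerate=dark)


def to_stokes(pair: ComplexBScanPair) -> StokesBScan:
    H, V = np.asarray(pair.H), np.asarray(pair.V)
    if H.shape != V.shape:
        raise ValueError("channel shape mismatch")
    if H.size == 0:
        raise ValueError("empty B-scan")
    aH2, aV2 = np.abs(H) ** 2, np.abs(V) ** 2
    cross = 2.0 * (np.conj(H) * V)
    return StokesBScan(I=aH2 + aV2, Q=aH2 - aV2,
                       U=cross.real, V=cross.imag)


def polarization_from_stokes(stokes: StokesBScan) -> PolarizationBScan:
    """Invert the Stokes mapping back to retardation / axis.

    For averaged (partially polarized) data the retardation is taken from
    the direction of the polarized part: d = arccos(Q / |(Q,U,V)|) / 2.
    Pixels with a vanishing polarized part are flagged and set to 0.
    """
    norm = np.sqrt(stokes.Q ** 2 + stokes.U ** 2 + stokes.V ** 2)
    degenerate = norm <= 1e-300
    safe = np.where(degenerate, 1.0, norm)
    ret = 0.5 * np.degrees(np.arccos(np.clip(stokes.Q / safe, -1.0, 1.0)))
    ret[degenerate] = 0.0
    dphi = np.arctan2(stokes.V, stokes.U)
    theta = _wrap_axis((180.0 - np.degrees(dphi)) / 2.0)
    theta[degenerate] = 0.0
    return PolarizationBScan(_to_db(stokes.I), ret, theta, degenerate)


def apply_retarder(pair: ComplexBScanPair, retardation_deg: float,
                   axis_deg: float) -> ComplexBScanPair:
    """Pre-multiply both channels by a linear retarder's Jones matrix
    (used to emulate anterior-segment birefringence on rendered data)."""
    from .synthetic_data import _jones_retarder_matrix
    J = _jones_retarder_matrix(retardation_deg, axis_deg)
    return ComplexBScanPair(J[0, 0] * pair.H + J[0, 1] * pair.V,
                            J[1, 0] * pair.H + J[1, 1] * pair.V)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal SO(3) rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def compensate_anterior_segment(
    bscans: list[StokesBScan], surface_idx: np.ndarray,
    band_px: int = 3,
) -> tuple[list[StokesBScan], np.ndarray]:
    """Remove a global anterior-segment (corneal) retarder.

    Estimates the intensity-weighted mean Stokes state in a ``band_px``-pixel
    band below the retinal surface across all frames, then rotates every
    pixel's (Q, U, V) by the minimal Poincare-sphere rotation taking that
    state to the ideal zero-retarder return state (+Q).  One rotation per
    acquisition: anterior-segment birefringence varies slowly over the
    1.5 mm-radius scan circle.  A residual rotation about +Q is harmless
    because retardation depends only on the Q component.

    Returns the compensated frames and the 3x3 rotation applied.
    """
    surface_idx = np.asarray(surface_idx)
    if not bscans:
        raise ValueError("no B-scans given")
    nz, nx = bscans[0].shape
    valid_cols = (surface_idx >= 0) & (surface_idx + band_px <= nz)
    if not valid_cols.any():
        raise ValueError("surface band is empty")
    cols = np.nonzero(valid_cols)[0]
    rows = surface_idx[cols][None, :] + np.arange(band_px)[:, None]

    acc = np.zeros(3)
    for sb in bscans:
        acc[0] += sb.Q[rows, cols[None, :]].sum()
        acc[1] += sb.U[rows, cols[None, :]].sum()
        acc[2] += sb.V[rows, cols[None, :]].sum()
    if np.linalg.norm(acc) == 0:
        raise ValueError("surface band carries no polarized signal")
    rot = _rotation_between(acc, np.array([1.0, 0.0, 0.0]))

    out = []
    for sb in bscans:
        quv = np.stack([sb.Q, sb.U, sb.V])
        q, u, v = np.einsum("ij,jkl->ikl", rot, quv)
        out.append(StokesBScan(I=sb.I.copy(), Q=q, U=u, V=v))
    return out, rot


def compute_dopu(stokes: StokesBScan,
                 window: tuple[int, int] = (4, 8),
                 min_signal_factor: float = 4.0) -> np.ndarray:
    """Degree of polarization uniformity over a (depth, lateral) window.

    Per-pixel Stokes vectors are normalized by intensity, averaged over the
    window (lateral axis treated as periodic — the circular scan seam),
    and the resultant length is the DOPU, in [0, 1].

    Pixels whose intensity is at or below ``min_signal_factor`` times the
    image's lower-quartile intensity carry no polarization information
    (vitreous, sub-RPE shadow); their DOPU is set to 1 so that only true
    depolarizing tissue scores low.
    """
    wz, wx = window
    if wz < 1 or wx < 1:
        raise ValueError("window must be >= (1, 1)")
    nz, nx = stokes.shape
    if wz > nz or wx > nx:
        raise ValueError("window larger than image")

    # identify no-signal pixels; images without a dark background
    # (lower quartile comparable to the bright end) are taken as all-bright
    p25 = np.percentile(stokes.I, 25.0)
    p99 = np.percentile(stokes.I, 99.0)
    if p25 < 0.05 * p99:
        bright = stokes.I > min_signal_factor * p25
    else:
        bright = np.ones(stokes.shape, dtype=bool)

    def _filt(arr: np.ndarray) -> np.ndarray:
        out = ndimage.uniform_filter1d(arr, wz, axis=0, mode="nearest")
        return ndimage.uniform_filter1d(out, wx, axis=1, mode="wrap")

    I = np.where(stokes.I > 0, stokes.I, np.inf)
    den = _filt(bright.astype(float))
    ok = den > 0
    res = np.zeros(stokes.shape)
    for comp in (stokes.Q, stokes.U, stokes.V):
        norm = np.where(bright, comp / I, 0.0)
        sm = np.zeros(stokes.shape)
        sm[ok] = _filt(norm)[ok] / den[ok]
        res += sm ** 2
    dopu = np.clip(np.sqrt(res), 0.0, 1.0)
    dopu[~bright | ~ok] = 1.0
    return dopu
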