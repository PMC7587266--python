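"""Synthetic PS-OCT scene generation and Jones-calculus rendering.

The clinical instrument this package targets records circumpapillary
polarization-sensitive OCT scans: 100 repeats of a circular B-scan
(2048 A-scans, 1.5 mm radius around the optic nerve head) acquired with a
circularly polarized sampling beam and a two-channel polarization-sensitive
detection unit.  Raw clinical data are proprietary, so this module builds
ground-truth retinal scenes (``Phantom``) and renders them into noisy
two-channel complex B-scan sequences that the analysis pipeline consumes.

The forward model is single-pass-cumulative Jones calculus: light enters
circularly polarized, accumulates round-trip retardation
``delta(z) = dn(phi) * depth-in-RNFL`` (``dn`` in deg/um) inside the
birefringent nerve fiber layer, and is returned unchanged by the
non-birefringent inner retina and photoreceptor bands.  The retinal pigment
epithelium scrambles the polarization state.  Speckle follows circular
complex Gaussian field statistics; detector noise is additive complex
Gaussian at a configured SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanGeometry",
    "LayerStack",
    "NoiseParams",
    "Phantom",
    "GroundTruth",
    "RasterGroundTruth",
    "ComplexBScanPair",
    "PRESETS",
    "make_phantom",
    "render_circular_sequence",
    "render_raster",
]

# retinal angular-to-linear conversion used for raster scans (mm per degree
# of visual angle, emmetropic schematic eye)
MM_PER_DEG = 0.3


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of a PS-OCT scan."""

    kind: str = "circular"  # "circular" | "raster"
    n_ascans_per_bscan: int = 2048
    n_bscans: int = 100
    circle_radius_mm: float = 1.5
    axial_pitch_um: float = 2.0
    n_depth_pixels: int = 512
    wavelength_nm: float = 860.0
    raster_extent_deg: tuple[float, float] = (28.0, 21.0)

    def __post_init__(self) -> None:
        if self.kind not in ("circular", "raster"):
            raise ValueError(f"unknown scan kind {self.kind!r}")
        for name in ("n_ascans_per_bscan", "n_bscans", "n_depth_pixels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.circle_radius_mm <= 0 or self.axial_pitch_um <= 0:
            raise ValueError("circle_radius_mm and axial_pitch_um must be > 0")

    @classmethod
    def circular(cls, **kw) -> "ScanGeometry":
        return cls(kind="circular", **kw)

    @classmethod
    def raster(cls, **kw) -> "ScanGeometry":
        kw.setdefault("n_ascans_per_bscan", 1024)
        kw.setdefault("n_bscans", 250)
        return cls(kind="raster", **kw)

    def um_to_px(self, um: float) -> int:
        return int(round(um / self.axial_pitch_um))

    def scan_angles_deg(self) -> np.ndarray:
        n = self.n_ascans_per_bscan
        return np.arange(n) * (360.0 / n)


@dataclass(frozen=True)
class LayerStack:
    """Axial layout of the simulated retina (absolute depths in um).

    Order from the top of the image: vitreous (empty), RNFL starting at the
    inner limiting membrane, non-birefringent inner retina, two bright
    photoreceptor bands (IS/OS junction and outer segment tips) sitting
    above the depolarizing RPE band.
    """

    ilm_um: float = 120.0
    rpe_top_um: float = 420.0
    rpe_thickness_um: float = 12.0
    # (offset of band top above rpe_top in um, band thickness um, reflectivity)
    pr_bands: tuple[tuple[float, float, float], ...] = (
        (50.0, 8.0, 1.6),
        (26.0, 6.0, 1.3),
    )
    rnfl_reflectivity: float = 1.0
    inner_reflectivity: float = 0.12
    rpe_reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.ilm_um < self.rpe_top_um):
            raise ValueError("layer depths must increase: ilm < rpe_top")
        for off, thick, _ in self.pr_bands:
            if off <= 0 or thick <= 0 or off > self.rpe_top_um:
                raise ValueError("photoreceptor band outside the retina")


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic acquisition model.

    ``snr_db`` is the detector signal-to-noise ratio at the ILM (RNFL
    reflectivity 1.0); ``None`` disables detector noise.  Corrupted repeats
    model tracking failures as a 70% intensity dropout plus a 30-pixel
    axial shift, which guarantees low correlation to clean frames.  A
    corneal (anterior segment) retarder can be placed in front of the
    retina to exercise the compensation stage.
    """

    speckle: bool = True
    snr_db: float | None = 30.0
    jitter_sd_px: float = 2.0
    corrupted_fraction: float = 0.05
    corneal_retardation_deg: float = 0.0
    corneal_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.corrupted_fraction < 1.0):
            raise ValueError("corrupted_fraction must be in [0, 1)")

    @classmethod
    def quiet(cls) -> "NoiseParams":
        """All stochastic terms disabled (analytic test scenes)."""
        return cls(speckle=False, snr_db=None, jitter_sd_px=0.0,
                   corrupted_fraction=0.0)


@dataclass(frozen=True)
class Phantom:
    """Ground-truth circumpapillary scene.

    Angular profiles are sampled on a uniform grid of ``n_phi`` angles in
    TSNIT order (phi = 0 deg temporal, increasing T -> S -> N -> I) and
    interpolated periodically at render time.
    """

    thickness_um: np.ndarray
    biref_deg_per_um: np.ndarray
    axis_deg: np.ndarray
    layers: LayerStack = LayerStack()
    vessels: tuple[tuple[float, float], ...] = ()
    defects: tuple[tuple[float, float, float], ...] = ()
    noise: NoiseParams = NoiseParams()
    eye: str = "OD"
    onh_radius_mm: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thickness_um", "biref_deg_per_um", "axis_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.thickness_um.shape != self.biref_deg_per_um.shape or \
                self.thickness_um.shape != self.axis_deg.shape:
            raise ValueError("profile arrays must share one angular grid")
        if np.any(self.thickness_um < 0):
            raise ValueError("thickness_um must be >= 0 everywhere")
        if np.any(self.biref_deg_per_um < 0):
            raise ValueError("biref_deg_per_um must be >= 0 everywhere")
        if self.eye not in ("OD", "OS"):
            raise ValueError("eye must be 'OD' or 'OS'")

    @property
    def n_phi(self) -> int:
        return self.thickness_um.size

    @property
    def phi_deg(self) -> np.ndarray:
        return np.arange(self.n_phi) * (360.0 / self.n_phi)

    def _interp(self, values: np.ndarray, phi: np.ndarray) -> np.ndarray:
        grid = self.phi_deg
        return np.interp(np.mod(phi, 360.0), np.append(grid, 360.0),
                         np.append(values, values[0]))

    def sample(self, phi_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolate (thickness, birefringence, axis) at scan angles.

        Left eyes (OS) are mirrored laterally, which swaps the temporal and
        nasal halves while keeping superior/inferior in place.
        """
        phi = np.asarray(phi_deg, dtype=float)
        if self.eye == "OS":
            phi = np.mod(180.0 - phi, 360.0)
        return (self._interp(self.thickness_um, phi),
                self._interp(self.biref_deg_per_um, phi),
                self._interp(self.axis_deg, phi))

    def vessel_mask(self, phi_deg: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi_deg, dtype=float)
        if self.eye == "OS":
            phi = np.mod(180.0 - phi, 360.0)
        mask = np.zeros(phi.shape, dtype=bool)
        for center, width in self.vessels:
            d = np.abs((phi - center + 180.0) % 360.0 - 180.0)
            mask |= d <= width / 2.0
        return mask


@dataclass
class GroundTruth:
    """Noise-free truth for a rendered circular sequence (recovery oracle)."""

    ilm_idx: np.ndarray
    rnfl_lower_idx: np.ndarray
    rpe_top_idx: np.ndarray
    rpe_bottom_idx: np.ndarray
    vessel_mask: np.ndarray
    thickness_um: np.ndarray          # true, unquantized
    biref_deg_per_um: np.ndarray
    axis_deg: np.ndarray
    corrupted: np.ndarray             # bool per repeat
    shifts: np.ndarray                # (n_repeats, 2) applied (axial, lateral)

    def __post_init__(self) -> None:
        ok = (self.ilm_idx <= self.rnfl_lower_idx) & \
             (self.rnfl_lower_idx <= self.rpe_top_idx)
        if not np.all(ok):
            raise ValueError("boundary indices must be ordered ILM <= RNFL-lower <= RPE")


@dataclass
class RasterGroundTruth:
    thickness_um: np.ndarray          # (ny, nx)
    biref_deg_per_um: np.ndarray      # (ny, nx)
    onh_mask: np.ndarray              # (ny, nx) True inside the disc
    vessel_mask: np.ndarray           # (ny, nx)
    ilm_idx: int
    rpe_top_idx: int


@dataclass
class ComplexBScanPair:
    """Co-registered two-channel complex B-scan (depth x lateral)."""

    H: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        if self.H.shape != self.V.shape:
            raise ValueError("H and V must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape


# ---------------------------------------------------------------------------
# phantom presets

def _angular_dist(phi: np.ndarray, center: float) -> np.ndarray:
    return np.abs((phi - center + 180.0) % 360.0 - 180.0)


def _double_hump(phi: np.ndarray, base: float, amp_sup: float,
                 amp_inf: float, sigma_deg: float = 40.0) -> np.ndarray:
    out = base + amp_sup * np.exp(-0.5 * (_angular_dist(phi, 90.0) / sigma_deg) ** 2)
    out = out + amp_inf * np.exp(-0.5 * (_angular_dist(phi, 270.0) / sigma_deg) ** 2)
    return out


def _superior_inferior_mask(phi: np.ndarray) -> np.ndarray:
    """The superior + inferior 180 degrees (quadrants centered at 90/270)."""
    return (_angular_dist(phi, 90.0) < 45.0) | (_angular_dist(phi, 270.0) < 45.0)


def _biref_profile(phi: np.ndarray, level: float) -> np.ndarray:
    """Angular birefringence: low temporally/nasally, high superior/inferior.

    Scaled so that the mean over the superior+inferior half equals ``level``
    exactly (the group preset value).
    """
    low = 0.6 * level
    hump = _double_hump(phi, 0.0, 1.0, 1.0, sigma_deg=45.0)
    si = _superior_inferior_mask(phi)
    scale = (level - low) / hump[si].mean()
    return low + scale * hump


# preset: (superior+inferior mean birefringence, between-subject SD,
#          thickness base, superior amp, inferior amp)
PRESETS: dict[str, dict] = {
    "healthy": dict(biref_level=0.135, biref_sd=0.007, n_subjects=7,
                    thick_base=70.0, amp_sup=80.0, amp_inf=85.0, defects=()),
    "diabetic": dict(biref_level=0.103, biref_sd=0.015, n_subjects=7,
                     thick_base=70.0, amp_sup=78.0, amp_inf=82.0, defects=()),
    "glaucoma": dict(biref_level=0.129, biref_sd=0.013, n_subjects=6,
                     thick_base=68.0, amp_sup=60.0, amp_inf=62.0,
                     # two localized RNFL holes in the superior quadrant
                     defects=((80.0, 5.0, 0.5), (100.0, 5.0, 0.5))),
    "flat": dict(biref_level=0.135, biref_sd=0.0, n_subjects=0,
                 thick_base=125.0, amp_sup=0.0, amp_inf=0.0, defects=()),
}

_DEFAULT_VESSEL_ANGLES = (25.0, 62.0, 108.0, 150.0, 205.0, 245.0, 288.0, 330.0)


def make_phantom(preset: str, overrides: dict | None = None,
                 seed: int = 0, n_phi: int = 2048) -> Phantom:
    """Build a ground-truth scene from a named group preset.

    Presets carry the group mean superior/inferior birefringence levels of
    the cohorts this package emulates (healthy 0.135, diabetic 0.103,
    glaucoma 0.129 deg/um).  ``flat`` is a constant analytic test scene.
    ``overrides`` replaces Phantom fields after construction; scalar values
    for the profile fields are broadcast to constant profiles.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}")
    p = PRESETS[preset]
    overrides = dict(overrides or {})
    rng = np.random.default_rng(seed)
    phi = np.arange(n_phi) * (360.0 / n_phi)

    level = overrides.pop("biref_level", p["biref_level"])
    if preset == "flat":
        thickness = np.full(n_phi, p["thick_base"])
        biref = np.full(n_phi, level)
        vessels: tuple = ()
    else:
        thickness = _double_hump(phi, p["thick_base"], p["amp_sup"], p["amp_inf"])
        biref = _biref_profile(phi, level)
        vessels = tuple(
            (float((a + rng.uniform(-8.0, 8.0)) % 360.0),
             float(rng.uniform(4.0, 9.0)))
            for a in _DEFAULT_VESSEL_ANGLES)

    defects = tuple(p["defects"])
    for center, width, drop in defects:
        hole = _angular_dist(phi, center) <= width / 2.0
        thickness = np.where(hole, thickness * (1.0 - drop), thickness)

    axis = np.mod(phi / 2.0, 180.0) - 90.0

    fields = dict(thickness_um=thickness, biref_deg_per_um=biref,
                  axis_deg=axis, vessels=vessels, defects=defects, seed=seed)
    # broadcast scalar overrides of the profile fields
    for key in ("thickness_um", "biref_deg_per_um", "axis_deg"):
        if key in overrides and np.isscalar(overrides[key]):
            overrides[key] = np.full(n_phi, float(overrides[key]))
    fields.update(overrides)
    return Phantom(**fields)


# ---------------------------------------------------------------------------
# rendering

def _jones_retarder_matrix(ret_deg: float, axis_deg: float) -> np.ndarray:
    """Jones matrix of a linear retarder (retardance in degrees)."""
    d = np.deg2rad(ret_deg)
    t = np.deg2rad(axis_deg)
    c, s = np.cos(t), np.sin(t)
    rot = np.array([[c, -s], [s, c]])
    core = np.diag([np.exp(-1j * d / 2.0), np.exp(1j * d / 2.0)])
    return rot @ core @ rot.T.conj()


def _scene_arrays(phantom: Phantom, geometry: ScanGeometry,
                  phi_deg: np.ndarray, rng_scramble: np.random.Generator,
                  thickness: np.ndarray | None = None,
                  no_retina: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build the noise-free complex channel images for one B-scan.

    Returns (H, V, info) where info carries the ground-truth indices.
    """
    pitch = geometry.axial_pitch_um
    nz = geometry.n_depth_pixels
    nx = len(phi_deg)
    layers = phantom.layers

    th, dn, ax = phantom.sample(phi_deg)
    if thickness is not None:
        th = thickness
    vessels = phantom.vessel_mask(phi_deg)
    if no_retina is not None:
        th = np.where(no_retina, 0.0, th)
        vessels = vessels & ~no_retina

    ilm_idx = int(round(layers.ilm_um / pitch))
    rpe_top = int(round(layers.rpe_top_um / pitch))
    rpe_bot = rpe_top + max(1, int(round(layers.rpe_thickness_um / pitch)))
    n_rnfl_px = np.ceil(th / pitch - 1e-9).astype(int)
    lower_idx = ilm_idx + n_rnfl_px
    if np.any(lower_idx >= nz):
        raise ValueError("RNFL thicker than the axial depth range")
    if rpe_bot > nz:
        raise ValueError("RPE below the axial depth range")

    z = np.arange(nz)[:, None]
    in_rnfl = (z >= ilm_idx) & (z < lower_idx[None, :])
    in_inner = (z >= lower_idx[None, :]) & (z < rpe_top)
    in_rpe = np.broadcast_to((z >= rpe_top) & (z < rpe_bot), (nz, nx))

    refl = np.zeros((nz, nx))
    refl[in_rnfl] = layers.rnfl_reflectivity
    refl[in_inner] = layers.inner_reflectivity
    for off, bthick, br in layers.pr_bands:
        b_top = rpe_top - int(round(off / pitch))
        b_bot = b_top + max(1, int(round(bthick / pitch)))
        band = (z >= b_top) & (z < b_bot) & ~in_rnfl
        refl[band] = br
    refl[in_rpe] = layers.rpe_reflectivity
    if no_retina is not None:
        refl[:, no_retina] = 0.0
        refl[in_rpe & no_retina[None, :]] = layers.rpe_reflectivity

    # vessel shadows attenuate everything below the vessel
    shadow_rows = z >= ilm_idx + 5
    refl = np.where(shadow_rows & vessels[None, :], refl * 0.08, refl)

    # cumulative round-trip retardation, measured at the bottom edge of each
    # pixel and clamped at dn*d below the RNFL (non-birefringent layers)
    depth_um = np.clip((z - ilm_idx + 1) * pitch, 0.0, None)
    delta_deg = dn[None, :] * np.minimum(depth_um, th[None, :])
    delta = np.deg2rad(delta_deg)

    theta = np.deg2rad(ax)[None, :]
    amp = np.sqrt(refl)
    H = amp * np.cos(delta)
    V = amp * np.sin(delta) * np.exp(1j * (np.pi - 2.0 * theta))
    H = H.astype(complex)

    # RPE scrambling: per-pixel uniform random pure state at full intensity
    rpe_mask = in_rpe & (refl > 0)
    n_rpe = int(rpe_mask.sum())
    if n_rpe:
        cos_psi = rng_scramble.uniform(-1.0, 1.0, n_rpe)
        chi = 0.5 * np.arccos(cos_psi)
        beta = rng_scramble.uniform(0.0, 2.0 * np.pi, n_rpe)
        a = amp[rpe_mask]
        H[rpe_mask] = a * np.cos(chi)
        V[rpe_mask] = a * np.sin(chi) * np.exp(1j * beta)

    info = dict(ilm_idx=np.full(nx, ilm_idx), rnfl_lower_idx=lower_idx,
                rpe_top_idx=np.full(nx, rpe_top),
                rpe_bottom_idx=np.full(nx, rpe_bot),
                vessel_mask=vessels, thickness_um=th,
                biref_deg_per_um=dn, axis_deg=ax)
    return H, V, info


def _apply_corneal(H: np.ndarray, V: np.ndarray,
                   noise: NoiseParams) -> tuple[np.ndarray, np.ndarray]:
    if noise.corneal_retardation_deg == 0.0:
        return H, V
    J = _jones_retarder_matrix(noise.corneal_retardation_deg,
                               noise.corneal_axis_deg)
    return J[0, 0] * H + J[0, 1] * V, J[1, 0] * H + J[1, 1] * V


def _axial_roll(arr: np.ndarray, shift: int) -> np.ndarray:
    """Roll along depth with zero fill (no wrap-around of tissue)."""
    out = np.roll(arr, shift, axis=0)
    if shift > 0:
        out[:shift, :] = 0
    elif shift < 0:
        out[shift:, :] = 0
    return out


def render_circular_sequence(
    phantom: Phantom, geometry: ScanGeometry, seed: int = 0,
) -> tuple[list[ComplexBScanPair], GroundTruth]:
    """Render the repeated circular scan protocol.

    Each of ``geometry.n_bscans`` repeats shares the same noise-free scene;
    speckle, detector noise, integer axial/lateral jitter, and occasional
    corrupted frames (intensity dropout + large axial shift) are drawn
    per repeat.  Deterministic in (phantom, geometry, seed).
    """
    if geometry.kind != "circular":
        raise ValueError("geometry.kind must be 'circular'")
    noise = phantom.noise
    ss = np.random.SeedSequence([seed, phantom.seed, 0x5C0C])
    rng_scene, rng_corr, rng_rep = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]

    phi = geometry.scan_angles_deg()
    H0, V0, info = _scene_arrays(phantom, geometry, phi, rng_scene)
    H0, V0 = _apply_corneal(H0, V0, noise)

    n_rep = geometry.n_bscans
    n_corr = int(round(noise.corrupted_fraction * n_rep))
    corrupted = np.zeros(n_rep, dtype=bool)
    if n_corr:
        corrupted[rng_corr.choice(n_rep, size=n_corr, replace=False)] = True

    sigma2 = 0.0
    if noise.snr_db is not None:
        sigma2 = 10.0 ** (-noise.snr_db / 10.0)  # per-channel noise power

    pairs: list[ComplexBScanPair] = []
    shifts = np.zeros((n_rep, 2), dtype=int)
    for r in range(n_rep):
        H, V = H0, V0
        if noise.speckle:
            g = (rng_rep.standard_normal(H.shape)
                 + 1j * rng_rep.standard_normal(H.shape)) / np.sqrt(2.0)
            H, V = H * g, V * g
        if noise.jitter_sd_px > 0:
            ax_sh = int(round(rng_rep.normal(0.0, noise.jitter_sd_px)))
            lat_sh = int(round(rng_rep.normal(0.0, noise.jitter_sd_px)))
        else:
            ax_sh = lat_sh = 0
        if corrupted[r]:
            # dropout hits the signal only; detector noise is unchanged
            H, V = H * np.sqrt(0.3), V * np.sqrt(0.3)
            ax_sh += 30
        if ax_sh:
            H, V = _axial_roll(H, ax_sh), _axial_roll(V, ax_sh)
        if lat_sh:
            H, V = np.roll(H, lat_sh, axis=1), np.roll(V, lat_sh, axis=1)
        if sigma2 > 0:
            s = np.sqrt(sigma2 / 2.0)
            H = H + s * (rng_rep.standard_normal(H.shape)
                         + 1j * rng_rep.standard_normal(H.shape))
            V = V + s * (rng_rep.standard_normal(V.shape)
                         + 1j * rng_rep.standard_normal(V.shape))
        shifts[r] = (ax_sh, lat_sh)
        pairs.append(ComplexBScanPair(np.ascontiguousarray(H),
                                      np.ascontiguousarray(V)))

    gt = GroundTruth(corrupted=corrupted, shifts=shifts, **info)
    return pairs, gt


def render_raster(
    phantom: Phantom, geometry: ScanGeometry, seed: int = 0,
) -> tuple[list[ComplexBScanPair], RasterGroundTruth]:
    """Render a single-repeat raster volume centered on the optic nerve head.

    The ONH is modeled as an RNFL-free disc of ``phantom.onh_radius_mm``;
    outside the disc the scene at image position (x, y) is the
    circumpapillary profile evaluated at the polar angle of (x, y).  Used
    for en-face map demonstrations only.
    """
    if geometry.kind != "raster":
        raise ValueError("geometry.kind must be 'raster'")
    noise = phantom.noise
    ss = np.random.SeedSequence([seed, phantom.seed, 0x7A57])
    rng_scene, rng_rep = [np.random.default_rng(s) for s in ss.spawn(2)]

    nx, ny = geometry.n_ascans_per_bscan, geometry.n_bscans
    ex, ey = geometry.raster_extent_deg
    x_mm = (np.arange(nx) - (nx - 1) / 2.0) * (ex * MM_PER_DEG / nx)
    y_mm = (np.arange(ny) - (ny - 1) / 2.0) * (ey * MM_PER_DEG / ny)

    sigma2 = 0.0
    if noise.snr_db is not None:
        sigma2 = 10.0 ** (-noise.snr_db / 10.0)

    pairs: list[ComplexBScanPair] = []
    thick_map = np.zeros((ny, nx))
    biref_map = np.zeros((ny, nx))
    onh_map = np.zeros((ny, nx), dtype=bool)
    vessel_map = np.zeros((ny, nx), dtype=bool)
    ilm_idx = rpe_idx = 0
    for j, y in enumerate(y_mm):
        r = np.hypot(x_mm, y)
        phi = np.mod(np.degrees(np.arctan2(y, x_mm)), 360.0)
        inside = r < phantom.onh_radius_mm
        H, V, info = _scene_arrays(phantom, geometry, phi, rng_scene,
                                   no_retina=inside)
        H, V = _apply_corneal(H, V, noise)
        if noise.speckle:
            g = (rng_rep.standard_normal(H.shape)
                 + 1j * rng_rep.standard_normal(H.shape)) / np.sqrt(2.0)
            H, V = H * g, V * g
        if sigma2 > 0:
            s = np.sqrt(sigma2 / 2.0)
            H = H + s * (rng_rep.standard_normal(H.shape)
                         + 1j * rng_rep.standard_normal(H.shape))
            V = V + s * (rng_rep.standard_normal(V.shape)
                         + 1j * rng_rep.standard_normal(V.shape))
        pairs.append(ComplexBScanPair(np.ascontiguousarray(H),
                                      np.ascontiguousarray(V)))
        thick_map[j] = info["thickness_um"]
        biref_map[j] = info["biref_deg_per_um"]
        onh_map[j] = inside
        vessel_map[j] = info["vessel_mask"]
        ilm_idx = int(info["ilm_idx"][0])
        rpe_idx = int(info["rpe_top_idx"][0])

    gt = RasterGroundTruth(thickness_um=thick_map, biref_deg_per_um=biref_map,
                           onh_mask=onh_map, vessel_mask=vessel_map,
                           ilm_idx=ilm_idx, rpe_top_idx=rpe_idx)
    return pairs, gt
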