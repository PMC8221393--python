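"""Synthetic 4D light-sheet-like beating zebrafish heart phantom.

The phantom emulates a tg(cmlc2:gfp) acquisition: a bright myocardial shell
surrounding a dark two-chamber lumen (atrium + ventricle joined by the
atrioventricular canal), imaged as axial z-stacks at 2 μm pitch over one
cardiac cycle sampled at N evenly spaced phases.

Each chamber is an axis-aligned ellipsoid whose axial (z) semi-axis is
modulated sinusoidally in time, so the chamber volume follows

    V(t) = (4/3) π a b c̄ (1 + α sin(2πt/T + φ)),

which gives exact closed-form oracles for EDV, ESV, SV and EF. Atrium and
ventricle contract in counter-phase (φ_A − φ_V = π). Trabeculation — the
sponge-like ridges on the inner ventricular wall that appear around 3–5 dpf —
is modeled as a multiplicative radial perturbation of the ellipsoid surface
with a fixed number of angular lobes; the multiplicative form inflates all
phases of the volume trace by the same exact factor (1 + 3ε²/2), so ejection
fraction is unaffected.

Ground-truth chamber maps are voxelizations of the implicit surfaces (a voxel
belongs to the lumen iff its center lies inside), making voxel-counted
volumes converge to the closed forms as the pitch shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .containers import CineSequence, ChamberMap, Volume3D

__all__ = [
    "ChamberGeom",
    "PhantomParams",
    "preset",
    "analytic_chamber_volume",
    "make_truth",
    "render_frame",
    "make_cine",
    "training_slice",
    "training_slices",
]

TWO_PI = 2.0 * math.pi


@dataclass
class ChamberGeom:
    """Geometry and contraction recipe for one chamber.

    Parameters
    ----------
    center
        Chamber center (z, y, x) in μm.
    semi_axes
        Mean semi-axes (c̄_z, b_y, a_x) in μm; the first (axial) entry is the
        modulated axis.
    alpha
        Dimensionless volume-modulation amplitude, 0 ≤ α < 1.
    phase_offset
        Contraction phase φ in radians.
    trabeculation_amplitude
        Radial roughness amplitude in μm (0 for the smooth atrium).
    trabeculation_lobes
        Number of angular lobes of the roughness pattern.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    alpha: float = 0.0
    phase_offset: float = 0.0
    trabeculation_amplitude: float = 0.0
    trabeculation_lobes: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must satisfy 0 <= alpha < 1")
        if self.trabeculation_amplitude < 0 or self.trabeculation_lobes < 0:
            raise ValueError("trabeculation parameters must be non-negative")
        if self.trabeculation_amplitude >= min(self.semi_axes) / 2:
            raise ValueError("trabeculation amplitude must be < min(semi-axes)/2")

    @property
    def mean_volume(self) -> float:
        """Time-averaged smooth-ellipsoid volume (4/3)π a b c̄ in μm³."""
        return 4.0 / 3.0 * math.pi * float(np.prod(self.semi_axes))

    @property
    def trabeculation_eps(self) -> float:
        """Normalized roughness amplitude ε = amplitude / geometric-mean radius."""
        r_gm = float(np.prod(self.semi_axes)) ** (1.0 / 3.0)
        return self.trabeculation_amplitude / r_gm

    def axial_semi_axis(self, t: float, period: float) -> float:
        """Modulated axial semi-axis c(t) = c̄ (1 + α sin(2πt/T + φ))."""
        return self.semi_axes[0] * (
            1.0 + self.alpha * math.sin(TWO_PI * t / period + self.phase_offset)
        )


@dataclass
class PhantomParams:
    """Full recipe for one synthetic 4D acquisition."""

    atrium: ChamberGeom
    ventricle: ChamberGeom
    canal_radius: float = 8.0  # μm
    wall_thickness: float = 8.0  # μm, myocardial shell
    period: float = 400.0  # ms
    frames_per_cycle: int = 20
    grid_shape: tuple[int, int, int] = (96, 160, 160)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    attenuation_depth: float = 300.0  # μm, 1/e depth of the z attenuation
    noise_sigma: float = 0.08  # fraction of shell intensity
    dpf_preset: int | None = None

    def __post_init__(self) -> None:
        if self.frames_per_cycle < 2:
            raise ValueError("frames_per_cycle must be >= 2 to represent a cycle")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.canal_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("canal_radius and wall_thickness must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        self._check_margins()

    def _check_margins(self) -> None:
        # chambers + shell must fit inside the grid with >= wall + 2 voxels slack
        extent = np.asarray(self.grid_shape, float) * np.asarray(self.voxel_spacing)
        for geom in (self.atrium, self.ventricle):
            semi = np.asarray(geom.semi_axes, float).copy()
            semi[0] *= 1.0 + geom.alpha  # worst phase
            semi += geom.trabeculation_amplitude
            need = (
                semi
                + self.wall_thickness
                + self.wall_thickness  # required margin
                + 2.0 * np.asarray(self.voxel_spacing)
            )
            lo = np.asarray(geom.center) - need
            hi = np.asarray(geom.center) + need
            if np.any(lo < 0) or np.any(hi > extent):
                raise ValueError(
                    f"chamber at {geom.center} does not fit in the grid with the "
                    f"required margin (grid extent {tuple(extent)} μm)"
                )

    @property
    def frame_interval(self) -> float:
        """Time between consecutive phases in ms."""
        return self.period / self.frames_per_cycle

    def frame_time(self, frame_index: int) -> float:
        """Acquisition time t_k = k T / N of phase ``frame_index`` in ms."""
        if not 0 <= frame_index < self.frames_per_cycle:
            raise ValueError(
                f"frame_index {frame_index} outside [0, {self.frames_per_cycle})"
            )
        return frame_index * self.frame_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        for key in ("atrium", "ventricle"):
            g = dict(d[key])
            g["center"] = tuple(g["center"])
            g["semi_axes"] = tuple(g["semi_axes"])
            d[key] = ChamberGeom(**g)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_spacing"] = tuple(d["voxel_spacing"])
        return cls(**d)


# ---------------------------------------------------------------------------
# presets

#: per-dpf scale of all semi-axes relative to 4 dpf
_DPF_SIZE_SCALE = {2: 0.75, 3: 0.90, 4: 1.00, 5: 1.05}
#: per-dpf scale of the ventricular trabeculation amplitude relative to 4 dpf
_DPF_TRAB_SCALE = {2: 0.0, 3: 0.5, 4: 1.0, 5: 1.25}

# 4-dpf calibration: total mean lumen ≈ 9.5e5 μm³ with the ventricle the
# larger chamber, atrial SV ≈ 3.6e5 μm³ with α_A = 3/7, EF_V = 40% with
# α_V = 1/4. Semi-axes in (z, y, x) order.
_V4_SEMI = (36.5, 55.0, 63.0)
_A4_SEMI = (35.2, 50.0, 57.0)
_ALPHA_V = 0.25
_ALPHA_A = 3.0 / 7.0
# φ_A − φ_V = π (counter-phase); ±π/2 so that N = 20 even samples hit the
# extrema exactly (sin = ±1 at k = 0 and k = N/2).
_PHI_V = -math.pi / 2.0
_PHI_A = +math.pi / 2.0
_TRAB_AMP_4DPF = 4.0  # μm
_TRAB_LOBES = 8
_PHYS_EXTENT = (192.0, 320.0, 320.0)  # μm, default field of view
_CENTER_Z = 96.0
_CENTER_X = 160.0
_CENTER_Y_V = 105.0
_CENTER_Y_A = 235.0


def preset(
    dpf: int = 4,
    *,
    pitch: float = 2.0,
    frames: int = 20,
    noise_sigma: float = 0.08,
) -> PhantomParams:
    """Build the default phantom recipe for a developmental day.

    Parameters
    ----------
    dpf
        Days postfertilization, one of {2, 3, 4, 5}. Sizes scale with age and
        the ventricular wall roughens as trabeculation develops.
    pitch
        Isotropic voxel pitch in μm. 2 μm matches the axial slice thickness
        of the emulated acquisitions; 4 μm is the fast profile.
    frames
        Phases per cardiac cycle (default 20 evenly spaced samples).
    """
    if dpf not in _DPF_SIZE_SCALE:
        raise ValueError(f"dpf preset must be one of {sorted(_DPF_SIZE_SCALE)}")
    s = _DPF_SIZE_SCALE[dpf]
    trab = _TRAB_AMP_4DPF * _DPF_TRAB_SCALE[dpf]
    ventricle = ChamberGeom(
        center=(_CENTER_Z, _CENTER_Y_V, _CENTER_X),
        semi_axes=tuple(s * a for a in _V4_SEMI),
        alpha=_ALPHA_V,
        phase_offset=_PHI_V,
        trabeculation_amplitude=trab,
        trabeculation_lobes=_TRAB_LOBES if trab > 0 else 0,
    )
    atrium = ChamberGeom(
        center=(_CENTER_Z, _CENTER_Y_A, _CENTER_X),
        semi_axes=tuple(s * a for a in _A4_SEMI),
        alpha=_ALPHA_A,
        phase_offset=_PHI_A,
    )
    grid_shape = tuple(int(round(e / pitch)) for e in _PHYS_EXTENT)
    return PhantomParams(
        atrium=atrium,
        ventricle=ventricle,
        canal_radius=8.0 * s,
        period=400.0,
        frames_per_cycle=frames,
        grid_shape=grid_shape,
        voxel_spacing=(pitch, pitch, pitch),
        noise_sigma=noise_sigma,
        dpf_preset=dpf,
    )


# ---------------------------------------------------------------------------
# closed-form oracle


def analytic_chamber_volume(
    geom: ChamberGeom,
    t: float,
    period: float,
    *,
    include_trabeculation: bool = False,
) -> float:
    """Closed-form chamber volume at time ``t`` (μm³).

    Implements V(t) = (4/3)π a b c̄ (1 + α sin(2πt/T + φ)). The time average
    over one full cycle equals the mean-geometry volume exactly.

    With ``include_trabeculation`` the exact roughness inflation factor
    (1 + 3ε²/2) is applied (the azimuthal average of (1 + ε sin Lθ)³), which
    is what voxel counts of the perturbed surface converge to.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    v = geom.mean_volume * (
        1.0 + geom.alpha * math.sin(TWO_PI * t / period + geom.phase_offset)
    )
    if include_trabeculation and geom.trabeculation_lobes > 0:
        v *= 1.0 + 1.5 * geom.trabeculation_eps**2
    return v


# ---------------------------------------------------------------------------
# implicit geometry evaluation


def _inside_chamber(geom, t, period, Z, Y, X, *, grow=0.0):
    """Boolean field: points inside the (perturbed) chamber surface at time t.

    ``grow`` expands every semi-axis by a fixed physical amount (used for the
    outer myocardial surface).
    """
    cz, cy, cx = geom.center
    az = geom.axial_semi_axis(t, period) + grow
    ay = geom.semi_axes[1] + grow
    ax = geom.semi_axes[2] + grow
    dz = (Z - cz) / az
    dy = (Y - cy) / ay
    dx = (X - cx) / ax
    rho2 = dz * dz + dy * dy + dx * dx
    if geom.trabeculation_lobes > 0 and geom.trabeculation_amplitude > 0:
        theta = np.arctan2(Y - cy, X - cx)
        bound = 1.0 + geom.trabeculation_eps * np.sin(geom.trabeculation_lobes * theta)
        return rho2 <= bound * bound
    return rho2 <= 1.0


def _rho(geom, t, period, Z, Y, X):
    """Normalized ellipsoid coordinate (1 on the smooth surface)."""
    cz, cy, cx = geom.center
    az = geom.axial_semi_axis(t, period)
    dz = (Z - cz) / az
    dy = (Y - cy) / geom.semi_axes[1]
    dx = (X - cx) / geom.semi_axes[2]
    return np.sqrt(dz * dz + dy * dy + dx * dx)


def _inside_canal(params, Z, Y, X, *, grow=0.0):
    """Cylinder of radius canal_radius around the segment joining the centers."""
    p0 = np.asarray(params.ventricle.center, float)
    p1 = np.asarray(params.atrium.center, float)
    axis = p1 - p0
    length2 = float(axis @ axis)
    # projection parameter of each point onto the segment, clipped to [0, 1]
    s = ((Z - p0[0]) * axis[0] + (Y - p0[1]) * axis[1] + (X - p0[2]) * axis[2]) / length2
    s = np.clip(s, 0.0, 1.0)
    dz = Z - (p0[0] + s * axis[0])
    dy = Y - (p0[1] + s * axis[1])
    dx = X - (p0[2] + s * axis[2])
    r = params.canal_radius + grow
    return dz * dz + dy * dy + dx * dx <= r * r


def _voxel_centers(grid_shape, spacing):
    # voxel i center at (i + 1/2) * pitch, so the grid spans [0, n*pitch]
    zs = (np.arange(grid_shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(grid_shape[1]) + 0.5) * spacing[1]
    xs = (np.arange(grid_shape[2]) + 0.5) * spacing[2]
    return np.meshgrid(zs, ys, xs, indexing="ij", sparse=True)


# ---------------------------------------------------------------------------
# ground truth and rendering


def make_truth(params: PhantomParams, frame_index: int) -> ChamberMap:
    """Voxelize the ground-truth chamber map for one phase.

    A voxel is labeled atrium/ventricle iff its center lies inside that
    chamber's (trabeculation-perturbed) inner surface at that phase; canal
    voxels outside both ellipsoids are assigned to the chamber whose
    normalized ellipsoid coordinate is smaller (the nearer chamber).
    """
    t = params.frame_time(frame_index)
    Z, Y, X = _voxel_centers(params.grid_shape, params.voxel_spacing)
    in_v = _inside_chamber(params.ventricle, t, params.period, Z, Y, X)
    in_a = _inside_chamber(params.atrium, t, params.period, Z, Y, X)
    labels = np.zeros(params.grid_shape, dtype=np.uint8)
    labels[in_a] = 1
    labels[in_v] = 2  # ventricle wins the (empty by construction) overlap
    canal_only = _inside_canal(params, Z, Y, X) & ~in_a & ~in_v
    if np.any(canal_only):
        rho_a = _rho(params.atrium, t, params.period, Z, Y, X)
        rho_v = _rho(params.ventricle, t, params.period, Z, Y, X)
        nearer_atrium = rho_a <= rho_v
        labels[canal_only & nearer_atrium] = 1
        labels[canal_only & ~nearer_atrium] = 2
    return ChamberMap(labels, params.voxel_spacing)


_SHELL_INTENSITY = 1.0
_DARK_INTENSITY = 0.04
_PSF_SIGMA_VOX = 1.0


def _noiseless_field(params, t, Z, Y, X):
    """Shell/lumen/background intensity field before blur and noise."""
    lumen = (
        _inside_chamber(params.ventricle, t, params.period, Z, Y, X)
        | _inside_chamber(params.atrium, t, params.period, Z, Y, X)
        | _inside_canal(params, Z, Y, X)
    )
    w = params.wall_thickness
    outer = (
        _inside_chamber(params.ventricle, t, params.period, Z, Y, X, grow=w)
        | _inside_chamber(params.atrium, t, params.period, Z, Y, X, grow=w)
        | _inside_canal(params, Z, Y, X, grow=w)
    )
    shell = outer & ~lumen
    img = np.full(shell.shape, _DARK_INTENSITY, dtype=np.float32)
    img[shell] = _SHELL_INTENSITY
    return img


def render_frame(
    params: PhantomParams,
    frame_index: int,
    seed: int | None = 0,
) -> Volume3D:
    """Render one 3D frame with LSFM-like appearance.

    Bright myocardial shell of ``wall_thickness`` around the lumen, dark lumen
    and background, depth-dependent attenuation exp(−z/attenuation_depth),
    ~1-voxel Gaussian PSF blur, additive Gaussian noise, 8-bit output.
    """
    t = params.frame_time(frame_index)
    Z, Y, X = _voxel_centers(params.grid_shape, params.voxel_spacing)
    img = _noiseless_field(params, t, Z, Y, X)
    if np.isfinite(params.attenuation_depth):
        img = img * np.exp(-Z / params.attenuation_depth).astype(np.float32)
    img = ndimage.gaussian_filter(img, sigma=_PSF_SIGMA_VOX)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(
            0.0, params.noise_sigma * _SHELL_INTENSITY, size=img.shape
        ).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    data = np.round(img * 255.0).astype(np.uint8)
    return Volume3D(data, params.voxel_spacing)


def make_cine(
    params: PhantomParams, seed: int = 0
) -> tuple[CineSequence, CineSequence]:
    """Generate one full cycle: (rendered images, ground-truth chamber maps).

    The N frames sample t_k = kT/N, k = 0..N−1 — exactly one period, evenly,
    so the per-chamber time-mean analytic volume equals the mean-geometry
    volume exactly (the sinusoid sums to zero over the uniform phases).
    """
    n = params.frames_per_cycle
    frame_seeds = np.random.SeedSequence(seed).generate_state(n)
    images, truths = [], []
    for k in range(n):
        truth = make_truth(params, k)
        images.append(render_frame(params, k, seed=int(frame_seeds[k])))
        truths.append(truth)
    interval = params.frame_interval
    return (
        CineSequence(images, interval, params.period),
        CineSequence(truths, interval, params.period),
    )


# ---------------------------------------------------------------------------
# 2D training-slice corpus


def training_slice(
    seed: int,
    *,
    size: int = 128,
    pitch: float = 4.0,
    dpf: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """One randomized axial slice through the phantom plus its truth mask.

    Emulates one hand-segmented training pair: a random cardiac phase, a
    random axial position spanning the full heart (pole slices showing only
    a myocardial ring, or nothing, included — a real training set covers
    every slice of the stack), and ±10% size / ±10 μm position jitter,
    rendered with the same shell/attenuation/noise model as the 3D frames
    (in-plane PSF blur only).

    Returns
    -------
    image : float32 (size, size) in [0, 1]
    mask : uint8 (size, size), 1 on the intracardiac lumen
    """
    rng = np.random.default_rng(seed)
    base = preset(dpf, pitch=pitch)
    field_extent = size * pitch

    scale = rng.uniform(0.9, 1.1)
    mid_y = 0.5 * (_CENTER_Y_V + _CENTER_Y_A)
    jit_heart = rng.uniform(-10.0, 10.0, size=2)  # (y, x) of the whole heart

    def jittered(geom: ChamberGeom) -> ChamberGeom:
        d = rng.uniform(-4.0, 4.0, size=2)
        cy = field_extent / 2.0 + (geom.center[1] - mid_y) * scale + jit_heart[0] + d[0]
        cx = field_extent / 2.0 + jit_heart[1] + d[1]
        return replace(
            geom,
            center=(geom.center[0], cy, cx),
            semi_axes=tuple(scale * a for a in geom.semi_axes),
            trabeculation_amplitude=scale * geom.trabeculation_amplitude,
        )

    params = replace(
        base,
        atrium=jittered(base.atrium),
        ventricle=jittered(base.ventricle),
        canal_radius=scale * base.canal_radius,
        grid_shape=(base.grid_shape[0], size, size),
    )
    t = rng.uniform(0.0, params.period)
    band = (
        max(
            params.atrium.axial_semi_axis(t, params.period),
            params.ventricle.axial_semi_axis(t, params.period),
        )
        + params.wall_thickness
    )
    z = _CENTER_Z + rng.uniform(-band, band)

    ys = (np.arange(size) + 0.5) * pitch
    xs = (np.arange(size) + 0.5) * pitch
    Y, X = np.meshgrid(ys, xs, indexing="ij", sparse=True)
    Z = np.float64(z)

    lumen = (
        _inside_chamber(params.ventricle, t, params.period, Z, Y, X)
        | _inside_chamber(params.atrium, t, params.period, Z, Y, X)
        | _inside_canal(params, Z, Y, X)
    )
    w = params.wall_thickness
    outer = (
        _inside_chamber(params.ventricle, t, params.period, Z, Y, X, grow=w)
        | _inside_chamber(params.atrium, t, params.period, Z, Y, X, grow=w)
        | _inside_canal(params, Z, Y, X, grow=w)
    )
    img = np.full((size, size), _DARK_INTENSITY, dtype=np.float32)
    img[outer & ~lumen] = _SHELL_INTENSITY
    img *= math.exp(-z / params.attenuation_depth)
    img = ndimage.gaussian_filter(img, sigma=_PSF_SIGMA_VOX)
    img += rng.normal(0.0, params.noise_sigma, size=img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32), lumen.astype(np.uint8)


def training_slices(
    seeds: Sequence[int],
    *,
    size: int = 128,
    pitch: float = 4.0,
    dpf: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of randomized training pairs, one per seed."""
    pairs = [training_slice(int(s), size=size, pitch=pitch, dpf=dpf) for s in seeds]
    images = np.stack([p[0] for p in pairs])
    masks = np.stack([p[1] for p in pairs])
    return images, masks
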