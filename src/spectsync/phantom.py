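"""Synthetic gated short-axis SPECT phantom with known contraction timing.

The left ventricle is a half-ellipsoid shell (hemispheric apex, open base)
whose long axis runs along the slice axis, apex at slice 0.  The wall holds a
uniform tracer concentration; per-frame, per-segment wall thickness follows

    w(t) = wall_mm_ed + thickening_mm * (1 - cos(2*pi*t/T - delay_seg)) / 2

so thickness peaks at cycle angle 180 degrees plus the segment's delay.  The
cavity shrinks in step: the endocardial radius is scaled each frame so cavity
volume interpolates end-diastole to end-systole, hitting the requested
ejection fraction exactly in the analytic model.  Apparent counts arise only
through the partial-volume effect: the shell is rasterized, blurred with a
Gaussian point-spread function, scaled so the noise-free maximum matches the
target maximum myocardial counts per pixel, then (optionally) Poisson-sampled.
This mirrors resting-perfusion normal-database acquisitions: 16 frames per
cycle, 64 x 64 matrices, maximum myocardial counts of order 123 per pixel.

Frame ``k`` covers cycle angle [k, k+1) * 360 / n_frames and is evaluated at
the interval midpoint (gating integrates over the bin).

A cohort generator draws per-sex end-diastolic volumes and ejection fractions
(defaults follow resting normal-database statistics: 36 males with
EDV 84.4 +/- 15.7 mL, EF 66.5 +/- 6.1%; 33 females with EDV 64.1 +/- 12.1 mL,
EF 72.0 +/- 5.7%), jitters segmental delays, and by default scales maximum
counts inversely with myocardial volume — larger hearts accumulate fewer
counts per pixel, the count-statistics mechanism behind the gender effect in
phase metrics.  Wall thickening scales with the drawn EF (physiologic
coupling of thickening to global contractile function).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .aha import APEX, segment_of
from .study_io import GatedStudy

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """LV shell does not fit inside the requested field of view."""


def _as_tuple17(value, name: str) -> tuple:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(17, float(arr))
    if arr.shape != (17,):
        raise ValueError(f"{name} must be a scalar or 17 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contraction timing and acquisition envelope of one subject."""

    matrix_size: int = 64
    pixel_mm: float = 6.4
    n_slices: int = 24
    slice_mm: float = 6.4
    n_frames: int = 16
    edv_ml: float = 74.7
    ef_true: float = 0.69
    wall_mm_ed: float = 10.0
    thickening_mm: float = 5.0
    delay_deg: tuple = (0.0,) * 17
    uptake: tuple = (1.0,) * 17
    psf_fwhm_mm: float = 12.0
    max_counts: float = 123.0
    axis_ratio: float = 2.0  # long-axis / short-axis semi-axis of the cavity
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "delay_deg", _as_tuple17(self.delay_deg, "delay_deg"))
        object.__setattr__(self, "uptake", _as_tuple17(self.uptake, "uptake"))
        for name in ("pixel_mm", "slice_mm", "edv_ml", "wall_mm_ed",
                     "psf_fwhm_mm", "max_counts", "axis_ratio"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not np.isfinite(self.thickening_mm) or self.thickening_mm < 0:
            raise ValueError("thickening_mm must be nonnegative")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if not 0.0 < self.ef_true < 1.0:
            raise ValueError("ef_true must be in (0, 1)")
        if any(not 0.0 <= d < 360.0 for d in self.delay_deg):
            raise ValueError("delay_deg entries must be in [0, 360)")
        if any(not 0.0 < u <= 1.0 for u in self.uptake):
            raise ValueError("uptake entries must be in (0, 1]")


@dataclass(frozen=True)
class SubjectTruth:
    """Analytic (pre-rasterization) ground truth for recovery tests."""

    edv_ml: float
    esv_ml: float
    ef: float
    tes_true_deg: tuple
    psd_true_deg: float

    def __post_init__(self):
        if not self.esv_ml < self.edv_ml:
            raise ValueError("ESV must be smaller than EDV")
        if abs(self.ef - (self.edv_ml - self.esv_ml) / self.edv_ml) > 1e-9:
            raise ValueError("EF inconsistent with volumes")


@dataclass(frozen=True)
class CohortSpec:
    """Per-sex population parameters for a simulated normal cohort."""

    n_male: int = 36
    n_female: int = 33
    edv_mean_ml: dict = field(default_factory=lambda: {"M": 84.4, "F": 64.1})
    edv_sd_ml: dict = field(default_factory=lambda: {"M": 15.7, "F": 12.1})
    ef_mean: dict = field(default_factory=lambda: {"M": 0.665, "F": 0.720})
    ef_sd: dict = field(default_factory=lambda: {"M": 0.061, "F": 0.057})
    counts_scaling: str = "inverse_myocardial_volume"  # or "none"
    delay_jitter_deg: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("group sizes must be >= 0")
        for d in (self.edv_sd_ml, self.ef_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("SDs must be >= 0")
        if self.delay_jitter_deg < 0:
            raise ValueError("delay_jitter_deg must be >= 0")
        if self.counts_scaling not in ("inverse_myocardial_volume", "none"):
            raise ValueError(f"unknown counts_scaling {self.counts_scaling!r}")


@dataclass(frozen=True)
class CohortSubject:
    id: str
    sex: str
    spec: PhantomSpec
    truth: SubjectTruth


# ---------------------------------------------------------------------------
# Geometry

def _geometry(spec: PhantomSpec):
    """End-diastolic semi-axes (a, c) in mm and the base plane position.

    Cavity volume of a half-ellipsoid open at the base: V = (2/3) pi a^2 c.
    The base is snapped to a slice boundary so the most basal wall slice is
    fully covered.
    """
    v_mm3 = spec.edv_ml * 1000.0
    a = (3.0 * v_mm3 / (2.0 * math.pi * spec.axis_ratio)) ** (1.0 / 3.0)
    c = spec.axis_ratio * a
    length = spec.n_slices * spec.slice_mm
    z_base = round(((length + c) / 2.0) / spec.slice_mm) * spec.slice_mm
    w_max = spec.wall_mm_ed + spec.thickening_mm
    if z_base - c - w_max < 0 or z_base > length:
        raise GeometryError("LV shell exceeds the slice stack")
    if a + w_max > (spec.matrix_size / 2.0 - 1.0) * spec.pixel_mm:
        raise GeometryError("LV shell exceeds the in-plane field of view")
    return a, c, z_base


def frame_angles_deg(spec: PhantomSpec) -> np.ndarray:
    """Cycle angle at which each gated frame is evaluated (bin midpoints)."""
    return (np.arange(spec.n_frames) + 0.5) * 360.0 / spec.n_frames


def _thickening_fraction(spec: PhantomSpec, theta_deg) -> np.ndarray:
    """Per-segment contraction fraction g in [0, 1]; shape (..., 17)."""
    th = np.asarray(theta_deg, dtype=float)[..., None]
    d = np.asarray(spec.delay_deg)
    return (1.0 - np.cos(np.radians(th - d))) / 2.0


def _cavity_curve_ml(spec: PhantomSpec, theta_deg) -> np.ndarray:
    """Analytic cavity volume at the given cycle angles, mL.

    The global contraction drive is the canonical fundamental
    (1 - cos(theta))/2, hitting end-systole at 180 degrees and the EF target
    exactly.  Per-segment delays modulate regional wall thickening only
    (the small-delay regime of a normal database); keeping the volume curve
    delay-independent prevents the global cavity motion from leaking a
    spurious phase reference into regional curves.
    """
    g = (1.0 - np.cos(np.radians(np.asarray(theta_deg, dtype=float)))) / 2.0
    return spec.edv_ml * (1.0 - spec.ef_true * g)


def true_function(spec: PhantomSpec) -> SubjectTruth:
    """Seed-independent analytic EDV/ESV/EF and per-segment TES."""
    esv = spec.edv_ml * (1.0 - spec.ef_true)
    tes = tuple((180.0 + d) % 360.0 for d in spec.delay_deg)
    return SubjectTruth(
        edv_ml=spec.edv_ml,
        esv_ml=esv,
        ef=spec.ef_true,
        tes_true_deg=tes,
        psd_true_deg=float(np.std(np.asarray(spec.delay_deg))),
    )


def _crop_box(spec: PhantomSpec, a: float, c: float, z_base: float):
    """Slice and in-plane index ranges that contain the shell plus blur."""
    w_max = spec.wall_mm_ed + spec.thickening_mm
    margin = 4.0 * spec.psf_fwhm_mm * _FWHM_TO_SIGMA + 2.0 * spec.pixel_mm
    r_ext = a + w_max + margin
    half = (spec.matrix_size - 1) / 2.0
    i0 = max(0, int(math.floor(half - r_ext / spec.pixel_mm)))
    i1 = min(spec.matrix_size, int(math.ceil(half + r_ext / spec.pixel_mm)) + 1)
    z_lo = z_base - c - w_max - margin
    z_hi = z_base + margin
    s0 = max(0, int(math.floor(z_lo / spec.slice_mm)))
    s1 = min(spec.n_slices, int(math.ceil(z_hi / spec.slice_mm)) + 1)
    return s0, s1, i0, i1


def _voxel_fields(spec: PhantomSpec, c: float, z_base: float, box):
    """Per-voxel height above apex, in-plane radius/angle and segment map."""
    s0, s1, i0, i1 = box
    z = (np.arange(s0, s1) + 0.5) * spec.slice_mm
    u = (z_base - z)[:, None, None]  # mm below the base plane
    half = (spec.matrix_size - 1) / 2.0
    coord = (np.arange(i0, i1) - half) * spec.pixel_mm
    yy = coord[:, None]  # rows
    xx = coord[None, :]  # cols
    rho = np.hypot(yy, xx)[None, :, :]
    angle = (np.degrees(np.arctan2(yy, xx)) % 360.0)[None, :, :]
    level_frac = np.clip(u / c, 0.0, None)
    level = np.minimum(np.floor(level_frac * 3.0), 2.0).astype(int)
    level = np.where(level_frac >= 1.0, APEX, level)
    seg = segment_of(np.broadcast_to(level, (s1 - s0,) + rho.shape[1:]),
                     np.broadcast_to(angle, (s1 - s0,) + rho.shape[1:]))
    return u, rho, seg


def _signed_distance(rho, u, a_k: float, c: float) -> np.ndarray:
    """First-order signed distance (mm) to the endocardial half-ellipsoid.

    Negative inside the cavity.  Valid for voxels below the base (u >= 0);
    callers mask u < 0 separately.
    """
    q = np.sqrt((rho / a_k) ** 2 + (u / c) ** 2)
    grad = np.sqrt((rho / a_k**2) ** 2 + (u / c**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (q - 1.0) * q / grad
    d = np.where(q < 1e-12, -min(a_k, c), d)
    return d


def generate_study(spec: PhantomSpec, seed: int | None = None) -> GatedStudy:
    """Rasterize, blur, scale and (optionally) Poisson-sample the phantom.

    ``seed`` overrides ``spec.seed`` for the Poisson draw.  Noise-free output
    (``spec.poisson = False``) is deterministic and its maximum voxel equals
    ``spec.max_counts`` within rounding.
    """
    a, c, z_base = _geometry(spec)
    box = _crop_box(spec, a, c, z_base)
    s0, s1, i0, i1 = box
    u, rho, seg = _voxel_fields(spec, c, z_base, box)
    uptake_vox = np.asarray(spec.uptake)[seg - 1]

    theta = frame_angles_deg(spec)
    w_seg = spec.wall_mm_ed + spec.thickening_mm * _thickening_fraction(spec, theta)
    vol_ml = _cavity_curve_ml(spec, theta)
    a_frames = a * np.sqrt(vol_ml / spec.edv_ml)

    h = 0.5 * spec.pixel_mm  # anti-aliasing half-width
    sigma = spec.psf_fwhm_mm * _FWHM_TO_SIGMA
    sig_vox = (sigma / spec.slice_mm, sigma / spec.pixel_mm, sigma / spec.pixel_mm)
    below_base = np.clip(u / h + 0.5, 0.0, 1.0)

    crop = np.empty((spec.n_frames, s1 - s0, i1 - i0, i1 - i0))
    for k in range(spec.n_frames):
        d = _signed_distance(rho, u, float(a_frames[k]), c)
        w_vox = w_seg[k][seg - 1]
        shell = np.clip(d / h + 0.5, 0.0, 1.0) * np.clip((w_vox - d) / h + 0.5, 0.0, 1.0)
        crop[k] = gaussian_filter(shell * uptake_vox * below_base, sigma=sig_vox,
                                  mode="constant")

    lam = crop * (spec.max_counts / crop.max())
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    vals = rng.poisson(lam) if spec.poisson else np.rint(lam)
    counts = np.zeros((spec.n_frames, spec.n_slices, spec.matrix_size,
                       spec.matrix_size), dtype=np.int32)
    counts[:, s0:s1, i0:i1, i0:i1] = vals.astype(np.int32)
    frame_ms = 1000.0 / spec.n_frames  # nominal 1-s cardiac cycle
    meta = {"spec": asdict(spec), "seed": int(spec.seed if seed is None else seed)}
    return GatedStudy(counts=counts, pixel_mm=spec.pixel_mm, slice_mm=spec.slice_mm,
                      frame_ms=frame_ms, meta=meta)


def rasterized_cavity_ml(spec: PhantomSpec, supersample: int = 2) -> np.ndarray:
    """Per-frame cavity volume by numerically integrating the voxelized cavity.

    Independent check of the analytic volume curve; ``supersample`` refines
    the grid to reduce voxelization error.
    """
    a, c, z_base = _geometry(spec)
    n = int(supersample)
    dz = spec.slice_mm / n
    dxy = spec.pixel_mm / n
    zmax = spec.n_slices * spec.slice_mm
    z = np.arange(dz / 2.0, zmax, dz)
    u = (z_base - z)[:, None, None]
    half_mm = (spec.matrix_size * spec.pixel_mm) / 2.0
    coord = np.arange(-half_mm + dxy / 2.0, half_mm, dxy)
    rho = np.hypot(coord[:, None], coord[None, :])[None, :, :]
    h = 0.5 * dxy
    theta = frame_angles_deg(spec)
    vol_ml = _cavity_curve_ml(spec, theta)
    a_frames = a * np.sqrt(vol_ml / spec.edv_ml)
    inside_ax = np.clip(u / h + 0.5, 0.0, 1.0)
    out = np.empty(spec.n_frames)
    voxel_ml = dz * dxy * dxy / 1000.0
    for k in range(spec.n_frames):
        d = _signed_distance(rho, np.clip(u, 0.0, None), float(a_frames[k]), c)
        w = np.clip(-d / h + 0.5, 0.0, 1.0) * inside_ax
        out[k] = w.sum() * voxel_ml
    return out


def myocardial_volume_ml(spec: PhantomSpec) -> float:
    """Analytic end-diastolic shell volume (epicardium minus cavity), mL."""
    a, c, _ = _geometry(spec)
    w = spec.wall_mm_ed
    v_epi = (2.0 / 3.0) * math.pi * (a + w) ** 2 * (c + w)
    return (v_epi - (2.0 / 3.0) * math.pi * a**2 * c) / 1000.0


# ---------------------------------------------------------------------------
# Cohort generation

_EDV_BOUNDS_ML = (35.0, 250.0)
_EF_BOUNDS = (0.40, 0.88)
_EF_REF = 0.69  # thickening reference: 5 mm at EF 0.69


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.clip(rng.normal(mean, sd, size=size), lo, hi)
    return out


def make_cohort(cohort: CohortSpec, base_spec: PhantomSpec | None = None):
    """Draw per-subject phantom specs and truths; deterministic under seed.

    Returns a list of :class:`CohortSubject` (id, sex, spec, truth), males
    first.  ``base_spec`` carries the acquisition geometry shared by all
    subjects; per-subject EDV, EF, thickening, delays, counts and seeds are
    overridden from the cohort draw.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(cohort.seed)
    subjects = []
    for sex, n in (("M", cohort.n_male), ("F", cohort.n_female)):
        edv = _truncated_normal(rng, cohort.edv_mean_ml[sex], cohort.edv_sd_ml[sex],
                                *_EDV_BOUNDS_ML, size=n)
        ef = _truncated_normal(rng, cohort.ef_mean[sex], cohort.ef_sd[sex],
                               *_EF_BOUNDS, size=n)
        for i in range(n):
            delays = rng.normal(0.0, cohort.delay_jitter_deg, size=17) % 360.0
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base,
                edv_ml=float(edv[i]),
                ef_true=float(ef[i]),
                thickening_mm=base.thickening_mm * float(ef[i]) / _EF_REF,
                delay_deg=tuple(delays),
                seed=sub_seed,
            )
            subjects.append((sex, spec))
    if cohort.counts_scaling == "inverse_myocardial_volume" and subjects:
        vols = np.array([myocardial_volume_ml(s) for _, s in subjects])
        ref = vols.mean()
        subjects = [
            (sex, replace(s, max_counts=base.max_counts * ref / v))
            for (sex, s), v in zip(subjects, vols)
        ]
    out = []
    counters = {"M": 0, "F": 0}
    for sex, spec in subjects:
        counters[sex] += 1
        out.append(CohortSubject(
            id=f"{sex}{counters[sex]:03d}", sex=sex, spec=spec,
            truth=true_function(spec),
        ))
    return out
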