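"""Fourier-harmonic fitting of gated time-activity curves.

A regional count curve v(k), k = 0..N-1 frames, is modelled as

    v(k) = a0 + sum_h a_h * cos(2*pi*h*k/N - phi_h),   h = 1 (and optionally 2)

with a_h >= 0 and phi_h in [0, 360) degrees.  For uniformly sampled frames the
least-squares solution is exactly the discrete Fourier transform coefficient
pair, which is how the fit is computed here.  The phase convention is the
location of the first-harmonic count *maximum*: under the partial-volume
mechanism counts peak when the wall is thickest, i.e. at end-systole.

Time to end-systole (TES) is read off an order-2 fit as the cycle angle that
maximises the fitted curve.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: Default first-harmonic amplitude floor, as a fraction of the mean level,
#: below which a sample's phase is treated as undefined (non-contracting or
#: noise-only tissue).
DEFAULT_AMPLITUDE_FLOOR = 0.02


@dataclass(frozen=True)
class HarmonicFit:
    """Result of a harmonic fit to one time-activity curve."""

    a0: float
    a1: float
    phi1_deg: float
    rmse: float
    order: int
    n_frames: int
    a2: float | None = None
    phi2_deg: float | None = None
    phase_defined: bool = True

    def __post_init__(self):
        if self.a1 < 0 or (self.a2 is not None and self.a2 < 0):
            raise ValueError("harmonic amplitudes must be nonnegative")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")


def _values(tac) -> np.ndarray:
    v = np.asarray(getattr(tac, "values", tac), dtype=float)
    if v.ndim != 1:
        raise ValueError("time-activity curve must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("time-activity curve contains non-finite values")
    return v


def fit_harmonics(tac, order: int = 1) -> HarmonicFit:
    """Least-squares cosine-series fit of order 1 or 2.

    Equals the DFT coefficients on uniformly sampled frames.  A constant
    curve returns ``a1 = 0`` with ``phase_defined = False``.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    v = _values(tac)
    n = v.size
    if n < 2 * order + 1:
        raise ValueError(f"need at least {2 * order + 1} frames for order {order}")
    x = np.fft.rfft(v)
    a0 = float(x[0].real / n)
    a1 = float(2.0 * np.abs(x[1]) / n)
    phi1 = float(np.degrees(-np.angle(x[1])) % 360.0)
    a2 = phi2 = None
    k = np.arange(n)
    recon = a0 + a1 * np.cos(2 * np.pi * k / n - np.radians(phi1))
    if order == 2:
        a2 = float(2.0 * np.abs(x[2]) / n)
        phi2 = float(np.degrees(-np.angle(x[2])) % 360.0)
        recon = recon + a2 * np.cos(4 * np.pi * k / n - np.radians(phi2))
    rmse = float(np.sqrt(np.mean((v - recon) ** 2)))
    defined = a1 > 1e-9 * (abs(a0) + 1.0)
    return HarmonicFit(
        a0=a0, a1=a1, phi1_deg=phi1, rmse=rmse, order=order, n_frames=n,
        a2=a2, phi2_deg=phi2, phase_defined=defined,
    )


def phase_deg(fit: HarmonicFit, floor_frac: float = DEFAULT_AMPLITUDE_FLOOR):
    """First-harmonic phase in degrees, or ``None`` for excluded samples.

    A sample is excluded (not an exception — histograms simply skip it) when
    its amplitude does not clear ``floor_frac`` of the mean level.
    """
    if not fit.phase_defined:
        return None
    if fit.a1 <= floor_frac * abs(fit.a0):
        return None
    return fit.phi1_deg


def _curve_order2(fit: HarmonicFit, theta_deg: np.ndarray) -> np.ndarray:
    out = fit.a1 * np.cos(np.radians(theta_deg - fit.phi1_deg))
    out = out + fit.a2 * np.cos(np.radians(2.0 * theta_deg - fit.phi2_deg))
    return out


def tes_deg(fit: HarmonicFit, grid_deg: float = 0.1):
    """Time to end-systole: cycle angle maximising the order-2 fitted curve.

    Searched on a ``grid_deg`` grid then refined by local quadratic
    interpolation.  Ties (two equal maxima within tolerance) resolve to the
    smaller angle.  Returns ``None`` when the fit carries no defined phase.
    """
    if fit.order != 2:
        raise ValueError("TES requires an order-2 fit")
    if not fit.phase_defined and (fit.a2 is None or fit.a2 <= 1e-9 * (abs(fit.a0) + 1.0)):
        return None
    theta = np.arange(0.0, 360.0, grid_deg)
    f = _curve_order2(fit, theta)
    fmax = f.max()
    # candidate maxima within tolerance; smallest angle wins on ties
    tol = 1e-9 * max(1.0, abs(fmax))
    i = int(np.flatnonzero(f >= fmax - tol)[0])
    fm, f0, fp = f[(i - 1) % f.size], f[i], f[(i + 1) % f.size]
    denom = fm - 2.0 * f0 + fp
    delta = 0.0 if abs(denom) < 1e-30 else 0.5 * (fm - fp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float((theta[i] + delta * grid_deg) % 360.0)


# ---------------------------------------------------------------------------
# Vectorised helpers used by the per-study pipeline (same math as above).

def fit_batch(values: np.ndarray, order: int = 1):
    """Harmonic coefficients for a stack of TACs, shape (..., n_frames).

    Returns ``(a0, a1, phi1_deg)`` for order 1, plus ``(a2, phi2_deg)`` for
    order 2, each with the leading shape of ``values``.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    if n < 2 * order + 1:
        raise ValueError("too few frames")
    x = np.fft.rfft(v, axis=-1)
    a0 = x[..., 0].real / n
    a1 = 2.0 * np.abs(x[..., 1]) / n
    phi1 = np.degrees(-np.angle(x[..., 1])) % 360.0
    if order == 1:
        return a0, a1, phi1
    a2 = 2.0 * np.abs(x[..., 2]) / n
    phi2 = np.degrees(-np.angle(x[..., 2])) % 360.0
    return a0, a1, phi1, a2, phi2


def phases_batch(values: np.ndarray, floor_frac: float = DEFAULT_AMPLITUDE_FLOOR):
    """Per-TAC first-harmonic phase with NaN where the phase is undefined."""
    a0, a1, phi1 = fit_batch(values, order=1)
    defined = a1 > np.maximum(floor_frac * np.abs(a0), 1e-9 * (np.abs(a0) + 1.0))
    return np.where(defined, phi1, np.nan)


def replace(fit: HarmonicFit, **kw) -> HarmonicFit:
    return dataclasses.replace(fit, **kw)
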