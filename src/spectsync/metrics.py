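"""Dyssynchrony indices from per-sample phases and segmental TES values.

The phase histogram collects the first-harmonic phase of every accepted
myocardial sample.  From it (or from the raw phase list) the package computes:

PSD
    wrap-safe standard deviation of the phase distribution, degrees.  The
    samples are rotated so their circular mean sits at 180 degrees, then the
    population SD of the rotated values is taken.
95% bandwidth
    the shortest circular arc containing at least 95% of the samples, degrees.
    An alternative tail-trimming definition is available since vendor
    programs differ.
entropy
    normalized Shannon entropy of the binned histogram,
    E = -sum f_i log f_i / log(n_bins), in [0, 1]: 0 is complete order (all
    phases in one bin), 1 complete disorder (uniform histogram).

Segmental time-to-end-systole statistics (maximum difference, SD, and the
lateral-minus-septal contrast) are expressed as percent of the cardiac cycle,
i.e. divided by 360 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aha import LATERAL_SEGMENTS, SEPTAL_SEGMENTS


class MetricInputError(ValueError):
    pass


def circular_mean_deg(phases_deg) -> float:
    """Direction of the resultant vector of unit phasors, degrees in [0, 360)."""
    p = np.radians(np.asarray(phases_deg, dtype=float))
    if p.size == 0:
        raise MetricInputError("empty phase list")
    return float(np.degrees(np.angle(np.mean(np.exp(1j * p)))) % 360.0)


@dataclass(frozen=True)
class PhaseHistogram:
    """Normalized phase histogram on [start_deg, start_deg + 360)."""

    bin_deg: float
    start_deg: float
    freq: np.ndarray
    n_samples: int

    def __post_init__(self):
        f = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", f)
        if f.ndim != 1 or f.size < 1:
            raise MetricInputError("freq must be a nonempty vector")
        if np.any(f < 0):
            raise MetricInputError("freq must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-12:
            raise MetricInputError("freq must sum to 1")
        if abs(self.n_bins * self.bin_deg - 360.0) > 1e-9:
            raise MetricInputError("bins must tile the full circle")

    @property
    def n_bins(self) -> int:
        return int(self.freq.size)

    @property
    def edges_deg(self) -> np.ndarray:
        return self.start_deg + np.arange(self.n_bins + 1) * self.bin_deg


@dataclass(frozen=True)
class DyssyncMetrics:
    """Histogram-family dyssynchrony indices for one study."""

    psd_deg: float
    bandwidth_deg: float
    entropy: float
    n_samples: int

    def __post_init__(self):
        if self.psd_deg < 0 or not (0 <= self.bandwidth_deg <= 360):
            raise MetricInputError("invalid dyssynchrony metrics")
        if not (0.0 <= self.entropy <= 1.0):
            raise MetricInputError("entropy out of [0, 1]")


@dataclass(frozen=True)
class TesMetrics:
    """Segmental time-to-end-systole statistics, percent of the cycle."""

    tes_deg: tuple
    mdtes_pct: float
    sdtes_pct: float
    dtes_ls_pct: float

    def __post_init__(self):
        if self.mdtes_pct < 0:
            raise MetricInputError("mdtes must be nonnegative")
        for v in (self.mdtes_pct, self.sdtes_pct, self.dtes_ls_pct):
            if not -100.0 <= v <= 100.0:
                raise MetricInputError("TES percent out of range")


def build_histogram(phases_deg, bin_deg: float = 1.0, start_deg: float = 0.0) -> PhaseHistogram:
    """Bin phases on half-open bins (lower edge inclusive) and normalize."""
    p = np.asarray(phases_deg, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise MetricInputError("no phases to histogram")
    n_bins = 360.0 / bin_deg
    if bin_deg <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise MetricInputError("bin_deg must evenly divide 360")
    n_bins = int(round(n_bins))
    shifted = (p - start_deg) % 360.0
    idx = np.floor(shifted / bin_deg).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard 359.999999 float edge
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return PhaseHistogram(bin_deg=bin_deg, start_deg=start_deg,
                          freq=counts / p.size, n_samples=int(p.size))


def psd(phases_deg, recenter: bool = True) -> float:
    """Phase standard deviation, degrees, wrap-safe by default.

    With ``recenter`` the distribution is rotated so its circular mean sits at
    180 degrees before the (population) SD is taken; disabling recentring
    reproduces a naive linear SD for emulation studies.
    """
    p = np.asarray(phases_deg, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 2:
        raise MetricInputError("PSD needs at least 2 samples")
    if recenter:
        p = (p - circular_mean_deg(p) + 180.0) % 360.0
    return float(np.std(p))


def bandwidth95(phases_deg, coverage: float = 0.95, mode: str = "shortest_arc",
                min_n: int = 20) -> float:
    """Width of the phase histogram containing ``coverage`` of the samples.

    ``shortest_arc`` sweeps the sorted sample positions for the shortest
    circular arc holding at least ceil(coverage * n) samples.  ``trim_tails``
    instead drops (1-coverage)/2 of the samples from each tail about the
    circular mean.  Below ``min_n`` samples the 95% notion is ill-defined;
    the full-coverage arc is returned with a warning.
    """
    p = np.asarray(phases_deg, dtype=float)
    p = p[np.isfinite(p)] % 360.0
    n = p.size
    if n == 0:
        raise MetricInputError("no phases")
    if not 0 < coverage <= 1:
        raise MetricInputError("coverage must be in (0, 1]")
    flagged = n < min_n
    if flagged:
        warnings.warn(
            f"bandwidth with {n} < {min_n} samples: returning full-range arc",
            stacklevel=2,
        )
    m = n if flagged else int(math.ceil(coverage * n))
    s = np.sort(p)
    if mode == "shortest_arc":
        idx = np.arange(n)
        widths = (s[(idx + m - 1) % n] - s[idx]) % 360.0
        return float(widths.min())
    if mode == "trim_tails":
        r = np.sort((p - circular_mean_deg(p) + 180.0) % 360.0)
        drop = (n - m) // 2
        r = r[drop:n - (n - m - drop)]
        return float(r[-1] - r[0])
    raise MetricInputError(f"unknown bandwidth mode {mode!r}")


def entropy(hist: PhaseHistogram) -> float:
    """Normalized histogram entropy in [0, 1] (0 order, 1 disorder).

    Uses the convention 0*log 0 = 0; base-invariant through the log(n_bins)
    normalization.
    """
    if hist.n_bins < 2:
        raise MetricInputError("entropy needs at least 2 bins")
    f = hist.freq[hist.freq > 0]
    e = float(-(f * np.log(f)).sum() / np.log(hist.n_bins))
    return min(max(e, 0.0), 1.0) + 0.0  # +0.0 normalizes -0.0


def dyssync_metrics(phases_deg, bin_deg: float = 1.0,
                    bandwidth_mode: str = "shortest_arc") -> DyssyncMetrics:
    """PSD, 95% bandwidth and entropy from one study's phase samples."""
    p = np.asarray(phases_deg, dtype=float)
    p = p[np.isfinite(p)]
    hist = build_histogram(p, bin_deg=bin_deg)
    return DyssyncMetrics(
        psd_deg=psd(p),
        bandwidth_deg=bandwidth95(p, mode=bandwidth_mode),
        entropy=entropy(hist),
        n_samples=int(p.size),
    )


def _tes_array(tes_by_segment) -> np.ndarray:
    if isinstance(tes_by_segment, dict):
        missing = [s for s in range(1, 18) if s not in tes_by_segment]
        if missing:
            raise MetricInputError(f"missing segments: {missing}")
        arr = np.array([tes_by_segment[s] for s in range(1, 18)], dtype=float)
    else:
        arr = np.asarray(tes_by_segment, dtype=float)
        if arr.shape != (17,):
            raise MetricInputError("expected 17 segmental TES values")
    if not np.all(np.isfinite(arr)):
        raise MetricInputError("undefined TES value in strict mode")
    return arr


def tes_metrics(tes_by_segment, lateral_ids=LATERAL_SEGMENTS,
                septal_ids=SEPTAL_SEGMENTS) -> TesMetrics:
    """Maximum difference, SD, and lateral-minus-septal TES, % of cycle.

    Values are first rotated so their circular mean sits at 180 degrees,
    preventing a 359/1 degree pair from reading as a 358-degree spread.
    """
    arr = _tes_array(tes_by_segment)
    r = (arr - circular_mean_deg(arr) + 180.0) % 360.0
    lat = np.array([r[s - 1] for s in lateral_ids], dtype=float)
    sep = np.array([r[s - 1] for s in septal_ids], dtype=float)
    return TesMetrics(
        tes_deg=tuple(float(v) for v in arr),
        mdtes_pct=float((r.max() - r.min()) / 360.0 * 100.0),
        sdtes_pct=float(np.std(r) / 360.0 * 100.0),
        dtes_ls_pct=float((lat.mean() - sep.mean()) / 360.0 * 100.0),
    )


@dataclass(frozen=True)
class NormalLimits:
    mean: float
    sd: float
    lower: float
    upper: float


def normal_limits(values) -> NormalLimits:
    """Normal-database limits: mean +/- 2 * sample SD (ddof = 1), unrounded."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise MetricInputError("normal limits need at least 2 values")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    return NormalLimits(mean=m, sd=sd, lower=m - 2 * sd, upper=m + 2 * sd)
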