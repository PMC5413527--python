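"""Per-study analysis pipeline: sampling -> harmonics -> metrics -> function.

The :class:`PipelineConfig` collects every knob the stages expose, with a
strict loader (unknown keys rejected) so configuration files fail loudly.
:func:`analyze_study` runs the full chain on one gated study and returns the
per-subject quantities that feed the cohort table.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields

import numpy as np

from . import harmonics
from .function import estimate_volumes
from .metrics import (bandwidth95, build_histogram, entropy, psd, tes_metrics)
from .sampling import (SamplingGrid, aggregate_17seg, base_cut, sample_profiles,
                       smooth_phases)
from .study_io import GatedStudy


@dataclass(frozen=True)
class PipelineConfig:
    # sampling
    n_angles: int = 36
    radial_window_mm: float = 20.0
    basal_fraction: float = 0.2
    sampling_mode: str = "max"
    # base cut
    base_cut_mode: str = "auto"  # auto | manual | none
    base_cut_frac: float = 0.5
    manual_slices: tuple = ()
    # phase metrics
    bin_deg: float = 1.0
    amplitude_floor: float = harmonics.DEFAULT_AMPLITUDE_FLOOR
    bandwidth_mode: str = "shortest_arc"
    smooth_kernel_deg: float = 0.0
    smooth_kernel_slices: float = 0.0
    # function
    threshold_frac: float = 1.0 / 3.0
    volumes: str = "estimated"  # estimated | truth

    def __post_init__(self):
        if self.volumes not in ("estimated", "truth"):
            raise ValueError("volumes must be 'estimated' or 'truth'")
        if self.base_cut_mode not in ("auto", "manual", "none"):
            raise ValueError("base_cut_mode must be auto, manual or none")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["manual_slices"] = list(self.manual_slices)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "manual_slices" in d:
            d["manual_slices"] = tuple(d["manual_slices"])
        return cls(**d)

    def sampling_grid(self) -> SamplingGrid:
        return SamplingGrid(n_angles=self.n_angles,
                            radial_window_mm=self.radial_window_mm,
                            basal_fraction=self.basal_fraction,
                            mode=self.sampling_mode)


@dataclass
class AnalysisResult:
    """Everything the pipeline measures on one gated study."""

    psd_deg: float = math.nan
    bandwidth_deg: float = math.nan
    entropy_pct: float = math.nan
    mdtes_pct: float = math.nan
    sdtes_pct: float = math.nan
    dtes_ls_pct: float = math.nan
    edv_ml: float = math.nan
    esv_ml: float = math.nan
    ef_pct: float = math.nan
    n_phase_samples: int = 0
    phases_deg: np.ndarray | None = None
    histogram: object = None
    tes_by_segment: dict | None = None
    sample_rows: list | None = None


def _phase_grid(samples, phases):
    """Arrange per-sample phases on the (slice, angle) grid for smoothing."""
    slices = sorted({s.slice for s in samples})
    angles = sorted({s.angle_deg for s in samples})
    sl_idx = {s: i for i, s in enumerate(slices)}
    an_idx = {a: i for i, a in enumerate(angles)}
    grid = np.full((len(slices), len(angles)), np.nan)
    for s, ph in zip(samples, phases):
        grid[sl_idx[s.slice], an_idx[s.angle_deg]] = ph
    return grid, slices, angles


def analyze_study(study: GatedStudy, config: PipelineConfig | None = None,
                  truth=None) -> AnalysisResult:
    """Run sampling, harmonic phase extraction, dyssynchrony metrics and
    volume estimation on one study.

    ``truth`` (a phantom :class:`~spectsync.phantom.SubjectTruth`) is only
    consulted when ``config.volumes == 'truth'``.
    """
    config = config or PipelineConfig()
    grid = config.sampling_grid()
    samples = sample_profiles(study, grid)
    samples = base_cut(samples, mode=config.base_cut_mode,
                       manual_slices=config.manual_slices or None,
                       frac=config.base_cut_frac)
    values = np.stack([s.tac.values for s in samples])
    phases = harmonics.phases_batch(values, floor_frac=config.amplitude_floor)
    if config.smooth_kernel_deg > 0 or config.smooth_kernel_slices > 0:
        pgrid, slices, angles = _phase_grid(samples, phases)
        pgrid = smooth_phases(pgrid, config.smooth_kernel_deg,
                              config.smooth_kernel_slices)
        sl_idx = {s: i for i, s in enumerate(slices)}
        an_idx = {a: i for i, a in enumerate(angles)}
        phases = np.array([pgrid[sl_idx[s.slice], an_idx[s.angle_deg]]
                           for s in samples])
    finite = phases[np.isfinite(phases)]
    out = AnalysisResult()
    out.sample_rows = [
        {"slice": s.slice, "angle_deg": s.angle_deg, "basal": s.basal,
         "phase_deg": float(ph) if np.isfinite(ph) else math.nan,
         **{f"f{k}": float(v) for k, v in enumerate(s.tac.values)}}
        for s, ph in zip(samples, phases)
    ]
    out.n_phase_samples = int(finite.size)
    if finite.size >= 2:
        hist = build_histogram(finite, bin_deg=config.bin_deg)
        out.histogram = hist
        out.psd_deg = psd(finite)
        out.bandwidth_deg = bandwidth95(finite, mode=config.bandwidth_mode)
        out.entropy_pct = 100.0 * entropy(hist)
        out.phases_deg = finite
    # segmental TES from order-2 fits
    segs = aggregate_17seg(samples, grid)
    tes = {}
    for seg in segs:
        fit = harmonics.fit_harmonics(seg.tac, order=2)
        t = harmonics.tes_deg(fit)
        tes[seg.segment] = math.nan if t is None else t
    out.tes_by_segment = tes
    if len(tes) == 17 and all(np.isfinite(v) for v in tes.values()):
        tm = tes_metrics(tes)
        out.mdtes_pct = tm.mdtes_pct
        out.sdtes_pct = tm.sdtes_pct
        out.dtes_ls_pct = tm.dtes_ls_pct
    # cavity volumes
    if config.volumes == "truth":
        if truth is None:
            raise ValueError("volumes='truth' requires phantom ground truth")
        out.edv_ml, out.esv_ml = truth.edv_ml, truth.esv_ml
        out.ef_pct = 100.0 * truth.ef
    else:
        fr = estimate_volumes(study, threshold_frac=config.threshold_frac,
                              grid=grid)
        out.edv_ml, out.esv_ml, out.ef_pct = fr.edv_ml, fr.esv_ml, fr.ef_pct
    return out
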