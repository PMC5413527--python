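"""Cohort simulation driver and the study's statistical toolbox.

Runs the per-subject pipeline (phantom -> sampling -> harmonics -> metrics ->
function) over a simulated normal cohort and provides the group statistics a
normal-database comparison needs: per-sex means compared by one-way ANOVA,
rank-sum (Wilcoxon/Mann-Whitney) contrasts with exact small-sample p values,
Pearson correlations with Fisher-z confidence intervals, least-squares
regressions, normal limits (mean +/- 2 SD), and the volume-matched subgroup
contrast (males below the male median EDV vs females at or above the female
median), which isolates heart-size effects from sex per se.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import CohortSpec, CohortSubject, generate_study, make_cohort
from .pipeline import PipelineConfig, analyze_study

DEFAULT_METRICS = ("psd_deg", "bandwidth_deg", "entropy_pct",
                   "mdtes_pct", "sdtes_pct", "dtes_ls_pct")


@dataclass
class SubjectRecord:
    """One row of the cohort table: function + dyssynchrony per subject."""

    id: str
    sex: str
    edv_ml: float = math.nan
    esv_ml: float = math.nan
    ef_pct: float = math.nan
    psd_deg: float = math.nan
    bandwidth_deg: float = math.nan
    entropy_pct: float = math.nan
    mdtes_pct: float = math.nan
    sdtes_pct: float = math.nan
    dtes_ls_pct: float = math.nan
    n_phase_samples: int = 0
    edv_true_ml: float = math.nan
    ef_true_pct: float = math.nan
    seed: int = -1
    error: str = ""


@dataclass
class CohortTable:
    records: list
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        cols = list(SubjectRecord.__dataclass_fields__)
        return pd.DataFrame([asdict(r) for r in self.records], columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: dict | None = None) -> "CohortTable":
        recs = [SubjectRecord(**{k: row[k] for k in SubjectRecord.__dataclass_fields__
                                 if k in row}) for row in df.to_dict("records")]
        return cls(records=recs, config=config or {})


def run_subject(subject: CohortSubject, config: PipelineConfig) -> SubjectRecord:
    rec = SubjectRecord(id=subject.id, sex=subject.sex, seed=subject.spec.seed,
                        edv_true_ml=subject.truth.edv_ml,
                        ef_true_pct=100.0 * subject.truth.ef)
    try:
        study = generate_study(subject.spec)
        res = analyze_study(study, config, truth=subject.truth)
        for name in ("edv_ml", "esv_ml", "ef_pct", "psd_deg", "bandwidth_deg",
                     "entropy_pct", "mdtes_pct", "sdtes_pct", "dtes_ls_pct",
                     "n_phase_samples"):
            setattr(rec, name, getattr(res, name))
    except Exception as exc:  # flagged, not silently dropped
        rec.error = f"{type(exc).__name__}: {exc}"
    return rec


def run_cohort(cohort: CohortSpec, config: PipelineConfig | None = None) -> CohortTable:
    """Simulate and analyze every subject; deterministic under the seed."""
    config = config or PipelineConfig()
    subjects = make_cohort(cohort)
    records = [run_subject(s, config) for s in subjects]
    return CohortTable(records=records,
                       config={"cohort": asdict(cohort), "pipeline": config.to_dict()})


# ---------------------------------------------------------------------------
# Statistics

@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    f_stat: float
    p_value: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str
    all_tied: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _metric_values(table: CohortTable, metric: str, sex: str | None = None) -> np.ndarray:
    df = table.to_frame()
    if metric not in df.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if sex is not None:
        df = df[df["sex"] == sex]
    v = pd.to_numeric(df[metric], errors="coerce").to_numpy(dtype=float)
    return v[np.isfinite(v)]


def compare_sexes(table: CohortTable, metric: str) -> GroupComparison:
    """One-way ANOVA across sexes (two groups: equivalent to a t test)."""
    m = _metric_values(table, metric, "M")
    f = _metric_values(table, metric, "F")
    if m.size < 2 or f.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(m) == 0 and np.ptp(f) == 0 and m[0] == f[0]:
        fstat, p = 0.0, 1.0
    else:
        fstat, p = stats.f_oneway(m, f)
    return GroupComparison(metric=metric,
                           mean_a=float(m.mean()), sd_a=float(m.std(ddof=1)), n_a=m.size,
                           mean_b=float(f.mean()), sd_b=float(f.std(ddof=1)), n_b=f.size,
                           f_stat=float(fstat), p_value=float(min(p, 1.0)))


def wilcoxon_groups(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Rank-sum test: exact enumeration when both n <= 10 and untied,
    otherwise the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 1 or y.size < 1:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return WilcoxonResult(statistic=float(x.size * y.size / 2.0), p_value=1.0,
                              method="degenerate", all_tied=True)
    ties = np.unique(pooled).size < pooled.size
    exact = x.size <= 10 and y.size <= 10 and not ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return WilcoxonResult(statistic=float(res.statistic),
                          p_value=float(min(res.pvalue, 1.0)), method=method)


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher CI needs n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + confidence / 2.0)
    return (math.tanh(z - q * se), math.tanh(z + q * se))


def correlate(x, y) -> CorrelationResult:
    """Pearson r with 95% Fisher-z CI and two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, ci_low=math.nan, ci_high=math.nan,
                                 p_value=math.nan, n=x.size, undefined=True)
    r, p = stats.pearsonr(x, y)
    lo, hi = fisher_ci(float(r), x.size)
    return CorrelationResult(r=float(r), ci_low=lo, ci_high=hi,
                             p_value=float(p), n=x.size)


def correlate_metrics(table: CohortTable, x_metric: str, y_metric: str) -> CorrelationResult:
    df = table.to_frame()
    return correlate(pd.to_numeric(df[x_metric], errors="coerce"),
                     pd.to_numeric(df[y_metric], errors="coerce"))


def regress(x, y) -> RegressionResult:
    """Ordinary least squares y on x (slope, intercept, r^2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
                            n=x.size)


def regress_metrics(table: CohortTable, x_metric: str, y_metric: str) -> RegressionResult:
    df = table.to_frame()
    return regress(pd.to_numeric(df[x_metric], errors="coerce"),
                   pd.to_numeric(df[y_metric], errors="coerce"))


def volume_matched_contrast(table: CohortTable, male_max_edv: float | None = None,
                            female_min_edv: float | None = None,
                            metrics: tuple = DEFAULT_METRICS) -> dict:
    """Small-male vs large-female subgroup Wilcoxon contrasts.

    Thresholds default to the per-sex EDV medians of the table itself.  The
    EDV balance check is reported first: a valid contrast needs the two
    subgroups to span overlapping volumes.
    """
    df = table.to_frame()
    males = df[df["sex"] == "M"]
    females = df[df["sex"] == "F"]
    if males.empty or females.empty:
        raise ValueError("both sexes required")
    if male_max_edv is None:
        male_max_edv = float(males["edv_ml"].median())
    if female_min_edv is None:
        female_min_edv = float(females["edv_ml"].median())
    small_m = males[males["edv_ml"] < male_max_edv]
    large_f = females[females["edv_ml"] >= female_min_edv]
    if small_m.empty or large_f.empty:
        raise ValueError("empty volume-matched subgroup")
    out = {
        "male_max_edv": male_max_edv,
        "female_min_edv": female_min_edv,
        "n_male": int(len(small_m)),
        "n_female": int(len(large_f)),
        "tests": {},
    }
    for met in ("edv_ml", "esv_ml", "ef_pct") + tuple(metrics):
        x = pd.to_numeric(small_m[met], errors="coerce").to_numpy(dtype=float)
        y = pd.to_numeric(large_f[met], errors="coerce").to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size == 0 or y.size == 0:
            continue  # metric absent for a subgroup (e.g. flagged subjects)
        res = wilcoxon_groups(x, y)
        out["tests"][met] = {
            "male_mean": float(x.mean()), "female_mean": float(y.mean()),
            "p_value": res.p_value, "method": res.method,
        }
    return out


def build_report(table: CohortTable, metrics: tuple = DEFAULT_METRICS) -> dict:
    """Full cohort report: per-sex summaries, normal limits, correlations,
    EDV/EF regressions and the volume-matched contrast."""
    from .metrics import normal_limits

    report: dict = {"n_subjects": len(table.records), "by_sex": {}, "normal_limits": {},
                    "regressions": {}, "correlations": {}}
    if not table.records:
        report["note"] = "no subjects"
        return report
    for met in ("edv_ml", "esv_ml", "ef_pct") + tuple(metrics):
        try:
            cmp = compare_sexes(table, met)
            report["by_sex"][met] = asdict(cmp)
        except ValueError:
            continue
        vals = _metric_values(table, met)
        if vals.size >= 2:
            report["normal_limits"][met] = asdict(normal_limits(vals))
    for x_met, y_met in (("edv_ml", "psd_deg"), ("ef_pct", "psd_deg"),
                         ("edv_ml", "bandwidth_deg"), ("ef_pct", "bandwidth_deg")):
        try:
            report["regressions"][f"{y_met}~{x_met}"] = asdict(
                regress_metrics(table, x_met, y_met))
        except ValueError:
            pass
    for x_met, y_met in (("psd_deg", "bandwidth_deg"), ("psd_deg", "entropy_pct"),
                         ("bandwidth_deg", "entropy_pct")):
        try:
            report["correlations"][f"{x_met}~{y_met}"] = asdict(
                correlate_metrics(table, x_met, y_met))
        except ValueError:
            pass
    try:
        report["volume_matched"] = volume_matched_contrast(table, metrics=metrics)
    except ValueError as exc:
        report["volume_matched"] = {"error": str(exc)}
    return report
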