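"""Noncompartmental analysis of concentration-time profiles.

Model-light exposure metrics (Cmax, Tmax, Cmin, interval AUC, terminal slope,
half-life, clearance and volume of distribution), dose normalization to a
reference maintenance dose, and the day-1 versus later-days accumulation
comparison by paired t test.

Conventions
-----------
* AUC uses the linear-up / log-down trapezoid: a linear panel when the
  concentration rises (or either endpoint is zero), a logarithmic panel
  ``(C1 - C2) * dt / ln(C1/C2)`` when it falls through positive values.
* The terminal slope ``lambda_z`` is the log-linear regression over the tail
  window (all candidates of >= 3 points strictly after Tmax) that maximises
  the adjusted R-squared, ties broken toward more points.
* Quantities that cannot be estimated are reported as NaN with an explicit
  flag — never fabricated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "REFERENCE_DOSES_MG_PER_KG",
    "TerminalFit",
    "NCAResult",
    "AccumulationComparison",
    "auc_interval",
    "terminal_slope",
    "nca_summary",
    "accumulation_test",
]

#: Reference q12h maintenance doses (mg/kg) used for dose normalization:
#: the standard voriconazole maintenance dose and its 16x SBECD vehicle load.
REFERENCE_DOSES_MG_PER_KG = {
    "SBECD": 64.0,
    "voriconazole": 4.0,
    "voriconazole_N_oxide": 4.0,  # normalized to the parent dose
}


def _validate_times(times: np.ndarray) -> None:
    if times.size < 2:
        raise ValueError("at least two samples required")
    d = np.diff(times)
    if np.any(d <= 0):
        raise ValueError("times must be strictly increasing without duplicates")


def auc_interval(times: Sequence[float], concs: Sequence[float]) -> float:
    """Linear-up / log-down trapezoidal AUC (mg*hr/L) over the sampled span."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concs must have equal length")
    _validate_times(t)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    auc = 0.0
    for i in range(t.size - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c1 > c2 > 0.0:
            auc += (c1 - c2) * dt / (math.log(c1) - math.log(c2))
        else:
            auc += 0.5 * (c1 + c2) * dt
    return auc


@dataclass(frozen=True)
class TerminalFit:
    """Terminal log-linear regression result."""

    lambda_z: float  # 1/hr
    half_life: float  # hr
    n_points: int
    adj_r2: float
    intercept: float  # log concentration at t=0 of the fitted line


def terminal_slope(times: Sequence[float], concs: Sequence[float]) -> Optional[TerminalFit]:
    """Estimate the terminal elimination rate constant, or ``None``.

    Candidate windows are the last ``m`` points strictly after Tmax for every
    ``m`` from 3 up to the tail length (zero concentrations excluded).  Each
    is fit by log-linear regression; the window with maximal adjusted
    R-squared wins, ties going to the longer window.  Windows with a
    non-negative slope are discarded.  Returns ``None`` when no valid window
    exists (flat or rising tails, < 3 usable points).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concs must have equal length")
    _validate_times(t)
    i_max = int(np.argmax(c))
    tail_mask = np.arange(t.size) > i_max
    tail_mask &= c > 0
    tt, cc = t[tail_mask], np.log(c[tail_mask])
    best: Optional[TerminalFit] = None
    for m in range(3, tt.size + 1):
        x, y = tt[-m:], cc[-m:]
        fit = stats.linregress(x, y)
        if not (fit.slope < 0):
            continue
        r2 = fit.rvalue**2
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best.adj_r2 + 1e-12 or (abs(adj - best.adj_r2) <= 1e-12 and m > best.n_points):
            lam = -fit.slope
            best = TerminalFit(
                lambda_z=lam,
                half_life=math.log(2.0) / lam,
                n_points=m,
                adj_r2=adj,
                intercept=fit.intercept,
            )
    return best


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental metrics for one subject/analyte/day profile.

    Clearance and volume are per kg (the study's reporting scale); on
    non-steady-state days the clearance is apparent (dose over a
    non-steady-state interval AUC) and flagged via ``steady_state``.
    """

    cmax: float  # mg/L
    tmax: float  # hr
    cmin: float  # mg/L (trough at interval end)
    auc0_12: float  # mg*hr/L
    lambda_z: float  # 1/hr, NaN when not estimable
    half_life: float  # hr, NaN when not estimable
    cl_per_kg: float  # L/hr/kg
    vd_per_kg: float  # L/kg, NaN when lambda_z is not estimable
    dn_cmax: float
    dn_cmin: float
    dn_auc0_12: float
    dose_mg_per_kg: float
    steady_state: bool
    lambda_n_points: int
    lambda_adj_r2: float
    cmin_extrapolated: bool

    @property
    def estimable_lambda(self) -> bool:
        return np.isfinite(self.lambda_z)


def nca_summary(
    times: Sequence[float],
    concs: Sequence[float],
    dose_mg_per_kg: float,
    weight_kg: float,
    analyte: str = "SBECD",
    ref_dose_mg_per_kg: Optional[float] = None,
    at_steady_state: bool = True,
    interval_hr: float = 12.0,
    bql: Optional[Sequence[bool]] = None,
) -> NCAResult:
    """Full NCA of one dosing-interval profile.

    Parameters
    ----------
    times, concs
        Samples over one dosing interval, hr from dose start / mg/L.
    dose_mg_per_kg
        Dose administered at the start of this interval, mg/kg.
    weight_kg
        Body weight; retained for unit bookkeeping (clearance is reported
        per kg, so only the per-kg dose enters).
    ref_dose_mg_per_kg
        Reference dose for normalization; defaults to the analyte's standard
        maintenance dose (:data:`REFERENCE_DOSES_MG_PER_KG`).
    at_steady_state
        When false the reported clearance is apparent (non-steady-state).
    bql
        Below-quantification flags, aligned with ``concs`` (which then carry
        the quantification limit).  BQL samples are excluded from the
        terminal fit, counted at limit/2 inside the profile, and dropped at
        the profile edges.

    Requires a rich profile (>= 6 samples).  A missing trough at
    ``interval_hr`` is extrapolated from the terminal fit and flagged.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 6:
        raise ValueError(f"rich profile required (>= 6 samples), got {t.size}")
    _validate_times(t)
    if dose_mg_per_kg <= 0:
        raise ValueError("dose must be positive")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    flags = np.zeros(t.size, dtype=bool) if bql is None else np.asarray(bql, dtype=bool)
    if flags.shape != t.shape:
        raise ValueError("bql flags must align with samples")

    # BQL policy: halve interior flagged values for AUC, drop edge ones.
    c_auc = c.copy()
    c_auc[flags] *= 0.5
    keep = np.ones(t.size, dtype=bool)
    for idx in (0, t.size - 1):
        if flags[idx]:
            keep[idx] = False
    t_auc, c_auc = t[keep], c_auc[keep]

    quant = ~flags
    i_max = int(np.argmax(np.where(quant, c, -np.inf)))
    cmax, tmax = float(c[i_max]), float(t[i_max])

    fit = terminal_slope(t[quant], c[quant]) if quant.sum() >= 4 else None
    lam = fit.lambda_z if fit else float("nan")
    thalf = fit.half_life if fit else float("nan")

    # Trough: observed sample at the interval end, else terminal extrapolation.
    at_end = np.isclose(t, interval_hr) & quant
    cmin_extrapolated = False
    if at_end.any():
        cmin = float(c[at_end][-1])
    elif fit is not None:
        t_last, c_last = t[quant][-1], c[quant][-1]
        cmin = float(c_last * math.exp(-lam * (interval_hr - t_last)))
        cmin_extrapolated = True
        warnings.warn(
            f"no {interval_hr}-h trough sample; Cmin extrapolated from the terminal fit",
            stacklevel=2,
        )
    else:
        cmin = float("nan")
        warnings.warn("no trough sample and no terminal fit; Cmin not estimable", stacklevel=2)

    auc = auc_interval(t_auc, c_auc)
    if cmin_extrapolated and t_auc[-1] < interval_hr and np.isfinite(cmin):
        # complete the interval with a log-down panel to the extrapolated trough
        auc += auc_interval([t_auc[-1], interval_hr], [c_auc[-1], cmin])

    cl_per_kg = dose_mg_per_kg / auc if auc > 0 else float("nan")
    vd_per_kg = cl_per_kg / lam if fit else float("nan")
    ref = REFERENCE_DOSES_MG_PER_KG.get(analyte, dose_mg_per_kg) if ref_dose_mg_per_kg is None else ref_dose_mg_per_kg
    scale = ref / dose_mg_per_kg
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        cmin=cmin,
        auc0_12=auc,
        lambda_z=lam,
        half_life=thalf,
        cl_per_kg=cl_per_kg,
        vd_per_kg=vd_per_kg,
        dn_cmax=cmax * scale,
        dn_cmin=cmin * scale,
        dn_auc0_12=auc * scale,
        dose_mg_per_kg=dose_mg_per_kg,
        steady_state=at_steady_state,
        lambda_n_points=fit.n_points if fit else 0,
        lambda_adj_r2=fit.adj_r2 if fit else float("nan"),
        cmin_extrapolated=cmin_extrapolated,
    )


@dataclass(frozen=True)
class AccumulationComparison:
    """Paired day-1 versus days >= 3 comparison of a dose-normalized metric."""

    n_pairs: int
    excluded_subjects: tuple[str, ...]
    day1_mean: float
    day1_sd: float
    later_mean: float
    later_sd: float
    t_stat: float
    p_value: float
    estimable: bool


def accumulation_test(
    day1: Mapping[str, float],
    later: Mapping[str, Sequence[float]],
) -> AccumulationComparison:
    """Paired t test of a metric on day 1 versus the within-subject mean of days >= 3.

    Subjects missing either side (or with no finite values) are excluded and
    reported.  Fewer than 2 complete pairs yields a flagged, non-estimable
    result.  A comparison with identically zero differences reports t=0, P=1.
    """
    pairs, excluded = [], []
    for sid in sorted(set(day1) | set(later)):
        a = day1.get(sid, float("nan"))
        vals = [v for v in later.get(sid, []) if np.isfinite(v)]
        if not np.isfinite(a) or not vals:
            excluded.append(sid)
            continue
        pairs.append((a, float(np.mean(vals))))
    n = len(pairs)
    if n < 2:
        return AccumulationComparison(
            n_pairs=n,
            excluded_subjects=tuple(excluded),
            day1_mean=float("nan"),
            day1_sd=float("nan"),
            later_mean=float("nan"),
            later_sd=float("nan"),
            t_stat=float("nan"),
            p_value=float("nan"),
            estimable=False,
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    d = y - x
    if np.allclose(d, 0.0):
        t_stat, p_value = 0.0, 1.0
    else:
        res = stats.ttest_rel(y, x)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    return AccumulationComparison(
        n_pairs=n,
        excluded_subjects=tuple(excluded),
        day1_mean=float(x.mean()),
        day1_sd=float(x.std(ddof=1)),
        later_mean=float(y.mean()),
        later_sd=float(y.std(ddof=1)),
        t_stat=t_stat,
        p_value=p_value,
        estimable=True,
    )
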