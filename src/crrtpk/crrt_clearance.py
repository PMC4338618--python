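"""Extracorporeal clearance accounting for continuous venovenous hemofiltration.

Quantifies drug removal by the hemofilter from paired plasma/effluent
concentration profiles: the sieving coefficient (effluent/plasma ratio), the
mass of drug recovered in the effluent, the CVVH clearance (effluent mass
over plasma exposure), and the fraction of total clearance attributable to
CVVH.

The CVVH clearance estimator is deliberately the rate-over-exposure form
``CL_CVVH = recovered effluent mass / plasma AUC`` rather than ``S x Q_uf``:
it is the only estimator simultaneously consistent with reporting a percent
of dose recovered in effluent and a fraction of total clearance, and it
requires no assumption about predilution.  ``S x Q_effluent`` is exposed as a
cross-check diagnostic; the two coincide exactly when the effluent
concentration is identically ``S x`` plasma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .nca import auc_interval

__all__ = [
    "CRRTSettings",
    "SievingResult",
    "EffluentRecovery",
    "CVVHClearance",
    "sieving_coefficient",
    "effluent_mass_recovered",
    "cvvh_clearance",
    "clearance_fraction",
    "sieving_times_flow",
]


@dataclass(frozen=True)
class CRRTSettings:
    """Machine settings for one subject on CVVH.

    ``effluent`` flow — what leaves the filter and carries drug away — is the
    predilution replacement rate plus the net ultrafiltration rate.
    Predilution replacement dilutes plasma entering the filter by
    ``Q_plasma / (Q_plasma + Q_predilution)`` with
    ``Q_plasma = Q_blood * (1 - hematocrit)``.
    """

    blood_flow_ml_min: float
    predilution_ml_hr: float
    net_uf_ml_hr: float = 0.0
    hematocrit: float = 0.30
    mode: str = "CVVH"

    def __post_init__(self) -> None:
        if self.mode != "CVVH":
            raise ValueError(f"only CVVH is modelled, got {self.mode!r}")
        if self.blood_flow_ml_min <= 0:
            raise ValueError("blood flow must be positive")
        if self.predilution_ml_hr < 0 or self.net_uf_ml_hr < 0:
            raise ValueError("flows must be non-negative")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in [0, 1)")

    @property
    def effluent_ml_hr(self) -> float:
        """Total effluent flow = predilution replacement + net ultrafiltration."""
        return self.predilution_ml_hr + self.net_uf_ml_hr

    @property
    def plasma_flow_ml_hr(self) -> float:
        return self.blood_flow_ml_min * 60.0 * (1.0 - self.hematocrit)

    @property
    def predilution_factor(self) -> float:
        """Dilution of filter-inlet plasma by predilution replacement fluid (<= 1)."""
        qp = self.plasma_flow_ml_hr
        return qp / (qp + self.predilution_ml_hr)


@dataclass(frozen=True)
class SievingResult:
    """Per-timepoint effluent/plasma ratios with their median and IQR."""

    ratios: tuple[float, ...]
    median: float
    q25: float
    q75: float
    n_pairs: int
    n_skipped: int  # pairs dropped for zero plasma concentration


def sieving_coefficient(
    plasma: Sequence[float],
    effluent: Sequence[float],
) -> SievingResult:
    """Sieving coefficient from matched plasma/effluent concentrations.

    Ratios are taken as measured — not clipped at 1 (observed upper quartiles
    exceed 1) and not corrected for predilution, matching how apparent
    sieving is reported clinically.  Pairs with zero plasma concentration are
    skipped and counted.
    """
    p = np.asarray(plasma, dtype=float)
    e = np.asarray(effluent, dtype=float)
    if p.shape != e.shape:
        raise ValueError("plasma and effluent sequences must have equal length")
    if np.any(p < 0) or np.any(e < 0):
        raise ValueError("concentrations must be non-negative")
    ok = p > 0
    if not ok.any():
        raise ValueError("at least one pair with positive plasma concentration required")
    ratios = e[ok] / p[ok]
    return SievingResult(
        ratios=tuple(float(r) for r in ratios),
        median=float(np.median(ratios)),
        q25=float(np.percentile(ratios, 25)),
        q75=float(np.percentile(ratios, 75)),
        n_pairs=int(ok.sum()),
        n_skipped=int((~ok).sum()),
    )


@dataclass(frozen=True)
class EffluentRecovery:
    """Drug mass carried out in the effluent over a sampling interval."""

    mass_mg: float
    percent_of_dose: float  # NaN when no administered dose supplied


def effluent_mass_recovered(
    times: Sequence[float],
    effluent_concs: Sequence[float],
    effluent_rate_ml_hr: float,
    administered_mg: Optional[float] = None,
) -> EffluentRecovery:
    """Mass (mg) removed in effluent: flow (L/hr) x effluent concentration AUC."""
    if effluent_rate_ml_hr < 0:
        raise ValueError("effluent rate must be non-negative")
    mass = (effluent_rate_ml_hr / 1000.0) * auc_interval(times, effluent_concs)
    pct = float("nan")
    if administered_mg is not None:
        if administered_mg <= 0:
            raise ValueError("administered dose must be positive")
        pct = 100.0 * mass / administered_mg
    return EffluentRecovery(mass_mg=mass, percent_of_dose=pct)


@dataclass(frozen=True)
class CVVHClearance:
    """Extracorporeal clearance and its share of total clearance."""

    cl_L_hr: float
    cl_L_hr_kg: float


def cvvh_clearance(effluent_mass_mg: float, plasma_auc: float, weight_kg: float) -> CVVHClearance:
    """CVVH clearance = effluent mass recovered / plasma AUC over the same interval."""
    if effluent_mass_mg < 0:
        raise ValueError("effluent mass must be non-negative")
    if not plasma_auc > 0:
        raise ValueError("plasma AUC must be positive (clearance not estimable otherwise)")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    cl = effluent_mass_mg / plasma_auc
    return CVVHClearance(cl_L_hr=cl, cl_L_hr_kg=cl / weight_kg)


def clearance_fraction(cl_cvvh: float, cl_total: float) -> float:
    """Fraction of total clearance attributable to CVVH.

    Values above 1 are possible under estimation noise; they are allowed up
    to 1.05 (and flagged by callers) but rejected beyond that as physically
    inconsistent inputs.
    """
    if not cl_total > 0:
        raise ValueError("total clearance must be positive")
    if cl_cvvh < 0:
        raise ValueError("CVVH clearance must be non-negative")
    return cl_cvvh / cl_total


def sieving_times_flow(sieving: float, effluent_rate_ml_hr: float) -> float:
    """Diagnostic cross-check estimator: CL_CVVH ~= S x Q_effluent (L/hr)."""
    if sieving < 0 or effluent_rate_ml_hr < 0:
        raise ValueError("inputs must be non-negative")
    return sieving * effluent_rate_ml_hr / 1000.0
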