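"""Virtual-cohort generator emulating the study design.

Ten critically ill adults on continuous venovenous hemofiltration receive
intravenous voriconazole (6 mg/kg q12h x2 loading then 4 mg/kg q12h, 1-h
infusions) with the SBECD vehicle co-administered at 16x the voriconazole
mass.  Plasma and effluent are sampled on the study schedule (rich 9-point
profiles on days 1/3/5, a sparse 0/2/8-h day 7, trough-only thereafter).
The generator draws subject weights, CRRT settings, true PK parameters and
CYP2C19 genotypes, simulates true concentrations with the one-compartment
engine, derives effluent concentrations from apparent sieving coefficients,
applies combined proportional+additive residual error, and emits the four
pipeline tables (concentrations, doses, CRRT settings, genotypes) plus a
truth table for recovery testing.  Cohorts are bit-identical under a fixed
(config, seed).

Clearance structure
-------------------
SBECD is cleared almost exclusively by the filter, so by default
(``sbecd_clearance_model="crrt_consistent"``) each subject's total SBECD
clearance is derived from their CRRT settings:

    CL_total = S_apparent * Q_effluent / f_CVVH

with apparent sieving 0.85 and CVVH fraction 0.86.  This reproduces the
observed correlation of SBECD clearance with ultrafiltration rate and makes
the configured sieving and clearance fraction exactly recoverable from
noise-free data.  The alternative ``"independent"`` model draws SBECD
clearance from the configured log-normal (0.03 +/- 0.02 L/hr/kg) — useful
for population-recovery studies where the generating distribution must be
known in closed form — at the price of mass-balance consistency between the
sieving, flow and clearance settings.

Voriconazole is cleared hepatically; its extracorporeal removal is
parameterised by the target CVVH clearance fraction (default 0.15) and the
implied apparent sieving ``f * CL / Q_effluent`` is back-computed, because
protein binding makes a fixed sieving coefficient mechanistically wrong for
it.  The N-oxide metabolite is modelled as a one-compartment species with
clearance ``ratio x`` the parent's (so the parent/metabolite AUC ratio is the
configured ratio draw) and apparent sieving 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crrt_clearance import CRRTSettings
from .pgx import assign_phenotype
from .pk_model import PKParams, Regimen, conc_regimen, lognormal_from_moments
from .pta import MICDistribution

__all__ = [
    "AnalytePopulation",
    "CohortConfig",
    "SyntheticCohort",
    "sampling_schedule",
    "generate_cohort",
    "generate_mic_distribution",
]

RICH_SCHEDULE = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
DAY7_SCHEDULE = (0.0, 2.0, 8.0)
RICH_DAYS = (1, 3, 5)


def sampling_schedule(day: int, sparse_interval_days: int = 4) -> list[float]:
    """Sampling times (hr from that day's first dose) for a study day.

    Days 1/3/5 carry the rich 9-point grid, day 7 the sparse 0/2/8-h grid,
    and beyond day 7 a single trough sample every ``sparse_interval_days``
    days (empty list on non-sampling days).
    """
    if int(day) != day or day < 1:
        raise ValueError(f"study day must be an integer >= 1, got {day}")
    day = int(day)
    if day in RICH_DAYS:
        return list(RICH_SCHEDULE)
    if day == 7:
        return list(DAY7_SCHEDULE)
    if day > 7 and (day - 7) % sparse_interval_days == 0:
        return [0.0]
    return []


@dataclass(frozen=True)
class AnalytePopulation:
    """Arithmetic mean/SD of per-kg clearance and volume for one analyte."""

    cl_mean: float  # L/hr/kg
    cl_sd: float
    v_mean: float  # L/kg
    v_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants and population distributions for generation.

    Defaults encode the study conditions: n=10 subjects of 81 +/- 14 kg,
    voriconazole 6/4 mg/kg q12h with SBECD at 16x mass, CVVH with predilution
    replacement at 2,000/3,000/6,000 ml/hr, apparent sieving 0.85 (SBECD) and
    0.8 (N-oxide), CVVH clearance fractions 0.86 (SBECD) and 0.15
    (voriconazole), 10% proportional + 0.01 mg/L additive residual error and
    the genotype counts observed in the cohort (6x *1/*1, 2x *1/*2,
    1x *2/*17, 1x *1/*17).
    """

    n_subjects: int = 10
    seed: int = 0
    weight_mean: float = 81.0
    weight_sd: float = 14.0
    weight_bounds: tuple[float, float] = (40.0, 140.0)
    vori_pop: AnalytePopulation = AnalytePopulation(0.13, 0.06, 3.2, 1.5)
    sbecd_pop: AnalytePopulation = AnalytePopulation(0.03, 0.02, 0.3, 0.2)
    sbecd_clearance_model: str = "crrt_consistent"  # or "independent"
    noxide_auc_ratio_median: float = 2.8  # parent/metabolite AUC ratio
    noxide_auc_ratio_log_sd: float = 0.45
    noxide_v_mean: float = 2.0  # L/kg
    noxide_v_sd: float = 0.8
    sieving_sbecd: float = 0.85  # apparent (post-predilution) effluent/plasma
    sieving_noxide: float = 0.80
    cvvh_fraction_sbecd: float = 0.86
    cvvh_fraction_vori: float = 0.15
    predilution_levels: tuple[float, ...] = (2000.0, 3000.0, 6000.0)
    predilution_probs: tuple[float, ...] = (0.4, 0.4, 0.2)
    blood_flow_bounds: tuple[float, float] = (200.0, 300.0)
    net_uf_bounds: tuple[float, float] = (50.0, 250.0)
    hematocrit: float = 0.30
    vori_loading_mg_per_kg: float = 6.0
    vori_maintenance_mg_per_kg: float = 4.0
    n_loading: int = 2
    sbecd_mass_ratio: float = 16.0
    interval_hr: float = 12.0
    infusion_hr: float = 1.0
    n_days: int = 7
    prop_sd: float = 0.10
    add_sd: float = 0.01  # mg/L
    lloq_mg_L: float = 0.05
    genotype_counts: tuple[tuple[str, str, int], ...] = (
        ("*1", "*1", 6),
        ("*1", "*2", 2),
        ("*2", "*17", 1),
        ("*1", "*17", 1),
    )
    sparse_interval_days: int = 4

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sbecd_clearance_model not in ("crrt_consistent", "independent"):
            raise ValueError(
                "sbecd_clearance_model must be 'crrt_consistent' or 'independent'"
            )
        if abs(sum(self.predilution_probs) - 1.0) > 1e-9:
            raise ValueError("predilution probabilities must sum to 1")
        if len(self.predilution_probs) != len(self.predilution_levels):
            raise ValueError("predilution levels and probabilities must align")
        for name in ("prop_sd", "add_sd", "weight_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.cvvh_fraction_sbecd <= 1 and 0 < self.cvvh_fraction_vori <= 1):
            raise ValueError("CVVH clearance fractions must lie in (0, 1]")

    def noise_free(self) -> "CohortConfig":
        """Copy with residual error switched off (observations on the model)."""
        return replace(self, prop_sd=0.0, add_sd=0.0)


@dataclass
class SyntheticCohort:
    """A generated cohort: truth, design tables and observations."""

    config: CohortConfig
    seed: int
    subjects: pd.DataFrame  # truth table, one row per subject
    observations: pd.DataFrame  # plasma + effluent samples, long format
    doses: pd.DataFrame
    crrt: pd.DataFrame
    genotypes: pd.DataFrame
    regimens: dict  # (subject_id, analyte) -> Regimen

    def write(self, out_dir) -> dict[str, Path]:
        """Write the pipeline CSVs; returns the paths keyed by table name."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        demo = self.subjects[["subject_id", "weight_kg"]]
        for name, df in [
            ("concentrations", self.observations),
            ("doses", self.doses),
            ("crrt_settings", self.crrt),
            ("genotypes", self.genotypes),
            ("subjects", demo),
            ("truth", self.subjects),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _genotype_list(config: CohortConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    pool = [(a1, a2) for a1, a2, n in config.genotype_counts for _ in range(n)]
    total = sum(n for _, _, n in config.genotype_counts)
    if config.n_subjects == total:
        idx = rng.permutation(total)
        return [pool[i] for i in idx]
    probs = np.array([n / total for _, _, n in config.genotype_counts])
    picks = rng.choice(len(config.genotype_counts), size=config.n_subjects, p=probs)
    return [(config.genotype_counts[i][0], config.genotype_counts[i][1]) for i in picks]


def generate_cohort(config: Optional[CohortConfig] = None, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a synthetic cohort under ``config`` (seed overrides config.seed)."""
    config = config or CohortConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    weights = _truncnorm(
        rng, config.weight_mean, config.weight_sd, *config.weight_bounds, size=n
    ) if config.weight_sd > 0 else np.full(n, config.weight_mean)
    genotypes = _genotype_list(config, rng)

    subj_rows, obs_rows, dose_rows, crrt_rows, geno_rows = [], [], [], [], []
    regimens: dict = {}
    sample_days = [d for d in range(1, config.n_days + 1) if sampling_schedule(d, config.sparse_interval_days)]
    n_doses = 2 * config.n_days  # q12h through the horizon

    for i in range(n):
        sid = f"S{i + 1:02d}"
        w = float(weights[i])
        # --- CRRT settings ---
        predil = float(rng.choice(config.predilution_levels, p=config.predilution_probs))
        qb = float(rng.uniform(*config.blood_flow_bounds))
        net_uf = float(rng.uniform(*config.net_uf_bounds))
        settings = CRRTSettings(
            blood_flow_ml_min=qb,
            predilution_ml_hr=predil,
            net_uf_ml_hr=net_uf,
            hematocrit=config.hematocrit,
        )
        q_eff_L_hr = settings.effluent_ml_hr / 1000.0

        # --- true PK parameters (absolute) ---
        def ln_draw(mean, sd):
            mu, s = lognormal_from_moments(mean, sd)
            return float(rng.lognormal(mu, s)) if s > 0 else mean

        cl_vori = ln_draw(config.vori_pop.cl_mean, config.vori_pop.cl_sd) * w
        v_vori = ln_draw(config.vori_pop.v_mean, config.vori_pop.v_sd) * w
        v_sbecd = ln_draw(config.sbecd_pop.v_mean, config.sbecd_pop.v_sd) * w
        cl_sbecd_indep = ln_draw(config.sbecd_pop.cl_mean, config.sbecd_pop.cl_sd) * w
        if config.sbecd_clearance_model == "crrt_consistent":
            cl_sbecd = config.sieving_sbecd * q_eff_L_hr / config.cvvh_fraction_sbecd
        else:
            cl_sbecd = cl_sbecd_indep
        ratio = float(
            rng.lognormal(math.log(config.noxide_auc_ratio_median), config.noxide_auc_ratio_log_sd)
        )
        cl_nox = ratio * cl_vori
        v_nox = ln_draw(config.noxide_v_mean, config.noxide_v_sd) * w

        sieving_vori = config.cvvh_fraction_vori * cl_vori / q_eff_L_hr
        sieving = {
            "SBECD": config.sieving_sbecd,
            "voriconazole": sieving_vori,
            "voriconazole_N_oxide": config.sieving_noxide,
        }
        params = {
            "SBECD": PKParams(cl_sbecd, v_sbecd),
            "voriconazole": PKParams(cl_vori, v_vori),
            "voriconazole_N_oxide": PKParams(cl_nox, v_nox),
        }

        # --- regimens: voriconazole and its 16x SBECD vehicle load ---
        vori_reg = Regimen.intermittent(
            config.vori_maintenance_mg_per_kg,
            w,
            interval_hr=config.interval_hr,
            infusion_hr=config.infusion_hr,
            n_doses=n_doses,
            n_loading=config.n_loading,
            loading_mg_per_kg=config.vori_loading_mg_per_kg,
            analyte="voriconazole",
        )
        sbecd_reg = Regimen(
            events=tuple(
                ev.__class__("SBECD", ev.amount * config.sbecd_mass_ratio, ev.start, ev.duration)
                for ev in vori_reg.events
            ),
            tau=vori_reg.tau,
        )
        # the metabolite is driven by the parent dose (complete conversion,
        # exposure set by its clearance ratio); shape approximation documented
        nox_reg = Regimen(
            events=tuple(
                ev.__class__("voriconazole_N_oxide", ev.amount, ev.start, ev.duration)
                for ev in vori_reg.events
            ),
            tau=vori_reg.tau,
        )
        regimens[(sid, "voriconazole")] = vori_reg
        regimens[(sid, "SBECD")] = sbecd_reg
        regimens[(sid, "voriconazole_N_oxide")] = nox_reg
        for reg in (vori_reg, sbecd_reg):
            for ev in reg.events:
                dose_rows.append(
                    {
                        "subject_id": sid,
                        "analyte": ev.analyte,
                        "amount_mg": ev.amount,
                        "start_hr": ev.start,
                        "duration_hr": ev.duration,
                        "tau_hr": reg.tau,
                    }
                )

        # --- observations ---
        for day in sample_days:
            sched = sampling_schedule(day, config.sparse_interval_days)
            abs_times = np.array([(day - 1) * 24.0 + t for t in sched])
            for analyte in ("SBECD", "voriconazole", "voriconazole_N_oxide"):
                true_plasma = conc_regimen(abs_times, regimens[(sid, analyte)], params[analyte])
                true_effluent = sieving[analyte] * true_plasma
                for matrix, true_c in (("plasma", true_plasma), ("effluent", true_effluent)):
                    sd = np.sqrt((config.prop_sd * true_c) ** 2 + config.add_sd**2)
                    noise = sd * rng.standard_normal(true_c.size) if (config.prop_sd or config.add_sd) else 0.0
                    obs = np.maximum(true_c + noise, 0.0)
                    for t_rel, c_obs in zip(sched, obs):
                        bql = c_obs < config.lloq_mg_L
                        obs_rows.append(
                            {
                                "subject_id": sid,
                                "study_day": day,
                                "time_hr": t_rel,
                                "analyte": analyte,
                                "matrix": matrix,
                                "conc_mg_L": config.lloq_mg_L if bql else float(c_obs),
                                "bql": bool(bql),
                            }
                        )

        crrt_rows.append(
            {
                "subject_id": sid,
                "blood_flow_ml_min": qb,
                "predilution_ml_hr": predil,
                "net_uf_ml_hr": net_uf,
                "hematocrit": config.hematocrit,
            }
        )
        a1, a2 = genotypes[i]
        geno_rows.append({"subject_id": sid, "allele1": a1, "allele2": a2})
        subj_rows.append(
            {
                "subject_id": sid,
                "weight_kg": w,
                "allele1": a1,
                "allele2": a2,
                "phenotype": assign_phenotype(a1, a2),
                "cl_sbecd_L_hr": cl_sbecd,
                "v_sbecd_L": v_sbecd,
                "cl_vori_L_hr": cl_vori,
                "v_vori_L": v_vori,
                "cl_noxide_L_hr": cl_nox,
                "v_noxide_L": v_nox,
                "noxide_auc_ratio": ratio,
                "sieving_sbecd_apparent": config.sieving_sbecd,
                "sieving_vori_apparent": sieving_vori,
                "sieving_noxide_apparent": config.sieving_noxide,
                "membrane_sieving_sbecd": config.sieving_sbecd / settings.predilution_factor,
                "cvvh_fraction_sbecd": config.sieving_sbecd * q_eff_L_hr / cl_sbecd,
                "cvvh_fraction_vori": config.cvvh_fraction_vori,
                "predilution_ml_hr": predil,
                "blood_flow_ml_min": qb,
                "net_uf_ml_hr": net_uf,
                "effluent_ml_hr": settings.effluent_ml_hr,
                "predilution_factor": settings.predilution_factor,
            }
        )

    return SyntheticCohort(
        config=config,
        seed=seed,
        subjects=pd.DataFrame(subj_rows),
        observations=pd.DataFrame(obs_rows),
        doses=pd.DataFrame(dose_rows),
        crrt=pd.DataFrame(crrt_rows),
        genotypes=pd.DataFrame(geno_rows),
        regimens=regimens,
    )


def generate_mic_distribution(
    organism: str,
    modal_mic: float,
    log2_spread: float,
    n_isolates: int,
    seed: Optional[int] = None,
    source: str = "synthetic",
    half_width: int = 5,
) -> MICDistribution:
    """Synthesise a two-fold-grid MIC frequency table.

    Counts follow a multinomial draw over grid points within ``half_width``
    dilutions of the modal MIC, weighted by a normal density on the log2
    scale with SD ``log2_spread`` (``0`` puts every isolate at the mode).
    Stands in for reference susceptibility-database tallies, which are not
    redistributable.
    """
    l = math.log2(modal_mic)
    if abs(l - round(l)) > 1e-6:
        raise ValueError(f"modal MIC {modal_mic} is not on the two-fold dilution grid")
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    if log2_spread < 0:
        raise ValueError("log2_spread must be non-negative")
    center = int(round(l))
    if log2_spread == 0:
        return MICDistribution(organism, source, (float(2.0**center),), (float(n_isolates),))
    grid = np.arange(center - half_width, center + half_width + 1)
    weights = np.exp(-0.5 * ((grid - center) / log2_spread) ** 2)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_isolates, weights)
    keep = counts > 0
    return MICDistribution(
        organism,
        source,
        tuple(float(2.0**g) for g in grid[keep]),
        tuple(float(c) for c in counts[keep]),
    )
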