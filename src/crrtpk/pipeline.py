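"""End-to-end orchestration: simulate -> NCA -> CRRT -> pop-PK -> PTA -> PGx.

Every stage consumes and emits delimited text; a run log records the seed,
a hash of the configuration and the package version so each emitted number
is traceable to its inputs.  Stage failures propagate as
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crrt_clearance import (
    CRRTSettings,
    cvvh_clearance,
    effluent_mass_recovered,
    sieving_coefficient,
)
from .io import (
    read_concentrations,
    read_crrt_settings,
    read_genotypes,
    read_mic_table,
    read_doses,
    read_subjects,
    regimens_from_doses,
)
from .nca import accumulation_test, auc_interval, nca_summary
from .pgx import assign_phenotype, metabolite_ratios, phenotype_comparison
from .pk_model import Regimen
from .poppk import fit_subject, pool_population, stratum_envelope
from .pta import PTAConfig, pta_table
from .synthetic_data import (
    RICH_DAYS,
    CohortConfig,
    generate_cohort,
    generate_mic_distribution,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_mic_distributions"]

log = logging.getLogger("crrtpk")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    With ``input_dir`` unset, a synthetic cohort is generated into
    ``out_dir/inputs`` first; otherwise the four pipeline CSVs are read from
    ``input_dir``.
    """

    out_dir: str = "crrtpk_out"
    input_dir: Optional[str] = None
    seed: int = 0
    n_subjects: int = 10
    noise_free: bool = False
    pta_n_sim: int = 1000
    pta_doses: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0)
    pta_targets: tuple[float, ...] = (25.0, 35.0)
    mic_csv: Optional[str] = None
    envelope_n_sim: int = 500
    run_pgx: bool = True
    run_pta: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pta_doses", "pta_targets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def default_mic_distributions(seed: int = 0):
    """Synthetic MIC frequency tables for the study organisms.

    Modal MICs sit at field-typical two-fold grid points (wild-type modes:
    susceptible *Candida* well below 0.5 mg/L, *C. glabrata* and the molds
    around 0.25-1 mg/L) with about one dilution of spread; counts are
    multinomial draws, standing in for reference-database tallies that are
    not redistributable.
    """
    specs = [
        ("C. albicans", 0.03125, 1.0, 3000),
        ("C. glabrata", 0.5, 1.2, 2000),
        ("C. krusei", 0.5, 0.8, 800),
        ("C. parapsilosis", 0.0625, 1.0, 1500),
        ("C. tropicalis", 0.0625, 1.0, 1200),
        ("A. fumigatus", 0.5, 0.8, 1000),
        ("A. niger", 1.0, 0.8, 400),
        ("A. terreus", 0.5, 0.8, 300),
    ]
    ss = np.random.SeedSequence(seed).spawn(len(specs))
    return [
        generate_mic_distribution(org, mode, spread, n, seed=child, source="synthetic")
        for (org, mode, spread, n), child in zip(specs, ss)
    ]


def _interval_dose(doses: pd.DataFrame, sid: str, analyte: str, day: int) -> Optional[float]:
    """Dose (mg) started at the beginning of study day ``day``'s interval."""
    start = (day - 1) * 24.0
    sel = doses[
        (doses["subject_id"] == sid)
        & (doses["analyte"] == analyte)
        & (np.isclose(doses["start_hr"], start))
    ]
    return float(sel["amount_mg"].iloc[0]) if len(sel) else None


def _nca_stage(conc: pd.DataFrame, doses: pd.DataFrame, weights: dict) -> dict:
    """Per subject/analyte/rich-day NCA plus summaries and accumulation tests."""
    rows = []
    plasma = conc[conc["matrix"] == "plasma"]
    for (sid, analyte, day), grp in plasma.groupby(["subject_id", "analyte", "study_day"], sort=True):
        if day not in RICH_DAYS or len(grp) < 6:
            continue
        dose_analyte = "voriconazole" if analyte == "voriconazole_N_oxide" else analyte
        dose_mg = _interval_dose(doses, sid, dose_analyte, int(day))
        if dose_mg is None:
            continue
        w = weights[sid]
        grp = grp.sort_values("time_hr")
        res = nca_summary(
            grp["time_hr"].to_numpy(),
            grp["conc_mg_L"].to_numpy(),
            dose_mg_per_kg=dose_mg / w,
            weight_kg=w,
            analyte=analyte,
            at_steady_state=day >= 3,
            bql=grp["bql"].to_numpy(),
        )
        rows.append(
            {
                "subject_id": sid,
                "analyte": analyte,
                "study_day": int(day),
                "cmax_mg_L": res.cmax,
                "tmax_hr": res.tmax,
                "cmin_mg_L": res.cmin,
                "auc0_12_mg_hr_L": res.auc0_12,
                "lambda_z_1_hr": res.lambda_z,
                "t_half_hr": res.half_life,
                "cl_L_hr_kg": res.cl_per_kg,
                "vd_L_kg": res.vd_per_kg,
                "dn_cmax_mg_L": res.dn_cmax,
                "dn_cmin_mg_L": res.dn_cmin,
                "dn_auc0_12_mg_hr_L": res.dn_auc0_12,
                "dose_mg_per_kg": res.dose_mg_per_kg,
                "steady_state": res.steady_state,
                "lambda_n_points": res.lambda_n_points,
                "lambda_adj_r2": res.lambda_adj_r2,
                "cmin_extrapolated": res.cmin_extrapolated,
            }
        )
    results = pd.DataFrame(rows)

    # steady-state summary (days >= 3), one block per analyte
    metrics = ["cmax_mg_L", "cmin_mg_L", "t_half_hr", "auc0_12_mg_hr_L", "cl_L_hr_kg", "vd_L_kg"]
    summaries = []
    if len(results):
        ss = results[results["steady_state"]]
        per_subject = ss.groupby(["analyte", "subject_id"])[metrics].mean().reset_index()
        for analyte, grp in per_subject.groupby("analyte"):
            for stat, fn in [
                ("mean", np.mean),
                ("sd", lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0),
                ("median", np.median),
                ("q25", lambda v: np.percentile(v, 25)),
                ("q75", lambda v: np.percentile(v, 75)),
            ]:
                row = {"analyte": analyte, "statistic": stat}
                for m in metrics:
                    vals = grp[m].dropna().to_numpy()
                    row[m] = fn(vals) if len(vals) else np.nan
                summaries.append(row)
    summary = pd.DataFrame(summaries)

    # day-1 vs days >= 3 accumulation comparison, dose-normalized metrics
    acc_rows = []
    if len(results):
        for analyte, grp in results.groupby("analyte"):
            for metric in ("dn_cmax_mg_L", "dn_cmin_mg_L", "dn_auc0_12_mg_hr_L"):
                day1 = {
                    r.subject_id: getattr(r, metric)
                    for r in grp[grp["study_day"] == 1].itertuples()
                }
                later: dict[str, list] = {}
                for r in grp[grp["study_day"] >= 3].itertuples():
                    later.setdefault(r.subject_id, []).append(getattr(r, metric))
                cmp_res = accumulation_test(day1, later)
                acc_rows.append(
                    {
                        "analyte": analyte,
                        "metric": metric,
                        "n_pairs": cmp_res.n_pairs,
                        "day1_mean": cmp_res.day1_mean,
                        "day1_sd": cmp_res.day1_sd,
                        "later_mean": cmp_res.later_mean,
                        "later_sd": cmp_res.later_sd,
                        "t_stat": cmp_res.t_stat,
                        "p_value": cmp_res.p_value,
                        "estimable": cmp_res.estimable,
                    }
                )
    return {"nca_results": results, "nca_summary": summary, "accumulation": pd.DataFrame(acc_rows)}


def _crrt_stage(
    conc: pd.DataFrame,
    doses: pd.DataFrame,
    crrt: pd.DataFrame,
    weights: dict,
    nca_results: pd.DataFrame,
) -> dict:
    """Sieving, effluent recovery and CVVH clearance per subject/analyte."""
    settings = {
        r.subject_id: CRRTSettings(
            blood_flow_ml_min=r.blood_flow_ml_min,
            predilution_ml_hr=r.predilution_ml_hr,
            net_uf_ml_hr=r.net_uf_ml_hr,
            hematocrit=r.hematocrit,
        )
        for r in crrt.itertuples()
    }
    rows = []
    for (sid, analyte), grp in conc.groupby(["subject_id", "analyte"], sort=True):
        if sid not in settings:
            continue
        st = settings[sid]
        wide = grp.pivot_table(
            index=["study_day", "time_hr"], columns="matrix", values="conc_mg_L"
        )
        if "plasma" not in wide or "effluent" not in wide:
            continue
        wide = wide.dropna()
        if wide.empty or not (wide["plasma"] > 0).any():
            continue
        siv = sieving_coefficient(wide["plasma"].to_numpy(), wide["effluent"].to_numpy())

        mass = 0.0
        plasma_auc = 0.0
        dose_total = 0.0
        dose_analyte = "voriconazole" if analyte == "voriconazole_N_oxide" else analyte
        for day in RICH_DAYS:
            if day not in wide.index.get_level_values(0):
                continue
            sub = wide.loc[day]
            if len(sub) < 2:
                continue
            t = sub.index.to_numpy(dtype=float)
            mass += effluent_mass_recovered(t, sub["effluent"].to_numpy(), st.effluent_ml_hr).mass_mg
            plasma_auc += auc_interval(t, sub["plasma"].to_numpy())
            d = _interval_dose(doses, sid, dose_analyte, day)
            dose_total += d if d is not None else 0.0
        if plasma_auc <= 0:
            continue
        w = weights[sid]
        cl = cvvh_clearance(mass, plasma_auc, w)
        # total clearance from the subject's steady-state NCA
        ss = nca_results[
            (nca_results["subject_id"] == sid)
            & (nca_results["analyte"] == analyte)
            & nca_results["steady_state"]
        ]["cl_L_hr_kg"].dropna()
        cl_total = float(ss.mean()) * w if len(ss) else np.nan
        frac = cl.cl_L_hr / cl_total if np.isfinite(cl_total) and cl_total > 0 else np.nan
        rows.append(
            {
                "subject_id": sid,
                "analyte": analyte,
                "sieving_median": siv.median,
                "sieving_q25": siv.q25,
                "sieving_q75": siv.q75,
                "n_pairs": siv.n_pairs,
                "effluent_mass_mg": mass,
                "percent_dose_recovered": 100.0 * mass / dose_total if dose_total > 0 else np.nan,
                "cl_cvvh_L_hr": cl.cl_L_hr,
                "cl_cvvh_L_hr_kg": cl.cl_L_hr_kg,
                "cl_total_L_hr": cl_total,
                "fraction_of_total": frac,
                "fraction_flagged": bool(np.isfinite(frac) and frac > 1.0),
                "effluent_ml_hr": st.effluent_ml_hr,
            }
        )
    per_subject = pd.DataFrame(rows)
    summ_rows = []
    if len(per_subject):
        for analyte, grp in per_subject.groupby("analyte"):
            summ_rows.append(
                {
                    "analyte": analyte,
                    "sieving_cohort_median": float(grp["sieving_median"].median()),
                    "fraction_cohort_median": float(grp["fraction_of_total"].median()),
                    "percent_dose_recovered_median": float(grp["percent_dose_recovered"].median()),
                    "n_subjects": len(grp),
                }
            )
    return {"crrt_clearance": per_subject, "crrt_summary": pd.DataFrame(summ_rows)}


def _poppk_stage(
    conc: pd.DataFrame,
    doses: pd.DataFrame,
    crrt: pd.DataFrame,
    out_dir: Path,
    envelope_n_sim: int,
    seed: int,
) -> dict:
    """Two-stage SBECD population fit and per-stratum simulation envelopes."""
    regimens = regimens_from_doses(doses)
    plasma = conc[(conc["matrix"] == "plasma") & (conc["analyte"] == "SBECD") & (~conc["bql"])]
    fits = []
    for sid, grp in plasma.groupby("subject_id", sort=True):
        reg = regimens.get((sid, "SBECD"))
        if reg is None or len(grp) < 4:
            continue
        t_abs = (grp["study_day"].to_numpy() - 1) * 24.0 + grp["time_hr"].to_numpy()
        fits.append(fit_subject(sid, t_abs, grp["conc_mg_L"].to_numpy(), reg))
    strata = {r.subject_id: f"{r.predilution_ml_hr:g}" for r in crrt.itertuples()}
    estimates = pool_population(fits, strata)

    fits_df = pd.DataFrame(
        [
            {
                "subject_id": f.subject_id,
                "cl_L_hr": f.clearance,
                "v_L": f.volume,
                "residual_sd": f.residual_sd,
                "objective": f.objective,
                "n_iter": f.n_iter,
                "success": f.success,
            }
            for f in fits
        ]
    )
    est_df = pd.DataFrame(
        [
            {
                "stratum": e.label,
                "n": e.n,
                "log_cl_mean": e.log_cl_mean,
                "log_cl_sd": e.log_cl_sd,
                "log_v_mean": e.log_v_mean,
                "log_v_sd": e.log_v_sd,
                "residual_sd": e.residual_sd,
            }
            for e in estimates
        ]
    )
    # simulation regimen: the standard SBECD administration for an 80-kg adult
    sim_reg = Regimen.intermittent(
        64.0, 80.0, n_doses=14, n_loading=2, loading_mg_per_kg=96.0, analyte="SBECD"
    )
    envelopes = {}
    for i, est in enumerate(estimates):
        env = stratum_envelope(est, sim_reg, n_sim=envelope_n_sim, seed=seed + i)
        envelopes[est.label] = env
        env.to_csv(out_dir / f"envelope_{est.label}.csv", index=False)
    return {"poppk_fits": fits_df, "poppk_strata": est_df, "envelopes": envelopes}


def _pgx_stage(conc: pd.DataFrame, genotypes: pd.DataFrame, nca_results: pd.DataFrame) -> dict:
    """Phenotype assignment, metabolite ratios and phenotype-stratified stats."""
    pheno = {
        r.subject_id: assign_phenotype(r.allele1, r.allele2) for r in genotypes.itertuples()
    }
    pheno_df = pd.DataFrame(
        [{"subject_id": s, "phenotype": p} for s, p in sorted(pheno.items())]
    )
    ss = nca_results[nca_results["steady_state"]]
    per_subject = (
        ss.groupby(["subject_id", "analyte"])[["t_half_hr", "auc0_12_mg_hr_L", "cmax_mg_L"]]
        .mean()
        .reset_index()
    )
    ratio_rows = []
    for sid in sorted(pheno):
        sub = per_subject[per_subject["subject_id"] == sid].set_index("analyte")
        if {"voriconazole", "voriconazole_N_oxide"} <= set(sub.index):
            parent = sub.loc["voriconazole"]
            metab = sub.loc["voriconazole_N_oxide"]
            ratios = metabolite_ratios(
                parent["auc0_12_mg_hr_L"], parent["cmax_mg_L"],
                metab["auc0_12_mg_hr_L"], metab["cmax_mg_L"],
            )
            ratio_rows.append(
                {
                    "subject_id": sid,
                    "phenotype": pheno[sid],
                    "auc_ratio": ratios.auc_ratio if ratios else np.nan,
                    "cmax_ratio": ratios.cmax_ratio if ratios else np.nan,
                }
            )
    comp_rows = []
    vori = per_subject[per_subject["analyte"] == "voriconazole"]
    for metric in ("t_half_hr", "auc0_12_mg_hr_L", "cmax_mg_L"):
        vals, labels = [], []
        for r in vori.itertuples():
            if r.subject_id in pheno and np.isfinite(getattr(r, metric)):
                vals.append(getattr(r, metric))
                labels.append(pheno[r.subject_id])
        if not vals:
            continue
        summ = phenotype_comparison(vals, labels)
        row = {"metric": metric, "f_stat": summ.f_stat, "p_value": summ.p_value}
        for g, m in summ.group_means.items():
            row[f"mean_{g}"] = m
            row[f"n_{g}"] = summ.group_ns[g]
        comp_rows.append(row)
    return {
        "phenotypes": pheno_df,
        "metabolite_ratios": pd.DataFrame(ratio_rows),
        "phenotype_comparison": pd.DataFrame(comp_rows),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the table bundle and writes CSVs + run log."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict = {}

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must propagate
            raise PipelineError(name, exc) from exc

    if config.input_dir is None:
        def _simulate():
            cc = CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
            if config.noise_free:
                cc = cc.noise_free()
            cohort = generate_cohort(cc)
            cohort.write(out_dir / "inputs")
            return cohort
        cohort = stage("simulate", _simulate)
        input_dir = out_dir / "inputs"
    else:
        input_dir = Path(config.input_dir)

    def _read():
        return {
            "concentrations": read_concentrations(input_dir / "concentrations.csv"),
            "doses": read_doses(input_dir / "doses.csv"),
            "crrt": read_crrt_settings(input_dir / "crrt_settings.csv"),
            "subjects": read_subjects(input_dir / "subjects.csv"),
        }

    inputs = stage("read", _read)
    conc, doses = inputs["concentrations"], inputs["doses"]
    weights = {r.subject_id: float(r.weight_kg) for r in inputs["subjects"].itertuples()}

    tables.update(stage("nca", lambda: _nca_stage(conc, doses, weights)))
    tables.update(
        stage(
            "crrt",
            lambda: _crrt_stage(conc, doses, inputs["crrt"], weights, tables["nca_results"]),
        )
    )
    tables.update(
        stage(
            "poppk",
            lambda: _poppk_stage(
                conc, doses, inputs["crrt"], out_dir, config.envelope_n_sim, config.seed
            ),
        )
    )
    if config.run_pta:
        def _pta():
            dists = (
                read_mic_table(config.mic_csv)
                if config.mic_csv
                else default_mic_distributions(config.seed)
            )
            pcfg = PTAConfig(
                doses=tuple(config.pta_doses),
                targets=tuple(config.pta_targets),
                n_sim=config.pta_n_sim,
            )
            return {"pta_table": pta_table(dists, pcfg, seed=config.seed)}
        tables.update(stage("pta", _pta))
    if config.run_pgx:
        geno_path = input_dir / "genotypes.csv"
        if geno_path.exists():
            tables.update(
                stage(
                    "pgx",
                    lambda: _pgx_stage(conc, read_genotypes(geno_path), tables["nca_results"]),
                )
            )
        else:
            log.warning("genotypes.csv absent; skipping pgx stage")

    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out_dir / f"{name}.csv", index=False)
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "tables": sorted(k for k, v in tables.items() if isinstance(v, pd.DataFrame)),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    tables["run_log"] = run_log
    return tables
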