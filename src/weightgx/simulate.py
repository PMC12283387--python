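"""Seeded synthetic multi-study biobank data generator.

Real weight-loss pharmacogenomics data live behind gated biobank access,
so the pipeline is exercised on simulated data with the same structure:
persons with sex/age/ancestry/study labels, 20 genetic principal
components and T2D status; irregular longitudinal weight measurements
around a treatment start; GLP1-RA purchase/refill chains that either
persist for 12 months or truncate early; bariatric procedures; per-
ancestry Hardy-Weinberg SNP dosages for the candidate registry; and
standard-normal polygenic scores with configurable effects on baseline
weight, T2D liability and treatment response.

Generative model, per person:

* true baseline weight  W = b0 + b_sex·female + b_age·(age − 55)
  + Σ b_e·exposure_e + N(0, σ_W);
* target percentage change  Δ% = m_arm + c_W·(W − 100) + c_sex·female
  + c_age·(age − 55) + Σ c_e·exposure_e + N(0, σ_Δ)
  (coefficients per arm, exposures as dosages or PGS s.d. units);
* post-treatment trajectory: exponential approach to the target,
  weight(t) = W·(1 + Δ%/100·(1 − 2^(−t/half-life))), so that
  median-of-window and minimum-of-window outcomes genuinely differ;
* measurements: Poisson counts per window, uniform times, i.i.d.
  Gaussian measurement noise added to the true weight.

Identical (seed, config) pairs produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import REGISTRY

__all__ = [
    "StudySpec",
    "BaselineWeightModel",
    "ResponseModel",
    "VisitProcess",
    "SimConfig",
    "DEFAULT_SNP_MAFS",
    "simulate_study",
    "simulate_dosages",
    "write_tables",
    "config_from_dict",
]

ANCESTRIES = ("EUR", "AFR", "AMR", "EAS", "SAS", "MID")
PROCEDURE_TYPES = ("RYGB", "SG", "AGB", "VBG", "BPD-DS")
SNP_IDS = tuple(e.exposure_id for e in REGISTRY if e.kind == "snp")
PGS_IDS = tuple(e.exposure_id for e in REGISTRY if e.kind == "pgs")

# Default per-ancestry minor allele frequencies for the candidate SNPs.
# Common missense/functional variants get moderate frequencies; the two
# variants that were too rare to analyze get sub-percent frequencies.
_COMMON = {"EUR": 0.25, "AFR": 0.20, "AMR": 0.22, "EAS": 0.18, "SAS": 0.24, "MID": 0.23}
_LOWFREQ = {"EUR": 0.03, "AFR": 0.02, "AMR": 0.03, "EAS": 0.01, "SAS": 0.02, "MID": 0.02}
_RARE = {"EUR": 0.002, "AFR": 0.001, "AMR": 0.002, "EAS": 0.001, "SAS": 0.001, "MID": 0.002}
DEFAULT_SNP_MAFS: dict[str, dict[str, float]] = {
    "rs10305492": dict(_LOWFREQ),
    "rs146868158": dict(_RARE) | {"EUR": 0.01},
    "rs6923761": dict(_COMMON),
    "rs1042044": dict(_COMMON) | {"EUR": 0.45, "AFR": 0.35},
    "rs10305420": dict(_COMMON),
    "rs3765467": dict(_LOWFREQ) | {"EAS": 0.25},
    "rs10305421": dict(_LOWFREQ),
    "rs2295006": dict(_RARE),
    "rs10305510": dict(_LOWFREQ) | {"AFR": 0.12},
    "rs201672448": dict(_RARE),
    "rs6232": dict(_LOWFREQ),
    "rs6235": dict(_COMMON),
    "rs429358": {"EUR": 0.15, "AFR": 0.21, "AMR": 0.12, "EAS": 0.09, "SAS": 0.09, "MID": 0.12},
    "rs728996": dict(_COMMON),
    "rs17702901": dict(_LOWFREQ) | {"EUR": 0.08},
}


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    ancestry_mix: Mapping[str, float]
    n_individuals: int


@dataclass(frozen=True)
class BaselineWeightModel:
    """True baseline weight in kg for a 55-year-old male of reference genotype."""

    intercept_kg: float = 108.0
    sex_female_kg: float = -8.0
    age_kg_per_year: float = -0.10
    exposure_kg: Mapping[str, float] = field(default_factory=lambda: {"PGS_BMI": 2.5})
    residual_sd_kg: float = 18.0


@dataclass(frozen=True)
class ResponseModel:
    """Target percentage weight change; covariates centered at 100 kg / 55 y."""

    mean_pct: Mapping[str, float] = field(default_factory=lambda: {"glp1": -3.93, "bs": -21.17})
    baseline_pct_per_kg: Mapping[str, float] = field(default_factory=lambda: {"glp1": -0.05, "bs": -0.14})
    sex_female_pct: Mapping[str, float] = field(default_factory=lambda: {"glp1": -1.54, "bs": -2.66})
    age_pct_per_year: Mapping[str, float] = field(default_factory=lambda: {"glp1": -0.02, "bs": 0.15})
    exposure_pct: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"PGS_BMI": {"glp1": 0.0, "bs": 0.70}}
    )
    between_sd_pct: float = 7.8
    # short enough that the plateau is essentially reached by the start of
    # each arm's outcome window, so regression recovers the injected
    # coefficients without attenuation from a still-moving trajectory
    half_life_days: Mapping[str, float] = field(default_factory=lambda: {"glp1": 60.0, "bs": 75.0})


@dataclass(frozen=True)
class VisitProcess:
    mean_baseline_visits: float = 2.0
    mean_followup_visits: float = 3.0
    mean_early_visits: float = 1.0  # between T0 and the outcome window
    baseline_weight_prob: float = 0.92  # chance a person has >=1 pre-T0 candidate


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic multi-study dataset."""

    seed: int = 0
    studies: Sequence[StudySpec] = (
        StudySpec("STUDY1", {"EUR": 1.0}, 1000),
    )
    female_fraction: float = 0.65
    age_range_years: tuple[float, float] = (18.0, 80.0)
    glp1_fraction: float = 0.62
    t2d_prevalence: Mapping[str, float] = field(default_factory=lambda: {"glp1": 0.72, "bs": 0.37})
    pgs_t2d_liability: float = 0.5  # log-odds of T2D per PGS_T2D s.d.
    snp_mafs: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: DEFAULT_SNP_MAFS)
    baseline_weight_model: BaselineWeightModel = BaselineWeightModel()
    response_model: ResponseModel = ResponseModel()
    visit_process: VisitProcess = VisitProcess()
    measurement_noise_sd_kg: float = 1.0
    discontinuation_prob: float = 0.20
    refill_interval_days: int = 30
    followup_horizon_days: int = 1460
    glp1_codes: Mapping[str, float] = field(
        default_factory=lambda: {"A10BJ06": 0.40, "A10BJ02": 0.30, "A10BJ05": 0.25, "A10BJ01": 0.05}
    )
    procedure_mix: Mapping[str, float] = field(
        default_factory=lambda: {"RYGB": 0.45, "SG": 0.45, "AGB": 0.04, "VBG": 0.03, "BPD-DS": 0.03}
    )
    glp1_bs_crossover_prob: float = 0.01  # GLP1 users also operated in year 1

    def validate(self) -> None:
        for frac_name in ("female_fraction", "glp1_fraction", "discontinuation_prob",
                          "glp1_bs_crossover_prob"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        for arm, v in self.t2d_prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"t2d_prevalence[{arm}] must be in [0, 1], got {v}")
        if not self.studies:
            raise ValueError("studies must be non-empty")
        for st in self.studies:
            tot = sum(st.ancestry_mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"ancestry_mix of study {st.study_id} sums to {tot}, expected 1")
            bad = set(st.ancestry_mix) - set(ANCESTRIES)
            if bad:
                raise ValueError(f"unknown ancestries in study {st.study_id}: {sorted(bad)}")
            if st.n_individuals < 1:
                raise ValueError(f"n_individuals must be >= 1 in study {st.study_id}")
        if self.baseline_weight_model.residual_sd_kg < 0:
            raise ValueError("baseline_weight_model.residual_sd_kg must be >= 0")
        if self.response_model.between_sd_pct < 0:
            raise ValueError("response_model.between_sd_pct must be >= 0")
        if self.measurement_noise_sd_kg < 0:
            raise ValueError("measurement_noise_sd_kg must be >= 0")
        if not 0.0 <= self.visit_process.baseline_weight_prob <= 1.0:
            raise ValueError("visit_process.baseline_weight_prob must be in [0, 1]")
        for rsid, by_anc in self.snp_mafs.items():
            for anc, f in by_anc.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"snp_mafs[{rsid}][{anc}] must be in [0, 1], got {f}")


def simulate_dosages(
    persons: pd.DataFrame,
    snp_mafs: Mapping[str, Mapping[str, float]],
    seed: int,
) -> pd.DataFrame:
    """Hardy-Weinberg dosages (Binomial(2, MAF)) per ancestry-specific MAF.

    Raises ``KeyError`` if any person's ancestry lacks a MAF for any SNP.
    """
    rng = np.random.default_rng(seed)
    anc = persons["ancestry"].to_numpy()
    out = {"person_id": persons["person_id"].to_numpy()}
    for rsid, by_anc in snp_mafs.items():
        missing = set(anc) - set(by_anc)
        if missing:
            raise KeyError(f"no MAF for SNP {rsid} in ancestries {sorted(missing)}")
        mafs = np.array([by_anc[a] for a in anc])
        out[rsid] = rng.binomial(2, mafs).astype(int)
    return pd.DataFrame(out)


def _choice(rng: np.random.Generator, mapping: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(mapping.keys())
    p = np.asarray(list(mapping.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=size, p=p)


def simulate_study(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Generate one synthetic dataset; returns the five analysis tables.

    Keys: ``persons``, ``weights``, ``drugs``, ``procedures``,
    ``genetics`` (SNP dosages + raw PGS values in one table).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vp = config.visit_process
    bw = config.baseline_weight_model
    rm = config.response_model

    person_rows, weight_rows, drug_rows, proc_rows = [], [], [], []
    persons_for_geno = []

    for st in config.studies:
        n = st.n_individuals
        anc = _choice(rng, dict(st.ancestry_mix), n)
        sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
        lo, hi = config.age_range_years
        age = rng.uniform(lo, hi, n)
        arm = np.where(rng.random(n) < config.glp1_fraction, "glp1", "bs")
        # anchor calendar dates: T0 uniform over 2012-2019
        t0 = pd.Timestamp("2012-01-01") + pd.to_timedelta(rng.integers(0, 8 * 365, n), unit="D")
        pcs = rng.standard_normal((n, 20))
        pgs = {pid: rng.standard_normal(n) for pid in PGS_IDS}
        pids = np.array([f"{st.study_id}_{i:06d}" for i in range(n)])
        pers = pd.DataFrame({
            "person_id": pids, "study_id": st.study_id, "ancestry": anc,
            "sex": sex, "age": age, "arm": arm, "t0": t0,
        })
        dosages = simulate_dosages(pers, config.snp_mafs, int(rng.integers(0, 2**31)))
        geno = dosages.copy()
        for pid_col, vals in pgs.items():
            geno[pid_col] = vals
        persons_for_geno.append(geno)

        # T2D liability: arm-specific prevalence shifted by the T2D PGS
        prev = np.array([config.t2d_prevalence[a] for a in arm])
        logit = np.log(prev / (1 - prev)) + config.pgs_t2d_liability * pgs["PGS_T2D"]
        t2d = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)

        # true baseline weight
        w_base = (
            bw.intercept_kg
            + bw.sex_female_kg * (sex == "F")
            + bw.age_kg_per_year * (age - 55.0)
            + rng.normal(0, bw.residual_sd_kg, n)
        )
        for exp_id, coef in bw.exposure_kg.items():
            vals = geno[exp_id].to_numpy(float)
            w_base = w_base + coef * vals
        w_base = np.maximum(w_base, 40.0)

        # target percentage change
        target = np.empty(n)
        for a in ("glp1", "bs"):
            m = arm == a
            if not m.any():
                continue
            t = (
                rm.mean_pct[a]
                + rm.baseline_pct_per_kg[a] * (w_base[m] - 100.0)
                + rm.sex_female_pct[a] * (sex[m] == "F")
                + rm.age_pct_per_year[a] * (age[m] - 55.0)
            )
            for exp_id, by_arm in rm.exposure_pct.items():
                coef = by_arm.get(a, 0.0)
                if coef:
                    t = t + coef * geno.loc[m, exp_id].to_numpy(float)
            target[m] = t
        target = target + rng.normal(0, rm.between_sd_pct, n)

        birth = t0 - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")
        person_rows.append(pd.DataFrame({
            "person_id": pids, "study_id": st.study_id, "ancestry": anc, "sex": sex,
            "birth_date": birth, "t2d": t2d,
            **{f"pc{j+1}": pcs[:, j] for j in range(20)},
        }))

        # --- longitudinal records per person --------------------------------
        for i in range(n):
            pid = pids[i]
            a = arm[i]
            half = rm.half_life_days[a]

            def true_weight(day: np.ndarray) -> np.ndarray:
                frac = np.where(day <= 0, 0.0, 1.0 - 2.0 ** (-day / half))
                return w_base[i] * (1.0 + target[i] / 100.0 * frac)

            # baseline-window visits
            n_base = rng.poisson(vp.mean_baseline_visits)
            if n_base == 0 and rng.random() < vp.baseline_weight_prob:
                n_base = 1
            base_days = rng.integers(-364, 0, n_base) if n_base else np.array([], int)
            # early + outcome-window visits
            n_early = rng.poisson(vp.mean_early_visits)
            early_days = rng.integers(1, 180, n_early) if n_early else np.array([], int)
            if a == "glp1":
                lo_d, hi_d = 182, 364
            else:
                lo_d, hi_d = 180, min(1460, config.followup_horizon_days)
            n_fu = rng.poisson(vp.mean_followup_visits)
            fu_days = rng.integers(lo_d, hi_d + 1, n_fu) if n_fu else np.array([], int)
            days = np.concatenate([base_days, early_days, fu_days])
            if days.size:
                noise = rng.normal(0, config.measurement_noise_sd_kg, days.size)
                wkg = true_weight(days.astype(float)) + noise
                for d, w in zip(days, wkg):
                    weight_rows.append((pid, t0[i] + pd.Timedelta(days=int(d)), round(float(w), 2)))

            if a == "glp1":
                atc = _choice(rng, dict(config.glp1_codes), 1)[0]
                interval = config.refill_interval_days
                if rng.random() < config.discontinuation_prob:
                    stop_day = int(rng.integers(30, 270))
                else:
                    stop_day = 364 + interval
                d = 0
                while d <= stop_day:
                    drug_rows.append((pid, atc, t0[i] + pd.Timedelta(days=d), interval))
                    d += interval
                if rng.random() < config.glp1_bs_crossover_prob:
                    ptype = _choice(rng, dict(config.procedure_mix), 1)[0]
                    cross_day = int(rng.integers(0, 365))
                    proc_rows.append((pid, f"BS-{ptype}", t0[i] + pd.Timedelta(days=cross_day), ptype))
            else:
                ptype = _choice(rng, dict(config.procedure_mix), 1)[0]
                proc_rows.append((pid, f"BS-{ptype}", t0[i], ptype))

    persons = pd.concat(person_rows, ignore_index=True)
    weights = pd.DataFrame(weight_rows, columns=["person_id", "date", "weight_kg"])
    drugs = pd.DataFrame(drug_rows, columns=["person_id", "atc_code", "date", "days_supply"])
    procedures = pd.DataFrame(proc_rows, columns=["person_id", "code", "date", "procedure_type"])
    genetics_df = pd.concat(persons_for_geno, ignore_index=True)
    return {
        "persons": persons,
        "weights": weights,
        "drugs": drugs,
        "procedures": procedures,
        "genetics": genetics_df,
    }


def write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path, seed: int | None = None) -> None:
    """Write the five tables as TSV (ISO dates) plus a metadata JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    meta = {"seed": seed, "tables": sorted(tables.keys()),
            "n_rows": {k: int(len(v)) for k, v in tables.items()}}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def config_from_dict(d: Mapping) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping (partial override)."""
    d = dict(d)
    if "studies" in d:
        d["studies"] = tuple(
            StudySpec(s["study_id"], dict(s["ancestry_mix"]), int(s["n_individuals"]))
            for s in d["studies"]
        )
    for key, cls in (
        ("baseline_weight_model", BaselineWeightModel),
        ("response_model", ResponseModel),
        ("visit_process", VisitProcess),
    ):
        if key in d and isinstance(d[key], Mapping):
            d[key] = cls(**d[key])
    if "age_range_years" in d:
        d["age_range_years"] = tuple(d["age_range_years"])
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
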