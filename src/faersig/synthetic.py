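"""Synthetic FAERS-schema data with known ground truth.

The generator emits quarterly DEMO/DRUG/REAC/THER/OUTC/INDI tables in the
exact dollar-delimited dialect :mod:`faersig.faers_io` reads, together with
per-case bookkeeping (:class:`GroundTruth`) so every pipeline stage can be
tested without downloading anything:

* a target drug under several name spellings, role PS (mostly) or SS;
* a comparator population reporting other drugs;
* per-PT background reporting rates and *planted* drug–event associations
  of known relative risk (target reports draw a planted PT with probability
  ``min(1, RR · p_background)``);
* duplicate case versions sharing a CASEID with increasing FDA_DT /
  PRIMARYID (plus occasional FDA_DT ties broken by PRIMARYID);
* therapy and event dates consistent with a lognormal time-to-onset model;
* missingness patterns modelled on real spontaneous-report data (weight
  mostly unknown, onset dates recorded in roughly a fifth of reports).

Reports with no spontaneous event draw one filler term from the
*non-planted* vocabulary, so planted-PT counts stay exactly binomial in
both cohorts.  Determinism: two runs with the same config produce
byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle, write_quarter
from .meddra import TOY_PT_SOC, toy_map, write_map
from .subgroups import DEFAULT_CONTINENTS

logger = logging.getLogger("faersig")

TARGET_SPELLINGS = (
    "MIRABEGRON", "MYRBETRIQ", "BETMIGA", "BETANIS",
    "MIRABEGRON 50 MG FILM-COATED TABLET", "Myrbetriq",
)

#: co-prescription pool (name, probability weight)
CO_DRUG_POOL: tuple[tuple[str, float], ...] = (
    ("ASPIRIN", 0.24),
    ("ATORVASTATIN", 0.18),
    ("SOLIFENACIN SUCCINATE", 0.16),
    ("METFORMIN", 0.12),
    ("AMLODIPINE", 0.09),
    ("OMEPRAZOLE", 0.07),
    ("LISINOPRIL", 0.05),
    ("SIMVASTATIN", 0.04),
    ("LEVOTHYROXINE", 0.03),
    ("FUROSEMIDE", 0.02),
)

#: comparator-population suspect drugs
BACKGROUND_PS_POOL: tuple[tuple[str, float], ...] = (
    ("ADALIMUMAB", 0.16), ("METHOTREXATE", 0.13), ("IBUPROFEN", 0.12),
    ("PREDNISONE", 0.11), ("WARFARIN", 0.10), ("INSULIN GLARGINE", 0.10),
    ("AMOXICILLIN", 0.09), ("SERTRALINE", 0.08), ("RAMIPRIL", 0.08),
    ("OXYBUTYNIN", 0.03),
)

TARGET_INDICATIONS: tuple[tuple[str, float], ...] = (
    ("Hypertonic bladder", 0.45), ("Incontinence", 0.20), ("Pollakiuria", 0.12),
    ("Micturition urgency", 0.10), ("Nocturia", 0.06), ("Neurogenic bladder", 0.04),
    ("Benign prostatic hyperplasia", 0.03),
)

BACKGROUND_INDICATIONS: tuple[tuple[str, float], ...] = (
    ("Rheumatoid arthritis", 0.3), ("Hypertension", 0.25), ("Pain", 0.2),
    ("Diabetes mellitus", 0.15), ("Depression", 0.1),
)

#: elevated background reporting rates for the commonest terms; every other
#: toy-ontology PT gets the base rate below.
_COMMON_PT_RATES: dict[str, float] = {
    "Fatigue": 0.080, "Nausea": 0.060, "Headache": 0.055, "Dizziness": 0.045,
    "Fall": 0.030, "Hypertension": 0.030, "Constipation": 0.025,
    "Dry mouth": 0.020, "Blood pressure increased": 0.020,
    "Atrial fibrillation": 0.015, "Tachycardia": 0.015, "Palpitations": 0.015,
    "Nasopharyngitis": 0.015, "Overdose": 0.012, "Product quality issue": 0.010,
    "Urinary retention": 0.010, "Dysuria": 0.008, "Urinary incontinence": 0.008,
    "Pollakiuria": 0.008, "Haematuria": 0.008, "Vision blurred": 0.008,
    "Hyperglycaemia": 0.008, "Arrhythmia": 0.006,
}
_BASE_PT_RATE = 0.004

DEFAULT_PT_RATES: tuple[tuple[str, float], ...] = tuple(
    (pt, _COMMON_PT_RATES.get(pt, _BASE_PT_RATE)) for pt, _ in TOY_PT_SOC
)

_WINDOW_QUARTERS: tuple[str, ...] = tuple(
    f"{y}Q{q}" for y in range(2012, 2024) for q in (1, 2, 3, 4)
)[:47]  # 2012Q1 … 2023Q3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults define the emulated study conditions."""

    seed: int = 0
    n_background_reports: int = 20_000
    n_target_reports: int = 2_000
    n_quarters: int = 4
    duplicate_rate: float = 0.10
    fda_dt_tie_rate: float = 0.05  # duplicate versions sharing the FDA date
    pt_vocabulary: tuple[tuple[str, float], ...] = DEFAULT_PT_RATES
    planted_signals: tuple[tuple[str, float], ...] = (("Urinary retention", 5.0),)
    #: (kind, parameter, pt, rr) applied only inside one stratum of the target cohort
    planted_subgroup_signals: tuple[tuple[str, str, str, float], ...] = ()
    ps_role_rate: float = 0.90  # target drug reported as PS (else SS)
    target_as_concomitant_rate: float = 0.005  # background reports co-listing the target
    duplicate_reac_row_rate: float = 0.02
    # missingness / precision (fractions of reports)
    event_date_rate: float = 0.35
    start_day_rate: float = 0.60
    start_month_rate: float = 0.20
    end_date_rate: float = 0.50
    negative_tto_rate: float = 0.01
    dose_known_rate: float = 0.16
    age_known_rate: float = 0.57
    weight_known_rate: float = 0.11
    indication_rate: float = 0.70
    # time-to-onset model (lognormal, days)
    tto_mu: float = float(np.log(25.0))
    tto_sigma: float = 1.76
    # demographics
    sex_probs: tuple[tuple[str, float], ...] = (("F", 0.60), ("M", 0.35), ("", 0.05))
    occp_probs: tuple[tuple[str, float], ...] = (
        ("MD", 0.28), ("OT", 0.19), ("PH", 0.08), ("CN", 0.33),
        ("LW", 0.04), ("HP", 0.03), ("", 0.05),
    )
    country_probs: tuple[tuple[str, float], ...] = (
        ("US", 0.50), ("JP", 0.16), ("GB", 0.11), ("ES", 0.04), ("CA", 0.04),
        ("FR", 0.03), ("DE", 0.03), ("AU", 0.02), ("BR", 0.01), ("ZA", 0.005),
        ("", 0.055),
    )
    age_band_probs: tuple[float, float, float, float] = (0.01, 0.24, 0.62, 0.13)
    weight_mean: float = 75.0
    weight_sd: float = 18.0

    def __post_init__(self) -> None:
        if not self.pt_vocabulary:
            raise ValueError("empty PT vocabulary")
        for pt, p in self.pt_vocabulary:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background rate for {pt!r} outside [0,1]")
        for pt, rr in self.planted_signals:
            if rr <= 0:
                raise ValueError(f"relative risk for {pt!r} must be positive")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0,1)")


@dataclass
class GroundTruth:
    """Per-case bookkeeping emitted alongside the synthetic files."""

    cases: pd.DataFrame      # one row per true case
    reactions: pd.DataFrame  # (caseid, pt, planted)
    lineage: pd.DataFrame    # (caseid, primaryid, fda_dt, version) per emitted report
    co_drugs: pd.DataFrame   # (caseid, name) co-prescription rows
    config: SyntheticConfig

    @property
    def n_true_cases(self) -> int:
        return len(self.cases)

    @property
    def n_emitted_reports(self) -> int:
        return len(self.lineage)

    def co_drug_counts(self) -> dict[str, int]:
        """Distinct-report co-drug counts over HCP PS target cases."""
        mask = (self.cases["is_target"] & self.cases["is_hcp"]
                & (self.cases["target_role"] == "PS"))
        ids = set(self.cases.loc[mask, "caseid"])
        rows = self.co_drugs[self.co_drugs["caseid"].isin(ids)]
        return rows.drop_duplicates()["name"].value_counts().to_dict()


def _choice(rng: np.random.Generator, pairs: Sequence[tuple[str, float]], size: int) -> np.ndarray:
    names = np.array([p[0] for p in pairs], dtype=object)
    probs = np.array([p[1] for p in pairs], dtype=float)
    return rng.choice(names, size=size, p=probs / probs.sum())


def _ymd(days: np.ndarray) -> np.ndarray:
    """datetime64[D] array → YYYYMMDD strings (vectorized)."""
    return np.char.replace(np.datetime_as_string(days, unit="D"), "-", "")


def generate(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
) -> tuple[list[QuarterBundle], GroundTruth]:
    """Generate quarterly bundles plus ground truth (deterministic per seed).

    When ``outdir`` is given, also writes the ASCII tables per quarter, the
    toy PT→SOC map (``pt_soc_map.tsv``), a country→continent map
    (``continents.tsv``) and the ground-truth sidecars.
    """
    rng = np.random.default_rng(config.seed)
    nt, nb = config.n_target_reports, config.n_background_reports
    n = nt + nb
    is_target = np.zeros(n, dtype=bool)
    is_target[:nt] = True
    t_idx = np.nonzero(is_target)[0]
    b_idx = np.nonzero(~is_target)[0]

    # object dtype up front: pandas would otherwise re-convert fixed-width
    # unicode arrays on every frame construction
    caseids_u = (30_000_001 + np.arange(n)).astype("U9")
    caseids = caseids_u.astype(object)

    # ---- demographics -----------------------------------------------------
    sex = _choice(rng, config.sex_probs, n)
    occp = _choice(rng, config.occp_probs, n)
    country = _choice(rng, config.country_probs, n)

    age_known = rng.random(n) < config.age_known_rate
    probs = np.asarray(config.age_band_probs, dtype=float)
    band = rng.choice(4, size=n, p=probs / probs.sum())
    age_years = rng.integers(np.array([2, 18, 65, 86])[band],
                             np.array([17, 64, 85, 97])[band] + 1).astype(float)
    age_dec = rng.random(n) < 0.03  # a few reports use decades
    age_val = np.where(age_dec, np.round(age_years / 10, 1), age_years)
    age_unit = np.where(age_dec, "DEC", "YR")

    weight_known = rng.random(n) < config.weight_known_rate
    weight_kg = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 35, 140).round(1)
    weight_lbs = rng.random(n) < 0.2
    wt_val = np.where(weight_lbs, np.round(weight_kg / 0.453592, 1), weight_kg)
    wt_unit = np.where(weight_lbs, "LBS", "KG")

    weight_group = np.where(
        ~weight_known, "Unknown",
        np.where(weight_kg < 50, "<50", np.where(weight_kg <= 100, "50–100", ">100")),
    )
    continent = np.array(
        [DEFAULT_CONTINENTS.get(c, "Unknown") if c else "Unknown" for c in country],
        dtype=object,
    )

    # ---- dates ------------------------------------------------------------
    q_pick = np.linspace(0, len(_WINDOW_QUARTERS) - 1, config.n_quarters).round().astype(int)
    labels = [_WINDOW_QUARTERS[i] for i in q_pick]
    q_starts, q_ends = [], []
    for lab in labels:
        year, q = int(lab[:4]), int(lab[-1])
        first = _dt.date(year, 3 * q - 2, 1)
        last = (_dt.date(year + 1, 1, 1) if q == 4 else _dt.date(year, 3 * q + 1, 1))
        q_starts.append(np.datetime64(first))
        q_ends.append(np.datetime64(last - _dt.timedelta(days=1)))
    q_starts = np.array(q_starts)
    q_ends = np.array(q_ends)

    case_q = rng.integers(0, config.n_quarters, n)
    span = (q_ends[case_q] - q_starts[case_q]).astype(int) + 1
    fda = q_starts[case_q] + rng.integers(0, span)  # final-version receipt date

    lag = rng.integers(0, 61, n)
    event = fda - lag
    tto = np.round(rng.lognormal(config.tto_mu, config.tto_sigma, n)).astype(int)
    tto = np.maximum(tto, 0)
    neg = rng.random(n) < config.negative_tto_rate
    tto = np.where(neg, -rng.integers(1, 31, n), tto)
    start = event - tto.astype("timedelta64[D]")
    duration = np.round(rng.lognormal(np.log(60.0), 1.0, n)).astype(int)
    end = start + duration.astype("timedelta64[D]")

    event_recorded = rng.random(n) < config.event_date_rate
    u = rng.random(n)
    start_prec = np.where(
        u < config.start_day_rate, "day",
        np.where(u < config.start_day_rate + config.start_month_rate, "month", "none"),
    )
    end_recorded = (rng.random(n) < config.end_date_rate) & (start_prec == "day")

    # ---- reactions --------------------------------------------------------
    vocab = np.array([pt for pt, _ in config.pt_vocabulary], dtype=object)
    base_p = np.array([p for _, p in config.pt_vocabulary], dtype=float)
    nv = len(vocab)
    pt_index = {pt: j for j, pt in enumerate(vocab)}
    pmat = np.broadcast_to(base_p, (n, nv)).copy()
    for pt, rr in config.planted_signals:
        if pt not in pt_index:
            raise ValueError(f"planted PT {pt!r} not in vocabulary")
        pmat[is_target, pt_index[pt]] *= rr
    for kind, parameter, pt, rr in config.planted_subgroup_signals:
        if kind == "weight_band":
            member = weight_group == parameter
        elif kind == "continent":
            member = continent == parameter
        else:
            raise ValueError(f"unsupported planted subgroup kind {kind!r}")
        pmat[is_target & member, pt_index[pt]] *= rr

    clipped = pmat > 1.0
    if clipped.any():
        logger.warning("%d planted probabilities clamped to 1.0", int(clipped.sum()))
        np.minimum(pmat, 1.0, out=pmat)

    has_pt = rng.random((n, nv)) < pmat
    # every report carries at least one reaction; the filler term is drawn
    # from the non-planted vocabulary so planted counts stay exactly binomial
    planted_cols = sorted(
        {pt_index[pt] for pt, _ in config.planted_signals}
        | {pt_index[pt] for *_, pt, _rr in config.planted_subgroup_signals}
    )
    filler_p = base_p.copy()
    filler_p[planted_cols] = 0.0
    empty = np.nonzero(~has_pt.any(axis=1))[0]
    if empty.size:
        extra = rng.choice(nv, size=empty.size, p=filler_p / filler_p.sum())
        has_pt[empty, extra] = True

    rrow, rcol = np.nonzero(has_pt)
    reac_truth = pd.DataFrame({
        "caseid": caseids[rrow],
        "pt": vocab[rcol],
        "planted": np.isin(rcol, planted_cols) & is_target[rrow],
    })

    # ---- drugs ------------------------------------------------------------
    target_role = np.full(n, "", dtype=object)
    target_role[t_idx] = np.where(rng.random(nt) < config.ps_role_rate, "PS", "SS")

    primary_name = np.empty(n, dtype=object)
    primary_ai = np.empty(n, dtype=object)
    primary_role = np.empty(n, dtype=object)
    spell = rng.choice(len(TARGET_SPELLINGS), size=nt,
                       p=[0.45, 0.25, 0.10, 0.05, 0.10, 0.05])
    primary_name[t_idx] = np.array(TARGET_SPELLINGS, dtype=object)[spell]
    primary_ai[t_idx] = np.where(rng.random(nt) < 0.8, "MIRABEGRON", "")
    primary_role[t_idx] = target_role[t_idx]
    primary_name[b_idx] = _choice(rng, BACKGROUND_PS_POOL, nb)
    primary_ai[b_idx] = ""
    primary_role[b_idx] = "PS"

    dose_known = rng.random(n) < config.dose_known_rate
    dose_amt = np.where(rng.random(n) < 0.35, "25", "50")
    dose_freq = np.where(rng.random(n) < 0.10, "BID", "QD")

    primary_drug = pd.DataFrame({
        "case_idx": np.arange(n),
        "drug_seq": "1",
        "role_cod": primary_role,
        "drugname": primary_name,
        "prod_ai": primary_ai,
        "dose_amt": np.where(dose_known, dose_amt, ""),
        "dose_unit": np.where(dose_known, "MG", ""),
        "dose_freq": np.where(dose_known, dose_freq, ""),
    })

    n_co = rng.integers(1, 6, n)
    co_case = np.repeat(np.arange(n), n_co)
    total_co = int(n_co.sum())
    co_names = _choice(rng, CO_DRUG_POOL, total_co)
    co_role = rng.choice(np.array(["C", "SS", "I"], dtype=object),
                         size=total_co, p=[0.80, 0.15, 0.05])
    # within-report sequence numbers 2..n_co+1 (vectorized cumcount)
    first_of_case = np.r_[0, np.cumsum(n_co)[:-1]]
    co_seq = np.arange(total_co) - np.repeat(first_of_case, n_co) + 2
    co = pd.DataFrame({
        "case_idx": co_case,
        "drug_seq": co_seq.astype(str),
        "role_cod": co_role,
        "drugname": co_names,
        "prod_ai": "", "dose_amt": "", "dose_unit": "", "dose_freq": "",
    })

    # a few background reports co-list the target drug in a non-suspect role
    extra_target = b_idx[rng.random(nb) < config.target_as_concomitant_rate]
    extra = pd.DataFrame({
        "case_idx": extra_target,
        "drug_seq": "99",
        "role_cod": "C",
        "drugname": "MIRABEGRON",
        "prod_ai": "", "dose_amt": "", "dose_unit": "", "dose_freq": "",
    })
    drug_truth = pd.concat([primary_drug, co, extra], ignore_index=True)
    drug_truth = drug_truth.sort_values(["case_idx", "drug_seq"], kind="mergesort",
                                        key=lambda s: s.astype(int) if s.name == "drug_seq" else s
                                        ).reset_index(drop=True)

    # ---- therapy / outcomes / indications ---------------------------------
    start_full = _ymd(start)
    start_str = np.where(
        start_prec == "day", start_full,
        np.where(start_prec == "month", start_full.astype("U6"), ""),
    ).astype(object)
    end_str = np.where(end_recorded, _ymd(end), "").astype(object)
    has_ther = np.nonzero(start_prec != "none")[0]
    ther_truth = pd.DataFrame({
        "case_idx": has_ther,
        "dsg_drug_seq": "1",
        "start_dt": start_str[has_ther],
        "end_dt": end_str[has_ther],
    })

    outc_parts = []
    for code, p in (("DE", 0.019), ("DS", 0.025), ("HO", 0.17), ("LT", 0.022), ("OT", 0.51)):
        hit = np.nonzero(rng.random(n) < p)[0]
        outc_parts.append(pd.DataFrame({"case_idx": hit, "outc_cod": code}))
    outc_truth = pd.concat(outc_parts, ignore_index=True).sort_values(
        ["case_idx", "outc_cod"], kind="mergesort").reset_index(drop=True)

    has_indi = np.nonzero(rng.random(n) < config.indication_rate)[0]
    indi_pt = np.empty(n, dtype=object)
    indi_pt[t_idx] = _choice(rng, TARGET_INDICATIONS, nt)
    indi_pt[b_idx] = _choice(rng, BACKGROUND_INDICATIONS, nb)
    indi_truth = pd.DataFrame({
        "case_idx": has_indi,
        "indi_drug_seq": "1",
        "indi_pt": indi_pt[has_indi],
    })

    # ---- duplicate versions & lineage (vectorized) ------------------------
    dup = rng.random(n) < config.duplicate_rate
    n_versions = np.where(dup, np.where(rng.random(n) < 0.2, 3, 2), 1)
    n_extra = n_versions - 1
    ex_case = np.repeat(np.arange(n), n_extra)  # case index per earlier version
    first_ex = np.r_[0, np.cumsum(n_extra)[:-1]]
    ex_version = np.arange(len(ex_case)) - np.repeat(first_ex, n_extra) + 1

    room = (fda - q_starts[case_q]).astype(int)  # days available before the final date
    if ex_case.size:
        back_cap = np.maximum(room[ex_case], 1)
        back = rng.integers(1, back_cap + 1)
        back = np.where(room[ex_case] > 0, back, 0)
        # receipt dates must be non-decreasing in version: for cases with two
        # earlier versions (contiguous rows), give version 1 the larger offset
        pair_first = np.nonzero((n_extra[ex_case] == 2) & (ex_version == 1))[0]
        if pair_first.size:
            b1 = np.maximum(back[pair_first], back[pair_first + 1])
            b2 = np.minimum(back[pair_first], back[pair_first + 1])
            back[pair_first], back[pair_first + 1] = b1, b2
        # the latest earlier version sometimes shares the final FDA date (tie
        # → the dedup rule must fall back to the PRIMARYID comparison)
        is_last_extra = ex_version == n_extra[ex_case]
        tie = is_last_extra & (rng.random(len(ex_case)) < config.fda_dt_tie_rate)
        back = np.where(tie, 0, back)
    else:
        back = np.zeros(0, dtype=int)
    ex_fda = fda[ex_case] - back.astype("timedelta64[D]")

    fda_final_str = _ymd(fda).astype(object)
    final_pid = np.char.add(caseids_u, n_versions.astype("U1")).astype(object)
    if ex_case.size:
        ex_pid = np.char.add(caseids_u[ex_case], ex_version.astype("U1")).astype(object)
        ex_fda_str = _ymd(ex_fda).astype(object)
    else:
        ex_pid = np.zeros(0, dtype=object)
        ex_fda_str = np.zeros(0, dtype=object)

    lineage = pd.concat([
        pd.DataFrame({"case_idx": np.arange(n), "caseid": caseids,
                      "primaryid": final_pid, "fda_dt": fda_final_str,
                      "version": n_versions}),
        pd.DataFrame({"case_idx": ex_case, "caseid": caseids[ex_case],
                      "primaryid": ex_pid, "fda_dt": ex_fda_str,
                      "version": ex_version}),
    ], ignore_index=True).sort_values(["case_idx", "version"],
                                      kind="mergesort").reset_index(drop=True)

    # ---- assemble FAERS tables (child rows replicated per version) --------
    lin_case = lineage["case_idx"].to_numpy()
    lin_pid = lineage["primaryid"].to_numpy()
    event_str = np.where(event_recorded, _ymd(event), "").astype(object)
    age_str = np.where(age_known, age_val.astype("U6"), "").astype(object)
    age_cod_str = np.where(age_known, age_unit, "").astype(object)
    wt_str = np.where(weight_known, wt_val.astype("U6"), "").astype(object)
    wt_cod_str = np.where(weight_known, wt_unit, "").astype(object)
    demo_all = pd.DataFrame({
        "primaryid": lin_pid,
        "caseid": lineage["caseid"],
        "event_dt": event_str[lin_case],
        "fda_dt": lineage["fda_dt"],
        "age": age_str[lin_case],
        "age_cod": age_cod_str[lin_case],
        "sex": sex[lin_case],
        "wt": wt_str[lin_case],
        "wt_cod": wt_cod_str[lin_case],
        "occp_cod": occp[lin_case],
        "reporter_country": country[lin_case],
        "occr_country": country[lin_case],
    })

    # per-version replication: every version repeats the case's child rows
    order = np.argsort(lin_case, kind="stable")
    counts_per_case = np.bincount(lin_case, minlength=n)

    def _replicate(truth_frame: pd.DataFrame) -> pd.DataFrame:
        child_case = truth_frame["case_idx"].to_numpy()
        reps = counts_per_case[child_case]
        idx = np.repeat(np.arange(len(truth_frame)), reps)
        # rows of `lineage` belonging to each child row's case, in order
        starts = np.r_[0, np.cumsum(counts_per_case)[:-1]]
        offset = np.arange(reps.sum()) - np.repeat(np.r_[0, np.cumsum(reps)[:-1]], reps)
        lin_rows = order[np.repeat(starts[child_case], reps) + offset]
        out = truth_frame.iloc[idx].reset_index(drop=True)
        out.insert(0, "primaryid", lin_pid[lin_rows])
        out.insert(1, "caseid", caseids[lin_case[lin_rows]])
        return out.drop(columns="case_idx")

    drug_all = _replicate(drug_truth)
    reac_case = pd.DataFrame({"case_idx": rrow, "pt": vocab[rcol]})
    reac_all = _replicate(reac_case)
    if config.duplicate_reac_row_rate > 0 and len(reac_all):
        dup_rows = rng.random(len(reac_all)) < config.duplicate_reac_row_rate
        reac_all = pd.concat([reac_all, reac_all[dup_rows]], ignore_index=True)
    ther_all = _replicate(ther_truth)
    outc_all = _replicate(outc_truth)
    indi_all = _replicate(indi_truth)

    # quarter of each emitted version, by its own receipt date
    q_start_str = _ymd(q_starts)  # chronological by construction
    version_q = np.searchsorted(q_start_str, lineage["fda_dt"].to_numpy(),
                                side="right") - 1
    version_q = np.clip(version_q, 0, config.n_quarters - 1)

    bundles: list[QuarterBundle] = []
    for qi, lab in enumerate(labels):
        pids = set(lin_pid[version_q == qi])
        dm = demo_all[demo_all["primaryid"].isin(pids)].reset_index(drop=True)
        bundles.append(QuarterBundle(
            demo=dm,
            drug=drug_all[drug_all["primaryid"].isin(pids)].reset_index(drop=True),
            reac=reac_all[reac_all["primaryid"].isin(pids)].reset_index(drop=True),
            ther=ther_all[ther_all["primaryid"].isin(pids)].reset_index(drop=True),
            outc=outc_all[outc_all["primaryid"].isin(pids)].reset_index(drop=True),
            indi=indi_all[indi_all["primaryid"].isin(pids)].reset_index(drop=True),
            label=lab,
        ))

    cases = pd.DataFrame({
        "caseid": caseids,
        "primaryid_final": final_pid,
        "is_target": is_target,
        "target_role": target_role,
        "is_hcp": np.isin(occp.astype(str), ("MD", "PH", "OT")),
        "occp_cod": occp,
        "sex": sex,
        "age_years": np.where(age_known, age_years, np.nan),
        "weight_kg": np.where(weight_known, weight_kg, np.nan),
        "weight_group": weight_group,
        "country": country,
        "continent": continent,
        "true_tto": tto,
        "tto_evaluable": event_recorded & (start_prec == "day") & (tto >= 0),
        "n_versions": n_versions,
        "quarter": np.array(labels, dtype=object)[case_q],
    })
    co_truth = pd.DataFrame({"caseid": caseids[co_case], "name": co_names})
    truth = GroundTruth(cases=cases, reactions=reac_truth, lineage=lineage,
                        co_drugs=co_truth, config=config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for b in bundles:
            write_quarter(b, outdir / b.label)
        write_map(toy_map(), outdir / "pt_soc_map.tsv")
        with (outdir / "continents.tsv").open("w") as fh:
            for k in sorted(DEFAULT_CONTINENTS):
                fh.write(f"{k}\t{DEFAULT_CONTINENTS[k]}\n")
        cases.to_csv(outdir / "ground_truth_cases.tsv", sep="\t", index=False)
        reac_truth.to_csv(outdir / "ground_truth_reactions.tsv", sep="\t", index=False)
        lineage.to_csv(outdir / "ground_truth_lineage.tsv", sep="\t", index=False)
    return bundles, truth


def regenerate_check(config: SyntheticConfig, workdir: str | Path) -> tuple[bool, str]:
    """Write the same config twice and byte-compare every emitted file."""
    workdir = Path(workdir)
    dirs = (workdir / "run1", workdir / "run2")
    for d in dirs:
        generate(replace(config), outdir=d)
    files1 = sorted(p.relative_to(dirs[0]) for p in dirs[0].rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(dirs[1]) for p in dirs[1].rglob("*") if p.is_file())
    if files1 != files2:
        return False, "file sets differ"
    for rel in files1:
        b1 = (dirs[0] / rel).read_bytes()
        b2 = (dirs[1] / rel).read_bytes()
        if b1 != b2:
            for i, (x, y) in enumerate(zip(b1.splitlines(), b2.splitlines())):
                if x != y:
                    return False, f"{rel}: first differing line {i}: {x!r} vs {y!r}"
            return False, f"{rel}: lengths differ"
    return True, ""
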