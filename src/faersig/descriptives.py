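"""Descriptive characterization of the target cohort.

Produces the conventional clinical-characteristics panels of a
pharmacovigilance report: sex, age band, weight band, reporter occupation,
reporting country and continent, indications, serious outcomes, daily dose
and medication duration — each as label / count / percent rows against the
cohort size.  Some panels (outcomes, dose, duration) are intrinsically
non-exhaustive because a case may carry several codes or none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import floor, isnan

import pandas as pd

from .cohort import CaseData, NameMatcher
from .faers_io import parse_date

logger = logging.getLogger("faersig")

AGE_LABELS = ("≤17", "18–64", "65–85", "≥86", "Unknown")
WEIGHT_LABELS = ("<50", "50–100", ">100", "Unknown")
SEX_LABELS = ("Female", "Male", "Unknown")
OUTCOME_ORDER = ("DE", "LT", "HO", "DS", "CA", "OT")
DOSE_LABELS = ("12.5", "25", "25–50", "50", "75", "100", "150", "Unknown")
DURATION_LABELS = ("0–30", "31–60", "61–90", "91–180", "181–360", ">361", "Unknown")

#: dose_freq codes convertible to a per-day multiplier
FREQ_PER_DAY = {"QD": 1.0, "BID": 2.0, "TID": 3.0, "QID": 4.0, "QOD": 0.5}


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (publication convention)."""
    if denominator <= 0:
        raise ZeroDivisionError("percent undefined for denominator 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def assign_age_group(age_years: float | None) -> str:
    """Band an age in years; fractional ages floor to completed years."""
    if age_years is None or (isinstance(age_years, float) and isnan(age_years)):
        return "Unknown"
    years = floor(age_years)
    if years <= 17:
        return "≤17"
    if years <= 64:
        return "18–64"
    if years <= 85:
        return "65–85"
    return "≥86"


def assign_weight_group(weight_kg: float | None) -> str:
    if weight_kg is None or (isinstance(weight_kg, float) and isnan(weight_kg)):
        return "Unknown"
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:  # band labels read as inclusive at both printed ends
        return "50–100"
    return ">100"


def dose_per_day(drug: dict | pd.Series) -> float | None:
    """Daily dose in mg, defined only for mg doses with a known frequency."""
    unit = str(drug.get("dose_unit", "") or "").strip().upper()
    if unit != "MG":
        return None
    try:
        amt = float(drug.get("dose_amt"))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if amt != amt or amt <= 0:
        return None
    freq = str(drug.get("dose_freq", "") or "").strip().upper()
    if freq not in FREQ_PER_DAY:
        return None
    return amt * FREQ_PER_DAY[freq]


def assign_dose_group(mg_per_day: float | None) -> str:
    """Bin a daily dose into the conventional panel bins.

    Exact matches map to their bin; doses strictly between 25 and 50 mg/day
    map to "25–50"; anything else is reported as Unknown.
    """
    if mg_per_day is None:
        return "Unknown"
    for exact, label in ((12.5, "12.5"), (25.0, "25"), (50.0, "50"),
                         (75.0, "75"), (100.0, "100"), (150.0, "150")):
        if mg_per_day == exact:
            return label
    if 25.0 < mg_per_day < 50.0:
        return "25–50"
    return "Unknown"


def duration_days(therapy: dict | pd.Series) -> int | None:
    """Medication duration in whole days (end − start).

    Same-day start/stop is 0 days, matching the FAERS duration convention.
    Either date missing or below day precision → unknown; end before start
    → unknown with a warning.
    """
    start = parse_date(therapy.get("start_dt"))
    end = parse_date(therapy.get("end_dt"))
    if not (start.is_day and end.is_day):
        return None
    delta = (end.value - start.value).days
    if delta < 0:
        logger.warning("therapy end before start (%s < %s)", end.value, start.value)
        return None
    return delta


def assign_duration_group(days: int | None) -> str:
    if days is None:
        return "Unknown"
    if days <= 30:
        return "0–30"
    if days <= 60:
        return "31–60"
    if days <= 90:
        return "61–90"
    if days <= 180:
        return "91–180"
    if days <= 360:
        return "181–360"
    return ">361"  # printed label; internally the band is every day > 360


@dataclass
class CharacteristicsTable:
    """All descriptive panels for one cohort; each panel is a DataFrame with
    columns label / count / percent."""

    n_cases: int
    panels: dict[str, pd.DataFrame] = field(default_factory=dict)

    def panel(self, name: str) -> pd.DataFrame:
        return self.panels[name]


def _panel(counts: dict[str, int], order: tuple[str, ...] | None, n: int) -> pd.DataFrame:
    if order is not None:
        labels = list(order)
    else:
        labels = sorted(counts, key=lambda k: (-counts[k], k))
    return pd.DataFrame({
        "label": labels,
        "count": [counts.get(l, 0) for l in labels],
        "percent": [percent(counts.get(l, 0), n) for l in labels],
    })


def summarize(
    data: CaseData,
    target_ids,
    matcher: NameMatcher | None = None,
    continent_of: dict[str, str] | None = None,
    top_countries: int = 10,
    top_indications: int = 10,
) -> CharacteristicsTable:
    """Build every descriptive panel for the given cohort.

    Dose and duration are taken from the matched target drug's rows; when a
    case has several candidate rows, the first defined value wins (dose) or
    the earliest start / latest end pair is used (duration).
    """
    matcher = matcher or NameMatcher()
    ids = pd.Index(target_ids).unique()
    demo = data.demo[data.demo["primaryid"].isin(set(ids))]
    n = len(demo)
    if n == 0:
        raise ValueError("empty cohort")

    sex_map = {"F": "Female", "M": "Male"}
    sex_counts = demo.get("sex", pd.Series("", index=demo.index)).map(
        lambda s: sex_map.get(str(s).upper(), "Unknown")
    ).value_counts().to_dict()

    age_counts = demo["age_years"].map(assign_age_group).value_counts().to_dict()
    weight_counts = demo["weight_kg"].map(assign_weight_group).value_counts().to_dict()

    occp_counts = demo.get("occp_cod", pd.Series("", index=demo.index)).replace(
        "", "Unknown").value_counts().to_dict()

    country = demo.get("reporter_country", pd.Series("", index=demo.index)).replace("", "Unknown")
    country_counts = country.value_counts().to_dict()
    if top_countries and len(country_counts) > top_countries:
        top = sorted(country_counts, key=lambda k: (-country_counts[k], k))[:top_countries]
        others = sum(v for k, v in country_counts.items() if k not in top)
        country_counts = {k: country_counts[k] for k in top}
        country_counts["Others"] = others

    if continent_of is not None:
        cont_counts = country.map(
            lambda c: continent_of.get(str(c).upper(), "Unknown")
        ).value_counts().to_dict()
    else:
        cont_counts = {}

    indi = data.indi[data.indi["primaryid"].isin(set(ids))]
    indi_counts = (
        indi[["primaryid", "indi_pt"]].drop_duplicates()["indi_pt"]
        .value_counts().head(top_indications).to_dict()
        if not indi.empty else {}
    )

    outc = data.outc[data.outc["primaryid"].isin(set(ids))]
    outc_counts = (
        outc[["primaryid", "outc_cod"]].drop_duplicates()["outc_cod"]
        .value_counts().to_dict()
        if not outc.empty else {}
    )

    # dose and duration from the matched drug rows
    drugs = data.drug[data.drug["primaryid"].isin(set(ids))]
    matched = drugs[matcher.mask(drugs)] if not drugs.empty else drugs
    dose_group_by_case: dict[str, str] = {}
    for pid, grp in matched.groupby("primaryid"):
        doses = [dose_per_day(r) for _, r in grp.iterrows()]
        doses = [x for x in doses if x is not None]
        dose_group_by_case[pid] = assign_dose_group(doses[0] if doses else None)
    dose_counts = pd.Series(
        [dose_group_by_case.get(pid, "Unknown") for pid in ids]
    ).value_counts().to_dict()

    matched_keys = set(zip(matched["primaryid"], matched["drug_seq"])) if not matched.empty else set()
    ther = data.ther[data.ther["primaryid"].isin(set(ids))]
    dur_by_case: dict[str, int | None] = {}
    if not ther.empty:
        link = ther[[k in matched_keys for k in zip(ther["primaryid"], ther["dsg_drug_seq"])]]
        for pid, grp in link.groupby("primaryid"):
            starts = [parse_date(v) for v in grp["start_dt"]]
            ends = [parse_date(v) for v in grp.get("end_dt", pd.Series("", index=grp.index))]
            day_starts = [p.value for p in starts if p.is_day]
            day_ends = [p.value for p in ends if p.is_day]
            if day_starts and day_ends:
                delta = (max(day_ends) - min(day_starts)).days
                dur_by_case[pid] = delta if delta >= 0 else None
    dur_counts = pd.Series(
        [assign_duration_group(dur_by_case.get(pid)) for pid in ids]
    ).value_counts().to_dict()

    table = CharacteristicsTable(n_cases=n)
    table.panels["sex"] = _panel(sex_counts, SEX_LABELS, n)
    table.panels["age_group"] = _panel(age_counts, AGE_LABELS, n)
    table.panels["weight_group"] = _panel(weight_counts, WEIGHT_LABELS, n)
    table.panels["reporter"] = _panel(occp_counts, None, n)
    table.panels["country"] = _panel(country_counts, None, n)
    if cont_counts:
        table.panels["continent"] = _panel(cont_counts, None, n)
    table.panels["indication"] = _panel(indi_counts, None, n)
    table.panels["outcome"] = _panel(outc_counts, OUTCOME_ORDER, n)
    table.panels["dose_group"] = _panel(dose_counts, DOSE_LABELS, n)
    table.panels["duration_group"] = _panel(dur_counts, DURATION_LABELS, n)
    return table
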