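"""Reading and writing FAERS quarterly ASCII extract tables.

FAERS ships each quarter as seven dollar-delimited ASCII tables (DEMO, DRUG,
REAC, THER, OUTC, INDI, RPSR), one header line each.  This module parses them
into plain :class:`pandas.DataFrame` objects with lower-cased, alias-resolved
column names, normalizes MedDRA preferred-term text, and provides tolerant
parsers for the partial dates, ages and weights found in spontaneous reports.

Everything is kept as strings at the I/O boundary (identifiers may carry
leading zeros); numeric/date views are added by :func:`derive_demo_fields`.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("faersig")

DEFAULT_DELIMITER = "$"

#: Minimal column set we require per table (2012Q4+ schema; the handful of
#: 2012Q1–Q3 aliases actually needed are resolved via COLUMN_ALIASES).
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
    "rpsr": ("primaryid", "rpsr_cod"),
}

#: Canonical column order used when writing fixtures.
WRITE_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid", "caseid", "event_dt", "fda_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "occp_cod", "reporter_country", "occr_country",
    ),
    "drug": (
        "primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai",
        "dose_amt", "dose_unit", "dose_freq",
    ),
    "reac": ("primaryid", "caseid", "pt"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "rpsr": ("primaryid", "caseid", "rpsr_cod"),
}

# early-2012 / legacy spellings that still occur inside the study window
COLUMN_ALIASES: dict[str, str] = {
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
    "lot_nbr": "lot_num",
}

MANDATORY_TABLES = ("demo", "drug", "reac")
OPTIONAL_TABLES = ("ther", "outc", "indi", "rpsr")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1429,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_TO_KG = {"KG": 1.0, "LBS": 0.453592, "GMS": 0.001}


# ---------------------------------------------------------------------------
# text / date / unit normalization
# ---------------------------------------------------------------------------

def normalize_pt(raw: str | None) -> str:
    """Canonicalize a MedDRA preferred term for counting.

    Collapses internal whitespace and applies sentence case (first letter
    upper, rest lower).  FAERS PT casing is inconsistent across quarters and
    counts must not split on case variants.
    """
    if raw is None:
        return ""
    text = " ".join(str(raw).split())
    if not text:
        return ""
    return text[0].upper() + text[1:].lower()


@dataclass(frozen=True)
class ParsedDate:
    """A calendar date with a precision tag (``day``/``month``/``year``/``none``)."""

    value: _dt.date | None
    precision: str

    @property
    def is_day(self) -> bool:
        return self.precision == "day"


_NONE_DATE = ParsedDate(None, "none")


def parse_date(raw: object) -> ParsedDate:
    """Parse a FAERS date field (YYYYMMDD / YYYYMM / YYYY) tolerantly.

    Total function: empty, non-digit, wrong-length or calendar-impossible
    input yields precision ``none`` instead of raising.  Month- and
    year-precision values are anchored to the first day of the period.
    """
    if raw is None:
        return _NONE_DATE
    text = str(raw).strip()
    if text.endswith(".0"):  # numeric round-trip through floats
        text = text[:-2]
    if not text or not text.isdigit():
        return _NONE_DATE
    try:
        if len(text) == 8:
            return ParsedDate(
                _dt.date(int(text[:4]), int(text[4:6]), int(text[6:8])), "day"
            )
        if len(text) == 6:
            return ParsedDate(_dt.date(int(text[:4]), int(text[4:6]), 1), "month")
        if len(text) == 4:
            return ParsedDate(_dt.date(int(text), 1, 1), "year")
    except ValueError:
        return _NONE_DATE
    return _NONE_DATE


def format_date(parsed: ParsedDate) -> str:
    if parsed.value is None:
        return ""
    if parsed.precision == "day":
        return parsed.value.strftime("%Y%m%d")
    if parsed.precision == "month":
        return parsed.value.strftime("%Y%m")
    return parsed.value.strftime("%Y")


def normalize_age(age_value: object, age_unit: object) -> float | None:
    """Convert a FAERS age (value, unit-code) pair to years.

    Unit codes follow the FAERS dictionary (YR, DEC, MON, WK, DY, HR).  An
    unknown/blank unit with a value plausible as years (18–120) is treated as
    years; anything else is unknown.  Negative values are unknown.
    """
    try:
        value = float(age_value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if value != value or value < 0:  # NaN or negative
        return None
    unit = str(age_unit).strip().upper() if age_unit is not None else ""
    if unit in AGE_TO_YEARS:
        return value * AGE_TO_YEARS[unit]
    if 18.0 <= value <= 120.0:  # bare value plausible as years
        return value
    return None


def normalize_weight(weight_value: object, weight_unit: object) -> float | None:
    """Convert a FAERS weight (value, unit-code) pair to kilograms.

    Non-positive or unparsable values are unknown; an unknown unit is treated
    as kilograms only when the value is plausible (20–300 kg).
    """
    try:
        value = float(weight_value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if value != value or value <= 0:
        return None
    unit = str(weight_unit).strip().upper() if weight_unit is not None else ""
    if unit in WEIGHT_TO_KG:
        return value * WEIGHT_TO_KG[unit]
    if 20.0 <= value <= 300.0:
        return value
    return None


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------

@dataclass
class QuarterBundle:
    """All tables of one FAERS quarterly extract, plus parse bookkeeping."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    label: str = ""
    warnings: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_reports(self) -> int:
        return len(self.demo)


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in WRITE_COLUMNS[name]})


def read_table(
    path: str | Path, name: str, delimiter: str = DEFAULT_DELIMITER
) -> tuple[pd.DataFrame, int]:
    """Read one FAERS ASCII table.

    Returns the frame (string dtype, lower-cased/alias-resolved headers,
    cell-level whitespace stripped) and the number of malformed lines that
    had to be skipped.  Column order in the file is irrelevant; extra
    columns are preserved.
    """
    path = Path(path)
    bad = {"n": 0}

    def _on_bad(line: list[str]):  # pragma: no cover - exercised via counter
        bad["n"] += 1
        return None

    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=[],
        engine="python",
        on_bad_lines=_on_bad,
    )
    df.columns = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: table {name!r} missing required columns {missing}")
    for col in df.columns:
        df[col] = df[col].str.strip()
    if bad["n"]:
        logger.warning("%s: skipped %d malformed lines", path, bad["n"])
    return df, bad["n"]


def read_quarter(
    paths: Mapping[str, str | Path],
    delimiter: str = DEFAULT_DELIMITER,
    label: str = "",
) -> QuarterBundle:
    """Read one quarter's tables into a :class:`QuarterBundle`.

    ``paths`` maps table names (``demo``, ``drug``, ``reac``, optionally
    ``ther``/``outc``/``indi``) to files.  DEMO/DRUG/REAC are mandatory;
    missing optional tables yield empty frames plus a warning counter.
    Rows referencing a primaryid absent from DEMO are counted as orphans
    and excluded.  Nothing is dropped without a counter.
    """
    warnings: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    for name in MANDATORY_TABLES:
        if name not in paths or not Path(paths[name]).exists():
            raise FileNotFoundError(f"mandatory table {name!r} not found in {dict(paths)}")
        tables[name], warnings[f"{name}_malformed"] = read_table(paths[name], name, delimiter)

    for name in ("ther", "outc", "indi"):
        if name in paths and Path(paths[name]).exists():
            tables[name], warnings[f"{name}_malformed"] = read_table(paths[name], name, delimiter)
        else:
            tables[name] = _empty_table(name)
            warnings[f"{name}_missing_table"] = 1
            logger.warning("optional table %s absent for quarter %s", name, label)

    demo = tables["demo"]
    # demo integrity: primaryid and fda_dt must be present
    bad_demo = (demo["primaryid"] == "") | (demo["fda_dt"] == "")
    if bad_demo.any():
        warnings["demo_missing_key"] = int(bad_demo.sum())
        demo = demo[~bad_demo].reset_index(drop=True)
    tables["demo"] = demo

    known = set(demo["primaryid"])
    for name in ("drug", "reac", "ther", "outc", "indi"):
        tbl = tables[name]
        if tbl.empty:
            continue
        orphan = ~tbl["primaryid"].isin(known)
        if orphan.any():
            warnings[f"{name}_orphan_rows"] = int(orphan.sum())
            logger.warning(
                "quarter %s: %d %s rows reference a primaryid absent from DEMO",
                label, int(orphan.sum()), name.upper(),
            )
            tbl = tbl[~orphan].reset_index(drop=True)
        tables[name] = tbl

    reac = tables["reac"]
    if not reac.empty:
        reac = reac.copy()
        reac["pt"] = reac["pt"].map(normalize_pt)
        empty_pt = reac["pt"] == ""
        if empty_pt.any():
            warnings["reac_empty_pt"] = int(empty_pt.sum())
            reac = reac[~empty_pt].reset_index(drop=True)
        tables["reac"] = reac

    indi = tables["indi"]
    if not indi.empty:
        indi = indi.copy()
        indi["indi_pt"] = indi["indi_pt"].map(normalize_pt)
        tables["indi"] = indi

    drug = tables["drug"]
    if not drug.empty:
        bad_role = ~drug["role_cod"].str.upper().isin(ROLE_CODES)
        if bad_role.any():
            warnings["drug_unknown_role"] = int(bad_role.sum())

    return QuarterBundle(
        demo=tables["demo"], drug=tables["drug"], reac=tables["reac"],
        ther=tables["ther"], outc=tables["outc"], indi=tables["indi"],
        label=label, warnings=warnings,
    )


def quarter_paths(directory: str | Path, suffix: str = ".txt") -> dict[str, Path]:
    """Locate per-table files (DEMO.txt etc., case-insensitive) in a directory."""
    directory = Path(directory)
    found: dict[str, Path] = {}
    for p in sorted(directory.iterdir()):
        stem = p.stem.lower()
        for name in REQUIRED_COLUMNS:
            if stem.startswith(name) and p.suffix.lower() == suffix:
                found.setdefault(name, p)
    return found


def write_quarter(
    bundle: QuarterBundle,
    directory: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
) -> dict[str, Path]:
    """Write a bundle back to FAERS-dialect ASCII files (fixture writer)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("demo", "drug", "reac", "ther", "outc", "indi"):
        df = bundle.table(name)
        cols = [c for c in WRITE_COLUMNS[name] if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        path = directory / f"{name.upper()}{bundle.label}.txt"
        out = df[cols].fillna("")
        out.columns = [c.upper() for c in cols]
        out.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
        written[name] = path
    return written


def write_cache(bundle: QuarterBundle, directory: str | Path) -> None:
    """Write a columnar (parquet) cache of a bundle for fast re-reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("demo", "drug", "reac", "ther", "outc", "indi"):
        bundle.table(name).to_parquet(directory / f"{name}.parquet")


def read_cache(directory: str | Path, label: str = "") -> QuarterBundle:
    directory = Path(directory)
    frames = {
        name: pd.read_parquet(directory / f"{name}.parquet")
        for name in ("demo", "drug", "reac", "ther", "outc", "indi")
    }
    return QuarterBundle(label=label, **frames)


def concat_quarters(bundles: Iterable[QuarterBundle]) -> QuarterBundle:
    """Concatenate several quarterly bundles into one (warnings summed)."""
    bundles = list(bundles)
    if not bundles:
        raise ValueError("no bundles to concatenate")
    warnings: dict[str, int] = {}
    for b in bundles:
        for k, v in b.warnings.items():
            warnings[k] = warnings.get(k, 0) + v
    frames = {
        name: pd.concat([b.table(name) for b in bundles], ignore_index=True)
        for name in ("demo", "drug", "reac", "ther", "outc", "indi")
    }
    label = "+".join(b.label for b in bundles if b.label)
    return QuarterBundle(label=label, warnings=warnings, **frames)


# ---------------------------------------------------------------------------
# derived numeric/date views
# ---------------------------------------------------------------------------

def derive_demo_fields(demo: pd.DataFrame) -> pd.DataFrame:
    """Add parsed/normalized columns to a DEMO frame.

    Adds ``fda_dt_i`` and ``primaryid_i`` (integer views used by the
    deduplication rule), ``age_years``, ``weight_kg``, ``event_date`` and
    ``event_precision``.  The original string columns are untouched.
    """
    out = demo.copy()
    out["fda_dt_i"] = pd.to_numeric(out["fda_dt"], errors="coerce").fillna(-1).astype("int64")
    out["primaryid_i"] = pd.to_numeric(out["primaryid"], errors="coerce").fillna(-1).astype("int64")

    def _col(name: str) -> pd.Series:
        return out[name] if name in out.columns else pd.Series("", index=out.index)

    # vectorized age: value × unit factor, unknown unit accepted only for
    # values plausible as years (18–120)
    age_v = pd.to_numeric(_col("age"), errors="coerce")
    factor = _col("age_cod").str.strip().str.upper().map(AGE_TO_YEARS)
    years = age_v * factor
    bare = factor.isna() & age_v.between(18, 120)
    years = years.where(~bare, age_v)
    out["age_years"] = years.where(age_v >= 0, other=pd.NA).astype(float)

    wt_v = pd.to_numeric(_col("wt"), errors="coerce")
    wfac = _col("wt_cod").str.strip().str.upper().map(WEIGHT_TO_KG)
    kg = wt_v * wfac
    bare_w = wfac.isna() & wt_v.between(20, 300)
    kg = kg.where(~bare_w, wt_v)
    out["weight_kg"] = kg.where(wt_v > 0, other=pd.NA).astype(float)

    raw = _col("event_dt").str.strip().str.removesuffix(".0")
    digits = raw.str.isdigit().fillna(False)
    day = pd.to_datetime(raw.where(digits & (raw.str.len() == 8)),
                         format="%Y%m%d", errors="coerce")
    month = pd.to_datetime(raw.where(digits & (raw.str.len() == 6)),
                           format="%Y%m", errors="coerce")
    year = pd.to_datetime(raw.where(digits & (raw.str.len() == 4)),
                          format="%Y", errors="coerce")
    combined = day.fillna(month).fillna(year)
    out["event_date"] = pd.Series(
        [ts.date() if ts is not pd.NaT else None for ts in combined], index=out.index,
        dtype=object,
    )
    out["event_precision"] = np.select(
        [day.notna(), month.notna(), year.notna()],
        ["day", "month", "year"], default="none",
    )
    return out
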