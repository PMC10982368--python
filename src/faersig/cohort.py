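"""Case-level curation: deduplication, drug-name matching, cohort selection.

Spontaneous reports arrive in versions: one *case* (CASEID) may be submitted
several times with distinct report identifiers (PRIMARYID).  The FDA
recommendation keeps, per case, the version with the latest FDA receipt date
and, among ties, the largest PRIMARYID.  On top of the deduplicated case set
this module applies the study filters: reports naming the target drug as
primary suspect (PS) and reports submitted by healthcare professionals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import QuarterBundle, derive_demo_fields

logger = logging.getLogger("faersig")

#: Default target-drug name patterns: generic plus worldwide brand names.
DEFAULT_PATTERNS: tuple[str, ...] = ("MIRABEGRON", "BETMIGA", "BETANIS", "MYRBETRIQ")

#: Healthcare-professional reporter occupation codes.
HCP_CODES: frozenset[str] = frozenset({"MD", "PH", "OT"})

#: SOCs conventionally excluded from drug-AE screening.
DEFAULT_EXCLUDED_SOCS: tuple[str, ...] = (
    "Injury, poisoning and procedural complications",
    "Product issues",
    "Surgical and medical procedures",
    "Social circumstances",
)


class CohortError(RuntimeError):
    """Raised when curation produces an unusable cohort (e.g. empty target)."""


@dataclass(frozen=True)
class NameMatcher:
    """Word-bounded, case-insensitive drug-name matcher.

    A pattern matches when it occurs in ``drugname`` or ``prod_ai`` delimited
    by non-alphanumeric characters (or string edges), so ``MIRABEGRON 50 MG``
    matches but ``MIRTAZAPINE`` does not; verbatim FAERS names carry dose and
    form suffixes that a plain equality test would miss.
    """

    patterns: tuple[str, ...] = DEFAULT_PATTERNS

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("NameMatcher needs at least one pattern")

    @property
    def regex(self) -> re.Pattern[str]:
        alternatives = "|".join(re.escape(p) for p in self.patterns)
        return re.compile(
            rf"(?<![A-Za-z0-9])(?:{alternatives})(?![A-Za-z0-9])", re.IGNORECASE
        )

    def matches(self, text: object) -> bool:
        return bool(text) and self.regex.search(str(text)) is not None

    def mask(self, drug: pd.DataFrame) -> pd.Series:
        """Boolean row mask over a DRUG frame (drugname OR prod_ai)."""
        m = drug["drugname"].str.contains(self.regex, na=False, regex=True)
        if "prod_ai" in drug.columns:
            m = m | drug["prod_ai"].str.contains(self.regex, na=False, regex=True)
        return m


def match_target(drugs: pd.DataFrame | Iterable[dict], matcher: NameMatcher) -> set[str]:
    """Return the set of ``drug_seq`` values of one report that match."""
    if not isinstance(drugs, pd.DataFrame):
        drugs = pd.DataFrame(list(drugs))
    if drugs.empty:
        return set()
    return set(drugs.loc[matcher.mask(drugs), "drug_seq"])


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report version per case (FDA rule).

    Per CASEID the version with the maximum FDA_DT is kept; FDA_DT ties are
    broken by the maximum PRIMARYID, compared as integers, not
    lexicographically.  Records with a missing caseid are conservatively kept
    as singleton cases (counted via a warning).  The result is independent of
    input order and idempotent.
    """
    if demo.empty:
        return demo.copy()
    df = demo
    if "fda_dt_i" not in df.columns or "primaryid_i" not in df.columns:
        df = derive_demo_fields(df)
    df = df.copy()
    missing = df["caseid"] == ""
    if missing.any():
        logger.warning("%d DEMO records lack a caseid; kept as singleton cases",
                       int(missing.sum()))
    key = df["caseid"].where(~missing, "__pid__" + df["primaryid"])
    df["_dedup_key"] = key
    df = df.sort_values(
        ["_dedup_key", "fda_dt_i", "primaryid_i"], kind="mergesort"
    ).drop_duplicates("_dedup_key", keep="last")
    return (
        df.drop(columns="_dedup_key")
        .sort_values("primaryid_i", kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# assembled case-level data
# ---------------------------------------------------------------------------

@dataclass
class CaseData:
    """Deduplicated case-level view of one or more FAERS quarters.

    ``demo`` holds exactly one row per case (with derived numeric fields);
    the child tables are restricted to the retained report versions.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    n_raw_reports: int = 0

    @classmethod
    def from_bundle(cls, bundle: QuarterBundle) -> "CaseData":
        demo = derive_demo_fields(bundle.demo)
        deduped = deduplicate(demo)
        keep = set(deduped["primaryid"])
        children = {
            name: bundle.table(name)[bundle.table(name)["primaryid"].isin(keep)]
            .reset_index(drop=True)
            for name in ("drug", "reac", "ther", "outc", "indi")
        }
        return cls(demo=deduped, n_raw_reports=len(demo), **children)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    @property
    def n_duplicates_removed(self) -> int:
        return self.n_raw_reports - self.n_cases

    def case_ids(self) -> pd.Series:
        return self.demo["primaryid"]

    def events(self) -> pd.DataFrame:
        """Distinct (primaryid, pt) pairs — report-level event set semantics."""
        return self.reac[["primaryid", "pt"]].drop_duplicates()


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report, fully assembled (convenience view)."""

    primaryid: str
    caseid: str
    sex: str
    age_years: float | None
    weight_kg: float | None
    reporter_country: str
    occp_cod: str
    drugs: tuple[dict, ...]
    reactions: frozenset[str]
    therapies: tuple[dict, ...]
    outcomes: frozenset[str]
    indications: tuple[dict, ...]
    is_target: bool
    event_date: object = None
    event_precision: str = "none"


def build_case(data: CaseData, primaryid: str, matcher: NameMatcher | None = None) -> CaseReport:
    """Assemble the :class:`CaseReport` for one retained report version."""
    row = data.demo.loc[data.demo["primaryid"] == primaryid]
    if row.empty:
        raise KeyError(f"primaryid {primaryid!r} not in case set")
    row = row.iloc[0]
    drugs = data.drug[data.drug["primaryid"] == primaryid]
    matched = match_target(drugs, matcher) if matcher is not None else set()
    is_target = bool(
        not drugs.empty
        and matcher is not None
        and (drugs["drug_seq"].isin(matched) & (drugs["role_cod"] == "PS")).any()
    )
    return CaseReport(
        primaryid=primaryid,
        caseid=row["caseid"],
        sex=row.get("sex", ""),
        age_years=row.get("age_years"),
        weight_kg=row.get("weight_kg"),
        reporter_country=row.get("reporter_country", ""),
        occp_cod=row.get("occp_cod", ""),
        drugs=tuple(drugs.to_dict("records")),
        reactions=frozenset(data.reac.loc[data.reac["primaryid"] == primaryid, "pt"]),
        therapies=tuple(
            data.ther[data.ther["primaryid"] == primaryid].to_dict("records")
        ),
        outcomes=frozenset(data.outc.loc[data.outc["primaryid"] == primaryid, "outc_cod"]),
        indications=tuple(
            data.indi[data.indi["primaryid"] == primaryid].to_dict("records")
        ),
        is_target=is_target,
        event_date=row.get("event_date"),
        event_precision=row.get("event_precision", "none"),
    )


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

@dataclass
class CohortSplit:
    """Disjoint target / comparator report-id sets plus attrition counts."""

    target_ids: pd.Index
    background_ids: pd.Index
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_target(self) -> int:
        return len(self.target_ids)

    @property
    def n_background(self) -> int:
        return len(self.background_ids)


def select_cohort(
    data: CaseData,
    matcher: NameMatcher | None = None,
    reporter_codes: Iterable[str] = HCP_CODES,
    strict_ps: bool = False,
    filter_background: bool = True,
) -> CohortSplit:
    """Split the deduplicated case set into target and comparator cohorts.

    Target: cases where a drug matching ``matcher`` carries role PS and the
    reporter occupation is in ``reporter_codes``.  Comparator: every other
    case under the same reporter filter, so numerator and denominator are
    curated identically (set ``filter_background=False`` for the unfiltered
    database comparator).  ``strict_ps`` additionally requires that no
    non-matching drug in the report carries role PS.
    """
    matcher = matcher or NameMatcher()
    reporter_codes = frozenset(reporter_codes)

    drugs = data.drug
    matched_rows = matcher.mask(drugs) if not drugs.empty else pd.Series(dtype=bool)
    target_any = set(drugs.loc[matched_rows, "primaryid"]) if not drugs.empty else set()
    role = drugs["role_cod"].str.upper() if not drugs.empty else pd.Series(dtype=str)
    target_ps = (
        set(drugs.loc[matched_rows & (role == "PS"), "primaryid"])
        if not drugs.empty else set()
    )
    if strict_ps and not drugs.empty:
        other_ps = set(drugs.loc[~matched_rows & (role == "PS"), "primaryid"])
        target_ps = target_ps - other_ps

    demo = data.demo
    occp = demo["occp_cod"].str.upper() if "occp_cod" in demo.columns else pd.Series("", index=demo.index)
    hcp_mask = occp.isin(reporter_codes)
    is_target = demo["primaryid"].isin(target_ps) & hcp_mask
    if filter_background:
        is_background = hcp_mask & ~is_target
    else:
        is_background = ~is_target

    counts = {
        "cases_total": len(demo),
        "cases_reporter_filter": int(hcp_mask.sum()),
        "target_any_role": len(target_any),
        "target_ps": len(target_ps),
        "target_final": int(is_target.sum()),
        "background_final": int(is_background.sum()),
    }
    if counts["target_final"] == 0:
        raise CohortError(f"empty target cohort after filtering; diagnostics: {counts}")
    logger.info("cohort selection: %s", counts)
    return CohortSplit(
        target_ids=pd.Index(demo.loc[is_target, "primaryid"]),
        background_ids=pd.Index(demo.loc[is_background, "primaryid"]),
        counts=counts,
    )


def exclude_socs(
    events: pd.DataFrame,
    excluded: Sequence[str] = DEFAULT_EXCLUDED_SOCS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop event triples whose SOC is in the excluded set.

    ``events`` must carry columns ``primaryid``, ``pt`` and ``soc``.  Removal
    counts per excluded SOC are returned alongside the filtered frame; an
    empty exclusion set is the identity.
    """
    if not len(excluded) or events.empty:
        return events, {}
    excluded_lc = {s.casefold() for s in excluded}
    mask = events["soc"].str.casefold().isin(excluded_lc)
    removed = (
        events.loc[mask, "soc"].value_counts().to_dict() if mask.any() else {}
    )
    if removed:
        logger.info("SOC exclusion removed %d event rows: %s", int(mask.sum()), removed)
    return events.loc[~mask].reset_index(drop=True), {str(k): int(v) for k, v in removed.items()}
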