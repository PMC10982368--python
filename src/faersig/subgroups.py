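"""Stratified re-screening: weight bands, continents, concomitant drugs.

Each stratum restricts *both* the target and the comparator cohort (a
within-stratum 2×2), so a subgroup signal reflects disproportionality
inside the stratum rather than the stratum's overall reporting volume; a
``within_stratum=False`` switch keeps the global comparator instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CaseData, NameMatcher
from .descriptives import assign_weight_group
from .disproportionality import (
    IcPriorConfig,
    ScreenResult,
    SignalResult,
    Thresholds,
    screen,
)
from .meddra import PtSocMap

logger = logging.getLogger("faersig")

CONTINENTS = ("North America", "Europe", "Asia", "South America",
              "Oceania", "Africa", "Unknown")

#: Country code/name → continent for the countries the bundled generator
#: emits plus common FAERS spellings; anything else resolves to Unknown.
DEFAULT_CONTINENTS: dict[str, str] = {
    "US": "North America", "UNITED STATES": "North America",
    "CA": "North America", "CANADA": "North America",
    "MX": "North America", "MEXICO": "North America",
    "GB": "Europe", "GREAT BRITAIN": "Europe", "UNITED KINGDOM": "Europe",
    "ES": "Europe", "SPAIN": "Europe",
    "FR": "Europe", "FRANCE": "Europe",
    "DE": "Europe", "GERMANY": "Europe",
    "IT": "Europe", "ITALY": "Europe",
    "NL": "Europe", "NETHERLANDS": "Europe",
    "JP": "Asia", "JAPAN": "Asia",
    "CN": "Asia", "CHINA": "Asia",
    "KR": "Asia", "KOREA, REPUBLIC OF": "Asia",
    "IN": "Asia", "INDIA": "Asia",
    "BR": "South America", "BRAZIL": "South America",
    "AR": "South America", "ARGENTINA": "South America",
    "AU": "Oceania", "AUSTRALIA": "Oceania",
    "NZ": "Oceania", "NEW ZEALAND": "Oceania",
    "ZA": "Africa", "SOUTH AFRICA": "Africa",
    "EG": "Africa", "EGYPT": "Africa",
}


@dataclass
class CountryContinentMap:
    """Total country → continent mapping with Unknown default."""

    entries: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CONTINENTS))

    def __post_init__(self) -> None:
        self.entries = {k.strip().upper(): v.strip() for k, v in self.entries.items()}

    def resolve(self, country: object) -> str:
        if not country:
            return "Unknown"
        return self.entries.get(str(country).strip().upper(), "Unknown")


def load_continent_map(path: str | Path, delimiter: str = "\t") -> CountryContinentMap:
    """Load a two-column (country, continent) delimited file."""
    entries: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}: expected 2 columns in {line!r}")
            entries[parts[0]] = parts[1]
    return CountryContinentMap(entries=entries)


@dataclass(frozen=True)
class SubgroupSpec:
    """Declarative definition of a report stratum.

    kind: ``all`` (no-op), ``weight_band`` (parameter: band label),
    ``continent`` (parameter: continent name) or ``concomitant_drug``
    (parameter: co-reported drug name pattern, word-bounded matching).
    """

    kind: str
    parameter: str = ""

    def __post_init__(self) -> None:
        kinds = {"all", "weight_band", "continent", "concomitant_drug"}
        if self.kind not in kinds:
            raise ValueError(f"unknown subgroup kind {self.kind!r}")
        if self.kind == "weight_band" and self.parameter not in (
            "<50", "50–100", ">100", "Unknown"
        ):
            raise ValueError(f"unknown weight band {self.parameter!r}")
        if self.kind == "continent" and self.parameter not in CONTINENTS:
            raise ValueError(f"unknown continent {self.parameter!r}")
        if self.kind == "concomitant_drug" and not self.parameter:
            raise ValueError("concomitant_drug needs a drug name pattern")

    @property
    def label(self) -> str:
        return self.kind if self.kind == "all" else f"{self.kind}:{self.parameter}"


def _member_ids(
    data: CaseData,
    spec: SubgroupSpec,
    continent_map: CountryContinentMap | None,
    target_matcher: NameMatcher,
) -> set[str]:
    demo = data.demo
    if spec.kind == "weight_band":
        member = demo["weight_kg"].map(assign_weight_group) == spec.parameter
        return set(demo.loc[member, "primaryid"])
    if spec.kind == "continent":
        cmap = continent_map or CountryContinentMap()
        country = demo.get("reporter_country", pd.Series("", index=demo.index))
        member = country.map(cmap.resolve) == spec.parameter
        return set(demo.loc[member, "primaryid"])
    # concomitant_drug: any drug row matching the pattern that is not itself
    # a target-drug row (the co-drug may carry any role, including SS)
    co_matcher = NameMatcher(patterns=(spec.parameter,))
    drugs = data.drug
    if drugs.empty:
        return set()
    co_rows = co_matcher.mask(drugs) & ~target_matcher.mask(drugs)
    return set(drugs.loc[co_rows, "primaryid"])


def stratify(
    data: CaseData,
    target_ids,
    background_ids,
    spec: SubgroupSpec,
    continent_map: CountryContinentMap | None = None,
    matcher: NameMatcher | None = None,
    within_stratum: bool = True,
) -> tuple[pd.Index, pd.Index]:
    """Restrict the cohorts to a stratum; empty target is a warning, not an error."""
    target_ids = pd.Index(target_ids)
    background_ids = pd.Index(background_ids)
    if spec.kind == "all":
        return target_ids, background_ids
    matcher = matcher or NameMatcher()
    members = _member_ids(data, spec, continent_map, matcher)
    target_sub = target_ids[target_ids.isin(members)]
    background_sub = (
        background_ids[background_ids.isin(members)] if within_stratum else background_ids
    )
    if len(target_sub) == 0:
        logger.warning("subgroup %s: empty target stratum", spec.label)
    return target_sub, background_sub


def top_concomitants(
    data: CaseData,
    target_ids,
    matcher: NameMatcher | None = None,
    k: int = 10,
) -> list[tuple[str, int]]:
    """Rank co-reported (non-target) drugs by distinct-report count.

    Drug names are whitespace-collapsed and upper-cased before counting; a
    drug listed twice in one report counts once.  Ties break alphabetically.
    """
    matcher = matcher or NameMatcher()
    ids = set(pd.Index(target_ids).unique())
    drugs = data.drug[data.drug["primaryid"].isin(ids)]
    if drugs.empty:
        return []
    co = drugs[~matcher.mask(drugs)].copy()
    if co.empty:
        return []
    co["name"] = co["drugname"].map(lambda s: " ".join(str(s).split()).upper())
    co = co[co["name"] != ""]
    counts = co[["primaryid", "name"]].drop_duplicates()["name"].value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, int(cnt)) for name, cnt in ranked[:k]]


def screen_subgroup(
    data: CaseData,
    target_ids,
    background_ids,
    spec: SubgroupSpec,
    ptsoc: PtSocMap | None = None,
    continent_map: CountryContinentMap | None = None,
    matcher: NameMatcher | None = None,
    thresholds: Thresholds = Thresholds(),
    priors: IcPriorConfig = IcPriorConfig(),
    within_stratum: bool = True,
    **screen_kwargs,
) -> ScreenResult:
    """Run the standard dual-criterion screen inside one stratum."""
    t_sub, b_sub = stratify(
        data, target_ids, background_ids, spec,
        continent_map=continent_map, matcher=matcher, within_stratum=within_stratum,
    )
    if len(t_sub) == 0:
        return ScreenResult(label=spec.label)
    return screen(
        data, t_sub, b_sub, ptsoc=ptsoc, thresholds=thresholds, priors=priors,
        label=spec.label, **screen_kwargs,
    )


def top_terms(result: ScreenResult, k: int = 10) -> list[SignalResult]:
    """Top PT signals by intensity: descending ROR among of-interest terms."""
    hits = [r for r in result.pt if r.of_interest]
    hits.sort(key=lambda r: (-r.ror.ror, -r.table.a, r.term))
    return hits[:k]


def exhaustive_weight_specs() -> tuple[SubgroupSpec, ...]:
    return tuple(SubgroupSpec("weight_band", band) for band in ("<50", "50–100", ">100", "Unknown"))
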