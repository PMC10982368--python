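"""Disproportionality statistics: reporting odds ratio and BCPNN information
component on drug-by-event 2×2 report tables.

For each event term the deduplicated reports are cross-classified as

    ===============  =========  ==========
                      event      no event
    ===============  =========  ==========
    target cohort        a          b
    comparator           c          d
    ===============  =========  ==========

Counting is report-level: a report contributes at most once per distinct
term no matter how many duplicate reaction rows it carries.

*ROR* = ad/(bc) with Wald CI ``exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))``; any
zero cell triggers the Haldane–Anscombe 0.5 correction (flagged).

*IC* (BCPNN) = log2 of the observed over expected co-reporting probability.
The closed-form posterior expectation and variance follow the standard
formulation with prior pseudo-counts γ11=α1=β1=1, α=β=2; ``IC025 =
E(IC) − 2·sqrt(V(IC))``.  A Monte-Carlo posterior (independent Beta draws
for the joint and the two margins) is available as a validation oracle.

A term is flagged *of interest* only when both criteria fire: ROR CI lower
bound > 1 with at least 3 target reports, and IC025 > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import DEFAULT_EXCLUDED_SOCS, CaseData, exclude_socs
from .meddra import UNMAPPED, PtSocMap, resolve

logger = logging.getLogger("faersig")

LN2 = float(np.log(2.0))

#: The 23 preferred terms listed in the product label / instructions for the
#: default target drug, used to annotate expected versus unexpected signals.
EXPECTED_TERMS: tuple[str, ...] = (
    "Cystitis",
    "Pyelonephritis acute",
    "Rhinitis",
    "Blood pressure increased",
    "Head discomfort",
    "Dry throat",
    "Dry mouth",
    "Bowel movement irregularity",
    "Blood pressure systolic increased",
    "Urinary retention",
    "Dysuria",
    "Cystitis interstitial",
    "Blood pressure abnormal",
    "Cystitis haemorrhagic",
    "Atrial fibrillation",
    "Tachycardia",
    "Atrial tachycardia",
    "Hypertension",
    "Hypertensive crisis",
    "Accelerated hypertension",
    "Malignant hypertension",
    "Essential hypertension",
    "Dry eye",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts for one (cohort, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool
    defined: bool = True


@dataclass(frozen=True)
class IcResult:
    ic_raw: float
    ic_expected: float
    ic_variance: float
    ic025: float
    variance_model: str = "bate1998"
    defined: bool = True


@dataclass(frozen=True)
class IcPriorConfig:
    """BCPNN prior pseudo-counts (standard defaults)."""

    g11: float = 1.0
    a1: float = 1.0
    b1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.g11, self.a1, self.b1, self.alpha, self.beta) <= 0:
            raise ValueError("all prior pseudo-counts must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Dual signal criteria: ROR CI lower bound and minimum report count,
    plus the IC credibility lower bound."""

    min_cases: int = 3
    ror_ci_low: float = 1.0
    ic025: float = 0.0


@dataclass(frozen=True)
class SignalResult:
    level: str  # "PT" | "SOC"
    term: str
    soc: str
    table: ContingencyTable
    ror: RorResult
    ic: IcResult
    ror_positive: bool
    ic_positive: bool
    expected_flag: bool = False

    @property
    def of_interest(self) -> bool:
        return self.ror_positive and self.ic_positive


# ---------------------------------------------------------------------------
# vectorized cores (shared by scalar wrappers and the screen)
# ---------------------------------------------------------------------------

def _ror_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ROR with CI; returns (ror, lo, hi, corrected, defined)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    z = norm.ppf(1.0 - alpha / 2.0)
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa, bb, cc, dd = (x + 0.5 * corrected for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (aa * dd) / (bb * cc)
        se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
        lo = np.exp(np.log(ror) - z * se)
        hi = np.exp(np.log(ror) + z * se)
    defined = ((a + b) > 0) & ((c + d) > 0) & ((a + c) > 0)
    ror = np.where(defined, ror, np.nan)
    lo = np.where(defined, lo, np.nan)
    hi = np.where(defined, hi, np.nan)
    return ror, lo, hi, corrected, defined


def _ic_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    priors: IcPriorConfig = IcPriorConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized BCPNN closed form; returns (ic_raw, e_ic, v_ic, ic025, defined)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    row = a + b  # target-cohort margin
    col = a + c  # event margin
    p = priors
    with np.errstate(divide="ignore", invalid="ignore"):
        ic_raw = np.log2(a * n / (row * col))
        gamma = p.g11 * (n + p.alpha) * (n + p.beta) / ((row + p.a1) * (col + p.b1))
        e_ic = np.log2(
            (a + p.g11) * (n + p.alpha) * (n + p.beta)
            / ((n + gamma) * (row + p.a1) * (col + p.b1))
        )
        v_ic = (1.0 / LN2**2) * (
            (n - a + gamma - p.g11) / ((a + p.g11) * (1.0 + n + gamma))
            + (n - row + p.alpha - p.a1) / ((row + p.a1) * (1.0 + n + p.alpha))
            + (n - col + p.beta - p.b1) / ((col + p.b1) * (1.0 + n + p.beta))
        )
        ic025 = e_ic - 2.0 * np.sqrt(v_ic)
    defined = (row > 0) & (col > 0)
    ic_raw = np.where(defined & (a > 0), ic_raw, np.where(defined, -np.inf, np.nan))
    e_ic = np.where(defined, e_ic, np.nan)
    v_ic = np.where(defined, v_ic, np.nan)
    ic025 = np.where(defined, ic025, np.nan)
    return ic_raw, e_ic, v_ic, ic025, defined


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def compute_ror(table: ContingencyTable, alpha: float = 0.05) -> RorResult:
    """ROR with Wald CI for one table (0.5-corrected on any zero cell)."""
    ror, lo, hi, corrected, defined = _ror_arrays(
        np.array([table.a]), np.array([table.b]),
        np.array([table.c]), np.array([table.d]), alpha,
    )
    return RorResult(
        ror=float(ror[0]), ci_low=float(lo[0]), ci_high=float(hi[0]),
        corrected=bool(corrected[0]), defined=bool(defined[0]),
    )


def compute_ic(
    table: ContingencyTable,
    priors: IcPriorConfig = IcPriorConfig(),
    variance_model: str = "bate1998",
    n_draws: int = 200_000,
    rng: np.random.Generator | None = None,
) -> IcResult:
    """BCPNN information component for one table.

    ``variance_model='bate1998'`` uses the closed-form posterior moments;
    ``'montecarlo'`` draws from independent Beta posteriors of the joint and
    marginal reporting probabilities and takes the 2.5th percentile of the
    sampled IC — the validation oracle for the closed form.
    """
    if variance_model == "bate1998":
        ic_raw, e_ic, v_ic, ic025, defined = _ic_arrays(
            np.array([table.a]), np.array([table.b]),
            np.array([table.c]), np.array([table.d]), priors,
        )
        return IcResult(
            ic_raw=float(ic_raw[0]), ic_expected=float(e_ic[0]),
            ic_variance=float(v_ic[0]), ic025=float(ic025[0]),
            variance_model="bate1998", defined=bool(defined[0]),
        )
    if variance_model != "montecarlo":
        raise ValueError(f"unknown variance model {variance_model!r}")

    a, b, c, d = table.a, table.b, table.c, table.d
    n, row, col = table.n, a + b, a + c
    if row == 0 or col == 0:
        return IcResult(np.nan, np.nan, np.nan, np.nan, "montecarlo", defined=False)
    p = IcPriorConfig() if priors is None else priors
    gamma = p.g11 * (n + p.alpha) * (n + p.beta) / ((row + p.a1) * (col + p.b1))
    rng = np.random.default_rng(0) if rng is None else rng
    p11 = rng.beta(a + p.g11, n - a + gamma - p.g11, n_draws)
    p1x = rng.beta(row + p.a1, n - row + p.alpha - p.a1, n_draws)
    px1 = rng.beta(col + p.b1, n - col + p.beta - p.b1, n_draws)
    draws = np.log2(p11 / (p1x * px1))
    ic_raw = log2(a * n / (row * col)) if a > 0 else -np.inf
    return IcResult(
        ic_raw=ic_raw,
        ic_expected=float(np.mean(draws)),
        ic_variance=float(np.var(draws)),
        ic025=float(np.percentile(draws, 2.5)),
        variance_model="montecarlo",
    )


def build_contingency(
    target_ids: Iterable[str],
    background_ids: Iterable[str],
    events: pd.DataFrame,
    term: str,
    term_column: str = "pt",
) -> ContingencyTable:
    """Count the 2×2 table for one event term.

    ``events`` holds (primaryid, term) rows; duplicates within a report are
    collapsed (set semantics), so each report contributes at most 1 per cell.
    """
    target_ids = pd.Index(target_ids).unique()
    background_ids = pd.Index(background_ids).unique()
    with_event = set(events.loc[events[term_column] == term, "primaryid"])
    a = int(target_ids.isin(with_event).sum())
    c = int(background_ids.isin(with_event).sum())
    return ContingencyTable(a=a, b=len(target_ids) - a, c=c, d=len(background_ids) - c)


def is_signal(
    n_cases: int, ror_ci_low: float, ic025: float,
    thresholds: Thresholds = Thresholds(),
) -> bool:
    """Apply the dual criteria to precomputed statistics."""
    ror_pos = (n_cases >= thresholds.min_cases) and (ror_ci_low > thresholds.ror_ci_low)
    return ror_pos and (ic025 > thresholds.ic025)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """PT- and SOC-level signal tables for one cohort split."""

    pt: list[SignalResult] = field(default_factory=list)
    soc: list[SignalResult] = field(default_factory=list)
    label: str = ""
    removed_by_soc_exclusion: dict[str, int] = field(default_factory=dict)
    n_unmapped_pts: int = 0

    def of_interest(self, level: str = "PT") -> list[SignalResult]:
        results = self.pt if level.upper() == "PT" else self.soc
        return [r for r in results if r.of_interest]

    def to_frame(self, level: str = "PT") -> pd.DataFrame:
        results = self.pt if level.upper() == "PT" else self.soc
        rows = []
        for r in results:
            rows.append({
                "level": r.level, "soc": r.soc, "term": r.term,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "ror": r.ror.ror, "ror_ci_low": r.ror.ci_low,
                "ror_ci_high": r.ror.ci_high, "ror_corrected": r.ror.corrected,
                "ic_raw": r.ic.ic_raw, "ic_expected": r.ic.ic_expected,
                "ic025": r.ic.ic025,
                "ror_positive": r.ror_positive, "ic_positive": r.ic_positive,
                "of_interest": r.of_interest, "expected": r.expected_flag,
            })
        return pd.DataFrame(rows)

    def publication_table(self, level: str = "PT") -> pd.DataFrame:
        """Columns mirroring the conventional published layout."""
        df = self.to_frame(level)
        if df.empty:
            return df
        out = pd.DataFrame({
            "SOC": df["soc"], "term": df["term"], "N": df["a"],
            "ROR (95% CI)": [
                f"{r:.2f} ({lo:.2f}-{hi:.2f})"
                for r, lo, hi in zip(df["ror"], df["ror_ci_low"], df["ror_ci_high"])
            ],
            "IC (IC025)": [
                f"{e:.2f} ({l:.2f})" for e, l in zip(df["ic_expected"], df["ic025"])
            ],
            "expected": np.where(df["expected"], "Yes", "No"),
        })
        if level.upper() == "SOC":
            out = out.drop(columns=["SOC", "expected"]).rename(columns={"term": "SOC"})
        return out


def _screen_level(
    level: str,
    events: pd.DataFrame,
    term_column: str,
    soc_of: dict[str, str],
    n_target: int,
    n_background: int,
    target_set: frozenset,
    thresholds: Thresholds,
    priors: IcPriorConfig,
    alpha: float,
    expected: frozenset[str],
) -> list[SignalResult]:
    pairs = events[["primaryid", term_column]].drop_duplicates()
    in_target = pairs["primaryid"].isin(target_set)
    a_counts = pairs.loc[in_target, term_column].value_counts()
    c_counts = pairs.loc[~in_target, term_column].value_counts()
    terms = sorted(set(a_counts.index) | set(c_counts.index))
    if not terms:
        return []
    a = np.array([a_counts.get(t, 0) for t in terms], dtype=float)
    c = np.array([c_counts.get(t, 0) for t in terms], dtype=float)
    b = n_target - a
    d = n_background - c
    ror, lo, hi, corrected, ror_def = _ror_arrays(a, b, c, d, alpha)
    ic_raw, e_ic, v_ic, ic025, ic_def = _ic_arrays(a, b, c, d, priors)
    results = []
    for i, term in enumerate(terms):
        if a[i] == 0:  # only terms observed in the target cohort are screened
            continue
        table = ContingencyTable(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        rr = RorResult(float(ror[i]), float(lo[i]), float(hi[i]),
                       bool(corrected[i]), bool(ror_def[i]))
        icr = IcResult(float(ic_raw[i]), float(e_ic[i]), float(v_ic[i]),
                       float(ic025[i]), "bate1998", bool(ic_def[i]))
        ror_pos = bool(rr.defined and table.a >= thresholds.min_cases
                       and rr.ci_low > thresholds.ror_ci_low)
        ic_pos = bool(icr.defined and icr.ic025 > thresholds.ic025)
        results.append(SignalResult(
            level=level, term=term,
            soc=soc_of.get(term, term if level == "SOC" else UNMAPPED),
            table=table, ror=rr, ic=icr,
            ror_positive=ror_pos, ic_positive=ic_pos,
            expected_flag=term in expected,
        ))
    # stable presentation order: SOC, then descending ROR, descending a, term
    results.sort(key=lambda r: (
        r.soc, -(r.ror.ror if np.isfinite(r.ror.ror) else -np.inf),
        -r.table.a, r.term,
    ))
    return results


def screen(
    data: CaseData,
    target_ids: Iterable[str],
    background_ids: Iterable[str],
    ptsoc: PtSocMap | None = None,
    thresholds: Thresholds = Thresholds(),
    priors: IcPriorConfig = IcPriorConfig(),
    alpha: float = 0.05,
    excluded_socs: Sequence[str] = DEFAULT_EXCLUDED_SOCS,
    expected_terms: Sequence[str] = EXPECTED_TERMS,
    label: str = "",
) -> ScreenResult:
    """Run the dual-criterion disproportionality screen at PT and SOC level.

    Events from the excluded SOCs are removed before counting.  Unmapped PTs
    are screened at PT level but cannot contribute to any SOC.  When no
    PT→SOC map is given, only the PT level is produced.
    """
    target_ids = pd.Index(target_ids).unique()
    background_ids = pd.Index(background_ids).unique()
    keep = target_ids.append(background_ids)
    events = data.events()
    events = events[events["primaryid"].isin(set(keep))].copy()

    removed: dict[str, int] = {}
    n_unmapped = 0
    if ptsoc is not None:
        # PTs in `events` are already canonicalized by the reader, so the
        # dict lookup is equivalent to resolve() but vectorized
        events["soc"] = events["pt"].map(ptsoc.entries).fillna(UNMAPPED)
        n_unmapped = int((events["soc"] == UNMAPPED).sum())
        events, removed = exclude_socs(events, excluded_socs)
    else:
        events["soc"] = UNMAPPED

    target_set = frozenset(target_ids)
    expected = frozenset(expected_terms)
    soc_of = (
        {pt: soc for pt, soc in events[["pt", "soc"]].drop_duplicates().itertuples(index=False)}
        if ptsoc is not None else {}
    )
    result = ScreenResult(label=label, removed_by_soc_exclusion=removed,
                          n_unmapped_pts=n_unmapped)
    result.pt = _screen_level(
        "PT", events, "pt", soc_of, len(target_ids), len(background_ids),
        target_set, thresholds, priors, alpha, expected,
    )
    if ptsoc is not None:
        soc_events = events.loc[events["soc"] != UNMAPPED, ["primaryid", "soc"]]
        result.soc = _screen_level(
            "SOC", soc_events, "soc", {}, len(target_ids), len(background_ids),
            target_set, thresholds, priors, alpha, frozenset(),
        )
    else:
        logger.warning("no PT→SOC map supplied; SOC-level screen skipped")
    return result
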