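"""Time-to-onset (TTO) analysis.

TTO is the number of days from the start of the suspect drug's therapy to
the recorded adverse-event onset date.  Only day-precision dates qualify;
when several therapy rows are linked to the matched primary-suspect drug
the earliest valid start date is used (onset is measured from first
exposure).  Negative intervals are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import CaseData, CaseReport, NameMatcher, match_target
from .faers_io import parse_date

logger = logging.getLogger("faersig")

TTO_BINS = ("0–30", "31–60", "61–90", "91–180", "181–360", ">360")
_BIN_EDGES = (30, 60, 90, 180, 360)


def assign_tto_bin(days: int) -> str:
    """Bin a non-negative TTO; 0–30 is inclusive at both ends."""
    if days < 0:
        raise ValueError("TTO must be non-negative")
    for edge, label in zip(_BIN_EDGES, TTO_BINS):
        if days <= edge:
            return label
    return ">360"


@dataclass(frozen=True)
class TtoRecord:
    caseid: str
    tto_days: int

    @property
    def bin(self) -> str:
        return assign_tto_bin(self.tto_days)


@dataclass
class TtoSummary:
    n_valid: int
    median_days: float
    iqr_low: float
    iqr_high: float
    bin_counts: dict[str, int] = field(default_factory=dict)
    bin_percents: dict[str, float] = field(default_factory=dict)
    counters: dict[str, int] = field(default_factory=dict)


def compute_tto(case: CaseReport, matcher: NameMatcher | None = None) -> int | None:
    """TTO in days for one assembled case, or None when not evaluable.

    Start = earliest day-precision therapy start linked to a matched
    primary-suspect drug; event = the report's day-precision onset date.
    """
    matcher = matcher or NameMatcher()
    if case.event_precision != "day" or case.event_date is None:
        return None
    drugs = pd.DataFrame(list(case.drugs))
    if drugs.empty:
        return None
    matched = match_target(drugs, matcher)
    ps_seqs = {
        r["drug_seq"] for r in case.drugs
        if r.get("drug_seq") in matched and str(r.get("role_cod", "")).upper() == "PS"
    }
    starts = [
        parse_date(t.get("start_dt"))
        for t in case.therapies
        if t.get("dsg_drug_seq") in ps_seqs
    ]
    day_starts = [p.value for p in starts if p.is_day]
    if not day_starts:
        return None
    tto = (case.event_date - min(day_starts)).days
    return tto if tto >= 0 else None


def compute_tto_frame(
    data: CaseData,
    target_ids,
    matcher: NameMatcher | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized TTO over a cohort; returns (records, exclusion counters)."""
    matcher = matcher or NameMatcher()
    ids = set(pd.Index(target_ids).unique())
    demo = data.demo[data.demo["primaryid"].isin(ids)]

    drugs = data.drug[data.drug["primaryid"].isin(ids)]
    role = drugs["role_cod"].str.upper() if not drugs.empty else pd.Series(dtype=str)
    matched_ps = drugs[(matcher.mask(drugs)) & (role == "PS")] if not drugs.empty else drugs
    ps_keys = set(zip(matched_ps["primaryid"], matched_ps["drug_seq"]))

    ther = data.ther[data.ther["primaryid"].isin(ids)]
    start_by_case: dict[str, object] = {}
    if not ther.empty:
        linked = ther[[k in ps_keys for k in zip(ther["primaryid"], ther["dsg_drug_seq"])]]
        for pid, grp in linked.groupby("primaryid"):
            day_starts = [p.value for p in (parse_date(v) for v in grp["start_dt"]) if p.is_day]
            if day_starts:
                start_by_case[pid] = min(day_starts)

    counters = {"valid": 0, "no_event_date": 0, "no_start_date": 0, "negative": 0}
    rows = []
    for _, r in demo.iterrows():
        pid = r["primaryid"]
        if r.get("event_precision") != "day" or r.get("event_date") is None:
            counters["no_event_date"] += 1
            continue
        start = start_by_case.get(pid)
        if start is None:
            counters["no_start_date"] += 1
            continue
        tto = (r["event_date"] - start).days
        if tto < 0:
            counters["negative"] += 1
            continue
        counters["valid"] += 1
        rows.append({"primaryid": pid, "caseid": r["caseid"], "tto_days": int(tto),
                     "bin": assign_tto_bin(int(tto))})
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "tto_days", "bin"]), counters


def summarize_tto(values: Iterable[int], counters: dict[str, int] | None = None) -> TtoSummary:
    """Median / IQR (linear-interpolation quantiles) and binned distribution."""
    vals = np.asarray(sorted(int(v) for v in values), dtype=float)
    if vals.size == 0:
        return TtoSummary(0, float("nan"), float("nan"), float("nan"),
                          {b: 0 for b in TTO_BINS}, {b: 0.0 for b in TTO_BINS},
                          counters or {})
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    bin_counts = {b: 0 for b in TTO_BINS}
    for v in vals:
        bin_counts[assign_tto_bin(int(v))] += 1
    n = int(vals.size)
    from .descriptives import percent
    bin_percents = {b: percent(c, n) for b, c in bin_counts.items()}
    return TtoSummary(
        n_valid=n, median_days=float(q50), iqr_low=float(q25), iqr_high=float(q75),
        bin_counts=bin_counts, bin_percents=bin_percents, counters=counters or {},
    )


def plot_tto(summary: TtoSummary, path) -> None:
    """Render the binned TTO distribution as a bar chart (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(summary.bin_counts)
    ax.bar(labels, [summary.bin_counts[b] for b in labels], color="#4878d0")
    ax.set_xlabel("Time to onset (days)")
    ax.set_ylabel("Reports")
    ax.set_title(f"Time to onset (n={summary.n_valid}, median {summary.median_days:.0f} d)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
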