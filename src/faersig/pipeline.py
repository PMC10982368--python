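"""End-to-end pipeline orchestration and run manifest.

Chains ingestion → deduplication → cohort selection → disproportionality
screen → descriptives → time-to-onset → subgroups, writing delimited output
tables plus a machine-readable manifest (config echo, attrition counts at
every filter step, input hashes).  The CLI in :mod:`faersig.cli` is a thin
wrapper over :func:`run_all`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import descriptives as _descriptives
from . import subgroups as _subgroups
from . import tto as _tto
from .cohort import (
    DEFAULT_EXCLUDED_SOCS,
    DEFAULT_PATTERNS,
    HCP_CODES,
    CaseData,
    CohortSplit,
    NameMatcher,
    select_cohort,
)
from .disproportionality import IcPriorConfig, ScreenResult, Thresholds, screen
from .faers_io import QuarterBundle, concat_quarters, quarter_paths, read_quarter
from .meddra import PtSocMap, load_map, toy_map
from .subgroups import CountryContinentMap, SubgroupSpec, load_continent_map
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger("faersig")


def configure_logging(level: int = logging.INFO) -> None:
    """Log to stderr with levels; safe to call repeatedly."""
    root = logging.getLogger("faersig")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    quarters_dir: str = ""            # directory containing per-quarter subdirs
    ptsoc_path: str = ""              # two-column PT→SOC file ("" → toy map)
    continent_path: str = ""          # two-column country→continent file
    drug_patterns: tuple[str, ...] = DEFAULT_PATTERNS
    reporter_codes: tuple[str, ...] = tuple(sorted(HCP_CODES))
    excluded_socs: tuple[str, ...] = DEFAULT_EXCLUDED_SOCS
    strict_ps: bool = False
    filter_background: bool = True
    min_cases: int = 3
    ror_ci_low: float = 1.0
    ic025: float = 0.0
    subgroup_specs: tuple[tuple[str, str], ...] = ()
    top_concomitants: int = 3
    outdir: str = "faersig_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drug_patterns", "reporter_codes", "excluded_socs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "subgroup_specs" in raw:
            raw["subgroup_specs"] = tuple((s["kind"], s.get("parameter", ""))
                                          for s in raw["subgroup_specs"])
        return cls(**raw)

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(min_cases=self.min_cases, ror_ci_low=self.ror_ci_low,
                          ic025=self.ic025)

    @property
    def matcher(self) -> NameMatcher:
        return NameMatcher(patterns=tuple(self.drug_patterns))


@dataclass
class PipelineResult:
    """Artifacts of one full run."""

    data: CaseData
    split: CohortSplit
    screen: ScreenResult
    characteristics: object
    tto_summary: object
    subgroup_screens: dict[str, ScreenResult] = field(default_factory=dict)
    top_concomitants: list[tuple[str, int]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def ingest(config: PipelineConfig) -> tuple[QuarterBundle, dict]:
    """Read every quarter directory under ``quarters_dir`` and concatenate."""
    base = Path(config.quarters_dir)
    if not base.is_dir():
        raise FileNotFoundError(f"quarters_dir {base} does not exist")
    qdirs = sorted(p for p in base.iterdir() if p.is_dir())
    if not qdirs:
        qdirs = [base]  # tables sit directly in the directory
    bundles, hashes = [], {}
    for qd in qdirs:
        paths = quarter_paths(qd)
        if not paths:
            continue
        bundles.append(read_quarter(paths, label=qd.name))
        for name, p in paths.items():
            hashes[f"{qd.name}/{p.name}"] = _hash_file(p)
    if not bundles:
        raise FileNotFoundError(f"no FAERS tables found under {base}")
    return concat_quarters(bundles), hashes


def _load_maps(config: PipelineConfig) -> tuple[PtSocMap | None, CountryContinentMap]:
    if config.ptsoc_path:
        ptsoc = load_map(config.ptsoc_path)
    else:
        logger.info("no PT→SOC map configured; using the bundled toy ontology")
        ptsoc = toy_map()
    cmap = (load_continent_map(config.continent_path)
            if config.continent_path else CountryContinentMap())
    return ptsoc, cmap


def run_all(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write tables plus manifest."""
    bundle, hashes = ingest(config)
    return run_on_bundle(bundle, config, input_hashes=hashes, write=write)


def run_on_bundle(
    bundle: QuarterBundle,
    config: PipelineConfig,
    input_hashes: dict | None = None,
    write: bool = True,
) -> PipelineResult:
    ptsoc, cmap = _load_maps(config)
    matcher = config.matcher

    data = CaseData.from_bundle(bundle)
    split = select_cohort(
        data, matcher, reporter_codes=config.reporter_codes,
        strict_ps=config.strict_ps, filter_background=config.filter_background,
    )
    result_screen = screen(
        data, split.target_ids, split.background_ids, ptsoc=ptsoc,
        thresholds=config.thresholds, excluded_socs=config.excluded_socs,
        label="global",
    )
    chars = _descriptives.summarize(
        data, split.target_ids, matcher=matcher,
        continent_of=cmap.entries,
    )
    tto_frame, tto_counters = _tto.compute_tto_frame(data, split.target_ids, matcher)
    tto_summary = _tto.summarize_tto(tto_frame["tto_days"], tto_counters)

    top_co = _subgroups.top_concomitants(data, split.target_ids, matcher,
                                         k=config.top_concomitants)
    specs = [SubgroupSpec(kind, param) for kind, param in config.subgroup_specs]
    if not specs:
        specs = [SubgroupSpec("weight_band", b) for b in ("<50", "50–100", ">100")]
        specs += [SubgroupSpec("continent", c) for c in ("North America", "Europe", "Asia")]
        specs += [SubgroupSpec("concomitant_drug", name) for name, _ in top_co]
    sub_screens = {}
    for spec in specs:
        sub_screens[spec.label] = _subgroups.screen_subgroup(
            data, split.target_ids, split.background_ids, spec,
            ptsoc=ptsoc, continent_map=cmap, matcher=matcher,
            thresholds=config.thresholds, excluded_socs=config.excluded_socs,
        )

    manifest = {
        "config": dataclasses.asdict(config),
        "input_hashes": input_hashes or {},
        "parse_warnings": bundle.warnings,
        "attrition": {
            "raw_reports": data.n_raw_reports,
            "deduplicated_cases": data.n_cases,
            "removed_duplicates": data.n_duplicates_removed,
            **split.counts,
        },
        "screen": {
            "n_pt_screened": len(result_screen.pt),
            "n_pt_of_interest": len(result_screen.of_interest("PT")),
            "n_soc_screened": len(result_screen.soc),
            "n_soc_of_interest": len(result_screen.of_interest("SOC")),
            "n_unmapped_pts": result_screen.n_unmapped_pts,
            "removed_by_soc_exclusion": result_screen.removed_by_soc_exclusion,
        },
        "tto": {
            "n_valid": tto_summary.n_valid,
            "median_days": tto_summary.median_days,
            "iqr": [tto_summary.iqr_low, tto_summary.iqr_high],
            "counters": tto_counters,
        },
        "seed": config.seed,
    }

    result = PipelineResult(
        data=data, split=split, screen=result_screen, characteristics=chars,
        tto_summary=tto_summary, subgroup_screens=sub_screens,
        top_concomitants=top_co, manifest=manifest,
    )
    if write:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.screen.to_frame("PT").to_csv(outdir / "screen_pt.tsv", sep="\t", index=False)
    result.screen.to_frame("SOC").to_csv(outdir / "screen_soc.tsv", sep="\t", index=False)
    result.screen.publication_table("PT").to_csv(
        outdir / "signals_pt_publication.tsv", sep="\t", index=False)
    result.screen.publication_table("SOC").to_csv(
        outdir / "signals_soc_publication.tsv", sep="\t", index=False)
    for name, panel in result.characteristics.panels.items():
        panel.to_csv(outdir / f"characteristics_{name}.tsv", sep="\t", index=False)
    ts = result.tto_summary
    with (outdir / "tto_summary.tsv").open("w") as fh:
        fh.write("n_valid\tmedian_days\tiqr_low\tiqr_high\n")
        fh.write(f"{ts.n_valid}\t{ts.median_days}\t{ts.iqr_low}\t{ts.iqr_high}\n")
    with (outdir / "tto_bins.tsv").open("w") as fh:
        fh.write("bin\tcount\tpercent\n")
        for b, c in ts.bin_counts.items():
            fh.write(f"{b}\t{c}\t{ts.bin_percents[b]}\n")
    if ts.n_valid:
        _tto.plot_tto(ts, outdir / "tto_histogram.png")
    for label, sub in result.subgroup_screens.items():
        safe = label.replace(":", "_").replace("/", "_").replace(" ", "_")
        sub.to_frame("PT").to_csv(outdir / f"subgroup_{safe}.tsv", sep="\t", index=False)
    with (outdir / "top_concomitants.tsv").open("w") as fh:
        fh.write("drug\tcases\n")
        for name, count in result.top_concomitants:
            fh.write(f"{name}\t{count}\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    logger.info("artifacts written to %s", outdir)


def simulate(config: PipelineConfig, synth: SyntheticConfig | None = None) -> Path:
    """Generate synthetic quarters under ``quarters_dir`` (or outdir/quarters)."""
    synth = synth or SyntheticConfig(seed=config.seed)
    target = Path(config.quarters_dir or Path(config.outdir) / "quarters")
    generate(synth, outdir=target)
    logger.info("synthetic quarters written to %s", target)
    return target
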