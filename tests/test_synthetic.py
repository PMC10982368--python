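"""Generator contracts: determinism, duplicates, planted signals, clamping."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from faersig.cohort import CaseData, NameMatcher, select_cohort
from faersig.disproportionality import screen
from faersig.faers_io import concat_quarters
from faersig.meddra import toy_map
from faersig.synthetic import SyntheticConfig, generate, regenerate_check

TINY = dict(n_target_reports=80, n_background_reports=600, n_quarters=2)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        ok, msg = regenerate_check(SyntheticConfig(seed=3, **TINY), tmp_path)
        assert ok, msg

    def test_different_seeds_differ(self, tmp_path):
        b1, _ = generate(SyntheticConfig(seed=1, **TINY))
        b2, _ = generate(SyntheticConfig(seed=2, **TINY))
        assert not b1[0].demo.equals(b2[0].demo)


class TestDuplicates:
    def test_zero_duplicate_rate_one_version_per_case(self):
        cfg = SyntheticConfig(seed=4, duplicate_rate=0.0, **TINY)
        bundles, truth = generate(cfg)
        merged = concat_quarters(bundles)
        assert truth.n_emitted_reports == truth.n_true_cases
        assert merged.demo["caseid"].is_unique

    def test_pipeline_dedup_recovers_true_case_count(self, small_dataset):
        _, truth, data, _ = small_dataset
        assert data.n_cases == truth.n_true_cases
        assert data.n_raw_reports == truth.n_emitted_reports

    def test_retained_version_is_ground_truth_final(self, small_dataset):
        _, truth, data, _ = small_dataset
        assert set(data.demo["primaryid"]) == set(truth.cases["primaryid_final"])

    def test_duplicate_versions_ordered_within_case(self, small_dataset):
        _, truth, _, _ = small_dataset
        multi = truth.lineage[truth.lineage.groupby("caseid")["version"].transform("max") > 1]
        for _, grp in multi.groupby("caseid"):
            grp = grp.sort_values("version")
            fda = grp["fda_dt"].astype(int).tolist()
            assert fda == sorted(fda)  # receipt date non-decreasing in version
            pids = grp["primaryid"].astype(int).tolist()
            assert pids == sorted(pids)


class TestPlantedSignals:
    def test_unknown_planted_pt_rejected(self):
        with pytest.raises(ValueError, match="not in vocabulary"):
            generate(SyntheticConfig(seed=1, planted_signals=(("Nonexistent", 5.0),),
                                     **TINY))

    def test_infeasible_probability_clamped_with_warning(self, caplog):
        cfg = SyntheticConfig(seed=1, planted_signals=(("Fatigue", 500.0),), **TINY)
        with caplog.at_level("WARNING", logger="faersig"):
            bundles, truth = generate(cfg)
        assert any("clamped" in rec.message for rec in caplog.records)
        # clamped at 1: every target report carries the PT
        merged = concat_quarters(bundles)
        data = CaseData.from_bundle(merged)
        target = set(truth.cases.loc[truth.cases["is_target"], "primaryid_final"])
        with_pt = set(data.reac.loc[data.reac["pt"] == "Fatigue", "primaryid"])
        assert target <= with_pt

    def test_subgroup_planting_confined_to_stratum(self):
        cfg = SyntheticConfig(
            seed=9, n_target_reports=3000, n_background_reports=15000,
            planted_signals=(),
            planted_subgroup_signals=(("continent", "Asia", "Peptic ulcer", 30.0),),
        )
        bundles, truth = generate(cfg)
        cases = truth.cases
        reac = truth.reactions
        target = cases[cases["is_target"]]
        with_pt = set(reac.loc[reac["pt"] == "Peptic ulcer", "caseid"])
        asia = target[target["continent"] == "Asia"]
        other = target[target["continent"] != "Asia"]
        rate_asia = asia["caseid"].isin(with_pt).mean()
        rate_other = other["caseid"].isin(with_pt).mean()
        assert rate_asia > 5 * rate_other

    def test_planted_ror_converges_to_implied_odds_ratio(self):
        """At large n the screened ROR approaches the planted effect (±15%)."""
        cfg = SyntheticConfig(seed=13, n_target_reports=8000,
                              n_background_reports=42000)
        bundles, truth = generate(cfg)
        data = CaseData.from_bundle(concat_quarters(bundles))
        split = select_cohort(data, NameMatcher())
        res = screen(data, split.target_ids, split.background_ids, ptsoc=toy_map())
        planted = {r.term: r for r in res.pt}["Urinary retention"]
        assert planted.ror.ror == pytest.approx(5.0, rel=0.15)
        assert planted.of_interest

    def test_reaction_probabilities_match_config(self, small_dataset, small_config):
        """Observed background PT rate matches p + P(no draw at all)·filler
        weight — the exact marginal probability the generator implements."""
        _, truth, _, _ = small_dataset
        rates = dict(small_config.pt_vocabulary)
        planted = {pt for pt, _ in small_config.planted_signals}
        p_f = rates["Fatigue"]
        p_none = np.prod([1.0 - p for p in rates.values()])
        filler_total = sum(p for pt, p in rates.items() if pt not in planted)
        expected = p_f + p_none * p_f / filler_total
        reac = truth.reactions
        background = truth.cases[~truth.cases["is_target"]]
        with_fatigue = reac[(reac["pt"] == "Fatigue")
                            & reac["caseid"].isin(set(background["caseid"]))]
        observed = len(set(with_fatigue["caseid"])) / len(background)
        # ±3 binomial standard errors at n ≈ 2500
        se = float(np.sqrt(expected * (1 - expected) / len(background)))
        assert observed == pytest.approx(expected, abs=3 * se)


class TestEmittedStructure:
    def test_every_report_has_at_least_one_reaction(self, small_dataset):
        _, truth, data, _ = small_dataset
        with_reac = set(data.reac["primaryid"])
        assert set(data.demo["primaryid"]) <= with_reac

    def test_tto_evaluable_fraction_is_realistic(self, small_dataset):
        _, truth, _, _ = small_dataset
        frac = truth.cases["tto_evaluable"].mean()
        assert 0.10 < frac < 0.35  # roughly a fifth, as in spontaneous data

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(pt_vocabulary=(("X", 1.5),))
        with pytest.raises(ValueError):
            SyntheticConfig(planted_signals=(("X", -1.0),))
        with pytest.raises(ValueError):
            SyntheticConfig(duplicate_rate=1.0)

    def test_maps_written_alongside_quarters(self, tmp_path):
        cfg = dataclasses.replace(SyntheticConfig(seed=2, **TINY))
        generate(cfg, outdir=tmp_path)
        assert (tmp_path / "pt_soc_map.tsv").exists()
        assert (tmp_path / "continents.tsv").exists()
        assert (tmp_path / "ground_truth_cases.tsv").exists()
        qdirs = [p for p in tmp_path.iterdir() if p.is_dir()]
        assert len(qdirs) == 2
        for qd in qdirs:
            assert (qd / f"DEMO{qd.name}.txt").exists()
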