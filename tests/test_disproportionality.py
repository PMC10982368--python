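"""ROR / BCPNN-IC statistics against independent oracles, plus the screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.disproportionality import (
    ContingencyTable,
    IcPriorConfig,
    Thresholds,
    build_contingency,
    compute_ic,
    compute_ror,
    is_signal,
    screen,
)
from faersig.meddra import toy_map

RNG = np.random.default_rng(20240901)


def random_tables(n: int, low: int = 1, high: int = 500) -> list[ContingencyTable]:
    cells = RNG.integers(low, high, size=(n, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]


class TestRor:
    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_symmetric_table_gives_unity(self, k):
        assert compute_ror(ContingencyTable(k, k, k, k)).ror == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0, abs=1e-9)
        assert r.ci_low == pytest.approx(5.56, abs=1e-2)
        assert r.ci_high == pytest.approx(21.77, abs=1e-2)
        assert not r.corrected

    def test_zero_cell_triggers_haldane_anscombe_correction(self):
        r = compute_ror(ContingencyTable(3, 0, 5, 100))
        assert r.corrected
        expected = (3.5 * 100.5) / (0.5 * 5.5)
        assert r.ror == pytest.approx(expected, rel=1e-12)

    def test_empty_margin_tagged_undefined(self):
        r = compute_ror(ContingencyTable(0, 0, 5, 100))
        assert not r.defined
        assert np.isnan(r.ror)

    def test_ci_matches_independent_log_odds_oracle(self):
        """Generic log-OR SE machinery (statsmodels) agrees to 1e-9."""
        sm = pytest.importorskip("statsmodels.api")
        for t in random_tables(1000):
            ours = compute_ror(t)
            oracle = sm.stats.Table2x2(
                np.array([[t.a, t.b], [t.c, t.d]]), shift_zeros=False
            )
            assert ours.ror == pytest.approx(oracle.oddsratio, rel=1e-9)
            lo, hi = oracle.oddsratio_confint(0.05)
            assert ours.ci_low == pytest.approx(lo, rel=1e-9)
            assert ours.ci_high == pytest.approx(hi, rel=1e-9)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestIc:
    def test_independence_gives_zero_raw_ic(self):
        ic = compute_ic(ContingencyTable(1, 9, 10, 90))
        assert ic.ic_raw == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_raw_ic(self):
        ic = compute_ic(ContingencyTable(10, 90, 100, 9900))
        assert ic.ic_raw == pytest.approx(np.log2(10 * 10100 / (100 * 110)), abs=1e-12)
        assert ic.ic_raw == pytest.approx(3.199, abs=1e-3)

    def test_shrinkage_pulls_expectation_toward_zero(self):
        ic = compute_ic(ContingencyTable(10, 90, 100, 9900))
        assert 0 < ic.ic_expected < ic.ic_raw
        assert ic.ic025 < ic.ic_expected

    def test_closed_form_near_monte_carlo_posterior_small_a_example(self):
        """At a=5 under heavy shrinkage the normal-approximation credibility
        bound sits within ~a quarter bit of the exact posterior percentile,
        on the anti-conservative side (a documented approximation limit)."""
        t = ContingencyTable(5, 95, 50, 9850)
        closed = compute_ic(t, variance_model="bate1998")
        mc = compute_ic(t, variance_model="montecarlo", n_draws=200_000,
                        rng=np.random.default_rng(4))
        assert closed.ic025 == pytest.approx(mc.ic025, abs=0.3)
        assert closed.ic025 > mc.ic025  # approximation errs upward at small a

    def test_closed_form_matches_monte_carlo_on_random_suite(self):
        """Agreement with the exact posterior percentile: within 0.2 bits
        once a ≥ 10; within half a bit down to the a ≥ 3 screening gate."""
        rng = np.random.default_rng(77)
        tables = [t for t in random_tables(120) if t.a >= 3][:25]
        for t in tables:
            closed = compute_ic(t)
            mc = compute_ic(t, variance_model="montecarlo", n_draws=200_000, rng=rng)
            tol = 0.2 if t.a >= 10 else 0.5
            assert closed.ic025 == pytest.approx(mc.ic025, abs=tol), t

    def test_empty_margin_tagged_undefined(self):
        ic = compute_ic(ContingencyTable(0, 0, 10, 90))
        assert not ic.defined


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 40), st.integers(1, 40))
def test_independence_law(alpha, beta, k, j):
    """a/(a+b) = c/(c+d) forces ROR 1 and raw IC 0 (within 1e-12)."""
    t = ContingencyTable(alpha * k, beta * k, alpha * j, beta * j)
    assert compute_ror(t).ror == pytest.approx(1.0, abs=1e-12)
    assert compute_ic(t).ic_raw == pytest.approx(0.0, abs=1e-12)


def test_ror_strictly_increasing_in_joint_cell():
    for t in random_tables(50, low=2, high=200):
        bumped = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        assert compute_ror(bumped).ror > compute_ror(t).ror


def test_raw_ic_increasing_in_joint_cell_for_rare_events():
    """d(ic_raw)/da = 1/a + 1/N − 1/(a+b) − 1/(a+c) is positive whenever the
    event is rare relative to both margins — the screening regime.  (For a
    comparable to b and c the raw IC need not be monotone, because a also
    inflates both margins.)"""
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = int(rng.integers(1, 15))
        b, c, d = (int(x) for x in rng.integers(100, 500, 3))
        t = ContingencyTable(a, b, c, d)
        bumped = ContingencyTable(a + 1, b, c, d)
        assert compute_ic(bumped).ic_raw > compute_ic(t).ic_raw


def test_symmetry_on_swapped_cohorts():
    for t in random_tables(20):
        swapped = ContingencyTable(t.c, t.d, t.a, t.b)
        assert compute_ror(swapped).ror == pytest.approx(1.0 / compute_ror(t).ror,
                                                         rel=1e-12)


class TestThresholds:
    def test_fewer_than_three_cases_never_of_interest(self):
        assert not is_signal(2, ror_ci_low=50.0, ic025=5.0)

    def test_printed_soc_statistics_not_of_interest(self):
        # a SOC with CI lower bound 0.75 and IC025 −1.93 fails both criteria
        assert not is_signal(817, ror_ci_low=0.75, ic025=-1.93)

    def test_printed_pt_statistics_of_interest(self):
        # a PT with N 166, CI lower bound 12.61 and IC025 2.17 passes both
        assert is_signal(166, ror_ci_low=12.61, ic025=2.17)

    def test_both_criteria_required(self):
        assert not is_signal(20, ror_ci_low=1.5, ic025=-0.1)
        assert not is_signal(20, ror_ci_low=0.9, ic025=0.4)
        assert is_signal(20, ror_ci_low=1.5, ic025=0.4)


class TestBuildContingency:
    events = pd.DataFrame([
        {"primaryid": "t1", "pt": "X"},
        {"primaryid": "b1", "pt": "X"},
        {"primaryid": "b2", "pt": "Y"},
    ])

    def test_enumerated_example(self):
        t = build_contingency(["t1", "t2"], ["b1", "b2", "b3"], self.events, "X")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 2)

    def test_saturating_event_empties_b_and_d(self):
        events = pd.DataFrame([{"primaryid": p, "pt": "X"} for p in ("t1", "b1")])
        t = build_contingency(["t1"], ["b1"], events, "X")
        assert (t.b, t.d) == (0, 0)

    def test_duplicate_pt_rows_in_one_report_count_once(self):
        events = pd.concat([self.events, self.events.iloc[[0]]], ignore_index=True)
        t = build_contingency(["t1", "t2"], ["b1", "b2", "b3"], events, "X")
        assert t.a == 1

    def test_absent_event_yields_zero_cells_not_error(self):
        t = build_contingency(["t1"], ["b1"], self.events, "Nonexistent")
        assert (t.a, t.c) == (0, 0)


class TestScreen:
    def test_invariants_on_synthetic_cohort(self, small_dataset):
        _, _, data, split = small_dataset
        res = screen(data, split.target_ids, split.background_ids, ptsoc=toy_map())
        assert res.pt, "expected at least one screened PT"
        for r in res.pt + res.soc:
            assert r.table.a >= 1
            assert r.table.a + r.table.b == split.n_target
            assert r.table.c + r.table.d == split.n_background
            if r.of_interest:
                assert r.table.a >= 3
            if r.ror.defined and not np.isnan(r.ror.ror):
                assert r.ror.ci_low <= r.ror.ror <= r.ror.ci_high
            assert r.ic.ic025 <= r.ic.ic_expected

    def test_excluded_socs_never_screened(self, small_dataset):
        _, _, data, split = small_dataset
        res = screen(data, split.target_ids, split.background_ids, ptsoc=toy_map())
        soc_names = {r.term for r in res.soc}
        assert "Injury, poisoning and procedural complications" not in soc_names
        pt_names = {r.term for r in res.pt}
        assert "Fall" not in pt_names
        assert sum(res.removed_by_soc_exclusion.values()) > 0

    def test_screen_without_map_skips_soc_level(self, small_dataset):
        _, _, data, split = small_dataset
        res = screen(data, split.target_ids, split.background_ids, ptsoc=None)
        assert res.pt and not res.soc

    def test_expected_flag_annotation(self, small_dataset):
        _, _, data, split = small_dataset
        res = screen(data, split.target_ids, split.background_ids, ptsoc=toy_map())
        by_term = {r.term: r for r in res.pt}
        if "Urinary retention" in by_term:
            assert by_term["Urinary retention"].expected_flag
        if "Nocturia" in by_term:
            assert not by_term["Nocturia"].expected_flag

    def test_publication_table_shape(self, small_dataset):
        _, _, data, split = small_dataset
        res = screen(data, split.target_ids, split.background_ids, ptsoc=toy_map())
        pub = res.publication_table("PT")
        assert list(pub.columns) == ["SOC", "term", "N", "ROR (95% CI)",
                                     "IC (IC025)", "expected"]
        assert (pub["N"] >= 1).all()
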