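"""Differential-splicing calling: event statistics, IR gating, grouping
combination, rescue rule, and brute-force oracle equivalence."""

import math

import numpy as np
import pytest

import oracles
from conftest import make_psi_table
from crossplice.diffsplice import (
    Comparison,
    Grouping,
    SpeciesParams,
    call_species_events,
    combine_groupings,
    compute_event_stats,
    ir_balance_test,
    rescue_low_coverage,
)
from crossplice.model import SampleDesign, SampleInfo


def table_from_psis(controls, perturbed, tiers=None, ev_type="AltEx", ir=None):
    vals = {}
    samples = [f"c{i+1}" for i in range(len(controls))] + [f"p{i+1}" for i in range(len(perturbed))]
    for s, psi in zip(samples, list(controls) + list(perturbed)):
        tier = (tiers or {}).get(s, "OK")
        inc = int(round(psi))
        row = (psi, tier, inc, 100 - inc)
        if ir is not None:
            row = row + tuple(ir.get(s, (10, 10)))
        vals[s] = row
    return make_psi_table({"ev": vals}, {"ev": {"type": ev_type}})


def design_for(n_ctrl, n_pert):
    samples = {f"c{i+1}": SampleInfo("control", "loss", str(i + 1)) for i in range(n_ctrl)}
    samples.update({f"p{i+1}": SampleInfo("perturbed", "loss", str(i + 1)) for i in range(n_pert)})
    return SampleDesign(samples)


class TestEventStats:
    def test_no_change(self):
        table = table_from_psis([90, 90], [90, 90])
        st = compute_event_stats(table, design_for(2, 2), "ev")
        assert st.dpsi_avg == 0 and st.pairwise == [0, 0, 0, 0]

    def test_all_pairwise_enumerated(self):
        table = table_from_psis([95, 85], [60, 70])
        st = compute_event_stats(table, design_for(2, 2), "ev")
        assert st.dpsi_avg == pytest.approx(25)
        assert sorted(st.pairwise) == [15, 25, 25, 35]

    def test_tier_n_fails_coverage(self):
        table = table_from_psis([95, 85], [60, 70], tiers={"p2": "N"})
        st = compute_event_stats(table, design_for(2, 2), "ev")
        assert not st.coverage_ok and st.low_coverage_samples == ["p2"]

    def test_absent_event_errors(self):
        table = table_from_psis([90], [60])
        with pytest.raises(KeyError, match="missing"):
            table.event_records("missing")


class TestIrBalance:
    def test_perfect_balance(self):
        assert ir_balance_test(10, 10) == pytest.approx(1.0)

    def test_extreme_imbalance_closed_form(self):
        assert ir_balance_test(0, 20) == pytest.approx(2 * 0.5**20, abs=1e-12)

    def test_matches_enumeration(self):
        assert ir_balance_test(8, 12) == pytest.approx(oracles.oracle_binom_two_sided(8, 12), abs=1e-12)

    def test_no_reads_is_not_applicable(self):
        assert ir_balance_test(0, 0) is None


class TestSpeciesCalls:
    def test_passing_altex_called_enhanced(self):
        table = table_from_psis([95, 85], [60, 70])
        calls = call_species_events(table, design_for(2, 2), SpeciesParams())
        assert calls["ev"].called and calls["ev"].direction == "enhanced"

    def test_threshold_boundary(self):
        table = table_from_psis([64, 64], [50, 50])
        calls = call_species_events(table, design_for(2, 2), SpeciesParams(min_dpsi=15))
        assert not calls["ev"].called  # dpsi_avg 14 < 15
        calls = call_species_events(table, design_for(2, 2), SpeciesParams(min_dpsi=14))
        assert calls["ev"].called

    def test_ir_imbalance_vetoes_call(self):
        ir_bad = {"c1": (10, 10), "c2": (10, 10), "p1": (0, 20), "p2": (10, 10)}
        table = table_from_psis([95, 85], [60, 70], ev_type="IR", ir=ir_bad)
        calls = call_species_events(table, design_for(2, 2), SpeciesParams())
        assert not calls["ev"].called and calls["ev"].ir_balance_ok is False

    def test_config_error_when_min_dpsi_below_pairwise(self):
        with pytest.raises(ValueError):
            SpeciesParams(min_dpsi=3, min_pairwise=5)


class TestRescue:
    def base_table(self, low_tier="N", low_reads=3, extra_low=None):
        tiers = {"p2": low_tier}
        if extra_low:
            tiers[extra_low] = low_tier
        table = table_from_psis([95, 85], [60, 70], tiers=tiers)
        # give the low sample the requested read depth
        table.data.loc[table.data["sample_id"] == "p2", ["inc", "exc"]] = [low_reads, 0]
        table.data.loc[table.data["sample_id"] == "p2", "psi"] = 100.0
        return make_psi_table  # placeholder (unused)

    def _table(self, low_reads, n_low=1):
        tiers = {"p2": "N"}
        if n_low == 2:
            tiers["p1"] = "N"
        table = table_from_psis([95, 85], [60, 70], tiers=tiers)
        idx = table.data["sample_id"] == "p2"
        table.data.loc[idx, ["inc", "exc"]] = [low_reads, 0]
        table.data.loc[idx, "psi"] = 100.0 if low_reads else float("nan")
        return make_psi_table(
            {
                "ev": {
                    r["sample_id"]: (r["psi"], r["tier"], int(r["inc"]), int(r["exc"]))
                    for _, r in table.data.iterrows()
                }
            }
        )

    def test_one_low_sample_with_two_reads_rescued(self):
        table = self._table(low_reads=3)
        assert rescue_low_coverage(table, design_for(2, 2), "ev", True, SpeciesParams())

    def test_single_read_not_rescued(self):
        table = self._table(low_reads=1)
        assert not rescue_low_coverage(table, design_for(2, 2), "ev", True, SpeciesParams())

    def test_two_low_samples_not_rescued(self):
        table = self._table(low_reads=3, n_low=2)
        assert not rescue_low_coverage(table, design_for(2, 2), "ev", True, SpeciesParams())

    def test_without_homolog_not_applicable(self):
        table = self._table(low_reads=3)
        assert not rescue_low_coverage(table, design_for(2, 2), "ev", False, SpeciesParams())


class TestGroupings:
    def _table(self, kd_ctrl, kd_pert, oe_ctrl, oe_pert):
        vals = {}
        for s, psi in [("kc", kd_ctrl), ("kp", kd_pert), ("oc", oe_ctrl), ("op", oe_pert)]:
            inc = int(round(psi))
            vals[s] = (psi, "OK", inc, 100 - inc)
        return make_psi_table({"ev": vals})

    def groupings(self):
        kd = Comparison("kd", ["kc"], ["kp"], sign="loss")
        oe = Comparison("oe", ["oc"], ["op"], sign="gain")
        return [Grouping("iii", [kd, oe])]

    def test_opposite_direction_pair_called(self):
        # KD dPSI +20 (loss), OE dPSI -18 (gain) -> consistent, enhanced
        table = self._table(80, 60, 60, 78)
        params = SpeciesParams(dpsi_inclusive=False)
        calls = combine_groupings(table, self.groupings(), params)
        assert calls["ev"].called and calls["ev"].direction == "enhanced"
        assert calls["ev"].provenance == ["iii"]

    def test_same_direction_pair_fails(self):
        # KD dPSI +20, OE dPSI +20: both raw-positive -> grouping fails
        table = self._table(80, 60, 80, 60)
        calls = combine_groupings(table, self.groupings(), SpeciesParams(dpsi_inclusive=False))
        assert "ev" not in calls

    def test_union_semantics_with_single_grouping(self):
        table = self._table(80, 60, 60, 60)
        groupings = [Grouping("i", [Comparison("kd", ["kc"], ["kp"], sign="loss")])]
        calls = combine_groupings(table, groupings, SpeciesParams(dpsi_inclusive=False))
        assert calls["ev"].called and calls["ev"].provenance == ["i"]

    def test_merged_reads_recompute_psi_and_tier(self):
        # pooled reads shift PSI to the read-weighted value
        vals = {
            "a1": (100.0, "VLOW", 10, 0),
            "a2": (0.0, "VLOW", 0, 10),
            "b1": (0.0, "OK", 0, 40),
        }
        table = make_psi_table({"ev": vals})
        comp = Comparison("m", ["a1", "a2"], ["b1"], sign="loss", merge_reads=True)
        calls = combine_groupings(table, [Grouping("ii", [comp])], SpeciesParams())
        # merged control PSI = 100*10/20 = 50; dPSI = 50 - 0 = 50
        assert calls["ev"].called and calls["ev"].dpsi_avg == pytest.approx(50.0)


class TestProperties:
    def random_table(self, rng, n_ctrl, n_pert, ir=False):
        vals = {}
        for i in range(n_ctrl + n_pert):
            s = f"c{i+1}" if i < n_ctrl else f"p{i+1-n_ctrl}"
            total = int(rng.integers(0, 120))
            inc = int(rng.integers(0, total + 1)) if total else 0
            psi = round(100 * inc / total, 2) if total else float("nan")
            tier = oracles.TIERS[min(4, int(np.searchsorted([5, 15, 25, 100], total, side="right")))]
            row = (psi, tier, inc, total - inc)
            if ir:
                row = row + (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
            vals[s] = row
        return vals

    def test_oracle_equivalence_on_random_tables(self, rng):
        """Calls match an explicit brute-force reference on small tables."""
        for trial in range(300):
            n_ctrl, n_pert = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            is_ir = trial % 3 == 0
            vals = self.random_table(rng, n_ctrl, n_pert, ir=is_ir)
            table = make_psi_table({"ev": vals}, {"ev": {"type": "IR" if is_ir else "AltEx"}})
            design = design_for(n_ctrl, n_pert)
            params = SpeciesParams(min_dpsi=15, min_pairwise=5)
            got = call_species_events(table, design, params)["ev"].called
            want = oracles.oracle_splice_call(
                vals,
                [f"c{i+1}" for i in range(n_ctrl)],
                [f"p{i+1}" for i in range(n_pert)],
                is_ir=is_ir,
            )
            assert got == want, (vals, is_ir)

    def test_raising_thresholds_never_adds_calls(self, rng):
        tables = []
        for _ in range(60):
            vals = self.random_table(rng, 2, 2)
            tables.append(make_psi_table({"ev": vals}))
        design = design_for(2, 2)
        loose = SpeciesParams(min_dpsi=10, min_pairwise=5)
        tight = SpeciesParams(min_dpsi=20, min_pairwise=8)
        for table in tables:
            called_loose = call_species_events(table, design, loose)["ev"].called
            called_tight = call_species_events(table, design, tight)["ev"].called
            assert not (called_tight and not called_loose)

    def test_swapping_conditions_flips_direction(self, rng):
        design = design_for(2, 2)
        for _ in range(40):
            vals = self.random_table(rng, 2, 2)
            table = make_psi_table({"ev": vals})
            params = SpeciesParams()
            fwd = call_species_events(table, design, params)["ev"]
            rev = call_species_events(table, design.swap_conditions(), params)["ev"]
            if not (math.isnan(fwd.dpsi_avg) or math.isnan(rev.dpsi_avg)):
                assert rev.dpsi_avg == pytest.approx(-fwd.dpsi_avg)
            assert fwd.called == rev.called
            if fwd.called:
                assert {fwd.direction, rev.direction} == {"enhanced", "silenced"}
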