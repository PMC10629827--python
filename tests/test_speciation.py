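"""Carrier-protein speciation: closed-form binary solve and coupled ternary solve."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohflux.speciation import (
    BindingConstants,
    MixtureTotals,
    SpeciationError,
    build_speciation_table,
    solve_speciation,
    solve_two_component,
)

from conftest import grid_speciation_oracle


class TestTwoComponent:
    def test_physiological_mixture_splits_80_20(self):
        # 2 µM ROH + 2 µM RBP at Kd 100 nM: 0.4 free / 1.6 bound
        free, bound = solve_two_component(2.0, 2.0, 0.10)
        assert free == pytest.approx(0.4, abs=1e-12)
        assert bound == pytest.approx(1.6, abs=1e-12)

    def test_no_ligand_gives_zero_everywhere(self):
        assert solve_two_component(0.0, 2.0, 0.10) == (0.0, 0.0)

    def test_matches_fine_grid_scan(self):
        # independent oracle: scan bound on a 1e-6 µM grid, minimize the
        # mass-action residual (R-b)(P-b) - kd*b
        R, P, kd = 1.0, 1.0, 0.10
        b = np.arange(0.0, min(R, P), 1e-6)
        resid = np.abs((R - b) * (P - b) - kd * b)
        b_star = b[np.argmin(resid)]
        free, bound = solve_two_component(R, P, kd)
        assert bound == pytest.approx(b_star, abs=2e-6)
        assert bound == pytest.approx(0.7298437881, abs=1e-9)
        assert free == pytest.approx(1.0 - 0.7298437881, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(SpeciationError):
            solve_two_component(-1.0, 2.0, 0.1)
        with pytest.raises(SpeciationError):
            solve_two_component(1.0, 2.0, 0.0)

    @given(
        R=st.floats(0.0, 10.0),
        P=st.floats(0.0, 10.0),
        kd=st.floats(1e-4, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bound_within_stoichiometric_limits(self, R, P, kd):
        free, bound = solve_two_component(R, P, kd)
        assert 0.0 <= bound <= min(R, P) + 1e-12
        assert free + bound == pytest.approx(R, rel=1e-10, abs=1e-12)


class TestCoupledSpeciation:
    def test_ternary_mixture_matches_grid_oracle(self):
        sp = solve_speciation(MixtureTotals(2, 2, 4), BindingConstants(0.10, 0.25))
        x, rp, rpt, y = grid_speciation_oracle(2, 2, 4, 0.10, 0.25)
        assert sp.free_roh == pytest.approx(x, abs=1e-3)
        assert sp.roh_rbp == pytest.approx(rp, abs=1e-3)
        assert sp.roh_rbp_ttr == pytest.approx(rpt, abs=1e-3)

    def test_without_ttr_reduces_to_binary_solve(self):
        sp = solve_speciation(MixtureTotals(2, 2, 0))
        free, bound = solve_two_component(2, 2, 0.10)
        assert sp.free_roh == pytest.approx(free, rel=1e-12)
        assert sp.roh_rbp == pytest.approx(bound, rel=1e-12)
        assert sp.roh_rbp_ttr == 0.0

    def test_random_mixtures_agree_with_grid_oracle(self, rng):
        for _ in range(50):
            R, P, T = rng.uniform(0.0, 10.0, 3)
            sp = solve_speciation(MixtureTotals(R, P, T))
            x, rp, rpt, y = grid_speciation_oracle(R, P, T, 0.10, 0.25)
            assert abs(sp.free_roh - x) < 1e-3
            assert abs(sp.roh_rbp - rp) < 1e-3
            assert abs(sp.roh_rbp_ttr - rpt) < 1e-3

    def test_mass_conservation_and_equilibrium_residuals(self, rng):
        for _ in range(50):
            R, P, T = rng.uniform(0.0, 10.0, 3)
            sp = solve_speciation(MixtureTotals(R, P, T))
            assert sp.roh_total == pytest.approx(R, rel=1e-8, abs=1e-10)
            assert sp.rbp_total == pytest.approx(P, rel=1e-8, abs=1e-10)
            assert sp.ttr_total == pytest.approx(T, rel=1e-8, abs=1e-10)
            if sp.roh_rbp > 1e-9:
                assert abs(sp.residuals["kd1_rel"]) < 1e-6
            if sp.roh_rbp_ttr > 1e-9:
                assert abs(sp.residuals["kd2_rel"]) < 1e-6

    def test_free_roh_decreases_with_more_carrier(self):
        base = solve_speciation(MixtureTotals(2, 2, 4)).free_roh
        more_rbp = solve_speciation(MixtureTotals(2, 4, 4)).free_roh
        more_ttr = solve_speciation(MixtureTotals(2, 2, 8)).free_roh
        assert more_rbp <= base
        assert more_ttr <= base

    def test_weak_binding_limit_frees_all_ligand(self):
        sp = solve_speciation(MixtureTotals(2, 2, 4), BindingConstants(1e9, 0.25))
        assert sp.free_roh == pytest.approx(2.0, rel=1e-6)

    def test_deterministic(self):
        a = solve_speciation(MixtureTotals(2, 2, 4))
        b = solve_speciation(MixtureTotals(2, 2, 4))
        assert a.free_roh == b.free_roh and a.free_ttr == b.free_ttr


class TestSpeciationTable:
    @staticmethod
    def _conditions(rows):
        return pd.DataFrame(rows, columns=["label", "mode", "roh_uM", "rbp_uM", "ttr_uM"])

    def test_muttr_mode_disables_complex_step(self):
        table = build_speciation_table(
            self._conditions([("c1", "ROH-RBP-muTTR", 2.0, 2.0, 4.0)])
        )
        row = table.iloc[0]
        assert row.free_roh_uM == pytest.approx(0.4, abs=1e-9)
        assert row.roh_rbp_uM == pytest.approx(1.6, abs=1e-9)
        assert row.roh_rbp_ttr_uM == 0.0

    def test_free_mode_has_no_binding(self):
        table = build_speciation_table(self._conditions([("c1", "Free", 0.1, 0.0, 0.0)]))
        row = table.iloc[0]
        assert row.free_roh_uM == pytest.approx(0.1)
        assert row.roh_rbp_uM == 0.0 and row.roh_rbp_ttr_uM == 0.0

    def test_murbp_treated_as_rbp_without_ttr(self):
        # muRBP binds ROH like RBP but cannot engage TTR
        table = build_speciation_table(
            self._conditions([("c1", "ROH-muRBP", 2.0, 2.0, 0.0)])
        )
        assert table.iloc[0].roh_rbp_uM == pytest.approx(1.6, abs=1e-9)

    def test_empty_conditions_give_empty_table(self):
        table = build_speciation_table(self._conditions([]))
        assert len(table) == 0
        assert "free_roh_uM" in table.columns

    def test_unknown_mode_is_configuration_error(self):
        with pytest.raises(SpeciationError, match="unknown delivery mode"):
            build_speciation_table(self._conditions([("c1", "nonsense", 1, 1, 1)]))


def test_invalid_constants_rejected():
    with pytest.raises(SpeciationError):
        BindingConstants(kd_roh_rbp=0.0)
    with pytest.raises(SpeciationError):
        BindingConstants(kd_rohrbp_ttr=math.inf)
    with pytest.raises(SpeciationError):
        MixtureTotals(-1.0, 0.0, 0.0)
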