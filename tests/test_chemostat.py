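"""Steady-state solver: optimality, conservation, regimes, policies."""

import dataclasses

import numpy as np
import pytest

from diazosim import (
    AmbientEnvironment,
    InconsistentStateError,
    Regime,
    RespirationPolicy,
    classify_regime,
    protein_specific,
    solve_steady_state,
)
from diazosim.chemostat import _check_conservation

from conftest import make_conditions, oracle_best, oracle_biomass_at


def _random_conditions(rng: np.random.Generator):
    return make_conditions(
        sucrose=float(rng.uniform(0.0, 40.0)),
        ammonium=float(rng.choice([0.0, rng.uniform(0.2, 5.0)], p=[0.05, 0.95])),
        o2=float(rng.uniform(0.005, 0.8)),
        dilution=float(rng.uniform(0.05, 0.3)),
    )


def test_no_carbon_means_no_growth(phys):
    sol = solve_steady_state(make_conditions(sucrose=0.0, ammonium=2.5), phys)
    assert sol.biomass == 0.0
    assert sol.f_n2 == 0.0
    assert sol.residual_nh4 == 2.5


def test_solver_matches_brute_force_grid_oracle(phys):
    """The analytic optimum beats a 2001-point fixation-fraction grid.

    Two-sided check on 120 random condition draws: the solver's state is
    feasible under the independently derived budget, and its biomass is at
    least the grid maximum.
    """
    rng = np.random.default_rng(20260301)
    for _ in range(120):
        cond = _random_conditions(rng)
        sol = solve_steady_state(cond, phys)
        f_best, x_best = oracle_best(cond, phys)
        # at least as good as the grid optimum
        assert sol.biomass >= x_best * (1 - 1e-9)
        # and feasible according to the independent budget at the solver's f
        if sol.biomass > 0:
            x_feasible = float(oracle_biomass_at(np.array([sol.f_n2]), cond, phys)[0])
            assert np.isfinite(x_feasible)
            assert sol.biomass <= x_feasible * (1 + 1e-9)
        if x_best > 0 and abs(sol.f_n2 - f_best) > 1e-3:
            # grid resolution may displace f; biomass must still agree closely
            assert sol.biomass == pytest.approx(x_best, rel=5e-3)


def test_conservation_laws_on_random_draws(phys):
    """Carbon, nitrogen and electron balances close to 1e-9 relative."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        cond = _random_conditions(rng)
        sol = solve_steady_state(cond, phys)
        _check_conservation(sol, cond, phys)  # allocation sum + electron balance
        # nitrogen: biomass N production = ammonium uptake + fixation
        n_in_biomass = phys.biomass_formula.n_to_c * cond.dilution_rate * sol.biomass
        assert n_in_biomass == pytest.approx(sol.nh4_consumed + sol.n_fixed, rel=1e-9, abs=1e-15)
        # carbon: sucrose C consumed = biomass C + respired CO2
        co2 = 12 * sol.sucrose_consumed - cond.dilution_rate * sol.biomass
        assert co2 >= -1e-12
        # supply-side mass balance for both substrates
        assert sol.sucrose_consumed == pytest.approx(
            cond.dilution_rate * (cond.sucrose_in - sol.residual_sucrose), rel=1e-9, abs=1e-15
        )


class TestRegimes:
    def test_partition_along_cn_axis(self, phys):
        """A (residual ammonium) -> B (ammonium-limited) -> C (fixing)."""
        seen = []
        for s in np.linspace(0.25, 37.5, 60):
            sol = solve_steady_state(make_conditions(sucrose=float(s), o2=0.30), phys)
            seen.append(sol.regime)
            if sol.regime is Regime.A_CARBON_LIMITED:
                assert sol.residual_nh4 > 0 and sol.f_n2 == 0
            elif sol.regime is Regime.B_AMMONIUM_LIMITED:
                assert sol.residual_nh4 == 0 and sol.f_n2 == 0
            else:
                assert sol.residual_nh4 == 0 and sol.f_n2 > 0
        labels = [r.value for r in seen]
        # order is A then B then C with no interleaving
        assert labels == sorted(labels)
        assert set(labels) == {"A", "B", "C"}

    def test_inconsistent_state_rejected(self, phys):
        cond = make_conditions(sucrose=20.0)
        sol = solve_steady_state(cond, phys)
        bad = dataclasses.replace(sol, residual_nh4=0.5)
        with pytest.raises(InconsistentStateError):
            classify_regime(bad, cond)

    def test_extreme_cn_is_fully_diazotrophic(self, phys):
        sol = solve_steady_state(make_conditions(sucrose=37.5, ammonium=1e-4, o2=0.30), phys)
        assert sol.regime is Regime.C_MIXED_FIXING
        assert sol.f_n2 > 0.99

    def test_washout_below_oxygen_viability_floor(self, phys):
        sol = solve_steady_state(make_conditions(sucrose=10.0, o2=0.004), phys)
        assert sol.washed_out
        assert any("washout" in w for w in sol.warnings)


class TestMonotonicity:
    def test_fixation_and_biomass_along_cn(self, phys):
        """f_n2 non-decreasing; biomass rises (A), plateaus (B), rises (C)."""
        sols = [
            solve_steady_state(make_conditions(sucrose=float(s), o2=0.05), phys)
            for s in np.linspace(0.25, 37.5, 80)
        ]
        f = np.array([s.f_n2 for s in sols])
        x = np.array([s.biomass for s in sols])
        assert np.all(np.diff(f) >= -1e-12)
        for a, b in zip(sols, sols[1:]):
            if b.regime is Regime.A_CARBON_LIMITED:
                assert b.biomass > a.biomass
            elif b.regime is Regime.B_AMMONIUM_LIMITED and a.regime is Regime.B_AMMONIUM_LIMITED:
                assert b.biomass == pytest.approx(a.biomass, rel=1e-12)
            elif b.regime is Regime.C_MIXED_FIXING and a.regime is Regime.C_MIXED_FIXING:
                assert b.biomass >= a.biomass * (1 - 1e-12)
        assert x[-1] > x[0]

    def test_oxygen_suppresses_fixation_and_raises_threshold(self, phys):
        """More ambient O2: lower per-protein fixation, later onset."""
        rates, onsets = [], []
        for o2 in (0.05, 0.15, 0.30, 0.60):
            sol = solve_steady_state(make_conditions(sucrose=30.0, o2=o2), phys)
            ps = protein_specific(sol, phys)
            rates.append(ps.n_fixation_per_protein if ps.defined else 0.0)
            f_on = next(
                (
                    s
                    for s in np.linspace(0.25, 37.5, 150)
                    if solve_steady_state(make_conditions(sucrose=float(s), o2=o2), phys).f_n2 > 0
                ),
                np.inf,
            )
            onsets.append(f_on)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(rates, rates[1:]))
        assert all(b > a for a, b in zip(onsets, onsets[1:]))


class TestPolicies:
    @pytest.mark.parametrize("o2", [0.05, 0.30, 0.60])
    def test_sim1_sim2_same_biomass_different_regime_b_respiration(self, phys, o2):
        for s in np.linspace(0.25, 37.5, 40):
            cond = make_conditions(sucrose=float(s), o2=o2)
            s1 = solve_steady_state(cond, phys, RespirationPolicy.SIM1)
            s2 = solve_steady_state(cond, phys, RespirationPolicy.SIM2)
            assert s1.biomass == pytest.approx(s2.biomass, rel=1e-12)
            assert s1.f_n2 == pytest.approx(s2.f_n2, rel=1e-12)
            assert s1.n_fixed == pytest.approx(s2.n_fixed, rel=1e-12)
            assert s1.o2_respired >= s2.o2_respired * (1 - 1e-12)
            if s1.regime is not Regime.B_AMMONIUM_LIMITED:
                assert s1.o2_respired == pytest.approx(s2.o2_respired, rel=1e-12)

    def test_sim1_regime_b_respiration_rises_linearly_with_cn(self, phys):
        """Constitutive excess respiration grows linearly across regime B."""
        ss = np.array([3.0, 6.0, 9.0])  # inside regime B at 30% O2
        resp = []
        for s in ss:
            sol = solve_steady_state(make_conditions(sucrose=float(s), o2=0.30), phys)
            assert sol.regime is Regime.B_AMMONIUM_LIMITED
            resp.append(protein_specific(sol, phys).respiration_per_protein)
        resp = np.array(resp)
        slope1 = (resp[1] - resp[0]) / (ss[1] - ss[0])
        slope2 = (resp[2] - resp[1]) / (ss[2] - ss[1])
        assert slope1 > 0
        assert slope2 == pytest.approx(slope1, rel=1e-9)


class TestProteinSpecific:
    def test_undefined_at_zero_biomass(self, phys):
        sol = solve_steady_state(make_conditions(sucrose=0.0), phys)
        ps = protein_specific(sol, phys)
        assert not ps.defined
        assert ps.n_fixation_per_protein is None

    def test_constant_along_constant_cn_contour(self, phys):
        """In regime C the per-protein fixation rate depends on C/N only."""
        rates, volumetric = [], []
        for a in (1.0, 2.5, 5.0):
            sol = solve_steady_state(make_conditions(sucrose=8 * a, ammonium=a, o2=0.05), phys)
            assert sol.regime is Regime.C_MIXED_FIXING
            rates.append(protein_specific(sol, phys).n_fixation_per_protein)
            volumetric.append(sol.n_fixed)
        assert rates[1] == pytest.approx(rates[0], rel=1e-9)
        assert rates[2] == pytest.approx(rates[0], rel=1e-9)
        # while the per-volume rate grows with the absolute supply
        assert volumetric[0] < volumetric[1] < volumetric[2]


def test_uptake_ceiling_flags_pathological_physiology(phys):
    """A nearly impermeable, huge cell cannot sustain the assumed fluxes."""
    bad = phys.with_(radius=5e-8, carbon_per_cell=4e-12)
    cond = make_conditions(sucrose=20.0, o2=0.6)
    sol = solve_steady_state(cond, bad, RespirationPolicy.SIM1)
    if sol.biomass > 0:
        assert sol.warnings  # per-cell demand exceeds a diffusive ceiling
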