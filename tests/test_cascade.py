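"""Cascade construction, rate law, and ODE simulation."""

import numpy as np
import pytest
from scipy.optimize import brentq

import nanocascade as nc
from nanocascade.enzymes import MMParams

from conftest import chain_spec, toy_enzyme


class TestBuildCascade:
    @pytest.mark.parametrize(
        "preset, n_steps, sign, first, last",
        [
            ("7E", 7, +1, "Glk", "PGK"),
            ("8E", 8, +1, "Inv", "PGK"),
            ("9E", 9, +1, "Amy", "PGK"),
            ("10E", 10, +1, "Inv", "PGK"),
            ("4E", 4, -1, "PGM", "LDH"),
        ],
    )
    def test_presets(self, enzyme_table, preset, n_steps, sign, first, last):
        spec = nc.build_cascade(preset, enzyme_table)
        assert len(spec.steps) == n_steps
        assert spec.monitored_species == "NADH"
        assert spec.monitored_sign == sign
        assert spec.enzyme_abbrevs[0] == first
        assert spec.enzyme_abbrevs[-1] == last

    def test_4e_order(self, enzyme_table):
        spec = nc.build_cascade("4E", enzyme_table)
        assert spec.enzyme_abbrevs == ["PGM", "Eno", "PykA", "LDH"]

    def test_unknown_preset_rejected(self, enzyme_table):
        with pytest.raises(ValueError, match="11E"):
            nc.build_cascade("11E", enzyme_table)

    def test_missing_enzyme_rejected(self, enzyme_table):
        partial = {k: v for k, v in enzyme_table.items() if k != "GPD"}
        with pytest.raises(KeyError):
            nc.build_cascade("7E", partial)


class TestMMRate:
    def test_zero_substrate(self):
        p = MMParams(kcat=2.6, km=36.0)
        assert nc.mm_rate(p, 0.001, 0.0) == 0.0

    def test_half_saturation(self):
        # Glk free constants at 1 nM enzyme: half of kcat*E
        p = MMParams(kcat=2.6, km=36.0)
        assert nc.mm_rate(p, 1e-3, 36.0) == pytest.approx(1.3e-3)

    def test_saturation_limit(self):
        p = MMParams(kcat=5.0, km=100.0)
        v = nc.mm_rate(p, 0.01, 1000 * 100.0)
        assert v == pytest.approx(5.0 * 0.01, rel=1e-3)

    def test_negative_inputs_rejected(self):
        p = MMParams(kcat=1.0, km=1.0)
        with pytest.raises(ValueError):
            nc.mm_rate(p, -1.0, 1.0)
        with pytest.raises(ValueError):
            nc.mm_rate(p, 1.0, -1.0)


class TestSimulate:
    def test_null_dynamics(self, spec_7e, cond_7e):
        concs = {ab: 0.0 for ab in spec_7e.enzyme_abbrevs}
        res = nc.simulate(spec_7e, cond_7e, concs)
        for sp in res.species:
            traj = res.concentration(sp)
            assert np.allclose(traj, traj[0])

    def test_two_nadh_per_glucose(self, spec_7e, enzyme_table):
        # 10 uM glucose run to completion with excess cofactors: the FBA
        # split yields two trioses, hence 2 NADH per glucose
        cond = nc.AssayConditions(
            initial_concentrations={"glucose": 10.0, "ATP": 7500.0,
                                    "ADP": 7500.0, "NAD+": 1130.0, "Pi": 4000.0},
            t_end=80_000.0, sample_dt=200.0,
        )
        concs = {ab: 0.05 for ab in spec_7e.enzyme_abbrevs}
        res = nc.simulate(spec_7e, cond, concs)
        assert res.monitored()[-1] == pytest.approx(20.0, abs=0.01)
        consumed = res.concentration("glucose")[0] - res.concentration("glucose")[-1]
        assert res.monitored()[-1] == pytest.approx(2 * consumed, rel=1e-4)

    def test_cofactor_conservation(self, sim_7e):
        nad = sim_7e.concentration("NAD+") + sim_7e.concentration("NADH")
        atp = sim_7e.concentration("ATP") + sim_7e.concentration("ADP")
        assert np.max(np.abs(nad - nad[0])) < 1e-5 * nad[0]
        assert np.max(np.abs(atp - atp[0])) < 1e-5 * atp[0]

    def test_no_negative_trajectories(self, sim_7e):
        assert np.all(sim_7e.conc >= 0)

    def test_monitored_monotone(self, sim_7e):
        nadh = sim_7e.monitored()
        assert np.all(np.diff(nadh) >= -1e-9)

    def test_plateau_bounded_by_nad_pool(self, sim_7e, cond_7e):
        assert sim_7e.monitored()[-1] <= \
            cond_7e.initial_concentrations["NAD+"] * (1 + 1e-9)

    def test_4e_consumption_monotone(self, enzyme_table):
        spec = nc.build_cascade("4E", enzyme_table)
        cond = nc.assay_conditions("4E")
        concs = {"PGM": 0.0895, "Eno": 0.0385, "PykA": 0.0935, "LDH": 0.094}
        res = nc.simulate(spec, cond, concs)
        nadh = res.monitored()
        assert np.all(np.diff(nadh) <= 1e-9)
        assert nadh[-1] >= 0

    def test_single_step_matches_closed_form(self):
        # implicit solution of dS/dt = -Vmax*S/(KM+S):
        # KM*ln(S0/S) + (S0-S) = Vmax*t
        kcat, km, e_conc, s0 = 5.0, 120.0, 0.01, 400.0
        vmax = kcat * e_conc
        spec = chain_spec([toy_enzyme("E1", kcat, km)])
        cond = nc.AssayConditions(initial_concentrations={"S0": s0},
                                  t_end=50_000.0, sample_dt=500.0)
        res = nc.simulate(spec, cond, {"E1": e_conc})
        s_num = res.concentration("S0")

        def closed_form(t):
            if t == 0:
                return s0
            f = lambda s: km * np.log(s0 / s) + (s0 - s) - vmax * t
            return brentq(f, 1e-12, s0)

        for i in range(0, res.time.size, 10):
            expect = closed_form(res.time[i])
            assert s_num[i] == pytest.approx(expect, rel=1e-3, abs=1e-6)

    def test_missing_bound_params_raises(self):
        enz = toy_enzyme("E1", 1.0, 1.0)
        enz = enz.model_copy(update={"params_bound": None})
        spec = chain_spec([enz])
        cond = nc.AssayConditions(initial_concentrations={"S0": 10.0},
                                  t_end=100.0, sample_dt=10.0)
        with pytest.raises(ValueError, match="bound"):
            nc.simulate(spec, cond, {"E1": 0.1}, context="bound")


class TestCompetitor:
    def _gox(self, enzyme_table):
        return nc.gox_competitor_step(enzyme_table)

    def test_zero_competitor_is_neutral(self, spec_7e, enzyme_table, fig_concs):
        cond = nc.assay_conditions("7E").model_copy(
            update={"t_end": 10_000.0, "sample_dt": 200.0})
        base = nc.simulate(spec_7e, cond, fig_concs)
        branched = nc.add_competitor(spec_7e, self._gox(enzyme_table))
        res = nc.simulate(branched, cond, {**fig_concs, "GOx": 0.0})
        assert np.allclose(res.monitored(), base.monitored(), rtol=1e-6, atol=1e-9)

    def test_yield_non_increasing_with_competitor(self, spec_7e, enzyme_table,
                                                  fig_concs):
        cond = nc.assay_conditions("7E").model_copy(
            update={"t_end": 10_000.0, "sample_dt": 500.0})
        branched = nc.add_competitor(spec_7e, self._gox(enzyme_table))
        yields = []
        for gox in (0.0, 0.005, 0.02, 0.08, 0.3):
            res = nc.simulate(branched, cond, {**fig_concs, "GOx": gox})
            yields.append(res.monitored()[-1])
        assert all(a >= b for a, b in zip(yields, yields[1:]))
        assert yields[-1] < yields[0]

    def test_absent_species_rejected(self, spec_7e, enzyme_table):
        bad = nc.ReactionStep(
            enzyme=enzyme_table["GOx"],
            substrate_stoich={"xylose": 1},
            product_stoich={"xylonolactone": 1},
            limiting_species="xylose",
        )
        with pytest.raises(ValueError, match="xylose"):
            nc.add_competitor(spec_7e, bad)


class TestThermoProfile:
    def test_gpd_flagged_bottleneck(self, spec_7e):
        df = nc.thermo_profile(spec_7e)
        gpd = df[df.enzyme == "GPD"].iloc[0]
        assert gpd.delta_g_kj_mol == pytest.approx(15.9)
        assert gpd.bottleneck  # uphill and KM 3494 uM > 1 mM
        pgk = df[df.enzyme == "PGK"].iloc[0]
        assert not pgk.bottleneck

    def test_cumulative_gpd_pgk(self, spec_7e):
        df = nc.thermo_profile(spec_7e)
        assert df.cumulative_kj_mol.iloc[-1] == pytest.approx(15.9 - 20.2)

    def test_unknown_energies_not_imputed(self, spec_7e):
        df = nc.thermo_profile(spec_7e)
        assert df.delta_g_kj_mol.isna().sum() == 5  # only GPD and PGK known

    def test_empty_spec(self):
        spec = nc.CascadeSpec(
            name="empty", steps=[], species_registry={"X": "substrate"},
            input_substrate="X", monitored_species="X", monitored_sign=+1,
        )
        df = nc.thermo_profile(spec)
        assert len(df) == 0


class TestSimResult:
    def test_tidy_frame(self, sim_7e):
        df = sim_7e.to_frame()
        assert set(df.columns) == {"time_s", "species", "concentration_uM"}
        assert set(df.species.unique()) == set(sim_7e.species)
        assert len(df) == len(sim_7e.species) * sim_7e.time.size
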