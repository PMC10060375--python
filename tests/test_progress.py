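"""Beer-Lambert conversion, initial rates, MM fitting, enhancement tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanocascade as nc
from nanocascade.enzymes import MMParams
from nanocascade.progress import (
    MMFit,
    concentration_to_absorbance,
    read_progress_csv,
    write_progress_csv,
)

from conftest import chain_spec, toy_enzyme


def _line(t, slope, intercept=0.0):
    return nc.ProgressCurve(t, slope * t + intercept, "concentration", "line")


class TestBeerLambert:
    def test_known_conversion(self):
        t = np.arange(3.0)
        curve = nc.ProgressCurve(t, np.full(3, 0.06220), "absorbance", "w1")
        conc = nc.absorbance_to_concentration(curve, 6220.0, 1.0)
        assert conc.value == pytest.approx(10.0)
        assert conc.value_kind == "concentration"

    def test_zero_absorbance(self):
        curve = nc.ProgressCurve([0, 1, 2], [0, 0, 0], "absorbance", "w")
        assert np.all(nc.absorbance_to_concentration(curve).value == 0)

    def test_round_trip(self, rng):
        t = np.arange(50.0)
        a = rng.uniform(0, 1, 50)
        curve = nc.ProgressCurve(t, a, "absorbance", "w")
        back = concentration_to_absorbance(
            nc.absorbance_to_concentration(curve, 6220.0, 0.5), 6220.0, 0.5)
        assert np.allclose(back.value, a, rtol=1e-12)

    def test_double_conversion_rejected(self):
        curve = nc.ProgressCurve([0, 1, 2], [1, 2, 3], "concentration", "w")
        with pytest.raises(ValueError):
            nc.absorbance_to_concentration(curve)


class TestProgressCurveValidation:
    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            nc.ProgressCurve([0, 1], [0, 1], "absorbance", "w")

    def test_non_increasing_time(self):
        with pytest.raises(ValueError, match="increasing"):
            nc.ProgressCurve([0, 2, 1], [0, 1, 2], "absorbance", "w")


class TestInitialRate:
    def test_exact_line(self):
        t = np.arange(0, 1200, 60.0)
        rate, err = nc.initial_rate(_line(t, 0.01))
        assert rate == pytest.approx(0.01)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_flat_curve(self):
        t = np.arange(0, 1200, 60.0)
        rate, err = nc.initial_rate(_line(t, 0.0, 5.0))
        assert (rate, err) == (0.0, 0.0)

    def test_matches_rate_law_at_start(self):
        # single MM step; early window slope must match the rate at S0
        kcat, km, e_conc, s0 = 2.0, 100.0, 0.05, 500.0
        spec = chain_spec([toy_enzyme("E1", kcat, km)])
        cond = nc.AssayConditions(initial_concentrations={"S0": s0},
                                  t_end=2_000.0, sample_dt=10.0)
        res = nc.simulate(spec, cond, {"E1": e_conc})
        curve = nc.ProgressCurve(res.time, res.concentration("S1"),
                                 "concentration", "P")
        rate, _ = nc.initial_rate(curve)
        expect = nc.mm_rate(MMParams(kcat=kcat, km=km), e_conc, s0)
        assert rate == pytest.approx(expect, rel=0.02)

    def test_shift_and_scale_invariance(self):
        t = np.arange(0, 3000, 60.0)
        base = np.sin(t / 5e4) * 50  # gently curved
        c1 = nc.ProgressCurve(t, base, "concentration", "a")
        c2 = nc.ProgressCurve(t + 500.0, base, "concentration", "b")
        c3 = nc.ProgressCurve(t, base * 3.0, "concentration", "c")
        r1, _ = nc.initial_rate(c1)
        r2, _ = nc.initial_rate(c2)
        r3, _ = nc.initial_rate(c3)
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert r3 == pytest.approx(3 * r1, rel=1e-9)

    def test_requires_concentration_units(self):
        t = np.arange(0, 1200, 60.0)
        with pytest.raises(ValueError):
            nc.initial_rate(nc.ProgressCurve(t, t * 0.01, "absorbance", "w"))


class TestFitMM:
    def test_exact_recovery_amylase(self):
        # noiseless titration from the amylase free-enzyme constants
        params = MMParams(kcat=25.0, km=213.0)
        ds = nc.gen_mm_dataset(params, enzyme_conc=0.0025, noise_frac=0.0)
        fit = nc.fit_mm(ds, enzyme_conc=0.0025)
        assert fit.params.kcat == pytest.approx(25.0, rel=1e-4)
        assert fit.params.km == pytest.approx(213.0, rel=1e-4)
        assert fit.efficiency == pytest.approx(25.0 / 213.0 * 1e3, rel=1e-3)

    def test_all_zero_rates_rejected(self):
        ds = nc.RateDataset([10, 20, 40, 80], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="zero"):
            nc.fit_mm(ds, 0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        kcat=st.floats(min_value=0.07, max_value=2481.0),
        km=st.floats(min_value=36.0, max_value=3584.0),
    )
    def test_noiseless_recovery_property(self, kcat, km):
        params = MMParams(kcat=kcat, km=km)
        ds = nc.gen_mm_dataset(params, enzyme_conc=0.01, noise_frac=0.0)
        fit = nc.fit_mm(ds, enzyme_conc=0.01)
        assert fit.params.kcat == pytest.approx(kcat, rel=1e-3)
        assert fit.params.km == pytest.approx(km, rel=1e-3)

    def test_noisy_recovery_median(self):
        params = MMParams(kcat=10.0, km=200.0)
        errs = []
        for seed in range(50):
            ds = nc.gen_mm_dataset(params, 0.01, noise_frac=0.05, seed=seed)
            fit = nc.fit_mm(ds, 0.01)
            errs.append(abs(fit.params.km - 200.0) / 200.0)
        assert np.median(errs) < 0.10

    def test_warns_when_levels_below_km(self):
        # titrating far below KM leaves only the ratio Vmax/KM identified
        params = MMParams(kcat=10.0, km=1000.0)
        levels = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        ds = nc.gen_mm_dataset(params, 0.01, substrate_levels=levels,
                               noise_frac=0.05, seed=7)
        with pytest.warns(UserWarning, match="KM"):
            fit = nc.fit_mm(ds, 0.01)
        # identifiability loss shows up as inflated relative uncertainty
        assert not np.isfinite(fit.km_stderr) or \
            fit.km_stderr / fit.params.km > 0.10


class TestEnhancementTable:
    @staticmethod
    def _fit(kcat, km, kcat_se=0.0, km_se=0.0):
        return MMFit(params=MMParams(kcat=kcat, km=km), vmax=kcat * 0.01,
                     vmax_stderr=kcat_se * 0.01, km_stderr=km_se,
                     kcat_stderr=kcat_se, residual_rms=0.0, n_points=8)

    def test_identical_fits_are_unity_and_ns(self):
        fits = {"Amy": self._fit(25.0, 213.0, 0.4, 15.0)}
        df = nc.enhancement_table(fits, fits)
        assert df.loc["Amy", "kcat_fold"] == pytest.approx(1.0)
        assert df.loc["Amy", "km_fold"] == pytest.approx(1.0)
        assert bool(df.loc["Amy", "kcat_ns"])

    def test_maltase_and_glucokinase_folds(self):
        free = {"Mlt": self._fit(0.40, 335.0, 0.03, 80.0),
                "Glk": self._fit(2.6, 36.0, 0.1, 10.0)}
        bound = {"Mlt": self._fit(15.3, 347.0, 5.8, 90.0),
                 "Glk": self._fit(30.7, 109.0, 6.3, 14.0)}
        df = nc.enhancement_table(free, bound)
        assert df.loc["Mlt", "kcat_fold"] == pytest.approx(38.25, rel=0.01)
        assert not df.loc["Mlt", "kcat_ns"]
        assert df.loc["Glk", "kcat_fold"] == pytest.approx(11.8, rel=0.01)

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError):
            nc.enhancement_table({"Amy": self._fit(1, 1)}, {})


class TestCSVIO:
    def test_tidy_round_trip(self, tmp_path, rng):
        t = np.arange(0, 600, 60.0)
        curves = [
            nc.ProgressCurve(t, rng.uniform(0, 1, t.size), "absorbance", f"w{i}")
            for i in range(3)
        ]
        path = tmp_path / "curves.csv"
        write_progress_csv(curves, path)
        back = read_progress_csv(path)
        assert [c.label for c in back] == ["w0", "w1", "w2"]
        for a, b in zip(curves, back):
            assert np.allclose(a.value, b.value)
            assert b.value_kind == "absorbance"

    def test_wide_dialect(self, tmp_path):
        import pandas as pd

        t = np.arange(0, 300, 60.0)
        pd.DataFrame({"time_s": t, "A1": t * 1e-4, "A2": t * 2e-4}).to_csv(
            tmp_path / "wide.csv", index=False)
        curves = read_progress_csv(tmp_path / "wide.csv")
        assert [c.label for c in curves] == ["A1", "A2"]
        assert curves[1].value[-1] == pytest.approx(240 * 2e-4)
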