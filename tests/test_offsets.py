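"""RONA closed forms and the three genomic-offset formulations."""

import numpy as np
import pandas as pd
import pytest

from geoffset.core_data import AlleleFreqMatrix, EnvMatrix
from geoffset.offsets import (
    average_models,
    forward_offset,
    local_offset,
    reverse_offset,
    rgb_composite,
    rona,
)
from geoffset.turnover import TurnoverModel


def _env(values, name="X", **kw):
    values = np.asarray(values, dtype=float)
    sites = [f"P{i}" for i in range(len(values))]
    return EnvMatrix(sites, [name], values[:, None], **kw)


def _ramp_model(names=("X",)):
    """Exact two-point step models: F(2)=0.2, F(7)=0.7 for every predictor."""
    bp = {n: np.array([2.0, 7.0]) for n in names}
    cum = {n: np.array([0.2, 0.7]) for n in names}
    return TurnoverModel(list(names), bp, cum, pd.Series(dtype=float), pd.DataFrame())


class TestRona:
    def test_zero_when_future_equals_current(self):
        e = np.arange(6.0)
        F = AlleleFreqMatrix(
            [f"P{i}" for i in range(6)], ["L1"], (0.2 + 0.01 * e)[:, None], np.full((6, 1), 100)
        )
        E_fut = _env(e, period="future", model="m", scenario="SSP126")
        tab = rona(F, {"X": ["L1"]}, _env(e), [E_fut])
        assert (tab.per_model["rona"] == 0).all()

    def test_noise_free_closed_form(self):
        # p = 0.2 + 0.01 e, delta e = 5, no truncation -> RONA = 0.05 exactly
        e = np.arange(6.0)
        F = AlleleFreqMatrix(
            [f"P{i}" for i in range(6)], ["L1"], (0.2 + 0.01 * e)[:, None], np.full((6, 1), 100)
        )
        E_fut = _env(e + 5.0, period="future", model="m", scenario="SSP126")
        tab = rona(F, {"X": ["L1"]}, _env(e), [E_fut])
        assert np.allclose(tab.per_model["rona"], 0.05, atol=1e-10)
        reg = tab.regressions
        assert reg["slope"].iloc[0] == pytest.approx(0.01, abs=1e-12)
        assert reg["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_r2_weighted_mean_matches_naive_oracle(self):
        """R^2-weighted RONA equals an independently coded per-locus
        regression + weighted-mean implementation on a noisy instance."""
        rng = np.random.default_rng(8)
        n, L = 10, 6
        e = np.linspace(0, 9, n)
        Y = np.clip(0.3 + 0.04 * e[:, None] + rng.normal(0, 0.05, (n, L)), 0, 1)
        Y = np.round(Y, 6)
        F = AlleleFreqMatrix([f"P{i}" for i in range(n)], [f"L{j}" for j in range(L)],
                             Y, np.full((n, L), 10**6))
        e_fut = e + rng.normal(2, 1, n)
        tab = rona(F, {"X": [f"L{j}" for j in range(L)]}, _env(e),
                   [_env(e_fut, period="future", model="m", scenario="SSP126")])
        # naive oracle
        expected = []
        slopes, inters, r2s = [], [], []
        for j in range(L):
            b, a = np.polyfit(e, Y[:, j], 1)
            resid = Y[:, j] - (a + b * e)
            r2 = 1 - (resid**2).sum() / ((Y[:, j] - Y[:, j].mean()) ** 2).sum()
            slopes.append(b), inters.append(a), r2s.append(r2)
        for i in range(n):
            num = den = 0.0
            for j in range(L):
                pc = np.clip(inters[j] + slopes[j] * e[i], 0, 1)
                pf = np.clip(inters[j] + slopes[j] * e_fut[i], 0, 1)
                num += r2s[j] * abs(pf - pc)
                den += r2s[j]
            expected.append(num / den)
        got = tab.per_model.sort_values("population")["rona"].to_numpy()
        order = np.argsort([f"P{i}" for i in range(n)])
        assert np.allclose(got, np.array(expected)[order], atol=1e-10)

    def test_doubling_delta_doubles_rona_without_truncation(self):
        e = np.arange(8.0)
        F = AlleleFreqMatrix([f"P{i}" for i in range(8)], ["L1"],
                             (0.3 + 0.02 * e)[:, None], np.full((8, 1), 100))
        t1 = rona(F, {"X": ["L1"]}, _env(e), [_env(e + 2, period="future", model="m", scenario="s")])
        t2 = rona(F, {"X": ["L1"]}, _env(e), [_env(e + 4, period="future", model="m", scenario="s")])
        assert np.allclose(2 * t1.per_model["rona"], t2.per_model["rona"], atol=1e-12)

    def test_too_few_populations(self):
        F = AlleleFreqMatrix(["P0", "P1"], ["L1"], np.array([[0.2], [0.4]]), np.full((2, 1), 10))
        with pytest.raises(ValueError, match="3 population"):
            rona(F, {"X": ["L1"]}, _env(np.arange(2.0)), [])

    def test_variable_without_loci_skipped_with_warning(self):
        e = np.arange(6.0)
        F = AlleleFreqMatrix([f"P{i}" for i in range(6)], ["L1"],
                             (0.2 + 0.01 * e)[:, None], np.full((6, 1), 100))
        with pytest.warns(UserWarning, match="no associated loci"):
            tab = rona(F, {"X": ["L1"], "Y": []}, _env(e),
                       [_env(e + 1, period="future", model="m", scenario="s")])
        assert set(tab.per_model["variable"]) == {"X"}


class TestOffsets:
    def test_local_zero_when_future_equals_current(self):
        m = _ramp_model()
        E = _env(np.linspace(0, 10, 5))
        assert (local_offset(m, E, E) == 0).all()

    def test_local_closed_form_on_step_model(self):
        m = _ramp_model()
        cur = _env(np.array([2.0]))
        fut = _env(np.array([7.0]))
        assert local_offset(m, cur, fut).iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_forward_and_reverse_match_naive_double_loop(self):
        """5 sources x 50 cells oracle agreement to 1e-12."""
        rng = np.random.default_rng(10)
        names = ["X", "Y"]
        m = TurnoverModel(
            names,
            {n: np.sort(rng.uniform(0, 10, 8)) for n in names},
            {n: np.sort(rng.uniform(0, 0.5, 8)) for n in names},
            pd.Series(dtype=float),
            pd.DataFrame(),
        )
        pops = [f"P{i}" for i in range(5)]
        cells = [f"c{j}" for j in range(50)]
        E_pop = EnvMatrix(pops, names, rng.uniform(0, 10, (5, 2)))
        E_fut = EnvMatrix(cells, names, rng.uniform(0, 10, (50, 2)), period="future",
                          model="m", scenario="s")
        pc = pd.DataFrame({"lon": rng.uniform(0, 5, 5), "lat": rng.uniform(40, 45, 5)}, index=pops)
        cc = pd.DataFrame({"lon": rng.uniform(0, 5, 50), "lat": rng.uniform(40, 45, 50)}, index=cells)
        from geoffset.turnover import transform_climate
        from geoffset.landscape import haversine_km

        T_pop = transform_climate(m, E_pop).to_numpy()
        T_fut = transform_climate(m, E_fut).to_numpy()
        fwd = forward_offset(m, E_pop, pc, E_fut, cc, d_max=(150.0, np.inf))
        rev = reverse_offset(m, E_pop, E_fut)
        for i in range(5):
            best_capped, best_inf = np.inf, np.inf
            for j in range(50):
                d = np.sqrt(((T_pop[i] - T_fut[j]) ** 2).sum())
                km = float(haversine_km(pc.iloc[i, 0], pc.iloc[i, 1], cc.iloc[j, 0], cc.iloc[j, 1]))
                best_inf = min(best_inf, d)
                if km <= 150.0:
                    best_capped = min(best_capped, d)
            assert fwd["forward_inf"].iloc[i] == pytest.approx(best_inf, abs=1e-12)
            if np.isfinite(best_capped):
                assert fwd["forward_150"].iloc[i] == pytest.approx(best_capped, abs=1e-12)
        for j in range(50):
            best = min(np.sqrt(((T_fut[j] - T_pop[i]) ** 2).sum()) for i in range(5))
            assert rev.iloc[j] == pytest.approx(best, abs=1e-12)

    def test_forward_monotone_in_dispersal_cap(self):
        rng = np.random.default_rng(12)
        m = _ramp_model(("X",))
        pops = [f"P{i}" for i in range(6)]
        cells = [f"c{j}" for j in range(40)]
        E_pop = _env(rng.uniform(0, 10, 6))
        E_fut = EnvMatrix(cells, ["X"], rng.uniform(0, 10, (40, 1)), period="future")
        pc = pd.DataFrame({"lon": rng.uniform(100, 102, 6), "lat": rng.uniform(40, 42, 6)}, index=pops)
        cc = pd.DataFrame({"lon": rng.uniform(100, 102, 40), "lat": rng.uniform(40, 42, 40)}, index=cells)
        fwd = forward_offset(m, E_pop, pc, E_fut, cc, d_max=(50.0, 100.0, 200.0, np.inf))
        arr = fwd.to_numpy()
        with np.errstate(invalid="ignore"):
            diffs = np.diff(arr, axis=1)
        assert np.nanmax(diffs, initial=-np.inf) <= 1e-15

    def test_reverse_single_population(self):
        m = _ramp_model(("X",))
        E_pop = _env(np.array([3.0]))
        E_fut = _env(np.array([1.0, 8.0, 3.0]), period="future")
        rev = reverse_offset(m, E_pop, E_fut)
        from geoffset.turnover import transform_climate

        T_pop = transform_climate(m, E_pop).to_numpy()[0]
        T_fut = transform_climate(m, E_fut).to_numpy()
        expected = np.abs(T_fut[:, 0] - T_pop[0])
        assert np.allclose(rev.to_numpy(), expected, atol=1e-12)


class TestAverageAndRgb:
    def test_identical_models_average_to_input(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        mean, se, corr = average_models({"m1": s, "m2": s.copy()})
        assert np.allclose(mean, s)
        assert np.allclose(se, 0)
        assert np.allclose(corr, 1)

    def test_two_models_x_and_3x(self):
        s = pd.Series([1.0, 2.0], index=list("ab"))
        mean, _, _ = average_models({"m1": s, "m2": 3 * s})
        assert np.allclose(mean, 2 * s)

    def test_mismatched_indices_rejected(self):
        s1 = pd.Series([1.0], index=["a"])
        s2 = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError):
            average_models({"m1": s1, "m2": s2})

    def test_rgb_extremes_and_constant_channel(self):
        idx = list("abc")
        local = pd.Series([0.0, 0.5, 1.0], index=idx)
        fwd = pd.Series([0.0, 0.2, 0.9], index=idx)
        const = pd.Series([0.4, 0.4, 0.4], index=idx)
        rgb = rgb_composite(local, fwd, const)
        assert rgb.loc["c", ["R", "G"]].tolist() == [255, 255]
        assert rgb.loc["a", ["R", "G"]].tolist() == [0, 0]
        assert (rgb["B"] == 0).all()  # constant metric maps to 0
        assert rgb.loc["b", "R"] == 128  # round half-up of 127.5
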