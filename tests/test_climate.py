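"""Climate aggregation, bioclim variables, VIF screening and MESS."""

import numpy as np
import pandas as pd
import pytest

import nichetransfer as nt
from nichetransfer.climate import BIOCLIM_NAMES, compute_bioclim, vif
from nichetransfer.gridio import GridGeometry


def monthly_from_series(tmin, tmax, prec):
    """Wrap per-month scalars into 1-cell monthly-normal grids."""
    return {
        "tmin": np.asarray(tmin, float).reshape(12, 1, 1),
        "tmax": np.asarray(tmax, float).reshape(12, 1, 1),
        "prec": np.asarray(prec, float).reshape(12, 1, 1),
    }


def bioclim_oracle(tmin, tmax, prec):
    """Straight-loop scalar implementation of the 19 bioclim summaries,
    independent of the vectorized production path."""
    tmin, tmax, prec = map(lambda a: [float(x) for x in a],
                           (tmin, tmax, prec))
    tmean = [(a + b) / 2 for a, b in zip(tmin, tmax)]
    out = {}
    out["bio1"] = sum(tmean) / 12
    out["bio2"] = sum(tx - tn for tx, tn in zip(tmax, tmin)) / 12
    out["bio4"] = 100 * float(np.std(tmean))
    out["bio5"] = max(tmax)
    out["bio6"] = min(tmin)
    out["bio7"] = out["bio5"] - out["bio6"]
    out["bio3"] = 100 * out["bio2"] / out["bio7"] if out["bio7"] else 0.0
    out["bio12"] = sum(prec)
    out["bio13"] = max(prec)
    out["bio14"] = min(prec)
    out["bio15"] = 100 * float(np.std(prec)) / (1 + out["bio12"] / 12)
    q_p, q_t = [], []
    for i in range(12):
        months = [i, (i + 1) % 12, (i + 2) % 12]
        q_p.append(sum(prec[m] for m in months))
        q_t.append(sum(tmean[m] for m in months) / 3)
    wet = q_p.index(max(q_p)); dry = q_p.index(min(q_p))
    hot = q_t.index(max(q_t)); cold = q_t.index(min(q_t))
    out["bio8"], out["bio9"] = q_t[wet], q_t[dry]
    out["bio10"], out["bio11"] = q_t[hot], q_t[cold]
    out["bio16"], out["bio17"] = q_p[wet], q_p[dry]
    out["bio18"], out["bio19"] = q_p[hot], q_p[cold]
    return out


class TestDecadalAverage:
    geom = GridGeometry(2, 2)

    def make(self, values_by_year):
        data = {"tmin": {}, "tmax": {}, "prec": {}}
        for year, v in values_by_year.items():
            for var in data:
                data[var][year] = np.full((12, 2, 2), float(v))
        return nt.climate.MonthlyClimate(data=data, geometry=self.geom)

    def test_single_year_is_identity(self):
        m = self.make({1950: 7.0})
        normals = nt.decadal_average(m, [1950])
        assert np.all(normals["tmin"] == 7.0)

    def test_mean_of_two_years(self):
        m = self.make({1950: 10.0, 1951: 20.0})
        normals = nt.decadal_average(m, [1950, 1951])
        assert np.all(normals["prec"] == 15.0)

    def test_missing_year_names_year(self):
        m = self.make({1950: 1.0})
        with pytest.raises(ValueError, match="1951"):
            nt.decadal_average(m, [1950, 1951])


class TestComputeBioclim:
    geom = GridGeometry(1, 1)

    def test_constant_climate_landmarks(self):
        normals = monthly_from_series([10.0] * 12, [10.0] * 12, [50.0] * 12)
        stack = compute_bioclim(normals, self.geom)
        assert stack.grids["bio1"][0, 0] == pytest.approx(10.0)
        assert stack.grids["bio4"][0, 0] == pytest.approx(0.0)
        assert stack.grids["bio12"][0, 0] == pytest.approx(600.0)
        assert stack.grids["bio15"][0, 0] == pytest.approx(0.0)
        assert stack.grids["bio16"][0, 0] == pytest.approx(150.0)
        assert stack.grids["bio17"][0, 0] == pytest.approx(150.0)

    def test_zero_diurnal_range(self):
        t = list(range(12))
        normals = monthly_from_series(t, t, [10.0] * 12)
        stack = compute_bioclim(normals, self.geom)
        assert stack.grids["bio2"][0, 0] == pytest.approx(0.0)
        assert stack.grids["bio3"][0, 0] == pytest.approx(0.0)

    def test_oracle_equivalence_on_random_series(self):
        """100 random monthly series match the straight-loop oracle on
        all 19 variables to 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            tmin = rng.uniform(-20, 15, 12)
            tmax = tmin + rng.uniform(0.5, 15, 12)
            prec = rng.uniform(0, 300, 12)
            stack = compute_bioclim(monthly_from_series(tmin, tmax, prec),
                                    self.geom)
            expect = bioclim_oracle(tmin, tmax, prec)
            for name in BIOCLIM_NAMES:
                assert stack.grids[name][0, 0] == pytest.approx(
                    expect[name], abs=1e-9), name

    def test_stack_invariants(self):
        rng = np.random.default_rng(7)
        tmin = rng.uniform(-10, 10, 12)
        tmax = tmin + rng.uniform(0, 10, 12)
        prec = rng.uniform(0, 100, 12)
        stack = compute_bioclim(monthly_from_series(tmin, tmax, prec),
                                self.geom)
        assert stack.grids["bio5"][0, 0] >= stack.grids["bio6"][0, 0]
        assert stack.grids["bio4"][0, 0] >= 0
        assert stack.grids["bio12"][0, 0] == pytest.approx(prec.sum())

    def test_non_finite_input_rejected(self):
        normals = monthly_from_series([np.nan] * 12, [1.0] * 12, [0.0] * 12)
        with pytest.raises(ValueError, match="non-finite"):
            compute_bioclim(normals, self.geom)


class TestVif:
    def test_independent_variables_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10 ** 4, 2))
        assert np.all(vif(X) < 1.05)

    def test_exact_collinearity_flagged(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        rep = nt.vif_screen(X, threshold=0.9)
        assert not np.isfinite(rep.vif.iloc[2]) or rep.vif.iloc[2] >= 1e6
        assert len(rep.flagged) >= 1

    def test_closed_form_bivariate(self):
        """r = 0.8 -> VIF = 1/(1-0.64) = 2.78 within 0.1 at n = 1e4."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10 ** 4)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(10 ** 4)
        v = vif(np.column_stack([x, y]))
        assert np.allclose(v, 1 / (1 - 0.64), atol=0.1)

    def test_constant_variable_infinite_not_exception(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        rep = nt.vif_screen(X, threshold=0.9)
        assert np.isinf(rep.vif.iloc[0])
        assert rep.vif.index[0] in rep.flagged

    def test_stepwise_permutation_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((400, 3))
        X = np.column_stack([base, base @ [0.9, 0.1, 0.0]
                             + 0.05 * rng.standard_normal(400)])
        names = ["a", "b", "c", "d"]
        rep1 = nt.vif_screen(pd.DataFrame(X, columns=names),
                             threshold=5.0, method="stepwise-VIF")
        perm = [2, 0, 3, 1]
        rep2 = nt.vif_screen(
            pd.DataFrame(X[:, perm], columns=[names[i] for i in perm]),
            threshold=5.0, method="stepwise-VIF")
        assert set(rep1.flagged) == set(rep2.flagged)

    def test_both_methods_available_and_tagged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 3))
        for method in ["pairwise-correlation", "stepwise-VIF"]:
            rep = nt.vif_screen(X, threshold=0.9, method=method)
            assert rep.method == method


class TestMess:
    def make_stack(self, value):
        geom = GridGeometry(1, 1)
        return nt.ClimateStack("t", {"v1": np.full((1, 1), float(value))},
                               geom)

    ref = np.arange(1.0, 101.0)[:, None]     # 1..100, even count

    def test_median_scores_100(self):
        mess, _ = nt.mess_surface(self.ref, self.make_stack(50.5),
                                  variables=["v1"])
        assert mess[0, 0] == pytest.approx(100.0)

    def test_minimum_scores_0(self):
        mess, _ = nt.mess_surface(self.ref, self.make_stack(1.0),
                                  variables=["v1"])
        assert mess[0, 0] == pytest.approx(0.0)

    def test_below_minimum_negative(self):
        mess, _ = nt.mess_surface(self.ref, self.make_stack(-5.0),
                                  variables=["v1"])
        assert mess[0, 0] < 0.0

    def test_training_points_self_similarity_nonnegative(self, small_stacks):
        stack = small_stacks[0]
        rng = np.random.default_rng(0)
        cells = np.column_stack([rng.integers(0, 60, 200),
                                 rng.integers(0, 60, 200)])
        ref = stack.sample(cells)
        mess, _ = nt.mess_surface(ref, stack, variables=stack.variables)
        sampled = mess[cells[:, 0], cells[:, 1]]
        assert sampled.min() >= 0.0

    def test_most_dissimilar_variable_identified(self):
        geom = GridGeometry(1, 1)
        stack = nt.ClimateStack("t", {
            "v1": np.full((1, 1), 50.0),      # at reference median
            "v2": np.full((1, 1), -10.0),     # far below reference
        }, geom)
        ref = np.column_stack([np.arange(1.0, 101.0),
                               np.arange(1.0, 101.0)])
        mess, mdv = nt.mess_surface(ref, stack, variables=["v1", "v2"])
        assert mdv[0, 0] == 1
        assert mess[0, 0] < 0
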