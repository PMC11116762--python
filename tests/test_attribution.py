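import numpy as np
import pytest
import xarray as xr

from co2sens import attribution as at
from co2sens.synthetic import generate_attribution_windows


def make_drivers(rng, n=20):
    return {
        "vpd": rng.normal(5, 1, n),
        "wa": rng.normal(20, 4, n),
        "nit": rng.normal(600, 30, n),
        "pho": rng.normal(30, 2, n),
    }


class TestWindowMeans:
    def test_alignment_and_values(self):
        x = np.arange(10.0)
        out = at.window_means(x, window_len=4)
        assert out.shape == (7,)
        assert out[0] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert out[-1] == pytest.approx(np.mean([6, 7, 8, 9]))

    def test_matches_beta_window_count(self):
        assert at.window_means(np.arange(34.0), 15).shape == (20,)


class TestFitDriverRegression:
    def test_noiseless_recovery(self, rng):
        d = make_drivers(rng)
        beta = 2.0 * d["vpd"] - 1.0 * d["wa"] + 0.0 * d["nit"] + 0.0 * d["pho"]
        coefs = at.fit_driver_regression(beta, d)
        assert coefs["vpd"] == pytest.approx(2.0, abs=1e-8)
        assert coefs["wa"] == pytest.approx(-1.0, abs=1e-8)
        assert coefs["nit"] == pytest.approx(0.0, abs=1e-8)
        assert coefs["pho"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(200):
            d = make_drivers(rng, n=12)
            beta = rng.normal(size=12)
            coefs = at.fit_driver_regression(beta, d)
            X = np.column_stack([d[k] for k in d] + [np.ones(12)])
            ref = np.linalg.pinv(X) @ beta
            got = np.array([coefs[k] for k in d] + [coefs["intercept"]])
            assert np.allclose(got, ref, atol=1e-8)

    def test_fewer_windows_than_parameters_masked(self, rng):
        d = {k: v[:4] for k, v in make_drivers(rng).items()}
        assert at.fit_driver_regression(np.ones(4), d) is None

    def test_rank_deficient_masked(self, rng):
        d = make_drivers(rng)
        d["pho"] = 2.0 * d["vpd"]  # perfectly collinear
        assert at.fit_driver_regression(rng.normal(size=20), d) is None


class TestStandardizedCoefficients:
    def test_direct_evaluation(self):
        # Stc = |a| * std(X) / std(beta) = 2 * 1 / 2 = 1
        x = np.array([-1.0, 1.0, -1.0, 1.0])  # population sd 1
        beta = np.array([-2.0, 2.0, -2.0, 2.0])  # sd 2
        stc = at.standardized_coefficients({"vpd": 2.0}, {"vpd": x}, beta)
        assert stc["vpd"] == pytest.approx(1.0)

    def test_constant_driver_gets_zero(self, rng):
        beta = rng.normal(size=10)
        stc = at.standardized_coefficients({"wa": 3.0}, {"wa": np.full(10, 7.0)}, beta)
        assert stc["wa"] == 0.0

    def test_unit_rescaling_invariance(self, rng):
        d = make_drivers(rng)
        beta = 2.0 * d["vpd"] - 1.0 * d["wa"] + rng.normal(0, 0.1, 20)
        c1 = at.fit_driver_regression(beta, d)
        s1 = at.standardized_coefficients(c1, d, beta)
        scaled = dict(d, vpd=d["vpd"] * 10.0)  # hPa -> different unit
        c2 = at.fit_driver_regression(beta, scaled)
        s2 = at.standardized_coefficients(c2, scaled, beta)
        assert s2["vpd"] == pytest.approx(s1["vpd"], rel=1e-9)

    def test_constant_beta_masked(self, rng):
        d = make_drivers(rng)
        assert at.standardized_coefficients({"vpd": 1.0}, d, np.full(20, 3.0)) is None


class TestRelativeContributions:
    def test_normalization_example(self):
        r = at.relative_contributions({"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.0})
        assert r == {"a": 0.5, "b": 0.25, "c": 0.25, "d": 0.0}

    def test_single_nonzero(self):
        r = at.relative_contributions({"a": 1.0, "b": 0.0})
        assert r == {"a": 1.0, "b": 0.0}

    def test_all_zero_masked(self):
        assert at.relative_contributions({"a": 0.0, "b": 0.0}) is None

    def test_sum_to_one_and_nonnegative(self, rng):
        for _ in range(50):
            stc = {k: float(v) for k, v in zip("abcd", rng.uniform(0, 5, 4))}
            r = at.relative_contributions(stc)
            assert sum(r.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in r.values())

    def test_driver_permutation_equivariance(self, rng):
        d = make_drivers(rng)
        beta = 2 * d["vpd"] - d["wa"] + 0.1 * d["nit"] + rng.normal(0, 0.2, 20)
        res1 = at.attribute_pixel(beta, d)
        permuted = {k: d[k] for k in ["pho", "nit", "wa", "vpd"]}
        res2 = at.attribute_pixel(beta, permuted)
        for k in d:
            assert res2[f"r_{k}"] == pytest.approx(res1[f"r_{k}"], rel=1e-9)


class TestPartialCorrelation:
    def test_beta_equals_one_driver_exactly(self, rng):
        n = 40
        d = {"vpd": rng.normal(size=n), "tmax": rng.normal(size=n)}
        r = at.partial_correlation(d["vpd"].copy(), d)
        assert r["vpd"] == pytest.approx(1.0, abs=1e-10)
        assert abs(r["tmax"]) < 1e-10

    def test_matches_two_stage_ols_oracle(self, rng):
        n = 30
        d = make_drivers(rng, n)
        beta = rng.normal(size=n)
        r = at.partial_correlation(beta, d)
        names = list(d)
        X = np.column_stack([d[k] for k in names])
        for idx, name in enumerate(names):
            C = np.column_stack([np.delete(X, idx, axis=1), np.ones(n)])
            ry = beta - C @ np.linalg.pinv(C) @ beta
            rx = X[:, idx] - C @ np.linalg.pinv(C) @ X[:, idx]
            ref = float(np.corrcoef(ry, rx)[0, 1])
            assert r[name] == pytest.approx(ref, abs=1e-10)

    def test_duplicated_driver_masked(self, rng):
        n = 20
        x = rng.normal(size=n)
        d = {"vpd": x, "dup": x.copy()}
        assert at.partial_correlation(rng.normal(size=n), d) is None

    def test_too_few_windows_masked(self, rng):
        d = {"vpd": rng.normal(size=4), "tmax": rng.normal(size=4)}
        assert at.partial_correlation(rng.normal(size=4), d) is None

    def test_shares_normalized(self, rng):
        n = 30
        d = make_drivers(rng, n)
        beta = 2 * d["vpd"] + rng.normal(size=n)
        shares = at.partial_correlation_shares(beta, d)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        assert max(shares, key=shares.get) == "vpd"


class TestAttributeCube:
    def _cubes(self, rng, nw=20, nlat=3, nlon=3):
        years = np.arange(1982, 1982 + nw + 14)
        lats = np.linspace(35, 65, nlat)
        lons = np.linspace(-10, 10, nlon)
        mk = lambda v: xr.DataArray(
            v, dims=("year", "lat", "lon"),
            coords={"year": years, "lat": lats, "lon": lons}, attrs={"units": "u"},
        )
        drivers = {
            "vpd": mk(rng.normal(5, 1, (years.size, nlat, nlon))),
            "wa": mk(rng.normal(20, 4, (years.size, nlat, nlon))),
            "nit": mk(rng.normal(600, 30, (years.size, nlat, nlon))),
            "pho": mk(rng.normal(30, 2, (years.size, nlat, nlon))),
        }
        wm = {k: at.window_means(v.values, 15) for k, v in drivers.items()}
        beta_vals = 3 * wm["vpd"] - 0.5 * wm["wa"] + rng.normal(0, 0.05, (nw, nlat, nlon))
        beta_cube = xr.DataArray(
            beta_vals, dims=("window_center", "lat", "lon"),
            coords={"window_center": years[7 : 7 + nw], "lat": lats, "lon": lons},
        )
        return beta_cube, drivers

    def test_shares_sum_to_one_everywhere(self, rng):
        beta_cube, drivers = self._cubes(rng)
        ds = at.attribute_cube(beta_cube, drivers)
        total = sum(ds[f"r_{k}"] for k in drivers)
        assert np.allclose(total.values, 1.0, atol=1e-12)
        for k in drivers:
            assert np.all(ds[f"r_{k}"].values >= 0)

    def test_dominant_driver_identified(self, rng):
        beta_cube, drivers = self._cubes(rng)
        ds = at.attribute_cube(beta_cube, drivers)
        assert float(ds["r_vpd"].mean()) > float(ds["r_wa"].mean())
        assert float(ds["r_vpd"].mean()) > 0.4


class TestRegionalSummary:
    def _contrib(self, vpd_share, lats=(0.0, 60.0)):
        nlat, nlon = len(lats), 2
        ds = xr.Dataset(
            {
                "r_vpd": (("lat", "lon"), np.asarray(vpd_share, dtype=float)),
                "r_wa": (("lat", "lon"), 1.0 - np.asarray(vpd_share, dtype=float)),
            },
            coords={"lat": np.asarray(lats, dtype=float), "lon": [0.0, 10.0]},
        )
        ds.attrs["drivers"] = "vpd,wa"
        return ds

    def test_single_pixel_equals_pixel(self):
        ds = self._contrib([[0.7, np.nan], [np.nan, np.nan]])
        df = at.regional_contribution_summary(ds)
        assert df.set_index("driver").loc["vpd", "mean_contribution"] == pytest.approx(0.7)
        assert df.set_index("driver").loc["vpd", "n_pixels"] == 1

    def test_uniform_field_zero_spread(self):
        ds = self._contrib(np.full((2, 2), 0.6))
        df = at.regional_contribution_summary(ds)
        assert df.set_index("driver").loc["vpd", "spread"] == pytest.approx(0.0, abs=1e-12)

    def test_cos_latitude_weighted_2x2_hand_example(self):
        # shares 0.2, 0.4 at 0 degN (w=1) and 0.6, 0.8 at 60 degN (w=0.5)
        ds = self._contrib([[0.2, 0.4], [0.6, 0.8]])
        expected = (0.2 + 0.4 + 0.5 * (0.6 + 0.8)) / 3.0
        df = at.regional_contribution_summary(ds)
        assert df.set_index("driver").loc["vpd", "mean_contribution"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_pooled_nutrients_row(self, rng):
        ds = xr.Dataset(
            {f"r_{k}": (("lat", "lon"), rng.uniform(0, 0.25, (2, 2)))
             for k in ("vpd", "wa", "nit", "pho")},
            coords={"lat": [0.0, 30.0], "lon": [0.0, 10.0]},
        )
        ds.attrs["drivers"] = "vpd,wa,nit,pho"
        df = at.regional_contribution_summary(ds, pool_nutrients=True)
        idx = df.set_index("driver")
        assert idx.loc["nutrient", "mean_contribution"] == pytest.approx(
            idx.loc["nit", "mean_contribution"] + idx.loc["pho", "mean_contribution"],
            rel=1e-9,
        )

    def test_empty_region_raises(self):
        ds = self._contrib([[np.nan, np.nan], [np.nan, np.nan]])
        with pytest.raises(ValueError):
            at.regional_contribution_summary(ds)


class TestGeneratedShares:
    def test_generating_share_recovered(self):
        beta, drivers, truth = generate_attribution_windows(seed=11)
        shares = []
        for i in range(beta.shape[1]):
            for j in range(beta.shape[2]):
                res = at.attribute_pixel(
                    beta[:, i, j], {k: v[:, i, j] for k, v in drivers.items()}
                )
                shares.append(res["r_vpd"])
        assert abs(np.mean(shares) - truth["vpd"]) < 0.10

    def test_rank_agreement_across_replicates(self):
        wins = 0
        reps = 30
        for seed in range(reps):
            beta, drivers, truth = generate_attribution_windows(
                n_lat=2, n_lon=2, seed=seed, noise_sd=0.3
            )
            res = at.attribute_pixel(
                beta[:, 0, 0], {k: v[:, 0, 0] for k, v in drivers.items()}
            )
            r = {k[2:]: v for k, v in res.items() if k.startswith("r_")}
            wins += max(r, key=r.get) == max(truth, key=truth.get)
        assert wins / reps >= 0.95
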