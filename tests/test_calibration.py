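"""Assay conversion, sweeps, synthetic data and fit machinery."""

import numpy as np
import pandas as pd
import pytest

from myxospread import ConfigurationError, InputError, ModelParameters
from myxospread.calibration import (
    ExpansionDataset,
    density_sweep,
    density_to_rho_init,
    fit_parameters,
    generate_synthetic_assay,
    sweep_trajectories,
)


def fast_params(**kw):
    """Small-domain soft-agar set for quick forward simulations."""
    defaults = dict(DN=0.0, rb=1700.0 + 2200.0)
    defaults.update(kw)
    return ModelParameters(**defaults)


class TestDensityConversion:
    def test_assay_recipe_divides_by_radius(self):
        assert density_to_rho_init(1.7e6, 1700.0, "radius") == pytest.approx(1000.0)
        assert density_to_rho_init(6.0e4, 1700.0, "radius") == pytest.approx(35.294, abs=1e-2)

    def test_linearity(self):
        one = density_to_rho_init(1.0e5, 1700.0, "radius")
        assert density_to_rho_init(7.3e5, 1700.0, "radius") == pytest.approx(7.3 * one)

    def test_area_mode(self):
        assert density_to_rho_init(1.2e7, 1700.0, "area") == pytest.approx(
            1.2e7 / (np.pi * 1700.0**2)
        )

    def test_monolayer_mode_straddles_gating_threshold(self, soft_agar):
        # the assay ladder in monolayer units spans the EPS threshold
        # rho* = e0 * beta/alpha ~ 0.84
        low = density_to_rho_init(6e4, 1700.0, "monolayer")
        high = density_to_rho_init(1.2e7, 1700.0, "monolayer")
        rho_star = soft_agar.e0 * soft_agar.beta / soft_agar.alpha
        assert low < rho_star < high

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            density_to_rho_init(1e5, 1700.0, "volume")
        with pytest.raises(ValueError):
            density_to_rho_init(-1.0, 1700.0)


class TestSweeps:
    def test_equal_densities_give_identical_output(self):
        p = fast_params()
        table = density_sweep(p, [0.5, 0.5], 8.0, dx=40.0, dt=2.0)
        assert table["radius_increase_um"].iloc[0] == table["radius_increase_um"].iloc[1]

    def test_radius_increase_nondecreasing_in_density(self):
        p = fast_params()
        table = density_sweep(p, [0.05, 0.5, 2.0], 18.0, dx=40.0, dt=2.0)
        inc = table["radius_increase_um"].to_numpy()
        assert np.all(np.diff(inc) >= -1e-9)

    def test_trajectories_long_format(self):
        p = fast_params()
        traj = sweep_trajectories(p, [1.0], [2.0, 6.0], dx=40.0, dt=2.0)
        assert list(traj.columns) == ["density", "time_h", "radius_um"]
        assert len(traj) == 2
        assert traj["radius_um"].is_monotonic_increasing


class TestSyntheticAssay:
    def test_noise_free_equals_model_trajectories(self):
        p = fast_params()
        data = generate_synthetic_assay(
            p, cells_per_spot=(6e6,), sample_times_h=(4.0, 8.0), noise_sigma=0.0,
            seed=1, dx=40.0, dt=2.0,
        )
        rho = density_to_rho_init(6e6, p.r0, "monolayer")
        traj = sweep_trajectories(p, [rho], [4.0, 8.0], dx=40.0, dt=2.0)
        assert np.allclose(data.data["radius_um"].to_numpy(), traj["radius_um"].to_numpy())

    def test_reproducible_from_seed(self):
        p = fast_params()
        kwargs = dict(
            cells_per_spot=(6e5, 6e6), sample_times_h=(4.0, 8.0), noise_sigma=50.0,
            dx=40.0, dt=2.0,
        )
        d1 = generate_synthetic_assay(p, seed=42, **kwargs)
        d2 = generate_synthetic_assay(p, seed=42, **kwargs)
        d3 = generate_synthetic_assay(p, seed=43, **kwargs)
        pd.testing.assert_frame_equal(d1.data, d2.data)
        assert not np.allclose(d1.data["radius_um"], d3.data["radius_um"])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_assay(fast_params(), noise_sigma=-1.0, seed=0)


class TestDataset:
    def test_missing_columns_rejected(self):
        with pytest.raises(InputError, match="columns"):
            ExpansionDataset(pd.DataFrame({"time_h": [1.0]}))

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"initial_cells": [6e4, 6e4], "time_h": [2.0, 4.0], "radius_um": [1701.5, 1788.25]}
        )
        ds = ExpansionDataset(df)
        path = tmp_path / "assay.csv"
        ds.to_csv(path)
        back = ExpansionDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.data, df)

    def test_invalid_records_rejected(self):
        with pytest.raises(InputError):
            ExpansionDataset(
                pd.DataFrame({"initial_cells": [-1.0], "time_h": [1.0], "radius_um": [1700.0]})
            )


class TestFit:
    def test_recovers_generating_Dp_from_clean_data(self):
        true = fast_params()
        data = generate_synthetic_assay(
            true, cells_per_spot=(1.5e6, 1.2e7), sample_times_h=(8.0, 16.0, 24.0),
            noise_sigma=0.0, seed=0, dx=40.0, dt=2.0,
        )
        fit = fit_parameters(
            data, true, free=("Dp",), bounds={"Dp": (110.0, 440.0)},
            grid_points=3, dx=40.0, dt=2.0, maxiter=25,
        )
        assert fit.params["Dp"] == pytest.approx(true.Dp, rel=0.05)
        assert fit.sse < 1.0

    def test_unknown_free_parameter_rejected(self):
        data = ExpansionDataset(
            pd.DataFrame({"initial_cells": [6e4], "time_h": [2.0], "radius_um": [1700.0]})
        )
        with pytest.raises(ConfigurationError):
            fit_parameters(data, fast_params(), free=("beta",))

    def test_endpoint_data_underdetermines_Dp_alpha_tradeoff(self):
        # with a single late endpoint, a 1.5x error in Dp is absorbed
        # essentially perfectly by lowering alpha; a time course (lag +
        # steady slope) breaks the degeneracy and leaves a residual
        true = fast_params()
        mk = dict(cells_per_spot=(6e6,), noise_sigma=0.0, seed=0, dx=40.0, dt=2.0)
        endpoint = generate_synthetic_assay(true, sample_times_h=(24.0,), **mk)
        course = generate_synthetic_assay(true, sample_times_h=(6.0, 12.0, 18.0, 24.0), **mk)

        def compensate(data):
            wrong = true.evolve(Dp=1.5 * true.Dp)
            fit = fit_parameters(
                data, wrong, free=("alpha",),
                bounds={"alpha": (true.alpha / 4, true.alpha * 4)},
                grid_points=5, dx=40.0, dt=2.0, maxiter=25,
            )
            return fit.sse / len(data.data), fit.params["alpha"]

        sse_end, alpha_end = compensate(endpoint)
        sse_course, _ = compensate(course)
        assert sse_end < 1e-6                      # exact compensation
        assert abs(alpha_end / true.alpha - 1) > 0.2  # ... by a wrong alpha
        assert sse_course > 10.0                   # degeneracy broken
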