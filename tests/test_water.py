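"""Water-correction fits: reference least squares, flatness, re-addition."""

import numpy as np
import pytest

from aquaspec.core import Spectrum, SpectrumSet
from aquaspec.errors import DegenerateFitError, RangeError
from aquaspec.water import (
    FitConfig,
    correct_set,
    fit_by_flatness,
    fit_water_coefficient,
    flatness_metric,
    iterative_readdition,
)


def normal_equations_oracle(sample, matrigel, pbs, lo=1500.0, hi=1700.0):
    """Independent OLS solve (X'X)θ = X'y with an explicit linear baseline."""
    mask = sample.grid.window_mask(lo, hi)
    x = sample.grid.values[mask]
    X = np.column_stack(
        [
            matrigel.intensity[mask],
            pbs.intensity[mask],
            np.ones(mask.sum()),
            (x - x.mean()) / (x.max() - x.min()),
        ]
    )
    theta = np.linalg.solve(X.T @ X, X.T @ sample.intensity[mask])
    return theta[0], theta[1]


class TestReferenceFit:
    @pytest.mark.parametrize("beta", [0.25, 0.5, 0.8, 1.0, 1.5, 2.0])
    def test_exact_recovery_on_noiseless_mixtures(self, matrigel, water, beta):
        sample = Spectrum(
            matrigel.grid, 1.0 * matrigel.intensity + beta * water.intensity
        )
        cfg = FitConfig(saturation_cutoff=None)
        res = fit_water_coefficient(sample, matrigel, water, cfg)
        assert abs(res.coefficient - beta) / beta < 1e-9
        np.testing.assert_allclose(
            res.corrected.intensity, matrigel.intensity, atol=1e-9
        )
        alpha_o, beta_o = normal_equations_oracle(sample, matrigel, water)
        assert abs(res.coefficient - beta_o) < 1e-9
        assert abs(res.reference_weight - alpha_o) < 1e-9

    def test_zero_water_sample_gives_zero_coefficient(self, matrigel, water):
        res = fit_water_coefficient(matrigel, matrigel, water)
        assert 0.0 <= res.coefficient < 1e-12
        np.testing.assert_allclose(
            res.corrected.intensity, matrigel.intensity, atol=1e-12
        )

    def test_default_fit_window_is_1500_1700(self):
        cfg = FitConfig()
        assert (cfg.fit_lo, cfg.fit_hi) == (1500.0, 1700.0)

    def test_oracle_equivalence_on_random_instances(self, matrigel, water, rng):
        cfg = FitConfig(saturation_cutoff=None, nonneg=False)
        for _ in range(100):
            alpha = rng.uniform(0.5, 2.0)
            beta = rng.uniform(0.1, 2.0)
            sample = Spectrum(
                matrigel.grid,
                alpha * matrigel.intensity
                + beta * water.intensity
                + rng.normal(0, 0.002, len(matrigel.grid)),
            )
            res = fit_water_coefficient(sample, matrigel, water, cfg)
            alpha_o, beta_o = normal_equations_oracle(sample, matrigel, water)
            assert abs(res.coefficient - beta_o) < 1e-8
            assert abs(res.reference_weight - alpha_o) < 1e-8

    def test_noisy_recovery_unbiased(self, matrigel, water, rng):
        """At 1% of amide-peak noise, beta is recovered within ~2% RMSE."""
        beta_true = 0.8
        noise_sd = 0.01 * matrigel.intensity.max()
        estimates = []
        for _ in range(100):
            sample = Spectrum(
                matrigel.grid,
                matrigel.intensity
                + beta_true * water.intensity
                + rng.normal(0, noise_sd, len(matrigel.grid)),
            )
            estimates.append(
                fit_water_coefficient(sample, matrigel, water).coefficient
            )
        estimates = np.array(estimates)
        assert abs(estimates.mean() - beta_true) / beta_true < 0.005
        assert np.sqrt(np.mean((estimates - beta_true) ** 2)) / beta_true < 0.02

    def test_linearity_in_sample_scale(self, matrigel, water):
        sample = Spectrum(
            matrigel.grid, matrigel.intensity + 0.6 * water.intensity
        )
        cfg = FitConfig(saturation_cutoff=None)
        b1 = fit_water_coefficient(sample, matrigel, water, cfg).coefficient
        doubled = Spectrum(matrigel.grid, 2.0 * sample.intensity)
        b2 = fit_water_coefficient(doubled, matrigel, water, cfg).coefficient
        assert abs(b2 - 2.0 * b1) < 1e-9

    def test_collinear_references_rejected(self, matrigel):
        clone = Spectrum(matrigel.grid, 2.0 * matrigel.intensity)
        sample = Spectrum(matrigel.grid, 3.0 * matrigel.intensity)
        with pytest.raises(DegenerateFitError):
            fit_water_coefficient(sample, matrigel, clone)

    def test_corrected_flatness_improves_on_mixture(self, matrigel, water):
        sample = Spectrum(
            matrigel.grid, matrigel.intensity + 1.0 * water.intensity
        )
        res = fit_water_coefficient(sample, matrigel, water)
        assert res.flatness_1800_2500 <= flatness_metric(sample)


class TestCorrectSet:
    def test_per_cell_coefficients_recovered_in_order(self, grid, matrigel, water):
        spectra, pairing = [], {}
        betas = [0.5, 1.0, 1.5]
        for i, b in enumerate(betas):
            cid, pid = f"c{i}", f"p{i}"
            spectra.append(
                Spectrum(
                    grid,
                    matrigel.intensity + b * water.intensity,
                    {"id": cid, "role": "cell", "pbs_id": pid},
                )
            )
            spectra.append(Spectrum(grid, water.intensity.copy(), {"id": pid, "role": "pbs"}))
            pairing[cid] = pid
        corrected, report = correct_set(
            SpectrumSet(spectra, pairing), matrigel, FitConfig(saturation_cutoff=None)
        )
        np.testing.assert_allclose(report["coefficient"].to_numpy(), betas, rtol=1e-8)

    def test_empty_set_gives_empty_output(self, matrigel):
        corrected, report = correct_set(SpectrumSet([]), matrigel)
        assert len(corrected) == 0 and len(report) == 0

    def test_unpaired_cell_flagged_not_dropped(self, grid, matrigel, water):
        paired = Spectrum(
            grid,
            matrigel.intensity + water.intensity,
            {"id": "c0", "role": "cell", "pbs_id": "p0"},
        )
        pbs = Spectrum(grid, water.intensity.copy(), {"id": "p0", "role": "pbs"})
        orphan = Spectrum(
            grid, matrigel.intensity + water.intensity, {"id": "c1", "role": "cell"}
        )
        corrected, report = correct_set(
            SpectrumSet([paired, pbs, orphan], {"c0": "p0"}), matrigel
        )
        assert len(corrected) == 2
        row = report.set_index("cell_id").loc["c1"]
        assert row["flags"] == "unpaired"
        assert np.isnan(row["coefficient"])


class TestFlatnessMethod:
    def test_recovers_scale_when_cell_is_linear_in_silent_region(self, grid, water):
        cell_component = 0.0001 * grid.values + 0.05  # exactly linear
        sample = Spectrum(grid, cell_component + 0.9 * water.intensity)
        res = fit_by_flatness(sample, water)
        assert abs(res.coefficient - 0.9) < 1e-4
        # dense grid-search oracle at step 1e-5 around the optimum
        betas = np.arange(0.88, 0.92, 1e-5)
        vals = [
            flatness_metric(sample.with_intensity(sample.intensity - b * water.intensity))
            for b in betas
        ]
        assert abs(res.coefficient - betas[int(np.argmin(vals))]) < 1e-4

    def test_zero_water_reference_is_degenerate(self, grid):
        sample = Spectrum(grid, np.full(len(grid), 0.1))
        zero = Spectrum(grid, np.zeros(len(grid)))
        res = fit_by_flatness(sample, zero, search_lo=0.0, search_hi=3.0)
        assert res.coefficient == 0.0
        assert "degenerate_zero_water" in res.flags

    def test_minimizer_beats_bracket_endpoints(self, grid, water, rng):
        sample = Spectrum(
            grid, 0.05 + 1.2 * water.intensity + rng.normal(0, 0.001, len(grid))
        )
        res = fit_by_flatness(sample, water)

        def metric(b):
            return flatness_metric(
                sample.with_intensity(sample.intensity - b * water.intensity)
            )

        assert res.flatness_1800_2500 <= metric(0.0)
        assert res.flatness_1800_2500 <= metric(3.0)


class TestIterativeReaddition:
    def test_balanced_spectrum_needs_no_readdition(self, grid, water):
        flat = Spectrum(grid, np.full(len(grid), 0.2))
        res = iterative_readdition(flat, water)
        assert res.coefficient == 0.0

    def test_recovers_known_oversubtraction(self, grid, cell, water):
        delta = 0.15
        over = Spectrum(grid, cell.intensity - delta * water.intensity)
        res = iterative_readdition(over, water)
        # dense-scan oracle over gamma
        m_lo = grid.window_mask(2750.0, 2800.0)
        m_hi = grid.window_mask(3000.0, 3050.0)

        def objective(g):
            adj = over.intensity + g * water.intensity
            return abs(adj[m_lo].mean() - adj[m_hi].mean())

        gammas = np.arange(0.0, 0.5, 1e-5)
        oracle = gammas[int(np.argmin([objective(g) for g in gammas]))]
        assert abs(res.coefficient - oracle) < 1e-3
        assert res.coefficient >= 0.0

    def test_flank_windows_straddle_2900(self):
        from aquaspec.water import READD_FLANKS

        (lo1, hi1), (lo2, hi2) = READD_FLANKS
        assert hi1 < 2900.0 < lo2

    def test_short_grid_rejected(self, water):
        from aquaspec.core import WavenumberGrid

        g = WavenumberGrid(np.arange(1000.0, 2000.0, 2.0))
        short = Spectrum(g, np.zeros(len(g)))
        with pytest.raises(RangeError):
            iterative_readdition(short, short)
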