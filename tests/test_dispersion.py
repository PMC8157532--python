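"""Tests for the dispersion forward models, Rex estimation and global fits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dyndesign import dispersion as DSP
from dyndesign.constants import ppm_to_rad_s
from dyndesign.errors import ValidationError
from dyndesign.synthetic import (DispersionSimSpec, canonical_dispersion_spec,
                                 simulate_dispersion)

GRID_PB = (0.005, 0.02, 0.1)
GRID_KEX = (500.0, 2200.0, 10_000.0)
GRID_DW = (100.0, 500.0, 1500.0)
NU_GRID = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1000.0])


class TestCPMGForward:
    def test_no_exchange_flat(self):
        for method in ("carver_richards", "numerical"):
            out = DSP.r2eff_two_state_cpmg(0.02, 2200.0, 0.0, 12.5, NU_GRID,
                                           method=method)
            assert np.allclose(out, 12.5, atol=1e-9)

    @pytest.mark.parametrize("pB", GRID_PB)
    @pytest.mark.parametrize("kex", GRID_KEX)
    @pytest.mark.parametrize("dw", GRID_DW)
    def test_carver_richards_matches_bloch_mcconnell(self, pB, kex, dw):
        """Closed form within 0.05 s^-1 of the numerical propagator."""
        cr = DSP.r2eff_two_state_cpmg(pB, kex, dw, 10.0, NU_GRID)
        num = DSP.r2eff_two_state_cpmg(pB, kex, dw, 10.0, NU_GRID,
                                       method="numerical")
        assert np.max(np.abs(cr - num)) < 0.05

    @pytest.mark.parametrize("pB", GRID_PB)
    @pytest.mark.parametrize("kex", GRID_KEX)
    @pytest.mark.parametrize("dw", GRID_DW)
    def test_r2eff_non_increasing_in_nu(self, pB, kex, dw):
        out = DSP.r2eff_two_state_cpmg(pB, kex, dw, 10.0, NU_GRID)
        assert np.all(np.diff(out) <= 1e-9)

    def test_invalid_nu_rejected(self):
        with pytest.raises(ValidationError, match="nu_cpmg"):
            DSP.r2eff_two_state_cpmg(0.02, 2200.0, 500.0, 10.0, -25.0)


class TestR1rhoForward:
    def test_no_exchange_on_resonance_gives_r20(self):
        for method in ("analytic", "numerical"):
            out = DSP.r1rho_two_state(0.02, 2200.0, 0.0, 14.0, 1.2,
                                      2000.0, 0.0, method=method)
            assert out == pytest.approx(14.0, abs=0.02)

    @pytest.mark.parametrize("kex", (2200.0, 10_000.0))
    @pytest.mark.parametrize("dw", GRID_DW)
    def test_analytic_matches_six_state_propagator(self, kex, dw):
        """Laguerre approximation within 5% of the 6x6 propagator for
        kex >= dw (fast/intermediate exchange)."""
        if kex < dw:
            pytest.skip("outside the fast/intermediate regime")
        for pB in GRID_PB:
            for w1 in (500.0, 1000.0, 2000.0, 4000.0):
                for off in (0.0, 200.0):
                    a = DSP.r1rho_two_state(pB, kex, dw, 10.0, 1.2, w1, off)
                    n = DSP.r1rho_two_state(pB, kex, dw, 10.0, 1.2, w1, off,
                                            method="numerical")
                    assert a == pytest.approx(n, rel=0.05)

    def test_exchange_quenched_by_spin_lock(self):
        rates = [DSP.r1rho_two_state(0.02, 2200.0, 800.0, 10.0, 1.2, w1, 0.0)
                 for w1 in (500.0, 1000.0, 2000.0, 4000.0)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < rates[0] - 0.5

    def test_invalid_omega1_rejected(self):
        with pytest.raises(ValidationError, match="omega1"):
            DSP.r1rho_two_state(0.02, 2200.0, 500.0, 10.0, 1.2, 0.0, 0.0)


def _noiseless(variant="WT"):
    spec = canonical_dispersion_spec(variant, noise_sd=0.0)
    with pytest.warns(UserWarning):
        return spec, simulate_dispersion(spec, seed=0)


class TestRexEstimate:
    def test_flat_curves_give_zero(self):
        spec, data = _noiseless()
        flat = dataclasses.replace(spec, dw_ppm={r: 0.0 for r in spec.dw_ppm})
        with pytest.warns(UserWarning):
            data = simulate_dispersion(flat, seed=0)
        rex = DSP.rex_estimate(data)
        assert np.allclose(rex.to_numpy(), 0.0, atol=1e-8)

    def test_noiseless_matches_forward_difference(self):
        spec, data = _noiseless()
        rex = DSP.rex_estimate(data)
        for r in spec.dw_ppm:
            diffs = []
            for f in spec.fields_mhz:
                dw = float(ppm_to_rad_s(spec.dw_ppm[r], f))
                lo = DSP.r2eff_two_state_cpmg(spec.pB, spec.kex, dw,
                                              spec.r20[(r, f)],
                                              min(spec.nu_cpmg_grid),
                                              method="numerical")
                hi = DSP.r2eff_two_state_cpmg(spec.pB, spec.kex, dw,
                                              spec.r20[(r, f)],
                                              max(spec.nu_cpmg_grid),
                                              method="numerical")
                diffs.append(lo - hi)
            assert rex[r] == pytest.approx(np.mean(diffs), abs=1e-10)

    def test_identical_fields_average_equals_either(self):
        nu = [25.0, 100.0, 400.0, 1000.0]
        rows = []
        for f in (600.0, 800.0):
            for v in nu:  # same parameters in rad/s at both fields
                rate = DSP.r2eff_two_state_cpmg(0.02, 2200.0, 600.0, 10.0, v)
                rows.append((1, f, "cpmg", v, np.nan, np.nan, rate, 0.3))
        data = DSP.DispersionDataset(points=pd.DataFrame(
            rows, columns=DSP.DispersionDataset.COLUMNS))
        rex = DSP.rex_estimate(data)
        one_field = (DSP.r2eff_two_state_cpmg(0.02, 2200.0, 600.0, 10.0, 25.0)
                     - DSP.r2eff_two_state_cpmg(0.02, 2200.0, 600.0, 10.0,
                                                1000.0))
        assert rex[1] == pytest.approx(one_field, abs=1e-12)


class TestGlobalFit:
    def test_noiseless_exact_recovery(self):
        """Inverse crime: noiseless data generated by the fit's own forward
        models (Carver-Richards + Laguerre) is recovered exactly."""
        spec, data = _noiseless("WT")
        pts = data.points
        rates = []
        for row in pts.itertuples(index=False):
            dw = float(ppm_to_rad_s(spec.dw_ppm[row.residue], row.field_mhz))
            r20 = spec.r20[(row.residue, row.field_mhz)]
            if row.experiment == "cpmg":
                rates.append(DSP.r2eff_two_state_cpmg(
                    spec.pB, spec.kex, dw, r20, row.nu_cpmg_hz))
            else:
                rates.append(DSP.r1rho_two_state(
                    spec.pB, spec.kex, dw, r20, 1.2, row.omega1_hz,
                    row.offset_hz, method="analytic"))
        pts = pts.assign(rate_s=rates)
        data = DSP.DispersionDataset(points=pts, metadata=data.metadata)
        fit = DSP.global_fit_two_state(data, seed=0)
        assert fit.redchi < 1e-6
        assert fit.kex == pytest.approx(spec.kex, rel=1e-3)
        assert fit.pB == pytest.approx(spec.pB, rel=1e-3)
        for r, dw in spec.dw_ppm.items():
            assert fit.dw_ppm[r] == pytest.approx(dw, rel=1e-2)

    def test_forward_model_invariance(self):
        """Data generated by the numerical model, fitted with the analytic
        model (the fit path), recovers parameters within 2%."""
        spec, data = _noiseless("D66A")
        fit = DSP.global_fit_two_state(data, seed=0)
        assert fit.kex == pytest.approx(spec.kex, rel=0.02)
        assert fit.pB == pytest.approx(spec.pB, rel=0.02)

    def test_fit_determinism(self):
        data = simulate_dispersion(canonical_dispersion_spec("WT"), seed=3)
        a = DSP.global_fit_two_state(data, seed=1)
        b = DSP.global_fit_two_state(data, seed=1)
        assert (a.kex, a.pB, a.chi2) == (b.kex, b.pB, b.chi2)

    def test_degeneracy_reported_as_wide_intervals(self):
        """In the fast-exchange limit only pB*dw^2 is constrained, so the
        bootstrap pB interval must be much wider than in the well-conditioned
        two-field CPMG+R1rho case."""
        well_spec = canonical_dispersion_spec("WT", noise_sd=0.3)
        well = simulate_dispersion(well_spec, seed=5)
        fit_well = DSP.global_fit_two_state(well, seed=5, n_boot=20)

        from dyndesign.constants import rad_s_to_ppm
        residues = {1: float(rad_s_to_ppm(400.0, 600.0)),
                    2: float(rad_s_to_ppm(700.0, 600.0)),
                    3: float(rad_s_to_ppm(1000.0, 600.0))}
        deg_spec = DispersionSimSpec(
            pB=0.02, kex=30_000.0, dw_ppm=residues,
            r20={(r, 600.0): 11.0 for r in residues}, fields_mhz=[600.0],
            nu_cpmg_grid=[25, 50, 100, 200, 300, 400, 600, 800, 1000],
            spinlock_grid=[(2000.0, 0.0), (3000.0, 0.0), (4000.0, 0.0),
                           (5000.0, 0.0)],
            noise_sd=0.3)
        deg = simulate_dispersion(deg_spec, seed=5)
        fit_deg = DSP.global_fit_two_state(deg, seed=5, n_boot=20)

        def rel_width(fit):
            level, lo, hi = fit.ci["pB"]
            return (hi - lo) / fit.pB

        assert rel_width(fit_deg) > 5.0 * rel_width(fit_well)

    def test_minor_state_convention_enforced(self):
        data = simulate_dispersion(canonical_dispersion_spec("WT"), seed=9)
        fit = DSP.global_fit_two_state(data, seed=9)
        assert 0.0 < fit.pB < 0.5
        fit.validate()


class TestModelCompare:
    def _small_dataset(self, dw_rad, seed, noise=0.3):
        from dyndesign.constants import rad_s_to_ppm
        spec = DispersionSimSpec(
            pB=0.02, kex=2200.0,
            dw_ppm={r: float(rad_s_to_ppm(dw_rad, 600.0)) for r in (1, 2)},
            r20={(r, 600.0): 11.0 for r in (1, 2)}, fields_mhz=[600.0],
            nu_cpmg_grid=[25, 50, 75, 100, 150, 200, 300, 400, 500, 700,
                          1000],
            spinlock_grid=[(1000.0, 0.0), (2000.0, 0.0), (3000.0, 0.0),
                           (4000.0, 0.0)],
            noise_sd=noise)
        return simulate_dispersion(spec, seed=seed)

    def test_null_data_prefers_flat_model(self):
        data = self._small_dataset(0.0, seed=11)
        fit2 = DSP.global_fit_two_state(data, seed=11)
        flat = DSP.fit_flat(data)
        out = DSP.model_compare(data, flat, fit2)
        assert out["preferred"] == "1-state"

    def test_planted_exchange_detected(self):
        """Two-state exchange with dw = 600 rad/s is detected (F-test
        p < 0.01) in at least 19 of 20 seeded regenerations."""
        wins = 0
        for seed in range(20):
            data = self._small_dataset(600.0, seed=100 + seed)
            fit2 = DSP.global_fit_two_state(data, seed=seed)
            flat = DSP.fit_flat(data)
            out = DSP.model_compare(data, flat, fit2)
            wins += out["preferred"] == "2-state"
        assert wins >= 19

    def test_chi2_nesting(self):
        data = self._small_dataset(600.0, seed=31)
        fit2 = DSP.global_fit_two_state(data, seed=31)
        flat = DSP.fit_flat(data)
        out = DSP.model_compare(data, flat, fit2)
        assert min(flat.chi2, fit2.chi2) <= flat.chi2
        assert out["aic_2state"] < out["aic_1state"]

    def test_mismatched_data_rejected(self):
        data = self._small_dataset(600.0, seed=41)
        fit2 = DSP.global_fit_two_state(data, seed=41)
        flat = DSP.fit_flat(data)
        flat = dataclasses.replace(flat, n_points=flat.n_points - 1)
        with pytest.raises(ValidationError, match="same data"):
            DSP.model_compare(data, flat, fit2)


class TestDatasetValidation:
    def test_nonpositive_errors_rejected(self):
        spec, data = _noiseless()
        data.points.loc[0, "error_s"] = 0.0
        with pytest.raises(ValidationError, match="error"):
            data.validate()

    def test_degenerate_grid_rejected(self):
        rows = [(1, 600.0, "cpmg", v, np.nan, np.nan, 10.0, 0.3)
                for v in (25.0, 50.0)]
        data = DSP.DispersionDataset(points=pd.DataFrame(
            rows, columns=DSP.DispersionDataset.COLUMNS))
        with pytest.raises(ValidationError, match="4 points"):
            data.validate()
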