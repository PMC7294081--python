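"""Global two-field fast-exchange dispersion fitting."""

import numpy as np
import pytest

from fluornmr.datasets import StudyFixture, generate_dispersion_dataset
from fluornmr.dispersion import (
    FastExchangeDispersionModel,
    fit_dispersion_global,
    profile_uncertainty,
    read_dispersion_csv,
    write_dispersion_csv,
)
from fluornmr.exchange import (
    CpmgSchedule,
    DispersionCurve,
    ExchangeSystem,
    FastExchangeFitParams,
    bloch_mcconnell_r2eff,
)

F_LOW, F_HIGH = 564.686, 658.780


class TestNoiselessRoundTrips:
    def test_recovers_generating_parameters(self, study, exchange_fixture):
        """Each reported parameter set is recovered to 4 significant digits
        from noiseless two-field curves."""
        key, truth = exchange_fixture
        curves = generate_dispersion_dataset(study, key[0], key[1], noise_frac=0.0)
        res = fit_dispersion_global(curves)
        assert res.converged
        assert res.identifiability_flags == ()
        assert res.params.kex == pytest.approx(truth.kex, rel=5e-4)
        for f in (F_LOW, F_HIGH):
            assert res.params.r20_at(f) == pytest.approx(truth.r20_at(f), rel=5e-4)
        assert res.params.phi_ex_ref == pytest.approx(truth.phi_ex_ref, rel=5e-4)

    def test_reparameterization_invariance(self, study):
        """Referencing Phi_ex at the high field instead of the low field
        leaves kex, R2_0 and chi^2 unchanged."""
        curves = generate_dispersion_dataset(study, "prethrombin-2", "Trp51",
                                             noise_frac=0.01, seed=3)
        lo = fit_dispersion_global(curves, ref_field_mhz=F_LOW)
        hi = fit_dispersion_global(curves, ref_field_mhz=F_HIGH)
        assert hi.params.kex == pytest.approx(lo.params.kex, rel=1e-8)
        assert hi.chi2 == pytest.approx(lo.chi2, rel=1e-8)
        for f in (F_LOW, F_HIGH):
            assert hi.params.r20_at(f) == pytest.approx(lo.params.r20_at(f), rel=1e-8)
        # and the two Phi_ex references describe the same amplitude
        assert hi.params.phi_ex_at(F_LOW) == pytest.approx(
            lo.params.phi_ex_ref, rel=1e-8
        )

    def test_flat_data_flagged_no_dispersion(self, study):
        flat = FastExchangeFitParams(
            kex=3000.0, phi_ex_ref=0.0,
            r20_by_field={F_LOW: 204.0, F_HIGH: 260.0}, ref_field_mhz=F_LOW,
        )
        fx = StudyFixture(exchange_sets={("x", "TrpX"): flat})
        curves = generate_dispersion_dataset(fx, "x", "TrpX", noise_frac=0.0)
        res = fit_dispersion_global(curves)
        assert "no dispersion" in res.identifiability_flags
        assert not np.isfinite(res.stderr["kex"])
        for c in curves:
            assert res.params.r20_at(c.field_mhz) == pytest.approx(
                float(np.mean(c.r2eff)), rel=1e-6
            )


class TestNoisyFits:
    def test_oracle_generated_median_recovery(self):
        """Numerically simulated (Bloch–McConnell) two-field data with
        kex/delta-omega = 20 and 1% noise: median fitted kex over 20 seeds
        within 5% of truth."""
        pa, dppm = 0.7, 0.15
        kex = 20.0 * 2 * np.pi * F_LOW * dppm
        grid = np.geomspace(25.0, 5000.0, 12)
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            curves = []
            for f in (F_LOW, F_HIGH):
                sys = ExchangeSystem(pa=pa, kex=kex, delta_omega_ppm=dppm,
                                     r2a0=20.0, r2b0=20.0, field_mhz=f)
                clean = bloch_mcconnell_r2eff(sys, CpmgSchedule(grid))
                sigma = 0.01 * clean.r2eff
                curves.append(DispersionCurve(
                    f, clean.nu_cpmg, clean.r2eff + rng.normal(0.0, sigma),
                    sigma=sigma, label="sim",
                ))
            ests.append(fit_dispersion_global(curves).params.kex)
        assert abs(np.median(ests) - kex) / kex < 0.05

    def test_stderr_coverage_all_fixtures(self, study, exchange_fixture):
        """1% noise, 20 seeds: truth inside +/-3 stderr in >= 18 runs."""
        key, truth = exchange_fixture
        hits = 0
        for seed in range(20):
            curves = generate_dispersion_dataset(study, key[0], key[1],
                                                 noise_frac=0.01, seed=seed)
            res = fit_dispersion_global(curves)
            hits += abs(res.params.kex - truth.kex) <= 3.0 * res.stderr["kex"]
        assert hits >= 18

    def test_subsampling_never_shrinks_kex_stderr(self, study):
        curves = generate_dispersion_dataset(study, "prethrombin-2", "Trp51",
                                             noise_frac=0.01, seed=0)
        full = fit_dispersion_global(curves).stderr["kex"]
        thinned = [
            DispersionCurve(c.field_mhz, c.nu_cpmg[::2], c.r2eff[::2],
                            sigma=c.sigma[::2], label=c.label)
            for c in curves
        ]
        sub = fit_dispersion_global(thinned).stderr["kex"]
        assert sub >= full


class TestValidation:
    def test_too_few_points_rejected(self):
        c = DispersionCurve(F_LOW, np.array([50.0, 100.0, 200.0]),
                            np.array([210.0, 205.0, 204.0]))
        with pytest.raises(ValueError):
            fit_dispersion_global([c])

    def test_mixed_labels_rejected(self, study):
        a = generate_dispersion_dataset(study, "prethrombin-2", "Trp51", noise_frac=0.0)
        b = generate_dispersion_dataset(study, "thrombin", "Trp215", noise_frac=0.0)
        with pytest.raises(ValueError):
            fit_dispersion_global([a[0], b[1]])

    def test_estimator_is_sklearn_compatible(self, study):
        from sklearn.base import clone

        curves = generate_dispersion_dataset(study, "thrombin", "Trp215", noise_frac=0.0)
        X = np.column_stack([
            np.concatenate([np.full_like(c.nu_cpmg, c.field_mhz) for c in curves]),
            np.concatenate([c.nu_cpmg for c in curves]),
        ])
        y = np.concatenate([c.r2eff for c in curves])
        m = FastExchangeDispersionModel()
        assert clone(m).get_params() == m.get_params()
        m.fit(X, y)
        assert np.allclose(m.predict(X), y, rtol=1e-6)
        assert m.kex_ == pytest.approx(7980.0, rel=5e-4)

    def test_curve_csv_round_trip(self, tmp_path, study):
        curves = generate_dispersion_dataset(study, "thrombin", "Trp51",
                                             noise_frac=0.01, seed=4)
        path = tmp_path / "curves.csv"
        write_dispersion_csv(curves, path)
        back = read_dispersion_csv(path, label="Trp51")
        assert len(back) == 2
        for orig, rt in zip(sorted(curves, key=lambda c: c.field_mhz), back):
            assert rt.field_mhz == orig.field_mhz
            assert np.allclose(rt.nu_cpmg, orig.nu_cpmg)
            assert np.allclose(rt.r2eff, orig.r2eff)
            assert np.allclose(rt.sigma, orig.sigma)


class TestProfiles:
    def test_profile_interval_matches_covariance_stderr(self, study):
        """In a quadratic basin the delta-chi2 = 1 interval and the
        covariance standard error agree within 10%."""
        curves = generate_dispersion_dataset(study, "prethrombin-2", "Trp51",
                                             noise_frac=0.01, seed=0)
        res = fit_dispersion_global(curves)
        prof = profile_uncertainty(res, curves, "kex")
        assert prof.flags == ()
        half = 0.5 * (prof.ci_high - prof.ci_low)
        assert half == pytest.approx(res.stderr["kex"], rel=0.10)

    def test_interval_brackets_optimum(self, study):
        curves = generate_dispersion_dataset(study, "thrombin", "Trp215",
                                             noise_frac=0.01, seed=1)
        res = fit_dispersion_global(curves)
        prof = profile_uncertainty(res, curves, "kex")
        assert prof.ci_low <= prof.optimum <= prof.ci_high

    def test_flat_curves_profile_unbounded(self, study):
        flat = FastExchangeFitParams(
            kex=3000.0, phi_ex_ref=0.0,
            r20_by_field={F_LOW: 204.0, F_HIGH: 260.0}, ref_field_mhz=F_LOW,
        )
        fx = StudyFixture(exchange_sets={("x", "TrpX"): flat})
        curves = generate_dispersion_dataset(fx, "x", "TrpX", noise_frac=0.0)
        res = fit_dispersion_global(curves)
        prof = profile_uncertainty(res, curves, "kex")
        assert "unbounded" in prof.flags
        assert not np.isfinite(prof.ci_low) or not np.isfinite(prof.ci_high)

    def test_refuses_nonconverged_input(self, study):
        curves = generate_dispersion_dataset(study, "thrombin", "Trp51", noise_frac=0.0)
        res = fit_dispersion_global(curves)
        res.converged = False
        with pytest.raises(ValueError):
            profile_uncertainty(res, curves, "kex")
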