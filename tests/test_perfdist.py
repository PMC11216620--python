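import numpy as np
import pytest
from scipy.special import erf

import placentadce as p
from placentadce import perfdist
from placentadce.errors import InvalidInputError, InvalidParameterError


class TestLogPDFEstimate:
    def test_point_mass_at_ten(self):
        centers, density, n_ex = p.log_pdf_estimate(np.full(100, 10.0), n_bins=5)
        assert n_ex == 0
        occupied = density > 0
        assert occupied.sum() == 1
        assert centers[occupied][0] == pytest.approx(1.0, abs=0.5)

    def test_density_integrates_to_one(self, rng):
        values = rng.lognormal(3.0, 0.5, size=2000)
        centers, density, _ = p.log_pdf_estimate(values)
        width = centers[1] - centers[0]
        assert np.sum(density) * width == pytest.approx(1.0, abs=1e-6)

    def test_zeros_excluded_and_counted(self, rng):
        values = np.r_[np.zeros(10), rng.lognormal(3.0, 0.5, size=90)]
        _c, _d, n_ex = p.log_pdf_estimate(values)
        assert n_ex == 10

    def test_all_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            p.log_pdf_estimate(np.zeros(5))

    def test_lognormal_sample_matches_normal_density(self, rng):
        """log10 of a lognormal sample is normal; the histogram should track
        the closed-form normal PDF within binning error."""
        mu, sigma = 1.6, 0.12
        values = 10.0 ** rng.normal(mu, sigma, size=60000)
        centers, density, _ = p.log_pdf_estimate(values, n_bins=40)
        analytic = np.exp(-0.5 * ((centers - mu) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        assert np.max(np.abs(density - analytic)) < 0.12 * analytic.max()


class TestFitGMM:
    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidInputError):
            p.fit_gmm_em(np.arange(5.0))

    def test_responsibilities_are_probabilities(self, rng):
        x = np.r_[rng.normal(0, 1, 200), rng.normal(4, 1, 200)]
        params = p.fit_gmm_em(x)
        g = params.responsibilities
        assert np.all((g >= 0) & (g <= 1))

    def test_log_likelihood_trace_non_decreasing(self, rng):
        x = np.r_[rng.normal(1.6, 0.1, 500), rng.normal(1.72, 0.06, 500)]
        params = p.fit_gmm_em(x)
        assert np.all(np.diff(params.ll_trace) >= -1e-9)

    def test_recovers_study_scale_mixture(self):
        """5000 draws from the late-gestation log-perfusion mixture
        (component means 1.60 / 1.72) are recovered to +-0.02 in the means
        and +-0.05 in the weight."""
        rng = np.random.default_rng(42)
        n, pi = 5000, 0.49
        z = rng.random(n) < pi
        x = np.where(z, rng.normal(1.72, 0.06, n), rng.normal(1.60, 0.10, n))
        params = p.fit_gmm_em(x)
        assert params.converged
        assert params.mu1 == pytest.approx(1.60, abs=0.02)
        assert params.mu2 == pytest.approx(1.72, abs=0.02)
        assert params.pi == pytest.approx(pi, abs=0.05)

    def test_matches_independent_restart_reference(self, rng):
        """On a 50-point toy sample, our deterministic-init EM reaches the
        same best log-likelihood as an independently coded EM run from 20
        random restarts (within 1e-6)."""
        x = np.r_[rng.normal(0.0, 0.5, 25), rng.normal(2.5, 0.4, 25)]

        def ref_em(x, pi, mu1, s1, mu2, s2, iters=2000):
            for _ in range(iters):
                phi1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
                phi2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
                g = pi * phi2 / ((1 - pi) * phi1 + pi * phi2)
                mu1 = ((1 - g) * x).sum() / (1 - g).sum()
                mu2 = (g * x).sum() / g.sum()
                s1 = max(np.sqrt(((1 - g) * (x - mu1) ** 2).sum() / (1 - g).sum()), 1e-3)
                s2 = max(np.sqrt((g * (x - mu2) ** 2).sum() / g.sum()), 1e-3)
                pi = g.mean()
            phi1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
            phi2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
            return np.log((1 - pi) * phi1 + pi * phi2).sum()

        restart_rng = np.random.default_rng(99)
        best_ref = -np.inf
        for _ in range(20):
            mus = restart_rng.choice(x, 2, replace=False)
            ll = ref_em(x, restart_rng.uniform(0.3, 0.7), mus.min(), x.std(), mus.max(), x.std())
            best_ref = max(best_ref, ll)
        ours = p.fit_gmm_em(x, tol=1e-14, max_iter=5000)
        assert ours.log_likelihood == pytest.approx(best_ref, abs=1e-6)


class TestPDFBiomarkers:
    def test_closed_forms_single_component(self):
        params = perfdist.GMMParams(
            pi=1e-9, mu1=1.0, sigma1=0.1, mu2=5.0, sigma2=0.1,
            log_likelihood=0.0, n_iter=1, converged=True,
        )
        bio = p.pdf_biomarkers(params)
        assert bio.peak_low == pytest.approx(1.0 / (0.1 * np.sqrt(2 * np.pi)), rel=1e-9)
        assert bio.fwhm_low == pytest.approx(0.2354820045, rel=1e-8)

    def test_aucs_sum_to_one(self, rng):
        x = np.r_[rng.normal(1.55, 0.08, 2000), rng.normal(1.75, 0.05, 1500)]
        bio = p.pdf_biomarkers(p.fit_gmm_em(x))
        assert bio.auc_low + bio.auc_high == pytest.approx(1.0, abs=1e-4)

    def test_trapezoid_auc_matches_error_function(self):
        params = perfdist.GMMParams(
            pi=0.31, mu1=1.54, sigma1=0.04, mu2=1.55, sigma2=0.01,
            log_likelihood=0.0, n_iter=1, converged=True,
        )
        bio = p.pdf_biomarkers(params)
        # closed-form mass of each weighted Gaussian over the same grid span
        grid_lo = min(params.mu1 - 6 * params.sigma1, params.mu2 - 6 * params.sigma2)
        grid_hi = max(params.mu1 + 6 * params.sigma1, params.mu2 + 6 * params.sigma2)

        def mass(w, mu, s):
            z = lambda v: (v - mu) / (s * np.sqrt(2))
            return w * 0.5 * (erf(z(grid_hi)) - erf(z(grid_lo)))

        assert bio.auc_low == pytest.approx(mass(0.69, 1.54, 0.04), abs=1e-4)
        assert bio.auc_high == pytest.approx(mass(0.31, 1.55, 0.01), abs=1e-4)

    def test_non_converged_fit_warns(self):
        params = perfdist.GMMParams(
            pi=0.5, mu1=0.0, sigma1=1.0, mu2=1.0, sigma2=1.0,
            log_likelihood=0.0, n_iter=1, converged=False,
        )
        with pytest.warns(UserWarning):
            bio = p.pdf_biomarkers(params)
        assert not bio.from_converged_fit


class TestApparentBloodVolume:
    def test_uniform_values(self):
        abv, _ = p.apparent_blood_volume(np.full(200, 40.0), voxel_volume_ml=0.02)
        assert abv == pytest.approx(200 * 0.02 * 40.0 / 100.0)

    def test_linearity_in_perfusion_and_size(self, rng):
        vals = rng.lognormal(3.5, 0.3, 300)
        abv, _ = p.apparent_blood_volume(vals, 0.01)
        abv2, _ = p.apparent_blood_volume(2 * vals, 0.01)
        abv3, _ = p.apparent_blood_volume(np.r_[vals, vals], 0.01)
        assert abv2 == pytest.approx(2 * abv)
        assert abv3 == pytest.approx(2 * abv)

    def test_nonpositive_voxel_volume_rejected(self):
        with pytest.raises(InvalidParameterError):
            p.apparent_blood_volume(np.ones(5), 0.0)

    def test_phantom_age_ordering(self):
        """Perfusion and placental size both increase with gestation, so the
        apparent blood volume must rise for every chamber."""
        abv = {}
        for age in ("E14.5", "E17.5"):
            spec = p.PhantomSpec(gestational_age=age, noise_sigma=0.0,
                                 motion=p.MotionSpec(enabled=False), seed=4)
            _s, _p1, _p2, truth = p.synthesize_dce(spec)
            vol = spec.voxel_size[0] * spec.voxel_size[1] * spec.voxel_size[2] / 1000.0
            for chamber, name in ((1, "low"), (2, "high")):
                n = (truth.chamber_map == chamber).sum()
                vals = np.full(n, truth.true_f_over_vt[name])
                abv[(age, name)], _ = p.apparent_blood_volume(vals, vol)
        assert abv[("E17.5", "low")] > abv[("E14.5", "low")]
        assert abv[("E17.5", "high")] > abv[("E14.5", "high")]
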