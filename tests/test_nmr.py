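import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from metaboqtl.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)
from metaboqtl.experiments import three_peak_fixture
from metaboqtl.nmr import (
    PeakIntensityMatrix,
    PeakModel,
    Spectrum,
    deconvolute,
    detect_peaks,
    estimate_noise_sd,
    group_peaks,
    peak_sum,
    pseudo_voigt,
    pseudo_voigt_area,
    qc_spectrum,
    quantify_cpmg,
)


class TestPseudoVoigt:
    @pytest.mark.parametrize("eta", [0.0, 0.3, 0.5, 1.0])
    def test_unit_height_at_center(self, eta):
        p = PeakModel(center=2.0, width=0.1, amplitude=3.0, eta=eta)
        assert pseudo_voigt(2.0, p) == pytest.approx(3.0)

    @pytest.mark.parametrize("eta", [0.0, 0.4, 1.0])
    def test_half_height_at_half_width(self, eta):
        """Both components share the FWHM, so x0 +- w/2 gives A/2."""
        p = PeakModel(center=1.0, width=0.2, amplitude=1.0, eta=eta)
        assert pseudo_voigt(1.1, p) == pytest.approx(0.5)
        assert pseudo_voigt(0.9, p) == pytest.approx(0.5)

    def test_gaussian_tail_closed_form(self):
        p = PeakModel(center=0.0, width=1.0, amplitude=2.0, eta=0.0)
        assert pseudo_voigt(1.0, p) == pytest.approx(2.0 * np.exp(-4 * np.log(2)))

    def test_invalid_parameters(self):
        with pytest.raises(InvalidArgumentError):
            PeakModel(center=0, width=0, amplitude=1)
        with pytest.raises(InvalidArgumentError):
            PeakModel(center=0, width=1, amplitude=-1)
        with pytest.raises(InvalidArgumentError):
            PeakModel(center=0, width=1, amplitude=1, eta=1.5)

    @pytest.mark.parametrize("eta", [0.0, 0.5, 1.0])
    def test_area_matches_quadrature(self, eta):
        p = PeakModel(center=0.0, width=0.05, amplitude=1.3, eta=eta)
        num, _ = quad(lambda x: pseudo_voigt(x, p), -np.inf, np.inf, limit=500)
        assert num == pytest.approx(pseudo_voigt_area(p), rel=1e-6)


class TestDetectPeaks:
    def test_two_resolved_peaks_found_at_centers(self):
        ppm = np.linspace(1.0, 1.4, 2000)
        peaks = [
            PeakModel(center=1.15, width=0.01, amplitude=1.0),
            PeakModel(center=1.25, width=0.01, amplitude=1.0),
        ]
        s = Spectrum(ppm, peak_sum(ppm, peaks))
        found = detect_peaks(s, min_prominence=0.1)
        assert len(found) == 2
        step = ppm[1] - ppm[0]
        for f, t in zip(found, peaks):
            assert abs(f.center - t.center) <= step

    def test_constant_spectrum_no_detections(self):
        s = Spectrum(np.linspace(0, 1, 100), np.ones(100))
        assert detect_peaks(s) == []

    def test_prominence_threshold_is_effective(self):
        ppm = np.linspace(0.0, 2.0, 4000)
        big = PeakModel(center=0.5, width=0.02, amplitude=1.0)
        small = PeakModel(center=1.5, width=0.02, amplitude=0.05)
        s = Spectrum(ppm, peak_sum(ppm, [big, small]))
        # the small peak is half the threshold -> not detected
        found = detect_peaks(s, min_prominence=0.1)
        assert len(found) == 1
        # twice the threshold -> detected
        found = detect_peaks(s, min_prominence=0.025)
        assert len(found) == 2


class TestDeconvolute:
    def test_single_peak_recovery_from_perturbed_init(self):
        truth = PeakModel(center=2.0, width=0.02, amplitude=1.5, eta=0.35)
        ppm = np.linspace(1.8, 2.2, 1200)
        s = Spectrum(ppm, peak_sum(ppm, [truth]))
        init = [PeakModel(center=2.004, width=0.024, amplitude=1.2, eta=0.5)]
        fitted, diag = deconvolute(s, init, n_restarts=3)
        f = fitted[0]
        for name in ("center", "width", "amplitude", "eta"):
            rel = abs(getattr(f, name) - getattr(truth, name)) / getattr(truth, name)
            assert rel < 1e-3, name

    def test_overlapping_three_peaks_amplitudes(self):
        s, truth, init = three_peak_fixture()
        fitted, _ = deconvolute(s, init, max_iter_per_dim=400, n_restarts=4)
        fitted = sorted(fitted, key=lambda p: p.center)
        for f, t in zip(fitted, truth):
            assert abs(f.amplitude - t.amplitude) / t.amplitude < 0.01

    def test_never_worse_than_initial(self):
        """Simplex result residual never exceeds the starting residual."""
        ppm = np.linspace(0.9, 1.1, 400)
        rng = np.random.default_rng(0)
        truth = PeakModel(center=1.0, width=0.01, amplitude=1.0, eta=0.5)
        s = Spectrum(ppm, peak_sum(ppm, [truth]) + rng.normal(0, 0.05, 400))
        init = [PeakModel(center=1.02, width=0.03, amplitude=0.4, eta=0.9)]
        _, diag = deconvolute(s, init, max_iter_per_dim=5)  # deliberately starved
        assert diag.residual_norm <= diag.initial_residual_norm + 1e-12

    def test_empty_init_rejected(self):
        s = Spectrum(np.linspace(0, 1, 50), np.zeros(50))
        with pytest.raises(InvalidArgumentError):
            deconvolute(s, [])


class TestQuantifyCpmg:
    def _basis(self):
        return [
            PeakModel(center=1.0, width=0.02, amplitude=1.0, eta=0.4),
            PeakModel(center=2.0, width=0.03, amplitude=1.0, eta=0.6),
        ]

    def test_exact_recovery_without_noise(self):
        basis = self._basis()
        ppm = np.linspace(0.5, 2.5, 3000)
        conc = np.array([0.7, 1.9])
        y = conc[0] * pseudo_voigt(ppm, basis[0]) + conc[1] * pseudo_voigt(ppm, basis[1])
        res = quantify_cpmg(Spectrum(ppm, y, kind="cpmg"), basis, baseline_degree=-1)
        assert np.allclose(res.amplitudes, conc, atol=1e-10)

    def test_nonoverlapping_coefficients_independent(self):
        """Orthogonal shapes: each coefficient is that peak's own projection."""
        basis = self._basis()
        ppm = np.linspace(0.5, 2.5, 3000)
        y1 = 0.7 * pseudo_voigt(ppm, basis[0])
        both = y1 + 1.9 * pseudo_voigt(ppm, basis[1])
        solo = quantify_cpmg(Spectrum(ppm, y1, kind="cpmg"), [basis[0]], baseline_degree=-1)
        joint = quantify_cpmg(Spectrum(ppm, both, kind="cpmg"), basis, baseline_degree=-1)
        assert joint.amplitudes[0] == pytest.approx(solo.amplitudes[0], abs=1e-6)

    def test_baseline_term_absorbs_linear_drift(self):
        basis = self._basis()
        ppm = np.linspace(0.5, 2.5, 3000)
        clean = 1.0 * pseudo_voigt(ppm, basis[0]) + 0.5 * pseudo_voigt(ppm, basis[1])
        drift = 0.2 + 0.3 * (ppm - ppm[0])
        s = Spectrum(ppm, clean + drift, kind="cpmg")
        with_base = quantify_cpmg(s, basis, baseline_degree=1)
        without = quantify_cpmg(s, basis, baseline_degree=-1)
        assert np.allclose(with_base.amplitudes, [1.0, 0.5], rtol=0.01)
        assert not np.allclose(without.amplitudes, [1.0, 0.5], rtol=0.01)

    def test_linearity_in_unconstrained_mode(self):
        basis = self._basis()
        ppm = np.linspace(0.5, 2.5, 2000)
        y = 0.9 * pseudo_voigt(ppm, basis[0]) + 0.4 * pseudo_voigt(ppm, basis[1])
        a = quantify_cpmg(Spectrum(ppm, y, kind="cpmg"), basis,
                          baseline_degree=-1, nonneg=False)
        b = quantify_cpmg(Spectrum(ppm, 3.0 * y, kind="cpmg"), basis,
                          baseline_degree=-1, nonneg=False)
        assert np.allclose(b.amplitudes, 3.0 * a.amplitudes, rtol=1e-10)

    def test_duplicate_shapes_rejected(self):
        p = PeakModel(center=1.0, width=0.02, amplitude=1.0)
        ppm = np.linspace(0.5, 1.5, 500)
        s = Spectrum(ppm, pseudo_voigt(ppm, p), kind="cpmg")
        with pytest.raises(DegenerateDesignError):
            quantify_cpmg(s, [p, p])


class TestGroupPeaks:
    def _matrix(self, values):
        v = np.asarray(values, float)
        meta = pd.DataFrame({"center": np.arange(v.shape[1]), "width": 0.01, "eta": 0.5})
        return PeakIntensityMatrix(v, meta, tuple(f"s{i}" for i in range(v.shape[0])))

    def test_shared_driver_groups_together(self):
        rng = np.random.default_rng(1)
        conc_a = rng.lognormal(0, 0.4, 30)
        conc_b = rng.lognormal(0, 0.4, 30)
        P = self._matrix(np.column_stack([conc_a, 2 * conc_a, conc_b]))
        labels = group_peaks(P, r_threshold=0.8)
        assert labels[0] == labels[1]
        assert labels[0] != labels[2]

    def test_unreachable_threshold_gives_singletons(self):
        rng = np.random.default_rng(2)
        P = self._matrix(rng.normal(size=(10, 4)))
        labels = group_peaks(P, r_threshold=1.0 + 1e-9)
        assert len(set(labels)) == 4

    def test_too_few_samples(self):
        P = self._matrix(np.ones((2, 3)))
        with pytest.raises(InsufficientDataError):
            group_peaks(P)


class TestQc:
    def test_pure_noise_fails_on_snr(self):
        rng = np.random.default_rng(3)
        s = Spectrum(np.linspace(0, 4, 2000), rng.normal(0, 1.0, 2000))
        res = qc_spectrum(s, min_snr=10)
        assert not res.passed and "snr" in res.reasons

    def test_clean_spectrum_passes(self):
        ppm = np.linspace(0, 4, 2000)
        rng = np.random.default_rng(4)
        p = PeakModel(center=2.0, width=0.05, amplitude=1.0)
        s = Spectrum(ppm, pseudo_voigt(ppm, p) + rng.normal(0, 0.01, 2000))
        assert qc_spectrum(s, min_snr=10, max_baseline_drift=0.2).passed

    def test_steep_ramp_fails_on_baseline(self):
        ppm = np.linspace(0, 4, 2000)
        rng = np.random.default_rng(5)
        p = PeakModel(center=2.0, width=0.05, amplitude=1.0)
        y = pseudo_voigt(ppm, p) + 0.5 * ppm + rng.normal(0, 0.01, 2000)
        res = qc_spectrum(Spectrum(ppm, y), min_snr=10, max_baseline_drift=0.2)
        assert not res.passed and "baseline" in res.reasons

    def test_noise_estimator_tracks_truth(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 0.3, 5000)
        assert estimate_noise_sd(y) == pytest.approx(0.3, rel=0.1)
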