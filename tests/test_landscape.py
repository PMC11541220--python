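"""Histogram, Lucy-Richardson deconvolution, Boltzmann inversion, features."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

import trapscape as ts
from trapscape.landscape import PdfEstimate, PsfKernel, FeatureExtractionError


def spike_pdf(positions, masses, n=128, bin_width=0.002441):
    p = np.zeros(n)
    for pos, m in zip(positions, masses):
        p[pos] = m
    centers = np.arange(n) * bin_width
    return PdfEstimate(centers, p, bin_width)


class TestHistogramPdf:
    def test_uniform_samples_fill_bins_evenly(self, rng):
        pdf = ts.histogram_pdf(rng.random(1_000_000))
        inner = pdf.probabilities[14:114]
        assert pdf.probabilities.size == 128
        assert pdf.pad_count == 14
        assert np.allclose(inner, 0.01, atol=5e-4)
        assert np.all(pdf.probabilities[:14] == 0)
        assert np.all(pdf.probabilities[114:] == 0)

    def test_padding_extends_grid_at_same_width(self, rng):
        pdf = ts.histogram_pdf(rng.random(1000))
        assert np.allclose(np.diff(pdf.bin_centers), pdf.bin_width)

    def test_gaussian_bins_match_cdf_differences(self, rng):
        mu, sd = 0.3, 0.02
        x = rng.normal(mu, sd, 2_000_000)
        pdf = ts.histogram_pdf(x)
        edges = pdf.bin_centers - pdf.bin_width / 2
        lo, hi = x.min(), x.max()
        expected = norm.cdf(edges + pdf.bin_width, mu, sd) - norm.cdf(edges, mu, sd)
        expected /= norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)
        inner = slice(14, 114)
        assert np.allclose(pdf.probabilities[inner], expected[inner], atol=4e-4)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="zero-width"):
            ts.histogram_pdf(np.full(100, 1.0))


class TestLucyRichardson:
    def test_delta_kernel_is_identity(self, rng):
        p = rng.random(128)
        p /= p.sum()
        pdf = PdfEstimate(np.arange(128.0), p, 1.0)
        delta = PsfKernel(sigma=1e-9, bin_width=1.0,
                          kernel=np.eye(128)[0])
        out = ts.lucy_richardson(pdf, delta, iterations=17)
        assert np.allclose(out.probabilities, p, atol=1e-12)

    def test_two_spike_recovery_after_forward_blur(self):
        true = spike_pdf([50, 85], [2 / 3, 1 / 3])
        psf = PsfKernel.gaussian(sigma=3 * true.bin_width, bin_width=true.bin_width)
        blurred = gaussian_filter1d(true.probabilities, 3.0, mode="wrap")
        pdf = PdfEstimate(true.bin_centers, blurred, true.bin_width)
        out = ts.lucy_richardson(pdf, psf, iterations=51)
        p = out.probabilities
        i = np.arange(1, 127)
        local_max = i[(p[i] > p[i - 1]) & (p[i] >= p[i + 1])]
        peaks = sorted(sorted(local_max, key=lambda k: -p[k])[:2])
        assert peaks == [50, 85]
        m1 = out.probabilities[42:59].sum()
        m2 = out.probabilities[77:94].sum()
        assert m1 / m2 == pytest.approx(2.0, rel=0.02)

    def test_output_nonnegative_unit_mass(self, rng):
        p = rng.random(128) ** 3
        p /= p.sum()
        pdf = PdfEstimate(np.arange(128.0), p, 1.0)
        psf = PsfKernel.gaussian(2.5, 1.0)
        out = ts.lucy_richardson(pdf, psf, iterations=51)
        assert np.all(out.probabilities >= 0)
        assert out.probabilities.sum() == pytest.approx(1.0)

    def test_counts_scale_damping_freezes_small_residuals(self):
        # with few counts behind the histogram, sub-threshold residuals are
        # not "corrected": the estimate stays closer to the blurred input
        true = spike_pdf([50, 85], [2 / 3, 1 / 3])
        blurred = gaussian_filter1d(true.probabilities, 5.5, mode="wrap")
        psf = PsfKernel.gaussian(5.5 * true.bin_width, true.bin_width)
        free = ts.lucy_richardson(
            PdfEstimate(true.bin_centers, blurred, true.bin_width), psf)
        damped = ts.lucy_richardson(
            PdfEstimate(true.bin_centers, blurred, true.bin_width, n_samples=100),
            psf)
        d_free = np.abs(free.probabilities - blurred).sum()
        d_damp = np.abs(damped.probabilities - blurred).sum()
        assert d_damp < d_free


class TestEnergyFromPdf:
    def test_uniform_support_constant_zero_energy(self):
        p = np.zeros(128)
        p[30:70] = 1 / 40
        scape = ts.energy_from_pdf(PdfEstimate(np.arange(128.0), p, 1.0), 310.0)
        assert np.allclose(scape.energy[30:70], 0.0)
        assert np.all(np.isinf(scape.energy[~scape.support_mask]))
        assert scape.support_mask.sum() == 40

    def test_two_bin_ratio_gives_ln2(self):
        p = np.zeros(128)
        p[10], p[11] = 2 / 3, 1 / 3
        scape = ts.energy_from_pdf(PdfEstimate(np.arange(128.0), p, 1.0), 310.0)
        assert scape.energy[10] == 0.0
        assert scape.energy[11] == pytest.approx(np.log(2))

    def test_gaussian_pdf_inverts_to_quadratic(self):
        centers = np.linspace(-0.1, 0.1, 128)
        s = 0.02
        p = np.exp(-0.5 * (centers / s) ** 2)
        p /= p.sum()
        scape = ts.energy_from_pdf(PdfEstimate(centers, p, centers[1] - centers[0]),
                                   310.0)
        m = scape.support_mask
        expect = 0.5 * (centers[m] / s) ** 2
        assert np.allclose(scape.energy[m], expect - expect.min(), atol=1e-9)

    def test_inversion_identity_round_trip(self, rng):
        # energy_from_pdf o (P -> exp(-U)/Z) is the identity up to the offset
        u = rng.random(60) * 4
        p = np.zeros(128)
        p[20:80] = np.exp(-u) / np.exp(-u).sum()
        scape = ts.energy_from_pdf(PdfEstimate(np.arange(128.0), p, 1.0), 300.0)
        got = scape.energy[20:80]
        assert np.allclose(got - got.min(), u - u.min(), atol=1e-9)


class TestExtractFeatures:
    def analytic_scape(self, **kwargs):
        spec = ts.design_three_state_spec(**kwargs)
        grid, u = ts.analytic_landscape(spec)
        return spec, ts.landscape_from_curve(grid, u, spec.temperature)

    def test_constructed_triple_well_recovered(self):
        # minima {0, 1.2, 2.0} k_BT, saddles {2.5, 3.0}: construct
        # P = exp(-U)/Z on a grid, invert, and extract
        spec = ts.design_three_state_spec(delta_g_nf=1.2, delta_g_fe=0.8,
                                          barrier_nf=2.5, barrier_fe=1.8)
        grid = np.linspace(spec.state_levels[0] - 0.1,
                           spec.state_levels[2] + 0.1, 400)
        p = ts.mixture_density(spec, grid)
        pdf = PdfEstimate(grid, p / p.sum(), grid[1] - grid[0])
        feats = ts.extract_features(ts.energy_from_pdf(pdf, 310.0))
        assert np.allclose(feats.minima_energy - feats.minima_energy[0],
                           [0.0, 1.2, 2.0], atol=0.05)
        assert np.allclose(feats.barrier_heights, [2.5, 3.0], atol=0.05)
        assert np.all(np.diff(np.sort(np.concatenate(
            [feats.minima_position, feats.saddle_position]))) > 0)

    def test_symmetric_double_well_keq_unity(self):
        centers = np.linspace(-1, 1, 200)
        u = (centers**2 - 0.5) ** 2 * 10
        feats = ts.extract_features(ts.landscape_from_curve(centers, u),
                                    expected_states=2)
        assert feats.keq(0) == pytest.approx(1.0, abs=1e-6)

    def test_keq_formula(self):
        spec, scape = self.analytic_scape(delta_g_nf=0.5, delta_g_fe=0.3)
        feats = ts.extract_features(scape)
        assert feats.keq(0) == pytest.approx(np.exp(-0.5), abs=0.01)

    def test_too_few_minima_raises(self):
        centers = np.linspace(-1, 1, 100)
        with pytest.raises(FeatureExtractionError, match="minima"):
            ts.extract_features(ts.landscape_from_curve(centers, centers**2))


class TestFitCurvature:
    def test_exact_parabola(self):
        centers = np.linspace(-1, 1, 101)
        scape = ts.landscape_from_curve(centers, 3 * centers**2)
        assert ts.fit_curvature(scape, 50, kind="min") == pytest.approx(6.0)

    def test_quartic_perturbation_window_limit(self):
        centers = np.linspace(-1, 1, 2001)
        u = 3 * centers**2 + centers**4
        scape = ts.landscape_from_curve(centers, u)
        wide = ts.fit_curvature(scape, 1000, window_bins=801, kind="min")
        narrow = ts.fit_curvature(scape, 1000, window_bins=11, kind="min")
        assert abs(narrow - 6.0) < abs(wide - 6.0)
        assert narrow == pytest.approx(6.0, rel=1e-3)

    def test_gaussian_well_curvature_matches_analytic(self):
        # Boltzmann inversion of N(0, s^2) has curvature exactly 1/s^2
        centers = np.linspace(-0.08, 0.08, 321)
        s = 0.02
        u = 0.5 * (centers / s) ** 2
        scape = ts.landscape_from_curve(centers, u)
        omega = ts.fit_curvature(scape, 160, window_bins=15, kind="min")
        assert omega == pytest.approx(1 / s**2, rel=0.02)

    def test_wrong_sign_detected(self):
        centers = np.linspace(-1, 1, 101)
        scape = ts.landscape_from_curve(centers, 3 * centers**2)
        with pytest.raises(ValueError, match="window too small|contradicts"):
            ts.fit_curvature(scape, 50, kind="max")


class TestAnalyticRoundTrip:
    def test_blur_then_deconvolve_recovers_features(self, three_state_spec):
        """Noise-free pipeline core: mixture PDF -> PSF blur -> 51 LR
        iterations -> inversion recovers dG and barrier heights closely."""
        spec = three_state_spec
        sigma = 0.0134
        lo = spec.state_levels[0] - 4 * 0.025 - 4 * sigma
        hi = spec.state_levels[2] + 4 * 0.025 + 4 * sigma
        bw = (hi - lo) / 100
        centers = (np.arange(128) - 14 + 0.5) * bw + lo
        p = ts.mixture_density(spec, centers) * bw
        psf = PsfKernel.gaussian(sigma, bw)
        blurred = gaussian_filter1d(p, sigma / bw, mode="wrap")
        pdf = PdfEstimate(centers, blurred / blurred.sum(), bw)
        out = ts.lucy_richardson(pdf, psf, iterations=51)
        feats = ts.extract_features(ts.energy_from_pdf(out, spec.temperature))
        assert feats.delta_g(0) == pytest.approx(1.0, abs=0.05)
        assert feats.delta_g(1) == pytest.approx(0.5, abs=0.05)
        assert feats.barrier_heights[0] == pytest.approx(3.5, abs=0.2)
        assert feats.barrier_heights[1] == pytest.approx(4.0, abs=0.2)
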