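"""Generator: transition matrix algebra, chain statistics, trace rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import trapscape as ts
from trapscape.synthetic import quantize, transition_matrix_from_params


def flat_activation(n_barriers):
    return np.zeros((n_barriers, 2))


class TestTransitionMatrix:
    def test_flat_landscape_unit_ratios(self):
        # exp(0)=1 and B=C=D=A: every off-diagonal equals A
        m = transition_matrix_from_params(flat_activation(2), (1, 1, 1), (1, 1), 0.1)
        assert m[0, 1] == pytest.approx(0.1)
        assert m[1, 0] == pytest.approx(0.1)
        assert m[1, 2] == pytest.approx(0.1)
        assert m[2, 1] == pytest.approx(0.1)
        assert m[0, 0] == pytest.approx(0.9)
        assert m[1, 1] == pytest.approx(0.8)
        assert m[2, 2] == pytest.approx(0.9)
        assert m[0, 2] == 0.0 and m[2, 0] == 0.0  # no direct N<->E hops

    def test_single_barrier_boltzmann_factor(self):
        act = np.array([[1.0, 0.0], [0.0, 0.0]])
        m = transition_matrix_from_params(act, (1, 1, 1), (1, 1), 0.1)
        assert m[0, 1] == pytest.approx(0.1 * np.exp(-1.0), rel=1e-12)

    def test_curvature_ratio_prefactors(self):
        # wF/wN = 2, wFE/wNF = 3, wF/wE = 0.5 and A = 0.05:
        # hand evaluation gives B = 0.1, C = 0.075, D = 0.3
        m = transition_matrix_from_params(flat_activation(2), (1, 2, 4), (1, 3), 0.05)
        assert m[0, 1] == pytest.approx(0.05)   # A
        assert m[1, 0] == pytest.approx(0.10)   # B
        assert m[2, 1] == pytest.approx(0.075)  # C
        assert m[1, 2] == pytest.approx(0.30)   # D

    def test_rejects_unphysical_prefactor(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            transition_matrix_from_params(flat_activation(2), (1, 1, 1), (1, 1), 0.6)

    def test_detailed_balance_from_designed_spec(self, three_state_spec):
        # equal well curvatures: stationary ratios are Gibbs factors of minima
        m = ts.build_transition_matrix(three_state_spec)
        pi = ts.stationary_distribution(m)
        e = three_state_spec.state_energies
        assert np.log(pi[1] / pi[0]) == pytest.approx(-(e[1] - e[0]), abs=5e-3)
        assert np.log(pi[2] / pi[1]) == pytest.approx(-(e[2] - e[1]), abs=5e-3)

    @given(a=st.floats(0.01, 0.2), e1=st.floats(0.0, 5.0), e2=st.floats(0.0, 5.0),
           w=st.tuples(*[st.floats(0.7, 1.4)] * 3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_rows_stochastic_for_valid_inputs(self, a, e1, e2, w):
        act = np.array([[e1, e1], [e2, e2]])
        m = transition_matrix_from_params(act, w, (1.0, 1.0), a)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert m.min() >= 0 and m.max() <= 1


class TestSimulateChain:
    def test_identity_matrix_is_absorbing(self):
        seq = ts.simulate_chain(np.eye(3), 100, initial_state=1, seed=0)
        assert np.all(seq.labels == 1)

    def test_deterministic_for_fixed_seed(self):
        m = transition_matrix_from_params(flat_activation(2), (1, 1, 1), (1, 1), 0.1)
        a = ts.simulate_chain(m, 1000, seed=7)
        b = ts.simulate_chain(m, 1000, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_dwells_are_geometric(self):
        # two-state, exit probability 0.1: mean dwell 10 steps, geometric law
        p = 0.1
        m = np.array([[1 - p, p], [p, 1 - p]])
        seq = ts.simulate_chain(m, 100_000, initial_state=0, seed=11)
        dw = ts.residence_statistics(seq)
        lengths = np.round(np.concatenate(dw.dwell_durations) / seq.slice_duration)
        n = lengths.size
        assert lengths.mean() == pytest.approx(1 / p, abs=4 * (1 / p) / np.sqrt(n))
        # KS distance of the empirical dwell-length law against Geom(0.1)
        ks = max(abs(np.mean(lengths <= k) - stats.geom.cdf(k, p))
                 for k in range(1, 60))
        assert ks < 1.63 / np.sqrt(n)  # 99% KS band, conservative for discrete

    def test_occupancy_matches_stationary_eigenvector(self, three_state_spec):
        m = ts.build_transition_matrix(three_state_spec)
        pi = ts.stationary_distribution(m)
        seq = ts.simulate_chain(m, 100_000, seed=5)
        dw = ts.residence_statistics(seq)
        occ = dw.occupancy
        for i in range(3):
            se = pi[i] * np.sqrt(2.0 / max(dw.n_dwells[i], 1))
            assert abs(occ[i] - pi[i]) < 3 * se

    def test_rejects_non_stochastic_matrix(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            ts.simulate_chain(np.array([[0.5, 0.4], [0.1, 0.9]]), 10, seed=0)


class TestRenderTrace:
    def make_states(self, labels, n_states=3):
        return ts.StateSequence(np.asarray(labels), 0.1, n_states)

    def test_noiseless_trace_sits_exactly_on_levels(self):
        acq = ts.AcquisitionSpec(duration=0.3, sampling_rate=1000, noise_sigma=0,
                                 lsb=0, drift_model="none", seed=0)
        levels = [0.1, 0.2, 0.4]
        tr = ts.render_trace(self.make_states([0, 2, 1]), acq, levels)
        expect = np.repeat([0.1, 0.4, 0.2], 100)
        assert np.array_equal(tr.samples, expect)

    def test_noiseless_render_invertible_by_slice_means(self, three_state_spec):
        acq = ts.AcquisitionSpec(duration=50, sampling_rate=1000, noise_sigma=0,
                                 lsb=0, drift_model="none", seed=3)
        m = ts.build_transition_matrix(three_state_spec)
        seq = ts.simulate_chain(m, acq.n_slices, seed=3)
        tr = ts.render_trace(seq, acq, three_state_spec.state_levels)
        values = ts.slice_means(tr, 0.1)
        rec = ts.classify_three_state(values, 0.1)
        assert rec.n_states == seq.labels.max() + 1
        assert np.array_equal(rec.labels, seq.labels)

    def test_noise_sd_recovered(self):
        acq = ts.AcquisitionSpec(duration=10, sampling_rate=10_000,
                                 noise_sigma=0.0134, lsb=0, drift_model="none", seed=9)
        seq = self.make_states([0] * 100, n_states=2)
        tr = ts.render_trace(seq, acq, [0.1, 0.2])
        sd = tr.samples.std()
        assert sd == pytest.approx(0.0134, rel=0.02)

    def test_quantization_to_lsb_grid(self):
        # 0.0100 V with LSB 0.002441 V rounds to 4 x LSB = 0.009764 V
        acq = ts.AcquisitionSpec(duration=0.1, sampling_rate=100, noise_sigma=0,
                                 lsb=0.002441, drift_model="none", seed=0)
        tr = ts.render_trace(self.make_states([1], 2), acq, [0.005, 0.0100])
        assert np.allclose(tr.samples, 0.009764)

    def test_segment_drift_recorded_in_metadata(self):
        acq = ts.AcquisitionSpec(duration=60, sampling_rate=1000, noise_sigma=0,
                                 lsb=0, drift_model="segment", drift_scale=0.005,
                                 seed=21)
        seq = self.make_states([0] * 600, 2)
        tr = ts.render_trace(seq, acq, [0.1, 0.2])
        offs = np.array(tr.metadata["drift_offsets"])
        assert offs.size == 3
        sm = tr.samples.reshape(3, 20_000).mean(axis=1)
        assert np.allclose(sm - 0.1, offs, atol=1e-12)

    def test_rejects_non_integral_samples_per_slice(self):
        with pytest.raises(ValueError, match="positive integer"):
            ts.AcquisitionSpec(duration=1, sampling_rate=1005, slice_duration=0.0101)

    @given(x=st.floats(-1, 1), lsb=st.sampled_from([0.002441, 0.01, 0.5]))
    @settings(max_examples=100, derandomize=True)
    def test_quantize_rounds_to_nearest_multiple(self, x, lsb):
        q = quantize(np.array([x]), lsb)[0]
        assert abs(q - x) <= lsb / 2 + 1e-15
        assert round(q / lsb) == pytest.approx(q / lsb, abs=1e-9)


class TestGroundTruthSpec:
    def test_invalid_specs_rejected(self):
        good = dict(state_levels=(0.1, 0.2), state_energies=(0.0, 1.0),
                    barrier_energies=(3.0,), well_curvatures=(1.0, 1.0),
                    barrier_curvatures=(1.0,), prefactor_a=0.5)
        ts.GroundTruthSpec(**good)
        with pytest.raises(ValueError, match="barrier"):
            ts.GroundTruthSpec(**{**good, "barrier_energies": (0.5,)})
        with pytest.raises(ValueError, match="increasing"):
            ts.GroundTruthSpec(**{**good, "state_levels": (0.2, 0.1)})
        with pytest.raises(ValueError, match="prefactor"):
            ts.GroundTruthSpec(**{**good, "prefactor_a": 1.5})

    def test_designed_spec_realizes_requested_landscape(self, three_state_spec):
        grid, u = ts.analytic_landscape(three_state_spec)
        feats = ts.extract_features(
            ts.landscape_from_curve(grid, u, three_state_spec.temperature))
        assert feats.delta_g(0) == pytest.approx(1.0, abs=0.01)
        assert feats.delta_g(1) == pytest.approx(0.5, abs=0.01)
        act = feats.activation_energies()
        assert act[0, 0] == pytest.approx(3.5, abs=0.02)
        assert act[1, 0] == pytest.approx(3.0, abs=0.02)
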