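from dataclasses import replace

import numpy as np
import pytest

from ornspike import liflib
from ornspike.types import SpikeTrain


def orn(times, receptor="OR22a", neuron="o0"):
    return SpikeTrain(neuron_id=neuron, trial=0, receptor=receptor,
                      odorant="methyl butyrate", concentration=-3.0,
                      spikes=np.asarray(times, dtype=float))


def volley(t0, n, receptor, spacing=0.05):
    return [orn([t0 + i * spacing], receptor=receptor, neuron=f"{receptor}{i}")
            for i in range(n)]


@pytest.fixture(scope="module")
def spec():
    return liflib.default_network()


class TestSimulate:
    def test_silence_in_silence_out(self, spec):
        res = liflib.simulate(spec, [orn([])], [orn([], receptor="OR59b")],
                              span=(-5.0, 30.0))
        assert all(len(s) == 0 for s in res.spikes.values())
        for name, trace in res.traces.items():
            np.testing.assert_allclose(trace, spec.pn_params.v_rest)
        assert res.classification == liflib.INVALID

    def test_single_psp_matches_analytic_peak(self, spec):
        # subthreshold response to one synaptic event: closed-form
        # double-exponential amplitude of the current->membrane cascade
        w = 5.0
        tiny = liflib.NetworkSpec(orn_pn_weight_x=w, orn_pn_weight_y=1e-6,
                                  pn_kc_strong=2.0, pn_kc_weak=1.0,
                                  pn_i_weight=1.0, i_kc_weight=-1.0)
        res = liflib.simulate(tiny, [orn([0.0])], [orn([], receptor="OR59b")],
                              span=(-5.0, 40.0))
        peak = res.traces["PN_X"].max() - tiny.pn_params.v_rest
        expected = liflib.psc_peak_amplitude(w, tiny.pn_params.tau_m,
                                             tiny.pn_params.tau_syn)
        assert peak == pytest.approx(expected, rel=1e-3)

    def test_early_or22a_volley_drives_kc_x_only(self, spec):
        # OR22a volley 2 ms before OR59b: feedforward inhibition recruited
        # by PN_X arrives before PN_Y's weaker drive brings KC_Y to threshold
        res = liflib.simulate(spec, volley(5.0, 8, "OR22a"),
                              volley(7.0, 23, "OR59b"), span=(-5.0, 50.0))
        assert len(res.spikes["KC_X"]) >= 1
        w0, w1 = spec.decision_window
        kcy = res.spikes["KC_Y"]
        assert not np.any((kcy >= w0) & (kcy < w1))
        assert res.classification == liflib.MB

    def test_early_or59b_volley_drives_kc_y_only(self, spec):
        res = liflib.simulate(spec, volley(8.0, 8, "OR22a"),
                              volley(5.0, 23, "OR59b"), span=(-5.0, 50.0))
        assert res.classification == liflib.EA

    def test_translation_invariance(self, spec):
        orn22 = volley(5.0, 8, "OR22a")
        orn59 = volley(6.0, 23, "OR59b")
        base = liflib.simulate(spec, orn22, orn59, span=(-5.0, 50.0))
        d = 7.0
        shifted = liflib.simulate(spec, [t.shifted(d) for t in orn22],
                                  [t.shifted(d) for t in orn59],
                                  span=(-5.0 + d, 50.0 + d))
        for name in liflib.NEURONS:
            np.testing.assert_allclose(shifted.spikes[name],
                                       base.spikes[name] + d, atol=0.026)

    def test_inhibition_ablation_abolishes_exclusivity(self, spec):
        ablated = replace(spec, i_kc_weight=0.0)
        res = liflib.simulate(ablated, volley(5.0, 8, "OR22a"),
                              volley(7.0, 23, "OR59b"), span=(-5.0, 50.0))
        assert len(res.spikes["KC_X"]) >= 1 and len(res.spikes["KC_Y"]) >= 1
        assert res.classification == liflib.INVALID

    def test_dt_convergence(self, spec):
        orn22 = volley(5.0, 8, "OR22a")
        orn59 = volley(6.0, 23, "OR59b")
        a = liflib.simulate(spec, orn22, orn59, dt=0.025, span=(-5.0, 50.0))
        b = liflib.simulate(spec, orn22, orn59, dt=0.0125, span=(-5.0, 50.0))
        assert abs(a.kc_first_spike_latency - b.kc_first_spike_latency) < 0.05

    def test_coarse_dt_rejected(self, spec):
        with pytest.raises(ValueError):
            liflib.simulate(spec, [orn([0.0])], [orn([], receptor="OR59b")],
                            dt=0.1)

    def test_spike_outside_span_rejected(self, spec):
        with pytest.raises(ValueError):
            liflib.simulate(spec, [orn([100.0])], [orn([], receptor="OR59b")],
                            span=(-5.0, 50.0))


class TestSpecValidation:
    def test_weight_signs(self):
        with pytest.raises(ValueError):
            liflib.NetworkSpec(orn_pn_weight_x=-1.0, orn_pn_weight_y=1.0,
                               pn_kc_strong=2.0, pn_kc_weak=1.0,
                               pn_i_weight=1.0, i_kc_weight=-1.0)
        with pytest.raises(ValueError):
            liflib.NetworkSpec(orn_pn_weight_x=1.0, orn_pn_weight_y=1.0,
                               pn_kc_strong=2.0, pn_kc_weak=1.0,
                               pn_i_weight=1.0, i_kc_weight=1.0)

    def test_strong_must_exceed_weak(self):
        with pytest.raises(ValueError):
            liflib.NetworkSpec(orn_pn_weight_x=1.0, orn_pn_weight_y=1.0,
                               pn_kc_strong=1.0, pn_kc_weak=2.0,
                               pn_i_weight=1.0, i_kc_weight=-1.0)

    def test_lif_params_ordering(self):
        with pytest.raises(ValueError):
            liflib.LIFParams(v_rest=-60.0, v_threshold=-65.0)


class TestClassifyTrial:
    def make_result(self, kcx, kcy):
        spikes = {n: np.asarray([]) for n in liflib.NEURONS}
        spikes["KC_X"] = np.asarray(kcx, dtype=float)
        spikes["KC_Y"] = np.asarray(kcy, dtype=float)
        return liflib.NetworkResult(spikes=spikes, trace_times=np.empty(0),
                                    traces={}, classification="",
                                    kc_first_spike_latency=None)

    def test_kc_x_only_is_methyl_butyrate(self):
        label, lat = liflib.classify_trial(self.make_result([12.0], []))
        assert label == liflib.MB and lat == 12.0

    def test_both_invalid(self):
        label, _ = liflib.classify_trial(self.make_result([12.0], [14.0]))
        assert label == liflib.INVALID

    def test_neither_invalid(self):
        label, _ = liflib.classify_trial(self.make_result([], []))
        assert label == liflib.INVALID

    def test_spikes_outside_window_ignored(self):
        label, _ = liflib.classify_trial(self.make_result([12.0], [60.0]),
                                         (0.0, 50.0))
        assert label == liflib.MB


class TestClassificationRate:
    def test_deterministic_separated_inputs_perfect(self, spec):
        def factory(odorant, rng):
            if odorant == liflib.MB:
                return volley(5.0, 8, "OR22a"), volley(7.0, 23, "OR59b")
            return volley(8.0, 8, "OR22a"), volley(5.0, 23, "OR59b")

        res = liflib.classification_rate(spec, factory, n_runs=3, rng_seed=1)
        assert res[liflib.MB]["rate_pct"] == 100.0
        assert res[liflib.EA]["rate_pct"] == 100.0

    def test_scrambled_rank_order_breaks_classification(self, spec):
        # when the OR22a/OR59b volley order is random, the odorant label
        # carries no information and correctness drops to ~chance
        def factory(odorant, rng):
            lead = rng.random() < 0.5
            t22, t59 = (5.0, 7.0) if lead else (7.0, 5.0)
            return volley(t22, 8, "OR22a"), volley(t59, 23, "OR59b")

        res = liflib.classification_rate(spec, factory, odorants=(liflib.MB,),
                                         n_runs=60, rng_seed=2)
        assert 25.0 <= res[liflib.MB]["rate_pct"] <= 75.0

    def test_rank_offset_swap_swaps_kc_outcome(self, spec):
        # swapping the two odorants' generator latency offsets swaps the
        # majority KC, demonstrating rank-order (not label) sensitivity
        swapped = {("ethyl acetate", "OR22a"): -3.0,
                   ("ethyl acetate", "OR59b"): 0.0,
                   ("methyl butyrate", "OR59b"): -1.0,
                   ("methyl butyrate", "OR22a"): 0.0}
        factory = liflib.synthetic_orn_factory(-3.0, latency_offsets=swapped,
                                               spont_rate=0.0)
        res = liflib.classification_rate(spec, factory, n_runs=20, rng_seed=3)
        # with offsets swapped the network now reports the *other* odorant
        assert res[liflib.MB]["rate_pct"] <= 20.0
        assert res[liflib.EA]["rate_pct"] <= 20.0


class TestTimeShiftSweep:
    def test_zero_shift_matches_unshifted(self, spec):
        factory = liflib.synthetic_orn_factory(-3.0)
        shifts, rates = liflib.time_shift_sweep(
            spec, factory, shifts=np.array([0.0]), n_runs=10, rng_seed=4)
        res = liflib.classification_rate(spec, factory, odorants=(liflib.MB,),
                                         n_runs=10, rng_seed=4)
        assert rates[0] == res[liflib.MB]["rate_pct"]

    def test_rank_reversing_shift_lowers_rate(self, spec):
        factory = liflib.synthetic_orn_factory(-3.0)
        shifts, rates = liflib.time_shift_sweep(
            spec, factory, shifts=np.array([0.0, 3.0]), n_runs=12, rng_seed=5)
        assert rates[1] < rates[0]

    def test_common_shift_leaves_rate_unchanged(self, spec):
        # shifting both populations is a pure time translation
        factory = liflib.synthetic_orn_factory(-3.0)
        rng = np.random.default_rng(6)
        orn22, orn59 = factory(liflib.MB, rng)
        base = liflib.simulate(spec, orn22, orn59, span=(-30.0, 75.0))
        d = 3.0
        moved = liflib.simulate(spec, [t.shifted(d) for t in orn22],
                                [t.shifted(d) for t in orn59],
                                span=(-30.0 + d, 75.0 + d))
        assert moved.classification == base.classification
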