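"""Trace selection, binding classification and binding-fraction statistics."""

import warnings

import numpy as np
import pytest

from dnattract.fret import (
    BindingFractionResult,
    TraceClassification,
    binding_fraction,
    classify_binding,
    fret_efficiency,
    parallel_preference,
    select_single_pairs,
    titration_peak,
)
from dnattract.synth.traces import (
    IntensityParams,
    KineticParams,
    simulate_trace_batch,
)


def _trace_from_arrays(I_D, I_A, I_dir, trace_id="t0", batch="rep1"):
    from dnattract.synth.traces import FluorescenceTrace

    return FluorescenceTrace(
        trace_id=trace_id, I_D=np.asarray(I_D, float),
        I_A=np.asarray(I_A, float), I_A_direct=np.asarray(I_dir, float),
        frame_dt=0.1, construct="both", batch=batch, c_spm=2.0,
    )


def _classification(e_series, trace_id="t", batch="rep1"):
    return TraceClassification(
        trace_id=trace_id, is_single_pair=True, donor_bleach_frame=None,
        acceptor_bleach_frame=None, E_series=np.asarray(e_series, float),
        batch=batch,
    )


class TestFretEfficiency:
    def test_symmetric_channels_give_half(self):
        tr = _trace_from_arrays([500] * 50, [500] * 50, [500] * 50)
        e = fret_efficiency(tr, background=(0.0, 0.0))
        assert np.allclose(e, 0.5)

    def test_zero_acceptor_gives_zero(self):
        tr = _trace_from_arrays([1000] * 50, [0] * 50, [500] * 50)
        e = fret_efficiency(tr, background=(0.0, 0.0))
        assert np.allclose(e, 0.0)

    def test_nonpositive_total_flagged_invalid(self):
        tr = _trace_from_arrays([0.0, 1000], [0.0, 0], [500, 500])
        e = fret_efficiency(tr, background=(0.0, 0.0))
        assert np.isnan(e[0]) and e[1] == 0.0

    def test_generator_round_trip_mean_level(self):
        # always-bound proximal trace at E=0.75, no bleaching
        kp = KineticParams(k_on_max=50.0, k_off=1e-9, bleach_mean=1e9,
                           n_frames=600)
        ip = IntensityParams(e_proximal=(0.75, 0.0))
        traces, gt = simulate_trace_batch(
            kp, 6, composition_probs={"1D+1A": 1.0}, seed=1, intensity=ip,
        )
        for tr, g in zip(traces, gt):
            if not g.events:
                continue
            e = fret_efficiency(tr, background=(0.0, 0.0))
            f0 = int(np.ceil(g.events[0].t_start / kp.frame_dt)) + 1
            assert np.nanmean(e[f0:]) == pytest.approx(0.75, abs=0.01)


@pytest.fixture(scope="module")
def labeled_batch():
    kp = KineticParams(c_spm=2.0, k_on_max=0.012)
    traces, gt = simulate_trace_batch(kp, 500, seed=17)
    cls = select_single_pairs(traces)
    return {g.trace_id: g for g in gt}, cls


class TestSelection:
    def test_confusion_matrix_on_labeled_vesicles(self, labeled_batch):
        gt, cls = labeled_batch
        tp = sum(tc.is_single_pair and gt[tc.trace_id].composition == "1D+1A"
                 for tc in cls)
        fp = sum(tc.is_single_pair and gt[tc.trace_id].composition != "1D+1A"
                 for tc in cls)
        fn = sum((not tc.is_single_pair)
                 and gt[tc.trace_id].composition == "1D+1A" for tc in cls)
        n_true = tp + fn
        assert n_true > 30
        assert tp / n_true >= 0.9  # selection sensitivity
        assert fp <= 0.05 * len(cls)  # multi-dye rejection

    def test_multi_donor_vesicles_rejected(self, labeled_batch):
        gt, cls = labeled_batch
        rejected = [tc for tc in cls
                    if gt[tc.trace_id].composition == "2D+1A"
                    and gt[tc.trace_id].donor_bleach_frames[0] < 1000
                    and gt[tc.trace_id].donor_bleach_frames[1] < 1000]
        assert rejected
        assert sum(not tc.is_single_pair for tc in rejected) \
            >= 0.8 * len(rejected)

    def test_no_bleach_accepted_via_intensity_bands(self):
        kp = KineticParams(k_on_max=0.0, bleach_mean=1e9)
        traces, _ = simulate_trace_batch(
            kp, 20, composition_probs={"1D+1A": 1.0}, seed=9,
        )
        cls = select_single_pairs(traces)
        assert np.mean([tc.is_single_pair for tc in cls]) >= 0.9

    def test_all_zero_trace_rejected(self):
        tr = _trace_from_arrays(np.zeros(100), np.zeros(100), np.zeros(100))
        tc = select_single_pairs([tr])[0]
        assert not tc.is_single_pair


class TestClassification:
    def test_flat_low_trace_is_none(self):
        tc = classify_binding(_classification([0.08] * 100))
        assert not tc.is_binding
        assert tc.binding_mode == "none"

    def test_brief_excursion_is_jump(self):
        e = [0.08] * 50 + [0.8, 0.82, 0.79] + [0.08] * 50
        tc = classify_binding(_classification(e))
        assert tc.is_binding and tc.binding_mode == "jump"

    def test_sustained_intermediate_level(self):
        tc = classify_binding(_classification([0.30] * 100))
        assert tc.is_binding and tc.binding_mode == "sustained"

    def test_single_frame_spike_rejected_by_dwell(self):
        e = [0.08] * 50 + [0.9] + [0.08] * 50
        tc = classify_binding(_classification(e))
        assert not tc.is_binding

    def test_too_few_valid_frames_warns(self):
        with pytest.warns(RuntimeWarning):
            tc = classify_binding(_classification([np.nan, 0.9]))
        assert not tc.is_binding

    def test_non_single_pair_refused(self):
        tc = TraceClassification("x", False, None, None)
        with pytest.raises(ValueError):
            classify_binding(tc)

    def test_determinism(self):
        e = list(np.linspace(0, 1, 100))
        a = classify_binding(_classification(e))
        b = classify_binding(_classification(e))
        assert (a.is_binding, a.binding_mode) == (b.is_binding, b.binding_mode)


class TestBindingFraction:
    def _mk(self, batch, bound, total):
        out = []
        for i in range(total):
            tc = _classification([0.08] * 10, trace_id=f"{batch}-{i}",
                                 batch=batch)
            tc.is_binding = i < bound
            tc.binding_mode = "jump" if tc.is_binding else "none"
            out.append(tc)
        return out

    def test_triplicate_mean_and_sem(self):
        cls = (self._mk("r1", 2, 10) + self._mk("r2", 3, 10)
               + self._mk("r3", 4, 10))
        res = binding_fraction(cls)
        assert res.fraction == pytest.approx(0.3)
        assert res.sem == pytest.approx(0.0577, abs=1e-3)
        assert res.n_single_pair == 30

    def test_all_binding(self):
        cls = self._mk("r1", 5, 5) + self._mk("r2", 5, 5)
        res = binding_fraction(cls)
        assert res.fraction == 1.0
        assert res.sem == 0.0

    def test_order_permutation_invariance(self, rng):
        cls = (self._mk("r1", 2, 9) + self._mk("r2", 5, 11)
               + self._mk("r3", 1, 7))
        shuffled = list(cls)
        rng.shuffle(shuffled)
        assert binding_fraction(shuffled).fraction == \
            pytest.approx(binding_fraction(cls).fraction)

    def test_empty_replicate_excluded_with_warning(self):
        cls = self._mk("r1", 2, 10)
        empty = TraceClassification("e", False, None, None, batch="r2")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(Warning):
                binding_fraction(cls + [empty])


class TestTitrationPeak:
    def test_exact_log_parabola_recovered(self):
        cs = [0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
        f = [0.5 - 0.3 * (np.log10(c / 2.0)) ** 2 for c in cs]
        peak = titration_peak(list(zip(cs, f)))
        assert peak.is_peak
        assert peak.c_peak_mM == pytest.approx(2.0, rel=1e-6)

    def test_rescaling_invariance(self):
        cs = [0.5, 1.0, 2.0, 5.0, 10.0]
        f = [0.1, 0.3, 0.4, 0.25, 0.05]
        p1 = titration_peak(list(zip(cs, f)))
        p2 = titration_peak(list(zip(cs, [3.7 * v for v in f])))
        assert p1.c_peak_mM == pytest.approx(p2.c_peak_mM)

    def test_monotone_curve_flagged_boundary(self):
        cs = [0.5, 1.0, 2.0, 5.0]
        peak = titration_peak(list(zip(cs, [0.4, 0.3, 0.2, 0.1])))
        assert not peak.is_peak
        assert peak.c_peak_mM == 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            titration_peak([(1.0, 0.1), (2.0, 0.2), (5.0, 0.1)])


class TestParallelPreference:
    def _res(self, frac, sem=0.01):
        return BindingFractionResult(fraction=frac, sem=sem, n_single_pair=100,
                                     per_replicate={})

    def test_thirty_percent_excess(self):
        pref = parallel_preference(self._res(0.39), self._res(0.30))
        assert pref.percent == pytest.approx(30.0, abs=1e-9)
        assert pref.defined

    def test_equal_fractions_zero(self):
        pref = parallel_preference(self._res(0.3), self._res(0.3))
        assert pref.percent == pytest.approx(0.0)

    def test_zero_anti_flagged_undefined(self):
        pref = parallel_preference(self._res(0.3), self._res(0.0))
        assert not pref.defined
        assert np.isnan(pref.percent)

    def test_error_propagation(self):
        pref = parallel_preference(self._res(0.4, 0.04), self._res(0.2, 0.02))
        ratio = 2.0
        expected = 100 * ratio * np.sqrt((0.04 / 0.4) ** 2 + (0.02 / 0.2) ** 2)
        assert pref.percent_err == pytest.approx(expected)
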