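"""Response criteria, magnitudes, kinetic clustering and FOV filters."""

import numpy as np
import pandas as pd
import pytest

from viscmap import SimConfig, StimulusEvent, StimulusProtocol
from viscmap.responses import (
    call_chemical_response,
    call_mechanical_response,
    classify_kinetics,
    filter_fovs,
    response_magnitude,
)
from viscmap.synth import synthesize_trace
from viscmap.traces import BaselineStats


def stats(theta=0.1, F0_m=0.0, s0_m=0.0, F0_c=0.0, s0_c=0.0):
    return BaselineStats(
        F0=0.0, s0=theta / 2.5, theta=theta, F0_m=F0_m, s0_m=s0_m, F0_c=F0_c, s0_c=s0_c
    )


def mech_stim(onset=40, offset=90):
    return StimulusEvent("stomach", "stretch", 600, onset, offset)


def chem_stim(onset=40, offset=70):
    return StimulusEvent("larynx", "chemical", 100, onset, offset)


def pulse(n_frames, start, width, height):
    row = np.zeros(n_frames)
    row[start : start + width] = height
    return row


class TestMechanicalCriterion:
    def test_flat_trace_below_theta_not_responsive(self):
        ok, _ = call_mechanical_response(np.zeros(120), stats(0.1), mech_stim())
        assert not ok

    def test_sustained_suprathreshold_pulse_is_responsive(self):
        row = pulse(120, 50, 5, 0.5)
        ok, diag = call_mechanical_response(row, stats(0.1), mech_stim())
        assert ok and diag["n_theta_frames"] == 5

    @pytest.mark.parametrize("width,expected", [(3, False), (4, True)])
    def test_more_than_three_frames_is_strict(self, width, expected):
        """Exactly 3 continuous frames above theta fails; 4 passes."""
        row = pulse(120, 50, width, 0.5)
        ok, _ = call_mechanical_response(row, stats(0.1), mech_stim())
        assert ok is expected

    def test_local_two_sd_bound_also_required(self):
        # above theta long enough, but never above F0' + 2 s0'
        row = pulse(120, 50, 10, 0.5)
        ok, _ = call_mechanical_response(
            row, stats(0.1, F0_m=0.4, s0_m=0.2), mech_stim()
        )
        assert not ok

    def test_short_stimulus_window_never_responsive(self, caplog):
        row = pulse(120, 50, 3, 0.5)
        with caplog.at_level("WARNING"):
            ok, _ = call_mechanical_response(row, stats(0.1), mech_stim(50, 53))
        assert not ok

    def test_positive_offset_preserves_responsiveness(self):
        """Adding a positive constant inside the window never turns a
        responsive call negative (monotonicity)."""
        row = pulse(120, 50, 6, 0.3)
        s = stats(0.1)
        assert call_mechanical_response(row, s, mech_stim())[0]
        boosted = row.copy()
        boosted[40:90] += 0.2
        assert call_mechanical_response(boosted, s, mech_stim())[0]


class TestChemicalCriterion:
    def test_all_zero_not_responsive(self):
        ok, _ = call_chemical_response(np.zeros(120), stats(0.1), chem_stim())
        assert not ok

    def test_post_offset_transient_counts(self):
        # transient entirely inside the 20 frames after offset
        row = pulse(120, 75, 6, 0.5)
        ok, _ = call_chemical_response(row, stats(0.1), chem_stim())
        assert ok

    @pytest.mark.parametrize("width,expected", [(4, False), (5, True)])
    def test_more_than_four_frames_is_strict(self, width, expected):
        row = pulse(120, 75, width, 0.5)
        ok, _ = call_chemical_response(row, stats(0.1), chem_stim())
        assert ok is expected

    def test_missing_chemical_baseline_rejected(self):
        s = stats(0.1)
        s.F0_c = float("nan")
        with pytest.raises(ValueError, match="chemical baseline"):
            call_chemical_response(np.zeros(120), s, chem_stim())


class TestResponseMagnitude:
    def test_constant_trace_at_theta_gives_zero(self):
        row = np.full(120, 0.1)
        assert np.isclose(response_magnitude(row, stats(0.1), mech_stim()), 0.0)

    def test_single_frame_spike_smoothed_to_fifth(self):
        h = 1.0
        row = pulse(120, 60, 1, h)
        mag = response_magnitude(row, stats(0.1), mech_stim())
        assert np.isclose(mag, h / 5 - 0.1)

    def test_chemical_window_includes_post_offset_frames(self):
        row = pulse(120, 80, 10, 1.0)  # after offset=70, inside +20
        mag_chem = response_magnitude(row, stats(0.0), chem_stim())
        assert mag_chem > 0.9
        mag_mech = response_magnitude(row, stats(0.0), chem_stim(), modality="stretch")
        assert mag_mech < 0.1


class TestClassifyKinetics:
    def _templates(self, n_per_class, noise_sd, seed=0):
        config = SimConfig(n_neurons=10, seed=0)
        protocol = StimulusProtocol(
            events=[StimulusEvent("stomach", "stretch", 600, 40, 90)], n_frames=140
        )
        slow = synthesize_trace(np.array([1.0]), "slow", protocol, config)[40:90]
        rapid = synthesize_trace(np.array([1.0]), "rapid", protocol, config)[40:90]
        rng = np.random.default_rng(seed)
        traces = np.vstack(
            [slow + rng.normal(0, noise_sd, 50) for _ in range(n_per_class)]
            + [rapid + rng.normal(0, noise_sd, 50) for _ in range(n_per_class)]
        )
        labels = np.array(["slow"] * n_per_class + ["rapid"] * n_per_class)
        return traces, labels

    def test_noiseless_templates_perfectly_separated(self):
        traces, truth = self._templates(50, 0.0)
        labels, info = classify_kinetics(traces, seed=0)
        assert info["n_clusters"] == 2
        assert np.array_equal(labels, truth)

    def test_noisy_templates_recovered(self):
        traces, truth = self._templates(50, 0.1)
        labels, _ = classify_kinetics(traces, seed=0)
        assert (labels == truth).mean() >= 0.95

    def test_identical_traces_collapse_to_slow(self):
        traces = np.tile(np.linspace(0, 1, 30), (10, 1))
        labels, info = classify_kinetics(traces, seed=0)
        assert info["n_clusters"] == 1
        assert set(labels) == {"slow"}

    def test_fewer_than_two_traces_labelled_none(self):
        labels, _ = classify_kinetics(np.ones((1, 30)), seed=0)
        assert list(labels) == ["none"]

    def test_order_invariance(self):
        traces, _ = self._templates(20, 0.05)
        labels, _ = classify_kinetics(traces, seed=0)
        perm = np.random.default_rng(4).permutation(len(traces))
        labels_p, _ = classify_kinetics(traces[perm], seed=0)
        assert np.array_equal(labels[perm], labels_p)


class TestFilterFovs:
    def _table(self, counts, n_stim=3, n_neurons=10):
        rows = []
        for j in range(n_stim):
            for i in range(n_neurons):
                rows.append(
                    {"neuron_id": i, "stim_index": j, "responsive": i < counts[j]}
                )
        return pd.DataFrame(rows)

    def test_empty_fov_excluded_everywhere(self):
        tables = {0: self._table([0, 0, 0])}
        for mode in ("glucose", "standard"):
            assert filter_fovs(tables, mode) == set()

    def test_glucose_requires_five_for_every_stimulus(self):
        tables = {0: self._table([5, 5, 4]), 1: self._table([5, 5, 5])}
        assert filter_fovs(tables, "glucose") == {1}

    def test_standard_boundary_inclusive(self):
        tables = {0: self._table([2, 2, 2])}
        assert filter_fovs(tables, "standard") == {0}

    def test_spatial_pairs_uses_selective_counts(self):
        counts = {0: {"stomach": 2, "duodenum": 2}, 1: {"stomach": 1, "duodenum": 5}}
        kept = filter_fovs(
            {}, "spatial_pairs", selective_counts=counts, pair=("stomach", "duodenum")
        )
        assert kept == {0}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            filter_fovs({}, "bogus")
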