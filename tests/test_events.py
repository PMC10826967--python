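"""Event detection, classification, periodicity, and synchrony."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pitnet as pn
from pitnet import events as ev
from pitnet.netsim import Trajectory


DT = 0.5


def bump(t_on, t_off, peak=-10.0, base=-60.0, n=4000):
    """Synthetic trace with one smooth supra-threshold bump."""
    t = DT * np.arange(n)
    v = np.full(n, base)
    mask = (t >= t_on) & (t <= t_off)
    phase = (t[mask] - t_on) / (t_off - t_on)
    v[mask] = base + (peak - base) * np.sin(np.pi * phase)
    return v


def multi_peak_event(n_peaks, plateau=-30.0, amp=15.0):
    """One long supra-threshold envelope carrying several ripples."""
    t = DT * np.arange(4000)
    v = np.full_like(t, -60.0)
    mask = (t >= 200) & (t <= 1200)
    phase = (t[mask] - 200) / 1000
    env = plateau + 10 * np.sin(np.pi * phase)
    v[mask] = env + amp * 0.5 * (1 - np.cos(2 * np.pi * n_peaks * phase)) ** 2
    return v


class TestDetection:
    def test_flat_trace_no_events(self):
        assert ev.detect_events(np.full(1000, -60.0), DT) == []

    def test_single_bump_single_peak(self):
        evs = ev.detect_events(bump(200, 500), DT)
        assert len(evs) == 1
        assert evs[0].n_peaks == 1
        assert 200 < evs[0].t_start < evs[0].t_end < 520

    def test_hysteresis_requires_on_above_off(self):
        with pytest.raises(ValueError):
            ev.detect_events(np.zeros(10), DT, v_on=-45, v_off=-35)

    def test_time_reversal_preserves_event_count(self):
        v = np.concatenate([bump(200, 400), bump(300, 600)])
        assert len(ev.detect_events(v, DT)) == len(ev.detect_events(v[::-1], DT))

    def test_classification_stable_under_small_noise(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([bump(200, 500), multi_peak_event(3)])
        clean = [e.label for e in ev.classify_events(ev.detect_events(v, DT))]
        noisy_v = v + rng.uniform(-0.4, 0.4, size=v.size)
        noisy = [e.label for e in ev.classify_events(ev.detect_events(noisy_v, DT))]
        assert clean == noisy


class TestClassification:
    def test_single_peak_is_spike(self):
        e = ev.Event(0.0, 50.0, n_peaks=1)
        assert ev.classify_event(e) == "spike"

    @pytest.mark.parametrize("k", [2, 4])
    def test_k_peaks_is_k_spike_burst(self, k):
        evs = ev.classify_events(ev.detect_events(multi_peak_event(k), DT))
        assert [e.label for e in evs] == [f"{k}-spike burst"]

    def test_rapid_spike_pair_merges_into_doublet(self):
        v = np.maximum(bump(200, 300), bump(305, 405))  # ~30 ms sub-threshold gap
        evs = ev.classify_events(ev.detect_events(v, DT))
        assert [e.label for e in evs] == ["doublet"]
        assert evs[0].n_peaks == 2

    def test_separated_spikes_stay_spikes(self):
        v = np.maximum(bump(200, 300), bump(500, 600))  # 200 ms gap
        evs = ev.classify_events(ev.detect_events(v, DT))
        assert [e.label for e in evs] == ["spike", "spike"]

    def test_overlong_burst_is_flagged(self):
        events = [
            ev.Event(1000.0 * k, 1000.0 * k + 100.0, n_peaks=2) for k in range(5)
        ]
        events.append(ev.Event(6000.0, 6400.0, n_peaks=2))
        labels = [e.label for e in ev.classify_events(events)]
        assert labels[:5] == ["2-spike burst"] * 5
        assert labels[5] == "long burst"


class TestConversion:
    def test_all_spikes_not_converted(self):
        train = ev.EventTrain(
            cell=0,
            events=tuple(
                ev.Event(100.0 * k, 100.0 * k + 30.0, 1, "spike") for k in range(6)
            ),
            window=(0, 1000),
        )
        assert ev.is_converted_burster(train) == (False, 0.0)

    def test_empty_train_undefined(self):
        train = ev.EventTrain(cell=0, events=(), window=(0, 1000))
        flag, frac = ev.is_converted_burster(train)
        assert flag is None and np.isnan(frac)

    def test_strongly_coupled_spiker_converted(self, strong_pair):
        flag, frac = ev.is_converted_burster(ev.event_train(strong_pair, 1))
        assert flag and frac >= 0.5

    def test_weakly_coupled_spiker_not_converted(self, weak_pair):
        flag, frac = ev.is_converted_burster(ev.event_train(weak_pair, 1))
        assert flag is False and frac < 0.5


class TestMinimalPeriod:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            (list("abab"), 2),
            (list("aaaa"), 1),
            (list("abcdefghijkl") * 3, 12),
            (list("abcabd"), None),
            (list("ab"), None),  # no period admits two full repeats
        ],
    )
    def test_examples(self, seq, expected):
        assert ev.minimal_period(seq) == expected

    @given(st.integers(1, 5), st.integers(2, 6))
    def test_minimal_period_divides_all_periods(self, k, reps):
        motif = [f"s{i}" for i in range(k)]
        seq = motif * reps
        p = ev.minimal_period(seq)
        assert p is not None and k % p == 0
        # every other admissible periodicity is a multiple of p
        n = len(seq)
        for q in range(1, n // 2 + 1):
            if all(seq[i] == seq[i + q] for i in range(n - q)):
                assert q % p == 0


def _make_traj(x, dt=1.0):
    x = np.asarray(x, dtype=float)
    times = dt * np.arange(x.shape[1])
    z = np.zeros_like(x)
    return Trajectory(times=times, v=x, n=z + 0.1, c=np.abs(x) + 0.1, b=z + 0.1)


class TestSynchrony:
    def test_identical_traces_unity(self):
        x = np.sin(np.linspace(0, 20, 500))
        traj = _make_traj(np.vstack([x, x]))
        assert ev.synchrony_index(traj, signal="v") == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        traj = _make_traj(rng.normal(size=(3, 4000)))
        assert abs(ev.synchrony_index(traj, signal="v")) < 0.1

    def test_constant_trace_excluded_with_warning(self):
        x = np.sin(np.linspace(0, 20, 500))
        traj = _make_traj(np.vstack([x, x, np.zeros(500)]))
        with pytest.warns(UserWarning):
            val = ev.synchrony_index(traj, signal="v")
        assert val == pytest.approx(1.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            ev.synchrony_index(_make_traj(np.zeros((1, 100))))

    def test_strong_coupling_synchronizes_weak_does_not(
        self, strong_pair, weak_pair
    ):
        assert ev.synchrony_index(strong_pair) >= 0.9
        assert ev.synchrony_index(weak_pair) < 0.9


class TestExport:
    def test_event_csv_round_trip(self, tmp_path, strong_pair):
        trains = [ev.event_train(strong_pair, i) for i in range(2)]
        path = tmp_path / "events.csv"
        ev.event_trains_to_csv(trains, path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["cell", "t_start", "t_end", "n_peaks", "label"]
        assert len(back) == sum(len(t.events) for t in trains)
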