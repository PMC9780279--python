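"""Synthetic population, spike-train and raw-trace generators."""

import numpy as np
import pandas as pd
import pytest

import retinacuity as ra
from retinacuity.simulate import empirical_rfr, spike_waveform_template
from retinacuity.stimulus import ConfigurationError, grating_phase_mask


def test_rfr_zero_forces_equal_phase_rates():
    spec = ra.PopulationSpec(n_units=20, rfr_mixture=ra.RFRMixture(1, 0, 0, 0.5), seed=1)
    for u in ra.generate_population(spec):
        assert u.phase_rates_hz[0] == u.phase_rates_hz[1]
        assert u.true_rfr == 0.0


def test_rfr_one_silences_phase2():
    spec = ra.PopulationSpec(n_units=20, rfr_mixture=ra.RFRMixture(0, 1, 0, 1.0), seed=1)
    for u in ra.generate_population(spec):
        assert u.phase_rates_hz[1] == 0.0
        assert u.true_rfr == 1.0


def test_population_is_deterministic_and_in_bounds():
    spec = ra.PopulationSpec(n_units=50, seed=7)
    a = ra.generate_population(spec)
    b = ra.generate_population(spec)
    assert a == b
    geom = ra.GeometrySpec()
    for u in a:
        assert 0 <= u.position_um[0] <= geom.extent_um[0]
        assert 0 <= u.position_um[1] <= geom.extent_um[1]
        # inverse-RFR consistency: (FR1-FR2)/(FR1+FR2) == true_rfr
        fr1, fr2 = u.phase_rates_hz
        if fr1 + fr2 > 0:
            assert (fr1 - fr2) / (fr1 + fr2) == pytest.approx(u.true_rfr)


def test_invalid_mixture_weights_raise():
    with pytest.raises(ConfigurationError):
        ra.RFRMixture(0.5, 0.5, 0.5, 0.3)


@pytest.mark.parametrize("true_rfr", [-1.0, -0.5, 0.0, 0.5, 1.0])
def test_empirical_rfr_converges(true_rfr):
    """Mean empirical RFR over repetitions approaches true RFR within 3 SE."""
    n_rep = 2000
    units = ra.generate_population(
        ra.PopulationSpec(
            n_units=1,
            rfr_mixture=ra.RFRMixture(0, 1, 0, true_rfr) if true_rfr >= 0
            else ra.RFRMixture(0, 0, 1, -true_rfr),
            base_rate_hz=4.0,
            seed=3,
        )
    )
    protocol = ra.optogenetic_protocol(n_repetitions=n_rep)
    trains = ra.simulate_spike_trains(units, protocol, seed=11)
    est = empirical_rfr(trains, 0)
    # SE of the count-ratio estimator, delta method on Poisson totals
    fr1, fr2 = units[0].phase_rates_hz
    total = (fr1 + fr2) * 0.2 * n_rep  # 200 ms windows
    se = max(np.sqrt((1 - true_rfr**2) / max(total, 1)), 1e-3)
    assert abs(est - true_rfr) < 3 * se + 0.01


def test_poisson_mean_matches_rate():
    """FR1=6, FR2=2 Hz with 200 ms windows: counts average 1.2 / 0.4."""
    units = ra.generate_population(
        ra.PopulationSpec(n_units=1, rfr_mixture=ra.RFRMixture(0, 1, 0, 0.5), base_rate_hz=4.0, seed=0)
    )
    assert units[0].phase_rates_hz == (6.0, 2.0)
    protocol = ra.optogenetic_protocol(n_repetitions=2000)
    trains = ra.simulate_spike_trains(units, protocol, seed=5)
    df = trains.spikes
    m1 = (df["phase_label"] == "phase1").sum() / 2000
    m2 = (df["phase_label"] == "phase2").sum() / 2000
    assert m1 == pytest.approx(1.2, abs=3 * np.sqrt(1.2 / 2000))
    assert m2 == pytest.approx(0.4, abs=3 * np.sqrt(0.4 / 2000))
    assert empirical_rfr(trains, 0) == pytest.approx(0.5, abs=0.03)


def test_zero_rate_units_emit_no_spikes():
    units = ra.generate_population(
        ra.PopulationSpec(n_units=3, base_rate_hz=0.0, seed=0)
    )
    trains = ra.simulate_spike_trains(units, ra.optogenetic_protocol(n_repetitions=50), seed=1)
    assert len(trains.spikes) == 0


def test_spike_times_stay_inside_their_phase_window():
    units = ra.generate_population(ra.PopulationSpec(n_units=5, seed=2))
    for proto in (ra.optogenetic_protocol(n_repetitions=20), ra.electrical_protocol(n_repetitions=20)):
        trains = ra.simulate_spike_trains(units, proto, seed=3)
        for label, phase in (("phase1", 1), ("phase2", 2)):
            sub = trains.spikes[trains.spikes["phase_label"] == label]
            lo, hi = proto.phase_window(phase)
            assert (sub["spike_time_ms"] >= lo).all()
            assert (sub["spike_time_ms"] <= hi).all()


def test_counts_independent_across_repetitions():
    """Lag-1 autocorrelation of per-repetition counts is null-distributed."""
    n_rep = 200
    units = ra.generate_population(ra.PopulationSpec(n_units=100, base_rate_hz=10.0, seed=4))
    trains = ra.simulate_spike_trains(units, ra.optogenetic_protocol(n_repetitions=n_rep), seed=6)
    df = trains.spikes[trains.spikes["phase_label"] == "phase1"]
    n_extreme = 0
    crit = 2.576 / np.sqrt(n_rep)  # alpha = 0.01 two-sided
    for uid in range(100):
        counts = np.bincount(
            df[df["unit_id"] == uid]["repetition_index"].to_numpy(), minlength=n_rep
        ).astype(float)
        c = counts - counts.mean()
        denom = (c**2).sum()
        if denom == 0:
            continue
        r1 = (c[:-1] * c[1:]).sum() / denom
        n_extreme += abs(r1) > crit
    assert n_extreme <= 6  # ~1 expected at alpha=0.01 over 100 units


# --------------------------- raw traces --------------------------------------

def _empty_trains(protocol):
    cols = ["unit_id", "repetition_index", "phase_label", "spike_time_ms"]
    empty = pd.DataFrame(columns=cols).astype(
        {"unit_id": int, "repetition_index": int, "phase_label": str, "spike_time_ms": float}
    )
    return ra.SpikeTrainSet(spikes=empty, protocol=protocol, unit_ids=())


def test_electrical_artifact_only_trace(small_geometry):
    """No units, no noise: pure sinusoid inside phase windows, zero elsewhere."""
    proto = ra.electrical_protocol(bar_width_um=32.0, n_repetitions=2)
    rec = ra.synthesize_raw_recording(
        _empty_trains(proto), [], proto, small_geometry, noise_sd_v=0.0, seed=0
    )
    fs = rec.sampling_rate_hz
    gap = rec.traces[:, int(0.110 * fs) : int(0.340 * fs)]  # between the windows
    assert np.abs(gap).max() == 0.0
    inside = rec.traces[:, int(0.005 * fs) : int(0.095 * fs)]
    assert np.abs(inside).max() > 0.0


def test_optogenetic_two_seconds_has_five_resets(small_geometry):
    proto = ra.optogenetic_protocol(bar_width_um=30.0, n_repetitions=5)  # 5 x 400 ms
    rec = ra.synthesize_raw_recording(
        _empty_trains(proto), [], proto, small_geometry, noise_sd_v=0.0, seed=0
    )
    assert len(rec.reset_times) == 5
    assert np.all(np.diff(rec.reset_times) == int(0.4 * rec.sampling_rate_hz))


def test_raw_synthesis_is_additive(small_geometry, opto_protocol):
    units = ra.generate_population(ra.PopulationSpec(n_units=3, seed=0), small_geometry)
    trains = ra.simulate_spike_trains(units, opto_protocol, seed=1)
    kw = dict(noise_sd_v=10e-6, seed=5)
    full = ra.synthesize_raw_recording(trains, units, opto_protocol, small_geometry, **kw)
    art = ra.synthesize_raw_recording(
        _empty_trains(opto_protocol), units, opto_protocol, small_geometry, **kw
    )
    spikes_only = ra.synthesize_raw_recording(
        trains, units, opto_protocol, small_geometry,
        noise_sd_v=0.0, seed=5, include_artifact=False,
    )
    np.testing.assert_allclose(
        full.traces - art.traces, spikes_only.traces, atol=1e-15
    )


def test_single_spike_peak_near_spike_time(small_geometry):
    """Brute-force argmax of the rendered trace lands at the spike time."""
    proto = ra.optogenetic_protocol(bar_width_um=30.0, n_repetitions=1)
    unit = ra.UnitGroundTruth(
        unit_id=0, position_um=(32.0, 32.0), true_rfr=0.0,
        phase_rates_hz=(1.0, 1.0), qc={"isoibg": 0.5, "separability": 3.0, "snr": 6.0},
    )
    t_ms = 123.0
    spikes = pd.DataFrame(
        [(0, 0, "phase1", t_ms)],
        columns=["unit_id", "repetition_index", "phase_label", "spike_time_ms"],
    )
    trains = ra.SpikeTrainSet(spikes=spikes, protocol=proto, unit_ids=(0,))
    rec = ra.synthesize_raw_recording(
        trains, [unit], proto, small_geometry, noise_sd_v=0.0, seed=0, include_artifact=False
    )
    fs = rec.sampling_rate_hz
    ch = np.argmax(np.abs(rec.traces).max(axis=1))
    peak = np.argmax(np.abs(rec.traces[ch]))
    tpl = spike_waveform_template(fs)
    offset = np.argmax(np.abs(tpl))  # template trough lag
    assert abs((peak - offset) - t_ms / 1000 * fs) <= 1


def test_low_sampling_rate_rejected(small_geometry, opto_protocol):
    with pytest.raises(ConfigurationError):
        ra.synthesize_raw_recording(
            _empty_trains(opto_protocol), [], opto_protocol, small_geometry,
            sampling_rate_hz=5_000.0,
        )


def test_grating_mask_phases_are_complementary():
    pos = ra.GeometrySpec().stim_positions()
    m1 = grating_phase_mask(pos, 64.0, 1)
    m2 = grating_phase_mask(pos, 64.0, 2)
    assert np.all(m1 ^ m2)
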