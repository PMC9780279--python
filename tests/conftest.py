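import numpy as np
import pytest

import retinacuity as ra


@pytest.fixture
def small_geometry() -> ra.GeometrySpec:
    """5x5 recording sites at 16 um with a 2x2 stimulation grid inside."""
    return ra.GeometrySpec(
        n_recording_rows=5,
        n_recording_cols=5,
        recording_pitch_um=16.0,
        n_stim_rows=2,
        n_stim_cols=2,
        stim_pitch_um=32.0,
    )


@pytest.fixture
def opto_protocol() -> ra.StimulusProtocol:
    return ra.optogenetic_protocol(bar_width_um=30.0, n_repetitions=10)


@pytest.fixture
def electrical_protocol_() -> ra.StimulusProtocol:
    return ra.electrical_protocol(bar_width_um=32.0, n_repetitions=10)


def decode_dataset(n_units=40, r=0.0, n_repetitions=60, seed=0, weights=(0.4, 0.3, 0.3)):
    """Simulated population -> firing-rate matrix -> decoding dataset."""
    units = ra.generate_population(
        ra.PopulationSpec(n_units=n_units, rfr_mixture=ra.RFRMixture(*weights, r), seed=seed)
    )
    protocol = ra.optogenetic_protocol(n_repetitions=n_repetitions)
    trains = ra.simulate_spike_trains(units, protocol, seed=seed + 1)
    matrix = ra.build_rate_matrix(ra.sorted_units_from_ground_truth(units, trains), protocol)
    return ra.DecodingDataset(
        X=matrix.values,
        y=(matrix.phase_labels == "phase1").astype(int),
        unit_ids=matrix.unit_ids,
    ), units, matrix
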