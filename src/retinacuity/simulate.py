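"""Synthetic RGC populations, phase-locked spike trains and raw MEA traces.

This module stands in for the ex vivo recordings the analysis pipeline was
designed for.  Each simulated retinal ganglion cell (RGC) carries a ground-truth
phase selectivity expressed as an RFR (relative change in firing rate),

    RFR = (FR1 - FR2) / (FR1 + FR2)  in [-1, 1],

and the generator inverts that relation at a given base rate B so that the
expected per-phase rates are FR1 = B (1 + RFR), FR2 = B (1 - RFR).  Spiking is
an inhomogeneous Poisson process per phase window; under electrical stimulation
spikes are additionally locked to the cycles of the 40 Hz carrier, mirroring
the raster structure seen on capacitively stimulated retina.

Raw voltage traces are optional and purely additive: Gaussian sensor noise +
biphasic spike waveforms on channels near each soma + the modality-specific
artifact (sinusoidal 40 Hz carrier crosstalk for electrical runs; slow sensor
drift with periodic 200 us sensor resets for optogenetic runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import (
    ConfigurationError,
    GeometrySpec,
    Modality,
    StimulusProtocol,
    grating_phase_mask,
)

PHASE_LABELS = ("phase1", "phase2")


@dataclass(frozen=True)
class RFRMixture:
    """Mixture the ground-truth RFR values are drawn from.

    Point mass at 0 (unselective cells) plus symmetric masses at +r and -r,
    emulating the bimodal selectivity-index distributions seen on grating
    reversal stimuli.
    """

    weight_zero: float = 0.4
    weight_pos: float = 0.3
    weight_neg: float = 0.3
    r: float = 0.8

    def __post_init__(self) -> None:
        w = self.weight_zero + self.weight_pos + self.weight_neg
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights sum to {w}, expected 1")
        if any(x < 0 for x in (self.weight_zero, self.weight_pos, self.weight_neg)):
            raise ConfigurationError("mixture weights must be non-negative")
        if not -1.0 <= self.r <= 1.0:
            raise ConfigurationError("selectivity magnitude r must lie in [-1, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """How to generate a ground-truth RGC population."""

    n_units: int = 40
    rfr_mixture: RFRMixture = field(default_factory=RFRMixture)
    base_rate_hz: float = 8.0
    seed: int = 0
    # QC metadata emulation; upstream spike sorting is out of scope, so these
    # are assigned by the generator rather than recomputed.
    template_amplitude_uv: float = 120.0
    noise_sd_uv: float = 20.0
    separability_range: tuple[float, float] = (2.5, 8.0)
    isoibg_range: tuple[float, float] = (0.2, 1.0)
    missing_isoibg_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ConfigurationError("n_units must be >= 0")
        if self.base_rate_hz < 0:
            raise ConfigurationError("base rate must be non-negative")


@dataclass(frozen=True)
class UnitGroundTruth:
    """One putative RGC with its true selectivity and QC metadata."""

    unit_id: int
    position_um: tuple[float, float]
    true_rfr: float
    phase_rates_hz: tuple[float, float]
    qc: dict
    axon_path_um: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.true_rfr <= 1.0:
            raise ConfigurationError("true_rfr outside [-1, 1]")
        if min(self.phase_rates_hz) < 0:
            raise ConfigurationError("expected rates must be non-negative")


@dataclass
class SpikeTrainSet:
    """Per-unit, per-repetition, per-phase spike times.

    ``spikes`` columns: unit_id, repetition_index, phase_label, spike_time_ms
    (time relative to the start of the repetition).
    """

    spikes: pd.DataFrame
    protocol: StimulusProtocol
    unit_ids: tuple[int, ...]

    def for_unit(self, unit_id: int) -> pd.DataFrame:
        return self.spikes[self.spikes["unit_id"] == unit_id]


@dataclass
class RawRecording:
    """Multi-channel extracellular voltage traces plus acquisition metadata."""

    traces: np.ndarray  # channels x samples, volts
    sampling_rate_hz: float
    channel_positions_um: np.ndarray  # channels x 2
    reset_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    reset_duration_us: float = 200.0

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def reset_duration_samples(self) -> int:
        return max(1, int(round(self.reset_duration_us * 1e-6 * self.sampling_rate_hz)))


def rates_from_rfr(true_rfr: float, base_rate_hz: float) -> tuple[float, float]:
    """Invert the RFR definition at a given base (phase-mean) rate.

    FR1 = B (1 + RFR) and FR2 = B (1 - RFR) satisfy
    (FR1 - FR2) / (FR1 + FR2) = RFR for any B > 0.
    """
    return base_rate_hz * (1.0 + true_rfr), base_rate_hz * (1.0 - true_rfr)


def generate_population(
    spec: PopulationSpec, geometry: GeometrySpec | None = None
) -> list[UnitGroundTruth]:
    """Draw a ground-truth population; reproducible under ``spec.seed``.

    Positions are uniform over the recording area; true RFR values come from
    the three-component mixture; axon paths are straight polylines toward the
    nearest array edge and never contribute spikes (selectivity is somatic by
    construction).
    """
    geometry = geometry or GeometrySpec()
    rng = np.random.default_rng(spec.seed)
    width, height = geometry.extent_um
    mix = spec.rfr_mixture
    components = rng.choice(
        3, size=spec.n_units, p=[mix.weight_zero, mix.weight_pos, mix.weight_neg]
    )
    rfr_values = np.choose(components, [0.0, mix.r, -mix.r])
    xs = rng.uniform(0, width, spec.n_units)
    ys = rng.uniform(0, height, spec.n_units)
    separability = rng.uniform(*spec.separability_range, spec.n_units)
    isoibg = rng.uniform(*spec.isoibg_range, spec.n_units)
    missing = rng.random(spec.n_units) < spec.missing_isoibg_fraction
    snr = spec.template_amplitude_uv / spec.noise_sd_uv

    units = []
    for i in range(spec.n_units):
        fr1, fr2 = rates_from_rfr(float(rfr_values[i]), spec.base_rate_hz)
        # axon runs straight toward the nearest vertical edge
        edge_x = 0.0 if xs[i] < width / 2 else width
        units.append(
            UnitGroundTruth(
                unit_id=i,
                position_um=(float(xs[i]), float(ys[i])),
                true_rfr=float(rfr_values[i]),
                phase_rates_hz=(fr1, fr2),
                qc={
                    "isoibg": float("nan") if missing[i] else float(isoibg[i]),
                    "separability": float(separability[i]),
                    "snr": float(snr),
                },
                axon_path_um=((float(xs[i]), float(ys[i])), (edge_x, float(ys[i]))),
            )
        )
    return units


def _electrical_spike_times(
    rng: np.random.Generator,
    n_spikes: int,
    window: tuple[float, float],
    carrier_hz: float,
    jitter_ms: float = 1.5,
) -> np.ndarray:
    """Spike times locked to the cycles of the sinusoidal carrier.

    Each spike is assigned a carrier cycle uniformly at random and jittered
    around the cycle midpoint, reproducing "one spike per carrier cycle"
    raster structure without imposing a refractory model.
    """
    cycle_ms = 1000.0 / carrier_hz
    n_cycles = max(1, int(round((window[1] - window[0]) / cycle_ms)))
    cycles = rng.integers(0, n_cycles, n_spikes)
    t = window[0] + (cycles + 0.5) * cycle_ms + rng.normal(0.0, jitter_ms, n_spikes)
    return np.clip(t, window[0], np.nextafter(window[1], window[0]))


def simulate_spike_trains(
    units: list[UnitGroundTruth],
    protocol: StimulusProtocol,
    seed: int = 0,
) -> SpikeTrainSet:
    """Simulate phase-locked Poisson spiking for every unit and repetition.

    Counts in each phase window are Poisson with mean ``rate * duration``;
    within-window times are uniform (optogenetic) or carrier-locked
    (electrical).  Long simulations converge to each unit's ``true_rfr``.
    """
    if not units:
        raise ConfigurationError("need at least one unit")
    if protocol.phase_duration_ms <= 0:
        raise ConfigurationError("zero-duration phase window")
    rng = np.random.default_rng(seed)
    records: list[tuple[int, int, str, float]] = []
    for unit in units:
        for phase, label in ((1, "phase1"), (2, "phase2")):
            window = protocol.phase_window(phase)
            duration_s = (window[1] - window[0]) / 1000.0
            rate = unit.phase_rates_hz[phase - 1]
            counts = rng.poisson(rate * duration_s, protocol.n_repetitions)
            for rep, n in enumerate(counts):
                if n == 0:
                    continue
                if protocol.modality is Modality.ELECTRICAL:
                    times = _electrical_spike_times(
                        rng, int(n), window, protocol.carrier_frequency_hz
                    )
                else:
                    times = rng.uniform(window[0], window[1], int(n))
                for t in np.sort(times):
                    records.append((unit.unit_id, rep, label, float(t)))
    spikes = pd.DataFrame(
        records, columns=["unit_id", "repetition_index", "phase_label", "spike_time_ms"]
    )
    if spikes.empty:
        spikes = spikes.astype(
            {
                "unit_id": int,
                "repetition_index": int,
                "phase_label": str,
                "spike_time_ms": float,
            }
        )
    return SpikeTrainSet(
        spikes=spikes, protocol=protocol, unit_ids=tuple(u.unit_id for u in units)
    )


def spike_waveform_template(
    sampling_rate_hz: float, amplitude_v: float = 120e-6
) -> np.ndarray:
    """Biphasic extracellular spike template (~0.7 ms, negative-leading).

    Lobes are kept narrow (~0.2 ms) relative to the 0.8 ms drift-smoothing
    window used downstream so that drift subtraction does not eat the spike.
    """
    t = np.arange(0, 0.7e-3, 1.0 / sampling_rate_hz)
    neg = -np.exp(-0.5 * ((t - 0.15e-3) / 0.06e-3) ** 2)
    pos = 0.45 * np.exp(-0.5 * ((t - 0.4e-3) / 0.1e-3) ** 2)
    w = neg + pos
    return amplitude_v * w / np.abs(w).max()


def synthesize_raw_recording(
    spike_trains: SpikeTrainSet,
    units: list[UnitGroundTruth],
    protocol: StimulusProtocol,
    geometry: GeometrySpec,
    noise_sd_v: float = 20e-6,
    seed: int = 0,
    sampling_rate_hz: float = 20_000.0,
    spike_amplitude_v: float = 120e-6,
    drift_amplitude_v: float = 5e-3,
    reset_amplitude_v: float = 10e-3,
    reset_interval_ms: float = 400.0,
    include_artifact: bool = True,
) -> RawRecording:
    """Render spike trains into multi-channel voltage traces with artifacts.

    The synthesis is strictly additive: noise, spike waveforms and artifact are
    generated independently and summed, so subtracting an artifact-only render
    (same seed) from a full render recovers the spikes-only render exactly.
    """
    if sampling_rate_hz * 200e-6 < 2:
        raise ConfigurationError(
            "sampling rate too low to represent a 200 us sensor reset"
        )
    positions = geometry.recording_positions()
    n_channels = positions.shape[0]
    n_samples = int(round(protocol.total_duration_ms / 1000.0 * sampling_rate_hz))
    rng = np.random.default_rng(seed)
    # noise drawn first from its own deterministic stream: additivity holds
    traces = (
        rng.normal(0.0, noise_sd_v, (n_channels, n_samples))
        if noise_sd_v > 0
        else np.zeros((n_channels, n_samples))
    )

    # --- spike waveforms on channels near each soma ---------------------------
    template = spike_waveform_template(sampling_rate_hz, spike_amplitude_v)
    unit_by_id = {u.unit_id: u for u in units}
    if len(spike_trains.spikes):
        phase_start = {
            "phase1": protocol.phase1_window_ms[0],
            "phase2": protocol.phase2_window_ms[0],
        }
        for row in spike_trains.spikes.itertuples(index=False):
            unit = unit_by_id[row.unit_id]
            t_abs_ms = row.repetition_index * protocol.period_ms + row.spike_time_ms
            start = int(round(t_abs_ms / 1000.0 * sampling_rate_hz))
            stop = min(start + template.size, n_samples)
            if start >= n_samples:
                continue
            d = np.hypot(
                positions[:, 0] - unit.position_um[0],
                positions[:, 1] - unit.position_um[1],
            )
            near = np.nonzero(d < 40.0)[0]
            for ch in near:
                gain = np.exp(-0.5 * (d[ch] / 20.0) ** 2)
                traces[ch, start:stop] += gain * template[: stop - start]

    # --- modality-specific artifact -------------------------------------------
    time_s = np.arange(n_samples) / sampling_rate_hz
    reset_times = np.array([], dtype=int)
    if not include_artifact:
        pass
    elif protocol.modality is Modality.ELECTRICAL:
        stim_pos = geometry.stim_positions()
        carrier = np.sin(2 * np.pi * protocol.carrier_frequency_hz * time_s)
        for phase in (1, 2):
            active = grating_phase_mask(
                stim_pos, protocol.bar_width_um, phase, protocol.grating_orientation
            )
            active_pos = stim_pos[active]
            if len(active_pos) == 0:
                continue
            dists = np.min(
                np.hypot(
                    positions[:, None, 0] - active_pos[None, :, 0],
                    positions[:, None, 1] - active_pos[None, :, 1],
                ),
                axis=1,
            )
            amp = (protocol.carrier_amplitude_vpp / 2.0) * 1e-2 * np.exp(-dists / 50.0)
            window = protocol.phase_window(phase)
            mask = np.zeros(n_samples, dtype=bool)
            for rep in range(protocol.n_repetitions):
                a = int(round((rep * protocol.period_ms + window[0]) / 1000 * sampling_rate_hz))
                b = int(round((rep * protocol.period_ms + window[1]) / 1000 * sampling_rate_hz))
                mask[a : min(b, n_samples)] = True
            traces += amp[:, None] * (carrier * mask)[None, :]
    else:
        # sawtooth drift reset to baseline at every sensor reset; a reset also
        # occurs at t=0 (acquisition starts with a reset)
        interval = int(round(reset_interval_ms / 1000.0 * sampling_rate_hz))
        reset_times = np.arange(0, n_samples, interval, dtype=int)
        n_reset = max(1, int(round(200e-6 * sampling_rate_hz)))
        phase_in_cycle = (np.arange(n_samples) % interval) / interval
        drift = drift_amplitude_v * phase_in_cycle
        transient = np.zeros(n_samples)
        for r in reset_times:
            seg = np.arange(r, min(r + n_reset, n_samples))
            transient[seg] = reset_amplitude_v * np.where(np.arange(seg.size) % 2 == 0, 1.0, -1.0)
        traces += (drift + transient)[None, :]

    return RawRecording(
        traces=traces,
        sampling_rate_hz=sampling_rate_hz,
        channel_positions_um=positions,
        reset_times=reset_times,
        reset_duration_us=200.0,
    )


def empirical_rfr(spike_trains: SpikeTrainSet, unit_id: int) -> float:
    """Empirical RFR of one simulated unit (diagnostic helper)."""
    df = spike_trains.for_unit(unit_id)
    n1 = int((df["phase_label"] == "phase1").sum())
    n2 = int((df["phase_label"] == "phase2").sum())
    if n1 + n2 == 0:
        return 0.0
    return (n1 - n2) / (n1 + n2)
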