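"""Band filtering and stimulus-artifact removal for raw MEA voltage traces.

Two fixed filter chains are used depending on the stimulation modality:

* optogenetic: 2nd-order high-pass Bessel at 200 Hz followed by a 2nd-order
  low-pass Bessel at 5 kHz;
* electrical: 4th-order high-pass Butterworth at 1 kHz followed by a 2nd-order
  low-pass Bessel at 3 kHz (the high cut suppresses the 40 Hz carrier artifact
  by many orders of magnitude while keeping the 1-3 kHz spike band).

Optogenetic recordings additionally suffer slow sensor drift under intense
blue light; the acquisition system resets the sensors every 400 ms (200 us
reset), leaving a sharp artifact.  ``remove_sensor_reset_artifacts`` removes
both: per inter-reset segment a drift curve (2nd-order Savitzky-Golay, 800 us
window) is subtracted, the result is high-pass filtered (2nd-order Butterworth,
100 Hz) and the reset samples themselves are replaced by noise resampled from
a quiescent stretch of the same channel.

All filters are applied forward-backward (zero phase) so spike timing relative
to the stimulus phase windows is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .simulate import RawRecording
from .stimulus import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    family: str  # bessel | butterworth | savitzky_golay
    order: int
    kind: str  # highpass | lowpass | smoother
    cutoff_hz: float | None = None
    window_us: float | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")


@dataclass
class FilteredRecording:
    traces: np.ndarray
    sampling_rate_hz: float
    provenance: tuple[FilterSpec, ...]
    reset_samples_replaced: bool = False


OPTO_CHAIN = (
    FilterSpec("bessel", 2, "highpass", cutoff_hz=200.0),
    FilterSpec("bessel", 2, "lowpass", cutoff_hz=5000.0),
)
ELECTRICAL_CHAIN = (
    FilterSpec("butterworth", 4, "highpass", cutoff_hz=1000.0),
    FilterSpec("bessel", 2, "lowpass", cutoff_hz=3000.0),
)


def design_sos(spec: FilterSpec, sampling_rate_hz: float) -> np.ndarray:
    """Realize an analog filter spec as digital second-order sections.

    Analog prototypes are mapped by the bilinear transform (scipy's default
    digital design); Bessel filters use phase-preserving norm so the nominal
    cutoff matches the analog -3 dB point closely in the passband.
    """
    nyq = sampling_rate_hz / 2.0
    if spec.cutoff_hz is None or spec.cutoff_hz >= nyq:
        raise ConfigurationError(
            f"cutoff {spec.cutoff_hz} Hz not below Nyquist {nyq} Hz"
        )
    btype = {"highpass": "highpass", "lowpass": "lowpass"}[spec.kind]
    wn = spec.cutoff_hz / nyq
    if spec.family == "bessel":
        return sps.bessel(spec.order, wn, btype=btype, norm="mag", output="sos")
    if spec.family == "butterworth":
        return sps.butter(spec.order, wn, btype=btype, output="sos")
    raise ConfigurationError(f"unknown filter family {spec.family!r}")


def apply_chain(
    traces: np.ndarray, chain: tuple[FilterSpec, ...], sampling_rate_hz: float
) -> np.ndarray:
    """Apply a sequence of IIR filters, zero-phase, along the sample axis."""
    out = np.asarray(traces, dtype=float)
    for spec in chain:
        sos = design_sos(spec, sampling_rate_hz)
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return out


def chain_frequency_response(
    chain: tuple[FilterSpec, ...], sampling_rate_hz: float, freqs_hz: np.ndarray
) -> np.ndarray:
    """|H(f)| of the composed chain as applied (zero-phase => magnitude squared)."""
    gain = np.ones_like(np.asarray(freqs_hz, dtype=float))
    for spec in chain:
        sos = design_sos(spec, sampling_rate_hz)
        _, h = sps.sosfreqz(sos, worN=freqs_hz, fs=sampling_rate_hz)
        gain *= np.abs(h) ** 2  # forward-backward application
    return gain


def filter_optogenetic_chain(rec: RawRecording) -> FilteredRecording:
    """200 Hz HP + 5 kHz LP Bessel chain (both 2nd order)."""
    if rec.sampling_rate_hz <= 10_000:
        raise ConfigurationError("optogenetic chain needs sampling rate > 10 kHz")
    out = apply_chain(rec.traces, OPTO_CHAIN, rec.sampling_rate_hz)
    return FilteredRecording(out, rec.sampling_rate_hz, OPTO_CHAIN)


def filter_electrical_chain(rec: RawRecording) -> FilteredRecording:
    """1 kHz HP Butterworth (4th order) + 3 kHz LP Bessel (2nd order) chain."""
    if rec.sampling_rate_hz <= 6_000:
        raise ConfigurationError("electrical chain needs sampling rate > 6 kHz")
    out = apply_chain(rec.traces, ELECTRICAL_CHAIN, rec.sampling_rate_hz)
    return FilteredRecording(out, rec.sampling_rate_hz, ELECTRICAL_CHAIN)


def _odd_window_samples(window_us: float, sampling_rate_hz: float) -> int:
    w = int(round(window_us * 1e-6 * sampling_rate_hz))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def _quiescent_noise_donor(
    trace: np.ndarray, sampling_rate_hz: float, exclude: np.ndarray, span_ms: float = 50.0
) -> np.ndarray:
    """Return the ~50 ms stretch of the channel with the lowest variance.

    Reset windows (``exclude`` mask) are skipped when scoring, so the donor
    contains only ongoing noise/spiking activity.
    """
    span = max(4, int(round(span_ms / 1000.0 * sampling_rate_hz)))
    n = trace.size
    if n <= span:
        return trace[~exclude] if (~exclude).any() else trace
    starts = np.arange(0, n - span, max(1, span // 2))
    best, best_var = None, np.inf
    for s in starts:
        seg = slice(s, s + span)
        if exclude[seg].any():
            continue
        v = float(np.var(trace[seg]))
        if v < best_var:
            best, best_var = seg, v
    if best is None:
        keep = trace[~exclude]
        return keep if keep.size else trace
    return trace[best]


def remove_sensor_reset_artifacts(
    rec: RawRecording,
    smoother_window_us: float = 800.0,
    highpass_hz: float = 100.0,
    seed: int = 0,
) -> RawRecording:
    """Remove slow drift and 200 us sensor-reset transients from raw traces.

    Per channel: the trace is split at the reset times; each inter-reset
    segment has its drift curve (2nd-order Savitzky-Golay, 800 us window)
    subtracted; reset-window samples are blanked before the 100 Hz 2nd-order
    Butterworth high-pass so the transient cannot ring into its neighbourhood;
    finally the blanked samples are replaced by noise drawn (with replacement,
    seeded) from the quietest 50 ms of the same channel.
    """
    fs = rec.sampling_rate_hz
    window = _odd_window_samples(smoother_window_us, fs)
    n = rec.n_samples
    n_reset = rec.reset_duration_samples
    reset_times = np.asarray(rec.reset_times, dtype=int)
    if reset_times.size and np.any(np.diff(reset_times) <= 0):
        raise ConfigurationError("reset_times must be strictly increasing")

    reset_mask = np.zeros(n, dtype=bool)
    for r in reset_times:
        reset_mask[r : min(r + n_reset, n)] = True

    boundaries = np.concatenate([[0], reset_times + n_reset, [n]])
    seg_ends = np.concatenate([reset_times, [n]])

    rng = np.random.default_rng(seed)
    out = np.array(rec.traces, dtype=float, copy=True)
    hp_sos = sps.butter(2, highpass_hz / (fs / 2.0), btype="highpass", output="sos")

    for ch in range(out.shape[0]):
        trace = out[ch]
        # drift subtraction per inter-reset segment
        for a, b in zip(boundaries[: seg_ends.size], seg_ends):
            a, b = int(a), int(b)
            if b - a <= 0:
                continue
            if b - a <= window:
                log.warning(
                    "segment [%d, %d) shorter than smoother window; drift step skipped",
                    a,
                    b,
                )
                continue
            drift = sps.savgol_filter(trace[a:b], window, polyorder=2, mode="interp")
            trace[a:b] -= drift
        # blank reset transients before the high-pass to avoid ringing
        trace[reset_mask] = 0.0
        trace[:] = sps.sosfiltfilt(hp_sos, trace)
        if reset_times.size:
            donor = _quiescent_noise_donor(trace, fs, reset_mask)
            k = int(reset_mask.sum())
            if donor.size:
                trace[reset_mask] = donor[rng.integers(0, donor.size, k)]

    return replace(rec, traces=out)
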