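"""Stimulation geometry and grating pattern-reversal protocols.

The hardware being emulated is a high-density CMOS microelectrode array with a
65 x 65 grid of recording sites (16 um pitch) interleaved with a 32 x 32 grid of
capacitive stimulation electrodes (32 um pitch), covering roughly 1 x 1 mm of
retina.  Stimuli are alternating spatial gratings: two complementary striped
patterns ("phase 1" / "phase 2") presented in alternation, either as a 40 Hz
sinusoidal electrical carrier or as patterned light driving channelrhodopsin.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class Modality(str, Enum):
    ELECTRICAL = "electrical"
    OPTOGENETIC = "optogenetic"


class ConfigurationError(ValueError):
    """Raised when a geometry, protocol or population spec is inconsistent."""


@dataclass(frozen=True)
class GeometrySpec:
    """Recording / stimulation array geometry.

    Defaults match a CMOS-MEA with 65x65 recording sites at 16 um pitch and a
    32x32 stimulation grid at 32 um pitch inside the same ~1 mm square.
    """

    n_recording_rows: int = 65
    n_recording_cols: int = 65
    recording_pitch_um: float = 16.0
    n_stim_rows: int = 32
    n_stim_cols: int = 32
    stim_pitch_um: float = 32.0

    def __post_init__(self) -> None:
        if self.recording_pitch_um <= 0 or self.stim_pitch_um <= 0:
            raise ConfigurationError("array pitches must be positive")
        if (self.n_stim_cols - 1) * self.stim_pitch_um > self.extent_um[0] or (
            self.n_stim_rows - 1
        ) * self.stim_pitch_um > self.extent_um[1]:
            raise ConfigurationError("stimulation grid exceeds recording extent")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the recording area in micrometres."""
        return (
            (self.n_recording_cols - 1) * self.recording_pitch_um,
            (self.n_recording_rows - 1) * self.recording_pitch_um,
        )

    def recording_positions(self) -> np.ndarray:
        """(n_sites, 2) array of recording-site x/y positions in um."""
        xs = np.arange(self.n_recording_cols) * self.recording_pitch_um
        ys = np.arange(self.n_recording_rows) * self.recording_pitch_um
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def stim_positions(self) -> np.ndarray:
        """(n_electrodes, 2) array of stimulation-electrode positions in um."""
        xs = np.arange(self.n_stim_cols) * self.stim_pitch_um
        ys = np.arange(self.n_stim_rows) * self.stim_pitch_um
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and pattern of one grating pattern-reversal experiment.

    ``phase1_window_ms`` / ``phase2_window_ms`` are intervals relative to the
    start of each repetition; ``period_ms`` is the full repetition length.
    Electrical runs use two 100 ms bursts of a 40 Hz sinusoidal carrier
    (phase 1 at 0-100 ms, phase 2 at 350-450 ms) separated by gaps; optogenetic
    runs reverse the pattern every half reversal cycle (200 ms at 2.5 Hz).
    """

    modality: Modality
    bar_width_um: float
    n_repetitions: int
    phase1_window_ms: tuple[float, float]
    phase2_window_ms: tuple[float, float]
    period_ms: float
    reversal_frequency_hz: float | None = None
    inter_stimulus_gap_ms: float = 250.0
    carrier_frequency_hz: float = 40.0
    carrier_amplitude_vpp: float = 2.5
    charge_density_uc_cm2: float = 15.0
    grating_orientation: str = "columns"

    def __post_init__(self) -> None:
        if self.bar_width_um <= 0:
            raise ConfigurationError("bar width must be positive")
        if self.n_repetitions < 1:
            raise ConfigurationError("need at least one repetition")
        for w in (self.phase1_window_ms, self.phase2_window_ms):
            if w[1] <= w[0]:
                raise ConfigurationError(f"zero/negative-duration phase window {w}")
        if not (
            self.phase1_window_ms[1] <= self.phase2_window_ms[0]
            or self.phase2_window_ms[1] <= self.phase1_window_ms[0]
        ):
            raise ConfigurationError("phase windows must be disjoint")
        if self.period_ms < max(self.phase1_window_ms[1], self.phase2_window_ms[1]):
            raise ConfigurationError("period shorter than phase windows")

    @property
    def phase_duration_ms(self) -> float:
        return self.phase1_window_ms[1] - self.phase1_window_ms[0]

    def phase_window(self, phase: int) -> tuple[float, float]:
        if phase == 1:
            return self.phase1_window_ms
        if phase == 2:
            return self.phase2_window_ms
        raise ValueError(f"phase must be 1 or 2, got {phase}")

    @property
    def total_duration_ms(self) -> float:
        return self.period_ms * self.n_repetitions


def electrical_protocol(
    bar_width_um: float = 32.0, n_repetitions: int = 60, **kwargs
) -> StimulusProtocol:
    """Electrical grating reversal: 40 Hz carrier, 100 ms phase windows.

    Phase 1 occupies 0-100 ms and phase 2 350-450 ms of each repetition,
    followed by a 250 ms inter-stimulus gap (700 ms period).
    """
    gap = kwargs.pop("inter_stimulus_gap_ms", 250.0)
    return StimulusProtocol(
        modality=Modality.ELECTRICAL,
        bar_width_um=bar_width_um,
        n_repetitions=n_repetitions,
        phase1_window_ms=(0.0, 100.0),
        phase2_window_ms=(350.0, 450.0),
        period_ms=450.0 + gap,
        inter_stimulus_gap_ms=gap,
        **kwargs,
    )


def optogenetic_protocol(
    bar_width_um: float = 30.0,
    reversal_frequency_hz: float = 2.5,
    n_repetitions: int = 60,
    **kwargs,
) -> StimulusProtocol:
    """Optogenetic grating reversal at 2.5 or 10 Hz.

    One full reversal cycle lasts ``1 / reversal_frequency``; each half cycle
    shows one grating phase (200 ms per phase at 2.5 Hz, 50 ms at 10 Hz).
    """
    if reversal_frequency_hz <= 0:
        raise ConfigurationError("reversal frequency must be positive")
    half_ms = 1000.0 / (2.0 * reversal_frequency_hz)
    return StimulusProtocol(
        modality=Modality.OPTOGENETIC,
        bar_width_um=bar_width_um,
        n_repetitions=n_repetitions,
        phase1_window_ms=(0.0, half_ms),
        phase2_window_ms=(half_ms, 2 * half_ms),
        period_ms=2 * half_ms,
        reversal_frequency_hz=reversal_frequency_hz,
        inter_stimulus_gap_ms=0.0,
        **kwargs,
    )


def grating_phase_mask(
    positions: np.ndarray, bar_width_um: float, phase: int, orientation: str = "columns"
) -> np.ndarray:
    """Boolean mask of which positions lie on active bars in a given phase.

    The grating is a square wave of period ``2 * bar_width_um``; phase 2 is the
    complement of phase 1 (pattern reversal).
    """
    axis = 0 if orientation == "columns" else 1
    band = np.floor(positions[:, axis] / bar_width_um).astype(int) % 2
    active = band == 0
    return active if phase == 1 else ~active
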