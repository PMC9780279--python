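"""Unit curation, per-phase firing-rate matrices and the RFR selectivity index.

A sorted unit survives curation when its spike-sorting quality metrics meet
the thresholds used on the original recordings: IsoIBG must be a number (the
sorter assigns NaN when only a single waveform cluster was found),
separability >= 2.5, and — for electrical stimulation recordings only — SNR
within [3.3, 14].  Boundary values are inclusive.

The decoder's feature space is the firing-rate matrix: one row per
(repetition, phase), one column per unit, each entry the spike count inside
that phase window divided by the window duration (Hz).  Inter-stimulus
intervals never enter the matrix.

Per-unit phase selectivity is summarised by the relative change in firing
rate, RFR = (FR1 - FR2) / (FR1 + FR2), where FR_k is the mean rate over
repetitions of phase k.  RFR is 1 for activity exclusive to phase 1, -1 for
phase 2, and undefined (reported as 0 with a flag) when both means are zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SpikeTrainSet, UnitGroundTruth
from .stimulus import StimulusProtocol
from .dip import dip_test

log = logging.getLogger(__name__)

PHASES = ("phase1", "phase2")


@dataclass
class SortedUnit:
    """A spike-sorted putative RGC with QC metadata."""

    unit_id: int
    spike_times_ms: dict  # (repetition_index, phase_label) -> array of times
    qc: dict  # isoibg (may be NaN), separability, snr
    position_um: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class CurationThresholds:
    separability_min: float = 2.5
    snr_range: tuple[float, float] = (3.3, 14.0)
    require_isoibg: bool = True
    apply_snr: bool = False  # electrical recordings only


@dataclass
class FiringRateMatrix:
    values: np.ndarray  # (2 * n_repetitions) x n_units, Hz
    phase_labels: np.ndarray  # row labels, "phase1" / "phase2"
    repetition_index: np.ndarray
    unit_ids: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"unit_{u}" for u in self.unit_ids])
        df.insert(0, "phase_label", self.phase_labels)
        df.insert(0, "repetition_index", self.repetition_index)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FiringRateMatrix":
        unit_cols = [c for c in df.columns if c.startswith("unit_")]
        return cls(
            values=df[unit_cols].to_numpy(dtype=float),
            phase_labels=df["phase_label"].to_numpy(),
            repetition_index=df["repetition_index"].to_numpy(dtype=int),
            unit_ids=tuple(int(c.removeprefix("unit_")) for c in unit_cols),
        )


@dataclass
class RFRTable:
    unit_ids: tuple[int, ...]
    rfr: np.ndarray
    mean_rate_phase1_hz: np.ndarray
    mean_rate_phase2_hz: np.ndarray
    undefined: np.ndarray  # True where both phase means were zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "rfr": self.rfr,
                "mean_rate_phase1_hz": self.mean_rate_phase1_hz,
                "mean_rate_phase2_hz": self.mean_rate_phase2_hz,
                "undefined": self.undefined,
            }
        )


def sorted_units_from_ground_truth(
    units: list[UnitGroundTruth], spike_trains: SpikeTrainSet
) -> list[SortedUnit]:
    """Bundle ground-truth spike trains into the curation-facing unit type."""
    out = []
    grouped: dict[int, dict] = {u.unit_id: {} for u in units}
    for (uid, rep, label), g in spike_trains.spikes.groupby(
        ["unit_id", "repetition_index", "phase_label"]
    ):
        grouped[uid][(int(rep), str(label))] = g["spike_time_ms"].to_numpy()
    for u in units:
        out.append(
            SortedUnit(
                unit_id=u.unit_id,
                spike_times_ms=grouped.get(u.unit_id, {}),
                qc=dict(u.qc),
                position_um=u.position_um,
            )
        )
    return out


def curate_units(
    units: list[SortedUnit], thresholds: CurationThresholds | None = None
) -> list[SortedUnit]:
    """Keep units passing the QC thresholds; order preserved, counts logged."""
    th = thresholds or CurationThresholds()
    removed = {"isoibg": 0, "separability": 0, "snr": 0}
    survivors = []
    for u in units:
        isoibg = u.qc.get("isoibg", float("nan"))
        if th.require_isoibg and (isoibg is None or np.isnan(isoibg)):
            removed["isoibg"] += 1
            continue
        if u.qc.get("separability", -np.inf) < th.separability_min:
            removed["separability"] += 1
            continue
        if th.apply_snr:
            snr = u.qc.get("snr", np.nan)
            if not (th.snr_range[0] <= snr <= th.snr_range[1]):
                removed["snr"] += 1
                continue
        survivors.append(u)
    log.info(
        "curation: kept %d / %d units (removed: %s)", len(survivors), len(units), removed
    )
    if not survivors:
        log.warning("curation removed every unit")
    return survivors


def build_rate_matrix(
    units: list[SortedUnit], protocol: StimulusProtocol
) -> FiringRateMatrix:
    """Count spikes per phase window / duration -> (2 * reps) x units matrix.

    Rows are ordered (repetition 0 phase1, repetition 0 phase2, repetition 1
    phase1, ...); silent units keep their all-zero column.
    """
    n_rep = protocol.n_repetitions
    durations_s = {
        label: (protocol.phase_window(k)[1] - protocol.phase_window(k)[0]) / 1000.0
        for k, label in ((1, "phase1"), (2, "phase2"))
    }
    n_rows = 2 * n_rep
    values = np.zeros((n_rows, len(units)))
    phase_labels = np.empty(n_rows, dtype=object)
    rep_index = np.zeros(n_rows, dtype=int)
    for r in range(n_rep):
        for j, label in enumerate(PHASES):
            row = 2 * r + j
            phase_labels[row] = label
            rep_index[row] = r
            for c, u in enumerate(units):
                times = u.spike_times_ms.get((r, label), ())
                values[row, c] = len(times) / durations_s[label]
    return FiringRateMatrix(
        values=values,
        phase_labels=phase_labels.astype(str),
        repetition_index=rep_index,
        unit_ids=tuple(u.unit_id for u in units),
    )


def compute_rfr(matrix: FiringRateMatrix) -> RFRTable:
    """Per-unit RFR from phase-mean firing rates."""
    if matrix.values.size == 0:
        raise ValueError("empty firing-rate matrix")
    is_p1 = matrix.phase_labels == "phase1"
    fr1 = matrix.values[is_p1].mean(axis=0)
    fr2 = matrix.values[~is_p1].mean(axis=0)
    total = fr1 + fr2
    undefined = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rfr = np.where(undefined, 0.0, (fr1 - fr2) / np.where(undefined, 1.0, total))
    return RFRTable(
        unit_ids=matrix.unit_ids,
        rfr=rfr,
        mean_rate_phase1_hz=fr1,
        mean_rate_phase2_hz=fr2,
        undefined=undefined,
    )


def rfr_dip_test(
    rfr_values: np.ndarray, n_bootstrap: int = 500, seed: int = 0
) -> dict:
    """Hartigan dip test of the RFR distribution against unimodality.

    Returns ``{"dip_statistic", "p_value", "n", "computable"}``; the p-value is
    a bootstrap tail probability under the uniform null.  Fewer than 10 defined
    values yields an explicit not-computable result.
    """
    x = np.asarray(rfr_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        return {
            "dip_statistic": float("nan"),
            "p_value": float("nan"),
            "n": int(x.size),
            "computable": False,
        }
    stat, p = dip_test(x, n_bootstrap=n_bootstrap, seed=seed)
    return {
        "dip_statistic": stat,
        "p_value": p,
        "n": int(x.size),
        "computable": True,
    }
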