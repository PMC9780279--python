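"""On-disk fixture bundles: protocol + ground truth + spike trains (+ raw).

Layout of a bundle directory::

    manifest.json      protocol, seed, per-unit ground truth
    spike_trains.csv   unit_id, repetition_index, phase_label, spike_time_ms
    raw_traces.bin     optional; little-endian float32, channel-major
    raw_header.json    optional; sampling rate, channel positions, resets

Writes are atomic: everything is staged in a temporary sibling directory and
renamed into place, so a failed write never leaves a stale partial bundle.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    PopulationSpec,
    RawRecording,
    SpikeTrainSet,
    UnitGroundTruth,
    generate_population,
    simulate_spike_trains,
    synthesize_raw_recording,
)
from .stimulus import GeometrySpec, Modality, StimulusProtocol

SPIKE_COLUMNS = ["unit_id", "repetition_index", "phase_label", "spike_time_ms"]


def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    d = asdict(protocol)
    d["modality"] = protocol.modality.value
    return d


def protocol_from_dict(d: dict) -> StimulusProtocol:
    d = dict(d)
    d["modality"] = Modality(d["modality"])
    for key in ("phase1_window_ms", "phase2_window_ms"):
        d[key] = tuple(d[key])
    return StimulusProtocol(**d)


def _unit_to_dict(u: UnitGroundTruth) -> dict:
    d = asdict(u)
    d["qc"] = {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in u.qc.items()}
    return d


def _unit_from_dict(d: dict) -> UnitGroundTruth:
    qc = {k: (float("nan") if v is None else v) for k, v in d["qc"].items()}
    return UnitGroundTruth(
        unit_id=d["unit_id"],
        position_um=tuple(d["position_um"]),
        true_rfr=d["true_rfr"],
        phase_rates_hz=tuple(d["phase_rates_hz"]),
        qc=qc,
        axon_path_um=tuple(tuple(p) for p in d.get("axon_path_um", ())),
    )


def write_raw_recording(rec: RawRecording, bin_path: Path, header_path: Path) -> None:
    bin_path.write_bytes(rec.traces.astype("<f4").tobytes())
    header = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
        "channel_positions_um": rec.channel_positions_um.tolist(),
        "reset_times": np.asarray(rec.reset_times).tolist(),
        "reset_duration_us": rec.reset_duration_us,
    }
    header_path.write_text(json.dumps(header, indent=1))


def read_raw_recording(bin_path: Path, header_path: Path) -> RawRecording:
    header = json.loads(Path(header_path).read_text())
    data = np.frombuffer(Path(bin_path).read_bytes(), dtype="<f4").astype(float)
    traces = data.reshape(header["n_channels"], header["n_samples"])
    return RawRecording(
        traces=traces,
        sampling_rate_hz=header["sampling_rate_hz"],
        channel_positions_um=np.asarray(header["channel_positions_um"], dtype=float),
        reset_times=np.asarray(header["reset_times"], dtype=int),
        reset_duration_us=header["reset_duration_us"],
    )


def make_fixture_bundle(
    out_dir: str | Path,
    protocol: StimulusProtocol,
    population: PopulationSpec,
    geometry: GeometrySpec | None = None,
    include_raw: bool = False,
    noise_sd_v: float = 20e-6,
    sampling_rate_hz: float = 20_000.0,
) -> Path:
    """Generate a population + spike trains (+ optional raw traces) and write
    them as a bundle directory.  Returns the bundle path."""
    out_dir = Path(out_dir)
    geometry = geometry or GeometrySpec()
    units = generate_population(population, geometry)
    if units:
        trains = simulate_spike_trains(units, protocol, seed=population.seed + 1)
    else:
        empty = pd.DataFrame(columns=SPIKE_COLUMNS).astype(
            {"unit_id": int, "repetition_index": int, "phase_label": str, "spike_time_ms": float}
        )
        trains = SpikeTrainSet(spikes=empty, protocol=protocol, unit_ids=())

    parent = out_dir.parent
    parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(dir=parent, prefix=".staging-"))
    try:
        manifest = {
            "protocol": protocol_to_dict(protocol),
            "seed": population.seed,
            "n_units": population.n_units,
            "empty": len(trains.spikes) == 0,
            "units": [_unit_to_dict(u) for u in units],
        }
        (staging / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        # %.17g guarantees bit-exact float64 round-trips through text
        trains.spikes.to_csv(staging / "spike_trains.csv", index=False, float_format="%.17g")
        if include_raw:
            rec = synthesize_raw_recording(
                trains,
                units,
                protocol,
                geometry,
                noise_sd_v=noise_sd_v,
                seed=population.seed + 2,
                sampling_rate_hz=sampling_rate_hz,
            )
            write_raw_recording(rec, staging / "raw_traces.bin", staging / "raw_header.json")
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(staging, out_dir)
    finally:
        if staging.exists():
            shutil.rmtree(staging, ignore_errors=True)
    return out_dir


def load_bundle(bundle_dir: str | Path) -> dict:
    """Read a bundle back; spike trains round-trip bit-exactly through CSV."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    protocol = protocol_from_dict(manifest["protocol"])
    units = [_unit_from_dict(d) for d in manifest["units"]]
    spikes = pd.read_csv(
        bundle_dir / "spike_trains.csv",
        dtype={
            "unit_id": int,
            "repetition_index": int,
            "phase_label": str,
            "spike_time_ms": float,
        },
        float_precision="round_trip",
    )
    out = {
        "manifest": manifest,
        "protocol": protocol,
        "units": units,
        "spike_trains": SpikeTrainSet(
            spikes=spikes, protocol=protocol, unit_ids=tuple(u.unit_id for u in units)
        ),
    }
    if (bundle_dir / "raw_traces.bin").exists():
        out["raw"] = read_raw_recording(
            bundle_dir / "raw_traces.bin", bundle_dir / "raw_header.json"
        )
    return out
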