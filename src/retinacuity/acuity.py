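"""End-to-end acuity pipeline: grating width grid -> f1 curve -> threshold.

For each grating bar width the pipeline generates (or loads) a recording,
curates units, builds the per-phase firing-rate matrix, summarises per-unit
selectivity (RFR + dip test of the RFR distribution), decodes the phase with
the cross-validated SVM, and records the mean f1.  The resulting f1-vs-width
curve is the primary output; a configurable criterion (default 0.75, midway
between chance 0.5 and perfect 1.0) turns it into an acuity threshold — the
smallest bar width from which decoding stays above criterion.

Bar widths convert to cycles per degree via the retinal magnification factor
M (um of retina per degree of visual angle): one grating cycle spans two bar
widths, so cpd = M / (2 w).  The default M = 35 um/deg reproduces the
printed equivalences 10 um = 1.75 cpd and 32 um = 0.54 cpd.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .decoding import (
    DecoderConfig,
    DecodingDataset,
    DecodingResult,
    cross_validated_decode,
    feature_importance,
)
from .simulate import PopulationSpec, RFRMixture, generate_population, simulate_spike_trains
from .stimulus import ConfigurationError, GeometrySpec, Modality, electrical_protocol, optogenetic_protocol
from .units import (
    CurationThresholds,
    build_rate_matrix,
    compute_rfr,
    curate_units,
    rfr_dip_test,
    sorted_units_from_ground_truth,
)

log = logging.getLogger(__name__)

DEFAULT_MAGNIFICATION_UM_PER_DEG = 35.0
OPTO_WIDTHS_UM = (5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 500.0)
ELECTRICAL_WIDTHS_UM = (32.0, 64.0, 128.0)


def saturating_selectivity(
    r_max: float = 0.8, w_scale_um: float = 15.0
) -> Callable[[float], float]:
    """Selectivity magnitude grows with bar width and saturates at ``r_max``.

    Models the loss of differential activation once bars shrink below the
    spatial scale of a cell's activation zone: r(w) = r_max (1 - exp(-w/s)).
    """
    return lambda w: r_max * (1.0 - math.exp(-w / w_scale_um))


def step_selectivity(w_star_um: float, r_high: float = 0.8) -> Callable[[float], float]:
    """Zero selectivity below ``w_star_um``, constant ``r_high`` at and above."""
    return lambda w: r_high if w >= w_star_um else 0.0


def constant_selectivity(r: float) -> Callable[[float], float]:
    return lambda w: r


@dataclass(frozen=True)
class PipelineConfig:
    modality: Modality = Modality.OPTOGENETIC
    widths_um: tuple[float, ...] | None = None  # None => modality default grid
    reversal_frequency_hz: float = 2.5
    n_units: int = 40
    n_repetitions: int = 60
    base_rate_hz: float = 8.0
    mixture_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    selectivity: Callable[[float], float] = field(default_factory=saturating_selectivity)
    seed: int = 0
    curation: CurationThresholds | None = None
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    dip_bootstrap: int = 200
    criterion: float = 0.75
    compute_importance: bool = False

    def resolved_widths(self) -> tuple[float, ...]:
        if self.widths_um is not None:
            widths = self.widths_um
        elif self.modality is Modality.ELECTRICAL:
            widths = ELECTRICAL_WIDTHS_UM
        else:
            widths = OPTO_WIDTHS_UM
        if self.modality is Modality.ELECTRICAL:
            for w in widths:
                if w % 32.0 != 0:
                    raise ConfigurationError(
                        f"electrical grating width {w} um is not a multiple of "
                        "the 32 um stimulation-electrode pitch"
                    )
        return tuple(sorted(widths))


@dataclass
class AcuityCurve:
    entries: list[dict]  # sorted by width
    criterion: float
    threshold_width_um: float | None

    def to_dict(self) -> dict:
        return {
            "entries": self.entries,
            "criterion": self.criterion,
            "threshold_width_um": self.threshold_width_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcuityCurve":
        return cls(
            entries=list(d["entries"]),
            criterion=d["criterion"],
            threshold_width_um=d["threshold_width_um"],
        )


@dataclass
class PipelineResult:
    curve: AcuityCurve
    rfr_tables: dict  # width -> RFRTable
    dip_results: dict  # width -> dict
    decoding_results: dict  # width -> DecodingResult
    unit_positions: dict  # width -> (n_units, 2) array


def width_to_cpd(
    bar_width_um: float,
    magnification_um_per_deg: float = DEFAULT_MAGNIFICATION_UM_PER_DEG,
) -> float:
    """Cycles per degree of a grating with the given bar width.

    One cycle = two bar widths, so cpd = magnification / (2 * bar_width).
    """
    if bar_width_um <= 0 or magnification_um_per_deg <= 0:
        raise ConfigurationError("bar width and magnification must be positive")
    return magnification_um_per_deg / (2.0 * bar_width_um)


def cpd_printed(cpd: float) -> float:
    """Reported cpd values are truncated (not rounded) to two decimals."""
    return math.floor(cpd * 100.0) / 100.0


def acuity_threshold(curve: AcuityCurve, criterion: float | None = None) -> float | None:
    """Smallest width from which every width meets the f1 criterion."""
    criterion = curve.criterion if criterion is None else criterion
    threshold = None
    for entry in sorted(curve.entries, key=lambda e: e["bar_width_um"], reverse=True):
        f1 = entry.get("f1_mean")
        if f1 is None or not np.isfinite(f1) or f1 < criterion:
            break
        threshold = entry["bar_width_um"]
    return threshold


def _decode_one_width(
    width: float, config: PipelineConfig, seed: int
) -> tuple[dict, object, dict, DecodingResult, np.ndarray]:
    r = float(np.clip(config.selectivity(width), -1.0, 1.0))
    w0, wp, wn = config.mixture_weights
    pop_spec = PopulationSpec(
        n_units=config.n_units,
        rfr_mixture=RFRMixture(w0, wp, wn, r),
        base_rate_hz=config.base_rate_hz,
        seed=seed,
    )
    if config.modality is Modality.ELECTRICAL:
        protocol = electrical_protocol(bar_width_um=width, n_repetitions=config.n_repetitions)
    else:
        protocol = optogenetic_protocol(
            bar_width_um=width,
            reversal_frequency_hz=config.reversal_frequency_hz,
            n_repetitions=config.n_repetitions,
        )
    units = generate_population(pop_spec)
    trains = simulate_spike_trains(units, protocol, seed=seed + 1)
    sorted_units = sorted_units_from_ground_truth(units, trains)
    thresholds = config.curation or CurationThresholds(
        apply_snr=config.modality is Modality.ELECTRICAL
    )
    kept = curate_units(sorted_units, thresholds)
    log.info("width %g um: %d/%d units survive curation", width, len(kept), len(units))

    entry = {
        "bar_width_um": width,
        "modality": config.modality.value,
        "reversal_frequency_hz": (
            config.reversal_frequency_hz if config.modality is Modality.OPTOGENETIC else None
        ),
        "cpd": cpd_printed(width_to_cpd(width)),
        "n_units": len(kept),
        "n_repetitions": config.n_repetitions,
        "true_selectivity": r,
    }
    if not kept:
        entry.update({"f1_mean": None, "f1_sd": None})
        return entry, None, {}, None, np.empty((0, 2))

    matrix = build_rate_matrix(kept, protocol)
    rfr = compute_rfr(matrix)
    dip = rfr_dip_test(rfr.rfr, n_bootstrap=config.dip_bootstrap, seed=seed)
    ds = DecodingDataset(
        X=matrix.values,
        y=(matrix.phase_labels == "phase1").astype(int),
        unit_ids=matrix.unit_ids,
    )
    decoder_cfg = dataclasses.replace(config.decoder, seed=seed)
    result = cross_validated_decode(ds, decoder_cfg)
    if config.compute_importance:
        result.importance = feature_importance(ds, decoder_cfg)
    entry.update(
        {
            "f1_mean": result.f1_mean,
            "f1_sd": result.f1_sd,
            "dip_statistic": dip["dip_statistic"] if dip["computable"] else None,
            "dip_p_value": dip["p_value"] if dip["computable"] else None,
        }
    )
    positions = np.array([u.position_um for u in kept])
    return entry, rfr, dip, result, positions


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run generate -> curate -> rates -> RFR -> decode over the width grid."""
    widths = config.resolved_widths()
    seeds = np.random.SeedSequence(config.seed).generate_state(len(widths)) % (2**31)
    entries, rfr_tables, dip_results, dec_results, positions = [], {}, {}, {}, {}
    for width, seed in zip(widths, seeds):
        entry, rfr, dip, dec, pos = _decode_one_width(width, config, int(seed))
        entries.append(entry)
        rfr_tables[width] = rfr
        dip_results[width] = dip
        dec_results[width] = dec
        positions[width] = pos
    curve = AcuityCurve(entries=entries, criterion=config.criterion, threshold_width_um=None)
    curve.threshold_width_um = acuity_threshold(curve)
    return PipelineResult(curve, rfr_tables, dip_results, dec_results, positions)


def write_report(result: PipelineResult, out_dir: str | Path, make_plots: bool = True) -> Path:
    """Write the machine-readable report (+ figures) atomically."""
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(dir=out_dir.parent, prefix=".report-"))
    try:
        (staging / "acuity_curve.json").write_text(
            json.dumps(result.curve.to_dict(), indent=1, sort_keys=True)
        )
        lines = ["bar_width_um,modality,f1_mean,f1_sd,cpd,n_units"]
        for e in result.curve.entries:
            lines.append(
                f"{e['bar_width_um']},{e['modality']},{e['f1_mean']},"
                f"{e['f1_sd']},{e['cpd']},{e['n_units']}"
            )
        (staging / "acuity_curve.csv").write_text("\n".join(lines) + "\n")
        if make_plots:
            _plot_report(result, staging)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(staging, out_dir)
    finally:
        if staging.exists():
            shutil.rmtree(staging, ignore_errors=True)
    return out_dir


def read_report(out_dir: str | Path) -> AcuityCurve:
    d = json.loads((Path(out_dir) / "acuity_curve.json").read_text())
    return AcuityCurve.from_dict(d)


def _plot_report(result: PipelineResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = [e for e in result.curve.entries if e.get("f1_mean") is not None]
    if entries:
        fig, ax = plt.subplots(figsize=(6, 4))
        widths = [str(int(e["bar_width_um"])) for e in entries]
        f1s = [e["f1_mean"] for e in entries]
        sds = [e["f1_sd"] for e in entries]
        ax.bar(widths, f1s, yerr=sds, color="steelblue")
        ax.axhline(0.5, ls="--", c="gray", label="chance")
        ax.axhline(result.curve.criterion, ls=":", c="firebrick", label="criterion")
        ax.set_xlabel("bar width (um)")
        ax.set_ylabel("f1 score")
        ax.set_ylim(0, 1.05)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_dir / "f1_vs_width.png", dpi=120)
        plt.close(fig)

    for width, rfr in result.rfr_tables.items():
        if rfr is None:
            continue
        pos = result.unit_positions[width]
        if len(pos) == 0:
            continue
        fig, ax = plt.subplots(figsize=(5, 4.4))
        sc = ax.scatter(pos[:, 0], pos[:, 1], c=rfr.rfr, cmap="coolwarm", vmin=-1, vmax=1, s=30)
        fig.colorbar(sc, ax=ax, label="RFR")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_title(f"{int(width)} um grating")
        fig.tight_layout()
        fig.savefig(out_dir / f"rfr_map_{int(width)}um.png", dpi=120)
        plt.close(fig)
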