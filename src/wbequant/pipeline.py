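"""End-to-end orchestration: calibrate → sensitivity → quantify → QC → rates.

The pipeline is deterministic given fixed inputs: re-running on identical
files produces identical outputs. Every exclusion (missing IS, rejected fit,
undetermined limit, QC failure) is logged with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import batchio, calibrate, quantify, sensitivity
from .backcalc import rates_for_dataset
from .batchio import PeakRecord, SampleMeta, SiteMeta
from .panel import Panel
from .quantify import Measurement, QcReport
from .sensitivity import ReferenceState

log = logging.getLogger("wbequant")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and policies for one pipeline run."""

    weighting: str = "1/x"
    min_r2: float = calibrate.DEFAULT_ACCEPTANCE_R2
    # calibrants below S/N 3 are retained in the fit by default; set True to
    # drop them where heights/noise are recorded
    exclude_low_sn_calibrants: bool = False
    substitution: str = "half_lod"
    extract_volume_ml: float = quantify.DEFAULT_EXTRACT_VOLUME_ML
    batch_id: str = "batch"
    state_path: str | Path | None = None  # LOD/LOQ reference persistence


@dataclass
class PipelineResult:
    fits: dict[str, calibrate.CalibrationFit]
    sensitivity: dict[str, sensitivity.SensitivityRecord]
    measurements: list[Measurement]
    qc: QcReport | None
    rates: list | None
    rate_means: dict[str, float] | None


def _calibrate_all(
    peaks: Sequence[PeakRecord],
    manifest: Sequence[SampleMeta],
    panel: Panel,
    config: PipelineConfig,
) -> dict[str, calibrate.CalibrationFit]:
    ratios = calibrate.response_ratios(peaks, manifest, panel)
    nominal = {
        s.sample_id: s.nominal for s in manifest if s.sample_type == "calibrant"
    }
    low_sn: set[tuple[str, str]] = set()
    if config.exclude_low_sn_calibrants:
        for p in peaks:
            if (
                p.transition == "quant"
                and p.sample_id in nominal
                and p.height is not None
                and p.noise_sd is not None
                and p.height / p.noise_sd < sensitivity.LOD_SN
            ):
                low_sn.add((p.sample_id, p.compound))
    by_compound: dict[str, tuple[list[float], list[float]]] = {}
    for r in ratios:
        level = nominal.get(r.sample_id, {}).get(r.compound)
        if level is None:
            continue
        if (r.sample_id, r.compound) in low_sn:
            log.info("calibrate: %s: dropped calibrant %s (S/N < 3)", r.compound, r.sample_id)
            continue
        ys, xs = by_compound.setdefault(r.compound, ([], []))
        ys.append(r.ratio)
        xs.append(level)
    fits: dict[str, calibrate.CalibrationFit] = {}
    for compound, (ys, xs) in sorted(by_compound.items()):
        try:
            fit = calibrate.fit_calibration(
                ys, xs, compound=compound,
                weighting=config.weighting, acceptance_r2=config.min_r2,
            )
        except calibrate.CalibrationError as exc:
            log.warning("calibrate: %s: %s", compound, exc)
            continue
        if not fit.accepted:
            log.warning(
                "calibrate: %s rejected (R²=%.5f < %.5f)",
                compound, fit.r_squared, config.min_r2,
            )
        fits[compound] = fit
    return fits


def _sensitivity_all(
    peaks: Sequence[PeakRecord],
    manifest: Sequence[SampleMeta],
    config: PipelineConfig,
    run_id: str,
) -> dict[str, sensitivity.SensitivityRecord]:
    series = sensitivity.sn_series(peaks, manifest)
    state = (
        ReferenceState.load(config.state_path)
        if config.state_path
        else ReferenceState()
    )
    by_compound: dict[str, list] = {}
    for obs in series:
        by_compound.setdefault(obs.compound, []).append(obs)
    records: dict[str, sensitivity.SensitivityRecord] = {}
    for compound, obs in sorted(by_compound.items()):
        lod, loq = sensitivity.run_lod_loq(obs)
        if lod is None:
            log.warning("sensitivity: %s: LOD not determined this run", compound)
        rec = state.update(compound, run_id, lod, loq)
        records[compound] = rec
    if config.state_path:
        state.save(config.state_path)
    return records


def run_pipeline(
    peaks: Iterable[PeakRecord],
    manifest: Iterable[SampleMeta],
    panel: Panel,
    sites: Iterable[SiteMeta] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full computational workflow on one batch.

    Stages: isotope-dilution calibration, per-run LOD/LOQ with the
    conservative reference rule, sample quantitation with censoring, batch
    QC gates, and (when site metadata is given) excretion/consumption rates.
    QC failure flags measurements (``qc_pass=False``) without deleting them.
    """
    config = config or PipelineConfig()
    peaks = list(peaks)
    manifest = list(manifest)

    fits = _calibrate_all(peaks, manifest, panel, config)
    sens = _sensitivity_all(peaks, manifest, config, run_id=config.batch_id)

    limits = {
        c: (rec.lod_reported, rec.loq_reported)
        for c, rec in sens.items()
        if rec.lod_reported is not None and rec.loq_reported is not None
    }
    measurements = quantify.quantify_batch(
        peaks, manifest, fits, limits, panel,
        batch_id=config.batch_id, extract_volume_ml=config.extract_volume_ml,
    )

    # QC gate on spiked wastewater QCs
    qc_meta = {s.sample_id: s for s in manifest if s.sample_type == "qc_spiked"}
    blank_ids = {
        s.sample_id for s in manifest if s.sample_type in ("blank", "qc_unspiked")
    }
    qc_report = None
    qc_measurements = [m for m in measurements if m.sample_id in qc_meta]
    if qc_measurements:
        nominal: dict[str, float] = {}
        for s in qc_meta.values():
            nominal.update(s.nominal or {})
        qc_report = quantify.qc_evaluate(
            qc_measurements, nominal, batch_id=config.batch_id,
            blank_measurements=[m for m in measurements if m.sample_id in blank_ids],
        )
        if not qc_report.passed:
            log.warning(
                "qc: batch %s failed gates (accuracy_pass=%s precision_pass=%s "
                "blank_clean=%s); flagging measurements",
                config.batch_id, qc_report.accuracy_pass,
                qc_report.precision_pass, qc_report.blank_clean,
            )
            measurements = [
                Measurement(
                    m.sample_id, m.compound, m.extract_conc, m.sample_conc,
                    m.status, m.lod_ngl, m.loq_ngl, m.batch_id, qc_pass=False,
                )
                for m in measurements
            ]

    rates = rate_means = None
    if sites is not None:
        rates, rate_means = rates_for_dataset(
            measurements, manifest, list(sites), panel,
            substitution=config.substitution,
        )

    return PipelineResult(
        fits=fits,
        sensitivity=sens,
        measurements=measurements,
        qc=qc_report,
        rates=rates,
        rate_means=rate_means,
    )
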