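"""Sample quantitation: extract → wastewater concentrations, QC gating, queues.

Extract concentrations (ng/mL) from calibration inversion are scaled to
wastewater concentrations (ng/L) by the concentration factor implied by the
gravimetric sample mass, wastewater density, and the final reconstitution
volume of the extract (default 0.5 mL). LOD/LOQ are propagated to ng/L with
the same factor so a sample's censoring status is scale-consistent.

Batch QC follows standard analytical validation gates: spiked-QC accuracy
within ±20 % of nominal (inclusive) and replicate RSD below 20 % (strict).
A failed gate flags every measurement in the batch (``qc_pass=False``) but
does not delete data.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .batchio import PeakRecord, SampleMeta
from .calibrate import CalibrationFit, invert, response_ratios
from .panel import Panel
from .sensitivity import censor

__all__ = [
    "DEFAULT_EXTRACT_VOLUME_ML",
    "SUBSTITUTION_POLICIES",
    "Measurement",
    "QcReport",
    "QuantifyError",
    "concentration_factor",
    "quantify_batch",
    "qc_evaluate",
    "build_run_queue",
    "substitute",
]

DEFAULT_EXTRACT_VOLUME_ML = 0.5  # final reconstitution volume

ACCURACY_LOW, ACCURACY_HIGH = 80.0, 120.0
RSD_LIMIT = 20.0

SUBSTITUTION_POLICIES = ("half_lod", "zero", "lod_over_sqrt2", "exclude")


class QuantifyError(ValueError):
    pass


@dataclass(frozen=True)
class Measurement:
    """A censored wastewater concentration with provenance."""

    sample_id: str
    compound: str
    extract_conc: float
    sample_conc: float
    status: str
    lod_ngl: float
    loq_ngl: float
    batch_id: str = ""
    qc_pass: bool = True


@dataclass(frozen=True)
class QcReport:
    """Batch QC verdict: per-compound accuracy/precision plus blank check."""

    batch_id: str
    accuracy_pct: dict[str, float]
    rsd_pct: dict[str, float]
    blank_clean: bool
    accuracy_pass: bool
    precision_pass: bool

    @property
    def passed(self) -> bool:
        return self.accuracy_pass and self.precision_pass and self.blank_clean


def concentration_factor(
    mass_g: float,
    density_g_per_ml: float = 1.0,
    extract_volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML,
) -> float:
    """Factor converting extract ng/mL to wastewater ng/L.

    The gravimetric mass and density give the extracted wastewater volume
    (L); all analyte in that volume ends up in ``extract_volume_ml`` of final
    extract, so ``conc_ngl = conc_ng_ml * extract_volume_ml / volume_l``.
    A 100 g aliquot at density 1.0 with a 0.5 mL extract gives factor 5.
    """
    if not (mass_g > 0 and density_g_per_ml > 0 and extract_volume_ml > 0):
        raise QuantifyError(
            "mass_g, density_g_per_ml and extract_volume_ml must all be > 0"
        )
    sample_volume_l = mass_g / density_g_per_ml / 1000.0
    return extract_volume_ml / sample_volume_l


def quantify_batch(
    peaks: Iterable[PeakRecord],
    manifest: Iterable[SampleMeta],
    fits: Mapping[str, CalibrationFit],
    limits: Mapping[str, tuple[float, float]],
    panel: Panel,
    batch_id: str = "batch",
    extract_volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML,
    sample_types: Sequence[str] = ("field", "blank", "qc_unspiked", "qc_spiked"),
    recovery_correction: Mapping[str, float] | None = None,
) -> list[Measurement]:
    """Quantify every (sample, compound) with an accepted calibration fit.

    ``limits`` maps compound → (lod, loq) in extract units (ng/mL). Samples
    without a gravimetric mass (blanks, extract-level QCs) are quantified at
    extract scale with factor 1 (their ``sample_conc`` equals the extract
    concentration and limits stay in ng/mL-equivalent units). Field samples
    missing mass_g cannot occur (manifest invariant), but a defensive check
    lists offenders. Negative inverse predictions are reported 0-censored
    below the LOD.

    Concentrations are reported uncorrected for extraction losses by
    default; ``recovery_correction`` maps compound → extraction efficiency
    fraction (e.g. 0.85) to divide out per-compound recovery where a study
    chooses to correct.
    """
    manifest = list(manifest)
    peaks = list(peaks)
    ratios = response_ratios(peaks, manifest, panel, sample_types=sample_types)
    meta = {s.sample_id: s for s in manifest}

    missing_mass = [
        s.sample_id
        for s in manifest
        if s.sample_type == "field" and s.mass_g is None
    ]
    if missing_mass:
        raise QuantifyError(f"field samples missing mass_g: {missing_mass}")

    out: list[Measurement] = []
    skipped_fit: set[str] = set()
    for r in ratios:
        fit = fits.get(r.compound)
        if fit is None or not fit.accepted:
            skipped_fit.add(r.compound)
            continue
        if r.compound not in limits:
            skipped_fit.add(r.compound)
            continue
        lod_ml, loq_ml = limits[r.compound]
        s = meta[r.sample_id]
        factor = (
            concentration_factor(s.mass_g, s.density_g_per_ml, extract_volume_ml)
            if s.mass_g is not None
            else 1.0
        )
        extract_conc = invert(fit, r.ratio)
        if recovery_correction and r.compound in recovery_correction:
            eff = recovery_correction[r.compound]
            if not eff > 0:
                raise QuantifyError(f"{r.compound}: recovery fraction must be > 0")
            extract_conc /= eff
        status = censor(extract_conc, lod_ml, loq_ml)
        sample_conc = max(extract_conc, 0.0) * factor
        out.append(
            Measurement(
                sample_id=r.sample_id,
                compound=r.compound,
                extract_conc=extract_conc,
                sample_conc=sample_conc,
                status=status,
                lod_ngl=lod_ml * factor,
                loq_ngl=loq_ml * factor,
                batch_id=batch_id,
            )
        )
    for c in sorted(skipped_fit):
        warnings.warn(f"{c}: no accepted calibration fit or limits; not quantifiable")
    return out


def substitute(measurement: Measurement, policy: str = "half_lod") -> float | None:
    """Numeric value a censored measurement contributes to summaries.

    Quantified and between-LOD/LOQ measurements contribute their measured
    value; below-LOD measurements contribute per policy (default LOD/2).
    Returns None under the ``exclude`` policy.
    """
    if policy not in SUBSTITUTION_POLICIES:
        raise QuantifyError(f"policy must be one of {SUBSTITUTION_POLICIES}")
    if measurement.status != "below_lod":
        return measurement.sample_conc
    return {
        "half_lod": measurement.lod_ngl / 2.0,
        "zero": 0.0,
        "lod_over_sqrt2": measurement.lod_ngl / np.sqrt(2.0),
        "exclude": None,
    }[policy]


def qc_evaluate(
    measurements: Iterable[Measurement],
    nominal: Mapping[str, float],
    batch_id: str = "batch",
    blank_measurements: Iterable[Measurement] = (),
) -> QcReport:
    """Accuracy and precision gates on spiked-QC replicate measurements.

    Accuracy = 100 × mean(measured extract conc)/nominal per compound;
    RSD = 100 × sd/mean over replicates (needs ≥ 2). The batch passes
    accuracy when every compound is within [80, 120] % and precision when
    every RSD < 20 %. ``blank_clean`` requires every blank measurement to be
    below the LOD.
    """
    by_compound: dict[str, list[float]] = {}
    for m in measurements:
        by_compound.setdefault(m.compound, []).append(m.extract_conc)

    accuracy: dict[str, float] = {}
    rsd: dict[str, float] = {}
    for compound, values in sorted(by_compound.items()):
        nom = nominal.get(compound)
        if nom is None:
            continue
        if nom == 0:
            raise QuantifyError(f"{compound}: nominal must be nonzero")
        if len(values) < 2:
            raise QuantifyError(
                f"{compound}: need >= 2 QC replicates for RSD, got {len(values)}"
            )
        mean = statistics.fmean(values)
        accuracy[compound] = 100.0 * mean / nom
        rsd[compound] = 100.0 * statistics.stdev(values) / mean if mean != 0 else float("inf")

    blank_clean = all(m.status == "below_lod" for m in blank_measurements)
    return QcReport(
        batch_id=batch_id,
        accuracy_pct=accuracy,
        rsd_pct=rsd,
        blank_clean=blank_clean,
        accuracy_pass=all(ACCURACY_LOW <= a <= ACCURACY_HIGH for a in accuracy.values()),
        precision_pass=all(r < RSD_LIMIT for r in rsd.values()),
    )


def build_run_queue(
    sample_ids: Sequence[str],
    seed: int,
) -> list[str]:
    """Deterministic random injection order: calibrants, blanks, QCs and
    extracts shuffled together so instrument drift cannot align with sample
    class. Same seed → identical queue; the queue is a permutation."""
    rng = np.random.default_rng(seed)
    ids = list(sample_ids)
    order = rng.permutation(len(ids))
    return [ids[i] for i in order]
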