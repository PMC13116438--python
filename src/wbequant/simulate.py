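"""Seeded synthetic batches emulating a targeted LC-MS/MS surveillance campaign.

The generator produces everything the pipeline consumes — calibrant series,
method blanks, spiked/unspiked wastewater QCs, weekly field samples across
multiple sites, and spike-before/spike-after recovery triplicates — together
with a truth table recording every generating value, so each stage can be
tested against known ground truth without instrument data.

Statistical model:

* peak areas carry multiplicative lognormal noise (areas are positive and MS
  area noise scales with signal); the lognormal is mean-1 so the noise is
  unbiased on the area scale;
* each extracted sample gets one matrix suppression/enhancement factor
  applied equally to native and internal-standard areas — this is exactly
  the situation isotope dilution is designed to cancel, and a
  ``differential_suppression`` knob breaks the cancellation for stress
  tests;
* baseline noise for S/N studies is additive Gaussian on peak height.

Defaults mirror the emulated campaign: a 22-level calibrant series spanning
0.001–200 ng/mL, 5 % area noise, triplicate QCs and recovery spikes with
10 % noise, 100 g (≈100 mL) gravimetric aliquots reconstituted to 0.5 mL,
and a 17-site × 35-week field design.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .batchio import PeakRecord, SampleMeta, SiteMeta
from .calibrate import default_levels
from .panel import Panel, default_panel

__all__ = [
    "SimConfig",
    "simulate_batch",
    "simulate_recovery",
    "recovery_estimates",
    "simulate_sn_series",
]

# typical influent medians (ng/L) for well-characterized biomarkers; everything
# else defaults to SimConfig.field_median_ngl
_FIELD_MEDIANS_NGL = {
    "benzoylecgonine": 800.0,
    "cocaine": 400.0,
    "amphetamine": 300.0,
    "methamphetamine": 400.0,
    "caffeine": 50000.0,
    "norfentanyl": 20.0,
    "EDDP": 300.0,
    "ketamine": 50.0,
    "xylazine": 30.0,
}


@dataclass
class SimConfig:
    """Generator configuration; a fixed seed gives byte-identical output."""

    seed: int = 0
    compounds: tuple[str, ...] | None = None  # None → all panel natives
    calibration_levels: np.ndarray = field(default_factory=default_levels)
    noise_cv: float = 0.05
    area_per_ng: float = 1.0e4          # area units per (ng/mL) of extract conc
    is_area_nominal: float = 1.0e5
    height_per_area: float = 0.05       # peak height per unit area
    noise_floor_sd: float = 10.0        # baseline height noise SD
    height_slope: float = 300.0         # height per (ng/mL) in S/N studies
    suppression_range: tuple[float, float] = (0.6, 1.2)
    differential_suppression: float = 0.0  # extra native-only suppression CV
    field_median_ngl: float = 50.0
    field_gcv: float = 0.5              # geometric CV of site-week truth
    true_field_conc: Mapping[str, float] | None = None  # fixed ng/L overrides
    qc_nominal_ng_ml: float = 10.0
    replicates: int = 3
    n_sites: int = 17
    n_weeks: int = 35
    mass_g: float = 100.0
    density_g_per_ml: float = 1.0
    extract_volume_ml: float = 0.5
    recovery_truth: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("amphetamine", "MCX"): 0.85,
            ("amphetamine", "HLB"): 1.00,
            ("methamphetamine", "MCX"): 0.78,
            ("methamphetamine", "HLB"): 1.12,
        }
    )
    recovery_cv: float = 0.10

    def __post_init__(self) -> None:
        for name in ("noise_cv", "recovery_cv", "differential_suppression"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "area_per_ng", "is_area_nominal", "height_per_area",
            "noise_floor_sd", "height_slope", "qc_nominal_ng_ml",
            "field_median_ngl", "mass_g", "density_g_per_ml", "extract_volume_ml",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def _lognoise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _resolve_compounds(config: SimConfig, panel: Panel) -> tuple[str, ...]:
    if config.compounds is None:
        return panel.native_names
    unknown = [c for c in config.compounds if not panel.is_native(c)]
    if unknown:
        raise ValueError(f"compounds not in panel: {unknown}")
    return tuple(config.compounds)


def _emit_sample(
    peaks: list[PeakRecord],
    rng: np.random.Generator,
    config: SimConfig,
    panel: Panel,
    compounds: Sequence[str],
    sample_id: str,
    extract_conc: Mapping[str, float],
    suppression: float,
) -> None:
    """Append native + IS quant/confirm peaks for one injected sample."""
    is_names = {panel.native(c).internal_standard for c in compounds}
    for c in compounds:
        diff = _lognoise(rng, config.differential_suppression)
        area = (
            extract_conc.get(c, 0.0)
            * config.area_per_ng
            * suppression
            * diff
            * _lognoise(rng, config.noise_cv)
        )
        height = max(
            area * config.height_per_area + rng.normal(0.0, config.noise_floor_sd), 0.0
        )
        peaks.append(
            PeakRecord(sample_id, c, "quant", area, height, config.noise_floor_sd)
        )
        peaks.append(
            PeakRecord(
                sample_id, c, "confirm",
                0.3 * area * _lognoise(rng, config.noise_cv),
            )
        )
    for s in sorted(is_names):
        area = config.is_area_nominal * suppression * _lognoise(rng, config.noise_cv)
        peaks.append(PeakRecord(sample_id, s, "quant", area))


def simulate_batch(
    config: SimConfig,
    panel: Panel | None = None,
) -> tuple[list[PeakRecord], list[SampleMeta], list[SiteMeta], pd.DataFrame]:
    """Generate one complete analytical batch plus its truth table.

    Returns (peaks, manifest, sites, truth); truth has one row per
    (sample, compound) with the generating extract and sample concentrations
    and the sample's matrix suppression factor.
    """
    panel = panel or default_panel()
    compounds = _resolve_compounds(config, panel)
    rng = np.random.default_rng(config.seed)

    peaks: list[PeakRecord] = []
    manifest: list[SampleMeta] = []
    truth_rows: list[dict] = []

    def record_truth(sample_id, conc_map, suppression, factor=None):
        for c in compounds:
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "compound": c,
                    "true_extract_conc_ng_ml": conc_map.get(c, 0.0),
                    "true_sample_conc_ngl": (
                        conc_map.get(c, 0.0) * factor if factor is not None else np.nan
                    ),
                    "suppression": suppression,
                }
            )

    # calibrants: solvent standards, no matrix suppression
    for i, level in enumerate(np.asarray(config.calibration_levels, dtype=float)):
        sid = f"cal{i:02d}"
        conc = {c: float(level) for c in compounds}
        manifest.append(SampleMeta(sid, "calibrant", nominal=conc))
        _emit_sample(peaks, rng, config, panel, compounds, sid, conc, 1.0)
        record_truth(sid, conc, 1.0)

    # method blank + unspiked wastewater QC
    for sid, stype in (("blank0", "blank"), ("qcu0", "qc_unspiked")):
        supp = 1.0 if stype == "blank" else rng.uniform(*config.suppression_range)
        manifest.append(SampleMeta(sid, stype))
        _emit_sample(peaks, rng, config, panel, compounds, sid, {}, supp)
        record_truth(sid, {}, supp)

    # spiked wastewater QCs (replicates at one nominal level)
    qc_conc = {c: config.qc_nominal_ng_ml for c in compounds}
    for r in range(config.replicates):
        sid = f"qcs{r}"
        supp = rng.uniform(*config.suppression_range)
        manifest.append(SampleMeta(sid, "qc_spiked", nominal=qc_conc))
        _emit_sample(peaks, rng, config, panel, compounds, sid, qc_conc, supp)
        record_truth(sid, qc_conc, supp)

    # sites and weekly field samples
    factor = config.extract_volume_ml / (config.mass_g / config.density_g_per_ml / 1000.0)
    sites = [
        SiteMeta(
            site_id=f"site{k:02d}",
            population=float(rng.integers(20_000, 500_000)),
            flow_l_per_day=float(rng.uniform(5e6, 5e7)),
        )
        for k in range(config.n_sites)
    ]
    start = _dt.date(2025, 1, 6)
    medians = {
        c: (
            config.true_field_conc.get(c)
            if config.true_field_conc and c in config.true_field_conc
            else _FIELD_MEDIANS_NGL.get(c, config.field_median_ngl)
        )
        for c in compounds
    }
    gsigma = np.sqrt(np.log1p(config.field_gcv**2))
    for k, site in enumerate(sites):
        for w in range(config.n_weeks):
            sid = f"f{k:02d}w{w:02d}"
            date = start + _dt.timedelta(weeks=w)
            if config.true_field_conc:
                ngl = {c: medians[c] for c in compounds}
            else:
                ngl = {
                    c: medians[c] * float(rng.lognormal(0.0, gsigma))
                    for c in compounds
                }
            conc = {c: v / factor for c, v in ngl.items()}
            supp = rng.uniform(*config.suppression_range)
            manifest.append(
                SampleMeta(
                    sid, "field",
                    mass_g=config.mass_g,
                    density_g_per_ml=config.density_g_per_ml,
                    site_id=site.site_id,
                    collected_on=date,
                )
            )
            _emit_sample(peaks, rng, config, panel, compounds, sid, conc, supp)
            record_truth(sid, conc, supp, factor=factor)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "compound", "true_extract_conc_ng_ml",
            "true_sample_conc_ngl", "suppression",
        ],
    )
    return peaks, manifest, sites, truth


def simulate_recovery(
    config: SimConfig,
    panel: Panel | None = None,
) -> tuple[list[PeakRecord], list[SampleMeta]]:
    """Spike-before/spike-after replicate groups per (compound, sorbent).

    Before-spike areas are the after-spike scale multiplied by the true
    extraction efficiency (plus noise); after-spike areas carry noise only.
    One replicate group of ``config.replicates`` pairs per sorbent.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)
    peaks: list[PeakRecord] = []
    manifest: list[SampleMeta] = []

    sorbents = sorted({s for (_, s) in config.recovery_truth})
    for sorbent in sorbents:
        group = f"rec-{sorbent}"
        compounds = sorted(c for (c, s) in config.recovery_truth if s == sorbent)
        for r in range(config.replicates):
            for arm, stype in (("b", "spike_before"), ("a", "spike_after")):
                sid = f"{group}-{arm}{r}"
                if not any(p.sample_id == sid for p in peaks):
                    manifest.append(
                        SampleMeta(
                            sid, stype, replicate_group=group, sorbent=sorbent
                        )
                    )
                for c in compounds:
                    truth = config.recovery_truth[(c, sorbent)]
                    scale = config.is_area_nominal
                    area = (
                        scale
                        * (truth if arm == "b" else 1.0)
                        * _lognoise(rng, config.recovery_cv)
                    )
                    peaks.append(PeakRecord(sid, c, "quant", area))
    return peaks, manifest


def recovery_estimates(
    truth: float,
    cv: float,
    n_seeds: int,
    replicates: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo ratio-of-means recovery estimates (percent), one per seed.

    Vectorized companion to :func:`simulate_recovery` for bias studies: each
    seed draws ``replicates`` before- and after-spike areas with mean-1
    lognormal noise at the given CV and returns 100·mean(before)/mean(after).
    """
    rng = np.random.default_rng(seed)
    before = truth * _lognoise(rng, cv, size=(n_seeds, replicates))
    after = _lognoise(rng, cv, size=(n_seeds, replicates))
    return 100.0 * before.mean(axis=1) / after.mean(axis=1)


def simulate_sn_series(
    config: SimConfig,
    compound: str = "amphetamine",
) -> tuple[list[PeakRecord], list[SampleMeta]]:
    """Calibrant heights with additive Gaussian baseline noise for LOD studies.

    ``height = height_slope · level + N(0, noise_floor_sd)``, floored at 0;
    the ``noise_sd`` column carries the generating noise SD, so S/N at level
    L is ≈ height_slope·L/noise_floor_sd.
    """
    rng = np.random.default_rng(config.seed)
    peaks: list[PeakRecord] = []
    manifest: list[SampleMeta] = []
    for i, level in enumerate(np.asarray(config.calibration_levels, dtype=float)):
        sid = f"sn{i:02d}"
        manifest.append(SampleMeta(sid, "calibrant", nominal={compound: float(level)}))
        height = max(
            config.height_slope * level + rng.normal(0.0, config.noise_floor_sd), 0.0
        )
        area = height / config.height_per_area
        peaks.append(
            PeakRecord(sid, compound, "quant", area, height, config.noise_floor_sd)
        )
    return peaks, manifest
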