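"""Population-normalized excretion and consumption rates.

A wastewater concentration C (ng/L) at a treatment facility serving P people
with daily influent flow F (L/day) corresponds to an excretion rate

    E = C · F · 10⁻⁶ / (P / 1000)        [mg/day per 1000 inhabitants]

Consumption of the parent drug is back-calculated from the excretion rate of
its urinary biomarker using pharmacokinetic constants: the rate is divided
by the fraction of the dose excreted in urine as that biomarker, and — when
the biomarker is a metabolite rather than the parent itself — multiplied by
the ratio of the parent's molecular weight to the metabolite's to undo the
mass change of biotransformation:

    Consumption = E / f_excretion · (MW_parent / MW_metabolite)

Both rates are linear in concentration and in flow. Censored measurements
contribute through the same substitution policy as concentration summaries
(default LOD/2) and stay flagged in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import datetime as _dt

from .batchio import SampleMeta, SiteMeta
from .panel import Panel
from .quantify import Measurement, substitute

__all__ = [
    "PkConstants",
    "RateRecord",
    "BackcalcError",
    "excretion_rate",
    "consumption_rate",
    "pk_for_compound",
    "rates_for_dataset",
]


class BackcalcError(ValueError):
    pass


@dataclass(frozen=True)
class PkConstants:
    """Pharmacokinetic correction constants for one biomarker."""

    excretion_fraction: float
    mw_parent: float
    mw_metabolite: float

    def __post_init__(self) -> None:
        if not 0 < self.excretion_fraction <= 1:
            raise BackcalcError(
                f"excretion_fraction must be in (0, 1], got {self.excretion_fraction}"
            )
        if not (self.mw_parent > 0 and self.mw_metabolite > 0):
            raise BackcalcError("molecular weights must be > 0")


@dataclass(frozen=True)
class RateRecord:
    """Excretion/consumption rate of one biomarker at one site and date."""

    site_id: str
    collected_on: _dt.date | None
    compound: str
    parent_compound: str
    excretion_rate: float
    consumption_rate: float | None
    flags: str = "quantified"


def excretion_rate(conc_ngl: float, flow_l_per_day: float, population: float) -> float:
    """Mass load per day normalized per 1000 inhabitants (mg/day/1000 inh)."""
    if not (flow_l_per_day > 0 and population > 0):
        raise BackcalcError("flow and population must be > 0")
    if conc_ngl < 0:
        raise BackcalcError(f"concentration must be >= 0, got {conc_ngl}")
    return conc_ngl * flow_l_per_day * 1e-6 / (population / 1000.0)


def consumption_rate(
    excretion: float,
    pk: PkConstants,
    measured_is_metabolite: bool,
) -> float:
    """Back-calculate parent-drug consumption from a biomarker excretion rate."""
    mw_ratio = pk.mw_parent / pk.mw_metabolite if measured_is_metabolite else 1.0
    return excretion / pk.excretion_fraction * mw_ratio


def pk_for_compound(panel: Panel, compound: str) -> tuple[PkConstants | None, str, bool]:
    """Assemble PK constants for a biomarker from the panel.

    Returns (constants-or-None, parent name, measured_is_metabolite). None
    constants (with a warning downstream) when the excretion fraction is
    absent or a metabolite lacks a resolvable parent.
    """
    spec = panel.native(compound)
    is_metab = spec.role == "metabolite" and spec.parent_name is not None
    parent_name = spec.parent_name if is_metab else compound
    if spec.excretion_fraction is None:
        return None, parent_name, is_metab
    mw_parent = panel.native(parent_name).molecular_weight if is_metab else spec.molecular_weight
    return (
        PkConstants(
            excretion_fraction=spec.excretion_fraction,
            mw_parent=mw_parent,
            mw_metabolite=spec.molecular_weight,
        ),
        parent_name,
        is_metab,
    )


def rates_for_dataset(
    measurements: Iterable[Measurement],
    manifest: Iterable[SampleMeta],
    sites: Iterable[SiteMeta],
    panel: Panel,
    substitution: str = "half_lod",
) -> tuple[list[RateRecord], dict[str, float]]:
    """One RateRecord per field measurement, plus per-biomarker mean excretion.

    Each field sample joins to its site's flow/population: a SiteMeta dated
    to the sample's collection date wins over the site's undated constant
    record. Missing joins are an error listing the offending sample ids.
    Censored measurements contribute via ``substitution`` and keep their
    censor status in ``flags``; ``exclude``-policy below-LOD measurements
    are dropped from both records and means.
    """
    meta = {s.sample_id: s for s in manifest}
    dated: dict[tuple[str, _dt.date | None], SiteMeta] = {
        (s.site_id, s.measured_on): s for s in sites
    }
    constant: dict[str, SiteMeta] = {
        s.site_id: s for s in sites if s.measured_on is None
    }

    records: list[RateRecord] = []
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    missing_join: list[str] = []
    warned: set[str] = set()

    for m in measurements:
        s = meta.get(m.sample_id)
        if s is None or s.sample_type != "field":
            continue
        site = dated.get((s.site_id, s.collected_on)) or constant.get(s.site_id)
        if site is None:
            missing_join.append(m.sample_id)
            continue
        value = substitute(m, substitution)
        if value is None:
            continue
        exc = excretion_rate(value, site.flow_l_per_day, site.population)
        pk, parent, is_metab = pk_for_compound(panel, m.compound)
        if pk is None:
            if m.compound not in warned:
                warned.add(m.compound)
                warnings.warn(
                    f"{m.compound}: no excretion fraction in panel; "
                    "consumption rate not computed"
                )
            cons = None
        else:
            cons = consumption_rate(exc, pk, is_metab)
        records.append(
            RateRecord(
                site_id=site.site_id,
                collected_on=s.collected_on,
                compound=m.compound,
                parent_compound=parent,
                excretion_rate=exc,
                consumption_rate=cons,
                flags=m.status,
            )
        )
        sums[m.compound] = sums.get(m.compound, 0.0) + exc
        counts[m.compound] = counts.get(m.compound, 0) + 1

    if missing_join:
        raise BackcalcError(
            f"field samples with no matching site record: {sorted(set(missing_join))}"
        )
    means = {c: sums[c] / counts[c] for c in sums}
    return records, means
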