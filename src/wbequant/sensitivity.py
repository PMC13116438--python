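"""Per-run LOD/LOQ from signal-to-noise, with conservative multi-run reporting.

Detection and quantitation limits follow the chromatographic S/N convention:
the LOD is the lowest calibrant level whose peak height reaches 3× the
baseline noise SD, the LOQ the lowest level reaching 10×. Because noisy
series can dip back below threshold, the scan uses a monotone-suffix rule —
the reported level is the lowest level from which *every* higher level also
clears the threshold. This replaces the manual/visual determination common
in practice with a deterministic, auditable rule.

Reporting across runs is deliberately conservative: the mean of the first
five per-run determinations becomes a frozen reference, and each subsequent
run reports ``max(run value, reference)`` — a run that looks more sensitive
than the reference is *not* trusted below it, while a worse run raises the
reported limit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .batchio import PeakRecord, SampleMeta

__all__ = [
    "LOD_SN",
    "LOQ_SN",
    "N_REFERENCE_RUNS",
    "SnObservation",
    "SensitivityRecord",
    "ReferenceState",
    "sn_series",
    "run_lod_loq",
    "apply_reference_rule",
    "censor",
    "CENSOR_STATUSES",
]

LOD_SN = 3.0
LOQ_SN = 10.0
N_REFERENCE_RUNS = 5

CENSOR_STATUSES = ("below_lod", "between_lod_loq", "quantified")


@dataclass(frozen=True)
class SnObservation:
    """Signal-to-noise (peak height ÷ baseline noise SD) at one calibrant level."""

    compound: str
    level: float
    sn: float

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError(f"{self.compound}: level must be > 0")
        if not self.sn >= 0:
            raise ValueError(f"{self.compound}: sn must be >= 0")


@dataclass(frozen=True)
class SensitivityRecord:
    """Per-run and reported LOD/LOQ for one compound."""

    compound: str
    run_id: str
    lod_run: float | None
    loq_run: float | None
    lod_reported: float | None
    loq_reported: float | None
    reference_lod: float | None = None
    reference_loq: float | None = None


def sn_series(
    peaks: Iterable[PeakRecord],
    manifest: Iterable[SampleMeta],
) -> list[SnObservation]:
    """Build per-compound S/N series from calibrant quantifier peaks.

    Requires ``height`` and ``noise_sd`` on the peak records; compounds whose
    calibrant peaks lack a noise estimate are skipped with a warning. A zero
    ``noise_sd`` would make S/N undefined and is rejected upstream by the
    record invariant.
    """
    nominal = {
        s.sample_id: s.nominal
        for s in manifest
        if s.sample_type == "calibrant" and s.nominal
    }
    out: list[SnObservation] = []
    skipped: set[str] = set()
    for p in peaks:
        if p.transition != "quant" or p.sample_id not in nominal:
            continue
        level = nominal[p.sample_id].get(p.compound)
        if level is None:
            continue
        if p.height is None or p.noise_sd is None:
            skipped.add(p.compound)
            continue
        out.append(SnObservation(compound=p.compound, level=level, sn=p.height / p.noise_sd))
    for c in sorted(skipped):
        warnings.warn(f"{c}: calibrant peaks lack height/noise_sd; excluded from S/N")
    return sorted(out, key=lambda o: (o.compound, o.level))


def _threshold_scan(levels: Sequence[float], sn: Sequence[float], thr: float) -> float | None:
    """Lowest level such that it and every higher level have S/N >= thr."""
    order = sorted(range(len(levels)), key=lambda i: levels[i])
    result = None
    for i in reversed(order):
        if sn[i] >= thr:
            result = levels[i]
        else:
            break
    return result


def run_lod_loq(series: Sequence[SnObservation]) -> tuple[float | None, float | None]:
    """Monotone-suffix threshold scan: LOD at S/N ≥ 3, LOQ at S/N ≥ 10.

    Returns ``(None, None)``-style sentinels per limit when no level clears
    its threshold ("not determined this run"). By construction
    ``loq >= lod`` whenever both are determined.
    """
    if not series:
        return None, None
    compounds = {o.compound for o in series}
    if len(compounds) > 1:
        raise ValueError(f"series mixes compounds: {sorted(compounds)}")
    levels = [o.level for o in series]
    sn = [o.sn for o in series]
    lod = _threshold_scan(levels, sn, LOD_SN)
    loq = _threshold_scan(levels, sn, LOQ_SN)
    return lod, loq


def apply_reference_rule(history: Sequence[float], run_value: float) -> float:
    """Conservative reporting rule given earlier determined run values.

    The reference is the arithmetic mean of the first five determined runs.
    Before five runs exist the run value is reported unchanged; afterwards
    the report is ``max(run value, reference)`` — the average is applied when
    the run looks better than it, the (higher) run value when it looks worse.
    """
    determined = [v for v in history if v is not None]
    if len(determined) < N_REFERENCE_RUNS:
        return run_value
    reference = sum(determined[:N_REFERENCE_RUNS]) / N_REFERENCE_RUNS
    return max(run_value, reference)


def censor(conc: float, lod: float, loq: float) -> str:
    """Censoring status for a concentration against reported limits.

    Half-open convention: ``[lod, loq)`` is *between*; a value exactly at the
    LOQ is quantified. Negative concentrations (from inverse prediction below
    the intercept) are below_lod.
    """
    if not lod <= loq:
        raise ValueError(f"lod ({lod}) must be <= loq ({loq})")
    if conc < lod:
        return "below_lod"
    if conc < loq:
        return "between_lod_loq"
    return "quantified"


# ---------------------------------------------------------------------------
# persistent reference state


class ReferenceState:
    """Per-compound LOD/LOQ reference bookkeeping, persisted as JSON.

    Accumulates per-run determinations until five exist for a compound, then
    freezes the reference at their mean (non-detect runs do not count toward
    the five). Human-readable on disk.
    """

    def __init__(self) -> None:
        self._runs: dict[str, dict[str, list[float]]] = {}

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceState":
        state = cls()
        p = Path(path)
        if p.exists():
            state._runs = json.loads(p.read_text())
        return state

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._runs, indent=1, sort_keys=True) + "\n")

    def _hist(self, compound: str, kind: str) -> list[float]:
        return self._runs.setdefault(compound, {}).setdefault(kind, [])

    def reference(self, compound: str, kind: str) -> float | None:
        hist = self._runs.get(compound, {}).get(kind, [])
        if len(hist) < N_REFERENCE_RUNS:
            return None
        return sum(hist[:N_REFERENCE_RUNS]) / N_REFERENCE_RUNS

    def update(
        self, compound: str, run_id: str, lod_run: float | None, loq_run: float | None
    ) -> SensitivityRecord:
        """Record one run's determinations and return the reported values."""
        reported = {}
        for kind, value in (("lod", lod_run), ("loq", loq_run)):
            hist = self._hist(compound, kind)
            if value is None:
                ref = self.reference(compound, kind)
                reported[kind] = ref  # fall back to reference if one exists
            else:
                reported[kind] = apply_reference_rule(hist, value)
                if len(hist) < N_REFERENCE_RUNS:
                    hist.append(value)
        return SensitivityRecord(
            compound=compound,
            run_id=run_id,
            lod_run=lod_run,
            loq_run=loq_run,
            lod_reported=reported["lod"],
            loq_reported=reported["loq"],
            reference_lod=self.reference(compound, "lod"),
            reference_loq=self.reference(compound, "loq"),
        )
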