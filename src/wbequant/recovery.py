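"""SPE extraction efficiency from spike-before/spike-after experiments.

Recovery for a compound on a sorbent is the ratio of the mean peak area of
replicates spiked *before* extraction to the mean of replicates spiked
*after* extraction, ×100. Values above 100 % are reported as-is — they
signal matrix enhancement, not an error. The per-compound RSD is, by
default, the RSD of the before-spike (whole-method) replicates; the RSD of
replicate-wise before/after ratios is available as an alternative
attribution since a single printed RSD cannot disambiguate the two.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .batchio import PeakRecord, SampleMeta

__all__ = [
    "RecoveryResult",
    "extraction_efficiency",
    "compare_sorbents",
    "recovery_experiment_from_manifest",
]


@dataclass(frozen=True)
class RecoveryResult:
    """Extraction efficiency of one compound on one sorbent.

    ``recovery_pct``/``rsd_pct`` are None when the experiment is undefined
    (e.g., after-spike mean of zero) — missing is explicit, never silent.
    """

    compound: str
    sorbent: str
    recovery_pct: float | None
    rsd_pct: float | None
    n_before: int
    n_after: int
    reason: str | None = None


def extraction_efficiency(
    before: Sequence[float],
    after: Sequence[float],
    rsd_on: str = "before",
) -> tuple[float | None, float | None]:
    """Recovery % = 100 × mean(before)/mean(after); RSD % of the chosen group.

    ``rsd_on='before'`` (default) attributes variability to the whole-method
    replicates; ``rsd_on='ratio'`` uses replicate-wise before/after ratios
    (requires equal group sizes). Returns (None, None) when the after-spike
    mean is zero (undefined ratio).
    """
    if not before or not after:
        raise ValueError("both before and after groups must be non-empty")
    mean_after = statistics.fmean(after)
    if mean_after == 0:
        return None, None
    mean_before = statistics.fmean(before)
    recovery = 100.0 * mean_before / mean_after

    if rsd_on == "before":
        values = list(before)
    elif rsd_on == "ratio":
        if len(before) != len(after):
            raise ValueError("rsd_on='ratio' requires equal group sizes")
        values = [b / a for b, a in zip(before, after)]
    else:
        raise ValueError("rsd_on must be 'before' or 'ratio'")
    mean_v = statistics.fmean(values)
    if len(values) < 2 or mean_v == 0:
        rsd = None
    else:
        rsd = 100.0 * statistics.stdev(values) / mean_v
    return recovery, rsd


def recovery_experiment_from_manifest(
    peaks: Iterable[PeakRecord],
    manifest: Iterable[SampleMeta],
    rsd_on: str = "before",
) -> list[RecoveryResult]:
    """Group spike-before/spike-after replicates and compute recoveries.

    Samples are grouped by (sorbent, compound); a replicate_group missing one
    arm is excluded with a warning. Every compound present in the peak table
    is evaluated — isotopically labelled species included, since their
    recovery is equally informative.
    """
    manifest = list(manifest)
    meta = {s.sample_id: s for s in manifest}
    areas: dict[tuple[str, str], float] = {
        (p.sample_id, p.compound): p.area
        for p in peaks
        if p.transition == "quant"
    }

    # split sample ids by (sorbent, arm)
    groups: dict[str, dict[str, list[str]]] = {}
    for s in manifest:
        if s.sample_type in ("spike_before", "spike_after"):
            groups.setdefault(s.replicate_group, {}).setdefault(s.sample_type, []).append(
                s.sample_id
            )

    # collect before/after areas per (sorbent, compound)
    collected: dict[tuple[str, str], dict[str, list[float]]] = {}
    for group_name, arms in sorted(groups.items()):
        if "spike_before" not in arms or "spike_after" not in arms:
            warnings.warn(
                f"replicate group {group_name!r} has only one arm; excluded"
            )
            continue
        for arm, sample_ids in arms.items():
            for sid in sample_ids:
                sorbent = meta[sid].sorbent or "unknown"
                for (psid, compound), area in areas.items():
                    if psid != sid:
                        continue
                    entry = collected.setdefault((sorbent, compound), {"before": [], "after": []})
                    entry["before" if arm == "spike_before" else "after"].append(area)

    results: list[RecoveryResult] = []
    for (sorbent, compound), arms in sorted(collected.items()):
        before, after = arms["before"], arms["after"]
        if not before or not after:
            warnings.warn(f"{compound} ({sorbent}): missing an arm; no result")
            continue
        rec, rsd = extraction_efficiency(before, after, rsd_on=rsd_on)
        results.append(
            RecoveryResult(
                compound=compound,
                sorbent=sorbent,
                recovery_pct=rec,
                rsd_pct=rsd,
                n_before=len(before),
                n_after=len(after),
                reason=None if rec is not None else "after-spike mean is zero",
            )
        )
    return results


def compare_sorbents(
    results: Iterable[RecoveryResult],
) -> tuple[list[RecoveryResult], list[RecoveryResult]]:
    """Per-sorbent comparison table plus a mean summary row per sorbent.

    Missing (None) entries are excluded from that sorbent's means but do not
    affect other sorbents. Returns (per-compound rows, summary rows); the
    summary row's compound is ``"average_across_all_species"``.
    """
    rows = sorted(
        results, key=lambda r: (r.sorbent, r.compound)
    )
    summaries: list[RecoveryResult] = []
    for sorbent in sorted({r.sorbent for r in rows}):
        recs = [r.recovery_pct for r in rows if r.sorbent == sorbent and r.recovery_pct is not None]
        rsds = [r.rsd_pct for r in rows if r.sorbent == sorbent and r.rsd_pct is not None]
        summaries.append(
            RecoveryResult(
                compound="average_across_all_species",
                sorbent=sorbent,
                recovery_pct=statistics.fmean(recs) if recs else None,
                rsd_pct=statistics.fmean(rsds) if rsds else None,
                n_before=len(recs),
                n_after=len(recs),
            )
        )
    return rows, summaries
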