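"""Tabular I/O: peak-area exports, sample manifests, site metadata, results.

All files are delimited text (comma by default, tab selectable) with a header
row. Peak tables are long/tidy: one row per (sample, compound, transition).
Censored concentrations are encoded as a ``status`` column plus numeric
bounds — never as sentinel strings like ``"<LOD"`` — so downstream numeric
summaries stay well-defined. Writers emit a fixed column order and fixed
float formatting, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_TYPES",
    "TRANSITIONS",
    "PeakRecord",
    "SampleMeta",
    "SiteMeta",
    "SchemaError",
    "read_peak_table",
    "read_manifest",
    "read_sites",
    "peaks_to_frame",
    "write_peak_table",
    "write_manifest",
    "write_sites",
    "write_results",
    "write_rates",
    "write_recovery",
]

SAMPLE_TYPES = (
    "calibrant",
    "blank",
    "qc_unspiked",
    "qc_spiked",
    "field",
    "spike_before",
    "spike_after",
)
TRANSITIONS = ("quant", "confirm")

# shortest-exact is not available as a printf spec; 17 significant digits
# guarantee float round-trip, keeping read(write(x)) == x
_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A table failed schema or invariant validation; message carries row numbers."""


@dataclass(frozen=True)
class PeakRecord:
    """One (sample, compound, transition) peak-area observation."""

    sample_id: str
    compound: str
    transition: str
    area: float
    height: float | None = None
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.transition not in TRANSITIONS:
            raise SchemaError(
                f"transition must be one of {TRANSITIONS}, got {self.transition!r}"
            )
        if not self.area >= 0:
            raise SchemaError(f"area must be >= 0, got {self.area}")
        if self.height is not None and not self.height >= 0:
            raise SchemaError(f"height must be >= 0, got {self.height}")
        if self.noise_sd is not None and not self.noise_sd > 0:
            raise SchemaError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SampleMeta:
    """Manifest entry for one injected sample.

    ``nominal`` maps compound name to spiked concentration in ng/mL (required
    for calibrants and spiked QCs). ``mass_g`` is the gravimetric sample mass
    (required for field samples). ``replicate_group`` ties spike-before /
    spike-after recovery replicates together; ``sorbent`` labels the SPE
    cartridge used for a recovery sample.
    """

    sample_id: str
    sample_type: str
    nominal: dict[str, float] | None = None
    mass_g: float | None = None
    density_g_per_ml: float = 1.0
    site_id: str | None = None
    collected_on: _dt.date | None = None
    replicate_group: str | None = None
    sorbent: str | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise SchemaError(
                f"sample {self.sample_id!r}: sample_type must be one of "
                f"{SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.sample_type in ("calibrant", "qc_spiked") and not self.nominal:
            raise SchemaError(
                f"sample {self.sample_id!r}: {self.sample_type} requires nominal"
            )
        if self.sample_type == "field" and self.mass_g is None:
            raise SchemaError(f"sample {self.sample_id!r}: field requires mass_g")
        if self.sample_type in ("spike_before", "spike_after") and not self.replicate_group:
            raise SchemaError(
                f"sample {self.sample_id!r}: {self.sample_type} requires replicate_group"
            )
        if self.mass_g is not None and not self.mass_g > 0:
            raise SchemaError(f"sample {self.sample_id!r}: mass_g must be > 0")
        if not self.density_g_per_ml > 0:
            raise SchemaError(f"sample {self.sample_id!r}: density must be > 0")


@dataclass(frozen=True)
class SiteMeta:
    """Treatment-facility metadata needed for per-capita back-calculation."""

    site_id: str
    population: float
    flow_l_per_day: float
    measured_on: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.population > 0:
            raise SchemaError(f"site {self.site_id!r}: population must be > 0")
        if not self.flow_l_per_day > 0:
            raise SchemaError(f"site {self.site_id!r}: flow must be > 0")


# ---------------------------------------------------------------------------
# readers


def _read_table(path, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _num(value: str, column: str, row: int, path) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise SchemaError(
            f"{path} row {row}: column {column!r}: cannot parse {value!r} as number"
        ) from None


def read_peak_table(path: str | Path, delimiter: str = ",") -> list[PeakRecord]:
    """Read a long-format peak table (sample_id, compound, transition, area,
    height, noise_sd). Unknown compound names are preserved; panel validation
    happens downstream."""
    df = _read_table(path, delimiter, ["sample_id", "compound", "transition", "area"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                PeakRecord(
                    sample_id=row.sample_id,
                    compound=row.compound,
                    transition=row.transition,
                    area=_num(row.area, "area", i, path),
                    height=_num(getattr(row, "height", ""), "height", i, path),
                    noise_sd=_num(getattr(row, "noise_sd", ""), "noise_sd", i, path),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from None
        except TypeError:
            raise SchemaError(f"{path} row {i}: missing area") from None
    return records


def _parse_nominal(text: str) -> dict[str, float] | None:
    """Nominal spikes are serialized as ``compound=conc;compound=conc``."""
    if not text:
        return None
    out: dict[str, float] = {}
    for item in text.split(";"):
        k, _, v = item.partition("=")
        out[k.strip()] = float(v)
    return out


def _fmt_nominal(nominal: dict[str, float] | None) -> str:
    if not nominal:
        return ""
    return ";".join(f"{k}={_FLOAT_FMT % v}" for k, v in sorted(nominal.items()))


def read_manifest(path: str | Path, delimiter: str = ",") -> list[SampleMeta]:
    df = _read_table(path, delimiter, ["sample_id", "sample_type"])
    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sample_id in seen:
            raise SchemaError(f"{path} row {i}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        try:
            records.append(
                SampleMeta(
                    sample_id=row.sample_id,
                    sample_type=row.sample_type,
                    nominal=_parse_nominal(getattr(row, "nominal", "")),
                    mass_g=_num(getattr(row, "mass_g", ""), "mass_g", i, path),
                    density_g_per_ml=_num(
                        getattr(row, "density_g_per_ml", "") or "1.0",
                        "density_g_per_ml", i, path,
                    ),
                    site_id=getattr(row, "site_id", "") or None,
                    collected_on=(
                        _dt.date.fromisoformat(row.collected_on)
                        if getattr(row, "collected_on", "")
                        else None
                    ),
                    replicate_group=getattr(row, "replicate_group", "") or None,
                    sorbent=getattr(row, "sorbent", "") or None,
                )
            )
        except SchemaError as exc:
            msg = str(exc)
            raise SchemaError(msg if str(path) in msg else f"{path} row {i}: {exc}") from None
    return records


def read_sites(path: str | Path, delimiter: str = ",") -> list[SiteMeta]:
    df = _read_table(path, delimiter, ["site_id", "population", "flow_l_per_day"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SiteMeta(
                    site_id=row.site_id,
                    population=_num(row.population, "population", i, path),
                    flow_l_per_day=_num(row.flow_l_per_day, "flow_l_per_day", i, path),
                    measured_on=(
                        _dt.date.fromisoformat(row.measured_on)
                        if getattr(row, "measured_on", "")
                        else None
                    ),
                )
            )
        except SchemaError as exc:
            msg = str(exc)
            raise SchemaError(msg if str(path) in msg else f"{path} row {i}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# writers — deterministic column order and float formatting


def _write(df: pd.DataFrame, path, delimiter: str) -> None:
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def peaks_to_frame(peaks: Iterable[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "compound": p.compound,
                "transition": p.transition,
                "area": p.area,
                "height": np.nan if p.height is None else p.height,
                "noise_sd": np.nan if p.noise_sd is None else p.noise_sd,
            }
            for p in peaks
        ],
        columns=["sample_id", "compound", "transition", "area", "height", "noise_sd"],
    )


def write_peak_table(peaks: Iterable[PeakRecord], path, delimiter: str = ",") -> None:
    _write(peaks_to_frame(peaks), path, delimiter)


def write_manifest(samples: Iterable[SampleMeta], path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "sample_type": s.sample_type,
                "nominal": _fmt_nominal(s.nominal),
                "mass_g": np.nan if s.mass_g is None else s.mass_g,
                "density_g_per_ml": s.density_g_per_ml,
                "site_id": s.site_id or "",
                "collected_on": s.collected_on.isoformat() if s.collected_on else "",
                "replicate_group": s.replicate_group or "",
                "sorbent": s.sorbent or "",
            }
            for s in samples
        ],
        columns=[
            "sample_id", "sample_type", "nominal", "mass_g", "density_g_per_ml",
            "site_id", "collected_on", "replicate_group", "sorbent",
        ],
    )
    _write(df, path, delimiter)


def write_sites(sites: Iterable[SiteMeta], path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "population": s.population,
                "flow_l_per_day": s.flow_l_per_day,
                "measured_on": s.measured_on.isoformat() if s.measured_on else "",
            }
            for s in sites
        ],
        columns=["site_id", "population", "flow_l_per_day", "measured_on"],
    )
    _write(df, path, delimiter)


_RESULT_COLUMNS = [
    "sample_id", "compound", "batch_id", "extract_conc_ng_ml", "sample_conc_ngl",
    "status", "lod_ngl", "loq_ngl", "qc_pass",
]


def write_results(measurements, path, delimiter: str = ",") -> None:
    """Write quantified measurements; censoring is (status, bound) encoded."""
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "compound": m.compound,
                "batch_id": m.batch_id,
                "extract_conc_ng_ml": m.extract_conc,
                "sample_conc_ngl": m.sample_conc,
                "status": m.status,
                "lod_ngl": m.lod_ngl,
                "loq_ngl": m.loq_ngl,
                "qc_pass": m.qc_pass,
            }
            for m in measurements
        ],
        columns=_RESULT_COLUMNS,
    )
    _write(df, path, delimiter)


def write_rates(rates, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "date": r.collected_on.isoformat() if r.collected_on else "",
                "biomarker": r.compound,
                "parent": r.parent_compound,
                "excretion_mg_day_1000": r.excretion_rate,
                "consumption_mg_day_1000": (
                    np.nan if r.consumption_rate is None else r.consumption_rate
                ),
                "status": r.flags,
            }
            for r in rates
        ],
        columns=[
            "site_id", "date", "biomarker", "parent",
            "excretion_mg_day_1000", "consumption_mg_day_1000", "status",
        ],
    )
    _write(df, path, delimiter)


def write_recovery(results, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "compound": r.compound,
                "sorbent": r.sorbent,
                "recovery_pct": np.nan if r.recovery_pct is None else r.recovery_pct,
                "rsd_pct": np.nan if r.rsd_pct is None else r.rsd_pct,
                "n_before": r.n_before,
                "n_after": r.n_after,
            }
            for r in results
        ],
        columns=["compound", "sorbent", "recovery_pct", "rsd_pct", "n_before", "n_after"],
    )
    _write(df, path, delimiter)
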