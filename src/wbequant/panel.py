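"""Compound registry: the analyte panel and internal-standard assignments.

Every downstream stage (calibration, quantitation, back-calculation) consults
the panel for the native/labelled-standard mapping, molecular weights,
parent–metabolite links, and urinary excretion fractions. The panel is data,
not code: it ships as a YAML file and can be replaced wholesale by the user.

A panel distinguishes *natives* (the analytes being measured) from *standards*
(co-spiked isotopically labelled analogs). Several natives may share one
surrogate standard when no exact labelled analog is spiked.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "DRUG_CLASSES",
    "ROLES",
    "Transitions",
    "CompoundSpec",
    "InternalStandardSpec",
    "Panel",
    "PanelError",
    "load_panel",
    "save_panel",
    "panel_from_csv",
    "default_panel",
    "resolve_is",
    "class_counts",
]

DRUG_CLASSES = (
    "opioid",
    "stimulant",
    "benzodiazepine",
    "synthetic_cathinone",
    "dissociative",
    "other",
)
ROLES = ("parent", "metabolite", "other")


class PanelError(ValueError):
    """Raised when a panel file fails validation."""


@dataclass(frozen=True)
class Transitions:
    """SRM transition metadata: precursor and product m/z with collision energies.

    Carried for documentation/export only; no computation depends on these.
    """

    precursor_mz: float
    quantifier_mz: float
    confirmer_mz: float | None = None
    ce_quantifier: float | None = None
    ce_confirmer: float | None = None


@dataclass(frozen=True)
class CompoundSpec:
    """One native analyte: chemistry, class, IS assignment, PK constants."""

    name: str
    drug_class: str
    molecular_weight: float
    internal_standard: str
    role: str = "parent"
    parent_name: str | None = None
    excretion_fraction: float | None = None
    transitions: Transitions | None = None

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise PanelError(
                f"{self.name}: drug_class {self.drug_class!r} not one of {DRUG_CLASSES}"
            )
        if self.role not in ROLES:
            raise PanelError(f"{self.name}: role {self.role!r} not one of {ROLES}")
        if not self.molecular_weight > 0:
            raise PanelError(f"{self.name}: molecular_weight must be > 0")
        if self.excretion_fraction is not None and not (
            0 < self.excretion_fraction <= 1
        ):
            raise PanelError(
                f"{self.name}: excretion_fraction must be in (0, 1], "
                f"got {self.excretion_fraction}"
            )


@dataclass(frozen=True)
class InternalStandardSpec:
    """One isotopically labelled internal standard."""

    name: str
    labelled_analog_of: str | None = None
    transitions: Transitions | None = None


@dataclass(frozen=True)
class Panel:
    """A validated analyte panel: natives plus labelled standards."""

    natives: tuple[CompoundSpec, ...]
    standards: tuple[InternalStandardSpec, ...]
    _native_index: Mapping[str, CompoundSpec] = field(
        default=None, repr=False, compare=False
    )
    _standard_index: Mapping[str, InternalStandardSpec] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_native_index", {c.name: c for c in self.natives}
        )
        object.__setattr__(
            self, "_standard_index", {s.name: s for s in self.standards}
        )
        self._validate()

    def _validate(self) -> None:
        names = [c.name for c in self.natives] + [s.name for s in self.standards]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise PanelError(f"duplicate compound name in panel: {n!r}")
            seen.add(n)
        for c in self.natives:
            if c.internal_standard not in self._standard_index:
                raise PanelError(
                    f"{c.name}: internal_standard {c.internal_standard!r} "
                    "is not a declared standard"
                )
            if c.role == "metabolite" and c.parent_name is not None:
                parent = self._native_index.get(c.parent_name)
                if parent is None:
                    raise PanelError(
                        f"{c.name}: parent_name {c.parent_name!r} "
                        "does not resolve to a panel native"
                    )
                if parent.role != "parent":
                    raise PanelError(
                        f"{c.name}: parent {c.parent_name!r} has role "
                        f"{parent.role!r}, expected 'parent'"
                    )
        for s in self.standards:
            if (
                s.labelled_analog_of is not None
                and s.labelled_analog_of not in self._native_index
            ):
                raise PanelError(
                    f"{s.name}: labelled_analog_of {s.labelled_analog_of!r} "
                    "does not resolve to a panel native"
                )

    # -- queries -----------------------------------------------------------

    def native(self, name: str) -> CompoundSpec:
        try:
            return self._native_index[name]
        except KeyError:
            raise KeyError(f"unknown native compound: {name!r}") from None

    def standard(self, name: str) -> InternalStandardSpec:
        try:
            return self._standard_index[name]
        except KeyError:
            raise KeyError(f"unknown internal standard: {name!r}") from None

    def is_native(self, name: str) -> bool:
        return name in self._native_index

    def is_standard(self, name: str) -> bool:
        return name in self._standard_index

    @property
    def native_names(self) -> tuple[str, ...]:
        return tuple(self._native_index)

    @property
    def standard_names(self) -> tuple[str, ...]:
        return tuple(self._standard_index)


# ---------------------------------------------------------------------------
# construction / (de)serialisation


def _transitions_from_dict(d: Mapping | None) -> Transitions | None:
    if d is None:
        return None
    return Transitions(
        precursor_mz=float(d["precursor_mz"]),
        quantifier_mz=float(d["quantifier_mz"]),
        confirmer_mz=(None if d.get("confirmer_mz") is None else float(d["confirmer_mz"])),
        ce_quantifier=(None if d.get("ce_quantifier") is None else float(d["ce_quantifier"])),
        ce_confirmer=(None if d.get("ce_confirmer") is None else float(d["ce_confirmer"])),
    )


def _panel_from_mapping(doc: Mapping) -> Panel:
    natives = []
    for entry in doc.get("natives", []):
        try:
            natives.append(
                CompoundSpec(
                    name=str(entry["name"]),
                    drug_class=str(entry["class"]),
                    molecular_weight=float(entry["molecular_weight"]),
                    internal_standard=str(entry["internal_standard"]),
                    role=str(entry.get("role", "parent")),
                    parent_name=entry.get("parent"),
                    excretion_fraction=(
                        None
                        if entry.get("excretion_fraction") is None
                        else float(entry["excretion_fraction"])
                    ),
                    transitions=_transitions_from_dict(entry.get("transitions")),
                )
            )
        except KeyError as exc:
            raise PanelError(
                f"native entry {entry.get('name', '<unnamed>')!r}: "
                f"missing required key {exc}"
            ) from None
    standards = [
        InternalStandardSpec(
            name=str(e["name"]),
            labelled_analog_of=e.get("labelled_analog_of"),
            transitions=_transitions_from_dict(e.get("transitions")),
        )
        for e in doc.get("standards", [])
    ]
    return Panel(natives=tuple(natives), standards=tuple(standards))


def load_panel(path: str | Path) -> Panel:
    """Load and validate a panel from a YAML config file.

    Raises :class:`PanelError` naming the offending compound on any
    invariant violation (dangling IS assignment, missing molecular weight,
    unresolvable parent link, duplicate name).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise PanelError(f"{path}: expected a mapping with 'natives'/'standards'")
    return _panel_from_mapping(doc)


def _transitions_to_dict(t: Transitions | None):
    if t is None:
        return None
    d = asdict(t)
    return {k: v for k, v in d.items() if v is not None}


def save_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to YAML; ``load_panel(save_panel(p)) == p``."""
    doc = {
        "natives": [
            {
                "name": c.name,
                "class": c.drug_class,
                "molecular_weight": c.molecular_weight,
                "internal_standard": c.internal_standard,
                "role": c.role,
                **({"parent": c.parent_name} if c.parent_name else {}),
                **(
                    {"excretion_fraction": c.excretion_fraction}
                    if c.excretion_fraction is not None
                    else {}
                ),
                **(
                    {"transitions": _transitions_to_dict(c.transitions)}
                    if c.transitions is not None
                    else {}
                ),
            }
            for c in panel.natives
        ],
        "standards": [
            {
                "name": s.name,
                **(
                    {"labelled_analog_of": s.labelled_analog_of}
                    if s.labelled_analog_of
                    else {}
                ),
                **(
                    {"transitions": _transitions_to_dict(s.transitions)}
                    if s.transitions is not None
                    else {}
                ),
            }
            for s in panel.standards
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_CSV_COLUMNS = {"name", "class", "mw", "role", "parent", "excretion_fraction", "is_name"}


def panel_from_csv(path: str | Path) -> Panel:
    """Import a panel from a flat CSV table.

    Expected columns: ``name, class, mw, role, parent, excretion_fraction,
    is_name`` and optionally ``q1, q3_quant, q3_confirm, ce1, ce2``. Standards
    are derived from the distinct ``is_name`` values; a row whose ``name``
    equals an ``is_name`` declares that standard's own transition metadata.
    """
    df = pd.read_csv(path)
    missing = _CSV_COLUMNS - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing columns {sorted(missing)}")
    natives = []
    for _, row in df.iterrows():
        trans = None
        if "q1" in df.columns and pd.notna(row.get("q1")):
            trans = Transitions(
                precursor_mz=float(row["q1"]),
                quantifier_mz=float(row["q3_quant"]),
                confirmer_mz=(
                    float(row["q3_confirm"]) if pd.notna(row.get("q3_confirm")) else None
                ),
                ce_quantifier=float(row["ce1"]) if pd.notna(row.get("ce1")) else None,
                ce_confirmer=float(row["ce2"]) if pd.notna(row.get("ce2")) else None,
            )
        natives.append(
            CompoundSpec(
                name=str(row["name"]),
                drug_class=str(row["class"]),
                molecular_weight=float(row["mw"]),
                internal_standard=str(row["is_name"]),
                role=str(row["role"]) if pd.notna(row["role"]) else "parent",
                parent_name=str(row["parent"]) if pd.notna(row["parent"]) else None,
                excretion_fraction=(
                    float(row["excretion_fraction"])
                    if pd.notna(row["excretion_fraction"])
                    else None
                ),
                transitions=trans,
            )
        )
    standards = [
        InternalStandardSpec(name=n) for n in dict.fromkeys(df["is_name"].astype(str))
    ]
    return Panel(natives=tuple(natives), standards=tuple(standards))


def default_panel() -> Panel:
    """Load the packaged default 52-native / 22-standard panel."""
    ref = importlib.resources.files("wbequant.data") / "default_panel.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_panel(p)


# ---------------------------------------------------------------------------
# queries


def resolve_is(panel: Panel, compound: str) -> InternalStandardSpec:
    """Return the internal standard assigned to a native compound.

    Multiple natives may share one surrogate standard; the mapping lives in
    the panel config.
    """
    spec = panel.native(compound)
    return panel.standard(spec.internal_standard)


def class_counts(panel: Panel) -> dict[str, int]:
    """Count natives per drug class (standards excluded); all classes present."""
    counts = {cls: 0 for cls in DRUG_CLASSES}
    for c in panel.natives:
        counts[c.drug_class] += 1
    return counts
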