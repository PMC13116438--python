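"""Isotope-dilution calibration: response ratios, weighted linear fits, inversion.

Quantitation is by isotope dilution: each native's quantifier peak area is
divided by the quantifier area of its assigned isotopically labelled internal
standard, cancelling per-sample matrix suppression/enhancement and injection
variability. The response ratio is regressed on nominal concentration over
the calibrant series with weighted least squares; inverse prediction converts
field-sample ratios to extract concentrations (ng/mL).

Over a five-orders-of-magnitude range (0.001–200 ng/mL) an unweighted fit is
dominated by the top level, so the default weighting is 1/x; ``none`` and
``1/x²`` are selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .batchio import PeakRecord, SampleMeta
from .panel import Panel

__all__ = [
    "WEIGHTINGS",
    "ResponseRatio",
    "CalibrationFit",
    "CalibrationError",
    "default_levels",
    "response_ratios",
    "fit_calibration",
    "slope_relative_se",
    "predict",
    "invert",
]

WEIGHTINGS = ("none", "1/x", "1/x^2")

DEFAULT_ACCEPTANCE_R2 = 0.995  # strict default; 0.99 selectable


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseRatio:
    """Native quantifier area ÷ assigned-IS quantifier area for one sample."""

    compound: str
    sample_id: str
    ratio: float

    def __post_init__(self) -> None:
        if not self.ratio >= 0:
            raise CalibrationError(f"{self.compound}: ratio must be >= 0")


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted (and possibly rejected) isotope-dilution calibration line."""

    compound: str
    slope: float
    intercept: float
    weighting: str
    r_squared: float
    level_range: tuple[float, float]
    n_levels: int
    accepted: bool

    def __post_init__(self) -> None:
        if self.accepted and not self.slope > 0:
            raise CalibrationError(
                f"{self.compound}: accepted fit requires slope > 0"
            )
        if not self.level_range[0] < self.level_range[1]:
            raise CalibrationError(f"{self.compound}: level_range min must be < max")


def default_levels(
    n_levels: int = 22, low: float = 0.001, high: float = 200.0
) -> np.ndarray:
    """The default calibrant design: 22 levels spaced geometrically 0.001–200 ng/mL."""
    if n_levels < 3:
        raise CalibrationError("need at least 3 levels")
    return np.geomspace(low, high, n_levels)


def _quant_areas(peaks: Iterable[PeakRecord]) -> dict[tuple[str, str], float]:
    return {
        (p.sample_id, p.compound): p.area
        for p in peaks
        if p.transition == "quant"
    }


def response_ratios(
    peaks: Iterable[PeakRecord],
    manifest: Iterable[SampleMeta],
    panel: Panel,
    sample_types: Sequence[str] = ("calibrant",),
) -> list[ResponseRatio]:
    """Form native/IS quantifier-area ratios for samples of the given types.

    Samples whose IS area is zero or missing are excluded with a warning —
    without an IS signal the isotope-dilution ratio is undefined. A native
    area of zero yields ratio 0 and is retained.
    """
    areas = _quant_areas(peaks)
    wanted = {s.sample_id for s in manifest if s.sample_type in sample_types}
    out: list[ResponseRatio] = []
    for (sample_id, compound), area in sorted(areas.items()):
        if sample_id not in wanted or not panel.is_native(compound):
            continue
        is_name = panel.native(compound).internal_standard
        is_area = areas.get((sample_id, is_name))
        if is_area is None:
            warnings.warn(
                f"{compound} in {sample_id}: no IS record for {is_name}; excluded"
            )
            continue
        if is_area == 0:
            warnings.warn(
                f"{compound} in {sample_id}: IS area is 0; ratio undefined, excluded"
            )
            continue
        out.append(ResponseRatio(compound=compound, sample_id=sample_id, ratio=area / is_area))
    return out


def fit_calibration(
    ratios: Sequence[float],
    levels: Sequence[float],
    compound: str = "",
    weighting: str = "1/x",
    acceptance_r2: float = DEFAULT_ACCEPTANCE_R2,
) -> CalibrationFit:
    """Weighted least-squares line ``ratio = slope·conc + intercept``.

    R² is computed on the weighted fit (weighted residual and total sums of
    squares about the weighted mean). ``accepted`` is ``r_squared >=
    acceptance_r2`` and slope > 0; a degenerate flat series yields a rejected
    fit rather than an exception when the algebra is well-posed.
    """
    y = np.asarray(ratios, dtype=float)
    x = np.asarray(levels, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError(f"{compound}: ratios and levels length mismatch")
    if np.unique(x).size < 3:
        raise CalibrationError(
            f"{compound}: need >= 3 distinct calibration levels, got {np.unique(x).size}"
        )
    if np.any(x <= 0):
        raise CalibrationError(f"{compound}: nominal levels must be > 0")
    if weighting not in WEIGHTINGS:
        raise CalibrationError(
            f"{compound}: weighting must be one of {WEIGHTINGS}, got {weighting!r}"
        )

    w = {"none": np.ones_like(x), "1/x": 1.0 / x, "1/x^2": 1.0 / x**2}[weighting]
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise CalibrationError(f"{compound}: zero variance in levels")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    ss_res = (w * (y - slope * x - intercept) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    accepted = bool(r2 >= acceptance_r2 and slope > 0)
    return CalibrationFit(
        compound=compound,
        slope=slope,
        intercept=intercept,
        weighting=weighting,
        r_squared=float(min(r2, 1.0)),
        level_range=(float(x.min()), float(x.max())),
        n_levels=int(np.unique(x).size),
        accepted=accepted,
    )


def slope_relative_se(
    levels: Sequence[float], weighting: str = "1/x", ratio_cv: float = 0.05
) -> float:
    """Analytic relative standard error of the WLS slope under multiplicative
    response noise.

    With response variance ``(ratio_cv·slope·x)²`` (pure multiplicative noise,
    negligible intercept) the sandwich variance of the weighted slope depends
    only on the level design, the weighting, and ``ratio_cv``. Used to
    propagate calibration uncertainty into measurement-error predictions:
    the total measurement CV is ``hypot(ratio_cv, slope_relative_se(...))``.
    """
    x = np.asarray(levels, dtype=float)
    if weighting not in WEIGHTINGS:
        raise CalibrationError(f"weighting must be one of {WEIGHTINGS}")
    w = {"none": np.ones_like(x), "1/x": 1.0 / x, "1/x^2": 1.0 / x**2}[weighting]
    xbar = (w * x).sum() / w.sum()
    c = w * (x - xbar)
    denom = (c * x).sum()
    return float(np.sqrt((c**2 * ratio_cv**2 * x**2).sum()) / denom)


def predict(fit: CalibrationFit, conc: float) -> float:
    """Forward model: expected response ratio at an extract concentration."""
    return fit.slope * conc + fit.intercept


def invert(fit: CalibrationFit, ratio: float) -> float:
    """Inverse prediction: extract concentration (ng/mL) from a response ratio.

    Negative predictions (ratio below the intercept) are returned as-is;
    censoring against the LOD happens downstream. Refuses unaccepted fits.
    """
    if not fit.accepted:
        raise CalibrationError(
            f"{fit.compound}: refusing inverse prediction from unaccepted fit "
            f"(R²={fit.r_squared:.4f})"
        )
    return (ratio - fit.intercept) / fit.slope
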