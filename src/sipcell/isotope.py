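"""Isotope-ratio arithmetic shared by every downstream stage.

Atom fractions from secondary-ion counts, natural-abundance baselines,
Poisson counting error of a ratio summed over acquisition planes, and the
atom-percent bookkeeping for the labeled substrate pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "UndefinedMeasurementError",
    "IonCountPair",
    "AtomFraction",
    "NaturalAbundance",
    "LabelingState",
    "atom_fraction",
    "atom_percent_excess",
    "poisson_relative_error",
    "passes_poisson_filter",
    "labeling_atom_percent",
    "DEFAULT_NATURAL_ABUNDANCE",
    "DEFAULT_POISSON_THRESHOLD",
]

#: Per-cell Poisson relative-error cutoff below which an enrichment
#: measurement is considered usable.
DEFAULT_POISSON_THRESHOLD: float = 0.05


class UndefinedMeasurementError(ValueError):
    """Raised when a ratio is requested from zero total ion counts."""


@dataclass(frozen=True)
class IonCountPair:
    """Minor/major isotope ion counts for one acquisition plane.

    ``minor`` is the rare-isotope-bearing ion count (e.g. 15N), ``major``
    the common one (e.g. 14N).
    """

    minor: int
    major: int
    plane_index: int = 0

    def __post_init__(self) -> None:
        if self.minor < 0 or self.major < 0:
            raise ValueError("ion counts must be non-negative")
        if self.plane_index < 0:
            raise ValueError("plane_index must be non-negative")

    @property
    def total(self) -> int:
        return self.minor + self.major


@dataclass(frozen=True)
class AtomFraction:
    """A rare-isotope atom fraction minor/(minor+major) for one element."""

    value: float
    element: str = "N"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"atom fraction {self.value} outside [0, 1]")
        if self.element not in ("N", "C"):
            raise ValueError(f"unknown element {self.element!r}")


@dataclass(frozen=True)
class NaturalAbundance:
    """Natural-abundance rare-isotope fractions used as enrichment baseline."""

    n15_fraction: float = 0.0037
    c13_fraction: float = 0.0111

    def fraction(self, element: str) -> float:
        if element == "N":
            return self.n15_fraction
        if element == "C":
            return self.c13_fraction
        raise ValueError(f"unknown element {element!r}")

    def atom_percent(self, element: str) -> float:
        return 100.0 * self.fraction(element)


DEFAULT_NATURAL_ABUNDANCE = NaturalAbundance()


@dataclass
class LabelingState:
    """Isotopic composition of a substrate pool after tracer addition.

    Concentrations are in mol/L. ``tracer_atom_fraction`` is the isotopic
    purity of the added tracer (configurable; 0.99 by default). If the
    labeling percentage of the pool was measured directly at t0, set
    ``measured_excess_at_percent`` and it takes precedence.
    """

    substrate: str
    added_concentration: float
    ambient_concentration: float
    tracer_atom_fraction: float = 0.99
    measured_excess_at_percent: float | None = None

    def __post_init__(self) -> None:
        if self.added_concentration < 0 or self.ambient_concentration < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 < self.tracer_atom_fraction <= 1.0:
            raise ValueError("tracer_atom_fraction must be in (0, 1]")

    def label_excess(
        self, baseline: NaturalAbundance = DEFAULT_NATURAL_ABUNDANCE, element: str = "N"
    ) -> float:
        """At%-excess of the pool; measured value wins over the computed one."""
        if self.measured_excess_at_percent is not None:
            return self.measured_excess_at_percent
        return labeling_atom_percent(self, baseline, element=element)


def atom_fraction(minor: float, major: float, element: str = "N") -> AtomFraction:
    """Rare-isotope atom fraction minor/(minor + major).

    Raises
    ------
    UndefinedMeasurementError
        If both counts are zero (no ions collected).
    """
    if minor < 0 or major < 0:
        raise ValueError("counts must be non-negative")
    total = minor + major
    if total <= 0:
        raise UndefinedMeasurementError("zero total ion counts: ratio undefined")
    return AtomFraction(minor / total, element=element)


def atom_percent_excess(
    x: AtomFraction, baseline: NaturalAbundance = DEFAULT_NATURAL_ABUNDANCE
) -> float:
    """At% above the natural-abundance baseline for the fraction's element.

    Negative excess (measurement scatter below baseline) is preserved, not
    clipped, so that population means stay unbiased.
    """
    return 100.0 * x.value - baseline.atom_percent(x.element)


def _summed_counts(planes: Iterable[IonCountPair]) -> tuple[int, int]:
    total_minor = 0
    total_major = 0
    n = 0
    for p in planes:
        total_minor += p.minor
        total_major += p.major
        n += 1
    if n == 0:
        raise ValueError("at least one plane is required")
    return total_minor, total_major


def poisson_relative_error(planes: Sequence[IonCountPair]) -> float:
    """Relative Poisson counting error of the plane-summed isotope ratio.

    Counts are summed across all planes of the cell; the standard error
    propagation for a ratio of two Poisson counts gives
    ``sqrt(1/sum_minor + 1/sum_major)``. Returns ``inf`` if the summed
    minor count is zero.
    """
    total_minor, total_major = _summed_counts(planes)
    if total_minor + total_major == 0:
        raise UndefinedMeasurementError("zero total ion counts across all planes")
    if total_minor == 0 or total_major == 0:
        return math.inf
    return math.sqrt(1.0 / total_minor + 1.0 / total_major)


def passes_poisson_filter(
    planes: Sequence[IonCountPair], threshold: float = DEFAULT_POISSON_THRESHOLD
) -> tuple[bool, float, str]:
    """Apply the per-cell counting-error filter.

    Returns ``(passed, relative_error, reason)``; ``reason`` is empty for
    passing cells and names the failure otherwise.
    """
    err = poisson_relative_error(planes)
    if math.isinf(err):
        return False, err, "zero minor- or major-isotope counts"
    if err >= threshold:
        return False, err, f"relative error {err:.4f} >= {threshold}"
    return True, err, ""


def labeling_atom_percent(
    state: LabelingState,
    baseline: NaturalAbundance = DEFAULT_NATURAL_ABUNDANCE,
    element: str = "N",
) -> float:
    """At%-excess of the substrate pool after tracer addition.

    Mixes the added tracer (at its atom-fraction purity) with the ambient
    pool at natural abundance and subtracts the natural-abundance at%.
    """
    added = state.added_concentration
    ambient = state.ambient_concentration
    total = added + ambient
    if total <= 0:
        raise ValueError("added + ambient concentration must be positive")
    base = baseline.fraction(element)
    pool_fraction = (state.tracer_atom_fraction * added + base * ambient) / total
    return 100.0 * pool_fraction - 100.0 * base
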