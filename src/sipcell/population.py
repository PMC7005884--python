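"""Population-level bookkeeping.

Growth rates and doubling times from cell counts, per-cell rates from bulk
volumetric rates, population carbon stocks and assimilation fluxes, and
FPKM-based marker-gene fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .units import FG_PER_UG, FG_C_PER_FMOL, FMOL_PER_NMOL

__all__ = [
    "PopulationSnapshot",
    "growth_rate_counts",
    "growth_rate_counts_se",
    "doubling_time",
    "mean_abundance",
    "per_cell_bulk_rate",
    "population_carbon",
    "population_assimilation",
    "c_assim_from_count_increase",
    "marker_fpkm",
    "gene_fraction",
]


@dataclass
class PopulationSnapshot:
    """Abundance of one taxon at the start and end of an incubation."""

    taxon: str
    abundance_t0: float  # cells/L
    abundance_t1: float  # cells/L
    t_days: float
    counted_t0: int | None = None  # raw cells counted (for error models)
    counted_t1: int | None = None

    def __post_init__(self) -> None:
        if self.abundance_t0 < 0 or self.abundance_t1 < 0:
            raise ValueError("abundances must be non-negative")
        if self.t_days <= 0:
            raise ValueError("t_days must be positive")


def growth_rate_counts(n0: float, nt: float, t_days: float) -> float:
    """Growth rate (d-1) from cell counts: ln(Nt/N0)/t."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("cell counts must be positive")
    if t_days <= 0:
        raise ValueError("t_days must be positive")
    return math.log(nt / n0) / t_days


def growth_rate_counts_se(counted_t0: int, counted_t1: int, t_days: float) -> float:
    """Delta-method standard error of the count-based growth rate.

    Models raw counted cells at each time point as Poisson, so
    Var(ln N) ~ 1/counted; SE(GR) = sqrt(1/c0 + 1/c1)/t.
    """
    if counted_t0 <= 0 or counted_t1 <= 0:
        raise ValueError("counted cells must be positive")
    return math.sqrt(1.0 / counted_t0 + 1.0 / counted_t1) / t_days


def doubling_time(gr: float) -> float:
    """Doubling time in days: ln(2)/GR."""
    if gr <= 0:
        raise ValueError("doubling time undefined for non-positive growth rate")
    return math.log(2.0) / gr


def mean_abundance(n0: float, nt: float) -> float:
    """Arithmetic mean of start and end abundances (cells/L)."""
    if n0 < 0 or nt < 0:
        raise ValueError("abundances must be non-negative")
    return 0.5 * (n0 + nt)


def per_cell_bulk_rate(bulk_rate_nmol_l_d: float, abundance_cells_l: float) -> float:
    """Per-cell rate (fmol cell-1 d-1) from a bulk volumetric rate.

    Divides the bulk rate by the mean abundance of the mediating
    population; nmol -> fmol is a factor 1e6.
    """
    if abundance_cells_l <= 0:
        raise ValueError("abundance must be positive")
    if bulk_rate_nmol_l_d < 0:
        raise ValueError("bulk rate must be non-negative")
    return bulk_rate_nmol_l_d * FMOL_PER_NMOL / abundance_cells_l


def population_carbon(abundance_cells_l: float, fg_c_cell: float) -> float:
    """Population carbon stock (µg-C L-1) = abundance x per-cell fg-C."""
    if abundance_cells_l < 0 or fg_c_cell < 0:
        raise ValueError("inputs must be non-negative")
    return abundance_cells_l * fg_c_cell / FG_PER_UG


def population_assimilation(per_cell_fmol_d: float, abundance_cells_l: float) -> float:
    """Population assimilation flux (nmol L-1 d-1) from a per-cell rate."""
    if per_cell_fmol_d < 0 or abundance_cells_l < 0:
        raise ValueError("inputs must be non-negative")
    return per_cell_fmol_d * abundance_cells_l / FMOL_PER_NMOL


def c_assim_from_count_increase(
    n0: float, nt: float, fg_c_cell: float, t_days: float
) -> float:
    """Population C-assimilation (nmol-C L-1 d-1) from the count increase.

    (Nt - N0) * fg-C per cell over the incubation, converted from fg-C
    (12 fg per fmol) to nmol. A count decrease yields 0 with a warning.
    """
    if t_days <= 0:
        raise ValueError("t_days must be positive")
    if nt < n0:
        warnings.warn("cell counts decreased during incubation; returning 0", stacklevel=2)
        return 0.0
    return (nt - n0) * fg_c_cell / (t_days * FG_C_PER_FMOL * FMOL_PER_NMOL)


def marker_fpkm(
    mapped_read_pairs: float, mean_gene_length_kb: float, library_read_pairs_millions: float
) -> float:
    """Fragments per kilobase per million read pairs."""
    if mean_gene_length_kb <= 0 or library_read_pairs_millions <= 0:
        raise ValueError("gene length and library size must be positive")
    if mapped_read_pairs < 0:
        raise ValueError("mapped read pairs must be non-negative")
    return mapped_read_pairs / (mean_gene_length_kb * library_read_pairs_millions)


def gene_fraction(fpkm_gene: float, fpkm_single_copy_marker: float) -> float:
    """Fraction of the population carrying a gene, as FPKM_gene / FPKM_marker.

    The marker is assumed universal and single copy; values near 1 mean
    essentially all cells carry the gene.
    """
    if fpkm_single_copy_marker <= 0:
        raise ValueError("marker FPKM must be positive")
    if fpkm_gene < 0:
        raise ValueError("gene FPKM must be non-negative")
    return fpkm_gene / fpkm_single_copy_marker
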