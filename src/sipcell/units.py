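"""Centralized unit conversions.

All mass/amount conversions used across the package live here so that the
fg <-> fmol and nmol <-> fmol factors have a single source of truth.
"""

#: grams (or fg) of nitrogen per mole (or fmol); the canonical factor used
#: when converting cellular N between mass and molar units.
FG_N_PER_FMOL: float = 14.0

#: grams (or fg) of carbon per mole (or fmol).
FG_C_PER_FMOL: float = 12.0

#: femtomoles per nanomole.
FMOL_PER_NMOL: float = 1.0e6

#: femtograms per microgram.
FG_PER_UG: float = 1.0e9

#: hours per day.
HOURS_PER_DAY: float = 24.0


def fg_n_to_fmol(fg: float) -> float:
    """Convert femtograms of nitrogen to femtomoles."""
    return fg / FG_N_PER_FMOL


def fg_c_to_fmol(fg: float) -> float:
    """Convert femtograms of carbon to femtomoles."""
    return fg / FG_C_PER_FMOL


def fmol_to_nmol(fmol: float) -> float:
    """Convert femtomoles to nanomoles."""
    return fmol / FMOL_PER_NMOL


def nmol_to_fmol(nmol: float) -> float:
    """Convert nanomoles to femtomoles."""
    return nmol * FMOL_PER_NMOL
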