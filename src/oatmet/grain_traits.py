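"""Deterministic grain-quality trait derivations.

Formulas used by oat millers and breeders to turn raw dehulling,
imaging and combine measurements into the standard quality traits:

* groat content — mass fraction of kernel recovered after dehulling;
* hullability — percentage of grains dehulled in one standard pass;
* roundness — grain width / length (0 elongated, 1 round);
* protein — nitrogen x 5.36, the oat-specific Jones factor;
* grain number per m2 — from yield and thousand-grain weight;
* yield moisture adjustment — rescaling fresh yield to a reference
  moisture content (15% by default) by dry-matter conservation.

All functions accept scalars or numpy arrays and raise
:class:`~oatmet.errors.DomainError` outside their mathematical domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError

__all__ = [
    "DehullResult",
    "OAT_NITROGEN_TO_PROTEIN",
    "groat_content",
    "hullability",
    "roundness",
    "protein_from_nitrogen",
    "grain_number",
    "adjust_yield_moisture",
    "derive_traits",
]

#: Nitrogen-to-protein conversion factor for oat groats.
OAT_NITROGEN_TO_PROTEIN = 5.36


@dataclass(frozen=True)
class DehullResult:
    """Masses (g) from one pass of a laboratory dehuller.

    ``initial`` whole-grain input mass; ``residual`` grain that came
    through still hulled; ``groat`` recovered kernel mass.  The hull
    mass absorbs the remainder, so ``residual + groat <= initial``.
    """

    initial: float
    residual: float
    groat: float

    def __post_init__(self) -> None:
        if self.initial <= 0:
            raise DomainError(f"initial mass must be > 0, got {self.initial}")
        if self.residual < 0 or self.groat < 0:
            raise DomainError("masses must be non-negative")
        if self.residual + self.groat > self.initial * (1 + 1e-9):
            raise DomainError(
                f"residual ({self.residual}) + groat ({self.groat}) exceeds "
                f"initial mass ({self.initial})"
            )


def groat_content(d: DehullResult) -> float:
    """Groat content (%) = 100 x groat / (initial - residual).

    The denominator is the mass actually dehulled; if nothing was
    dehulled (residual >= initial) the quantity is undefined.
    """
    if d.residual >= d.initial:
        raise DegenerateInputError(
            "nothing was dehulled (residual >= initial); groat content undefined"
        )
    return 100.0 * d.groat / (d.initial - d.residual)


def hullability(d: DehullResult) -> float:
    """Hullability (%) = 100 - 100 x residual / initial."""
    return 100.0 - 100.0 * d.residual / d.initial


def roundness(width, length):
    """Grain roundness: width / length, in (0, 1] for sane grains.

    A width exceeding the length usually means the two dimensions were
    swapped upstream; that triggers a warning, not an error.
    """
    width = np.asarray(width, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise DomainError("grain length must be > 0")
    if np.any(width <= 0):
        raise DomainError("grain width must be > 0")
    if np.any(width > length):
        warnings.warn(
            "grain width > length; dimensions possibly swapped", stacklevel=2
        )
    out = width / length
    return float(out) if out.ndim == 0 else out


def protein_from_nitrogen(n):
    """Groat protein (%) from nitrogen (%): N x 5.36."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise DomainError("nitrogen content cannot be negative")
    out = n * OAT_NITROGEN_TO_PROTEIN
    return float(out) if out.ndim == 0 else out


def grain_number(yield_t_ha, tgw_g):
    """Grain number (thousand grains per m2) from yield and TGW.

    1 t/ha = 100 g/m2, so grains per m2 = yield x 100 / TGW when TGW
    is in g per 1000 grains and the result is in thousands.
    """
    y = np.asarray(yield_t_ha, dtype=float)
    t = np.asarray(tgw_g, dtype=float)
    if np.any(t <= 0):
        raise DomainError("thousand grain weight must be > 0")
    out = y * 100.0 / t
    return float(out) if out.ndim == 0 else out


def adjust_yield_moisture(fresh_yield, measured_moisture, target: float = 15.0):
    """Rescale fresh yield (t/ha) to a reference moisture content.

    Dry matter is conserved:
    ``adjusted = fresh x (100 - measured) / (100 - target)``.
    The standard trading reference for UK oats is 15% moisture.
    """
    y = np.asarray(fresh_yield, dtype=float)
    m = np.asarray(measured_moisture, dtype=float)
    if not 0 <= target < 100:
        raise DomainError(f"target moisture must be in [0, 100), got {target}")
    if np.any((m < 0) | (m >= 100)):
        raise DomainError("measured moisture must be in [0, 100)")
    out = y * (100.0 - m) / (100.0 - target)
    return float(out) if out.ndim == 0 else out


#: Derived columns appended by :func:`derive_traits`, with the input
#: columns each one needs.
_DERIVATIONS = {
    "roundness": (("width", "length"), lambda df: roundness(df["width"], df["length"])),
    "protein": (("nitrogen",), lambda df: protein_from_nitrogen(df["nitrogen"])),
    "grain_number": (("yield", "tgw"), lambda df: grain_number(df["yield"], df["tgw"])),
}


def derive_traits(df: pd.DataFrame, overwrite: bool = False) -> pd.DataFrame:
    """Append derivable trait columns to a wide phenotype frame.

    Adds ``roundness`` (from width/length), ``protein`` (from
    nitrogen) and ``grain_number`` (from yield/tgw) wherever the input
    columns are present.  Existing columns are kept unless
    ``overwrite`` is set.
    """
    out = df.copy()
    for name, (needs, fn) in _DERIVATIONS.items():
        if all(c in out.columns for c in needs) and (overwrite or name not in out.columns):
            out[name] = fn(out)
    return out
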