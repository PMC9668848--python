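"""Core stable-isotope arithmetic.

Everything downstream reduces to four primitives:

* conversion between delta notation (permil vs an international standard) and
  heavy-isotope atom percent,
* atom percent *excess* of an enriched sample over an unlabelled baseline,
* removal of the methanol-derived carbon added when a PLFA is measured as its
  methyl ester (FAME), and
* carbon-weighted pooling of the enrichment of several fatty acids into one
  group value.

Delta values are permil; atom percent is the heavy-isotope atom fraction
times 100.  The delta <-> atom percent maps are exact inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import METHANOL_D13C, R_AIR, R_VPDB

__all__ = [
    "IsotopeValue",
    "ExcessValue",
    "FameRecord",
    "reference_ratio",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "correct_derivatization",
    "forward_derivatization",
    "pool_group_enrichment",
]


def reference_ratio(element: str) -> float:
    """Heavy/light isotope ratio of the reference material for *element*."""
    if element in ("C", "13C"):
        return R_VPDB
    if element in ("N", "15N"):
        return R_AIR
    raise ValueError(f"unknown element {element!r}; expected 'C' or 'N'")


def delta_to_atom_percent(delta_permil, element: str):
    """Convert delta (permil vs VPDB or AIR) to heavy-isotope atom percent.

    atom% = 100 * R / (1 + R) with R = R_std * (delta/1000 + 1).

    Accepts scalars or arrays; delta must exceed -1000 permil (a delta of
    -1000 would mean a sample containing no heavy isotope at all).
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta <= -1000 permil implies a non-positive isotope ratio")
    r = reference_ratio(element) * (delta / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return out.item() if np.isscalar(delta_permil) else out


def atom_percent_to_delta(atom_percent, element: str):
    """Inverse of :func:`delta_to_atom_percent` (exact to round-off)."""
    ap = np.asarray(atom_percent, dtype=float)
    if np.any((ap <= 0.0) | (ap >= 100.0)):
        raise ValueError("atom percent must lie strictly between 0 and 100")
    r = ap / (100.0 - ap)
    out = (r / reference_ratio(element) - 1.0) * 1000.0
    return out.item() if np.isscalar(atom_percent) else out


@dataclass(frozen=True)
class IsotopeValue:
    """One isotope measurement carried in both notations."""

    element: str
    delta_permil: float

    @property
    def atom_percent(self) -> float:
        return delta_to_atom_percent(self.delta_permil, self.element)

    @classmethod
    def from_atom_percent(cls, atom_percent: float, element: str) -> "IsotopeValue":
        return cls(element=element, delta_permil=atom_percent_to_delta(atom_percent, element))


@dataclass(frozen=True)
class ExcessValue:
    """Atom percent excess of a sample over its unlabelled baseline.

    Negative excess (sample below baseline, e.g. measurement noise on an
    unenriched pool) is retained, not clipped, so that budget sums stay
    unbiased; ``is_negative`` flags it for QC.
    """

    atom_percent_excess: float
    baseline_atom_percent: float
    element: str

    @property
    def is_negative(self) -> bool:
        return self.atom_percent_excess < 0.0


def atom_percent_excess(sample: IsotopeValue, baseline: IsotopeValue) -> ExcessValue:
    """Enrichment of *sample* over the matched unlabelled *baseline*."""
    if sample.element != baseline.element:
        raise ValueError(
            f"element mismatch: sample is {sample.element}, baseline is {baseline.element}"
        )
    return ExcessValue(
        atom_percent_excess=sample.atom_percent - baseline.atom_percent,
        baseline_atom_percent=baseline.atom_percent,
        element=sample.element,
    )


@dataclass(frozen=True)
class FameRecord:
    """A fatty-acid methyl ester measurement prior to derivatization correction.

    The methyl ester carries one methanol-derived carbon, so
    ``c_fame = c_plfa + 1``.
    """

    plfa_name: str
    c_plfa: int
    delta_fame: float
    delta_meoh: float = METHANOL_D13C
    amount_nmol: float = 0.0

    @property
    def c_fame(self) -> int:
        return self.c_plfa + 1

    def __post_init__(self) -> None:
        if self.c_plfa <= 0:
            raise ValueError("c_plfa must be a positive carbon count")


def correct_derivatization(rec: FameRecord) -> float:
    """delta 13C of the underlying PLFA, with the methanol carbon removed.

    delta_PLFA = (C_FAME * delta_FAME - C_MeOH * delta_MeOH) / C_PLFA,
    the exact inverse of the one-carbon mixing that derivatization applies.
    """
    c_meoh = 1
    return (rec.c_fame * rec.delta_fame - c_meoh * rec.delta_meoh) / rec.c_plfa


def forward_derivatization(delta_plfa: float, c_plfa: int, delta_meoh: float = METHANOL_D13C) -> float:
    """delta 13C of the FAME formed from a PLFA of known delta (mixing model)."""
    if c_plfa <= 0:
        raise ValueError("c_plfa must be a positive carbon count")
    return (c_plfa * delta_plfa + delta_meoh) / (c_plfa + 1)


def pool_group_enrichment(members: Iterable[tuple[float, float]]) -> float:
    """Carbon-weighted mean enrichment of a group of fatty acids.

    *members* are (carbon_amount, atom_percent_excess) pairs; the result is
    sum(C_i * e_i) / sum(C_i): the net heavy-isotope excess of the pooled
    carbon divided by the pooled carbon.
    """
    members = list(members)
    if not members:
        raise ValueError("cannot pool an empty group")
    carbon = np.array([m[0] for m in members], dtype=float)
    excess = np.array([m[1] for m in members], dtype=float)
    if np.any(carbon < 0):
        raise ValueError("carbon amounts must be non-negative")
    total = carbon.sum()
    if total <= 0:
        raise ValueError("cannot pool a group whose total carbon is zero")
    return float(np.dot(carbon, excess) / total)
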