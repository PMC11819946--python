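"""Hemolytic activity: percent hemolysis and probit HC50 estimation.

Erythrocytes incubated with a compound at a grid of concentrations release
hemoglobin in proportion to membrane damage; supernatant absorbance at
540 nm relative to a buffer blank and a Triton X-100 positive control gives

    hemolysis% = (Abs_sample - Abs_blank) / (Abs_control - Abs_blank) * 100.

HC50, the lowest concentration causing 50 % hemolysis, is estimated by the
classical probit method: the empirical probit Phi^{-1}(p/100) + 5 is
regressed on log10(concentration) by OLS and the line is inverted at
probit 5.  Percentages outside (0, 100) are clipped to [0.5, 99.5] before
the transform so that exact 0/100 observations remain usable (standard
Finney practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "HemolysisCurve",
    "ProbitFit",
    "pct_hemolysis",
    "probit_fit",
    "hc50_probit",
    "rank_toxicity",
]

CLIP_LO, CLIP_HI = 0.5, 99.5


def pct_hemolysis(abs_sample, abs_blank: float, abs_control: float) -> float:
    """Percent hemolysis from absorbances; replicates averaged on the AU scale.

    Raises DomainError when abs_control <= abs_blank (invalid plate).
    """
    if abs_control <= abs_blank:
        raise DomainError(
            f"positive-control absorbance ({abs_control}) must exceed the blank ({abs_blank})"
        )
    sample = float(np.mean(np.asarray(abs_sample, dtype=float)))
    return 100.0 * (sample - abs_blank) / (abs_control - abs_blank)


@dataclass
class HemolysisCurve:
    """Concentration/absorbance grid for one compound.

    absorbances has shape (n_concentrations, n_replicates).  Curves can also
    be built from already-reduced percentages via :meth:`from_pct`.
    """

    compound_id: str
    concentrations: np.ndarray   # µM, strictly increasing
    absorbances: np.ndarray      # AU
    abs_blank: float
    abs_control: float

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.absorbances = np.atleast_2d(np.asarray(self.absorbances, dtype=float))
        if self.absorbances.shape[0] != len(self.concentrations):
            raise DomainError(
                f"{self.compound_id}: absorbance rows ({self.absorbances.shape[0]}) "
                f"!= concentrations ({len(self.concentrations)})"
            )
        if np.any(np.diff(self.concentrations) <= 0):
            raise DomainError(f"{self.compound_id}: concentrations must be strictly increasing")
        if self.abs_control <= self.abs_blank:
            raise DomainError(
                f"{self.compound_id}: control absorbance must exceed the blank"
            )

    @classmethod
    def from_pct(cls, compound_id: str, concentrations, pct) -> "HemolysisCurve":
        """Ingest a curve reported directly as percent hemolysis."""
        pct = np.asarray(pct, dtype=float)
        return cls(
            compound_id=compound_id,
            concentrations=np.asarray(concentrations, dtype=float),
            absorbances=(pct / 100.0)[:, None],
            abs_blank=0.0,
            abs_control=1.0,
        )

    @property
    def pct(self) -> np.ndarray:
        """Percent hemolysis per concentration (replicates averaged first)."""
        mean_abs = self.absorbances.mean(axis=1)
        return 100.0 * (mean_abs - self.abs_blank) / (self.abs_control - self.abs_blank)

    def hc50(self) -> float:
        return hc50_probit(self)

    def grid_hc50(self) -> float | None:
        """Diagnostic reading: the lowest tested concentration with >= 50 %."""
        above = self.pct >= 50.0
        return float(self.concentrations[above][0]) if above.any() else None


@dataclass
class ProbitFit:
    """OLS line probit(p) = intercept + slope * log10(conc) and its inverse."""

    slope: float
    intercept: float
    hc50: float       # µM
    n_points: int
    offset: float = 5.0
    used_pct: np.ndarray = field(default=None, repr=False)


def probit_fit(concentrations, pct, *, offset: float = 5.0) -> ProbitFit:
    """Probit regression of percent response on log10 dose.

    The +5 offset is the classical convention; the estimated HC50,
    10**((offset - intercept)/slope), is invariant to the offset choice.
    """
    conc = np.asarray(concentrations, dtype=float)
    pct = np.asarray(pct, dtype=float)
    if conc.shape != pct.shape:
        raise DomainError("concentrations and percentages differ in length")
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    p = np.clip(pct, CLIP_LO, CLIP_HI)
    if len(p) < 3:
        raise DomainError(f"need at least 3 usable points, got {len(p)}")
    y = stats.norm.ppf(p / 100.0) + offset
    x = np.log10(conc)
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise DomainError(
            f"probit slope {res.slope:.4g} is not positive (non-monotone response)"
        )
    hc50 = 10.0 ** ((offset - res.intercept) / res.slope)
    return ProbitFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        hc50=float(hc50),
        n_points=len(p),
        offset=offset,
        used_pct=p,
    )


def hc50_probit(curve: HemolysisCurve | None = None, *, concentrations=None, pct=None) -> float:
    """HC50 in µM by the probit method, from a curve or raw (conc, pct) vectors."""
    if curve is not None:
        concentrations, pct = curve.concentrations, curve.pct
    return probit_fit(concentrations, pct).hc50


def rank_toxicity(curves: list[HemolysisCurve]) -> pd.DataFrame:
    """Ascending-HC50 table (most hemolytic compound first).

    HC50 is reported to the nearest 1 µM; ties break lexicographically on
    compound_id.
    """
    rows = [(c.compound_id, round(c.hc50())) for c in curves]
    rows.sort(key=lambda r: (r[1], r[0]))
    return pd.DataFrame(rows, columns=["compound_id", "HC50_uM"])
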