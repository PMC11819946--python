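"""Chromatographic retention factors and Collander-type calibrations.

Retention on the two biomimetic systems — an immobilized-artificial-membrane
(IAM) column eluted with pH 7.4 buffer, and an ODS column with a 0.04 M
Brij 35 micellar mobile phase (biopartitioning micellar chromatography,
BMC) — is summarised by the retention factor

    log k = log10((t_r - t_0) / t_0),

with triplicate retention times averaged on the time scale before the
transform.  Collander-type equations, log P_1 = a log P_2 + b, link the two
chromatographic lipophilicity scales to each other and to log P_o/w; they
are ordinary univariate OLS fits and carry the same statistic set as the
QSPR models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .mlr import fit_mlr

__all__ = ["RetentionRecord", "CollanderFit", "log_k", "collander_fit"]

SYSTEMS = ("IAM", "BMC")


def log_k(t_r, t_0: float) -> float:
    """Retention factor log10((t_r - t_0)/t_0); replicate t_r averaged first.

    Parameters
    ----------
    t_r : float or sequence of floats, retention time(s), minutes.
    t_0 : float, dead (void) time, minutes.
    """
    if t_0 <= 0:
        raise DomainError(f"dead time must be positive, got t_0={t_0}")
    t_r_mean = float(np.mean(np.asarray(t_r, dtype=float)))
    if t_r_mean <= t_0:
        raise DomainError(
            f"mean retention time {t_r_mean} min does not exceed the dead time "
            f"{t_0} min (unretained solute or void-time artifact)"
        )
    return float(np.log10((t_r_mean - t_0) / t_0))


@dataclass
class RetentionRecord:
    """Per-compound, per-system retention times with the derived log k."""

    compound_id: str
    system: str      # "IAM" or "BMC"
    t_r: list[float]  # replicate retention times, minutes
    t_0: float        # dead time, minutes

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise DomainError(f"unknown system {self.system!r}; expected one of {SYSTEMS}")
        if self.t_0 <= 0:
            raise DomainError(f"t_0 must be positive, got {self.t_0}")
        if len(self.t_r) < 1:
            raise DomainError("at least one replicate retention time is required")

    @property
    def log_k(self) -> float:
        return log_k(self.t_r, self.t_0)


@dataclass
class CollanderFit:
    """Univariate calibration y = a x + b between two lipophilicity scales."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    sd: float
    r2: float
    r2_adj: float
    r2_pred: float
    n: int


def collander_fit(x, y, *, x_name: str = "x", y_name: str = "y") -> CollanderFit:
    """OLS fit of y on x with the standard QSPR statistics.

    Requires n >= 3 and non-constant x; standard errors come from the OLS
    covariance matrix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise DomainError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DomainError(f"predictor {x_name!r} is constant")
    model = fit_mlr(x[:, None], y, predictors=[x_name], response=y_name)
    return CollanderFit(
        x_name=x_name,
        y_name=y_name,
        slope=model.coef[x_name],
        intercept=model.intercept,
        slope_se=model.coef_se[x_name],
        intercept_se=model.intercept_se,
        sd=model.sd,
        r2=model.r2,
        r2_adj=model.r2_adj,
        r2_pred=model.r2_pred,
        n=model.n,
    )
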