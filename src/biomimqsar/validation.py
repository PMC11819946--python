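"""Model validation: applicability domain (Williams plot) and cross-validation.

A QSPR model is trusted only inside its applicability domain.  The leverage
approach plots internally studentized residuals against the hat-matrix
diagonal h_ii of the intercept-augmented design; points with
h_ii > h* = 3(p+1)/n are structurally extreme, points with |residual| > 3
are response outliers.  Predictive power is measured by leave-one-out
(Q^2 identical to the PRESS-based predicted R^2) and repeated
leave-33%-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .mlr import MlrModel, _as_frame

__all__ = [
    "AdReport",
    "CvReport",
    "LOO",
    "LMO",
    "warning_leverage",
    "williams_report",
    "cross_validate",
]


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3(p + 1)/n for p predictors and n samples."""
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    if p < 0:
        raise DomainError(f"p must be nonnegative, got {p}")
    return 3.0 * (p + 1) / n


@dataclass
class AdReport:
    """Williams-plot applicability-domain table for one model."""

    response: str
    predictors: list[str]
    h_star: float
    sd_band: float
    table: pd.DataFrame  # compound_id, leverage, std_residual, flag

    @property
    def outside(self) -> list:
        return self.table.loc[self.table["flag"] != "in_domain", "compound_id"].tolist()


def _hat_diag(design: np.ndarray) -> np.ndarray:
    # explicit dense algebra; panels are small
    q, _ = np.linalg.qr(design)
    return np.sum(q * q, axis=1)


def williams_report(
    model: MlrModel,
    X,
    y,
    *,
    residual_type: str = "studentized",
    sd_band: float = 3.0,
) -> AdReport:
    """Leverages, standardized residuals and in/out-of-domain flags.

    residual_type "studentized" divides each residual by SD*sqrt(1 - h_ii);
    "raw" divides by SD alone.
    """
    Xdf = _as_frame(X, model.predictors)
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n), Xdf.to_numpy(dtype=float)])
    h = _hat_diag(design)
    if np.any(h >= 1.0 - 1e-12):
        raise DomainError("leverage h_ii = 1 encountered")
    resid = y - model.predict(Xdf)
    y_scale = float(np.std(y)) or 1.0
    if model.sd <= 1e-10 * y_scale:  # numerically exact fit
        std_resid = np.zeros(n)
    elif residual_type == "studentized":
        std_resid = resid / (model.sd * np.sqrt(1.0 - h))
    elif residual_type == "raw":
        std_resid = resid / model.sd
    else:
        raise DomainError(f"unknown residual_type {residual_type!r}")
    h_star = warning_leverage(model.p, n)
    flags = []
    for hi, ri in zip(h, std_resid):
        lev = hi > h_star
        out = abs(ri) > sd_band
        flags.append("both" if lev and out else "high_leverage" if lev else "outlier_response" if out else "in_domain")
    ids = model.compound_ids if model.compound_ids is not None else list(range(n))
    table = pd.DataFrame(
        {"compound_id": ids, "leverage": h, "std_residual": std_resid, "flag": flags}
    )
    return AdReport(
        response=model.response,
        predictors=list(model.predictors),
        h_star=h_star,
        sd_band=sd_band,
        table=table,
    )


@dataclass
class LOO:
    """Leave-one-out scheme."""

    name: str = "LOO"


@dataclass
class LMO:
    """Repeated leave-many-out: each repeat holds out ceil(n*fraction) compounds."""

    fraction: float = 1.0 / 3.0
    repeats: int = 100
    seed: int = 20250204
    name: str = "LMO"


@dataclass
class CvReport:
    """Cross-validation outcome with per-fold held-out predictions."""

    scheme: str
    params: dict
    predictions: pd.DataFrame  # fold, index, y, y_pred
    q2: float
    rmse: float
    n_folds: int
    skipped_folds: int = 0


def _fit_predict(design, y, train, test):
    beta, *_ = np.linalg.lstsq(design[train], y[train], rcond=None)
    return design[test] @ beta


def cross_validate(X, y, scheme=LOO()) -> CvReport:
    """Refit per fold and score held-out predictions.

    Q^2 = 1 - sum (y_held - yhat_held)^2 / sum (y_held - ybar)^2, with ybar
    the full-sample mean.  Rank-deficient training folds are skipped with a
    warning and counted.
    """
    Xdf = _as_frame(X, None)
    y = np.asarray(y, dtype=float)
    n, p = Xdf.shape
    design = np.column_stack([np.ones(n), Xdf.to_numpy(dtype=float)])
    if isinstance(scheme, LOO):
        if n <= p + 2:
            raise DomainError(f"LOO needs n > p + 2 (n={n}, p={p})")
        folds = [np.array([i]) for i in range(n)]
    elif isinstance(scheme, LMO):
        m = int(np.ceil(n * scheme.fraction))
        if n - m <= p + 1:
            raise DomainError("LMO training folds would retain <= p + 1 samples")
        rng = np.random.default_rng(scheme.seed)
        folds = [rng.choice(n, size=m, replace=False) for _ in range(scheme.repeats)]
    else:
        raise DomainError(f"unknown scheme {scheme!r}")

    rows = []
    skipped = 0
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if np.linalg.matrix_rank(design[train]) < p + 1:
            warnings.warn(f"fold {k} skipped: rank-deficient training design")
            skipped += 1
            continue
        pred = _fit_predict(design, y, train, test)
        for i, yp in zip(test, pred):
            rows.append((k, int(i), y[i], float(yp)))
    if not rows:
        raise DomainError("all folds were skipped")
    preds = pd.DataFrame(rows, columns=["fold", "index", "y", "y_pred"])
    err = preds["y"] - preds["y_pred"]
    denom = float(np.sum((preds["y"] - y.mean()) ** 2))
    q2 = 1.0 - float(np.sum(err**2)) / denom
    rmse = float(np.sqrt(np.mean(err**2)))
    params = {"fraction": scheme.fraction, "repeats": scheme.repeats, "seed": scheme.seed} if isinstance(scheme, LMO) else {}
    return CvReport(
        scheme=scheme.name,
        params=params,
        predictions=preds,
        q2=q2,
        rmse=rmse,
        n_folds=len(folds),
        skipped_folds=skipped,
    )
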