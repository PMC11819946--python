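"""Multiple linear regression for QSPR model building.

A solute property SP (an in-silico endpoint such as log P_w/pc, log K_p,
log P_w/HSA, log BB, or an experimental HC50) is modelled as a linear
function of a lipophilicity descriptor plus orthogonal structural
descriptors,

    SP = b0 + b1 x1 + ... + bp xp + eps,

fitted by ordinary least squares.  Besides the usual goodness-of-fit
measures (SD, R^2, adjusted R^2, MSE) every fit carries its leave-one-out
prediction statistics: PRESS = sum_i (e_i / (1 - h_ii))^2, computed from
the hat-matrix diagonal, and the derived predicted R^2 and Q^2_cv.  The
exhaustive model search fits every admissible predictor set and ranks by
adjusted R^2 with PRESS as tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DomainError, RankError

__all__ = [
    "MlrModel",
    "ModelSearchResult",
    "fit_mlr",
    "standardized_coefficients",
    "press_statistics",
    "search_models",
]


def _as_frame(X, predictors: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X if predictors is None else X.loc[:, list(predictors)]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(predictors) if predictors is not None else [f"x{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


def _dependent_columns(design: pd.DataFrame) -> list[str]:
    """Name columns whose removal restores full rank."""
    full_rank = np.linalg.matrix_rank(design.to_numpy())
    culprits = []
    for col in design.columns:
        if col == "const":
            continue
        reduced = design.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(reduced) == full_rank:
            culprits.append(col)
    return culprits


@dataclass
class MlrModel:
    """A fitted OLS model with the full QSPR statistic set."""

    response: str
    predictors: list[str]
    n: int
    p: int
    intercept: float
    coef: dict[str, float]
    intercept_se: float
    coef_se: dict[str, float]
    sd: float              # residual standard deviation, sqrt(RSS/(n-p-1))
    r2: float
    r2_adj: float
    mse: float             # RSS/n
    press: float
    r2_pred: float
    q2_cv: float
    f_statistic: float
    std_coef: dict[str, float]
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    leverages: np.ndarray = field(repr=False)
    compound_ids: list | None = field(default=None, repr=False)

    def to_record(self) -> dict:
        """Scalar statistics only, for serialization."""
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "n": self.n,
            "p": self.p,
            "intercept": self.intercept,
            "coef": dict(self.coef),
            "intercept_se": self.intercept_se,
            "coef_se": dict(self.coef_se),
            "SD": self.sd,
            "R2": self.r2,
            "R2_adj": self.r2_adj,
            "MSE": self.mse,
            "PRESS": self.press,
            "R2_pred": self.r2_pred,
            "Q2_cv": self.q2_cv,
            "F": self.f_statistic,
            "std_coef": dict(self.std_coef),
        }

    def predict(self, X) -> np.ndarray:
        Xdf = _as_frame(X, self.predictors)
        return self.intercept + Xdf.to_numpy() @ np.array([self.coef[c] for c in self.predictors])


def fit_mlr(
    X,
    y,
    *,
    predictors: Sequence[str] | None = None,
    response: str = "y",
    compound_ids: Sequence | None = None,
) -> MlrModel:
    """Fit an OLS model with intercept and compute the full statistic set.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
    y : array-like, shape (n,)
    predictors, response : names used in reports.

    Raises
    ------
    DomainError  if n <= p + 1.
    RankError    if the design is rank deficient (dependent columns named).
    """
    Xdf = _as_frame(X, predictors)
    y = np.asarray(y, dtype=float)
    n, p = Xdf.shape
    if y.shape != (n,):
        raise DomainError(f"y has shape {y.shape}, expected ({n},)")
    if n <= p + 1:
        raise DomainError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(Xdf, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < p + 1:
        raise RankError(
            "rank-deficient design; dependent columns: "
            + ", ".join(_dependent_columns(design))
        )

    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    sst = float(res.centered_tss)
    sd = float(np.sqrt(res.scale))
    resid = np.asarray(res.resid, dtype=float)
    h = np.asarray(OLSInfluence(res).hat_matrix_diag, dtype=float)
    if np.any(h >= 1.0 - 1e-12):
        raise DomainError("leverage h_ii = 1 encountered (self-predicting point)")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    r2_pred = 1.0 - press / sst if sst > 0 else np.nan
    names = list(Xdf.columns)
    params = res.params
    bse = res.bse
    y_sd = float(np.std(y, ddof=1))
    if y_sd == 0:
        raise DomainError("response has zero variance")
    std_coef = {
        c: float(params[c]) * float(np.std(Xdf[c].to_numpy(), ddof=1)) / y_sd for c in names
    }
    return MlrModel(
        response=response,
        predictors=names,
        n=n,
        p=p,
        intercept=float(params["const"]),
        coef={c: float(params[c]) for c in names},
        intercept_se=float(bse["const"]),
        coef_se={c: float(bse[c]) for c in names},
        sd=sd,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        mse=rss / n,
        press=press,
        r2_pred=float(r2_pred),
        q2_cv=float(r2_pred),
        f_statistic=float(res.fvalue),
        std_coef=std_coef,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=resid,
        leverages=h,
        compound_ids=list(compound_ids) if compound_ids is not None else None,
    )


def standardized_coefficients(model: MlrModel, X, y) -> np.ndarray:
    """b_j * sd(x_j) / sd(y) with n-1 denominators, ordered like the predictors.

    Identical to the slopes obtained by refitting on z-scored X and y.
    """
    Xdf = _as_frame(X, model.predictors)
    y = np.asarray(y, dtype=float)
    y_sd = float(np.std(y, ddof=1))
    if y_sd == 0:
        raise DomainError("response has zero variance")
    return np.array(
        [model.coef[c] * float(np.std(Xdf[c].to_numpy(), ddof=1)) / y_sd for c in model.predictors]
    )


def _loo_press(Xdf: pd.DataFrame, y: np.ndarray) -> float:
    """PRESS by explicit leave-one-out refitting (independent of the hat shortcut)."""
    design = np.column_stack([np.ones(len(y)), Xdf.to_numpy(dtype=float)])
    press = 0.0
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        beta, *_ = np.linalg.lstsq(design[keep], y[keep], rcond=None)
        press += (y[i] - design[i] @ beta) ** 2
    return float(press)


def press_statistics(model: MlrModel, X, y) -> tuple[float, float, float]:
    """Return (PRESS, R^2_pred, Q^2_cv) for a fitted model.

    PRESS comes from the hat-matrix shortcut sum (e_i/(1-h_ii))^2; Q^2_cv is
    recomputed by an explicit leave-one-out refit loop, and the two routes
    must agree to 1e-10 (relative) or the call aborts.
    """
    Xdf = _as_frame(X, model.predictors)
    y = np.asarray(y, dtype=float)
    press_loo = _loo_press(Xdf, y)
    if not np.isclose(model.press, press_loo, rtol=1e-10, atol=1e-10):
        raise FloatingPointError(
            f"PRESS shortcut {model.press!r} disagrees with explicit LOO {press_loo!r}"
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press_loo / sst
    return model.press, model.r2_pred, q2


@dataclass
class ModelSearchResult:
    """Exhaustive-search outcome: every candidate fitted, totally ordered."""

    models: list[MlrModel]
    criterion: str
    candidate_count: int

    @property
    def best(self) -> MlrModel:
        return self.models[0]

    def top(self, k: int) -> list[MlrModel]:
        return self.models[:k]


def search_models(
    panel,
    response: str,
    candidate_sets: Iterable[Sequence[str]],
) -> ModelSearchResult:
    """Fit every candidate predictor set against one response and rank.

    Ranking: adjusted R^2 descending, ties by lower PRESS, then by the
    lexicographic predictor-name tuple, so the order is total and
    deterministic.  Compounds with a missing response or predictor value are
    dropped per candidate (complete-case fitting).
    """
    frame = panel.frame if hasattr(panel, "frame") else panel
    candidates = [tuple(c) for c in candidate_sets]
    if not candidates:
        raise DomainError("no candidate predictor sets supplied")
    fitted: list[MlrModel] = []
    failures: list[str] = []
    for cand in candidates:
        cols = list(cand) + [response]
        sub = frame.loc[:, cols + (["compound_id"] if "compound_id" in frame.columns else [])].dropna(
            subset=cols
        )
        try:
            model = fit_mlr(
                sub.loc[:, list(cand)],
                sub[response].to_numpy(),
                predictors=list(cand),
                response=response,
                compound_ids=sub["compound_id"].tolist() if "compound_id" in sub.columns else None,
            )
        except (DomainError, RankError) as exc:
            failures.append(f"{cand}: {exc}")
            continue
        fitted.append(model)
    if not fitted:
        raise DomainError("no candidate set could be fitted: " + "; ".join(failures))
    fitted.sort(key=lambda m: (-m.r2_adj, m.press, tuple(sorted(m.predictors))))
    return ModelSearchResult(models=fitted, criterion="R2_adj desc, PRESS asc", candidate_count=len(candidates))
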