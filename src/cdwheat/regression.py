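"""Fitting and evaluating soil-to-wheat Cd transfer models.

The central objects follow the statsmodels convention: a
:class:`CdTransferModel` is built from a :class:`~cdwheat.dataset.Dataset`
(or DataFrame) plus a feature specification, and its :meth:`fit` returns a
:class:`TransferModelResults` carrying coefficient estimates, standard
errors, fit statistics and a ``summary()`` table.  The fitted equation is
exported as a frozen :class:`~cdwheat.equations.TransferModel` for
prediction, serialization and threshold inversion.

Fitting is ordinary least squares of log10 grain Cd on the transformed
features; Cd pools enter as log10, the remaining soil properties untransformed.
Mixing two soil Cd pools (total, CaCl2-extractable, model-dissolved) in one
model is refused because of their strong mutual correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import Dataset
from .equations import (
    CD_POOL_FEATURES,
    SOIL_FEATURES,
    AnyModel,
    BcfModel,
    DomainError,
    Term,
    TransferModel,
    predict_grain_cd,
)

__all__ = [
    "CdTransferModel",
    "TransferModelResults",
    "BcfQuadraticResults",
    "FitMetrics",
    "fit_transfer_model",
    "fit_bcf_quadratic",
    "evaluate_model",
    "pearson_correlations",
    "CorrelationResult",
]

#: default transform per feature: Cd pools are log10, the rest identity
def default_transform(feature: str) -> str:
    return "log10" if feature in CD_POOL_FEATURES else "identity"


def _as_df(data: Union[Dataset, pd.DataFrame]) -> pd.DataFrame:
    return data.df if isinstance(data, Dataset) else data


class CdTransferModel:
    """Log-linear transfer model of wheat-grain Cd, ready to fit.

    Parameters
    ----------
    data : Dataset or DataFrame
        Paired records supplying the features and ``cd_wheat``.
    features : sequence of str
        Feature names from the soil schema; exactly one soil Cd pool.
    transforms : sequence of str, optional
        Per-feature ``"log10"``/``"identity"``; defaults to log10 for Cd
        pools and identity otherwise.
    model_id : str
        Label attached to the fitted equation.
    """

    def __init__(self, data: Union[Dataset, pd.DataFrame],
                 features: Sequence[str],
                 transforms: Optional[Sequence[str]] = None,
                 model_id: str = "custom"):
        features = list(features)
        if not features:
            raise ValueError("at least one feature is required")
        unknown = [f for f in features if f not in SOIL_FEATURES]
        if unknown:
            raise ValueError(f"unknown feature(s): {unknown}")
        pools = [f for f in features if f in CD_POOL_FEATURES]
        if len(pools) > 1:
            raise ValueError(
                f"features mix the Cd pools {pools}; the pools are strongly "
                "correlated and must not enter one model together")
        if transforms is None:
            transforms = [default_transform(f) for f in features]
        if len(transforms) != len(features):
            raise ValueError("transforms must align with features")
        self.features = features
        self.transforms = list(transforms)
        self.model_id = model_id

        df = _as_df(data)
        cols = df[features + ["cd_wheat"]].dropna()
        n = len(cols)
        if n < len(features) + 1:
            raise ValueError(
                f"need at least {len(features) + 1} complete records "
                f"for {len(features)} features, got {n}")
        y = cols["cd_wheat"].to_numpy(dtype=float)
        if np.any(y <= 0):
            raise DomainError("cd_wheat must be positive for a log10 response")
        X = np.empty((n, len(features)))
        for j, (f, t) in enumerate(zip(features, transforms)):
            x = cols[f].to_numpy(dtype=float)
            if t == "log10":
                if np.any(x <= 0):
                    raise DomainError(
                        f"feature {f!r} must be positive under log10")
                x = np.log10(x)
            X[:, j] = x
        self._y = np.log10(y)
        self._X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            raise ValueError("collinear features: design matrix is rank-deficient")
        self._index = cols.index

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features: Sequence[str],
                       **kwargs) -> "CdTransferModel":
        return cls(df, features, **kwargs)

    def fit(self) -> "TransferModelResults":
        """Ordinary least squares on the log10 scale."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # df_resid may be 0 (exact fit)
            res = sm.OLS(self._y, self._X).fit()
        return TransferModelResults(self, res)


class TransferModelResults:
    """Fitted transfer model: estimates, uncertainties and diagnostics."""

    def __init__(self, model: CdTransferModel, sm_results):
        self.model = model
        self._sm = sm_results
        names = ["intercept"] + list(model.features)
        self.params = pd.Series(sm_results.params, index=names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero df_resid on exact fits
            self.bse = pd.Series(sm_results.bse, index=names)
            self.pvalues = pd.Series(sm_results.pvalues, index=names)
        self.nobs = int(sm_results.nobs)
        # guard against -0.0 / fp noise on exact fits
        self.rsquared = float(sm_results.rsquared)
        if math.isclose(self.rsquared, 1.0, abs_tol=1e-12):
            self.rsquared = min(self.rsquared, 1.0)

    @property
    def equation(self) -> TransferModel:
        """The fitted coefficients as a frozen, serializable equation."""
        terms = tuple(
            Term(f, t, float(self.params[f]))
            for f, t in zip(self.model.features, self.model.transforms))
        return TransferModel(
            id=self.model.model_id, terms=terms,
            intercept=float(self.params["intercept"]))

    def predict(self, data) -> np.ndarray:
        """Predicted grain Cd (mg/kg) on new records."""
        return self.equation.predict(_as_df(data) if isinstance(data, (Dataset, pd.DataFrame)) else data)

    def invert(self, grain_limit: float = 0.1, **covariates):
        """Soil Cd at which predicted grain Cd equals ``grain_limit``.

        Delegates to :func:`cdwheat.thresholds.invert_threshold`; pass the
        covariates the equation needs (``ph=``, ``cec=``).
        """
        from .thresholds import invert_threshold
        return invert_threshold(self.equation, grain_limit, **covariates)

    def simulate(self, n: int = 311, seed: int = 0,
                 noise_sd: Optional[float] = None) -> Dataset:
        """Generate a synthetic dataset whose wheat response follows this
        fitted equation (supported when the features are a subset of
        ``cd_total``, ``ph``, ``cec``)."""
        from .synthetic import SyntheticConfig, WheatResponse, generate_dataset
        allowed = {"cd_total", "ph", "cec"}
        if not set(self.model.features) <= allowed:
            raise ValueError(
                "simulate() supports equations over cd_total/ph/cec only")
        coef = {f: float(self.params.get(f, 0.0)) for f in allowed}
        resp = WheatResponse(
            coef_log10cd=coef["cd_total"], coef_ph=coef["ph"],
            coef_cec=coef["cec"], intercept=float(self.params["intercept"]),
            noise_sd=WheatResponse().noise_sd if noise_sd is None else noise_sd)
        cfg = SyntheticConfig(n=n, seed=seed, wheat=resp)
        return generate_dataset(cfg)

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels spirit."""
        lines = [
            f"Cd transfer model [{self.model.model_id}]  "
            f"response: log10(cd_wheat)",
            f"n = {self.nobs}   R2 = {self.rsquared:.4f}",
            f"{'term':<22}{'coef':>12}{'std err':>12}{'p-value':>12}",
        ]
        for name in self.params.index:
            tname = name if name == "intercept" else (
                f"log10({name})"
                if self.model.transforms[self.model.features.index(name)]
                == "log10" else name)
            lines.append(
                f"{tname:<22}{self.params[name]:>12.4f}"
                f"{self.bse[name]:>12.4f}{self.pvalues[name]:>12.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TransferModelResults {self.model.model_id}: "
                f"n={self.nobs}, R2={self.rsquared:.3f}>")


def fit_transfer_model(data: Union[Dataset, pd.DataFrame],
                       features: Sequence[str],
                       transforms: Optional[Sequence[str]] = None,
                       model_id: str = "custom") -> TransferModelResults:
    """Fit a log-linear transfer model by OLS (functional shorthand for
    ``CdTransferModel(data, features, ...).fit()``)."""
    return CdTransferModel(data, features, transforms, model_id).fit()


@dataclass(frozen=True)
class BcfQuadraticResults:
    """Fitted quadratic of BCF on pH, with fit quality."""

    model: BcfModel
    rsquared: float
    nobs: int

    def predict(self, data):
        return self.model.predict(data)


def fit_bcf_quadratic(data: Union[Dataset, pd.DataFrame],
                      model_id: str = "bcf_fit") -> BcfQuadraticResults:
    """Least-squares quadratic of the bioconcentration factor on soil pH.

    Needs at least 4 records with distinct pH so the parabola is
    overdetermined.
    """
    df = _as_df(data)
    if "bcf" not in df.columns:
        df = df.assign(bcf=df["cd_wheat"] / df["cd_total"])
    cols = df[["ph", "bcf"]].dropna()
    ph = cols["ph"].to_numpy(dtype=float)
    bcf = cols["bcf"].to_numpy(dtype=float)
    if len(np.unique(ph)) < 4:
        raise ValueError("need >= 4 records with distinct pH values")
    X = np.column_stack([ph ** 2, ph, np.ones_like(ph)])
    coef, *_ = np.linalg.lstsq(X, bcf, rcond=None)
    resid = bcf - X @ coef
    sst = float(np.sum((bcf - bcf.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    lo, hi = float(ph.min()), float(ph.max())
    model = BcfModel(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                     id=model_id, ph_domain=(lo, hi))
    return BcfQuadraticResults(model=model, rsquared=r2, nobs=len(ph))


@dataclass(frozen=True)
class FitMetrics:
    """Fit quality on the log10 grain-Cd scale.

    ``r2_*`` are ordinary coefficients of determination (1 - SSE/SST, not
    squared correlation; may be negative for a bad model).  ``rmse_test``
    and ``mae_test`` are on log10(mg/kg) residuals of the test set.
    """

    r2_train: float
    r2_test: float
    rmse_test: float
    mae_test: float

    def __post_init__(self):
        if self.rmse_test < 0 or self.mae_test < 0:
            raise ValueError("error metrics cannot be negative")


def _log_residuals(model, data) -> tuple[np.ndarray, np.ndarray]:
    df = _as_df(data)
    obs = df["cd_wheat"].to_numpy(dtype=float)
    if np.any(~(obs > 0)):
        raise DomainError("observed cd_wheat must be positive")
    pred = np.asarray(predict_grain_cd(model, df), dtype=float)
    if np.any(~(pred > 0)):
        raise DomainError("model produced non-positive grain Cd predictions")
    return np.log10(obs), np.log10(pred)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


def evaluate_model(model, train: Union[Dataset, pd.DataFrame],
                   test: Union[Dataset, pd.DataFrame]) -> FitMetrics:
    """Training/test R2 plus test RMSE and MAE, all on the log10 scale.

    ``model`` may be a frozen equation, a BCF model, or fitted results
    (anything predicting grain Cd in mg/kg).
    """
    if len(_as_df(test)) == 0:
        raise ValueError("empty test set")
    if len(_as_df(train)) == 0:
        raise ValueError("empty training set")
    y_tr, yhat_tr = _log_residuals(model, train)
    y_te, yhat_te = _log_residuals(model, test)
    resid = y_te - yhat_te
    return FitMetrics(
        r2_train=_r2(y_tr, yhat_tr),
        r2_test=_r2(y_te, yhat_te),
        rmse_test=float(np.sqrt(np.mean(resid ** 2))),
        mae_test=float(np.mean(np.abs(resid))),
    )


#: variables entering the correlation matrix; Cd variables on log10 scale
CORRELATION_VARIABLES = (
    "log10_cd_total", "log10_cd_cacl2", "log10_cd_msm", "log10_cd_wheat",
    "bcf", "ph", "cec", "clay", "som", "fe_dcb", "fe_ox",
)


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson correlations with two-tailed p-values.

    ``r`` and ``p`` are symmetric DataFrames; pairs involving a
    zero-variance (or too-sparse) column are NaN and listed in
    ``degenerate``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    degenerate: tuple[str, ...]


def pearson_correlations(data: Union[Dataset, pd.DataFrame]) -> CorrelationResult:
    """Pearson correlation matrix over soil properties, log10 Cd pools,
    log10 grain Cd and BCF, with two-tailed t-test p-values.

    Pairwise-complete observations are used so optional Cd pools with
    missing cells do not drop whole records.
    """
    df = _as_df(data)
    if len(df) < 3:
        raise ValueError("need at least 3 records for correlations")
    if "bcf" not in df.columns and {"cd_wheat", "cd_total"} <= set(df.columns):
        df = df.assign(bcf=df["cd_wheat"] / df["cd_total"])
    table = pd.DataFrame(index=df.index)
    for var in CORRELATION_VARIABLES:
        src = var[len("log10_"):] if var.startswith("log10_") else var
        if src not in df.columns:
            table[var] = np.nan  # absent column: its pairs are degenerate
            continue
        col = df[src].to_numpy(dtype=float)
        if var.startswith("log10_"):
            with np.errstate(invalid="ignore", divide="ignore"):
                table[var] = np.where(col > 0, np.log10(col), np.nan)
        else:
            table[var] = col

    k = len(CORRELATION_VARIABLES)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    degenerate = set()
    for i, a in enumerate(CORRELATION_VARIABLES):
        for j, b in enumerate(CORRELATION_VARIABLES[: i + 1]):
            pair = table[[a, b]].dropna()
            nmat[i, j] = nmat[j, i] = len(pair)
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            if len(pair) < 3:
                degenerate.update((a, b))
                continue
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                degenerate.add(a if np.std(x) == 0 else b)
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    idx = list(CORRELATION_VARIABLES)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        degenerate=tuple(sorted(degenerate)),
    )
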