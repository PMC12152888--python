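"""Soil Cd thresholds for safe wheat production and protection accuracy.

A fitted transfer equation predicts grain Cd from soil Cd and covariates;
solving it backwards at the food-safety limit (0.1 mg/kg Cd in wheat
grain) gives the soil Cd content — total or bioavailable, depending on
the model — at which the predicted grain Cd just reaches the limit.
:class:`ThresholdCurve` carries that inversion as a function of pH (and a
CEC default where the model needs it); :class:`StepStandard` encodes the
stepwise pH-banded soil standards (the mandatory GB 15618–2018 and the
wheat-specific recommended GB/T 41685–2022); and
:func:`classify_exceedance` scores any rule against observed grain Cd as
a TP/FN/FP/TN confusion summary with protection accuracy

    Acc% = (TP + TN) / (TP + FN + FP + TN) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .dataset import Dataset
from .equations import (
    AnyModel,
    BcfModel,
    DomainError,
    MissingFeatureError,
    TransferModel,
)

__all__ = [
    "ThresholdCurve",
    "StepStandard",
    "ConfusionSummary",
    "GB_15618_2018",
    "GBT_41685_2022",
    "invert_threshold",
    "threshold_table",
    "standard_threshold",
    "classify_exceedance",
    "DEFAULT_GRAIN_LIMIT",
    "BAND_REPRESENTATIVE_PH",
]

#: food-safety limit for Cd in wheat grain, mg/kg
DEFAULT_GRAIN_LIMIT = 0.1

#: pH band edges of the stepwise soil standards
BAND_EDGES = (5.5, 6.5, 7.5)

#: band labels in standard notation
BAND_LABELS = ("pH<=5.5", "5.5<pH<=6.5", "6.5<pH<=7.5", "pH>7.5")

#: default representative pH per band: the band lower boundary, with the
#: open-ended acid band represented at pH 4.0
BAND_REPRESENTATIVE_PH = (4.0, 5.5, 6.5, 7.5)


def invert_threshold(model: AnyModel, grain_limit: float = DEFAULT_GRAIN_LIMIT,
                     ph=None, cec=None, **covariates) -> float:
    """Soil Cd at which the model's predicted grain Cd equals the limit.

    Log-linear models are solved in closed form for their Cd-pool term at
    the given covariates; the BCF model returns ``grain_limit / BCF(pH)``.
    The result is in the model's Cd-pool units (mg/kg for total or
    CaCl2-extractable Cd, mg/L for model-dissolved Cd).
    """
    if not grain_limit > 0:
        raise DomainError(f"grain_limit must be > 0, got {grain_limit}")
    if isinstance(model, BcfModel):
        if ph is None:
            raise MissingFeatureError("the BCF model needs ph for inversion")
        bcf = model.bcf(ph)
        if np.any(bcf <= 0):
            raise DomainError(f"BCF(pH={ph}) is non-positive; cannot invert")
        out = grain_limit / bcf
        return float(out) if np.ndim(out) == 0 else out

    if model.response_transform != "log10":
        raise DomainError(
            f"model {model.id!r}: only log10-response equations invert "
            "in closed form")
    cov = dict(covariates)
    if ph is not None:
        cov["ph"] = ph
    if cec is not None:
        cov["cec"] = cec
    cd_feature = model.cd_feature
    rhs = np.log10(grain_limit) - model.intercept
    cd_term = None
    for t in model.terms:
        if t.feature == cd_feature:
            cd_term = t
            continue
        if t.feature not in cov or cov[t.feature] is None:
            raise MissingFeatureError(
                f"model {model.id!r} needs covariate {t.feature!r} "
                "for inversion")
        x = np.asarray(cov[t.feature], dtype=float)
        if t.transform == "log10":
            if np.any(x <= 0):
                raise DomainError(
                    f"covariate {t.feature!r} must be positive under log10")
            x = np.log10(x)
        rhs = rhs - t.coefficient * x
    if cd_term.coefficient == 0:
        raise DomainError(
            f"model {model.id!r}: zero coefficient on {cd_feature!r}; "
            "not invertible")
    solved = rhs / cd_term.coefficient
    out = 10.0 ** solved if cd_term.transform == "log10" else solved
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ThresholdCurve:
    """A transfer model inverted at a grain limit, as a function of pH.

    ``cec`` is the covariate default used when the model references CEC
    (conventionally the mean CEC of the dataset under study).
    """

    model: AnyModel
    grain_limit: float = DEFAULT_GRAIN_LIMIT
    cec: Optional[float] = None
    domain: tuple[float, float] = (3.97, 8.55)

    def __post_init__(self):
        if not self.grain_limit > 0:
            raise DomainError("grain_limit must be > 0")

    @property
    def cd_feature(self) -> str:
        return self.model.cd_feature

    @property
    def units(self) -> str:
        return "mg/L" if self.cd_feature == "cd_msm" else "mg/kg"

    def threshold(self, ph):
        """Soil Cd threshold at the given pH (vectorized)."""
        return invert_threshold(self.model, self.grain_limit,
                                ph=ph, cec=self.cec)

    def plot(self, ax=None, ph_grid=None, **kwargs):
        """Threshold-versus-pH curve on a matplotlib axis."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if ph_grid is None:
            ph_grid = np.linspace(self.domain[0], self.domain[1], 200)
        ax.plot(ph_grid, [self.threshold(p) for p in np.atleast_1d(ph_grid)],
                **kwargs)
        ax.set_xlabel("soil pH")
        ax.set_ylabel(f"soil Cd threshold ({self.units})")
        return ax


@dataclass(frozen=True)
class StepStandard:
    """Stepwise pH-banded soil Cd standard (bands: pH<=5.5; 5.5<pH<=6.5;
    6.5<pH<=7.5; pH>7.5; a boundary pH belongs to the lower band)."""

    name: str
    values: tuple[float, float, float, float]
    edges: tuple[float, float, float] = BAND_EDGES

    def __post_init__(self):
        if len(self.values) != 4:
            raise ValueError("a step standard has exactly four band values")
        if any(not v > 0 for v in self.values):
            raise ValueError("band values must be positive")
        if not (self.edges[0] < self.edges[1] < self.edges[2]):
            raise ValueError("band edges must be strictly increasing")

    def band_index(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        # a boundary pH belongs to the lower band, hence strict >
        idx = (ph > self.edges[0]).astype(int)
        idx += (ph > self.edges[1]).astype(int)
        idx += (ph > self.edges[2]).astype(int)
        return idx

    def threshold(self, ph):
        """Band value at the given pH (vectorized)."""
        out = np.asarray(self.values, dtype=float)[self.band_index(ph)]
        return float(out) if np.ndim(ph) == 0 else out


#: mandatory soil environmental-quality standard for agricultural land
GB_15618_2018 = StepStandard("GB 15618-2018", (0.30, 0.30, 0.30, 0.60))

#: recommended wheat-specific soil standard
GBT_41685_2022 = StepStandard("GB/T 41685-2022", (0.20, 0.23, 0.30, 0.36))


def standard_threshold(std: StepStandard, ph) -> float:
    """Soil Cd limit of a stepwise standard at the given pH."""
    ph_arr = np.asarray(ph, dtype=float)
    if np.any(~((ph_arr > 0) & (ph_arr < 14))):
        raise DomainError(f"ph must lie in (0, 14), got {ph}")
    return std.threshold(ph)


def threshold_table(curve: ThresholdCurve,
                    representative_ph=BAND_REPRESENTATIVE_PH) -> pd.DataFrame:
    """Evaluate a threshold curve at one representative pH per band.

    The default convention represents each band by its lower boundary,
    with the open acid band at pH 4.0; the convention used is recorded in
    ``DataFrame.attrs`` so tables are self-describing.
    """
    if len(representative_ph) != 4:
        raise ValueError("one representative pH per band is required")
    rows = []
    for label, ph in zip(BAND_LABELS, representative_ph):
        if not curve.domain[0] <= ph <= curve.domain[1]:
            warnings.warn(
                f"representative pH {ph} outside the curve domain "
                f"{curve.domain}; value reported anyway", stacklevel=2)
        rows.append({"band": label, "representative_ph": ph,
                     "threshold": curve.threshold(ph)})
    out = pd.DataFrame(rows)
    out.attrs["convention"] = ("band lower boundary; acid band at "
                               f"pH {representative_ph[0]}")
    out.attrs["units"] = curve.units
    out.attrs["grain_limit"] = curve.grain_limit
    out.attrs["model"] = getattr(curve.model, "id", "custom")
    return out


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FN/FP/TN counts of a threshold rule against observed grain Cd.

    Positive = the soil Cd pool exceeds the rule's threshold (predicted
    unsafe); actual positive = grain Cd exceeds the grain limit.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def acc(self) -> float:
        """Protection accuracy in percent: (TP+TN)/n * 100."""
        return 100.0 * (self.tp + self.tn) / self.n

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                "n": self.n, "acc_percent": self.acc}


Rule = Union[ThresholdCurve, StepStandard, float, Callable]


def _rule_thresholds(rule: Rule, df: pd.DataFrame) -> tuple[np.ndarray, str]:
    ph = df["ph"].to_numpy(dtype=float)
    if isinstance(rule, ThresholdCurve):
        needs_cec = any(t.feature == "cec"
                        for t in getattr(rule.model, "terms", ()))
        if needs_cec and rule.cec is None:
            # no fixed CEC default: invert at each record's own CEC
            cec = df["cec"].to_numpy(dtype=float)
            thr = np.asarray(invert_threshold(
                rule.model, rule.grain_limit, ph=ph, cec=cec), dtype=float)
        else:
            thr = np.asarray(rule.threshold(ph), dtype=float)
        return thr, rule.cd_feature
    if isinstance(rule, StepStandard):
        return np.asarray(rule.threshold(ph), dtype=float), "cd_total"
    if callable(rule):
        return np.asarray([rule(p) for p in ph], dtype=float), "cd_total"
    return np.full(len(df), float(rule)), "cd_total"


def classify_exceedance(data: Union[Dataset, pd.DataFrame], rule: Rule,
                        grain_limit: float = DEFAULT_GRAIN_LIMIT,
                        cd_pool: Optional[str] = None) -> ConfusionSummary:
    """Score a threshold rule's protection of the grain limit.

    Per record: predicted-unsafe iff the tested soil Cd pool exceeds the
    rule's threshold at the record's pH; actually-unsafe iff grain Cd
    exceeds ``grain_limit``.  A CEC-referencing curve with a fixed
    ``cec`` default is evaluated at that default; with ``cec=None`` it is
    inverted at each record's own CEC.  ``cd_pool`` defaults to the pool
    the rule's model is driven by (``cd_total`` for step standards and
    scalar rules).
    """
    df = data.df if isinstance(data, Dataset) else data
    if len(df) == 0:
        raise ValueError("empty dataset")
    thr, rule_pool = _rule_thresholds(rule, df)
    pool = cd_pool or rule_pool
    if pool not in df.columns:
        raise MissingFeatureError(f"dataset lacks the tested pool {pool!r}")
    vals = df[pool]
    if vals.isna().any():
        bad = list(df.index[vals.isna()])
        raise MissingFeatureError(
            f"tested pool {pool!r} missing in records: {bad[:10]}"
            + ("..." if len(bad) > 10 else ""))
    soil = vals.to_numpy(dtype=float)
    wheat = df["cd_wheat"].to_numpy(dtype=float)
    pred = soil > thr
    actual = wheat > grain_limit
    return ConfusionSummary(
        tp=int(np.sum(pred & actual)),
        fn=int(np.sum(~pred & actual)),
        fp=int(np.sum(pred & ~actual)),
        tn=int(np.sum(~pred & ~actual)),
    )
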