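"""Declarative soil-to-grain Cd transfer equations.

A :class:`TransferModel` is a frozen log-linear (or identity-response)
equation mapping soil properties to wheat-grain Cd, e.g.::

    log10(Cd_wheat) = 0.955 log10(Cd_soil) - 0.118 pH - 0.010 CEC + 0.114

The module ships the published equation suite (M1, M2, M4, M5, M5star as
log-linear models; M3 as a pH-quadratic bioconcentration-factor model) as
packaged YAML files, loadable with :func:`builtin_model`.

All logarithms are base 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Term",
    "TransferModel",
    "BcfModel",
    "builtin_model",
    "builtin_model_ids",
    "predict_grain_cd",
    "CD_POOL_FEATURES",
    "SOIL_FEATURES",
]

#: soil Cd pool columns that may appear as the model's Cd feature
CD_POOL_FEATURES = ("cd_total", "cd_cacl2", "cd_msm")

#: the full feature vocabulary a model may reference
SOIL_FEATURES = (
    "ph", "cec", "clay", "som", "fe_dcb", "fe_ox",
    "cd_total", "cd_cacl2", "cd_msm",
)

_TRANSFORMS = ("log10", "identity")


class ModelSpecError(ValueError):
    """An equation references unknown features or is otherwise malformed."""


class MissingFeatureError(KeyError):
    """A record lacks a feature the model references."""


class DomainError(ValueError):
    """A value is outside the mathematical domain of the equation."""


@dataclass(frozen=True)
class Term:
    """One additive term of a linear predictor: ``coefficient * transform(feature)``."""

    feature: str
    transform: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.feature not in SOIL_FEATURES:
            raise ModelSpecError(f"unknown feature {self.feature!r}")
        if self.transform not in _TRANSFORMS:
            raise ModelSpecError(f"unknown transform {self.transform!r}")
        if not np.isfinite(self.coefficient):
            raise ModelSpecError(f"non-finite coefficient for {self.feature!r}")


@dataclass(frozen=True)
class TransferModel:
    """A log-linear wheat-grain Cd transfer equation.

    Parameters
    ----------
    id : str
        Label, e.g. ``"M2"`` or ``"custom"``.
    terms : tuple of Term
        Ordered feature terms of the linear predictor.
    intercept : float
        The constant of the linear predictor.
    response_transform : {"log10", "identity"}
        Scale on which the linear predictor lives; ``log10`` models are
        inverted with ``10**`` at prediction time.
    """

    id: str
    terms: tuple[Term, ...]
    intercept: float
    response_transform: str = "log10"
    response_units: str = "mg/kg"

    def __post_init__(self) -> None:
        if self.response_transform not in _TRANSFORMS:
            raise ModelSpecError(
                f"unknown response transform {self.response_transform!r}")
        names = [t.feature for t in self.terms]
        if len(set(names)) != len(names):
            raise ModelSpecError("a feature is repeated across terms")
        if not np.isfinite(self.intercept):
            raise ModelSpecError("non-finite intercept")

    # -- introspection -------------------------------------------------
    @property
    def features(self) -> tuple[str, ...]:
        return tuple(t.feature for t in self.terms)

    @property
    def cd_feature(self) -> str:
        """The soil Cd pool the equation is driven by (and solved for
        during threshold inversion)."""
        pools = [t.feature for t in self.terms if t.feature in CD_POOL_FEATURES]
        if len(pools) != 1:
            raise ModelSpecError(
                f"model {self.id!r} must reference exactly one Cd pool, "
                f"found {pools!r}")
        return pools[0]

    # -- evaluation ----------------------------------------------------
    def linear_predictor(self, data: Union[Mapping, pd.DataFrame]) -> np.ndarray:
        """Evaluate the linear predictor on transformed features."""
        lp = np.asarray(self.intercept, dtype=float)
        for t in self.terms:
            x = _get_feature(data, t.feature, self.id)
            if t.transform == "log10":
                if np.any(~np.isfinite(x)) or np.any(x <= 0):
                    raise DomainError(
                        f"model {self.id!r}: feature {t.feature!r} must be "
                        "positive under a log10 transform")
                x = np.log10(x)
            lp = lp + t.coefficient * x
        return lp

    def predict(self, data: Union[Mapping, pd.DataFrame]) -> np.ndarray:
        """Predicted grain Cd (mg/kg) for one record or a table of records."""
        lp = self.linear_predictor(data)
        if self.response_transform == "log10":
            return 10.0 ** lp
        return lp

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "kind": "log_linear",
            "response": "cd_wheat",
            "response_transform": self.response_transform,
            "terms": [
                {"feature": t.feature, "transform": t.transform,
                 "coefficient": float(t.coefficient)}
                for t in self.terms
            ],
            "intercept": float(self.intercept),
            "response_units": self.response_units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransferModel":
        terms = tuple(
            Term(t["feature"], t["transform"], float(t["coefficient"]))
            for t in d["terms"]
        )
        return cls(
            id=str(d["id"]),
            terms=terms,
            intercept=float(d["intercept"]),
            response_transform=d.get("response_transform", "log10"),
            response_units=d.get("response_units", "mg/kg"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransferModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class BcfModel:
    """Quadratic bioconcentration-factor model ``BCF(pH) = a pH^2 + b pH + c``.

    Grain Cd is predicted as ``BCF(pH) * cd_total``; the published default
    (a, b, c) = (0.014, -0.236, 1.113) is shipped as model ``M3``.
    """

    a: float = 0.014
    b: float = -0.236
    c: float = 1.113
    id: str = "M3"
    ph_domain: tuple[float, float] = (3.97, 8.55)
    response_units: str = "mg/kg"

    def bcf(self, ph) -> np.ndarray:
        """Evaluate BCF(pH)."""
        ph = np.asarray(ph, dtype=float)
        return self.a * ph ** 2 + self.b * ph + self.c

    def predict(self, data: Union[Mapping, pd.DataFrame]) -> np.ndarray:
        """Predicted grain Cd (mg/kg): ``BCF(pH) * cd_total``."""
        ph = _get_feature(data, "ph", self.id)
        cd = _get_feature(data, "cd_total", self.id)
        return self.bcf(ph) * cd

    @property
    def cd_feature(self) -> str:
        return "cd_total"

    @property
    def features(self) -> tuple[str, ...]:
        return ("ph", "cd_total")

    def to_dict(self) -> dict:
        return {
            "id": self.id, "kind": "bcf_quadratic", "response": "cd_wheat",
            "a": float(self.a), "b": float(self.b), "c": float(self.c),
            "ph_domain": list(self.ph_domain),
            "response_units": self.response_units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BcfModel":
        return cls(
            a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
            id=str(d.get("id", "M3")),
            ph_domain=tuple(d.get("ph_domain", (3.97, 8.55))),
            response_units=d.get("response_units", "mg/kg"),
        )


AnyModel = Union[TransferModel, BcfModel]


def _get_feature(data: Union[Mapping, pd.DataFrame], name: str, model_id: str):
    if isinstance(data, pd.DataFrame):
        if name not in data.columns:
            raise MissingFeatureError(
                f"model {model_id!r} needs feature {name!r}, "
                "absent from the data")
        col = data[name].to_numpy(dtype=float)
        if np.any(pd.isna(col)):
            raise MissingFeatureError(
                f"model {model_id!r}: feature {name!r} has missing values")
        return col
    # mapping / record-like
    try:
        value = data[name]
    except (KeyError, TypeError):
        value = getattr(data, name, None)
    if value is None or (np.isscalar(value) and pd.isna(value)):
        raise MissingFeatureError(
            f"model {model_id!r} needs feature {name!r}, absent from the record")
    return np.asarray(value, dtype=float)


def predict_grain_cd(model: AnyModel, record) -> np.ndarray:
    """Predict wheat-grain Cd (mg/kg) from a transfer or BCF model.

    ``record`` may be a mapping, a :class:`~cdwheat.dataset.SoilRecord`,
    or a DataFrame of records.
    """
    return model.predict(record)


def _load_builtin(name: str) -> dict:
    text = resources.files("cdwheat").joinpath(
        "builtin_models", f"{name}.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def builtin_model_ids() -> tuple[str, ...]:
    """Labels of the packaged equation suite."""
    return ("M1", "M2", "M3", "M4", "M5", "M5star")


def builtin_model(model_id: str) -> AnyModel:
    """Load one of the packaged published equations by label.

    ``M1``, ``M2``, ``M4``, ``M5`` and ``M5star`` are log-linear
    :class:`TransferModel` instances; ``M3`` is the quadratic
    :class:`BcfModel`.
    """
    key = model_id.strip().replace("*", "star").lower()
    if key not in {m.lower() for m in builtin_model_ids()}:
        raise KeyError(
            f"unknown builtin model {model_id!r}; "
            f"choose from {builtin_model_ids()}")
    d = _load_builtin(key)
    if d.get("kind") == "bcf_quadratic":
        return BcfModel.from_dict(d)
    return TransferModel.from_dict(d)
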