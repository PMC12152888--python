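"""Paired soil–wheat Cd records: typed containers, CSV I/O, cleaning, splitting.

The analysis unit is a paired record: one soil sample's measured
properties and Cd pools together with the Cd content of the wheat grain
grown on it, from which the bioconcentration factor

    BCF = Cd_wheat / Cd_soil

is derived.  A :class:`Dataset` is an ordered collection of such records
backed by a :class:`pandas.DataFrame`; cleaning removes records with
missing required fields and BCF outliers beyond mean +/- 3 SD in a single
pass, and splitting produces repeated, seeded 4:1 train/test partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoilRecord",
    "PairedRecord",
    "Dataset",
    "SplitSpec",
    "CleaningReport",
    "compute_bcf",
    "clean_dataset",
    "split_dataset",
    "load_dataset",
    "write_dataset",
    "CSV_COLUMNS",
    "InvariantError",
    "ParseError",
]

#: canonical internal column order
COLUMNS = (
    "ph", "cec", "clay", "som", "fe_dcb", "fe_ox",
    "cd_total", "cd_cacl2", "cd_msm", "cd_wheat", "bcf", "source",
)

#: columns a record must have to survive cleaning (bcf derives from these)
REQUIRED = (
    "ph", "cec", "clay", "som", "fe_dcb", "fe_ox", "cd_total", "cd_wheat",
)

#: optional bioavailable Cd pools
OPTIONAL = ("cd_cacl2", "cd_msm")

#: on-disk CSV header -> internal column name
CSV_COLUMNS = {
    "ph": "ph",
    "cec_cmolkg": "cec",
    "clay_pct": "clay",
    "som_gkg": "som",
    "fe_dcb_gkg": "fe_dcb",
    "fe_ox_gkg": "fe_ox",
    "cd_total_mgkg": "cd_total",
    "cd_cacl2_mgkg": "cd_cacl2",
    "cd_msm_mgL": "cd_msm",
    "cd_wheat_mgkg": "cd_wheat",
    "source": "source",
}
_INTERNAL_TO_CSV = {v: k for k, v in CSV_COLUMNS.items()}


class InvariantError(ValueError):
    """A record violates a physical invariant (negative Cd, pH out of range...)."""


class ParseError(ValueError):
    """A CSV cell or header cannot be interpreted; carries the row number."""


def compute_bcf(cd_wheat, cd_soil):
    """Bioconcentration factor: grain Cd over soil total Cd (both mg/kg).

    Accepts scalars or arrays; both inputs must be strictly positive.
    """
    cd_wheat = np.asarray(cd_wheat, dtype=float)
    cd_soil = np.asarray(cd_soil, dtype=float)
    if np.any(~(cd_wheat > 0)):
        raise InvariantError("cd_wheat must be > 0 to compute BCF")
    if np.any(~(cd_soil > 0)):
        raise InvariantError("cd_soil must be > 0 to compute BCF")
    out = cd_wheat / cd_soil
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SoilRecord:
    """One soil sample's measured properties and Cd pools.

    Units: pH unitless; CEC cmol/kg; clay percent; SOM g/kg; DCB- and
    oxalate-extractable iron g/kg; total and CaCl2-extractable Cd mg/kg;
    model-dissolved Cd mg/L (1:10 solid-liquid ratio).
    """

    ph: float
    cec: float
    clay: float
    som: float
    fe_dcb: float
    fe_ox: float
    cd_total: float
    cd_cacl2: Optional[float] = None
    cd_msm: Optional[float] = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 < self.ph < 14:
            raise InvariantError(f"ph must lie in (0, 14), got {self.ph}")
        for name in ("cec", "clay", "som", "fe_dcb", "fe_ox"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        if self.clay > 100:
            raise InvariantError(f"clay is a percentage, got {self.clay}")
        if not self.cd_total > 0:
            raise InvariantError(f"cd_total must be > 0, got {self.cd_total}")
        for name in ("cd_cacl2", "cd_msm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvariantError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class PairedRecord:
    """A soil sample paired with the grain Cd of the wheat grown on it."""

    soil: SoilRecord
    cd_wheat: float
    bcf: float = field(default=math.nan)
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.cd_wheat > 0:
            raise InvariantError(f"cd_wheat must be > 0, got {self.cd_wheat}")
        expected = self.cd_wheat / self.soil.cd_total
        if math.isnan(self.bcf):
            object.__setattr__(self, "bcf", expected)
        elif not math.isclose(self.bcf, expected, rel_tol=1e-9):
            raise InvariantError(
                f"bcf {self.bcf} inconsistent with cd_wheat/cd_total {expected}")


@dataclass
class CleaningReport:
    """Which records cleaning removed and why."""

    removed: list = field(default_factory=list)  # (record_id, reason)
    n_in: int = 0
    n_out: int = 0
    bcf_mean: float = math.nan
    bcf_sd: float = math.nan

    @property
    def n_removed(self) -> int:
        return len(self.removed)


class Dataset:
    """Ordered collection of paired soil–wheat records.

    Thin wrapper over a DataFrame with the canonical column set plus a
    unique ``record_id`` index and free-form ``meta`` provenance.
    """

    def __init__(self, df: pd.DataFrame, meta: Optional[dict] = None):
        df = df.copy()
        if "record_id" in df.columns:
            df = df.set_index("record_id")
        if df.index.name != "record_id":
            df.index = pd.Index(
                [f"r{i}" for i in range(len(df))], name="record_id")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise InvariantError(f"duplicated record identifiers: {dupes}")
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "source" else ""
        # derive BCF wherever both parents are present and positive
        ok = (df["cd_wheat"] > 0) & (df["cd_total"] > 0)
        df.loc[ok, "bcf"] = df.loc[ok, "cd_wheat"] / df.loc[ok, "cd_total"]
        self._df = df[list(COLUMNS)]
        self.meta = dict(meta or {})

    # -- container protocol --------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return f"<Dataset: {len(self)} paired soil–wheat records>"

    @property
    def df(self) -> pd.DataFrame:
        """The underlying table (one row per record, indexed by record_id)."""
        return self._df

    @property
    def record_ids(self) -> list[str]:
        return list(self._df.index)

    def equals(self, other: "Dataset") -> bool:
        return self._df.equals(other._df)

    @property
    def records(self) -> list[PairedRecord]:
        """Materialize typed records (validates every invariant)."""
        out = []
        for rid, row in self._df.iterrows():
            soil = SoilRecord(
                ph=row["ph"], cec=row["cec"], clay=row["clay"], som=row["som"],
                fe_dcb=row["fe_dcb"], fe_ox=row["fe_ox"],
                cd_total=row["cd_total"],
                cd_cacl2=None if pd.isna(row["cd_cacl2"]) else row["cd_cacl2"],
                cd_msm=None if pd.isna(row["cd_msm"]) else row["cd_msm"],
                source=row["source"],
            )
            out.append(PairedRecord(soil=soil, cd_wheat=row["cd_wheat"],
                                    record_id=str(rid)))
        return out

    @classmethod
    def from_records(cls, records: Iterable[PairedRecord],
                     meta: Optional[dict] = None) -> "Dataset":
        rows, ids = [], []
        for i, rec in enumerate(records):
            s = rec.soil
            rows.append({
                "ph": s.ph, "cec": s.cec, "clay": s.clay, "som": s.som,
                "fe_dcb": s.fe_dcb, "fe_ox": s.fe_ox, "cd_total": s.cd_total,
                "cd_cacl2": np.nan if s.cd_cacl2 is None else s.cd_cacl2,
                "cd_msm": np.nan if s.cd_msm is None else s.cd_msm,
                "cd_wheat": rec.cd_wheat, "bcf": rec.bcf, "source": s.source,
            })
            ids.append(rec.record_id or f"r{i}")
        df = pd.DataFrame(rows, index=pd.Index(ids, name="record_id"))
        return cls(df, meta=meta)

    def subset(self, ids: Sequence[str], meta: Optional[dict] = None) -> "Dataset":
        return Dataset(self._df.loc[list(ids)], meta=meta or dict(self.meta))


@dataclass(frozen=True)
class SplitSpec:
    """Protocol for repeated seeded train/test splitting.

    Defaults follow the study protocol: 4:1 train/test, 10 independent
    repeats, 10-fold cross-validation inside training, and a 9:1
    pre-train/validation share within training.
    """

    test_fraction: float = 0.2
    n_repeats: int = 10
    cv_folds: int = 10
    pretrain_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.pretrain_fraction < 1:
            raise ValueError("pretrain_fraction must lie in (0, 1)")


def clean_dataset(data: Dataset) -> Dataset:
    """Remove records with missing required fields, then BCF outliers.

    The outlier screen is a single pass on the raw (not log) BCF of all
    records surviving the missing-value filter: records with BCF outside
    mean +/- 3 sample SD are removed; the SD is not recomputed after
    removals.  The screen bounds are frozen into the result's provenance
    (``meta["cleaning"]``), and cleaning an already-cleaned dataset
    re-applies its recorded bounds, so cleaning is idempotent rather than
    an iterated trim.  The report is also available as
    ``result.meta["cleaning_report"]`` (a :class:`CleaningReport`).
    """
    if len(data) == 0:
        raise InvariantError("cannot clean an empty dataset")
    df = data.df
    report = CleaningReport(n_in=len(df))
    prior_bounds = data.meta.get("cleaning", {}).get("bcf_bounds")

    missing_mask = df[list(REQUIRED)].isna().any(axis=1)
    for rid in df.index[missing_mask]:
        bad = [c for c in REQUIRED if pd.isna(df.loc[rid, c])]
        report.removed.append((str(rid), f"missing value: {', '.join(bad)}"))
    kept = df[~missing_mask]

    if len(kept):
        bcf = kept["bcf"].to_numpy(dtype=float)
        mean = float(np.mean(bcf))
        sd = float(np.std(bcf, ddof=1)) if len(bcf) > 1 else 0.0
        report.bcf_mean, report.bcf_sd = mean, sd
        if prior_bounds is not None:
            lo, hi = prior_bounds
        else:
            lo, hi = mean - 3.0 * sd, mean + 3.0 * sd
        out_mask = (kept["bcf"] < lo) | (kept["bcf"] > hi)
        for rid in kept.index[out_mask]:
            report.removed.append(
                (str(rid),
                 f"BCF outlier: {kept.loc[rid, 'bcf']:.4g} outside "
                 f"[{lo:.4g}, {hi:.4g}]"))
        kept = kept[~out_mask]

    if len(kept) == 0:
        raise InvariantError("empty dataset after cleaning")
    report.n_out = len(kept)

    meta = dict(data.meta)
    meta["cleaning"] = {
        "n_in": report.n_in, "n_out": report.n_out,
        "removed": [{"record_id": rid, "reason": why}
                    for rid, why in report.removed],
        "bcf_mean": report.bcf_mean, "bcf_sd": report.bcf_sd,
        "bcf_bounds": [lo, hi],
    }
    meta["cleaning_report"] = report
    return Dataset(kept, meta=meta)


def split_dataset(data: Dataset, spec: SplitSpec) -> list[tuple[Dataset, Dataset]]:
    """Repeated seeded train/test partitions at the requested ratio.

    Each repeat is an exhaustive, disjoint partition with the test size
    rounded to the nearest record; identical seeds give identical
    partitions.
    """
    n = len(data)
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    n_test = int(round(n * spec.test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_fraction {spec.test_fraction} yields an empty "
            "train or test set")
    ids = np.asarray(data.record_ids)
    out = []
    for rep in range(spec.n_repeats):
        rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, rep])
        perm = rng.permutation(n)
        test_ids = ids[perm[:n_test]]
        train_ids = ids[perm[n_test:]]
        meta = {"split": {"seed": spec.seed, "repeat": rep,
                          "test_fraction": spec.test_fraction}}
        out.append((data.subset(train_ids, meta=meta),
                    data.subset(test_ids, meta=meta)))
    return out


# ---------------------------------------------------------------------
# CSV I/O


def _validate_row(row: pd.Series, rownum: int) -> None:
    def bad(msg):
        raise ParseError(f"row {rownum}: {msg}")

    ph = row["ph"]
    if not pd.isna(ph) and not 0 < ph < 14:
        bad(f"ph out of range: {ph}")
    for col in ("cec", "clay", "som", "fe_dcb", "fe_ox"):
        v = row[col]
        if not pd.isna(v) and v < 0:
            bad(f"{col} negative: {v}")
    if not pd.isna(row["clay"]) and row["clay"] > 100:
        bad(f"clay above 100%: {row['clay']}")
    for col in ("cd_total", "cd_cacl2", "cd_msm", "cd_wheat"):
        v = row[col]
        if not pd.isna(v) and not v > 0:
            bad(f"{col} must be > 0: {v}")


def load_dataset(path, units: Optional[Mapping[str, str]] = None) -> Dataset:
    """Load the documented CSV schema into a :class:`Dataset`.

    Parameters
    ----------
    path : path-like
        CSV with header ``ph, cec_cmolkg, clay_pct, som_gkg, fe_dcb_gkg,
        fe_ox_gkg, cd_total_mgkg, cd_cacl2_mgkg, cd_msm_mgL,
        cd_wheat_mgkg, source``; empty cells encode missing optionals.
    units : mapping, optional
        Per-column unit override, e.g. ``{"cd_cacl2": "ug/kg"}`` when a
        file stores CaCl2-extractable Cd in micrograms per kilogram;
        values are converted to mg/kg on load.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in CSV_COLUMNS]
    if unknown:
        raise ParseError(f"unknown column(s): {unknown}")
    missing = [c for c in CSV_COLUMNS if c not in raw.columns and c != "source"]
    if missing:
        raise ParseError(f"missing column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    for csv_name, internal in CSV_COLUMNS.items():
        if internal == "source":
            df["source"] = (raw[csv_name].astype(str)
                            if csv_name in raw.columns else "unknown")
            continue
        vals = np.empty(len(raw))
        for i, cell in enumerate(raw[csv_name]):
            cell = cell.strip()
            if cell == "":
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i + 2}: non-numeric cell {cell!r} "
                    f"in column {csv_name!r}") from None
        df[internal] = vals

    # unit normalization (mass fractions to mg/kg)
    for col, unit in (units or {}).items():
        if col not in df.columns:
            raise ParseError(f"units declared for unknown column {col!r}")
        u = unit.replace("µ", "u").lower()
        if u in ("mg/kg", "mgkg", "mg/l", "mgl"):
            continue
        if u in ("ug/kg", "ugkg", "ug/l", "ugl"):
            df[col] = df[col] * 1e-3
        else:
            raise ParseError(f"unsupported unit {unit!r} for column {col!r}")

    for i, (_, row) in enumerate(df.iterrows()):
        _validate_row(row, i + 2)  # +2: header line is row 1

    df.index = pd.Index(
        [f"{path.name}:{i}" for i in range(len(df))], name="record_id")
    return Dataset(df, meta={"path": str(path), "n_raw": len(df)})


def write_dataset(data: Dataset, path) -> None:
    """Write a :class:`Dataset` to the documented CSV schema.

    Floats are written with 17 significant digits so that a load/write
    round trip is value-exact.
    """
    df = data.df
    out = pd.DataFrame(index=df.index)
    for csv_name, internal in CSV_COLUMNS.items():
        out[csv_name] = df[internal]
    out.to_csv(path, index=False, float_format="%.17g")
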