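"""Reading, validation and cleaning of bipartite incidence matrices and site tables.

A plant-animal mutualistic network is stored as an n x m incidence matrix M:
rows are plants, columns are animals, M[i, k] > 0 iff plant i interacts with
animal k.  Web-of-life style CSVs (header = animal labels, first column =
plant labels) and plain edge lists are both accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "SiteRecord",
    "read_incidence",
    "write_incidence",
    "binarize",
    "prune_isolates",
    "read_site_table",
    "SITE_COVARIATE_COLUMNS",
]

#: covariate columns a site table must carry (velocities optional when rasters
#: are supplied and velocities are computed downstream)
SITE_COVARIATE_COLUMNS = (
    "elevation",
    "t_mean",
    "t_seasonality",
    "p_ann",
    "p_seasonality",
    "hf",
)
VELOCITY_COLUMNS = ("t_velocity", "p_velocity")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Bipartite incidence matrix with row (plant) and column (animal) labels."""

    plant_labels: tuple[str, ...]
    animal_labels: tuple[str, ...]
    M: np.ndarray
    is_binary: bool = field(default=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 1:
            raise ValueError("incidence matrix must be 2-D with n >= 1, m >= 1")
        if M.shape != (len(self.plant_labels), len(self.animal_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.plant_labels)) != len(self.plant_labels):
            raise ValueError("duplicate plant labels")
        if len(set(self.animal_labels)) != len(self.animal_labels):
            raise ValueError("duplicate animal labels")
        if np.any(M < 0):
            raise ValueError("negative interaction values")
        binary = bool(np.all((M == 0) | (M == 1)))
        object.__setattr__(self, "is_binary", binary)

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def m(self) -> int:
        return self.M.shape[1]


@dataclass(frozen=True)
class SiteRecord:
    """One study site: coordinates, environment, and network-derived responses."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float
    t_mean: float
    t_seasonality: float
    p_ann: float
    p_seasonality: float
    hf: float
    t_velocity: float | None = None
    p_velocity: float | None = None
    richness: int | None = None
    beta_eff_plant: float | None = None
    beta_eff_animal: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude {self.longitude} out of range")


def read_incidence(
    path: str | Path, dialect: Literal["matrix", "edge_list"] = "matrix"
) -> IncidenceMatrix:
    """Read an incidence matrix from a CSV (matrix dialect) or TSV edge list.

    Matrix dialect: header row of animal labels, first column plant labels.
    Edge-list dialect: rows of (plant, animal, weight), tab- or comma-separated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    if dialect == "matrix":
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"no data rows/columns in {path}")
        plants = tuple(str(x) for x in df.index)
        animals = tuple(str(x) for x in df.columns)
        try:
            M = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
        return IncidenceMatrix(plants, animals, M)
    if dialect == "edge_list":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else "[,\t]"
        df = pd.read_csv(path, sep=sep, engine="python", header=None,
                         names=["plant", "animal", "weight"])
        if df.empty:
            raise ValueError(f"empty edge list: {path}")
        df["weight"] = pd.to_numeric(df["weight"], errors="raise")
        plants = tuple(dict.fromkeys(str(p) for p in df["plant"]))
        animals = tuple(dict.fromkeys(str(a) for a in df["animal"]))
        pi = {p: i for i, p in enumerate(plants)}
        ai = {a: j for j, a in enumerate(animals)}
        M = np.zeros((len(plants), len(animals)))
        for p, a, w in df.itertuples(index=False):
            M[pi[str(p)], ai[str(a)]] = float(w)
        return IncidenceMatrix(plants, animals, M)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_incidence(net: IncidenceMatrix, path: str | Path) -> Path:
    """Write a matrix-dialect CSV readable by :func:`read_incidence`."""
    path = Path(path)
    df = pd.DataFrame(net.M, index=list(net.plant_labels), columns=list(net.animal_labels))
    df.to_csv(path)
    return path


def binarize(net: IncidenceMatrix, threshold: float = 0.0) -> IncidenceMatrix:
    """Map entries to 1 where value > threshold, else 0.

    The default (any observed interaction counts) matches the convention of
    analysing weighted source webs as binary networks.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    B = (net.M > threshold).astype(float)
    return IncidenceMatrix(net.plant_labels, net.animal_labels, B)


def prune_isolates(net: IncidenceMatrix) -> IncidenceMatrix:
    """Iteratively drop all-zero rows and columns (unobserved species).

    Required before projection: a zero column/row would put a zero in the
    inverse-degree denominators.  Idempotent.
    """
    M = net.M
    plants = np.array(net.plant_labels, dtype=object)
    animals = np.array(net.animal_labels, dtype=object)
    while True:
        row_keep = M.sum(axis=1) > 0
        col_keep = M.sum(axis=0) > 0
        if row_keep.all() and col_keep.all():
            break
        M = M[row_keep][:, col_keep]
        plants = plants[row_keep]
        animals = animals[col_keep]
        if M.size == 0:
            raise ValueError("empty network after pruning")
    if M.size == 0:
        raise ValueError("empty network after pruning")
    return IncidenceMatrix(tuple(plants), tuple(animals), M)


def _as_float(value, column: str, site: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric {column} at site {site}: {value!r}") from exc
    if math.isnan(v):
        raise ValueError(f"missing {column} at site {site}")
    return v


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read and validate a per-site environment CSV.

    Velocity columns are optional (they may be computed later from climate
    rasters); all other covariates are required and must be numeric.
    """
    df = pd.read_csv(path)
    required = ["site_id", "latitude", "longitude", *SITE_COVARIATE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing required columns: {missing}")
    records: list[SiteRecord] = []
    for row in df.to_dict("records"):
        sid = str(row["site_id"])
        kwargs = {
            "site_id": sid,
            "latitude": _as_float(row["latitude"], "latitude", sid),
            "longitude": _as_float(row["longitude"], "longitude", sid),
        }
        for col in SITE_COVARIATE_COLUMNS:
            kwargs[col] = _as_float(row[col], col, sid)
        for col in VELOCITY_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = _as_float(row[col], col, sid)
        records.append(SiteRecord(**kwargs))
    if len({r.site_id for r in records}) != len(records):
        raise ValueError("duplicate site_id in site table")
    return records


def site_records_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    """Tabular view of site records (one row per site, site_id index)."""
    rows = [vars(r) if not hasattr(r, "__dataclass_fields__") else
            {f: getattr(r, f) for f in r.__dataclass_fields__} for r in records]
    return pd.DataFrame(rows).set_index("site_id")
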