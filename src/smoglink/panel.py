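"""Panel data model, validation, file I/O and pipeline configuration.

The panel is the spine of every stage: a balanced region-by-year table of
the outcome RS (regulation strength, the ratio of industrial added value to
industrial pollution-control investment projects) and six covariates:

========  =====================================================  =========
name      meaning                                                units
========  =====================================================  =========
HC        haze concentration (annual mean PM2.5)                 µg/m³
PG        per-capita GDP                                         level
PD        population density                                     level
ES        energy strength (energy use per unit output)           level
URB       urbanization rate                                      fraction
IND       industrial (secondary-sector) structure share          fraction
========  =====================================================  =========

On disk the panel is long format (one row per region-year, header
``region,year,RS,HC,PG,PD,ES,URB,IND``); in memory each variable is an
n-by-T matrix with a single region ordering (lexicographic at load) shared
with the spatial weight matrix.  Inputs must be complete: missing cells are
a validation error, never interpolated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("smoglink")

#: covariate column order used everywhere (matrices, coefficient vectors)
COVARIATES: tuple[str, ...] = ("HC", "PG", "PD", "ES", "URB", "IND")
#: outcome column name
OUTCOME = "RS"
#: covariates that must be strictly positive
POSITIVE_VARS = ("HC", "PG", "PD", "ES")
#: covariates constrained to [0, 1]
FRACTION_VARS = ("URB", "IND")


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """Panel violates a structural invariant (balance, ranges)."""


@dataclass(frozen=True)
class PanelData:
    """Balanced region x year panel.

    ``outcome`` and each entry of ``covariates`` are float matrices of
    shape (n, T); row i is ``region_ids[i]``, column t is ``years[t]``.
    """

    region_ids: tuple[str, ...]
    years: tuple[int, ...]
    outcome: np.ndarray
    covariates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_ids", tuple(str(r) for r in self.region_ids))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=float))
        object.__setattr__(
            self,
            "covariates",
            {k: np.asarray(v, dtype=float) for k, v in self.covariates.items()},
        )
        n, T = self.n, self.T
        if self.outcome.shape != (n, T):
            raise ValidationError(f"outcome shape {self.outcome.shape} != ({n}, {T})")
        for name, mat in self.covariates.items():
            if mat.shape != (n, T):
                raise ValidationError(f"{name} shape {mat.shape} != ({n}, {T})")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def T(self) -> int:
        return len(self.years)

    def covariate_stack(self) -> np.ndarray:
        """Covariates as an (n, T, k) array in ``COVARIATES`` order."""
        return np.stack([self.covariates[c] for c in COVARIATES], axis=-1)

    def subset_years(self, years: Sequence[int]) -> "PanelData":
        """Restrict to a consecutive run of years (used by staged fits)."""
        years = [int(y) for y in years]
        idx = [self.years.index(y) for y in years]
        return PanelData(
            region_ids=self.region_ids,
            years=tuple(years),
            outcome=self.outcome[:, idx],
            covariates={k: v[:, idx] for k, v in self.covariates.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (region, year)."""
        rows = {
            "region": np.repeat(self.region_ids, self.T),
            "year": np.tile(self.years, self.n),
            OUTCOME: self.outcome.ravel(),
        }
        for c in COVARIATES:
            rows[c] = self.covariates[c].ravel()
        return pd.DataFrame(rows)


def load_panel(path: str, schema: Mapping[str, str] | None = None) -> PanelData:
    """Read and validate a long-format panel CSV.

    Parameters
    ----------
    path : str
        CSV with header ``region,year,RS,HC,PG,PD,ES,URB,IND`` (or the
        names given by ``schema``).
    schema : mapping, optional
        Maps canonical names (``region``, ``year``, ``RS``, ...) to the
        column names actually present in the file.

    Raises
    ------
    SchemaError
        A required column is absent.
    ValidationError
        The panel is unbalanced (the message names the missing cells) or
        a cell is non-numeric (the message gives the row number).
    """
    df = pd.read_csv(path, dtype={0: str})
    schema = dict(schema or {})
    required = ["region", "year", OUTCOME, *COVARIATES]
    colmap = {name: schema.get(name, name) for name in required}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[required]
    df["region"] = df["region"].astype(str)

    for col in required[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
        elif df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2
        else:
            df[col] = coerced
            continue
        raise ValidationError(f"non-numeric or empty value in column {col!r}, file line {row}")

    regions = sorted(df["region"].unique())
    years = sorted(int(y) for y in df["year"].unique())
    expected = {(r, y) for r in regions for y in years}
    present = set(zip(df["region"], df["year"].astype(int)))
    if len(df) != len(present):
        dupes = df[df.duplicated(["region", "year"])]
        cell = (dupes.iloc[0]["region"], int(dupes.iloc[0]["year"]))
        raise ValidationError(f"duplicate (region, year) cell: {cell}")
    gaps = sorted(expected - present)
    if gaps:
        cells = ", ".join(f"({r}, {y})" for r, y in gaps[:10])
        raise ValidationError(f"unbalanced panel; missing cells: {cells}")

    df = df.sort_values(["region", "year"]).reset_index(drop=True)
    n, T = len(regions), len(years)
    panel = PanelData(
        region_ids=tuple(regions),
        years=tuple(years),
        outcome=df[OUTCOME].to_numpy().reshape(n, T),
        covariates={c: df[c].to_numpy().reshape(n, T) for c in COVARIATES},
    )
    findings = validate_panel(panel)
    if findings:
        raise ValidationError("; ".join(findings))
    return panel


def validate_panel(panel: PanelData) -> list[str]:
    """Check every panel invariant; return one finding per violation.

    Total on finite numeric input: returns findings, never raises.
    """
    findings: list[str] = []
    years = np.asarray(panel.years)
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        findings.append("years not consecutive with step 1")
    mats = {OUTCOME: panel.outcome, **panel.covariates}
    for name, mat in mats.items():
        bad = ~np.isfinite(mat)
        if bad.any():
            i, t = np.argwhere(bad)[0]
            findings.append(
                f"non-finite {name} at region {panel.region_ids[i]}, year {panel.years[t]}"
            )
    for name in POSITIVE_VARS:
        mat = panel.covariates[name]
        bad = np.isfinite(mat) & (mat <= 0)
        if bad.any():
            i, t = np.argwhere(bad)[0]
            findings.append(
                f"{name} not strictly positive at region {panel.region_ids[i]}, "
                f"year {panel.years[t]}"
            )
    for name in FRACTION_VARS:
        mat = panel.covariates[name]
        bad = np.isfinite(mat) & ((mat < 0) | (mat > 1))
        if bad.any():
            i, t = np.argwhere(bad)[0]
            findings.append(
                f"{name} out of [0,1] at region {panel.region_ids[i]}, year {panel.years[t]}"
            )
    return findings


def write_panel(panel: PanelData, path: str) -> None:
    """Write the long-format CSV that :func:`load_panel` reads."""
    panel.to_frame().to_csv(path, index=False)


def load_adjacency(path: str) -> list[tuple[str, str]]:
    """Read an adjacency CSV with header ``region_a,region_b``."""
    df = pd.read_csv(path, dtype=str)
    for col in ("region_a", "region_b"):
        if col not in df.columns:
            raise SchemaError(f"missing column(s): {col}")
    return list(zip(df["region_a"], df["region_b"]))


def load_distances(path: str) -> dict[tuple[str, str], float]:
    """Read a distance CSV with header ``region_a,region_b,km``."""
    df = pd.read_csv(path, dtype={"region_a": str, "region_b": str})
    for col in ("region_a", "region_b", "km"):
        if col not in df.columns:
            raise SchemaError(f"missing column(s): {col}")
    return {(a, b): float(km) for a, b, km in zip(df["region_a"], df["region_b"], df["km"])}


# ---------------------------------------------------------------------------
# configuration

#: stage boundaries of the policy periodization used for staged fits
DEFAULT_STAGES: tuple[tuple[int, int], ...] = (
    (2005, 2007),
    (2008, 2010),
    (2011, 2014),
    (2015, 2017),
)


@dataclass
class PipelineConfig:
    """Knobs for the end-to-end pipeline.

    Defaults mirror the study design: contiguity weights, distance-decay
    exponent b = 2 for the gravity model, the four policy stages, and
    999 Moran permutations.
    """

    panel_path: str | None = None
    adjacency_path: str | None = None
    distance_path: str | None = None
    distance_decay: float = 2.0
    sqrt_masses: bool = False
    edge_rule: str = "row-mean"  # "row-mean" | "all" | absolute float cutoff
    edge_cutoff: float | None = None
    network_years: tuple[int, ...] | None = None  # default: all panel years
    stages: tuple[tuple[int, int], ...] = DEFAULT_STAGES
    n_permutations: int = 999
    log_transform: bool = False  # opt-in log of HC/PG/PD/ES before fitting
    rho_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.distance_decay <= 0:
            raise ValueError("distance_decay must be positive")
        self.stages = tuple((int(a), int(b)) for a, b in self.stages)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(tuple(s) for s in raw["stages"])
        if "network_years" in raw and raw["network_years"] is not None:
            raw["network_years"] = tuple(raw["network_years"])
        return cls(**raw)

    def validate_stages(self, years: Sequence[int]) -> None:
        """Stages must partition the panel's year range."""
        covered: list[int] = []
        for a, b in self.stages:
            if b < a:
                raise ValueError(f"stage ({a}, {b}) reversed")
            covered.extend(range(a, b + 1))
        if sorted(covered) != sorted(int(y) for y in years):
            raise ValueError("stages do not partition the panel years")

    def digest(self) -> str:
        """Stable hash of the configuration, logged for provenance."""
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# result serialization


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(result, path: str, format: str = "json") -> None:
    """Serialize a result object (fit, Moran result, network, ...).

    ``json`` works for anything exposing ``to_dict``; ``csv`` for objects
    exposing ``to_frame``; ``graphml`` for gravity networks.  JSON numbers
    round-trip exactly (repr-based float encoding).
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if format == "json":
        payload = _to_jsonable(result)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "csv":
        if not hasattr(result, "to_frame"):
            raise ValueError(f"{type(result).__name__} has no tabular form")
        result.to_frame().to_csv(path, index=False)
    elif format == "graphml":
        import networkx as nx

        if not hasattr(result, "to_networkx"):
            raise ValueError(f"{type(result).__name__} is not a network")
        nx.write_graphml(result.to_networkx(), path)
    else:
        raise ValueError(f"unsupported format: {format!r}")


def read_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
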