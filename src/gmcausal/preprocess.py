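"""Variable derivation, exclusion, standardization and discretization.

Implements the cohort-building conventions used throughout the pipeline:
waist-to-hip ratio from circumferences, physical activity as the sum of
moderate and vigorous durations, systolic blood pressure as the mean of
two readings, ever-smoker binarization, complete-case filtering,
z-score standardization of continuous variables, and quartile
discretization into four ordinal states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .schema import BINARY, CONTINUOUS, DEFAULT_SCHEMA, VariableSchema, schema_by_name

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizationMap",
    "derive_whr",
    "derive_pa",
    "derive_sbp",
    "binarize_smoking",
    "drop_incomplete",
    "standardize",
    "StandardizationParams",
    "discretize",
]


# --------------------------------------------------------------------------
# derived variables


def derive_whr(waist, hip):
    """Waist-to-hip ratio. ``hip`` must be strictly positive."""
    waist = np.asarray(waist, dtype=float)
    hip = np.asarray(hip, dtype=float)
    if np.any(hip[~np.isnan(hip)] <= 0):
        raise ValueError("hip circumference must be positive")
    out = waist / hip
    return float(out) if out.ndim == 0 else out


def derive_pa(moderate, vigorous):
    """Total physical activity: moderate + vigorous duration.

    Missing values propagate; negative durations are rejected.
    """
    moderate = np.asarray(moderate, dtype=float)
    vigorous = np.asarray(vigorous, dtype=float)
    for arr, name in ((moderate, "moderate"), (vigorous, "vigorous")):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"{name} activity duration must be non-negative")
    out = moderate + vigorous
    return float(out) if out.ndim == 0 else out


def derive_sbp(reading1, reading2):
    """Mean of two systolic blood pressure readings; missing propagates."""
    r1 = np.asarray(reading1, dtype=float)
    r2 = np.asarray(reading2, dtype=float)
    for arr in (r1, r2):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError("blood pressure readings must be positive")
    out = (r1 + r2) / 2.0
    return float(out) if out.ndim == 0 else out


_SMOKING_MAP = {"never": 0, "previous": 1, "current": 1}


def binarize_smoking(status):
    """Map smoking status to 1 for current/previous smokers, 0 for never.

    Missing (None/NaN/"missing") propagates as NaN; any other category is
    rejected.
    """

    def _one(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        key = str(value).strip().lower()
        if key in ("missing", "nan", ""):
            return np.nan
        if key not in _SMOKING_MAP:
            raise ValueError(f"unknown smoking category {value!r}")
        return float(_SMOKING_MAP[key])

    if isinstance(status, (str, float, int)) or status is None:
        return _one(status)
    values = pd.Series(status).map(_one)
    return values.to_numpy(dtype=float)


# --------------------------------------------------------------------------
# exclusion and standardization


def drop_incomplete(table: pd.DataFrame, required: Sequence[str]) -> pd.DataFrame:
    """Remove rows missing any of the required variables (row order kept)."""
    unknown = [v for v in required if v not in table.columns]
    if unknown:
        raise ValueError(f"unknown variable(s) in required list: {unknown}")
    keep = table[list(required)].notna().all(axis=1)
    dropped = int((~keep).sum())
    logger.info("drop_incomplete: %d rows in, %d dropped, %d kept",
                len(table), dropped, int(keep.sum()))
    if keep.sum() == 0:
        logger.warning("drop_incomplete: all %d rows removed", len(table))
    return table.loc[keep]


class StandardizationParams(NamedTuple):
    """Per-variable means and standard deviations for inverting a z-score."""

    means: dict[str, float]
    sds: dict[str, float]


def standardize(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the selected columns (subtract mean, divide by SD).

    Returns the transformed table and the parameters needed to invert the
    transform.  Columns not selected (e.g. binary indicators) are left
    untouched.  A zero-variance column is a hard error naming the column.
    """
    if variables is None:
        variables = [c for c in table.columns]
    out = table.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for var in variables:
        if var not in table.columns:
            raise ValueError(f"unknown variable {var!r}")
        col = table[var].to_numpy(dtype=float)
        mean = float(np.nanmean(col))
        sd = float(np.nanstd(col, ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {var!r} has zero variance; cannot standardize")
        out[var] = (col - mean) / sd
        means[var], sds[var] = mean, sd
    return out, StandardizationParams(means, sds)


# --------------------------------------------------------------------------
# discretization


@dataclass(frozen=True)
class DiscretizationMap:
    """Ordered bin edges per variable: three edges define four states.

    States are half-open on the left, ``[low, high)``; state 0 is
    ``(-inf, e0)`` and state 3 is ``[e2, inf)``, so a value equal to a
    printed edge falls in the upper bin.  ``method`` records the percentile
    convention used when the edges were estimated from data.
    """

    edges: dict[str, tuple[float, float, float]]
    method: str = "linear"

    def __post_init__(self) -> None:
        for var, e in self.edges.items():
            if len(e) != 3:
                raise ValueError(f"{var!r}: exactly three edges required, got {len(e)}")
            if not (e[0] < e[1] < e[2]):
                raise ValueError(f"{var!r}: edges must be strictly increasing, got {e}")

    def assign(self, var: str, values) -> np.ndarray:
        """State labels 0-3 for ``values`` of ``var`` (NaN propagates as -1)."""
        values = np.asarray(values, dtype=float)
        states = np.searchsorted(np.asarray(self.edges[var]), values, side="right")
        states = states.astype(np.int64)
        states[np.isnan(values)] = -1
        return states

    def to_json(self) -> str:
        return json.dumps(
            {"method": self.method, "edges": {k: list(v) for k, v in self.edges.items()}},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        payload = json.loads(text)
        return cls(
            edges={k: tuple(float(x) for x in v) for k, v in payload["edges"].items()},
            method=payload.get("method", "linear"),
        )


def discretize(
    table: pd.DataFrame,
    dmap: DiscretizationMap | str = "quartiles",
    schema: Iterable[VariableSchema] = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, DiscretizationMap]:
    """Discretize continuous variables into four quartile states.

    With ``dmap="quartiles"`` the bin edges are the 25th, 50th and 75th
    percentiles of each continuous column (linear-interpolation
    convention); an explicit :class:`DiscretizationMap` applies fixed
    edges instead.  Binary variables pass through as states {0, 1}.

    Returns the table of integer states together with the map used.

    Raises
    ------
    ValueError
        If percentile edges tie (e.g. a constant column), with a hint to
        supply explicit edges.
    """
    by_name = schema_by_name(schema)
    out = pd.DataFrame(index=table.index)
    if isinstance(dmap, str):
        if dmap != "quartiles":
            raise ValueError(f"unknown discretization rule {dmap!r}")
        edges: dict[str, tuple[float, float, float]] = {}
        for var in table.columns:
            kind = by_name[var].kind if var in by_name else CONTINUOUS
            if kind != CONTINUOUS:
                continue
            col = table[var].to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            if len(col) < 4:
                raise ValueError(f"{var!r}: need at least 4 observations for quartiles")
            q = np.percentile(col, [25.0, 50.0, 75.0], method="linear")
            if not (q[0] < q[1] < q[2]):
                raise ValueError(
                    f"{var!r}: tied percentile edges {tuple(q)}; "
                    "supply explicit edges or jitter the data"
                )
            edges[var] = (float(q[0]), float(q[1]), float(q[2]))
        dmap = DiscretizationMap(edges=edges, method="linear")

    for var in table.columns:
        kind = by_name[var].kind if var in by_name else (
            CONTINUOUS if var in dmap.edges else BINARY
        )
        if kind == BINARY or var not in dmap.edges:
            vals = table[var].to_numpy(dtype=float)
            bad = vals[~np.isnan(vals)]
            if not np.all(np.isin(bad, (0.0, 1.0))):
                raise ValueError(f"binary variable {var!r} contains values outside {{0,1}}")
            out[var] = vals.astype(np.int64, copy=False) if not np.isnan(vals).any() else vals
        else:
            out[var] = dmap.assign(var, table[var])
    return out, dmap
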