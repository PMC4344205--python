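"""Discretization, imputation, and the per-year censoring grid.

Expression values are reduced to three ordered levels (low/medium/high) by
equal-width binning; missing clinical cells are completed by training-set
mode (categorical) or median (numeric); follow-up ``(day, status)`` is
expanded into a per-year status grid that makes right censoring explicit,
from which a binary landmark target (dead/alive at year Y) is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizedMatrix",
    "equal_width_discretize",
    "discretize_frame",
    "impute_clinical",
    "ImputationError",
    "build_year_table",
    "landmark_target",
    "DAYS_PER_YEAR",
    "LEVELS3",
]

DAYS_PER_YEAR = 365
LEVELS3 = ("low", "medium", "high")

ALIVE, DEAD, NA = "alive", "dead", "NA"


class ImputationError(ValueError):
    pass


def _labels(m: int) -> list[str]:
    return list(LEVELS3) if m == 3 else [f"bin_{i}" for i in range(m)]


def equal_width_discretize(
    values, m: int = 3, edges: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Equal-width binning of one feature into ``m`` ordered levels.

    Partitions ``[min, max]`` into ``m`` intervals of width ``(max-min)/m``;
    a value ``v`` goes to bin ``floor((v-min)/width)`` capped at ``m-1`` (so
    the maximum lands in the top bin).  When ``edges`` — the training-set
    ``(min, max)`` — is supplied, those bounds are reused and out-of-range
    values are clipped into the end bins.

    Returns ``(codes, (lo, hi), degenerate)``.  A constant feature is
    degenerate: every value is assigned the lowest bin and the flag is set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if m < 2:
        raise ValueError("m must be >= 2")
    if edges is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = float(edges[0]), float(edges[1])
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.int8), (lo, hi), True
    width = (hi - lo) / m
    codes = np.floor((v - lo) / width).astype(np.int64)
    codes = np.clip(codes, 0, m - 1).astype(np.int8)
    return codes, (lo, hi), False


@dataclass
class DiscretizedMatrix:
    """Patients x features table of ordered categorical levels."""

    data: pd.DataFrame
    bin_edges: dict[str, tuple[float, float]]
    m: int = 3
    degenerate: set[str] = field(default_factory=set)


def discretize_frame(
    df: pd.DataFrame, m: int = 3, fit: DiscretizedMatrix | None = None
) -> DiscretizedMatrix:
    """Discretize every column of ``df``; reuse ``fit``'s edges when given.

    Passing the training-fold result as ``fit`` applies the training bin
    edges to held-out data, so no information leaks from the evaluation fold.
    """
    dtype = pd.CategoricalDtype(categories=_labels(m), ordered=True)
    cols, edges, degen = {}, {}, set()
    for col in df.columns:
        e = fit.bin_edges[col] if fit is not None else None
        codes, edge, is_degen = equal_width_discretize(df[col].to_numpy(), m, edges=e)
        cols[col] = pd.Categorical.from_codes(codes, dtype=dtype)
        edges[col] = edge
        if is_degen:
            degen.add(col)
    out = pd.DataFrame(cols, index=df.index)
    return DiscretizedMatrix(data=out, bin_edges=edges, m=m, degenerate=degen)


def impute_clinical(df: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fill missing cells: categorical -> mode, numeric -> median.

    Statistics come from ``reference`` (the training fold) when supplied,
    otherwise from ``df`` itself.  Deterministic: modal ties resolve to the
    earliest level in the column's category order.  A column with no
    observed value in the reference raises ``ImputationError`` naming it.
    """
    ref = reference if reference is not None else df
    out = df.copy()
    for col in df.columns:
        rcol = ref[col]
        if rcol.notna().sum() == 0:
            raise ImputationError(f"column {col!r} has no observed values to impute from")
        if not df[col].isna().any():
            continue
        if isinstance(df[col].dtype, pd.CategoricalDtype) or df[col].dtype == object:
            counts = rcol.value_counts()
            best = counts.max()
            if isinstance(rcol.dtype, pd.CategoricalDtype):
                order = list(rcol.cat.categories)
            else:
                order = sorted(counts.index)
            fill = next(lv for lv in order if counts.get(lv, 0) == best)
        else:
            fill = rcol.median()
        out[col] = out[col].fillna(fill)
    return out


def build_year_table(
    day,
    status,
    horizon_years: int = 15,
    days_per_year: int = DAYS_PER_YEAR,
    patient_ids=None,
) -> pd.DataFrame:
    """Expand follow-up into a per-year alive/dead/NA grid.

    The event (or last-contact) year is ``ceil(day / days_per_year)``.  A
    patient who died in year ``e`` is ``alive`` for years before ``e`` and
    ``dead`` from ``e`` on; a censored patient is ``alive`` through the year
    last seen and ``NA`` (status unknown) afterwards.
    """
    day = np.asarray(day, dtype=float)
    status = np.asarray(status, dtype=object)
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if np.any(day <= 0):
        raise ValueError(f"day must be > 0 (first offender at row {int(np.argmax(day <= 0))})")
    event_year = np.ceil(day / days_per_year).astype(int)
    dead = status == DEAD
    years = np.arange(1, horizon_years + 1)
    grid = np.where(
        dead[:, None],
        np.where(years[None, :] >= event_year[:, None], DEAD, ALIVE),
        np.where(years[None, :] <= event_year[:, None], ALIVE, NA),
    )
    table = pd.DataFrame(grid, columns=[f"Year_{y}" for y in years])
    if patient_ids is not None:
        table.insert(0, "patient_id", list(patient_ids))
    return table


def landmark_target(year_table: pd.DataFrame, year: int) -> pd.Series:
    """Status at the landmark year: the ``Year_Y`` column of the grid.

    ``NA`` entries are censored-before-landmark patients; callers feeding a
    binary-target method (Relief) must drop them first.
    """
    col = f"Year_{year}"
    if col not in year_table.columns:
        raise ValueError(f"year {year} exceeds the table horizon")
    return year_table[col].copy()
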