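"""Behavioral and histological summary statistics.

Discrimination index and familiar-object exploration probability from raw
per-object exploration times, and the engram reactivation rate from
eYFP / c-Fos cell counts.  The two behavioral statistics are linked by the
identity DI = 1 - 2*mu_hat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ObjectTestRecord",
    "EngramCounts",
    "UndefinedMetricError",
    "discrimination_index",
    "familiar_exploration_probability",
    "engram_reactivation_rate",
    "per_mouse_reactivation",
    "LOW_EXPLORATION_FLOOR_S",
]

#: Records with less total exploration than this (seconds) are flagged.
LOW_EXPLORATION_FLOOR_S = 1.0


class UndefinedMetricError(ValueError):
    """The metric's denominator is zero."""


@dataclass(frozen=True)
class ObjectTestRecord:
    """Exploration times (s) for one mouse at one recognition test."""

    time_novel: float
    time_familiar: float

    def __post_init__(self) -> None:
        if self.time_novel < 0 or self.time_familiar < 0:
            raise ValueError("exploration times must be non-negative")

    @property
    def total(self) -> float:
        return self.time_novel + self.time_familiar

    @property
    def low_exploration(self) -> bool:
        """Flag (never silently drop) mice that barely explored."""
        return self.total < LOW_EXPLORATION_FLOOR_S


@dataclass(frozen=True)
class EngramCounts:
    """Cell counts in one slice: labeled engram cells (eYFP), recall-active
    cells (c-Fos), their overlap, and all nuclei (DAPI)."""

    n_eyfp: int
    n_cfos: int
    n_double: int
    n_dapi: int = 0

    def __post_init__(self) -> None:
        if min(self.n_eyfp, self.n_cfos, self.n_double, self.n_dapi) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_double > min(self.n_eyfp, self.n_cfos):
            raise ValueError(
                "double-labeled count cannot exceed either single-label count"
            )


def discrimination_index(record: ObjectTestRecord) -> float:
    """(novel - familiar) / (novel + familiar); 0 = chance, 1 = pure novelty."""
    if record.total <= 0:
        raise UndefinedMetricError("discrimination index undefined at zero exploration")
    return (record.time_novel - record.time_familiar) / record.total


def familiar_exploration_probability(record: ObjectTestRecord) -> float:
    """Fraction of exploration on the familiar object; DI = 1 - 2*mu_hat."""
    if record.total <= 0:
        raise UndefinedMetricError("exploration probability undefined at zero exploration")
    return record.time_familiar / record.total


def engram_reactivation_rate(counts: EngramCounts) -> float:
    """Fraction of labeled engram cells re-active at recall: n_double / n_eyfp."""
    if counts.n_eyfp == 0:
        raise UndefinedMetricError("reactivation rate undefined with no eYFP+ cells")
    return counts.n_double / counts.n_eyfp


def per_mouse_reactivation(slices: Iterable[EngramCounts]) -> float:
    """Unweighted mean of per-slice reactivation rates for one mouse."""
    rates = [engram_reactivation_rate(c) for c in slices]
    if not rates:
        raise UndefinedMetricError("no slices provided")
    return float(np.mean(rates))


def reactivation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse reactivation from a per-slice counts table.

    Expects columns subject_id, slice_id, n_eyfp, n_cfos, n_double
    (n_dapi optional); returns one row per mouse with the mean rate.
    """
    required = {"subject_id", "slice_id", "n_eyfp", "n_cfos", "n_double"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for subject, grp in df.groupby("subject_id", sort=True):
        counts = [
            EngramCounts(
                n_eyfp=int(r.n_eyfp),
                n_cfos=int(r.n_cfos),
                n_double=int(r.n_double),
                n_dapi=int(getattr(r, "n_dapi", 0) or 0),
            )
            for r in grp.itertuples(index=False)
        ]
        rows.append(
            {
                "subject_id": subject,
                "n_slices": len(counts),
                "reactivation": per_mouse_reactivation(counts),
            }
        )
    return pd.DataFrame(rows)
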