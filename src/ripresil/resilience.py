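"""Resistance (RS) and resilience (RL) indices of disturbance response.

The design collapses time into three sample groups per study area: a
never-disturbed *reference* group, a currently disturbed *flooding* group,
and a previously disturbed, now re-exposed *recovery* group.  With C0 the
reference-group mean of a variable, P0 the flooding-group mean and Px the
recovery-group mean (and the undisturbed control Cx taken equal to C0, the
space-for-time convention),

    RS = 1 - 2|C0 - P0| / (C0 + |C0 - P0|)
    RL = 2|C0 - P0| / (|C0 - P0| + |C0 - Px|) - 1

Both indices live in [-1, +1].  RS = +1 means the disturbance had no
effect (maximal resistance); RL = +1 means the variable returned exactly
to its reference value (complete recovery), RL = 0 means no recovery
beyond the disturbed state, and negative RL means further drift.  RL is
undefined when C0 = P0 — there is no displacement to recover from — and is
reported as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CompositionTable, GROUPS

__all__ = [
    "DisturbanceTriplet",
    "RsRlResult",
    "group_mean",
    "resistance_index",
    "resilience_index",
    "rs_rl_profile",
    "taxon_rs_rl",
    "results_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisturbanceTriplet:
    """Group means of one variable in one study area (C0, P0, Px)."""

    c0: float
    p0: float
    px: float
    variable_name: str = ""
    area: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        for name in ("c0", "p0", "px"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class RsRlResult:
    """RS and RL for one variable in one area; group means echoed for audit."""

    variable_name: str
    area: str
    rs: float
    rl: float  # NaN marks "undefined" (no disturbance displacement)
    c0: float
    p0: float
    px: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Report-table presentation: indices rounded to ``ndigits``."""
        rl = round(self.rl, ndigits) if not math.isnan(self.rl) else math.nan
        return round(self.rs, ndigits), rl


def group_mean(values: pd.Series, metadata: pd.DataFrame, area: str, group: str) -> float:
    """Unweighted arithmetic mean of ``values`` over samples in (area, group)."""
    mask = (metadata["area"] == area) & (metadata["group"] == group)
    sample_ids = metadata.index[mask]
    selected = values.reindex(sample_ids).dropna()
    if selected.empty:
        raise ValueError(f"no samples for area {area!r}, group {group!r}")
    return float(selected.mean())


def resistance_index(c0: float, p0: float) -> float:
    """RS = 1 - 2|C0-P0| / (C0 + |C0-P0|); +1 iff the variable did not change.

    The degenerate case C0 = P0 = 0 (variable absent before and during the
    disturbance) is defined as RS = 1: nothing changed.
    """
    d = abs(c0 - p0)
    if c0 == 0 and d == 0:
        logger.info("resistance_index: C0 = P0 = 0, returning RS = 1 (no change)")
        return 1.0
    return 1.0 - 2.0 * d / (c0 + d)


def resilience_index(c0: float, p0: float, px: float) -> float:
    """RL = 2|C0-P0| / (|C0-P0| + |C0-Px|) - 1, with Cx = C0.

    Returns NaN when C0 = P0: without disturbance displacement, "recovery"
    is meaningless (the raw formula's limit of -1 would be misleading).
    """
    d0 = abs(c0 - p0)
    if d0 == 0:
        logger.info("resilience_index: C0 = P0, RL undefined (no displacement)")
        return math.nan
    dx = abs(c0 - px)
    return 2.0 * d0 / (d0 + dx) - 1.0


def rs_rl_from_triplet(triplet: DisturbanceTriplet) -> RsRlResult:
    return RsRlResult(
        variable_name=triplet.variable_name,
        area=triplet.area,
        rs=resistance_index(triplet.c0, triplet.p0),
        rl=resilience_index(triplet.c0, triplet.p0, triplet.px),
        c0=triplet.c0,
        p0=triplet.p0,
        px=triplet.px,
    )


def rs_rl_profile(
    values: pd.Series,
    metadata: pd.DataFrame,
    area: str,
    variable_name: str = "",
) -> RsRlResult:
    """Compose group means into RS/RL for one per-sample variable in one area."""
    area_groups = set(metadata.loc[metadata["area"] == area, "group"])
    missing = [g for g in GROUPS if g not in area_groups]
    if missing:
        raise ValueError(f"area {area!r} is missing groups {missing}")
    c0 = group_mean(values, metadata, area, "reference")
    p0 = group_mean(values, metadata, area, "flooding")
    px = group_mean(values, metadata, area, "recovery")
    return rs_rl_from_triplet(
        DisturbanceTriplet(c0=c0, p0=p0, px=px, variable_name=variable_name, area=area)
    )


def taxon_rs_rl(
    composition: CompositionTable,
    metadata: pd.DataFrame,
    area: str,
    taxa: list[str],
) -> list[RsRlResult]:
    """RS/RL of each listed taxon's relative abundance in one area."""
    unknown = [t for t in taxa if t not in composition.proportions.index]
    if unknown:
        raise ValueError(f"taxa not present in table: {unknown}")
    return [
        rs_rl_profile(composition.proportions.loc[t], metadata, area, variable_name=t)
        for t in taxa
    ]


def results_frame(results: list[RsRlResult], ndigits: int | None = None) -> pd.DataFrame:
    """Tabulate results (area, variable, C0, P0, Px, RS, RL) for TSV output."""
    rows = []
    for r in results:
        rs, rl = (r.rs, r.rl) if ndigits is None else r.rounded(ndigits)
        rows.append(
            {
                "area": r.area,
                "variable": r.variable_name,
                "C0": r.c0,
                "P0": r.p0,
                "Px": r.px,
                "RS": rs,
                "RL": rl if not math.isnan(rl) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["area", "variable", "C0", "P0", "Px", "RS", "RL"])
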