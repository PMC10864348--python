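"""Projection onto current and future climates, and range-change accounting.

A fitted model is projected cell-wise onto any co-registered stack (with
training-range clamping, so novel climates cannot push features outside
[0, 1]); the logistic suitability map is binarized at a threshold τ*, and
two binary maps are compared by counting cells:

    loss%   = 100 · |C \\ F| / |C|
    gain%   = 100 · |F \\ C| / |C|
    change% = gain% − loss% = 100 · (|F| − |C|) / |C|

with C the currently suitable cells and F the future-suitable cells. Both
percentages share the *current* suitable area as denominator — the only
convention under which the net change equals gain minus loss row-wise.
Cell counts are the base quantity; multiply by the per-cell area (e.g.
~1 km² for 30 arc-second grids) for areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridAlignmentError, GridStack
from .maxent import MaxEntModel, predict_logistic

__all__ = [
    "ScenarioSet",
    "BinaryMap",
    "ChangeStats",
    "average_members",
    "project",
    "binarize",
    "range_change",
    "run_scenarios",
]


@dataclass
class ScenarioSet:
    """One (emission scenario, time horizon) cell of the forecast design.

    ``members`` holds one stack per climate-model realization (e.g. per
    GCM); a single pre-averaged stack is simply a one-member set.
    """

    label: str        # e.g. "RCP4.5"
    horizon: str      # e.g. "2050" (a 2041-2060 mean)
    members: list[GridStack] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("scenario needs at least one member stack")


@dataclass
class BinaryMap:
    """Boolean suitability grid plus the threshold and label that made it."""

    suitable: np.ndarray      # bool grid; False on invalid cells
    valid: np.ndarray         # bool grid of defined cells
    threshold: float
    label: str = ""

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


@dataclass
class ChangeStats:
    gain_pct: float
    loss_pct: float
    change_pct: float
    n_current: int
    n_gained: int
    n_lost: int


def average_members(scenario: ScenarioSet) -> GridStack:
    """Cell-wise arithmetic mean over member stacks (the GCM-ensemble mean).

    A cell is valid in the mean only where it is valid in every member;
    members must be co-registered with each other.
    """
    ref = scenario.members[0]
    for k, member in enumerate(scenario.members[1:], start=2):
        if (
            member.layer_names != ref.layer_names
            or member.shape != ref.shape
            or not member.transform.close_to(ref.transform)
        ):
            raise GridAlignmentError(
                f"scenario {scenario.label}/{scenario.horizon}: member {k} "
                "is not co-registered with member 1"
            )
    stacked = np.stack([m.values for m in scenario.members])  # (k, L, r, c)
    mean = stacked.mean(axis=0)  # NaN wherever any member is NaN
    return GridStack(
        layer_names=list(ref.layer_names),
        values=mean,
        transform=ref.transform,
        crs_label=ref.crs_label,
        nodata_value=ref.nodata_value,
    )


def project(model: MaxEntModel, stack: GridStack) -> np.ndarray:
    """Logistic suitability grid in [0, 1]; NaN on invalid cells."""
    missing = [l for l in model.spec.layers if l not in stack.layer_names]
    if missing:
        raise KeyError(f"stack lacks model layer(s): {missing}")
    mask = stack.valid_mask
    df = pd.DataFrame(
        {name: stack.layer(name)[mask] for name in model.spec.layers}
    )
    out = np.full(stack.shape, np.nan)
    out[mask] = predict_logistic(model, df)
    return out


def binarize(suitability: np.ndarray, threshold: float, label: str = "") -> BinaryMap:
    """Suitable iff suitability ≥ τ (boundary cells count as suitable)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    s = np.asarray(suitability, dtype=float)
    valid = np.isfinite(s)
    suitable = valid & (s >= threshold)
    return BinaryMap(suitable=suitable, valid=valid, threshold=threshold, label=label)


def range_change(current: BinaryMap, future: BinaryMap) -> ChangeStats:
    """Gain/loss/net-change percentages between two binary maps.

    Percentages are relative to the current suitable-cell count, so
    ``change_pct == gain_pct - loss_pct`` exactly. Cells valid in only one
    map are compared as unsuitable there.
    """
    if current.suitable.shape != future.suitable.shape:
        raise GridAlignmentError("current/future maps differ in shape")
    c = current.suitable
    f = future.suitable
    n_c = int(c.sum())
    if n_c == 0:
        raise ZeroDivisionError(
            "no currently suitable cells: gain/loss percentages are undefined"
        )
    n_lost = int((c & ~f).sum())
    n_gained = int((f & ~c).sum())
    gain_pct = 100.0 * n_gained / n_c
    loss_pct = 100.0 * n_lost / n_c
    return ChangeStats(
        gain_pct=gain_pct,
        loss_pct=loss_pct,
        change_pct=gain_pct - loss_pct,
        n_current=n_c,
        n_gained=n_gained,
        n_lost=n_lost,
    )


def run_scenarios(
    model: MaxEntModel,
    current: GridStack,
    scenarios: list[ScenarioSet],
    threshold: float,
    species: str | None = None,
) -> pd.DataFrame:
    """One gain/loss/change row per (scenario, horizon) vs the current map."""
    cur_map = binarize(project(model, current), threshold, label="current")
    rows = []
    for sc in scenarios:
        fut_stack = average_members(sc)
        fut_map = binarize(
            project(model, fut_stack), threshold, label=f"{sc.label}-{sc.horizon}"
        )
        st = range_change(cur_map, fut_map)
        row = {
            "scenario": sc.label,
            "horizon": sc.horizon,
            "gain_pct": st.gain_pct,
            "loss_pct": st.loss_pct,
            "change_pct": st.change_pct,
            "n_current": st.n_current,
            "n_gained": st.n_gained,
            "n_lost": st.n_lost,
        }
        if species is not None:
            row = {"species": species, **row}
        rows.append(row)
    return pd.DataFrame(rows)
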