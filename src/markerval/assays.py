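"""siRNA knockdown, viability/apoptosis and wound-healing quantification.

Percent-of-control summaries for plate-reader readouts (ATP
luminescence, caspase and dead-cell stains), knockdown efficiency from
normalized expression ratios, siRNA selection, and the three standard
scratch-wound kinetics metrics (wound width, wound confluence, relative
wound density).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KnockdownResult",
    "WoundSeries",
    "knockdown_efficiency",
    "percent_of_control",
    "wound_metrics",
    "best_sirna",
    "read_assay_table",
]

CONTROL_CONDITIONS = ("untreated", "scrambled", "mock", "allstar")


@dataclass(frozen=True)
class KnockdownResult:
    percent: float
    upregulated: bool  # treated expression above control


def knockdown_efficiency(treated: float, control: float) -> KnockdownResult:
    """Percent knockdown, 100*(1 - treated/control), from normalized expression.

    Negative values (treated above control) are reported, not clamped,
    and flagged as upregulation.
    """
    if control <= 0:
        raise ValueError("control expression must be positive")
    ratio = treated / control
    return KnockdownResult(percent=100.0 * (1.0 - ratio), upregulated=ratio > 1.0)


def percent_of_control(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
    control_condition: str = "untreated",
) -> pd.Series:
    """Condition-level percent of the control mean.

    Accepts a mapping condition -> replicate readouts or a long
    DataFrame with ``condition`` and ``readout`` columns.  The control
    condition maps to exactly 100.0.
    """
    if isinstance(values, pd.DataFrame):
        grouped = {c: sub["readout"].to_numpy() for c, sub in values.groupby("condition")}
    else:
        grouped = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    if control_condition not in grouped:
        raise ValueError(f"control condition {control_condition!r} absent")
    control_mean = float(np.mean(grouped[control_condition]))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    out = {c: 100.0 * float(np.mean(v)) / control_mean for c, v in grouped.items()}
    out[control_condition] = 100.0
    return pd.Series(out, name="percent_of_control").sort_index()


@dataclass
class WoundSeries:
    """Ordered binary confluence masks with the fixed initial wound region."""

    frames: list[np.ndarray]
    wound_region: np.ndarray
    timestamps: Sequence[float] | None = None

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("frames must share dimensions")
        if self.frames and self.frames[0].shape != self.wound_region.shape:
            raise ValueError("wound region must match frame dimensions")
        if not self.wound_region.any():
            raise ValueError("wound region is empty")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps, dtype=float)
            if len(ts) != len(self.frames):
                raise ValueError("one timestamp per frame required")
            if (np.diff(ts) <= 0).any():
                raise ValueError("timestamps must be strictly increasing")


def wound_metrics(series: WoundSeries, pixel_scale: float = 1.0) -> pd.DataFrame:
    """Per-frame wound width, wound confluence and relative wound density.

    wound_width: mean per-row extent of unoccupied pixels inside the
    wound region (times ``pixel_scale``).  wound_confluence: percent of
    the wound region occupied by cells.  RWD(t) = 100 * (w(t) - w(0)) /
    (c(t) - w(0)), comparing cell density w inside the wound with the
    density c outside it, clamped to [0, 100]; RWD is 0 at wounding and
    100 once the wound matches the surrounding monolayer.
    """
    wound = series.wound_region
    outside = ~wound
    if not outside.any():
        raise ValueError("no region outside the wound")
    w0 = float(series.frames[0][wound].mean())

    rows = []
    for t, frame in enumerate(series.frames):
        gap = (~frame) & wound
        width = float(gap.sum(axis=1).mean()) * pixel_scale
        w_t = float(frame[wound].mean())
        c_t = float(frame[outside].mean())
        confluence = 100.0 * w_t
        denom = c_t - w0
        if denom == 0:
            raise ZeroDivisionError(
                f"degenerate frame {t}: outside density equals initial wound density"
            )
        rwd = float(np.clip(100.0 * (w_t - w0) / denom, 0.0, 100.0))
        ts = series.timestamps[t] if series.timestamps is not None else float(t)
        rows.append((t, ts, width, confluence, rwd))
    return pd.DataFrame(
        rows,
        columns=["frame", "time", "wound_width", "wound_confluence", "relative_wound_density"],
    )


def best_sirna(efficiencies: Mapping[str, float]) -> str:
    """The siRNA with the highest knockdown; ties break on the smaller id."""
    if not efficiencies:
        raise ValueError("no efficiencies supplied")
    return min(efficiencies, key=lambda k: (-efficiencies[k], k))


def read_assay_table(path) -> pd.DataFrame:
    """Long assay TSV: condition, replicate, readout, readout_kind."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "readout"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    if (df["readout"] < 0).any():
        raise ValueError("readouts must be non-negative")
    return df
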