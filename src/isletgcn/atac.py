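"""Chromatin-accessibility signal-intensity (SI) summaries and categorization.

Works on a precomputed region x cell signal-intensity matrix (whatever the
upstream fragment pipeline produced, treated as opaque non-negative reals)
with per-cell group labels.  The high-accessibility rule is relative: a
query-group cell (e.g. an alpha cell at the Ins1 locus) is "high" when its
SI strictly exceeds a configured fraction of the reference group's (beta)
maximum SI at that region.  Zero-SI cells may be excluded from ranked
summaries on a per-region basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import _as_index


@dataclass
class SignalMatrix:
    """Region x cell accessibility signal with cell-group labels."""

    region_ids: pd.Index
    cell_ids: pd.Index
    values: np.ndarray  # regions x cells, non-negative
    cell_groups: pd.Series  # cell id -> group label

    def __post_init__(self) -> None:
        self.region_ids = _as_index(self.region_ids, "region")
        self.cell_ids = _as_index(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.region_ids), len(self.cell_ids)):
            raise ValueError("signal shape does not match region/cell ids")
        if self.values.size and self.values.min() < 0:
            raise ValueError("signal intensities must be non-negative")
        missing = self.cell_ids.difference(self.cell_groups.index)
        if len(missing):
            raise ValueError(f"cells without group label: {list(missing[:5])}")
        self.cell_groups = self.cell_groups.loc[self.cell_ids]

    def region_values(self, region: str, group: str | None = None) -> pd.Series:
        if region not in self.region_ids:
            raise KeyError(f"unknown region {region!r}")
        row = pd.Series(
            self.values[self.region_ids.get_loc(region), :], index=self.cell_ids
        )
        if group is not None:
            cells = self.cell_groups.index[self.cell_groups == group]
            if len(cells) == 0:
                raise KeyError(f"no cells in group {group!r}")
            row = row.loc[cells]
        return row


@dataclass
class AccessibilityParams:
    """Per-region relative thresholds and zero-SI conventions.

    Defaults encode the insulin-locus rule (more than 45% / 47% of the beta
    maximum at Ins1 / Ins2) and the convention that zero-SI cells are
    excluded from ranked summaries for Arx, Mnx1 and Gcg but retained for
    Ins1 and Ins2.
    """

    fraction_of_reference_max: dict[str, float] = field(
        default_factory=lambda: {"Ins1": 0.45, "Ins2": 0.47}
    )
    exclude_zero_si: dict[str, bool] = field(
        default_factory=lambda: {
            "Arx": True, "Mnx1": True, "Gcg": True, "Ins1": False, "Ins2": False,
        }
    )

    def threshold_fraction(self, region: str) -> float:
        try:
            f = self.fraction_of_reference_max[region]
        except KeyError:
            raise KeyError(f"no threshold fraction configured for {region!r}") from None
        if not 0.0 < f < 1.0:
            raise ValueError(f"threshold fraction for {region} must be in (0, 1)")
        return f


def region_signal_summary(
    signal: SignalMatrix,
    region: str,
    group: str,
    exclude_zero: bool | None = None,
    params: AccessibilityParams | None = None,
) -> tuple[pd.Series, float]:
    """Cells of ``group`` ranked by descending SI at ``region``, plus mean SI."""
    if exclude_zero is None:
        params = params or AccessibilityParams()
        exclude_zero = params.exclude_zero_si.get(region, False)
    si = signal.region_values(region, group)
    if exclude_zero:
        si = si[si > 0]
    if si.empty:
        raise ValueError(
            f"no cells retained for region {region!r}, group {group!r}"
        )
    ranked = si.sort_values(ascending=False, kind="stable")
    return ranked, float(ranked.mean())


def call_high_accessibility(
    signal: SignalMatrix,
    region: str,
    query_group: str,
    reference_group: str,
    params: AccessibilityParams | None = None,
) -> tuple[pd.Series, float]:
    """Flag query cells whose SI strictly exceeds fraction x reference max.

    Returns per-query-cell boolean flags and the fraction flagged high.
    """
    params = params or AccessibilityParams()
    frac = params.threshold_fraction(region)
    ref = signal.region_values(region, reference_group)
    ref_max = float(ref.max())
    if ref_max == 0:
        raise ValueError(
            f"reference group {reference_group!r} has zero maximal SI at {region!r}"
        )
    query = signal.region_values(region, query_group)
    flags = query > frac * ref_max
    flags.name = "high_accessibility"
    return flags, float(flags.mean())
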